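"""High-level feasibility analysis: TBR/CNR vs concentration ratio.

Drives the forward model over a sweep of synovium:background concentration
ratios at fixed geometry and optics, converts the resulting TBRs into a CNR
curve under the proportional-noise model, and interpolates the minimum
ratio required for detection at a given confidence.  The excitation field
is solved once per geometry/optics and reused across the sweep (the
excitation pass does not depend on dye concentration in the linear regime).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from handnir.detection import (
    BackgroundNoiseModel,
    RoiSpec,
    build_cnr_curve,
    compute_tbr,
    make_slab_roi,
    required_concentration_ratio,
    z_threshold,
)
from handnir.diffusion import SolverSettings
from handnir.geometry import (
    ConcentrationMap,
    FluorophoreSpec,
    OpticalProperties,
    TissueDomain,
    assign_concentrations,
)
from handnir.imaging import SurfaceImage, simulate_epifluorescence


@dataclass
class FeasibilityResult:
    """Sweep output: per-ratio TBR/CNR table and the interpolated required ratio."""

    table: pd.DataFrame  # columns: ratio, tbr, cnr
    required_ratio: float
    threshold: float
    confidence: float
    cv: float


def tbr_ratio_sweep(
    domain: TissueDomain,
    props_ex: OpticalProperties,
    props_em: OpticalProperties,
    dye: FluorophoreSpec,
    ratios,
    background_conc: float = 10.0,
    roi: RoiSpec | None = None,
    settings: SolverSettings | None = None,
    power: float = 1.0,
    method: str = "superposition",
) -> pd.DataFrame:
    """Simulate the surface image at each concentration ratio and tabulate TBR.

    The forward model is linear in the concentration map, so the default
    ``superposition`` method decomposes every sweep point into two basis
    solves — a uniform background at the target's concentration held equal
    to the background (ratio 1), and a synovium-only excess — and forms
    ``image(r) = image_bg + (r - 1) * image_syn`` exactly.  ``direct`` runs
    the full two-pass simulation per ratio instead (same result, used for
    cross-checking).
    """
    roi = roi or make_slab_roi(domain)
    settings = settings or SolverSettings()
    rows = []
    if method == "superposition":
        image_bg, u_x, _ = simulate_epifluorescence(
            domain,
            props_ex,
            props_em,
            dye,
            ConcentrationMap(background_conc, background_conc),
            power=power,
            settings=settings,
            full_output=True,
        )
        image_syn = simulate_epifluorescence(
            domain,
            props_ex,
            props_em,
            dye,
            ConcentrationMap(0.0, background_conc),
            power=power,
            settings=settings,
            u_x=u_x,
        )
        for ratio in ratios:
            pixels = image_bg.pixels + (float(ratio) - 1.0) * image_syn.pixels
            image = SurfaceImage(pixels=pixels, pixel_size=image_bg.pixel_size)
            rows.append({"ratio": float(ratio), "tbr": compute_tbr(image, roi)})
    elif method == "direct":
        u_x = None
        for ratio in ratios:
            conc: ConcentrationMap = assign_concentrations(
                domain, background_conc, float(ratio)
            )
            image, u_x, _ = simulate_epifluorescence(
                domain,
                props_ex,
                props_em,
                dye,
                conc,
                power=power,
                settings=settings,
                u_x=u_x,
                full_output=True,
            )
            rows.append({"ratio": float(ratio), "tbr": compute_tbr(image, roi)})
    else:
        raise ValueError("method must be 'superposition' or 'direct'")
    return pd.DataFrame(rows)


def required_ratio_analysis(
    domain: TissueDomain,
    props_ex: OpticalProperties,
    props_em: OpticalProperties,
    dye: FluorophoreSpec,
    ratios=tuple(range(1, 11)),
    background_conc: float = 10.0,
    cv: float = 0.64,
    confidence: float = 0.95,
    roi: RoiSpec | None = None,
    settings: SolverSettings | None = None,
) -> FeasibilityResult:
    """Full detectability analysis: sweep ratios, build the CNR curve, interpolate.

    Returns the minimum synovium:background concentration ratio whose CNR
    reaches the one-sided z-threshold at ``confidence`` under a background
    coefficient of variation ``cv``.
    """
    noise = BackgroundNoiseModel(cv=cv)
    table = tbr_ratio_sweep(
        domain,
        props_ex,
        props_em,
        dye,
        ratios,
        background_conc=background_conc,
        roi=roi,
        settings=settings,
    )
    table["cnr"] = (table["tbr"] - 1.0) / cv
    curve = build_cnr_curve(table["ratio"], table["tbr"], noise)
    thr = z_threshold(confidence)
    req = required_concentration_ratio(curve, thr)
    return FeasibilityResult(
        table=table,
        required_ratio=req,
        threshold=thr,
        confidence=confidence,
        cv=cv,
    )


def swelling_tbr(
    base_domain_builder,
    swelling_percents,
    ratio: float,
    props_ex: OpticalProperties,
    props_em: OpticalProperties,
    dye: FluorophoreSpec,
    background_conc: float = 10.0,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """TBR across swelling variants at a fixed concentration ratio.

    ``base_domain_builder(swelling_percent)`` must return a fresh domain for
    each variant (swelling changes the synovium geometry, so each variant
    needs its own excitation solve and ROI).
    """
    rows = []
    for sw in swelling_percents:
        domain = base_domain_builder(float(sw))
        roi = make_slab_roi(domain)
        table = tbr_ratio_sweep(
            domain,
            props_ex,
            props_em,
            dye,
            [ratio],
            background_conc=background_conc,
            roi=roi,
            settings=settings,
        )
        rows.append({"swelling_percent": float(sw), "tbr": table["tbr"].iloc[0]})
    return pd.DataFrame(rows)
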