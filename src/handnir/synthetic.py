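"""Synthetic inputs: optical-phantom presets, noisy backgrounds, plasma curves.

Everything the pipeline consumes can be generated here, deterministically
under a fixed seed, with no external data:

* phantom configurations emulating an agarose / 1% Intralipid / 50 ppm
  India-ink hand phantom with 10 nM background dye and a 50 or 100 nM
  synovial cavity ~2.3-2.5 mm deep;
* background-intensity replicates with a prescribed coefficient of
  variation (default 64%);
* one-compartment (Bateman) plasma concentration-time profiles on the
  8-point blood-draw schedule used for subcutaneous dosing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from handnir.geometry import (
    ConcentrationMap,
    FluorophoreSpec,
    OpticalProperties,
    TissueDomain,
    assign_concentrations,
    build_hand_slab,
    embed_synovial_shell,
)
from handnir.pk import ConcentrationTimeSeries

# blood-draw schedules, minutes post-administration
SC_SCHEDULE_MIN = (5.0, 15.0, 30.0, 60.0, 120.0, 240.0, 360.0, 1440.0)
IV_SCHEDULE_MIN = (1.0, 3.0, 5.0, 15.0, 30.0, 60.0, 180.0, 360.0, 1440.0)

# phantom optics: 1% Intralipid scattering, 50 ppm India-ink absorption,
# literature-typical values at NIR wavelengths
PHANTOM_MU_S_PRIME = 1.0  # 1/mm
PHANTOM_MU_A = 0.005  # 1/mm

# IRDye800CW-like photophysics; absolute values only scale the image
DEFAULT_DYE = FluorophoreSpec(quantum_yield=0.12, molar_absorption_ex=5.5e-5)


@dataclass(frozen=True)
class PhantomConfig:
    """Fully specified optical-phantom run: geometry, optics, concentrations."""

    slab_x_mm: float = 80.0
    slab_y_mm: float = 60.0
    slab_thickness_mm: float = 25.0
    spacing_mm: float = 0.5
    joint_depth_mm: float = 2.5
    shell_extent_sagittal_mm: float = 20.0
    shell_extent_transverse_mm: float = 12.0
    shell_thickness_mm: float = 2.5
    swelling_percent: float = 0.0
    mu_a: float = PHANTOM_MU_A
    mu_s_prime: float = PHANTOM_MU_S_PRIME
    cr: float = 2.95
    background_conc_nM: float = 10.0
    joint_conc_nM: float = 100.0
    quantum_yield: float = DEFAULT_DYE.quantum_yield
    molar_absorption_ex: float = DEFAULT_DYE.molar_absorption_ex

    @property
    def ratio(self) -> float:
        return self.joint_conc_nM / self.background_conc_nM

    def build(
        self,
    ) -> tuple[TissueDomain, OpticalProperties, FluorophoreSpec, ConcentrationMap]:
        """Materialize the domain, optics, dye and concentration map."""
        domain = build_hand_slab(
            self.slab_x_mm, self.slab_y_mm, self.slab_thickness_mm, self.spacing_mm
        )
        domain = embed_synovial_shell(
            domain,
            center_depth=self.joint_depth_mm,
            lateral_extent=(self.shell_extent_sagittal_mm, self.shell_extent_transverse_mm),
            thickness=self.shell_thickness_mm,
            swelling_percent=self.swelling_percent,
        )
        props = OpticalProperties(
            mu_a=self.mu_a, mu_s_prime=self.mu_s_prime, cr=self.cr
        )
        dye = FluorophoreSpec(
            quantum_yield=self.quantum_yield,
            molar_absorption_ex=self.molar_absorption_ex,
        )
        conc = assign_concentrations(domain, self.background_conc_nM, self.ratio)
        return domain, props, dye, conc


def make_phantom_preset(ratio: float, depth: float = 2.5) -> PhantomConfig:
    """Phantom preset at a 5:1 or 10:1 cavity:background ratio.

    ``ratio`` must be 5 or 10 (the physical phantom recipes: 50 or 100 nM
    cavity over 10 nM background); ``depth`` 2.3 mm (simulation placement)
    or 2.5 mm (physical phantom placement).  Custom values go through
    ``PhantomConfig`` directly.
    """
    if ratio not in (5, 10):
        raise ValueError(f"preset ratio must be 5 or 10, got {ratio}")
    if depth not in (2.3, 2.5):
        raise ValueError(f"preset depth must be 2.3 or 2.5 mm, got {depth}")
    return PhantomConfig(
        joint_depth_mm=depth,
        background_conc_nM=10.0,
        joint_conc_nM=10.0 * ratio,
    )


def gen_background_replicates(
    mean: float,
    cv: float = 0.64,
    n: int = 10_000,
    seed: int = 0,
    truncate: bool = True,
) -> np.ndarray:
    """Normal background-signal replicates with sd = cv * mean.

    Negative draws are clipped to zero when ``truncate`` is set (physical
    signals are nonnegative); pass ``truncate=False`` to audit the raw
    sample moments against the requested CV.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not cv > 0:
        raise ValueError("cv must be > 0")
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=mean, scale=cv * mean, size=n)
    if truncate:
        draws = np.clip(draws, 0.0, None)
    return draws


def gen_pk_profile(
    F: float,
    ka: float,
    ke: float,
    dose: float,
    Vd: float,
    times=SC_SCHEDULE_MIN,
    noise_cv: float = 0.0,
    seed: int = 0,
    route: str = "SC",
) -> ConcentrationTimeSeries:
    """Synthetic plasma profile: Bateman for extravascular routes, exponential for IV.

    Extravascular (SC/PO):
        C(t) = F * dose / Vd * ka / (ka - ke) * (exp(-ke t) - exp(-ka t))
    IV bolus:
        C(t) = dose / Vd * exp(-ke t)

    Multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` (mean-one) is applied when nonzero.  ``ka == ke`` is
    rejected (degenerate Bateman form).

    Parameters are first-order absorption/elimination rate constants in
    1/min, ``dose`` in nmol, ``Vd`` the distribution volume (concentration
    comes out in dose/Vd units, nM for nmol/L... consistent units are the
    caller's choice).
    """
    if not (ka > 0 and ke > 0):
        raise ValueError("ka and ke must be > 0")
    if ka == ke:
        raise ValueError("ka == ke: degenerate Bateman profile (not supported)")
    if not 0 < F <= 1:
        raise ValueError("F must be in (0, 1]")
    t = np.asarray(times, dtype=float)

    if route == "IV":
        conc = dose / Vd * np.exp(-ke * t)
    elif route in ("SC", "PO"):
        conc = (
            F * dose / Vd * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
        )
    else:
        raise ValueError("route must be IV, SC or PO")

    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=t.shape)
        conc = conc * noise
    conc = np.clip(conc, 0.0, None)
    return ConcentrationTimeSeries(times=t, concentrations=conc, dose=dose, route=route)
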