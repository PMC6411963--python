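"""Two-pass epifluorescence forward model and surface-image extraction.

Excitation light from the buried planar source is propagated by one
diffusion solve; fluorophores then re-emit in proportion to quantum yield,
molar absorption and local concentration, and that emission source drives a
second diffusion solve.  The detected image is the emission fluence in the
first tissue layer beneath the top surface — the same abstraction as planar
reflectance (IVIS-style) imaging, with no lens or camera model.  Cascaded
re-absorption of emission light is neglected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from handnir.diffusion import (
    EMISSION,
    EXCITATION,
    FluenceField,
    SolverSettings,
    solve_diffusion,
)
from handnir.geometry import (
    ConcentrationMap,
    FluorophoreSpec,
    OpticalProperties,
    TissueDomain,
    make_planar_source,
)


@dataclass
class SurfaceImage:
    """2D map of emission fluence (power/mm^2) over the top surface."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def emission_source_term(
    u_x: FluenceField,
    conc: ConcentrationMap,
    dye: FluorophoreSpec,
    domain: TissueDomain,
) -> np.ndarray:
    """Fluorescence source density: quantum_yield * mu_fx * u_x * [C].

    Every voxel with dye emits — background tissue included, which is how
    autofluorescence (the equivalent-dye background) enters the image.

    Raises
    ------
    ValueError
        If the excitation field and domain grids disagree, or ``u_x`` is not
        an excitation-band field.
    """
    if u_x.wavelength_band != EXCITATION:
        raise ValueError("emission source requires an EXCITATION fluence field")
    if u_x.values.shape != domain.shape:
        raise ValueError("fluence grid does not match domain grid")
    c_vol = conc.volume(domain)
    return dye.quantum_yield * dye.molar_absorption_ex * u_x.values * c_vol


def extract_surface_image(u_em: FluenceField, domain: TissueDomain) -> SurfaceImage:
    """Detected image: fluence in the first tissue layer beneath the top surface."""
    if u_em.wavelength_band != EMISSION:
        raise ValueError("surface image is extracted from an EMISSION field")
    if u_em.values.shape != domain.shape:
        raise ValueError("fluence grid does not match domain grid")
    iz = domain._top_tissue_index
    pixels = u_em.values[iz, 1:-1, 1:-1].copy()
    return SurfaceImage(pixels=pixels, pixel_size=domain.spacing)


def simulate_epifluorescence(
    domain: TissueDomain,
    props_ex: OpticalProperties,
    props_em: OpticalProperties,
    dye: FluorophoreSpec,
    conc: ConcentrationMap,
    power: float = 1.0,
    settings: SolverSettings | None = None,
    u_x: FluenceField | None = None,
    full_output: bool = False,
):
    """Run the full excitation -> emission chain and return the surface image.

    Chains ``make_planar_source`` -> excitation solve -> fluorescence
    source coupling -> emission solve -> surface extraction.  Pass a cached
    ``u_x`` to reuse an excitation field when sweeping concentrations at
    fixed geometry and optics (the excitation pass does not see the dye in
    the default linear regime).

    With ``full_output=True`` returns ``(image, u_x, u_em)``.
    """
    settings = settings or SolverSettings()
    if u_x is None:
        src_x = make_planar_source(domain, props_ex, power=power)
        u_x = solve_diffusion(
            domain, props_ex, src_x, settings, wavelength_band=EXCITATION
        )
    src_m = emission_source_term(u_x, conc, dye, domain)
    u_em = solve_diffusion(domain, props_em, src_m, settings, wavelength_band=EMISSION)
    image = extract_surface_image(u_em, domain)
    if full_output:
        return image, u_x, u_em
    return image
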