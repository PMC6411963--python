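"""Voxelized tissue geometry for diffuse-optics simulation.

The anatomy is deliberately parametric: a rectangular tissue slab stands in
for the hand, and an ellipsoidal-cap shell buried at a prescribed depth
stands in for the synovial membrane around a metacarpophalangeal joint.
Diffuse epifluorescence contrast at several scattering lengths of depth is
governed almost entirely by the depth and thickness of the fluorescent
target, not by its fine contours, so a parametric shell with the correct
shallowest depth and thickness reproduces the imaging physics.

Conventions
-----------
* Axis 0 is depth (z), increasing away from the imaging surface; axes 1 and
  2 are lateral.  All lengths are millimetres; voxels are isotropic cubes.
* Label volumes carry a one-voxel ``OUTSIDE`` border so that every tissue
  face on the domain boundary is an explicit tissue/air interface.
* Depth is measured from the top tissue surface plane to voxel centers:
  the first tissue layer has center depth ``spacing / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# voxel labels
OUTSIDE = 0
TISSUE = 1
SYNOVIUM = 2


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a tissue at one wavelength band.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, 1/mm.
    mu_s_prime : float
        Reduced scattering coefficient, 1/mm.  Its inverse is the transport
        scattering length at which a collimated beam is modeled as an
        isotropic source.
    refractive_index : float
        Tissue refractive index (air assumed 1.0).
    cr : float
        Internal-reflection parameter of the Robin boundary condition
        ``-n . (-D grad u) = u / (2 Cr)``; ~2.95 for a tissue/air mismatch
        with n ~ 1.4.
    """

    mu_a: float
    mu_s_prime: float
    refractive_index: float = 1.4
    cr: float = 2.95

    def __post_init__(self) -> None:
        if not self.mu_a > 0:
            raise ValueError(f"mu_a must be > 0, got {self.mu_a}")
        if not self.mu_s_prime > 0:
            raise ValueError(f"mu_s_prime must be > 0, got {self.mu_s_prime}")
        if not self.cr > 0:
            raise ValueError(f"cr must be > 0, got {self.cr}")

    @property
    def diffusion_coefficient(self) -> float:
        """Diffusion coefficient D = 1 / (3 (mu_a + mu_s')) in mm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    @property
    def scattering_length(self) -> float:
        """Transport scattering length 1/mu_s' in mm."""
        return 1.0 / self.mu_s_prime


@dataclass(frozen=True)
class FluorophoreSpec:
    """Photophysics of the imaging agent.

    ``molar_absorption_ex`` is the per-concentration absorption coefficient
    at the excitation wavelength, in 1/(mm nM); ``quantum_yield`` the
    fraction of absorbed excitation photons re-emitted in the emission band.
    """

    quantum_yield: float
    molar_absorption_ex: float

    def __post_init__(self) -> None:
        if not 0 < self.quantum_yield <= 1:
            raise ValueError(
                f"quantum_yield must be in (0, 1], got {self.quantum_yield}"
            )
        if not self.molar_absorption_ex > 0:
            raise ValueError(
                f"molar_absorption_ex must be > 0, got {self.molar_absorption_ex}"
            )


@dataclass
class TissueDomain:
    """Labeled voxel grid: OUTSIDE / TISSUE / SYNOVIUM plus grid metadata.

    ``labels`` has shape ``(nz + 2, nx + 2, ny + 2)`` for an ``nz x nx x ny``
    tissue box — the extra layer is the OUTSIDE border.  ``top_surface_axis``
    is always 0 in this package (the imaging surface faces low z).
    """

    labels: np.ndarray
    spacing: float
    top_surface_axis: int = 0
    source_depth: float | None = None
    _top_tissue_index: int = field(default=1, repr=False)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def depth_of_layer(self, iz: int) -> float:
        """Depth (mm) of voxel centers in grid layer ``iz`` below the top surface."""
        return (iz - self._top_tissue_index + 0.5) * self.spacing

    def layer_at_depth(self, depth: float) -> int:
        """Grid index of the voxel layer containing ``depth`` below the surface.

        A depth falling exactly on a layer boundary maps to the deeper layer.
        """
        return self._top_tissue_index + int(np.floor(depth / self.spacing + 1e-12))

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels == TISSUE

    @property
    def synovium_mask(self) -> np.ndarray:
        return self.labels == SYNOVIUM

    @property
    def interior_mask(self) -> np.ndarray:
        """Voxels belonging to the body (tissue or synovium)."""
        return self.labels != OUTSIDE

    def copy(self) -> "TissueDomain":
        return TissueDomain(
            labels=self.labels.copy(),
            spacing=self.spacing,
            top_surface_axis=self.top_surface_axis,
            source_depth=self.source_depth,
        )


@dataclass(frozen=True)
class ConcentrationMap:
    """Uniform fluorophore concentrations per tissue compartment, in nM.

    ``background_conc`` applies to all TISSUE voxels and folds tissue
    autofluorescence in as an equivalent-dye concentration;
    ``synovium_conc`` applies to SYNOVIUM voxels.
    """

    background_conc: float
    synovium_conc: float

    def __post_init__(self) -> None:
        if self.background_conc < 0 or self.synovium_conc < 0:
            raise ValueError("concentrations must be >= 0")

    @property
    def ratio(self) -> float:
        if self.background_conc <= 0:
            raise ValueError("ratio undefined for background_conc == 0")
        return self.synovium_conc / self.background_conc

    def volume(self, domain: TissueDomain) -> np.ndarray:
        """Render the per-voxel concentration array on the domain grid."""
        conc = np.zeros(domain.shape, dtype=float)
        conc[domain.tissue_mask] = self.background_conc
        conc[domain.synovium_mask] = self.synovium_conc
        return conc


def build_hand_slab(
    lateral_x: float, lateral_y: float, thickness: float, spacing: float
) -> TissueDomain:
    """Build a rectangular tissue slab surrounded by one OUTSIDE layer.

    Parameters are the physical slab dimensions (mm); the grid resolves them
    with isotropic voxels of size ``spacing``.  The top imaging surface is
    the low-z face.

    Raises
    ------
    ValueError
        If dimensions are not positive, if ``spacing`` does not divide each
        dimension into at least 4 voxels, or if ``spacing > thickness / 4``
        (an under-resolved depth axis).
    """
    dims = {"lateral_x": lateral_x, "lateral_y": lateral_y, "thickness": thickness}
    for name, value in dims.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")
    if not spacing > 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    if spacing > thickness / 4:
        raise ValueError(
            f"spacing {spacing} mm under-resolves thickness {thickness} mm "
            "(need >= 4 voxels across the slab)"
        )

    counts = {}
    for name, value in dims.items():
        n = value / spacing
        n_round = round(n)
        if n_round < 4 or abs(n - n_round) > 1e-9 * max(1.0, n):
            raise ValueError(
                f"spacing {spacing} must divide {name}={value} into >= 4 voxels"
            )
        counts[name] = n_round

    nz, nx, ny = counts["thickness"], counts["lateral_x"], counts["lateral_y"]
    labels = np.full((nz + 2, nx + 2, ny + 2), OUTSIDE, dtype=np.uint8)
    labels[1:-1, 1:-1, 1:-1] = TISSUE
    return TissueDomain(labels=labels, spacing=spacing)


def embed_synovial_shell(
    domain: TissueDomain,
    center_depth: float,
    lateral_extent: float | tuple[float, float] = (20.0, 12.0),
    thickness: float = 2.5,
    swelling_percent: float = 0.0,
    dome_sagitta: float = 2.0,
) -> TissueDomain:
    """Embed the synovial space: a curved uniform-thickness pocket at ``center_depth``.

    The target is the fluid-distended synovial pocket draped over the joint:
    an ellipsoidal-cap sheet, convex toward the imaging surface, of uniform
    vertical thickness ``thickness`` over an elliptical footprint.  The
    crown (shallowest point) sits at ``center_depth``; the cap surface
    falls away by ``dome_sagitta`` mm toward the footprint rim, following
    the curvature of the metacarpal head.  ``lateral_extent`` gives the
    footprint; a scalar makes it circular, a pair sets the sagittal (along
    the finger, where the cavity's recesses extend) and transverse extents
    separately.  ``swelling_percent`` scales the thickness by
    ``1 + swelling/100`` — effusion deepens the pocket but leaves its roof
    depth unchanged — and the pocket volume is exactly linear in that
    thickness (footprint area times thickness).

    Returns a new domain; the input is not modified.

    Raises
    ------
    ValueError
        If the scaled thickness is below one voxel (empty pocket), or if
        any pocket voxel would fall outside TISSUE or touch the OUTSIDE
        border.
    """
    if swelling_percent < 0:
        raise ValueError("swelling_percent must be >= 0")
    if center_depth <= 0:
        raise ValueError("center_depth must be > 0")
    if dome_sagitta < 0:
        raise ValueError("dome_sagitta must be >= 0")
    t_eff = thickness * (1.0 + swelling_percent / 100.0)
    if t_eff < domain.spacing:
        raise ValueError(
            f"pocket thickness {t_eff} mm is below one voxel "
            f"({domain.spacing} mm): empty shell"
        )

    h = domain.spacing
    nz, nx, ny = domain.shape
    if np.isscalar(lateral_extent):
        ax = ay = float(lateral_extent) / 2.0
    else:
        ax, ay = (float(e) / 2.0 for e in lateral_extent)
    if ax <= 0 or ay <= 0:
        raise ValueError("lateral_extent must be > 0")

    # voxel-center coordinates; lateral center of the slab
    z = (np.arange(nz) - domain._top_tissue_index + 0.5) * h  # depth, mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * h
    y = (np.arange(ny) - (ny - 1) / 2.0) * h
    zz, xx, yy = np.meshgrid(z, x, y, indexing="ij", sparse=True)

    # snap the pocket crown to the nearest voxel-center depth so the
    # shallowest SYNOVIUM voxel center sits within spacing/2 of center_depth
    d0 = (np.round(center_depth / h - 0.5) + 0.5) * h
    lat2 = (xx / ax) ** 2 + (yy / ay) ** 2
    footprint = lat2 <= 1.0 + 1e-9
    # dome profile: crown at d0 over the nearest-to-axis voxel centers (no
    # center need lie exactly on the axis), falling away toward the rim
    lat2_min = float(lat2.min())
    root = np.sqrt(np.clip(1.0 - lat2, 0.0, None))
    z_top = d0 + dome_sagitta * (np.sqrt(1.0 - lat2_min) - root)
    tol = 1e-9
    shell = footprint & (zz >= z_top - tol) & (zz < z_top + t_eff - tol)

    if not shell.any():
        raise ValueError("shell discretizes to zero voxels")
    if (domain.labels[shell] != TISSUE).any():
        raise ValueError("synovial shell escapes the tissue box")

    # reject shells adjacent to OUTSIDE (must be fully buried)
    outside = domain.labels == OUTSIDE
    for axis in range(3):
        for shift in (-1, 1):
            if (shell & np.roll(outside, shift, axis=axis)).any():
                raise ValueError("synovial shell touches the outer surface")

    out = domain.copy()
    out.labels[shell] = SYNOVIUM
    return out


def make_planar_source(
    domain: TissueDomain, props: OpticalProperties, power: float = 1.0
) -> np.ndarray:
    """Buried planar excitation source as a volumetric source-density field.

    Collimated surface illumination is modeled as an isotropic source one
    transport scattering length (``1/mu_s'``) below the top surface: the
    total emitted ``power`` (arbitrary units) is spread uniformly over the
    body voxels of the layer containing that depth.  Returns the source
    density (power per mm^3) on the full grid.

    Raises
    ------
    ValueError
        If the scattering length does not fit inside the slab, or if the
        source layer would sit at or below the top of the synovium.
    """
    if power < 0:
        raise ValueError("power must be >= 0")
    depth = props.scattering_length
    nz = domain.shape[0]
    max_depth = (nz - 2) * domain.spacing
    if depth >= max_depth:
        raise ValueError(
            f"scattering length {depth} mm does not fit in slab of "
            f"thickness {max_depth} mm"
        )
    iz = domain.layer_at_depth(depth)

    syn = domain.synovium_mask
    if syn.any():
        iz_syn_top = int(np.argwhere(syn.any(axis=(1, 2))).min())
        if iz >= iz_syn_top:
            raise ValueError(
                "source layer at or below the synovium top: geometry inversion"
            )

    source = np.zeros(domain.shape, dtype=float)
    layer = domain.interior_mask[iz]
    n_vox = int(layer.sum())
    if n_vox == 0:
        raise ValueError("source layer contains no tissue voxels")
    if power > 0:
        source[iz][layer] = power / (n_vox * domain.voxel_volume)
    domain.source_depth = depth
    return source


def assign_concentrations(
    domain: TissueDomain, background_conc: float, ratio: float
) -> ConcentrationMap:
    """Concentration map with ``synovium = ratio x background``.

    ``background_conc`` (nM) fills every TISSUE voxel — it bundles
    non-specific probe accumulation and autofluorescence as an equivalent
    dye concentration; the synovium carries ``ratio`` times that level.
    """
    if not background_conc > 0:
        raise ValueError("background_conc must be > 0")
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    return ConcentrationMap(
        background_conc=background_conc, synovium_conc=ratio * background_conc
    )
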