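"""Config parsing and on-disk formats.

Runs are described by a YAML/JSON document with ``geometry:``, ``optics:``,
``fluorophore:`` and ``concentrations:`` blocks; label volumes and fluence
fields round-trip through HDF5 with grid metadata, and surface images are
written as 32-bit float TIFF or CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from handnir.diffusion import FluenceField
from handnir.geometry import (
    FluorophoreSpec,
    OpticalProperties,
    TissueDomain,
    assign_concentrations,
    build_hand_slab,
    embed_synovial_shell,
)
from handnir.imaging import SurfaceImage
from handnir.synthetic import DEFAULT_DYE


DEFAULT_CONFIG = {
    "geometry": {
        "slab_x_mm": 80.0,
        "slab_y_mm": 60.0,
        "slab_thickness_mm": 25.0,
        "spacing_mm": 0.5,
        "joint_depth_mm": 2.3,
        "shell_extent_sagittal_mm": 20.0,
        "shell_extent_transverse_mm": 12.0,
        "shell_thickness_mm": 2.5,
        "swelling_percent": 0.0,
    },
    "optics": {
        "excitation": {"mu_a": 0.01, "mu_s_prime": 1.0, "cr": 2.95},
        "emission": {"mu_a": 0.01, "mu_s_prime": 1.0, "cr": 2.95},
    },
    "fluorophore": {
        "quantum_yield": DEFAULT_DYE.quantum_yield,
        "molar_absorption_ex": DEFAULT_DYE.molar_absorption_ex,
    },
    "concentrations": {"background_nM": 10.0, "ratio": 10.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML/JSON run config, filling gaps from package defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config for run provenance."""
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def build_from_config(cfg: dict):
    """Materialize (domain, props_ex, props_em, dye, conc) from a config dict."""
    g = cfg["geometry"]
    domain = build_hand_slab(
        g["slab_x_mm"], g["slab_y_mm"], g["slab_thickness_mm"], g["spacing_mm"]
    )
    domain = embed_synovial_shell(
        domain,
        center_depth=g["joint_depth_mm"],
        lateral_extent=(g["shell_extent_sagittal_mm"], g["shell_extent_transverse_mm"]),
        thickness=g["shell_thickness_mm"],
        swelling_percent=g.get("swelling_percent", 0.0),
    )
    props_ex = OpticalProperties(**cfg["optics"]["excitation"])
    props_em = OpticalProperties(**cfg["optics"]["emission"])
    dye = FluorophoreSpec(**cfg["fluorophore"])
    c = cfg["concentrations"]
    conc = assign_concentrations(domain, c["background_nM"], c["ratio"])
    return domain, props_ex, props_em, dye, conc


def save_labels_h5(path: str | Path, domain: TissueDomain) -> None:
    """Write the label volume and grid metadata to HDF5."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("labels", data=domain.labels, compression="gzip")
        ds.attrs["spacing_mm"] = domain.spacing
        ds.attrs["top_surface_axis"] = domain.top_surface_axis


def save_fluence_h5(
    path: str | Path, field: FluenceField, domain: TissueDomain
) -> None:
    """Write a fluence volume with grid metadata to HDF5."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("fluence", data=field.values, compression="gzip")
        ds.attrs["spacing_mm"] = domain.spacing
        ds.attrs["wavelength_band"] = field.wavelength_band
        ds.attrs["residual"] = field.residual


def load_fluence_h5(path: str | Path) -> FluenceField:
    with h5py.File(path, "r") as f:
        ds = f["fluence"]
        return FluenceField(
            values=ds[...],
            wavelength_band=str(ds.attrs["wavelength_band"]),
            residual=float(ds.attrs["residual"]),
        )


def save_image(path: str | Path, image: SurfaceImage) -> None:
    """Write a surface image as float32 TIFF (.tif) or CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            image.pixels.astype(np.float32),
            resolution=(1.0 / image.pixel_size, 1.0 / image.pixel_size),
        )
    else:
        np.savetxt(path, image.pixels, delimiter=",")


def load_image(path: str | Path, pixel_size: float | None = None) -> SurfaceImage:
    """Read a surface image from TIFF or CSV.

    For CSV the pixel size must be given; for TIFF it is recovered from the
    resolution tag when present.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            pixels = page.asarray().astype(float)
            if pixel_size is None:
                res = page.tags.get("XResolution")
                if res is not None:
                    num, den = res.value
                    pixel_size = den / num
                else:
                    pixel_size = 1.0
        return SurfaceImage(pixels=pixels, pixel_size=float(pixel_size))
    pixels = np.loadtxt(path, delimiter=",")
    if pixel_size is None:
        raise ValueError("pixel_size required for CSV images")
    return SurfaceImage(pixels=np.atleast_2d(pixels), pixel_size=float(pixel_size))
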