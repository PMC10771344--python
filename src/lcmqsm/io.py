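"""NIfTI volume I/O, YAML configuration and JSON provenance."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .geometry import GridGeometry, ValidationError


def read_volume(path) -> tuple[np.ndarray, GridGeometry, np.ndarray]:
    """Load a 3-D NIfTI volume; returns (data, geometry, affine).

    Voxel sizes come from the header; the affine is preserved for a
    lossless round trip. The stored axis order (x, y, z) is kept as-is.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path}: volume contains non-finite voxels")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    geom = GridGeometry(shape=data.shape, voxel_size=voxel_size)
    return data, geom, np.asarray(img.affine)


def write_volume(data, geometry: GridGeometry, path, affine=None,
                 overwrite: bool = False) -> None:
    """Write a 3-D volume as NIfTI with voxel sizes from the geometry."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite {path} (pass overwrite=True)")
    data = np.asarray(data)
    if affine is None:
        affine = np.diag(list(geometry.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    img.header.set_zooms(geometry.voxel_size)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def write_provenance(record: dict, path, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite {path}")
    path.write_text(json.dumps({"schema_version": 1, **record}, indent=2))


def read_provenance(path) -> dict:
    return json.loads(Path(path).read_text())


PHANTOM_SCHEMA = {
    "shape", "voxel_size", "b0_direction", "n_tissue_regions",
    "amplification_range", "n_sources", "source_value_range",
    "source_radius_range", "noise_std", "seed",
}
TRAIN_SCHEMA = {
    "learning_rate", "weight_decay", "epochs", "patch_size", "batch_size", "seed",
}
MODEL_SCHEMA = {
    "n_encoder_levels", "base_channels", "n_modulated_blocks", "epsilon",
    "kernel_size", "no_modulation", "no_fusion", "field_as_initial_input",
    "chi_init_residual",
}
LOSS_SCHEMA = {"alpha", "log_sigma", "log_kernel_size"}


def load_yaml_section(path, section: str, allowed: set) -> dict:
    """Read one section of a YAML config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    sec = raw.get(section, {}) or {}
    unknown = set(sec) - allowed
    if unknown:
        raise ValidationError(
            f"{path}: unknown key(s) in section {section!r}: {sorted(unknown)}"
        )
    return sec


def phantom_config_from_yaml(path, **overrides):
    from .phantom import PhantomConfig

    sec = load_yaml_section(path, "phantom", PHANTOM_SCHEMA)
    sec.update(overrides)
    shape = tuple(sec.pop("shape", (64, 64, 64)))
    voxel_size = tuple(sec.pop("voxel_size", (1.0, 1.0, 1.0)))
    b0 = tuple(sec.pop("b0_direction", (0.0, 0.0, 1.0)))
    for key in ("amplification_range", "source_value_range", "source_radius_range"):
        if key in sec:
            sec[key] = tuple(sec[key])
    geom = GridGeometry(shape=shape, voxel_size=voxel_size, b0_direction=b0)
    return PhantomConfig(geometry=geom, **sec)
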