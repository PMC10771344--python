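"""Synthetic brain-like QSM phantoms.

The generator emulates the construction of the training corpus: a
tissue-like susceptibility map (smooth background plus deep-gray-like
focal regions inside an ellipsoidal brain mask), a global linear
amplification with a factor drawn uniformly from [1, 3], spherical
susceptibility sources with values drawn uniformly from [-0.4, 0.4] ppm
inserted into the tissue, a field map obtained from the dipole forward
model plus additive Gaussian noise, and a co-registered magnitude image
whose region boundaries follow the susceptibility structure.

Every draw goes through one seeded ``numpy.random.Generator`` with a
fixed draw order (base brain, amplification, sources, noise, magnitude),
so a sample's provenance is its config plus one integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np
from scipy import ndimage

from .dipole import KSpaceDipoleKernel, build_dipole_kernel, forward_field
from .geometry import (
    FieldVolume,
    GridGeometry,
    SusceptibilityVolume,
    ValidationError,
    VOIMask,
)

#: Fractional semi-axes of the ellipsoidal VOI relative to the grid shape.
ELLIPSOID_SEMI_AXES = (0.40, 0.45, 0.35)


@dataclass(frozen=True)
class PhantomConfig:
    geometry: GridGeometry
    n_tissue_regions: int = 12
    amplification_range: tuple[float, float] = (1.0, 3.0)
    n_sources: int = 8
    source_value_range: tuple[float, float] = (-0.4, 0.4)
    source_radius_range: tuple[float, float] = (2.0, 5.0)
    noise_std: float = 0.005
    seed: int = 0

    def __post_init__(self):
        for name in ("amplification_range", "source_value_range", "source_radius_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} must be ordered low <= high")
        if max(abs(v) for v in self.source_value_range) > 1.0:
            raise ValidationError("source values must satisfy |chi| <= 1 ppm")
        if self.noise_std < 0:
            raise ValidationError("noise_std must be >= 0")
        if self.n_tissue_regions < 0 or self.n_sources < 0:
            raise ValidationError("counts must be >= 0")


@dataclass(frozen=True)
class SyntheticSample:
    chi: SusceptibilityVolume
    field: FieldVolume
    magnitude: np.ndarray
    mask: VOIMask
    provenance: dict[str, Any] = dc_field(default_factory=dict)


def _smooth_noise(shape, rng, sigma) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)


def generate_base_brain(config: PhantomConfig, rng: np.random.Generator):
    """Ellipsoidal VOI with smooth background and focal tissue regions.

    Background is Gaussian-smoothed noise rescaled to |chi| <= 0.05 ppm;
    the ``n_tissue_regions`` focal blobs (nuclei-like) overwrite their
    voxels with values drawn uniformly from [-0.15, 0.15] ppm.
    """
    geom = config.geometry
    shape = np.asarray(geom.shape)
    center = (shape - 1) / 2.0
    semi = np.asarray(ELLIPSOID_SEMI_AXES) * shape
    ix = np.indices(geom.shape).astype(float)
    e = sum(((ix[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    mask = e <= 1.0

    background = _smooth_noise(geom.shape, rng, sigma=min(shape) / 8.0)
    peak = np.max(np.abs(background))
    if peak > 0:
        background = background / peak * 0.04
    chi = background * mask

    interior = np.argwhere(mask)
    for _ in range(config.n_tissue_regions):
        c = interior[rng.integers(len(interior))]
        radii = rng.uniform(0.04, 0.10, size=3) * shape
        value = rng.uniform(-0.15, 0.15)
        blob = sum(((ix[a] - c[a]) / radii[a]) ** 2 for a in range(3)) <= 1.0
        blob &= mask
        chi[blob] = value

    return (
        SusceptibilityVolume(data=chi, geometry=geom),
        VOIMask(data=mask, geometry=geom),
    )


def apply_linear_amplification(chi: SusceptibilityVolume, factor: float) -> SusceptibilityVolume:
    """Global linear amplification chi' = factor * chi."""
    if not np.isfinite(factor):
        raise ValidationError("amplification factor must be finite")
    return SusceptibilityVolume(data=chi.data * factor, geometry=chi.geometry)


def add_spherical_sources(
    chi: SusceptibilityVolume,
    mask: VOIMask,
    config: PhantomConfig,
    rng: np.random.Generator,
):
    """Insert spherical susceptibility sources fully inside the VOI.

    Centers are drawn uniformly among mask voxels deep enough that the
    whole sphere fits inside the mask (checked on the Euclidean distance
    transform); sphere voxels are overwritten with a value drawn
    uniformly from ``source_value_range``. Returns the new volume and a
    list of source records (center, radius, value).
    """
    data = chi.data.copy()
    depth = ndimage.distance_transform_edt(mask.data)
    ix = np.indices(chi.geometry.shape).astype(float)
    sources = []
    for _ in range(config.n_sources):
        radius = rng.uniform(*config.source_radius_range)
        value = rng.uniform(*config.source_value_range)
        eligible = np.argwhere(depth >= radius + 1.0)
        if len(eligible) == 0:
            warnings.warn(
                f"mask too small to host a sphere of radius {radius:.2f}; skipped"
            )
            continue
        c = eligible[rng.integers(len(eligible))]
        d2 = sum((ix[a] - c[a]) ** 2 for a in range(3))
        data[d2 <= radius**2] = value
        sources.append(
            {"center": [int(v) for v in c], "radius": float(radius), "value": float(value)}
        )
    return SusceptibilityVolume(data=data, geometry=chi.geometry), sources


def synthesize_field(
    chi: SusceptibilityVolume,
    kernel: KSpaceDipoleKernel,
    noise_std: float,
    rng: np.random.Generator,
) -> FieldVolume:
    """deltaB = forward_field(chi) + iid Gaussian noise of sd noise_std (ppm)."""
    if noise_std < 0:
        raise ValidationError("noise_std must be >= 0")
    clean = forward_field(chi, kernel)
    noise = noise_std * rng.standard_normal(chi.geometry.shape) if noise_std > 0 else 0.0
    return FieldVolume(data=clean.data + noise, geometry=chi.geometry)


def synthesize_magnitude(
    chi: SusceptibilityVolume,
    mask: VOIMask,
    sources: list[dict],
    rng: np.random.Generator,
) -> np.ndarray:
    """Co-registered synthetic magnitude image in [0, 1].

    Smooth tissue intensity whose region boundaries follow the chi
    structure, spheres rendered with sharp, sign-dependent contrast
    (bright for paramagnetic, dark for diamagnetic sources, as in
    T2*-weighted images around hemorrhage/calcification), a mild
    multiplicative bias field, zero outside the VOI.
    """
    geom = chi.geometry
    tissue = chi.data.copy()
    span = np.max(np.abs(tissue[mask.data])) if mask.data.any() else 0.0
    contrast = 0.2 * tissue / span if span > 0 else np.zeros(geom.shape)
    mag = 0.65 + contrast  # in [0.45, 0.85] before sources/bias

    ix = np.indices(geom.shape).astype(float)
    for s in sources:
        c, r = s["center"], s["radius"]
        d2 = sum((ix[a] - c[a]) ** 2 for a in range(3))
        mag[d2 <= r**2] = 0.95 if s["value"] >= 0 else 0.25

    bias = 1.0 + 0.05 * np.tanh(_smooth_noise(geom.shape, rng, sigma=min(geom.shape) / 4.0))
    mag = np.clip(mag * bias, 0.0, 1.0)
    mag[~mask.data] = 0.0
    return mag


def generate_sample(config: PhantomConfig, sample_seed: int) -> SyntheticSample:
    """One fully synthetic (chi, field, magnitude, mask) sample.

    Draw order is fixed: base brain, amplification factor, spherical
    sources, field noise, magnitude bias — so ``(config, sample_seed)``
    regenerates the sample bit-identically.
    """
    rng = np.random.default_rng(sample_seed)
    chi, mask = generate_base_brain(config, rng)
    factor = float(rng.uniform(*config.amplification_range))
    chi = apply_linear_amplification(chi, factor)
    chi, sources = add_spherical_sources(chi, mask, config, rng)
    kernel = build_dipole_kernel(config.geometry)
    field = synthesize_field(chi, kernel, config.noise_std, rng)
    magnitude = synthesize_magnitude(chi, mask, sources, rng)
    provenance = {
        "sample_seed": int(sample_seed),
        "amplification_factor": factor,
        "sources": sources,
        "noise_std": float(config.noise_std),
    }
    return SyntheticSample(chi=chi, field=field, magnitude=magnitude, mask=mask,
                           provenance=provenance)


def _axis_starts(lo: int, hi: int, patch: int, stride: int) -> list[int]:
    """Regular starts with stride covering [lo, hi), final patch flush."""
    starts = list(range(lo, max(hi - patch, lo) + 1, stride))
    last = max(hi - patch, lo)
    if starts[-1] != last:
        starts.append(last)
    return sorted({max(0, s) for s in starts})


def patch_grid(
    bbox_lo, bbox_hi, patch_size, volume_shape, overlap: float = 0.5
) -> list[tuple[int, int, int]]:
    """Deterministic grid of 0-based patch corners tiling a bounding box.

    Stride is ``patch * (1 - overlap)`` per axis; the final patch on
    each axis is flush with the box end; corners are clamped so every
    patch lies inside the volume. Extents are half-open.
    """
    corners_per_axis = []
    for a in range(3):
        p = patch_size[a]
        if p > volume_shape[a]:
            raise ValidationError(
                f"patch size {patch_size} exceeds volume shape {volume_shape}"
            )
        stride = max(1, int(round(p * (1.0 - overlap))))
        lo = min(bbox_lo[a], volume_shape[a] - p)
        hi = min(bbox_hi[a], volume_shape[a])
        corners_per_axis.append(_axis_starts(lo, hi, p, stride))
    return [
        (x, y, z)
        for x in corners_per_axis[0]
        for y in corners_per_axis[1]
        for z in corners_per_axis[2]
    ]


@dataclass(frozen=True)
class PatchRecord:
    sample_index: int
    corner: tuple[int, int, int]


DEFAULT_PATCH_SIZE = (64, 64, 32)


def build_dataset(
    config: PhantomConfig,
    n_samples: int,
    patch_size: tuple[int, int, int] = DEFAULT_PATCH_SIZE,
    overlap: float = 0.5,
):
    """Generate ``n_samples`` volumes plus a deterministic patch index.

    Sample i is generated with seed ``config.seed + i``; patches tile
    each sample's VOI bounding box on a regular overlapping grid.
    """
    samples, index = [], []
    for i in range(n_samples):
        s = generate_sample(config, config.seed + i)
        samples.append(s)
        nz = np.argwhere(s.mask.data)
        lo, hi = nz.min(axis=0), nz.max(axis=0) + 1
        for corner in patch_grid(lo, hi, patch_size, config.geometry.shape, overlap):
            index.append(PatchRecord(sample_index=i, corner=corner))
    return samples, index
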