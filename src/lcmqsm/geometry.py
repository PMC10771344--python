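"""Grid geometry and typed 3-D volumes.

Every quantity in the package lives on a regular Cartesian voxel grid:
susceptibility maps (chi, ppm), normalized field-shift maps (deltaB/B0,
ppm) and boolean volume-of-interest (VOI) masks. A :class:`GridGeometry`
carries the grid shape, the voxel size in mm and the direction of the
static field B0 in the laboratory frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when a volume, geometry or config violates its contract."""


def _as_unit_vector(v, tol: float = 1e-9) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValidationError(f"b0_direction must be a 3-vector, got shape {v.shape}")
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > tol:
        raise ValidationError(f"b0_direction must be a unit vector (|v| = {n:.3e})")
    return v


@dataclass(frozen=True)
class GridGeometry:
    """Voxel grid: shape (nx, ny, nz), voxel size in mm, B0 unit vector."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 2 for s in shape):
            raise ValidationError(f"shape must be three entries >= 2, got {self.shape}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValidationError(f"voxel sizes must be positive, got {self.voxel_size}")
        b0 = tuple(float(x) for x in _as_unit_vector(self.b0_direction))
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "b0_direction", b0)

    @property
    def b0(self) -> np.ndarray:
        return np.asarray(self.b0_direction, dtype=float)

    def with_b0(self, b0_direction) -> "GridGeometry":
        """Same grid, different field direction (tilted-orientation scans)."""
        return GridGeometry(self.shape, self.voxel_size, tuple(np.asarray(b0_direction, float)))

    def frequency_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unshifted DFT frequencies per axis, cycles/mm, DC at index 0."""
        return tuple(
            np.fft.fftfreq(n, d=d) for n, d in zip(self.shape, self.voxel_size)
        )


@dataclass(frozen=True)
class _Volume:
    data: np.ndarray
    geometry: GridGeometry

    _dtype = float

    def __post_init__(self):
        data = np.asarray(self.data, dtype=self._dtype)
        if data.shape != self.geometry.shape:
            raise ValidationError(
                f"data shape {data.shape} does not match geometry {self.geometry.shape}"
            )
        if self._dtype is float and not np.all(np.isfinite(data)):
            raise ValidationError("volume contains non-finite values")
        object.__setattr__(self, "data", data)


@dataclass(frozen=True)
class SusceptibilityVolume(_Volume):
    """Tissue magnetic susceptibility chi on the grid, in ppm."""


@dataclass(frozen=True)
class FieldVolume(_Volume):
    """Normalized local field shift deltaB/B0 on the grid, in ppm."""


@dataclass(frozen=True)
class VOIMask(_Volume):
    """Boolean volume-of-interest mask; at least one voxel must be set."""

    _dtype = bool

    def __post_init__(self):
        super().__post_init__()
        if not bool(self.data.any()):
            raise ValidationError("VOI mask has no true voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def require_same_geometry(*objs) -> GridGeometry:
    geoms = [o.geometry for o in objs]
    g0 = geoms[0]
    for g in geoms[1:]:
        if g.shape != g0.shape or g.voxel_size != g0.voxel_size:
            raise ValidationError(f"grid mismatch: {g0} vs {g}")
    return g0
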