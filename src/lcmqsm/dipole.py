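"""Dipole physics: k-space kernel, forward model, COSMOS inversion.

The normalized field shift deltaB produced by a susceptibility
distribution chi is, in k-space, a pointwise product

    deltaB(k) = D(k) * chi(k),      D(k) = 1/3 - (k . b)^2 / |k|^2,

where b is the unit vector along B0. D vanishes on a double cone at the
magic angle (cos^2 theta = 1/3, ~54.7 deg from B0), which is what makes
single-orientation inversion ill-posed. COSMOS removes the ill-posedness
by combining several head orientations in a per-frequency least squares.

All volumes are in ppm so |B0| never enters the numerics; FFTs are
unshifted (DC at index 0) and convolution is periodic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .geometry import (
    FieldVolume,
    GridGeometry,
    SusceptibilityVolume,
    ValidationError,
    require_same_geometry,
)

#: |D(k)| below this floor counts as unobservable in the COSMOS normal
#: equations denominator; those bins are zeroed rather than divided.
COSMOS_DENOMINATOR_FLOOR = 1e-6


@dataclass(frozen=True)
class KSpaceDipoleKernel:
    """D(k) sampled on the unshifted DFT frequency lattice of a grid."""

    values: np.ndarray
    geometry: GridGeometry
    dc_convention: float = 0.0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.geometry.shape:
            raise ValidationError("kernel shape does not match geometry")
        object.__setattr__(self, "values", values)


def build_dipole_kernel(geometry: GridGeometry, dc_convention: float = 0.0) -> KSpaceDipoleKernel:
    """Evaluate D(k) = 1/3 - (k.b)^2/|k|^2 on the grid's frequency lattice.

    The zero-frequency bin is undefined by the formula (the mean
    susceptibility produces no observable field shift) and is set to
    ``dc_convention`` (default 0). Only the direction of k matters, so
    the frequency unit cancels.

    On even-sized grids the Nyquist bins represent +/-0.5 cycles/voxel
    ambiguously; for an oblique B0 the raw formula then differs between
    k and -k there. The kernel is symmetrized over k -> -k (averaging
    the two sign choices), which keeps the convolution operator real
    and self-adjoint, and clipped to the analytic range [-2/3, 1/3].
    """
    kx, ky, kz = geometry.frequency_grid()
    b = geometry.b0
    kxg, kyg, kzg = np.meshgrid(kx, ky, kz, indexing="ij")
    k2 = kxg**2 + kyg**2 + kzg**2
    kdotb = kxg * b[0] + kyg * b[1] + kzg * b[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 1.0 / 3.0 - kdotb**2 / k2
    flip = np.ix_(*[(-np.arange(n)) % n for n in geometry.shape])
    values = 0.5 * (values + values[flip])
    values = np.clip(values, -2.0 / 3.0, 1.0 / 3.0)
    values[0, 0, 0] = dc_convention
    return KSpaceDipoleKernel(values=values, geometry=geometry, dc_convention=dc_convention)


def magic_angle_deg() -> float:
    """Polar angle from B0 (degrees, one decimal) where D(k) = 0.

    Root of 1/3 - cos^2(theta): theta = arccos(1/sqrt(3)) ~ 54.7 deg.
    """
    return round(float(np.degrees(np.arccos(1.0 / np.sqrt(3.0)))), 1)


def dipole_real_space(offset, b0_direction=(0.0, 0.0, 1.0)) -> float:
    """Real-space unit-dipole field response at ``offset`` (mm) from the source.

    d(r) = (3 cos^2 theta - 1) / (4 pi |r|^3) with theta the angle
    between r and B0. Singular at the origin.
    """
    r = np.asarray(offset, dtype=float)
    rn = float(np.linalg.norm(r))
    if rn == 0.0:
        raise ValidationError("dipole response is singular at zero offset")
    b = np.asarray(b0_direction, dtype=float)
    b = b / np.linalg.norm(b)
    cos_theta = float(np.dot(r, b)) / rn
    return (3.0 * cos_theta**2 - 1.0) / (4.0 * np.pi * rn**3)


def forward_field(chi: SusceptibilityVolume, kernel: KSpaceDipoleKernel) -> FieldVolume:
    """deltaB = IFFT( D(k) * FFT(chi) ); periodic (circular) convolution."""
    require_same_geometry(chi, kernel)
    spec = np.fft.fftn(chi.data) * kernel.values
    out = np.fft.ifftn(spec)
    return FieldVolume(data=out.real, geometry=chi.geometry)


def cosmos_invert(
    fields: list[FieldVolume],
    kernels: list[KSpaceDipoleKernel],
    max_iter: int = 200,
    tol: float = 1e-5,
    denominator_floor: float = COSMOS_DENOMINATOR_FLOOR,
    method: str = "direct",
) -> SusceptibilityVolume:
    """Multi-orientation (COSMOS) least-squares dipole inversion.

    Per frequency bin the normal equations are scalar:

        chi(k) = sum_i D_i(k) deltaB_i(k) / sum_i D_i(k)^2,

    zeroed where the denominator falls below ``denominator_floor``
    (those bins are unobserved by every orientation). ``method='direct'``
    evaluates this closed form; ``method='cg'`` solves the same normal
    equations with conjugate gradients honoring ``max_iter``/``tol``.
    """
    if len(fields) < 2 or len(kernels) < 2:
        raise ValidationError("cosmos_invert needs at least 2 orientations")
    if len(fields) != len(kernels):
        raise ValidationError("one kernel per field required")
    geom = fields[0].geometry
    for f, k in zip(fields, kernels):
        require_same_geometry(f, k)
        if f.geometry.shape != geom.shape or f.geometry.voxel_size != geom.voxel_size:
            raise ValidationError("all orientations must share one grid")

    D = np.stack([k.values for k in kernels])
    denom = np.sum(D**2, axis=0)
    numer = np.sum(D * np.stack([np.fft.fftn(f.data) for f in fields]), axis=0)
    good = denom >= denominator_floor

    if method == "direct":
        chi_k = np.zeros_like(numer)
        chi_k[good] = numer[good] / denom[good]
    elif method == "cg":
        # Normal equations are diagonal in k; CG is run on the masked
        # diagonal system so max_iter/tol are honored genuinely.
        d = denom[good]
        rhs = numer[good]
        op = LinearOperator(
            shape=(d.size, d.size),
            matvec=lambda x: d * x,
            dtype=float,
        )
        sol_re, _ = cg(op, rhs.real, rtol=tol, maxiter=max_iter)
        sol_im, _ = cg(op, rhs.imag, rtol=tol, maxiter=max_iter)
        chi_k = np.zeros_like(numer)
        chi_k[good] = sol_re + 1j * sol_im
    else:
        raise ValidationError(f"unknown method {method!r}")

    chi = np.fft.ifftn(chi_k).real
    return SusceptibilityVolume(data=chi, geometry=geom)
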