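"""Thresholded k-space division (TKD).

Direct single-orientation dipole inversion: divide the field spectrum by
the dipole kernel wherever |D(k)| exceeds a threshold T, and zero the
ill-conditioned bins near the magic-angle cone. The result chi_int is a
fast, streaky pre-estimate of the susceptibility; the network consumes
it as the constant input of its first modulated block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    FieldVolume,
    SusceptibilityVolume,
    ValidationError,
    VOIMask,
    require_same_geometry,
)
from .dipole import KSpaceDipoleKernel


@dataclass(frozen=True)
class TKDConfig:
    """threshold T: bins with |D(k)| <= T are zeroed. Valid range (0, 2/3)."""

    threshold: float = 0.2

    def __post_init__(self):
        if not (0.0 < self.threshold < 2.0 / 3.0):
            raise ValidationError(
                f"TKD threshold must lie in (0, 2/3), got {self.threshold}"
            )


def tkd_invert(
    field: FieldVolume,
    kernel: KSpaceDipoleKernel,
    config: TKDConfig = TKDConfig(),
    mask: VOIMask | None = None,
) -> SusceptibilityVolume:
    """chi(k) = deltaB(k)/D(k) where |D(k)| > T, else 0.

    Equality |D| = T is zeroed (conservative). If ``mask`` is given the
    returned volume is restricted to the VOI.
    """
    require_same_geometry(field, kernel)
    T = config.threshold
    D = kernel.values
    keep = np.abs(D) > T
    chi_k = np.zeros_like(D, dtype=complex)
    spec = np.fft.fftn(field.data)
    chi_k[keep] = spec[keep] / D[keep]
    chi = np.fft.ifftn(chi_k).real
    if mask is not None:
        require_same_geometry(field, mask)
        chi = chi * mask.data
    return SusceptibilityVolume(data=chi, geometry=field.geometry)


def wellconditioned_fraction(kernel: KSpaceDipoleKernel, threshold: float) -> float:
    """Fraction of frequency bins with |D(k)| > threshold (diagnostic)."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    return float(np.mean(np.abs(kernel.values) > threshold))
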