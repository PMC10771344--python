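"""Reconstruction quality metrics over the VOI.

All metrics are computed inside the volume-of-interest mask:

* ``rmse``  — normalized root-mean-square error, 100 * ||e|| / ||ref||
  (the QSM-challenge convention, so 100 means "as wrong as the zero
  map");
* ``psnr``  — peak signal-to-noise ratio in dB with the peak taken as
  the reference dynamic range inside the VOI;
* ``mssim`` — mean structural similarity index over VOI voxels
  (uniform 7^3 window, unbiased covariance, standard constants);
* ``hfen``  — high-frequency error norm: the normalized error of
  Laplacian-of-Gaussian filtered volumes, sharing the LoG parameters
  with the training loss;
* ``roi_stats`` — per-region mean/std susceptibility (deep-gray-matter
  bar-graph analogue).

The formulas are this package's definitions; scores are comparable
within the package, not against externally reported tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import uniform_filter

from .geometry import ValidationError
from .training import LossConfig, log_filter


class UndefinedMetricError(ValueError):
    """The metric's denominator (or peak) is degenerate."""


PSNR_CAP_DB = 120.0


def _masked(x, mask):
    x = np.asarray(x, dtype=float)
    m = np.asarray(mask, bool)
    if x.shape != m.shape:
        raise ValidationError("volume and mask shapes must match")
    return x, m


def rmse(x_hat, x_ref, mask) -> float:
    """100 * ||x_hat - x_ref||_F / ||x_ref||_F over the VOI."""
    ref, m = _masked(x_ref, mask)
    hat, _ = _masked(x_hat, mask)
    denom = np.linalg.norm(ref[m])
    if denom == 0:
        raise UndefinedMetricError("reference has zero norm inside the VOI")
    return float(100.0 * np.linalg.norm(hat[m] - ref[m]) / denom)


def psnr(x_hat, x_ref, mask) -> float:
    """10 log10(peak^2 / MSE) dB; peak = reference range in the VOI."""
    ref, m = _masked(x_ref, mask)
    hat, _ = _masked(x_hat, mask)
    peak = float(ref[m].max() - ref[m].min())
    if peak == 0:
        raise UndefinedMetricError("reference is constant inside the VOI")
    mse = float(np.mean((hat[m] - ref[m]) ** 2))
    if mse < peak**2 * 1e-12:
        return PSNR_CAP_DB
    return float(10.0 * np.log10(peak**2 / mse))


def mssim(x_hat, x_ref, mask, win_size: int = 7, k1: float = 0.01,
          k2: float = 0.03) -> float:
    """Mean SSIM over VOI voxels, uniform window, sample covariance.

    Dynamic range is the reference range inside the VOI; the local
    SSIM map uses reflect boundary handling, and only VOI voxels enter
    the mean. Returns a value in [-1, 1]; 1 iff identical over the VOI.
    """
    ref, m = _masked(x_ref, mask)
    hat, _ = _masked(x_hat, mask)
    if any(win_size > s for s in ref.shape):
        raise ValidationError(f"window {win_size} larger than volume {ref.shape}")
    dr = float(ref[m].max() - ref[m].min())
    if dr == 0:
        raise UndefinedMetricError("reference is constant inside the VOI")
    c1, c2 = (k1 * dr) ** 2, (k2 * dr) ** 2
    np_win = win_size**3
    cov_norm = np_win / (np_win - 1)  # unbiased sample (co)variance
    f = lambda v: uniform_filter(v, size=win_size, mode="reflect")
    ux, uy = f(hat), f(ref)
    uxx, uyy, uxy = f(hat * hat), f(ref * ref), f(hat * ref)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    ssim_map = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )
    return float(ssim_map[m].mean())


def hfen(x_hat, x_ref, mask, loss_config: LossConfig = LossConfig()) -> float:
    """100 * ||LoG(x_hat) - LoG(x_ref)||_F / ||LoG(x_ref)||_F over the VOI."""
    ref, m = _masked(x_ref, mask)
    hat, _ = _masked(x_hat, mask)
    fr = log_filter(ref, loss_config)
    fh = log_filter(hat, loss_config)
    denom = np.linalg.norm(fr[m])
    if denom == 0:
        raise UndefinedMetricError("filtered reference has zero norm in the VOI")
    return float(100.0 * np.linalg.norm(fh[m] - fr[m]) / denom)


def roi_stats(chi, roi_masks: dict[str, np.ndarray]) -> list[tuple[str, float, float]]:
    """Per-ROI (label, mean, std) susceptibility in ppm; empty ROIs skipped."""
    chi = np.asarray(chi, dtype=float)
    out = []
    for label, m in roi_masks.items():
        m = np.asarray(m, bool)
        if not m.any():
            warnings.warn(f"ROI {label!r} is empty; skipped")
            continue
        out.append((label, float(chi[m].mean()), float(chi[m].std())))
    return out


@dataclass(frozen=True)
class MetricReport:
    psnr: float
    rmse: float
    mssim: float
    hfen: float
    roi_stats: list = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "psnr_db": self.psnr,
            "rmse_pct": self.rmse,
            "mssim": self.mssim,
            "hfen_pct": self.hfen,
            "roi_stats": [
                {"label": l, "mean_ppm": mu, "std_ppm": sd} for l, mu, sd in self.roi_stats
            ],
        }


def evaluate(x_hat, x_ref, mask, loss_config: LossConfig = LossConfig(),
             roi_masks: dict | None = None) -> MetricReport:
    return MetricReport(
        psnr=psnr(x_hat, x_ref, mask),
        rmse=rmse(x_hat, x_ref, mask),
        mssim=mssim(x_hat, x_ref, mask),
        hfen=hfen(x_hat, x_ref, mask, loss_config),
        roi_stats=roi_stats(x_hat, roi_masks) if roi_masks else [],
    )
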