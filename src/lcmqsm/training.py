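"""Loss, optimizer and the patch-based training loop.

The training objective combines a mean-squared-error term with a
high-frequency error term computed through a Laplacian-of-Gaussian
(LoG) filter:

    Loss = || M(chi_hat - chi_ref) ||_F^2
         + alpha * || f_LoG(M chi_hat) - f_LoG(M chi_ref) ||_F^2

where M is the VOI mask (applied before the norms) and alpha balances
the two terms. Optimization uses AdamW — adaptive moments with
decoupled weight decay — at the stated defaults (learning rate 1e-4,
weight decay 5e-4, 30 epochs, 64x64x32 patches). Network inputs are fed
in physical ppm units and are never rescaled per volume: the mapping
from field shift to susceptibility is quantitative, so any per-volume
normalization would destroy the very scale the model must learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .dipole import build_dipole_kernel
from .geometry import ValidationError
from .model import LCMnet, LCMnetConfig
from .phantom import PatchRecord, SyntheticSample
from .tkd import TKDConfig, tkd_invert


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.1
    log_sigma: float = 1.5
    log_kernel_size: int = 9

    def __post_init__(self):
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.log_sigma <= 0:
            raise ValidationError("log_sigma must be > 0")
        if self.log_kernel_size < 3 or self.log_kernel_size % 2 == 0:
            raise ValidationError("log_kernel_size must be odd and >= 3")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 5e-4
    epochs: int = 30
    patch_size: tuple[int, int, int] = (64, 64, 32)
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValidationError("learning_rate and weight_decay must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")


def log_stencil(config: LossConfig) -> np.ndarray:
    """Discrete 3-D Laplacian-of-Gaussian stencil, mean-subtracted.

    Sampled from the analytic LoG of an isotropic Gaussian (sigma in
    voxels) on an odd cubic support, then shifted by its mean so the
    kernel sums to exactly zero and annihilates constants.
    """
    k, s = config.log_kernel_size, config.log_sigma
    r = np.arange(k) - k // 2
    x, y, z = np.meshgrid(r, r, r, indexing="ij")
    r2 = x**2 + y**2 + z**2
    g = np.exp(-r2 / (2 * s**2))
    log = g * (r2 - 3 * s**2) / s**4
    log -= log.mean()
    return log


def log_filter(volume, config: LossConfig = LossConfig()):
    """LoG filtering with symmetric boundary padding; shape-preserving.

    Accepts a plain 3-D array (returns an array) or an autodiff tensor
    (returns a tensor on the tape); linear and shift-invariant.
    """
    stencil = log_stencil(config)
    pad = config.log_kernel_size // 2
    is_tensor = isinstance(volume, Tensor)
    t = volume if is_tensor else Tensor(np.asarray(volume, dtype=float))
    if t.data.ndim != 3:
        raise ValidationError("log_filter expects a 3-D volume")
    out = ad.correlate_valid(ad.pad_symmetric(t, pad), stencil)
    return out if is_tensor else out.data


def training_loss(chi_hat, chi_ref, mask, config: LossConfig = LossConfig()):
    """MSE + alpha * HFEN objective on VOI-masked volumes (scalar, >= 0)."""
    ref = np.asarray(chi_ref, dtype=float)
    m = np.asarray(mask, dtype=float)
    hat = chi_hat if isinstance(chi_hat, Tensor) else Tensor(np.asarray(chi_hat, float))
    if hat.data.shape != ref.shape or ref.shape != m.shape:
        raise ValidationError("chi_hat, chi_ref and mask shapes must match")
    hat_m = hat * m
    ref_m = Tensor(ref * m)
    mse = ((hat_m - ref_m) ** 2).sum()
    if config.alpha == 0:
        return mse
    hf = ((log_filter(hat_m, config) - log_filter(ref_m, config)) ** 2).sum()
    return mse + config.alpha * hf


class AdamW:
    """Adaptive moments with decoupled weight decay."""

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.weight_decay = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


@dataclass
class PatchSet:
    """Aligned training patches: field, magnitude, chi_init, mask, chi_ref."""

    field: list = dc_field(default_factory=list)
    magnitude: list = dc_field(default_factory=list)
    chi_init: list = dc_field(default_factory=list)
    mask: list = dc_field(default_factory=list)
    chi_ref: list = dc_field(default_factory=list)

    def __len__(self):
        return len(self.field)

    def append(self, f, m, ci, mk, cr):
        self.field.append(f)
        self.magnitude.append(m)
        self.chi_init.append(ci)
        self.mask.append(mk)
        self.chi_ref.append(cr)


def prepare_patches(
    samples: list[SyntheticSample],
    index: list[PatchRecord],
    patch_size: tuple[int, int, int],
    tkd_config: TKDConfig = TKDConfig(),
) -> PatchSet:
    """Slice aligned patches; chi_init is the whole-volume TKD inversion."""
    chi_inits = []
    for s in samples:
        kernel = build_dipole_kernel(s.field.geometry)
        chi_inits.append(tkd_invert(s.field, kernel, tkd_config, mask=s.mask).data)
    from .model import downsample_mask

    out = PatchSet()
    for rec in index:
        s = samples[rec.sample_index]
        sl = tuple(slice(c, c + p) for c, p in zip(rec.corner, patch_size))
        # keep only patches whose VOI survives the 4x pooled-mask threshold
        # (the latent decoder pools over that mask)
        if not downsample_mask(s.mask.data[sl], 4).any():
            continue
        out.append(s.field.data[sl], s.magnitude[sl], chi_inits[rec.sample_index][sl],
                   s.mask.data[sl], s.chi.data[sl])
    return out


def train(
    model: LCMnet,
    patches: PatchSet,
    train_config: TrainConfig,
    loss_config: LossConfig = LossConfig(),
    max_steps: int | None = None,
    callback=None,
):
    """Patch-based AdamW optimization; returns (model, per-epoch mean loss).

    Patches are visited in a seeded random order each epoch; a batch's
    loss is the mean of its per-patch losses. Aborts on a non-finite
    loss. ``max_steps`` caps the total number of optimizer steps (the
    loop still reports whole-epoch means for completed epochs).
    """
    if len(patches) == 0:
        raise ValidationError("empty training set")
    opt = AdamW(model.params, lr=train_config.learning_rate,
                weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed)
    history, steps = [], 0
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(patches))
        epoch_losses = []
        for start in range(0, len(order), train_config.batch_size):
            batch = order[start : start + train_config.batch_size]
            opt.zero_grad()
            losses = []
            for j in batch:
                pred = model.forward(patches.field[j], patches.magnitude[j],
                                     patches.chi_init[j], patches.mask[j])
                losses.append(training_loss(pred, patches.chi_ref[j],
                                            patches.mask[j], loss_config))
            total = losses[0]
            for extra in losses[1:]:
                total = total + extra
            total = total * (1.0 / len(losses))
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {steps}: {total.data}"
                )
            total.backward()
            opt.step()
            epoch_losses.append(float(total.data))
            steps += 1
            if max_steps is not None and steps >= max_steps:
                break
        history.append(float(np.mean(epoch_losses)))
        if callback is not None:
            callback(epoch, history[-1])
        if max_steps is not None and steps >= max_steps:
            break
    return model, history


ABLATION_VARIANTS = {
    "LCMnet": {},
    "LCMnet_NoMod": {"no_modulation": True},
    "LCMnet_NoFusion": {"no_fusion": True},
    "LCMnet_deltaB": {"field_as_initial_input": True},
}


def run_ablation_suite(
    train_patches: PatchSet,
    eval_patches: PatchSet,
    base_model_config: LCMnetConfig,
    train_config: TrainConfig,
    loss_config: LossConfig = LossConfig(),
    max_steps: int | None = None,
    variants: dict[str, dict] | None = None,
):
    """Train the full model and its ablations under identical budgets.

    Returns {variant: {"history": [...], "metrics": {...}}} where the
    metrics row holds held-out masked scores (table analogue). All
    variants share the weight-init and data-order seeds.
    """
    from dataclasses import replace

    from .metrics import rmse

    results = {}
    for name, flags in (variants or ABLATION_VARIANTS).items():
        cfg = replace(base_model_config, **flags)
        model = LCMnet(cfg, seed=train_config.seed)
        model, history = train(model, train_patches, train_config, loss_config,
                               max_steps=max_steps)
        errs = []
        for j in range(len(eval_patches)):
            pred = model.forward(eval_patches.field[j], eval_patches.magnitude[j],
                                 eval_patches.chi_init[j], eval_patches.mask[j]).data
            errs.append(rmse(pred, eval_patches.chi_ref[j], eval_patches.mask[j]))
        results[name] = {"history": history, "metrics": {"rmse": float(np.mean(errs))}}
    return results
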