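"""The latent-code modulated network (LCMnet) for dipole inversion.

The network maps four co-registered patches — local field, magnitude,
TKD-pre-estimated susceptibility chi_init and VOI mask — to a
susceptibility patch. Three ideas define the architecture:

* an encoder chain extracts multi-level features {FB1..FBn} from the
  field patch; two further downsampling encoders produce a bottleneck
  Fd, which a decoder turns into per-block *latent codes* via global
  average pooling restricted to the VOI;
* a *cross-fusion* block merges the field features with features of the
  (VOI-masked) magnitude image into fused maps {FBM1..FBMn};
* a *modulated convolution module* (MCM) — a chain of modulated blocks
  starting from chi_init features — whose convolution weights are
  multiplied per input channel by the latent code (modulation,
  w'_{pqrc} = l_c w_{pqrc}) and then renormalized per output channel
  (demodulation, w'' = w' / sqrt(sum w'^2 + eps)), making the filters
  adapt to the intensity distribution of the input while keeping their
  scale stable.

Ablation flags reproduce the variant networks: ``no_modulation``
(vanilla convolutions in the MCM), ``no_fusion`` (magnitude branch
removed) and ``field_as_initial_input`` (chi_init replaced by the field
map).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import ValidationError

CHECKPOINT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class LatentCode:
    """Per-channel modulation vector for one modulated block."""

    values: np.ndarray
    block_index: int = 0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or not np.all(np.isfinite(values)):
            raise ValidationError("latent code must be a finite 1-D vector")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class LCMnetConfig:
    n_encoder_levels: int = 3
    base_channels: int = 32
    n_modulated_blocks: int = 3
    epsilon: float = 1e-8
    kernel_size: int = 3
    no_modulation: bool = False
    no_fusion: bool = False
    field_as_initial_input: bool = False
    chi_init_residual: bool = False

    def __post_init__(self):
        if not (2 <= self.n_modulated_blocks <= 5):
            raise ValidationError("n_modulated_blocks must lie in [2, 5]")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValidationError("kernel_size must be odd")
        if self.n_encoder_levels < 1 or self.base_channels < 1:
            raise ValidationError("levels and channels must be >= 1")


def _values(latent) -> object:
    return latent.values if isinstance(latent, LatentCode) else latent


def modulate_weights(w, latent):
    """w'_{p,q,r,c} = l_c * w_{p,q,r,c}: scale each input channel c.

    Works on plain arrays and on autodiff tensors alike; the latent
    length must equal the weight array's input-channel count.
    """
    lv = _values(latent)
    n_in = w.shape[1]
    if lv.shape != (n_in,):
        raise ValidationError(
            f"latent length {lv.shape} does not match input channels ({n_in})"
        )
    return w * lv.reshape(1, n_in, 1, 1, 1)


def demodulate_weights(w_prime, epsilon: float = 1e-8):
    """Per-output-channel renormalization w'' = w'/sqrt(sum w'^2 + eps).

    The sum runs over each output channel's input channels and spatial
    taps, so every output filter ends up with squared norm s/(s+eps).
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be > 0")
    s = (w_prime**2).sum(axis=(1, 2, 3, 4), keepdims=True)
    return w_prime / (s + epsilon) ** 0.5


def downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Mean-pool a boolean mask by ``factor`` then threshold at 0.5."""
    m = mask.astype(float)
    X, Y, Z = m.shape
    f = factor
    if X % f or Y % f or Z % f:
        raise ValidationError(f"mask shape {m.shape} not divisible by {f}")
    pooled = m.reshape(X // f, f, Y // f, f, Z // f, f).mean(axis=(1, 3, 5))
    return pooled >= 0.5


class LCMnet:
    """Parameter container plus forward pass; weights live on the tape."""

    def __init__(self, config: LCMnetConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        B, n, k = config.base_channels, config.n_encoder_levels, config.kernel_size

        def conv_param(name, c_out, c_in, ksz=None):
            ksz = k if ksz is None else ksz
            fan_in = c_in * ksz**3
            w = rng.standard_normal((c_out, c_in, ksz, ksz, ksz)) * np.sqrt(2.0 / fan_in)
            self.params[name + "_w"] = ad.parameter(w)
            self.params[name + "_b"] = ad.parameter(np.zeros(c_out))

        # field encoder chain + two downsampling encoders
        for i in range(n):
            conv_param(f"enc{i}", B, 1 if i == 0 else B)
        conv_param("down0", 2 * B, B)
        conv_param("down1", 2 * B, 2 * B)
        # latent decoder: conv, masked GAP, one linear head per block
        conv_param("dec", 2 * B, 2 * B)
        for i in range(config.n_modulated_blocks):
            # small weights + unit bias: modulation starts near identity
            self.params[f"lat{i}_w"] = ad.parameter(
                rng.standard_normal((B, 2 * B)) * 0.01
            )
            self.params[f"lat{i}_b"] = ad.parameter(np.ones(B))
        # cross-fusion
        conv_param("mag0", B, 1)
        conv_param("mag1", B, B)
        for i in range(n):
            conv_param(f"cf_p{i}", B, B)
            conv_param(f"cf_out{i}", B, B)
        conv_param("cf_fuse", B, (n + 1) * B, ksz=1)
        conv_param("cf_fuse_nf", B, B, ksz=1)
        # modulated convolution module
        conv_param("lift", B, 1)
        for i in range(config.n_modulated_blocks):
            conv_param(f"mod{i}", B, B)
            conv_param(f"comb{i}", B, 2 * B)
        conv_param("head", 1, B)

    # -- helpers -----------------------------------------------------------

    def _conv(self, name, x, activate=True):
        y = ad.conv3d(x, self.params[name + "_w"], self.params[name + "_b"])
        return ad.leaky_relu(y) if activate else y

    @staticmethod
    def _check_patch(shape):
        if any(s % 4 for s in shape):
            raise ValidationError(
                f"patch dims {shape} must be multiples of 4 (two 2x downsamplings)"
            )

    # -- architecture pieces ----------------------------------------------

    def encode_field(self, field_patch) -> dict:
        """Full-resolution features {FB1..FBn} plus the bottleneck Fd."""
        x = _as_feature(field_patch)
        self._check_patch(x.data.shape[1:])
        levels = []
        for i in range(self.config.n_encoder_levels):
            x = self._conv(f"enc{i}", x)
            levels.append(x)
        d = self._conv("down0", ad.avg_pool2(levels[-1]))
        d = self._conv("down1", ad.avg_pool2(d))
        return {"levels": levels, "bottleneck": d}

    def decode_latent(self, fd, mask: np.ndarray) -> list[Tensor]:
        """Latent codes: conv, VOI-restricted GAP, per-block linear heads.

        The bottleneck feature is masked before the convolution so the
        codes are exactly independent of anything outside the VOI.
        """
        pooled_mask = downsample_mask(np.asarray(mask, bool), 4)
        count = int(pooled_mask.sum())
        if count == 0:
            raise ValidationError("VOI mask is empty at the bottleneck resolution")
        h = self._conv("dec", fd * pooled_mask[None].astype(float))
        m = pooled_mask[None].astype(float)
        pooled = (h * m).sum(axis=(1, 2, 3)) * (1.0 / count)  # (2B,)
        return [
            ad.linear(pooled, self.params[f"lat{i}_w"], self.params[f"lat{i}_b"])
            for i in range(self.config.n_modulated_blocks)
        ]

    def cross_fusion(self, field_features: dict, magnitude_patch, mask) -> list[Tensor]:
        """Fused maps {FBM1..FBMn}; magnitude is VOI-masked before features."""
        levels = field_features["levels"]
        proc = [self._conv(f"cf_p{i}", fb) for i, fb in enumerate(levels)]
        if self.config.no_fusion:
            fused = [self._conv("cf_fuse_nf", p) for p in proc]
        else:
            mag = _as_feature(np.asarray(magnitude_patch) * np.asarray(mask, float))
            m = self._conv("mag1", self._conv("mag0", mag), activate=False)
            f = self._conv("cf_fuse", ad.concat(proc + [m], axis=0))
            fused = [f] * len(levels)
        return [
            ad.leaky_relu(self._conv(f"cf_out{i}", f, activate=False))
            for i, f in enumerate(fused)
        ]

    def modulated_conv_block(self, features_in, latent, fused_features, block_index: int):
        """One MCM block: (de)modulated conv + concat-merge with fused maps."""
        if features_in.data.shape[1:] != fused_features.data.shape[1:]:
            raise ValidationError("features_in and fused_features shapes differ")
        w = self.params[f"mod{block_index}_w"]
        if not self.config.no_modulation:
            w = demodulate_weights(modulate_weights(w, latent), self.config.epsilon)
        t = ad.conv3d(features_in, w, self.params[f"mod{block_index}_b"])
        merged = self._conv(f"comb{block_index}", ad.concat([t, fused_features], axis=0),
                            activate=False)
        return ad.leaky_relu(merged)

    def forward(self, field_patch, magnitude_patch, chi_init_patch, mask_patch) -> Tensor:
        """Full pass; returns the susceptibility patch (same spatial shape)."""
        shapes = {np.asarray(p).shape for p in
                  (field_patch, magnitude_patch, chi_init_patch, mask_patch)}
        if len(shapes) != 1:
            raise ValidationError(f"input patches disagree in shape: {shapes}")
        cfg = self.config
        feats = self.encode_field(field_patch)
        latents = self.decode_latent(feats["bottleneck"], mask_patch)
        fused = self.cross_fusion(feats, magnitude_patch, mask_patch)
        initial = field_patch if cfg.field_as_initial_input else chi_init_patch
        h = self._conv("lift", _as_feature(initial))
        n_levels = len(fused)
        for i in range(cfg.n_modulated_blocks):
            h = self.modulated_conv_block(h, latents[i], fused[min(i, n_levels - 1)], i)
        out = self._conv("head", h, activate=False)
        out = out.reshape(*out.data.shape[1:])
        if cfg.chi_init_residual:
            out = out + np.asarray(chi_init_patch, float)
        return out

    __call__ = forward

    # -- persistence -------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data for k, v in self.params.items()}

    def save(self, path):
        meta = {"schema_version": CHECKPOINT_SCHEMA_VERSION, "config": asdict(self.config)}
        np.savez(path, __meta__=json.dumps(meta), **self.state_arrays())

    @classmethod
    def load(cls, path) -> "LCMnet":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            if meta.get("schema_version") != CHECKPOINT_SCHEMA_VERSION:
                raise ValidationError("unsupported checkpoint schema version")
            model = cls(LCMnetConfig(**meta["config"]))
            for k in model.params:
                model.params[k] = ad.parameter(z[k])
        return model


def _as_feature(patch) -> Tensor:
    """Lift a 3-D patch (array or tensor) to a 1-channel feature tensor."""
    if isinstance(patch, Tensor):
        return patch.reshape(1, *patch.data.shape) if patch.data.ndim == 3 else patch
    a = np.asarray(patch, dtype=float)
    return Tensor(a[None] if a.ndim == 3 else a)


def lcmnet_forward(model: LCMnet, field_patch, magnitude_patch, chi_init_patch,
                   mask_patch) -> np.ndarray:
    """Inference convenience: run the network and return a plain array."""
    return model.forward(field_patch, magnitude_patch, chi_init_patch, mask_patch).data


def _cosine_window(shape) -> np.ndarray:
    wins = [np.sin(np.pi * (np.arange(n) + 0.5) / n) for n in shape]
    return wins[0][:, None, None] * wins[1][None, :, None] * wins[2][None, None, :]


def reconstruct_volume(
    model: LCMnet,
    field: np.ndarray,
    magnitude: np.ndarray,
    chi_init: np.ndarray,
    mask: np.ndarray,
    patch_size=(64, 64, 32),
    overlap: float = 0.5,
) -> np.ndarray:
    """Whole-volume inference by overlapping patches with cosine blending."""
    from .phantom import patch_grid

    shape = field.shape
    patch_size = tuple(min(p, s) for p, s in zip(patch_size, shape))
    corners = patch_grid((0, 0, 0), shape, patch_size, shape, overlap)
    out = np.zeros(shape)
    wsum = np.zeros(shape)
    win = _cosine_window(patch_size)
    for c in corners:
        sl = tuple(slice(c[a], c[a] + patch_size[a]) for a in range(3))
        # skip patches that are (almost) all background: the VOI-restricted
        # pooling needs at least one surviving bottleneck voxel
        if not downsample_mask(mask[sl], 4).any():
            continue
        pred = lcmnet_forward(model, field[sl], magnitude[sl], chi_init[sl], mask[sl])
        out[sl] += pred * win
        wsum[sl] += win
    np.divide(out, wsum, out=out, where=wsum > 0)
    return out * mask
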