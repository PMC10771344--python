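"""Desk-scale experiment harness on synthetic phantoms.

Reusable, seeded experiment recipes sized for a single CPU: a tiny
network (2 encoder levels, 8 base channels) trained on 16^3 patches
from 32^3 phantoms. The phantom generator runs at its default study
conditions (amplification in [1, 3], sources in [-0.4, 0.4] ppm, field
noise 0.005 ppm); only the grid size and the network/optimizer budget
are scaled down. The learning rate for the short 200-step budget is
2e-3: Adam-style steps move parameters by roughly the learning rate per
step, so a 200-step run needs ~1/steps to traverse order-one weight
changes (the full-scale default of 1e-4 belongs to the 30-epoch
regime).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .dipole import build_dipole_kernel
from .geometry import GridGeometry
from .metrics import rmse
from .model import LCMnet, LCMnetConfig, reconstruct_volume
from .phantom import PhantomConfig, build_dataset, generate_sample
from .tkd import TKDConfig, tkd_invert
from .training import (
    ABLATION_VARIANTS,
    LossConfig,
    TrainConfig,
    prepare_patches,
    run_ablation_suite,
    train,
)

DESK_SHAPE = (32, 32, 32)
DESK_PATCH = (16, 16, 16)
HELDOUT_SEED_OFFSET = 100_000


def desk_phantom_config(seed: int, shape=DESK_SHAPE) -> PhantomConfig:
    return PhantomConfig(geometry=GridGeometry(shape), seed=seed)


def tiny_model_config(**flags) -> LCMnetConfig:
    return LCMnetConfig(n_encoder_levels=2, base_channels=8, **flags)


def tiny_train_config(seed: int, epochs: int = 50) -> TrainConfig:
    return TrainConfig(learning_rate=2e-3, weight_decay=5e-4, epochs=epochs,
                       patch_size=DESK_PATCH, batch_size=2, seed=seed)


def _heldout_samples(seed: int, n: int):
    config = desk_phantom_config(seed + HELDOUT_SEED_OFFSET)
    return [generate_sample(config, config.seed + i) for i in range(n)], config


def learning_signal_experiment(
    seed: int,
    n_train: int = 10,
    n_heldout: int = 5,
    max_steps: int = 200,
) -> dict:
    """Does the trained network beat its own TKD input on held-out data?

    Trains the tiny network for ``max_steps`` AdamW steps on patches
    from ``n_train`` phantoms, then compares masked normalized RMSE of
    the network reconstruction against that of the TKD pre-estimate on
    ``n_heldout`` unseen phantoms.
    """
    config = desk_phantom_config(seed)
    samples, index = build_dataset(config, n_train, DESK_PATCH)
    patches = prepare_patches(samples, index, DESK_PATCH)
    model = LCMnet(tiny_model_config(), seed=seed)
    model, history = train(model, patches, tiny_train_config(seed),
                           LossConfig(), max_steps=max_steps)

    heldout, _ = _heldout_samples(seed, n_heldout)
    rmse_tkd, rmse_net = [], []
    for s in heldout:
        kernel = build_dipole_kernel(s.field.geometry)
        chi_init = tkd_invert(s.field, kernel, TKDConfig(), mask=s.mask).data
        pred = reconstruct_volume(model, s.field.data, s.magnitude, chi_init,
                                  s.mask.data, patch_size=DESK_PATCH)
        rmse_tkd.append(rmse(chi_init, s.chi.data, s.mask.data))
        rmse_net.append(rmse(pred, s.chi.data, s.mask.data))
    return {
        "rmse_tkd": rmse_tkd,
        "rmse_net": rmse_net,
        "rmse_tkd_mean": float(np.mean(rmse_tkd)),
        "rmse_net_mean": float(np.mean(rmse_net)),
        "net_beats_tkd": bool(np.mean(rmse_net) < np.mean(rmse_tkd)),
        "loss_history": history,
    }


def chi_init_ablation_experiment(seed: int, n_train: int = 4) -> dict:
    """First-epoch mean loss: chi_init input versus field-map input.

    Trains the full tiny network and its variant with chi_init replaced
    by the field map for one epoch under identical seeds and budgets.
    """
    config = desk_phantom_config(seed)
    samples, index = build_dataset(config, n_train, DESK_PATCH)
    patches = prepare_patches(samples, index, DESK_PATCH)
    eval_patches = patches  # epoch-1 loss comparison only
    results = run_ablation_suite(
        patches, eval_patches, tiny_model_config(), tiny_train_config(seed, epochs=1),
        LossConfig(),
        variants={k: ABLATION_VARIANTS[k] for k in ("LCMnet", "LCMnet_deltaB")},
    )
    return {name: res["history"][0] for name, res in results.items()}


def simulator_distribution_check(seed: int, n_samples: int = 200, shape=(24, 24, 24)) -> dict:
    """Range and uniformity checks on the generator's random draws."""
    config = desk_phantom_config(seed, shape=shape)
    factors, values = [], []
    for i in range(n_samples):
        s = generate_sample(config, config.seed + i)
        factors.append(s.provenance["amplification_factor"])
        values.extend(src["value"] for src in s.provenance["sources"])
    factors = np.asarray(factors)
    values = np.asarray(values)
    lo, hi = config.amplification_range
    vlo, vhi = config.source_value_range
    return {
        "n_samples": n_samples,
        "factors_in_range": bool(np.all((factors >= lo) & (factors <= hi))),
        "values_in_range": bool(np.all((values >= vlo) & (values <= vhi))),
        "ks_p_amplification": float(
            stats.kstest(factors, "uniform", args=(lo, hi - lo)).pvalue
        ),
        "ks_p_source_values": float(
            stats.kstest(values, "uniform", args=(vlo, vhi - vlo)).pvalue
        ),
        "factor_min": float(factors.min()),
        "factor_max": float(factors.max()),
        "value_min": float(values.min()),
        "value_max": float(values.max()),
    }
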