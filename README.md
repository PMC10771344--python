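# lcmqsm

Dipole inversion and a latent-code modulated convolutional network for
quantitative susceptibility mapping (QSM).

## The problem

QSM reconstructs the tissue magnetic susceptibility distribution χ(r)
(in ppm) from the local magnetic field shift δB(r) measured by MRI
phase imaging. In k-space the two are related by a pointwise product
with the unit dipole kernel,

    δB(k) = D(k) · χ(k),      D(k) = 1/3 − (k·b̂)² / ‖k‖²,

where b̂ is the direction of the static field B0. D vanishes on a
double cone at the magic angle (cos²θ = 1/3, θ ≈ 54.7° from B0), so
single-orientation inversion is ill-posed: naive division amplifies
noise near the cone. This package implements, for researchers working
on learned QSM reconstruction:

* **dipole physics** — kernel construction for arbitrary B0 direction,
  the forward model, and COSMOS (multi-orientation least-squares
  inversion, the field's gold standard);
* **TKD** — thresholded k-space division, χ(k) = δB(k)/D(k) where
  |D(k)| > T and 0 elsewhere, the fast pre-estimate χ_int;
* **a phantom generator** — brain-like susceptibility maps with global
  linear amplification (factors in [1, 3]), spherical susceptibility
  sources in [−0.4, 0.4] ppm, forward-model fields with additive
  Gaussian noise, and co-registered magnitude images;
* **the reconstruction network** — an encoder chain over the field
  patch, a latent-code decoder with VOI-restricted global average
  pooling, a cross-fusion block merging field and magnitude features,
  and a modulated convolution module that starts from the TKD
  pre-estimate. The latent code L = {l_c} scales each input channel of
  a convolution kernel (w′ = l_c·w) and weight demodulation
  renormalizes each output filter (w″ = w′/√(Σw′² + ε)), letting the
  filters adapt to the intensity distribution of the input without
  destabilizing training. Ablation flags reproduce the variants with
  vanilla convolutions, without cross-fusion, and with the field map
  replacing χ_int;
* **training** — the loss ‖Ŷ−Y‖²_F + α‖f_LoG(Ŷ)−f_LoG(Y)‖²_F
  (mean-squared error plus a high-frequency error term through a
  Laplacian-of-Gaussian filter), optimized with AdamW (learning rate
  1e−4, weight decay 5e−4, 30 epochs, 64×64×32 patches by default).
  Inputs stay in physical ppm units — no per-volume normalization;
* **metrics** — PSNR, normalized RMSE (×100), mean SSIM and HFEN over
  the volume of interest, plus per-ROI mean/std reporting.

The network and its training run on a small numpy/numba reverse-mode
autodiff core inside the package (`lcmqsm.autodiff`); its gradients are
verified against central finite differences in the test suite.

## Worked example

Generate a synthetic sample, invert its field with TKD, and score the
result against the ground truth:

```python
import numpy as np
from lcmqsm import (GridGeometry, PhantomConfig, TKDConfig, build_dipole_kernel,
                    generate_sample, tkd_invert, evaluate, magic_angle_deg,
                    wellconditioned_fraction)

config = PhantomConfig(geometry=GridGeometry((32, 32, 32)), seed=7)
sample = generate_sample(config, 7)
kernel = build_dipole_kernel(config.geometry)
print(f"magic angle: {magic_angle_deg()} deg")
print(f"well-conditioned k-space fraction at T=0.2: "
      f"{wellconditioned_fraction(kernel, 0.2):.3f}")
chi_tkd = tkd_invert(sample.field, kernel, TKDConfig(threshold=0.2), mask=sample.mask)
report = evaluate(chi_tkd.data, sample.chi.data, sample.mask.data)
print(f"amplification factor drawn: {sample.provenance['amplification_factor']:.2f}")
print(f"TKD vs ground truth inside the VOI: RMSE {report.rmse:.1f}  "
      f"PSNR {report.psnr:.2f} dB  MSSIM {report.mssim:.3f}  HFEN {report.hfen:.1f}")
```

Output:

```
magic angle: 54.7 deg
well-conditioned k-space fraction at T=0.2: 0.528
amplification factor drawn: 1.03
TKD vs ground truth inside the VOI: RMSE 54.3  PSNR 21.21 dB  MSSIM 0.460  HFEN 51.5
```

The magic angle is where the dipole kernel vanishes; at threshold
T = 0.2 roughly half of k-space is retained by TKD, and the zeroed
cone is what drives the RMSE of ≈54 (on this scale 100 would mean "as
wrong as the zero map"). The network is trained to undo exactly this
residual error; on held-out phantoms its masked RMSE drops below the
TKD input's (see below).

A command-line interface mirrors the library
(`lcmqsm simulate | forward | tkd | cosmos | train | reconstruct |
evaluate | ablate`), reading and writing NIfTI volumes with YAML
configuration; run `lcmqsm <command> --help` for the options.

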