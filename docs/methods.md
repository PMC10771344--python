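# Methods

This note records the scientific and numerical choices behind the
package: the forward model and its discrete conventions, the network
design where the architecture was open, what the phantom generator does
and does not emulate, and the desk-scale study conditions used by the
tests and the acceptance script.

## Dipole physics

**Forward model.** The normalized field shift is δB(k) = D(k)·χ(k)
with D(k) = 1/3 − (k·b̂)²/‖k‖². Both χ and δB are in ppm, so the field
strength |B0| never enters the numerics. The frequency lattice is the
unshifted DFT grid (DC at index 0) in cycles/mm; only the direction of
k matters, so the frequency unit cancels in D.

**DC convention.** D is undefined at k = 0. The zero-frequency bin is
set to 0 (exposed as `dc_convention`): the mean susceptibility produces
no observable field shift, so it is taken as unobservable. A constant χ
therefore maps to a zero field.

**Boundary model.** Convolution is periodic (pure FFT, no padding).
The continuous model integrates over all space; a discrete
implementation must pick a boundary convention, and the circular one
matches the pointwise k-space product exactly. Tests that compare
against open-space dipole sums account for the first shell of periodic
images.

**Nyquist symmetrization.** On even-sized grids the Nyquist bins
represent ±0.5 cycles/voxel ambiguously. For an oblique B0 the raw
formula then yields D(k) ≠ D(−k) on Nyquist planes, which makes the
convolution operator complex (non-Hermitian spectrum) and breaks
self-adjointness and exact multi-orientation recovery. The kernel is
symmetrized over k → −k (the mean of the two sign choices) and clipped
to the analytic range [−2/3, 1/3]. For B0 along a grid axis the
symmetrization is a no-op.

**Known artifact.** Point-sampling the conical singularity of D(k)
leaves a slowly decaying discrepancy between the discrete Green's
function and the continuous dipole along the B0 axis (several percent
at 10–20 voxels, largely independent of zero padding); away from the
axis agreement with open-space dipole sums is at the 1–3% level. This
is a property of every FFT-based QSM forward model at finite
resolution, not of this implementation.

**COSMOS.** With orientations i = 1…n (n ≥ 2) the per-frequency normal
equations are scalar: χ(k) = Σᵢ Dᵢ(k)δBᵢ(k) / Σᵢ Dᵢ(k)². Bins whose
denominator falls below 1e−6 are zeroed — they are unobserved by every
orientation, and dividing by them would amplify noise exactly as in
single-orientation TKD. The default solver evaluates this closed form;
a conjugate-gradient mode solves the same system honoring
`max_iter`/`tol` (defaults 200 and 1e−5). Noiseless three-orientation
recovery on a 32³ phantom is exact to < 1e−4 relative RMS.

**TKD.** χ(k) = δB(k)/D(k) where |D(k)| > T, else 0. The default
threshold is T = 0.2, configurable in (0, 2/3); the boundary case
|D| = T is assigned 0 (the conservative choice — the bin is treated as
ill-conditioned). No amplitude-correction variant is applied: retained
bins are plain quotients. The output χ_int is masked by the VOI by
default (flag to disable), since it feeds a network whose contracts are
defined inside the VOI.

## Network

Feature maps are (channels, x, y, z); all convolutions are 3³, stride
1, zero same-padding, with leaky rectification (slope 0.1) and no
batch-dependent normalization — weight demodulation already stabilizes
the activation scale, and batch statistics would couple the output to
other samples and break the background-independence contract.

* **Field encoder**: n = 3 blocks (default) of one convolution each at
  full resolution produce {FB1…FBn}; two further encoder blocks with 2×
  average-pool downsampling produce the bottleneck Fd at 1/4 resolution
  with twice the base channel count. Patch dimensions must be multiples
  of 4.
* **Latent decoder**: the bottleneck is masked by the 4×-downsampled
  VOI (mean-pool then threshold at 0.5), convolved, average-pooled over
  the surviving VOI voxels only, and projected by one linear head per
  modulated block. Masking *before* the convolution makes the codes
  exactly independent of anything outside the VOI. Linear heads start
  at weight std 0.01 with unit bias, so modulation begins near the
  identity.
* **Cross-fusion**: the magnitude patch is multiplied by the VOI mask,
  passed through a two-convolution stack; each FBi is processed by a
  Conv3; all levels plus the magnitude features are concatenated and
  fused by a 1×1×1 convolution; per-level Conv3 heads emit {FBM1…FBMn}.
  The `no_fusion` variant routes each processed FBi through a
  same-capacity 1×1×1 + Conv3 path that never sees the magnitude.
* **Modulated convolution module**: three blocks (configurable 2–5).
  Block i convolves the running feature map with weights modulated per
  input channel by its latent code and demodulated per output channel
  (ε = 1e−8), concatenates the result with FBM_min(i, n−1) and merges
  with a Conv3. The chain starts from a one-convolution lift of χ_int
  (or of the field map under `field_as_initial_input`), and a final
  convolution maps to the single-channel susceptibility patch. χ_int is
  not added as an output residual by default (`chi_init_residual`
  enables it).

Unstated widths are implementation choices: 3 encoder levels, 32 base
channels at full scale. Where the interpretation of the demodulation
sum was open, it is per output channel over that channel's input
channels and spatial taps — the convention of the weight-demodulation
technique the operation derives from. The combination rule inside a
modulated block (concatenation + convolution) is likewise a documented
choice; the block's three inputs are fixed by the design.

**Autodiff core.** The network runs on a reverse-mode tape over numpy
arrays with numba-compiled convolution kernels (`lcmqsm.autodiff`).
Every operator's adjoint — including the gradient through the
demodulation normalization — is tested against central finite
differences at 1e−4 relative or better.

## Training

Loss = ‖M(Ŷ−Y)‖²_F + α‖f_LoG(MŶ) − f_LoG(MY)‖²_F with M the VOI mask
applied before both norms (background voxels are meaningless;
maskless operation is available). Defaults: α = 0.1 (the balance weight
is not prescribed anywhere; 0.1 keeps the two terms within an order of
magnitude on phantom data), LoG σ = 1.5 voxels on a 9³ support,
mean-subtracted so the stencil sums to exactly zero and annihilates
constants. The filter uses symmetric boundary padding and is applied
identically in the HFEN metric.

Optimization is AdamW — decoupled weight decay 5e−4, learning rate
1e−4, 30 epochs, 64×64×32 patches, batch 4 (batch size is a choice).
Patches come from a fixed regular grid with 50% overlap tiling each
sample's VOI bounding box; a random-crop mode is available. Patches
whose VOI vanishes at the pooled-mask resolution are dropped — the
latent decoder has nothing to pool there. Inputs are fed in physical
ppm units and never rescaled per volume: the field-to-susceptibility
mapping is quantitative, and per-volume normalization would erase the
scale information the latent modulation is designed to absorb.

Whole-volume inference tiles the volume with overlapping patches
blended under a separable cosine window.

## Phantom generator

Each sample is built in a fixed draw order from one seeded generator
(base brain, amplification, sources, field noise, magnitude bias), so a
config plus one integer seed regenerates it bit-identically.

* **Base brain**: ellipsoidal VOI (semi-axes 0.40/0.45/0.35 of the
  grid), a smooth background capped at |χ| ≤ 0.05 ppm, and 12 focal
  blob regions with values uniform in [−0.15, 0.15] ppm, emulating
  deep-gray-matter nuclei.
* **Amplification**: one global factor uniform in [1, 3].
* **Sources**: 8 spheres per volume, radii uniform in [2, 5] voxels,
  centers uniform among VOI voxels deep enough to contain the whole
  sphere, values uniform in [−0.4, 0.4] ppm. Sphere voxels are
  *overwritten*, not incremented — the stated value range is then the
  actual tissue value, and |χ| stays bounded.
* **Field**: dipole forward model plus i.i.d. Gaussian noise,
  σ = 0.005 ppm by default (the noise amplitude, source count and radii
  are not prescribed anywhere; these defaults give TKD inputs with
  realistic streaking without drowning the tissue signal).
* **Magnitude**: smooth tissue intensity around 0.65 whose contrast
  follows the χ structure, spheres rendered with sharp sign-dependent
  contrast (bright for paramagnetic, dark for diamagnetic — the
  T2*-weighted appearance of hemorrhage vs. calcification), a ±5%
  multiplicative bias field, clipped to [0, 1] and zero outside the
  VOI.

What it does **not** emulate: anatomically accurate brain geometry,
multi-echo complex MR signal formation, T2* decay, phase wrapping,
background fields, or registration error. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not performance on acquired brain data.

## Desk-scale study conditions

The training-dependent checks run a scaled-down configuration chosen
once (module `lcmqsm.experiments`): 32³ phantoms at generator defaults,
16³ patches, a 2-level / 8-channel network, 200 AdamW steps at batch 2,
10 training and 5 held-out samples, three seeds. The learning rate for
this short budget is 2e−3: Adam-style updates displace parameters by
roughly the learning rate per step, so a 200-step run needs on the
order of 1/steps to traverse order-one weight changes; the full-scale
default of 1e−4 belongs to the 30-epoch regime. Under these conditions
the trained network's held-out masked RMSE falls below that of its TKD
input, and the variant fed the raw field map instead of χ_int shows a
higher first-epoch mean loss than the full model — the qualitative
convergence benefit of susceptibility pre-estimation.

## Numerical notes and limitations

* Metric formulas are this package's definitions (normalized ×100 RMSE
  and HFEN, range-based PSNR capped at 120 dB for identical inputs,
  SSIM with a 7³ uniform window and unbiased covariance); scores are
  comparable within the package only.
* The COSMOS denominator floor (1e−6), the TKD equality convention, the
  0.5 pooled-mask threshold and the ε in demodulation are the tie-break
  and degenerate-input rules; each is asserted by a test.
* Seeded runs are reproducible bit-for-bit on a fixed platform; across
  platforms, floating-point reassociation in the compiled convolution
  kernels may change results at machine precision.
* Training at the full-scale defaults (32 base channels, 64×64×32
  patches, 30 epochs) is supported by the same code paths but is
  CPU-intensive; the shipped experiments use the desk-scale conditions
  above.
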