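# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `petcycle`. It is the package's own account of its
science; every number quoted here is computed by the test suite or the
worked example, not asserted from elsewhere.

## Recovery model

The core is a supervised cycle-consistent adversarial model for paired
low-dose (LD, domain A) / full-dose (FD, domain B) PET patches:

    L = L_adv + α·L_cyclic + β·L_identity + γ·L_sup,   α=10, β=5, γ=5

* **Adversarial term.** Each direction contributes a Wasserstein gap
  −E[D(real)] + E[D(fake)] plus the gradient penalty
  λ·E[(‖∇_ỹ D(ỹ)‖₂ − 1)²], λ=10, at interpolates ỹ = εx_real + (1−ε)x_fake,
  ε ~ U(0,1) per sample. The two directions are averaged with factor ½.
  The penalty is applied to the critic being optimized in each direction
  (the obvious reading in which the penalty constrains its own critic);
  the generator's adversarial objective is the negated fake-score term,
  which the model formulation leaves implicit.
* **Cycle/identity/supervised terms** are plain L1 means, computed exactly
  as written; the supervised term exists because training pairs are
  co-located by construction.
* **Ablation.** γ=0 removes the supervised term *from the computation*:
  the loss history then carries no `sup` component at all, giving the
  plain cycle-consistent adversarial baseline. β=0 similarly drops the
  identity term.

### Architectures

The generator follows the dense-residual layout: 2 stem convs (3×3, 64
filters), 6 residual modules of 3 × (conv → batch norm → ReLU) with an
additive skip and post-skip ReLU, concatenation of the six module inputs
plus the last module output (the alternative fan-in that also concatenates
the raw input sits behind `GeneratorSpec.include_raw_input_in_concat`),
two 64-filter fusion convs, and a final 3×3 conv joined by an end-to-end
additive bypass and a closing ReLU. Unit stride and symmetric zero padding
preserve spatial size, so whole slices of any H×W pass through at
inference. The closing ReLU guarantees non-negative activity outputs.

The critic is 4 × (4×4 stride-2 conv, leaky-ReLU 0.2) with 64/128/256/512
filters, then dense 1024 → dense 1 with no squashing. The critic has **no
batch normalization**: the gradient penalty is a per-sample constraint and
batch statistics would couple samples (standard practice for
gradient-penalized Wasserstein critics).

Batch normalization in the generator always uses the statistics of the
tensor being processed (no running averages); single-slice inference
therefore behaves like instance normalization. This keeps training and
inference code identical and is adequate at the batch sizes used here.

### Initialization

Weights are Gaussian with fan-in scaling, std = sqrt(2/fan_in), except the
final generator conv which is near-zero (std 1e-3) so the end-to-end
bypass makes the initial generator approximately the identity map. A fixed
small std (the DCGAN-style 0.02) was tried first and rejected: with 3×3×64
fan-ins it shrinks stem activations to ~1e-4 while the in-module batch
norms re-amplify them by ~1e5, and gradient quality collapses — training
runs measurably never left the identity map. Fan-in scaling keeps
activation variance roughly constant through the rectified stack.

### Optimization

Adam (β₁=0.5, β₂=0.999), learning rate 2e-4, batch 16, up to 200 epochs
with early stopping when the validation criterion has not improved for 5
consecutive epochs; the checkpoint returned is always the best epoch's.
The validation criterion is the supervised L1 on validation pairs — the
only loss component that directly measures recovery fidelity; it is also
what a γ=0 ablation run is validated on (as a metric, not a loss).
Critic and generators alternate per batch; `critic_steps_per_gen_step`
(default 1, the cycle-GAN convention) exposes the 5-step variant common
for gradient-penalized critics. Training is bit-reproducible given
(seed, config, dataset): per-epoch shuffles and per-step penalty draws all
derive from the master seed.

### NumPy autodiff engine

No deep-learning framework is used. `petcycle.autodiff` is a tape-based
reverse-mode engine over float64 NumPy arrays whose primitive VJPs are
themselves traced, so gradients are graph nodes and second derivatives
work — this is what makes the gradient penalty differentiable with respect
to critic weights during critic updates. Convolution is im2col/col2im (an
exactly adjoint linear pair) plus 2-D matmul. The engine is validated
against central finite differences, including a second-order check of the
penalty pathway.

## Phantom simulator

The simulator replaces a full Monte Carlo chain with the minimal physics
that distinguishes LD from FD images — count statistics:

1. **Truth phantom.** An ellipsoidal head support (semi-axes 0.45·n_x,
   0.45·n_y, 0.48·n_z voxels) at a uniform 30 kBq/ml background, with
   spherical lesions rendered at the equivalent-sphere diameter
   d = (6V/π)^(1/3) of their nominal volume. The bundled reference lesion
   table provides five lesions × three sizes (213–2018.9 mm³) on a
   192×192×96 grid of 2.1 mm voxels, with activity levels 45.23–274.47
   kBq/ml; size variants sharing a center are offset ±8 slices to keep
   them disjoint. Lesion masks double as ground-truth VOIs.
2. **Projection.** A 2-D parallel-beam line-integral projector applied
   slice-wise: each pixel center's detector coordinate is split linearly
   between two radial bins, making forward projection and backprojection
   an exactly adjoint sparse pair. Expected counts are normalized to a
   full-dose budget (default 2e5 per 192² slice; 4000 per 16² slice in the
   scaled-down tests) and realized as independent Poisson draws.
3. **Dose thinning.** Every event is kept independently with probability
   equal to the dose fraction (binomial thinning per bin), applied to the
   *same* full-dose realization — the statistical equivalent of discarding
   list-mode events, and the reason LD/FD pairs are aligned by
   construction. Thinning a Poisson(λ) count yields Poisson(fλ) exactly.
4. **Reconstruction.** MLEM (default 20 iterations, no post-filter), whose
   multiplicative update preserves non-negativity; with the exactly
   adjoint projector pair the sensitivity-weighted image total matches the
   measured counts after every update. Reconstructions are returned in
   kBq/ml using the known per-slice count-to-activity scale (for LD,
   including the dose fraction — the analogue of clinical dose
   correction).

**What the simulator does not model:** attenuation, scatter, randoms,
dead time, detector blur, 3-D (oblique) lines of response, time of flight,
or anatomical background texture. Passing tests therefore demonstrate the
statistical mechanism (noise grows as counts shrink; recovery reduces that
noise) and the full computational pipeline — not clinical image quality.
Absolute NRMSE/SSIM values on phantoms are not comparable to clinical
values.

## Patch pipeline

56×56 patches at sliding step 40, anchors {0, 40, 80, …} with
anchor+56 ≤ dimension and no edge-flush patches; on a 192×192 slice this
gives 4×4 = 16 patches, 1536 per 96-slice volume, and reproduces the
reference training/validation set sizes (89 volumes → 136 704 patches,
10 → 15 360). Each LD/FD volume pair is scaled **jointly** by max(FD):
per-image scaling would put the two domains on different intensity scales
and destroy the SUV comparability the evaluation relies on. The FD volume
lands exactly in [0,1]; LD noise peaks may slightly exceed 1. The
recorded factor maps recovered images back to kBq/ml. Empty slices are
retained (`drop_empty` exists but is off — no exclusion rule is part of
the standard protocol).

## Evaluation

* NRMSE = 100·sqrt(Σ(x−y)²/Σy²), in percent.
* PSNR = 10·log10(MAX²/MSE) dB with MAX the reference peak. The variant
  20·log10(MAX/MSE) seen in some reports is available behind
  `paper_formula=True`; the standard form is the default because the
  printed variant is dimensionally inconsistent with its own definition of
  MSE as a plain mean square error. Identical images report a finite
  sentinel (999.99 dB).
* SSIM uses an 11×11 Gaussian window (σ=1.5), C1=(0.01L)², C2=(0.03L)²
  with L the reference dynamic range (delegated to scikit-image with
  exactly these constants).
* SUV = r/(a′/w); SUV_mean/SUV_max are taken over ground-truth lesion
  masks (on clinical data VOI delineation would be a manual step; the
  simulator's masks are the only implementable choice here). Relative
  errors RE = 100·(model − ref)/ref are signed, referenced to the FD
  reconstruction (the clinically observable reference); truth-referenced
  errors are reported alongside as a simulator-only extra. Aggregates are
  bias ± sample s.d. (n−1) per group. Default metadata when a scan
  carries none: a′ = 370 810 kBq, w = 70 000 g (a mid-range adult at the
  mean injected activity).

## Scaled-down study conditions

The test suite exercises training at desk scale: 16×16×8 phantoms with one
central 310 mm³ lesion at 91.12 kBq/ml, 24 projection angles, 4000
full-dose counts per slice, 10 % dose, reduced networks (generator 8
filters / 2 modules; critic 8–64 filters / 64 dense units), learning rate
2e-3, batch 4, whole slices as 16×16 patches.

One deviation from the clinical configuration is deliberate and analysis-
driven: the recovery smoke runs use loss weights α=1, β=1, γ=5 (λ=10, all
four terms active) instead of α=10, β=5. At the identity map the L1 cycle
and identity terms have full subgradient slope against any denoising
perturbation (a denoised output cannot be cycled back onto its own noise),
so denoising only pays once γ·c > α+β for a sign-agreement fraction c < 1.
With the clinical weighting (α+β = 15 > γ = 5) a short desk-scale run is
pinned at identity — observed exactly, over hundreds of steps — and
escapes only through a mature critic, i.e. GPU-scale adversarial training.
The clinical weighting therefore remains the package default, and the
desk-scale weighting is the documented configuration under which the
5-epoch smoke training demonstrably denoises (held-out slice NRMSE vs
truth drops well below the low-dose input's in the majority of seeds).

## Known limitations

* 2-D slice-wise projection and recovery; no 3-D convolutions or
  cross-slice context.
* The critic's dense head fixes its input patch size per instance
  (generators are size-agnostic).
* MLEM with an approximate point-sampled projector at small grids leaves
  residual discretization error; reconstructions of small phantoms retain
  visible bias at lesion edges (partial-volume effect), which the
  SUV-vs-truth errors quantify.
* Learned-perceptual metrics (LPIPS) are out of scope: they require
  pretrained perceptual weights.
* float64 NumPy training is desk-scale: suitable for the bundled smoke
  configurations, not for 56×56×136k-patch clinical training runs.
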