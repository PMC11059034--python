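# Methods

This note documents the models and numerical procedures implemented in
`uswinct`, the defaults they use, and what the desk-scale experiments do and
do not demonstrate.

## Problem setting

Cardiac CT suffers motion blur because the heart beats during the gantry
rotation. Restricting the reconstruction to a limited angular range shortens
the effective scan window — the nominal temporal resolution is
`rotation_time * range/360` (117 ms for a 120° window of a 350 ms rotation) —
at the price of severe directional streak and shading artifacts, because the
measurement `g = A f + ε` no longer determines `f`. The package implements
the full chain: simulate the moving object, reconstruct with limited-angle
FBP, and train a hybrid U-Net/Swin-transformer network to map the
artifact-ridden image to its full-view motionless counterpart.

## Dynamic phantom

A phantom is a list of ellipses painted in order over an air background
(−1000 HU), which yields piecewise-constant organ maps. "Beating" is modelled
by scaling each ellipse's semi-axes with `1 + a·sin(2π(phase + offset))`;
amplitude `a = 0` gives a static component. The default cardiac template has
a soft-tissue body, two lungs, a spine, a beating heart (a = 0.08) and a
small contrast-filled vessel (a = 0.12, phase-offset 0.1). The amplitudes are
free parameters chosen to produce visible blur over a 350 ms scan with a 1 s
heart period; no quantitative amplitude is prescribed by the study design the
generator emulates. Patients are seeded jitters of the template geometry and
"slices" are smaller jitters (≈0.5 % of the field of view) of a patient,
since a 2-D pipeline has no z-axis.

What the generator does **not** emulate: anatomical realism, respiratory
motion, polychromatic spectra, detector physics and transmission (Poisson)
noise. Passing tests therefore demonstrate that the algorithms behave
correctly on piecewise-constant moving objects under the stated acquisition
model, not that the trained network transfers to clinical data.

## Fan-beam projection

Flat equispaced detector, source on a circle of radius 540 mm, source-to-
detector 950 mm. HU converts to linear attenuation as
`μ = μ_water(1 + HU/1000)` with `μ_water = 0.02/mm`. Line integrals are
computed by sampling each source→detector ray at half-pixel steps with
bilinear interpolation; the backprojector scatters through exactly the same
weights, so the adjoint identity `⟨Ax, y⟩ = ⟨x, Aᵀy⟩` holds to machine
precision (verified in the tests) — the property SART's convergence relies
on. Motion is sampled piecewise-constant in time: one object snapshot per
view at that view's acquisition time. Noise ε is i.i.d. Gaussian on the line
integrals. Geometry construction verifies that the detector fan covers the
field-of-view circle. Angles are degrees, 0° along +x, counter-clockwise;
limited ranges are half-open `[start, start+range)` with modular wrap.

## Reconstruction

**FBP** uses the standard equal-spaced fan-beam formulation: cosine
pre-weighting `SID/√(SID²+s²)` on the virtual detector through the
isocenter, ramp filtering per row in the Fourier domain on rows zero-padded
to the next power of two (the frequency response is the FFT of the discrete
spatial Ram-Lak kernel, avoiding DC bias; Shepp-Logan and Hamming windows
multiply it), and pixel-driven backprojection weighted by `SID²/L²` and the
angular increment, halved because a full 360° fan scan measures every line
twice. Limited-angle data are reconstructed with the same formula over the
valid views only — no short-scan weighting — so the artifacts the network is
trained to remove are exactly the plain-FBP ones.

**SART** iterates `x ← x + λ·Aᵀ((g − Ax)/A1)/(Aᵀ1)` over the valid views,
using the matched projector pair; λ defaults to 1 and must lie in (0, 2].
**SART-TV** interleaves each SART pass with steepest-descent steps on the
smoothed isotropic total variation `Σ√(∇x² + ∇y² + ε)` (ε = 1e-8), the
adaptive-POCS pattern: the step length is `tv_step` (default 0.2) times the
magnitude of the preceding data update, with backtracking halving so that no
TV sub-step can increase the TV. Defaults (10 SART iterations, 20 TV steps
per pass) are config-exposed; with `tv_iterations_per_sart = 0` SART-TV is
bit-for-bit SART.

## The U-Swin network

Composition (all convolutions 3×3, stride 1, zero-padded):

    I_out = Conv¹( UST_n(…UST₁(Conv^C(I_LA))) + Conv^C(I_LA) )
    f_out = Conv( U(f_in) + ST_k(…ST₁(f_in)) ) + f_in            (UST block)
    X = MSA(LN(X)) + X ;  X = MLP(LN(X)) + X                      (ST layer)
    Attention(Q,K,V) = SoftMax(QKᵀ/√d + B)V,  Q=XP_q, K=XP_k, V=XP_v

Attention operates on per-pixel tokens of the C-channel feature map inside
non-overlapping M×M windows (the restoration convention — the network must
stay full-resolution, so there is no patch-embedding downsample; the
"patch size 8" of the original design is read as window size M = 8). Odd
layers cyclically shift the feature by M/2 in both axes before partitioning
and unshift after, with an additive −1e9 mask blocking attention across the
wrapped boundary. B is a learned relative-position-bias table of (2M−1)²
scalars per head, indexed into an M²×M² matrix, so the bias depends only on
the query−key offset. The MLP is two linear layers with a GELU between them
(hidden width `mlp_ratio·C`, default 2.0 — the light-weight restoration
setting; the one mention of ReLU in the source description is treated as an
inconsistency and GELU is used throughout the transformer path, with ReLU in
the convolutional U-Net branch where it is conventional).

The U-Net branch has `unet_depth` scales (default 2): stride-2 convolutions
doubling channels on the way down, a bottleneck convolution, and
nearest-neighbour ×2 upsampling with skip concatenations on the way up,
re-projected to C channels. Inputs are reflect-padded to the least common
multiple of M and 2^depth and cropped after.

Flags and their meaning:

- `use_unet_branch` / `use_transformer_branch` — drop one parallel branch of
  every UST block (at least one must remain).
- `use_long_skip` — the "skip connection" ablation: removes the long
  residual around the UST stack **and** the U-Net encoder-decoder
  concatenations (with their fusion convolutions), so the ablated model has
  strictly fewer parameters, matching how the skip-connection study varies
  model capacity.
- `predict_residual` — adds the input image to the network output, so the
  network predicts an image-domain correction. Off by default (the
  composition above ends at Conv¹); the source description is ambiguous on
  this point, stating both the composition equation and that the network
  "learns the difference" between label and input.
- `zero_init_residual_paths` — zero-initializes the MSA output projection,
  the second MLP layer, the UST fusion convolution, the U-Net output
  convolution and the final 1-channel head, making every block (and, with
  `predict_residual`, the whole network) an exact identity map at
  initialization. Used by the identity tests; off for training.

Presets mirror the published size family: U-Swin1 (1 UST × 1 ST), Light
(2 × 1), Small (C=30, 3 × 3, 6 heads), Large (C=60, 6 × 6, 6 heads). The
channel width of U-Swin1/Light is not prescribed anywhere; C=24 with 6 heads
was chosen so the family's parameter ordering U-Swin1 < Small < Large holds
structurally. Weight init is truncated normal (σ=0.02, clipped at 2σ) for
projections and fan-in normal for convolutions, all drawn from the config
seed, so two builds at one seed are bit-identical.

Intensities: the HU window [−1000, 2000] maps affinely (and clipped) to
[0, 1] for network input, loss and metrics; reconstruction and storage stay
in full-range HU.

### Autodiff backend

The network runs on a small reverse-mode automatic-differentiation engine
over float64 NumPy arrays (`uswinct.autodiff`): broadcast arithmetic,
batched matmul, im2col convolution, window/shift reshapes, softmax, GELU,
an index-gather for the bias table, and Adam. Every operation's gradient is
validated against central finite differences in the test suite. The engine
favours correctness and determinism over speed, which is adequate at the
image sizes the package trains on (≈1 s per optimizer step for the U-Swin1
preset at 64×64 on one CPU core).

## Training and evaluation

A training pair is (FBP of the angle-restricted sinogram of the *moving*
phantom, FBP of the full-view sinogram of the *frozen* phantom at the same
phase), both normalized. Training minimizes the mean square loss
`(1/N)‖I_out − I_FV‖²_F` with Adam at batch size 1, shuffling each epoch
under the run seed; the reference settings are 100 epochs at learning rate
1e-5, and every field is overridable. Cross-validation folds partition
*patients* (seeded), so no patient appears on both sides of a split.

Metrics: RMSE on normalized intensities; SSIM in two modes — `standard` is
the sliding-Gaussian-window SSIM (scikit-image, σ=1.5, C₁=(0.01)², C₂=(0.03)²
at L=1) and `paper_global` evaluates the global-moment SSIM once over the
whole image (some studies report the global variant; both return 1 for
identical images). The noise power spectrum is
`log(|FFT₂(img − ref)|² + 1e-12)`, unnormalized and zero-frequency centered;
radial averaging over half-open annuli covering [0, Nyquist] yields the
frequency profile, with empty annuli marked missing rather than zero.

## Desk-scale experiment sizes

The package's own reference experiment (used by the test suite and by
`scripts/acceptance.py`) simulates 4 patients × 3 phases at 64×64 pixels
with a 180-view, 128-detector geometry, holds out one patient, and trains
the U-Swin1 preset for 200 Adam steps at learning rate 1e-3 with
`predict_residual` on. Residual learning is the appropriate regime at this
step budget: the network starts near the identity and learns the artifact
correction, rather than having to re-synthesize the whole image; it is also
one of the two readings of the ambiguous design discussed above. Typical
results at seed 1: training loss falls by ~99 %, held-out RMSE improves from
0.128 (limited-angle FBP input) to 0.029, SSIM from 0.54 to 0.88. These
numbers establish the *direction* of the full-scale findings (a hybrid
restorer substantially improves limited-angle inputs on held-out patients);
they are not comparable in magnitude to results obtained with hours of GPU
training on thousands of 256×256 images.

## Known limitations

- 2-D fan beam only; no cone-beam/FDK, no scatter, no polychromatic physics.
- Gaussian noise on line integrals stands in for transmission noise.
- The SART-TV hyperparameters are conventional defaults, not tuned to match
  any published iterative-reconstruction figure.
- The NumPy training backend is single-core; the Large preset is
  constructable and testable but impractical to train here.
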