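# Methods

`penreg` registers co-temporal frames from two fixed, tilted cameras
overlooking the same livestock pen. One view is declared *fixed* (I_f),
the other *moving* (I_m); the goal is a dense map carrying every moving
pixel onto its fixed-frame counterpart so that downstream tracking and
behaviour analysis can fuse the two viewpoints. This note records the
model, its assumptions, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Pipeline

1. **Preprocessing** — radial lens undistortion, pen masking, grayscale
   conversion (`penreg.preprocess`).
2. **Projective pre-registration** — a single homography per pen,
   estimated from ~35 hand-placed landmark pairs on one frame pair and
   applied to all frames of that pen (`penreg.homography`).
3. **Deformable refinement** — a convolutional network predicts a dense
   displacement field for each pre-registered pair; trained unsupervised
   on many unlabeled pairs, then fine-tuned semi-supervisedly on a few
   annotated pairs (`penreg.nn`, `penreg.train`).
4. **Evaluation** — landmark target registration error (TRE) with a
   foreground/background breakdown and a paired statistical comparison
   protocol (`penreg.evaluate`).

## Lens model

Radial distortion follows the even-order polynomial on normalized
coordinates x = (p − c)/s:

    x_d = x · (1 + k1 r² + k2 r⁴ + k3 r⁶),   r² = ‖x‖².

Only k1, k2 are normally calibrated; k3 defaults to 0. The
normalization (principal point `center` and focal-equivalent `scale`,
both in pixels) is part of the model because coefficients are meaningless
without it. Undistortion inverts the polynomial by fixed-point iteration
on the radial factor (tol 1e−9 in normalized units, ≤ 20 iterations) and
reports the worst residual on failure; the iteration converges whenever
the radial polynomial is monotone over the observed radii, which holds
for all realistic coefficient magnitudes. Coefficients enter via JSON
config — checkerboard calibration is upstream of this package.

Throughout the repository: x = column, y = row, 0-based, pixel centers at
integer coordinates, intensities in [0, 1]. Grayscale conversion uses
ITU-R BT.601 luma weights (0.299, 0.587, 0.114). Resampling anywhere
outside a source frame fills 0.

## Projective stage

The homography (moving → fixed) is estimated by the normalized DLT:
Hartley normalization of both point sets (centroid to origin, mean
distance √2), SVD null vector of the 2n×9 design matrix, de-normalization,
and scaling so H₃₃ = 1. Over-determined sets are solved in algebraic
least squares without a robust loop — the correspondences are manual and
assumed outlier-free. A configuration whose design matrix has a
near-zero eighth singular value (collinear/degenerate points) is
rejected. Image warping is backward: each output pixel samples the input
at H⁻¹(p) bilinearly. Pre-registration landmarks must be disjoint from
evaluation landmarks; the CLI takes them from separate files.

## Deformable stage

### Energy

For a pre-registered pair the network output Φ (H×W×2, pixels) is scored
by

    L = M(I_f, I_m ∘ (id + Φ)) + λ · R̄(Φ)            (unsupervised)
    L_semi = L + μ · (1/k) Σ_j ‖p_f,j − p′_j‖²        (semi-supervised)

where M is one of MSE (default), 1−NCC, or SSD; R̄ is the diffusion
regularizer — the sum over the grid of squared forward-difference
gradients of both displacement channels — divided by the pixel count.
Entering the regularizer as a per-pixel mean keeps λ commensurate with
the (mean) similarity term and independent of frame size, so one default
(λ = 0.01) serves 64×64 experiments and full-resolution frames alike;
the standalone `diffusion_regularizer` function returns the raw sum.
NCC is affine-invariant in intensity, which is what makes it an
interesting alternative under between-view illumination differences; it
is minimized as 1 − NCC, a monotone negation of maximizing it. SSD is
the sum (= n·MSE), so its gradients are n times larger — its loss-weight
semantics differ accordingly. Defaults λ = 0.01, μ = 1 are package
conventions; no reference values exist for them. Losses are computed
over the full frame by default (inputs are masked, losses are not); an
optional mask restricts the average.

### Warping semantics

The field is a **backward** warp — the standard spatial-transformer
convention: output(p) = I_m(p + Φ(p)), bilinearly sampled, zero fill
outside the frame. The warp is differentiable in both the image and the
field (the bilinear kernel is piecewise linear; its a.e. derivative is
used).

Because Φ lives on the fixed grid, carrying a *moving*-image landmark
into the fixed frame requires inverting p ↦ p + Φ(p):

* **Training** uses an unrolled damped fixed-point transfer: 4 explicit
  iterations p′ ← p′ − ½(p′ + Φ(p′) − p), each a bilinear field sample,
  so the composition is exactly differentiable — backpropagation walks
  the iterates in reverse, scattering onto the field at each iterate and
  carrying the 2×2 chain factor built from the field's spatial Jacobian.
  One step with damping 1 recovers the classic first-order transfer
  p′ ≈ p − Φ(p); that cheaper variant is biased against the exact
  inverse at sub-pixel accuracy (it optimizes a slightly different
  target), which is measurable once registration errors approach 1 px —
  hence the unrolled default.
* **Evaluation** uses the exact inverse, consistent with the image warp:
  damped fixed-point iteration p′ ← p′ − ½(p′ + Φ(p′) − p) (converges
  wherever the Jacobian eigenvalues of Φ exceed −1, i.e. wherever the
  map does not fold), with a grid-argmin restart plus Newton polish for
  locally steep fields. Non-convergence raises by default; evaluation
  paths instead score the nearest pre-image (`strict=False`), so a bad
  registration is measured as a large TRE rather than aborting a report.

### Network

A U-Net-style encoder–decoder maps the 2-channel (fixed, moving) stack to
the 2-channel field. Per level: 3×3 same-padded conv + leaky-ReLU
(slope 0.2); 2×2 max pooling between encoder levels; 2×2 stride-2
deconvolution upsampling; skip concatenation of encoder features, with
instance normalization (ε = 1e−5, no learned affine) on the skip path;
a final 1×1 conv with exactly 2 channels. The final layer is **linear**:
displacements are signed, so a non-negative activation there would be a
structural error. Weights use Kaiming initialization matched to the
leaky-ReLU slope, seeded — the same (config, seed) builds bit-identical
parameters. An optional residual block (a second 3×3 conv with identity
shortcut) can be enabled per encoder level.

Two profiles ship: the full-scale profile (5 levels, filters
32/64/128/256/512, input 928×1408 — exercised structurally, not trained
in the tests) and the desk-scale profile (3 levels, filters 8/16/32,
input 64×64, float32, residual blocks on). Residual blocks are enabled
at desk scale because the full-scale design is described with residual
connections and, at this size, the extra conv measurably lowers the
training-loss floor for the same schedule.

The network is implemented directly in NumPy with analytic
backpropagation for every layer (im2col convolutions, pooling argmax
scatter, instance-norm chain rule, bilinear-warp vector-Jacobian
products). Gradient correctness of the composed losses — through the
warp and the landmark layer — is pinned against central finite
differences at 1e−4 relative tolerance in the test-suite. Inference and
training are single-threaded-deterministic: seeded runs reproduce loss
traces and parameter checksums bit-for-bit.

There is no explicit bound on ‖Φ‖; the receptive field of the network
implicitly limits useful displacements. A configurable hard clamp
(`field_clamp`) exists and defaults to off.

### Training

Adam (β = 0.9/0.999, ε = 1e−8), minibatch 4, epoch-shuffled batches from
a seeded generator. Learning rate is constant until `decay_start_epoch`,
then decays linearly to 0 at the last epoch. Reference full-scale
schedule: lr 1e−4, 200 epochs, decay from 100. Desk-scale schedule:
lr 2e−3, 50 epochs, decay from 25 — 2e−3 chosen over 1e−3/3e−3 as the
rate that reliably reaches the training-loss floor within the short
schedule. Fine-tuning transfers all parameters into the semi-supervised
network (identical topology, verified by checksum), then updates **all**
layers (no freezing) at the reference lr 1e−4 under L_semi. Landmark
coordinates feed only the loss term, not the network input. With μ = 0,
fine-tuning reduces exactly to continued unsupervised training (the
traces coincide bit-for-bit for the same seed).

**Validated fine-tuning.** Continuing training on a handful of annotated
pairs is a double-edged sword: when the warm start is already near its
accuracy floor, any further updates on so small a set — even with μ = 0 —
drift the representation and can degrade held-out accuracy. The
recommended stage-2 entry point (`fine_tune_validated`, used by the
benchmark and the Model facade) therefore holds out half of the
annotated pairs as an internal validation set, scores validation TRE
(with the exact landmark transfer) after every epoch with the warm start
itself as a candidate, and adopts a fine-tuned epoch **only if** its
mean validation improvement exceeds twice the standard error of the
per-pair improvements. Absent that evidence the warm-start parameters
are returned bit-identical. No test data is ever consulted. At desk
scale the gate frequently keeps the warm start — the expected outcome
when stage 1 already saturates — while real improvements (an underfit
stage 1) are retained. The plain `fine_tune` (all annotated pairs, no
selection) remains available.

## Evaluation

TRE aggregates per-landmark distances between fixed landmarks and the
mapped moving landmarks. The default is the plain Euclidean mean in
pixels — the scale on which registration errors are conventionally
quoted — with a squared-distance variant available; every report records
which convention it used. Overall TRE pools all landmarks across pairs;
the per-pair list is kept for the paired tests. Foreground (animal) and
background (pen structure) landmarks are averaged separately; an empty
category reports as absent, never 0.

Method comparison: Shapiro–Wilk on each per-pair TRE sample; if both
p > 0.05, a paired t-test, otherwise the Wilcoxon signed-rank test. A
constant sample is treated as non-normal; all-zero paired differences
make the signed-rank statistic undefined and are reported as p = 1 with
a warning. p-values are raw — no multiple-testing correction.

## Synthetic scenes

`penreg.simulate` generates what the evaluation needs and the farm data
cannot provide offline: exact ground truth. A scene is a dark textured
floor (smoothed Gaussian noise, mean 0.22, sd 0.06) with `n_animals`
(default 10, a typical pen occupancy) brighter soft-edged textured
ellipses placed without overlap. The moving view applies, in order: a
smooth residual deformation, a random homography (corner jitter, default
8 px), an affine illumination change (gain 1 ± 0.1, bias ± 0.05), and
additive Gaussian noise (σ = 0.01). Landmarks — 3 on blobs, 3 on the
floor per pair — are carried exactly through the known transforms.

The ground-truth residual is the *backward* field Φ* a perfect network
should output: the moving view is synthesized by resampling the fixed
scene through the numerically inverted map (id + Φ*)⁻¹, so
warp(moving, Φ*) reproduces the fixed image and a fixed landmark p
appears in the moving view at p + Φ*(p), with self-consistency below
0.5 px by construction. Residual fields are bicubically interpolated
coarse grids (default spacing 16 px, amplitude rescaled to the requested
maximum, default 6 px). All randomness in a pair derives from one seed
via `SeedSequence` spawning; datasets written to disk are byte-reproducible.

What the generator does **not** emulate: perspective-dependent occlusion
between animals, specular lighting, motion blur, depth-dependent
parallax (the true residual of a two-camera rig is depth-structured, not
a random smooth field), and pre-registration error (the generator's
"pre-registered" view undoes the true homography exactly). Passing the
synthetic study therefore shows that the estimator, losses, optimization
and evaluation machinery work and interlock correctly — not that the
trained desk-scale weights transfer to farm footage.

## Reference study and observed behaviour

The packaged study (`penreg.benchmark.run_synthetic_benchmark`, also run
by `scripts/acceptance.py`) trains on 200 unlabeled 64×64 pairs with
6 px residuals for 50 epochs (MSE, λ = 0.01), fine-tunes on 10 annotated
pairs, trains the from-scratch semi-supervised ablation on the same 10,
and evaluates all rungs on 10 held-out annotated pairs. Problem sizes
were set so the whole study runs in minutes on one CPU core. Typical
behaviour at these conditions: unsupervised training cuts held-out TRE
by roughly half or more relative to pre-registration; fine-tuning is at
least as good as unsupervised; the from-scratch semi-supervised network
— 10 pairs of supervision, no transfer — is the worst of the learned
rungs. Exact numbers for a given seed are computed, not quoted: see the
README's worked example and `results/acceptance.json`.

## Known limitations

* No diffeomorphic guarantee: nothing prevents a predicted field from
  folding; evaluation then scores the nearest pre-image.
* Landmark transfer during training is a 4-step unrolled inversion; for
  fields with strong local gradients it can still lag the fully
  converged inverse used at evaluation time.
* With few annotated pairs, the fine-tuning evidence gate is
  conservative: genuine but small improvements (below its noise
  threshold) are discarded along with the harmful updates.
* The NumPy implementation is CPU-bound and practical at desk scale; the
  full-resolution profile builds and runs forward passes but is not a
  realistic training target on one core.
* Tangential/fisheye distortion, automatic calibration, SURF/intensity
  baselines, multi-resolution warping and 3D fields are out of scope;
  externally computed landmark mappings can still be compared via the
  evaluation CSV hooks.
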