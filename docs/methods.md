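# Methods

## Problem setting and model

White matter hyperintensity (WMH) annotations are noisy where lesion
boundaries are ambiguous — predominantly for deep lesions with blurry
edges — while a single rater's label is usually all that exists per
image.  A high-capacity segmentation network trained on every pixel of
such a label overfits the noise.  `saen` treats the problem in two
stages:

**Stage 1 — aleatoric (annotation) uncertainty.**  A 2D U-Net with
Monte-Carlo dropout approximates a Bayesian predictive distribution.
Dropout layers (Bernoulli drop probability θ) sit immediately before
each of the `depth − 1` max-pooling operators and immediately after each
of the `depth − 1` up-convolutions.  After full-supervision training,
the network is run `T` times on each training image with dropout still
active.  With `p_t` the foreground softmax map of draw `t`:

- mean probability: `Mean = (1/T) Σ_t p_t`
- probability variation: `U_raw = sqrt( (1/T) Σ_t p_t² − Mean² )`,

i.e. the *population* (divide-by-T) per-pixel SD of the foreground
probability.  For binary segmentation this is the diagonal element of
the predictive covariance of the softmax vector; the off-diagonal
carries no extra information, so the scalar SD is used.  Pixels where
every draw agrees get exactly 0 (enforced, not left to floating-point
cancellation).  `U_raw` is min–max normalized **per image** to `[0, 1]`
so that one threshold grid applies to every image; a constant raw map
normalizes to all zeros ("uniformly certain"), so every pixel survives
any threshold.

**Stage 2 — supervision augmentation and ensembling.**  For each of `K`
base learners a threshold λ is drawn from the grid
`{0.1, 0.2, …, 1.0}` — without replacement while `K ≤ 10`, since
distinct thresholds maximize the diversity of the supervision signals
(with replacement beyond that).  The binary mask `1{U ≤ λ}` (boundary
inclusive) gates the cross-entropy:

```
L = −(1/N)(1/M) Σ_n Σ_m Σ_c Mask(x_{n,m}) · y_{n,m}^c · log p_{n,m}^c
```

The denominator is the *total* pixel count `M`, a literal reading of the
loss as printed; this means smaller λ also shrinks the loss scale.  The
alternative masked-count normalization is available via
`TrainConfig(normalize_by_mask_count=True)` but is off by default.
Masks are computed once from the frozen oracle and never refreshed
during base-model training (two-stage design).  The oracle scores the
same images it was trained on; that is intentional — its job is to
locate annotation ambiguity, not to generalize.

At inference the `K` member softmax maps are averaged; the segmentation
is the class argmax with the fused foreground probability tie at exactly
0.5 resolving to foreground (fixed and tested).  The per-pixel
population SD of the member foreground probabilities is emitted as
epistemic uncertainty — deliberately an SD rather than a variance, so
oracle (aleatoric) and ensemble (epistemic) maps share one scale.

## Networks, optimization, and inference

- U-Net: two 3×3 convolutions + ReLU per level, channels doubling with
  depth, 2×2 max pooling, 2×2 stride-2 transposed convolutions, skip
  concatenation, 1×1 head.  Defaults for desk-scale work: depth 3,
  8 base filters, 2 input channels, 2 classes.  The nonlinearity and
  the absence of normalization layers are package choices; θ defaults
  to 0.5 (the classic MC-dropout setting) and is configurable.
- Weight init: zero-mean Gaussian with He scaling `sqrt(2/fan_in)`,
  seeded.
- Optimizer: Adam, learning rate 1e-4, weight decay 1e-5 (L2 folded
  into the gradient), batch size 16.
- Data pipeline: per-subject, per-channel standardization to zero mean
  / unit SD; random patch cropping (default 32×32 at the 64×64 phantom
  scale, with a lesion-biased redraw because lesion pixels are sparse);
  lossless augmentation — flips with probability 0.5 per axis and
  right-angle rotations, so labels and masks stay exactly binary.  A
  continuous ±15° rotation mode exists but is off by default.
- Epochs are a required config with default 20.  Because a pass over a
  few dozen single-slice phantoms yields far fewer gradient steps than
  a pass over stacks of MRI slices, the sampling density is explicit:
  `crops_per_image = 8` random patches per image per epoch (chosen once
  from training-loss convergence on the default phantoms, where the
  loss plateaus near 0.1).
- Probabilities are clipped at 1e-7 before the log.
- Whole images are predicted by sliding windows at 50 % overlap
  (stride = patch/2), the final window clamped to the image edge (no
  padding), overlapping windows averaged uniformly per pixel.

The networks run on a small pure-NumPy engine (`saen._nn`) written for
this package: float32 im2col/GEMM convolutions with explicit backward
passes, channel-major activation layout, and seeded `numpy.random`
generators everywhere.  On a fixed BLAS build every stage — phantom
generation, training, MC sampling, masking, fusion — is bit-for-bit
reproducible from its seed; across BLAS thread configurations weight
agreement is asserted at 1e-6.

## The phantom generator

The generator emulates the *uncertainty structure* of WMH data, not its
anatomy:

- 64×64 two-channel images (channel 0 "FLAIR" carries lesion contrast
  1.0, channel 1 "T1" half that, so multi-channel input is informative);
  smooth background field (amplitude 0.2) plus i.i.d. Gaussian sensor
  noise (SD 0.3).
- Lesions are random ellipses (radius 3–7 px, aspect 0.6–1.0) warped by
  a low-frequency sinusoidal boundary perturbation (amplitude ≤ 0.15,
  2–5 cycles).  "Periventricular" lesions sit in a central vertical
  band with hard edges; "deep" lesions sit anywhere else and get a
  Gaussian intensity ramp (σ = 1.5 px) for ambiguous edges.  Defaults:
  1 periventricular + 2 deep lesions per image.
- The observed annotation is the clean label with its boundary displaced
  by a smooth Gaussian random field (correlation length ≈ 4 px,
  pointwise SD = `annotation_jitter_sigma`, default 1.5 px, clipped to
  `3σ − 1`): thresholding the signed distance transform at the field
  yields correlated, rater-like boundary errors, never salt-and-pepper
  flips, confined by construction to a band of width ≤ 3σ around the
  true boundary.  σ = 0 reproduces the clean label exactly, and the
  disagreement rate grows monotonically in σ.

What the phantoms do **not** model: 3D context, anatomy-dependent
intensity (ventricles, cortex), scanner inhomogeneity, systematic rater
bias (the jitter field has zero mean), and multi-rater disagreement.
Passing tests therefore demonstrate the *mechanics and the qualitative
behaviour* of supervision augmentation under boundary-concentrated label
noise — not clinical segmentation accuracy.

## Benchmark protocol and problem sizes

The standard desk-scale benchmark trains on 60 phantoms and evaluates on
15 held-out phantoms against their *clean* labels, with depth-3 /
8-filter networks, 20 epochs, K up to 5, and the training repeated for
five master seeds on a fixed dataset (the repeats differ in
initialization, λ draws, dropout, and batch sampling).  Within one
repeat the K_max members are trained once and smaller ensembles are
nested prefixes, so a K-sweep costs no additional training.  Member
seeds are `master_seed + k`; the oracle uses `master_seed + 1000`, the
single baseline `master_seed + 500`.  The oracle trains on a doubled
epoch schedule (40 at the default 20): dropout active during training
halves the effective gradient signal, and the two-stage design requires
the uncertainty estimator to be at its loss plateau before its maps are
trusted — under-converged oracles score lesion interiors as uncertain
and destroy the boundary-concentration pattern.  These sizes keep a full benchmark
around 15 minutes on one CPU.  `scripts/acceptance.py` runs three
repeats (≈ 10 minutes).

Expected qualitative pattern (asserted in the acceptance tests): the
fused Dice beats the mean member Dice in every run, beats the single
fully supervised baseline in at least 4 of 5 seeds, the across-repeat SD
of fused Dice does not grow from K = 1 to K = 5, and oracle uncertainty
within 2 px of clean lesion boundaries exceeds the deep-interior mean in
at least 4 of 5 seeds.

## Evaluation metrics

- Dice with the both-empty convention 1.0 (agreement on absence —
  WMH slices can be lesion-free).
- H95: boundary voxels from face-connected erosion, directed distances
  via KD-trees, 95th percentile (linear interpolation), symmetrized by
  the max; spacing-scaled.  An empty mask makes the value undefined:
  the report carries the image diagonal as a flagged sentinel.
- Voxel recall |P∩G|/|G| (NaN for empty G).
- Lesion-wise recall/F1 over connected components (8-connectivity in
  2D, 26 in 3D): a GT lesion is detected iff any predicted voxel
  overlaps it; a predicted component with no GT overlap is one false
  positive.
- Size-stratified recall partitions GT lesions at the median component
  size, "≤ median" in the small stratum; an empty stratum is NaN.

## Known limitations

- The mask-denominator choice (total vs masked pixel count) rescales
  the effective learning rate as λ shrinks; both variants are
  implemented, only the total-count default is benchmarked.
- Per-image min–max normalization makes λ relative to each image's own
  uncertainty range; images with nearly uniform uncertainty get
  near-all-ones masks at every λ.
- 2D only; no learning-rate schedules, early stopping, or test-time
  augmentation.
- The RWI (random-weight-initialization) ensemble is included as a
  control and tested at small scale, but the benchmark grid defaults to
  SA-EN vs the single baseline.
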