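# Methods

This note records the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
studies do and do not demonstrate.

## Multi-view segmentation

A 3D volume is decomposed into 2D slices along the three anatomical views
(sagittal = array axis 0, coronal = axis 1, axial = axis 2 on a canonical
RAS-like grid; ascending index order, no per-view flips).  One 2D network is
trained per view; at prediction time each network's per-slice class-score
maps are stacked back along the view axis into a score volume aligned with
the input, and the three views are fused per voxel.

Fusion sums the per-class scores over the three views and takes the argmax
(default, `score_sum`), with ties broken toward the lowest class index.  The
alternative `label_vote` mode takes each view's argmax labels first, then a
per-voxel majority vote with the score sum and lowest-index as successive
tie-breaks.  Summing scores before the argmax keeps the fusion additive and
well defined; summing hard labels would not be.

### Architecture

The per-view network is a four-stage encoder-decoder with skip connections:

* **Inception-residual encoder block (EB)** — four parallel branches: a 1x1
  bottleneck + batch norm; the same followed by stride-1 3x3 max pooling;
  and two double-convolution branches at the two configurable kernel scales
  (default 3x3 and 5x5), each preceded by a 1x1 bottleneck and batch-
  normalised after every convolution.  Branches are concatenated, projected
  back by a batch-normalised 1x1 convolution, added to a (1x1-projected and
  batch-normalised, or identity) residual of the input, and ReLU-activated.
  The branch width is `c_out/8` (minimum 1); the block is deliberately far
  lighter than a plain double-3x3 stage.  Normalising the projection and
  residual convolutions is required for stability: the attention gate below
  is multiplicative, and an unnormalised skip path lets activation
  magnitudes compound cubically across stages until float32 overflows.
* **Dense spatial attention (DSAM)** — channel-wise average- and max-pooled
  maps (2 channels) feed a chain of 12 densely connected blocks
  (BN -> ReLU -> 3x3 convolution to 4 new channels, concatenated onto the
  running feature, so after i blocks the feature has 2 + 4i channels), then
  a 1x1 projection to a single-channel map passed through the swish
  activation x*sigmoid(x).  The output is `x * gate * swish(x)`, which
  vanishes wherever x vanishes.  The chain is evaluated at half spatial
  resolution (average-pool in, nearest-upsample out) when the map is even-
  sized and at least 8 voxels across; the gate is a smooth map and this
  quarters the chain's cost without changing any block contract.
* **Stages** — 1, 2, 3 and 4 EBs in stages 1-4, channels doubling each
  stage (default width 32, tests and reference studies use 8), a DSAM gate
  per stage, and a stride-2 depthwise-convolution downsampler.  Stage
  outputs 1-3 are additionally average-pooled to the bottleneck resolution,
  concatenated with the stage-4 output and fused by a 1x1 convolution
  (multi-scale routing).
* **Decoder** — four blocks of nearest x2 upsampling, skip concatenation,
  then a 1x1 and a 3x3 convolution with batch norm and ReLU; a 1x1 head
  with a per-class sigmoid produces the score maps.  A softmax head is
  available as a flag (see below).

Ablation variants: `unet` (plain double-3x3-conv UNet with max-pool
downsampling, a double-conv bottleneck and the classic double-3x3 decoder),
`inc_res` (EBs only), `inc_res_dsam` (EBs + attention), `full` (all plus
multi-scale routing).  At equal base width the `full` model has roughly half
the parameters of the `unet` baseline (the decoder's 1x1+3x3 design and the
thin EB branches are where the savings come from).

### Loss and training

The Combo loss is `L = alpha * CE_beta - (1 - alpha) * DiceTerm`, where
`CE_beta` weights the positive log-term by beta and the negative by
1 - beta, and `DiceTerm` is the smoothed soft Dice coefficient
(smoothing constant 1) averaged over classes.  The per-class Dice sum is
rescaled by the class count so both terms are O(1) and alpha = 0.5 balances
them at any number of classes; this is a pure rescaling of 1 - alpha.
Defaults alpha = beta = 0.5.  Plain BCE, Dice and BCE+Dice losses are
available through the same interface.  Optimisation is Adam (eps 1e-8, no
weight decay), default learning rate 1e-4; the CPU-scale reference studies
use 3e-3.  All weights are trained from scratch from a seeded He
initialisation; shuffling is seeded per epoch, so identical seeds give
identical runs.

A numerical detail that matters: the cross-entropy's log is clamped to
[1e-6, 1 - 1e-6] with a *straight-through* gradient (1/clamped(p)).  A hard
clamp zeroes the gradient once a sigmoid output saturates, permanently
silencing rare classes; the straight-through form keeps the composed
sigmoid-cross-entropy gradient equal to (p - t) in the saturated regime.

### Numerical core

No deep-learning framework is used: the package carries a small reverse-mode
automatic-differentiation core over NumPy float32 arrays (conv2d/conv3d,
transposed conv3d, batch norm, max/avg pooling, nearest upsampling, linear,
the elementwise activations and reductions), each primitive verified against
central finite differences in the test suite.  2D convolutions switch
between an im2col schedule (small fan-in) and an offset-loop schedule (large
fan-in) purely for speed; both compute the same operator.  Batch-norm layers
fall back to batch statistics in eval mode until they have seen a training
batch, so untrained forward passes stay bounded.

## Gestational-age (GA) prediction

Three feature families feed the same regression interface:

* **Radiomics (18 features)** — shape: elongation, flatness, major/minor
  axis length (4*sqrt(eigenvalue) of the spacing-scaled coordinate
  covariance), maximum 3D diameter and surface area from a triangulated
  isosurface, sphericity (36 pi V^2)^(1/3) / A with the mesh volume;
  first-order: energy, entropy (bits, 32 equal-width bins), kurtosis
  (Pearson), mean, skewness; GLCM: contrast, correlation, inverse difference
  moment from the symmetric matrix averaged over the 13 distance-1 3D
  offsets; NGTDM: coarseness (with a 1e-6 guard, capping at 1e6 for
  constant regions), complexity, strength (Amadasun-King).  Intensities are
  discretised to 32 equal-width bins over the masked range for both texture
  families.  The isosurface is extracted after a 0.7-voxel Gaussian
  smoothing of the binary indicator: raw binary marching cubes overstates a
  digital ball's area by ~9% (staircase bias), the smoothed surface is
  within ~1%.  The "contrast" of the selected set is the GLCM contrast (it
  sits between two GLCM features in the canonical list); NGTDM contrast is
  not part of the 18.  Features default to the whole segmented brain
  (union of tissue labels); per-tissue extraction is available.
* **Segmentation-encoder deep features** — per view, each slice's
  bottleneck tensor is globally average-pooled and mapped to 256 dimensions
  by a fixed, seeded, untrained Gaussian projection (the bottleneck width
  is 256 only at base width 32; the fixed projection makes the feature
  definition independent of width).  Slice vectors are mean-pooled over the
  volume (max pooling available) and the three views concatenated to a
  768-vector.
* **3D-autoencoder latents** — encoder stages of Conv3d + BN + ReLU +
  2x2x2 max-pool (default 4 stages, widths 8-64), bottleneck flattened to a
  256-dimensional latent; mirrored decoder with stride-2 transposed
  convolutions and a sigmoid head; MSE reconstruction loss on per-subject
  min-max normalised volumes resampled trilinearly to 32^3.  Latent size,
  widths and loss are this package's choices.

Regressors: random forest (100-1000 trees, default 500), a single
regression tree, linear regression (ridge fallback with a warning on
singular designs), and gradient-boosted trees (squared error, 300 rounds);
all seeded.  Evaluation reports RMSE in weeks and the concordance index
(pairs with distinct truth; prediction ties count one half).  Feature
importance is permutation-based: the mean RMSE increase over seeded column
shuffles.

## Synthetic phantoms

Phantoms are nests of ellipsoids on a cubic grid: an outer CSF shell (ECF),
a cortical shell (FGM), a white-matter interior (WM), and four structures
strictly inside the WM — paired ventricles, a posterior cerebellar blob, a
central deep-gray blob and an inferior brainstem cylinder.  Every semi-axis
scales as `r20 * (1 + 0.035 (GA - 20))`, so the maximum 3D diameter grows
strictly with gestational age over weeks 20-33 and geometric features carry
the age signal that the regression studies recover.  Each tissue has a
distinct mean intensity on [0.2, 1.0] with T2-like ordering (CSF bright,
WM dark); additive Gaussian noise (default sd 0.02) leaves at least five
standard deviations between adjacent intensity levels, so tissues are
separable in principle — a nearest-mean classifier reaches macro Dice ~0.98,
which bounds what segmentation scores on phantoms can mean.  Interior
structure sizes approximate real fetal tissue volume fractions (ventricles,
cerebellum and deep gray each ~1-2% of brain voxels).  An optional
low-frequency multiplicative bias field is off by default.

What phantoms do not emulate: partial-volume effects, motion and
reconstruction artefacts, anatomical shape variability beyond affine
growth, and inter-subject intensity variation.  Passing the phantom studies
demonstrates that the pipeline's machinery — slicing, training, fusion,
feature extraction, regression — is correct and end-to-end learnable, not
that the architecture reaches any particular accuracy on clinical data.

## Reference study sizes and protocol choices

The CPU-scale reference studies (used by the test suite and the
reproduction script) are:

* **Segmentation** — 48^3 phantoms, coronal view, 24 training / 8 test
  subjects, base width 8, batch 12, 6 epochs at learning rate 3e-3.
  Training slices: all brain-containing slices, every 4th background slice,
  and slices containing the small interior tissues repeated 4 times —
  without this oversampling the ~0.1% voxel share of the smallest tissues
  produces too little gradient signal for a short budget.  The experiment
  uses the softmax head: with one-vs-rest sigmoid outputs the smallest
  tissues stay collapsed at this budget (the sigmoid head remains the
  package default).  Held-out evaluation is per-subject 3D macro Dice over
  the seven tissues after stacking the coronal predictions.
* **Ablation** — unet vs full variant at an equal budget chosen so both
  converge (6 training / 3 test subjects, 10 epochs), averaged over three
  seeds.  Comparing under-trained models instead inverts the comparison:
  the attention model has fewer parameters but needs more steps to mature.
* **GA recovery** — 60 phantoms; radiomics + random forest under 5-fold
  cross-validation, against autoencoder latents (12 epochs) with the same
  regressor; permutation importance over 5 repeats.

## Known limitations

* The NumPy core is single-threaded BLAS-bound; the reference studies are
  sized for minutes, not for realistic training volumes.
* HD95 on phantoms is near zero because phantom boundaries are crisp; it
  exercises the metric, not boundary robustness.
* The fixed encoder-feature projection is untrained; encoder deep features
  on phantoms carry little age signal beyond scale, consistent with their
  weak ranking among the feature families.
* Phantoms encode gestational age through a single latent scale variable
  (isotropic affine growth).  Two consequences for the GA study: (i) the
  autoencoder latents, which read that scale from continuous intensity
  boundaries at sub-voxel resolution, recover GA as well as or better than
  the voxel-quantized radiomics geometry — on real data, where most
  variation is age-irrelevant, the ordering favours radiomics instead;
  (ii) eleven of the eighteen radiomics features are mutually collinear
  (|r| >= 0.97), so single-column permutation importance is masked for
  every member of that clique and no individual size feature (e.g. the
  maximum 3D diameter) can robustly dominate the ranking, even though the
  size clique as a whole carries essentially all of the signal.
* The correlation-based feature selector reproduces the canonical
  18-feature set as its fixture; the exact historical selection procedure
  behind that set is not specified anywhere, so the greedy |r|-ranked
  procedure here is a reasonable stand-in, not a reconstruction.
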