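# Methods

## The pretext task

`paircell` learns single-cell feature representations from unlabeled
multichannel fluorescence microscopy by *paired cell inpainting*.  The
organising assumption is that an image — all fields of view of one
experimental well — contains many genetically identical cells sharing one
protein-localization phenotype, while channels split into *structural
markers* Z1 (present in every image: a cytosolic stain, a nucleus /
microtubule pair) and a *protein* channel set Z2 (the tagged biomolecule that
varies image to image).

A training example draws two different cells from the same image.  The
network sees the source cell completely, (x_s, y_s), plus the target cell's
structural markers x_t, and predicts the target's protein channel:

    y_t_hat = f(x_s, y_s, x_t),
    L(y_t_hat, y_t) = (1 / (h w)) * sum over pixels of (y_t_hat - y_t)^2 .

To solve this the encoder must identify the localization pattern in the
source and re-express it in the target's geometry, while target structural
input hands the decoder the nuisance conditions (local illumination, gain,
morphology) for free — so the source-encoder features need not encode them.
The prediction itself is discarded after training; the per-cell feature
vector is the spatial maximum of each feature map of a chosen source-encoder
layer (Conv1..Conv5, taken post-batchnorm / post-ReLU; max-pooling makes the
pre/post-pool distinction immaterial).

## Architecture

* Source cell encoder: AlexNet-family, five 3x3 stride-1 same-padded
  convolutions with batch normalization and ReLU, 2x2 max-pooling after
  blocks 1, 2 and 5.  Canonical widths (96, 256, 384, 384, 256); a reduced
  profile (16, 32, 32, 32, 32) with 32-px crops is used for CPU-scale work.
* Target marker encoder: three blocks of 16/32/32 filters, pooled after
  each, consuming x_t only.
* Decoder: the source widths reversed, nearest-neighbour upsampling placed
  to mirror the encoder's pooling, a 3x3 head and a sigmoid onto [0,1].
  The two bottlenecks (both at crop/8 resolution) are concatenated along
  channels.  No skip connections.
* Training: Adam, batch 64, random horizontal/vertical flips applied to the
  source and the target cell independently (a cell's marker and protein
  channels always flip together).  One epoch visits every eligible cell once
  as a source with a uniformly drawn same-image target.  Defaults are 30
  epochs at learning rate 1e-4; the benchmark profile (below) uses 5 epochs
  at 1e-3, Adam's customary default, because the reduced model sees only
  ~200 optimizer steps and the conservative rate would leave it far from
  convergence at that budget.
* The autoencoder baseline reuses the source encoder + decoder to
  reconstruct the input crop's own channels; the target encoder is unused.

The network engine (convolution via im2col GEMM, batchnorm, pooling,
upsampling, Adam) is written directly on numpy in float32; every layer's
backward pass is verified against central finite differences in float64, and
the convolution forward pass against `scipy.signal.correlate2d`.  Weight
initialization is He-normal.  One master seed spawns independent streams for
initialization, pairing and augmentation, so runs are bit-reproducible on a
fixed BLAS.

## Preprocessing

Two recipes convert fields of view into normalized crops:

* `center_based` (yeast-style): externally supplied centers (segmentation is
  out of scope), fixed 64-px (default) crops, per-channel min-max rescale to
  [0,1]; an optional mask-area filter rejects crops whose object covers
  < 5% or > 95% of the crop; images with fewer than 30 surviving cells drop.
* `otsu_nucleus` (human-style): Otsu-binarize the nuclear channel, label
  connected components, drop objects under 400 px, crop 512 px around each
  centroid, resize to 64 px (bilinear, Gaussian prefilter at
  sigma = downscale/2), rescale to [0,1], zero structural values below 0.05;
  images with fewer than 5 cells drop.

Choices the recipes leave open, fixed here: the [0,1] rescale is per channel
per crop (channels have unrelated dynamic ranges); boundary crops are
zero-padded (reflective padding would fabricate cell content); the 0.05 clip
is applied after the resize and rescale; crops are ordered by (field, row,
col) so cell identifiers are reproducible.

## The synthetic benchmark

The generator emulates the statistical structure the pretext task relies on,
not microscope physics.  Cells are rotated ellipses with a concentric
nucleus (0.45 of the body axes); the protein channel realizes one of six
localization classes — nuclear, nucleolar (1-3 intranuclear blobs),
nucleolar rim, cytosolic, punctate (Poisson-count foci), membrane — or a
`mixture(A, B, alpha)` interpolation whose per-cell mixing fraction is
jittered (sd 0.15) to emulate single-cell variability of multi-localizing
proteins.  Structural channels are a body and a nucleus stain (or a single
cytosolic marker with a dim nuclear shadow).

Nuisance, sized after real screens so that trivial statistics do not solve
the benchmark: diffuse nonspecific background fluorescence in the protein
channel (0.35 of peak specific signal, body-wide), Gaussian PSF blur
(sigma 1.2 px), additive noise (sd 0.05 of full scale), a per-image planar
illumination ramp (+-30%), per-image gain in [0.6, 1.4], per-cell lognormal
brightness jitter (sd 0.15), and +-2 px crop-center error emulating
segmentation inaccuracy.  Two properties are enforced by test: per-image
mean intensity varies by >= 20% within a class (an intensity classifier
cannot win), and within-class protein-channel correlation exceeds
between-class correlation (the benchmark is solvable).  During development a
cleaner first rendering (no background, sigma 0.7, noise 0.02) was found to
be separable at 98% balanced accuracy by a randomly initialized Conv1
embedding — i.e. useless for ranking feature-learning methods — which is why
the nuisance above is deliberately heavy.

What the generator does not model: real optics (PSF anisotropy, chromatic
shifts), cell-cycle morphology, clumped or overlapping cells,
sub-image pattern penetrance (beyond the mixture jitter), and the texture
richness of real protein stains.  Passing benchmarks here shows the
machinery is correct and that the method ranking behaves as expected under
controlled nuisance; it does not certify performance on any real screen.

The benchmark configuration used by the test suite and the acceptance
script: 6 classes x 30 images x 10-16 cells on 256x256 fields, 32-px crops,
the reduced encoder profile, 5 epochs — sized to train in a few minutes on
one CPU.  Evaluation protocols are fixed: seeds (0, 1, 2) [the acceptance
script derives three consecutive seeds from its --seed]; leave-one-out kNN
(k = 11, Euclidean) on features standardized to zero mean / unit population
variance; each method scored by the better of its Conv3 and Conv4 layers,
the intermediate layers self-supervised transfer conventionally uses.

## Evaluation statistics

* Balanced accuracy: unweighted mean of per-class recalls under
  leave-one-out kNN.  Distance ties break by row index, vote ties by the
  smallest class in sorted order, so results are deterministic; an optional
  leave-one-group-out mode excludes same-image neighbours (the well-level
  confound control of morphological profiling).
* Normalized same-term distance: for images sharing a localization term,
  the mean cross-image cell distance is compared with an expectation built
  from the same number of pairs against every other term:
  (mean_same - mean_diff) / mean_diff.  Negative means same-term cells sit
  closer than expectation.  A z-score normalization and an unbalanced
  cell-line-constrained variant (pooled different-term pairs, same/different
  cell-line restriction) are available behind config flags.
* Multi-localization score: ln of the ratio of a cell's distance to two
  compartment centroids (means of single-compartment reference cells);
  negative = closer to the first compartment.  The per-image standard
  deviation of this score screens for single-cell variability.
* Clustering: agglomerative on Euclidean distances; Ward linkage by default
  (configurable to average/complete — the choice is genuinely open), with
  deterministic leaf order, flat cuts, and Newick export.

## Numerical and degenerate-input conventions

Constant channels min-max-normalize to zero.  Constant nuclear channels
yield no Otsu centers (warning, not an error).  Zero-variance feature
columns are centered but not scaled.  Cells lying exactly on a compartment
centroid score signed infinity with a warning.  Images with one cell
contribute no training pairs and no variability estimate (warned, skipped).
Half-precision crop storage bounds round-trip error by 2^-11; float32
storage is exact.  Training aborts with a diagnostic on non-finite loss.

## Known limitations

The CPU-scale engine is two to three orders of magnitude slower than a GPU
framework; proteome-scale runs (10^6 cells, 30 epochs, full AlexNet widths)
are out of reach here, so all quality statements are made at benchmark
scale.  Feature quality at Conv1/Conv2 is dominated by generic image
statistics on synthetic data; method comparisons are therefore made at
Conv3/Conv4.  The flip-augmentation symmetry does not make max-pooled
features flip-invariant (correlating a flipped image equals correlating the
original with flipped kernels); the exact identity is tested instead.
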