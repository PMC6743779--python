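# paircell

Self-supervised single-cell features for fluorescence microscopy via
**paired cell inpainting**.

High-content screens image thousands of wells, each containing many
genetically identical cells, in channels that split into *structural
markers* (a cytosolic stain, a nucleus/microtubule pair — present
everywhere) and a *protein channel* (a GFP-tagged ORF or antibody stain that
varies well to well).  Quantitative analysis of such screens — classifying
protein subcellular localization, clustering the proteome, scoring
multi-localizing or spatially variable proteins — needs per-cell feature
vectors, and labels for training feature extractors are scarce at the
single-cell level.

`paircell` learns those features without labels.  A convolutional
encoder–decoder is trained on a pretext task: given one cell's full channels
(x_s, y_s) and a *different* cell's structural markers x_t, both from the
same image, predict the second cell's protein channel,

    ŷ_t = f(x_s, y_s, x_t),    L = (1/hw) Σ (ŷ_t − y_t)²,

so the network must recognize the localization pattern in the source cell
and re-express it in the target's geometry, while nuisance conditions
(illumination, gain, morphology) are handed to the decoder through the
target markers and need not be encoded.  After training, the prediction is
discarded; a cell's feature vector is the spatial max of each feature map of
an intermediate source-encoder layer (Conv1..Conv5).  A plain autoencoder
baseline using the same encoder/decoder, a leave-one-out kNN benchmark,
pairwise-distance and multi-localization statistics, agglomerative
clustering, and a synthetic microscopy generator for fully self-contained
experiments are included.  The CNN engine itself is a compact numpy
implementation (gradient-checked against finite differences), so everything
runs on one CPU.

Intended users: computational biologists analysing multichannel single-cell
imaging who want label-free per-cell representations, and methods
researchers who need a transparent, dependency-light reference
implementation of the inpainting pretext task.

## Worked example

Generate a small synthetic screen (3 localization classes, 8 wells each),
train for 3 epochs, and classify single cells by their features:

```python
from paircell import (ModelConfig, PairedCellInpainting, TrainConfig,
                      knn_loo_balanced_accuracy, standardize_features)
from paircell.simulate import SyntheticSpec, generate_images, crops_from_images

spec = SyntheticSpec(pattern_classes=("nuclear", "cytosolic", "membrane"),
                     images_per_class=8, cells_per_image=(8, 12),
                     field_size=(192, 192), seed=42)
images = generate_images(spec)
crops, labels = crops_from_images(images, crop_size=32, center_jitter_px=2, seed=42)

model = PairedCellInpainting(crops, spec.channel_layout, ModelConfig.reduced(32, 2, 1))
res = model.fit(TrainConfig(epochs=3, learning_rate=1e-3, seed=0))
print(res.summary())

table = res.extract_features(layer="Conv3")
std, _, _ = standardize_features(table)
report = knn_loo_balanced_accuracy(std, [labels[c.image_id] for c in crops], k=11)
print(f"kNN (k=11) balanced accuracy: {report.balanced_accuracy:.3f}")
```

Output:

```
24 images, 237 single-cell crops
Paired cell inpainting results
==============================
mode:              paired_inpainting
crop size:         32
channels:          2 structural + 1 protein
source widths:     (16, 32, 32, 32, 32)
target widths:     (16, 32, 32)
cells:             237
epochs:            3
learning rate:     0.001
seed:              0
epoch   mean loss
    1   0.305963
    2   0.188241
    3   0.139672
kNN (k=11) balanced accuracy: 0.912
```

The loss history shows the pretext objective falling epoch over epoch; the
balanced accuracy (unweighted mean of per-class recalls under leave-one-out
kNN) shows that three epochs of self-supervision already organize single
cells by localization class.  On the full benchmark (6 classes × 30 wells,
5 epochs) trained Conv3/Conv4 features beat the autoencoder baseline by
6–10 percentage points and a random-initialization control by 2–10, seed
over seed.

The same pipeline is scriptable from the shell:

```sh
paircell simulate --seed 0 --out data/
paircell crop --manifest data/manifest.tsv --mode center_based \
         --crop-size 32 --min-cells 2 --centers data/centers.tsv --out crops.h5
paircell train --store crops.h5 --epochs 5 --lr 1e-3 --widths 16,32,32,32,32 \
         --seed 0 --out weights.npz
paircell extract --weights weights.npz --store crops.h5 --layer Conv3 --out feats.tsv
paircell evaluate knn --features feats.tsv --labels data/labels.tsv --out knn.tsv
```

Subcommands also cover `aggregate` (protein-level averaging),
`evaluate layers|pairdist|multiloc|cluster`, and `run` (the whole pipeline
with checksum-based stage caching).

## Layout

```
src/paircell/
  core.py        domain types, manifest/crop-store/feature-table I/O
  simulate.py    synthetic multichannel microscopy generator
  preprocess.py  Otsu center detection, cropping, normalization, filters
  nn.py          numpy CNN engine (conv/batchnorm/pool/upsample/Adam)
  pretext.py     pair sampling, augmentation, inpainting loss
  model.py       architecture + PairedCellInpainting / InpaintingResults
  features.py    layer taps, spatial max-pooling, standardization, averaging
  evaluate.py    kNN, distance statistics, multi-localization, clustering
  benchmark.py   the fixed synthetic benchmark configuration
  cli.py         command-line interface
docs/methods.md  model, assumptions, parameter choices, limitations
```
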