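# Methods

This note documents the models, the defaults and the design choices made
where the procedure was genuinely open, plus what the synthetic benchmark
does and does not establish.

## The chopped-picture procedure

Training data is produced by dissecting class-pure images into square
tiles on a regular grid. For tile side `s` and overlap fraction `v`, the
stride is `d = round(s(1 - v))`, floored at one pixel; an axis of length
`L` yields `floor((L - s)/d) + 1` tiles and trailing pixels that do not
fill a tile are dropped. Dropping (rather than padding) keeps every tile
statistically identical; none of the published sizes (84, 56, 28, 14)
need padding on the image sizes in use. Coordinates are 0-based with
origin at the top-left, `(x, y) = (column, row)`.

Training corpora are chopped with `v = 0.5`; evaluation pools and map
inference use `v = 0`. The train/validation split is 75/25 at tile
level: tiles are shuffled and assigned per class, with largest-remainder
rounding so each class's training share is within one tile of 75 % while
the global count is exactly `floor(0.75 N)`. Because half-overlapping
tiles from one parent image can land on both sides of the boundary, the
tile-level split is optimistic about validation independence; a
`split_by_parent` option assigns whole source images to one side for
leakage-free validation. The tile-level protocol remains the default
because it is the protocol of the original workflow.

## The convolutional classifier

The stack is fixed: conv 5×5×20 → pool 2×2 → conv 5×5×50 → pool 2×2 →
dense 500 → dense 2 → softmax, with ReLU after every parameterised layer
except the output. Convolutions are unpadded ("valid"), stride 1;
pooling is stride-2 with floor semantics. Three open details were
resolved as follows:

* **Pooling operator** — max pooling (the classic choice for this
  architecture); average pooling is available via the `pooling`
  parameter.
* **Degenerate pooling** — on 14-px input the second pool would act on a
  1×1 map; pooling layers whose input spatial extent is below 2 are
  pass-through, which keeps the one fixed stack well-defined for all
  four tile sizes. Flatten sizes are then 800 / 6050 / 16200 / 50 for
  inputs 28 / 56 / 84 / 14.
* **Optimisation details** — the protocol fixes epochs (30), learning
  rate (0.01, constant), train batch (64) and validation batch (32) but
  not the optimiser. Defaults here: SGD with classical momentum 0.9,
  uniform Xavier/Glorot weight initialisation, zero biases, pixel
  scaling to [0, 1] with no mean-image subtraction, last incomplete
  batch kept. All are documented defaults of this package, exposed as
  parameters, not claims about the original setup.

The per-batch loss gradient is the cross entropy averaged over the
batch, so the learning rate is batch-size independent. Training is
bitwise reproducible given the seed (single-threaded numpy float32);
checkpoints store architecture, weights, class order and preprocessing
convention, and reload to bit-identical predictions. Analytic gradients
are validated against central finite differences (relative error
< 1e-4 on a float64 14-px network) in the test suite.

Class order is alphabetical (`bamboo` before `other`); argmax ties
resolve to the first class.

## The texture baseline

The comparison classifier reduces each tile to 8 features: per-channel
RGB means plus five co-occurrence measures of the luminance image. With
`P` the normalised grey-level co-occurrence matrix and
`μ = Σ_ij i·P(i,j)`:

    mean = μ                        variance      = Σ (i-μ)² P
    contrast = Σ (i-j)² P           dissimilarity = Σ |i-j| P
    homogeneity = Σ P / (1+(i-j)²)

The original description names the measures without defining them; the
standard Haralick-style forms above are used. Other unstated parameters
were fixed as documented defaults: ITU-R BT.601 luminance weights
(0.299, 0.587, 0.114); 32 grey levels, uniformly binned over [0, 255];
four distance-1 offsets (1,0), (0,1), (1,1), (1,−1) counted over the
whole tile, summed across offsets and symmetrised *before* normalising;
z-score standardisation on training statistics; gamma ∈ {2⁻⁸…2²} and
cost ∈ {2⁻²…2⁶} with 5-fold stratified CV, ties resolved to the smallest
cost then smallest gamma. All are configurable.

## Evaluation protocol

Held-out class-pure images are chopped without overlap, tiles pooled,
and 500 tiles (fewer, with the shortfall recorded, if the pool is
smaller) sampled uniformly with a seed; the sample is not forced to be
class-balanced and the realised class ratio is recorded. Rates with a
zero denominator are reported as missing, never as zero. Proportions are
kept internally; percentages appear only in reports.

## Synthetic scenes: what they emulate and what they do not

The generator provides the statistical ingredients the method's claims
depend on, each a pure function of its seed:

* *bamboo*: band-limited oriented texture — sinusoidal stripes
  (wavelength 6 px, random orientation around 45°, smoothly varying
  phase) plus white speckle, amplitude 40 grey levels on a yellow-green
  base (120, 150, 70);
* *other*: by default a coarse-blob canopy (Gaussian-correlated noise,
  correlation 12 px, amplitude 35) on a darker green (70, 110, 60);
  smooth-gradient and block-mosaic presets are available. Base colours
  are deliberately similar so texture, not colour, carries most of the
  class signal and the GLCM baseline has something to measure;
* *zoom*: block-mean downsampling by 1/2/4 emulating ~0.13/0.26/0.65 m
  per pixel, rounding half-up; the 6-px stripe wavelength is destroyed
  at factor 4, which is what drives the resolution-degradation result;
* *sites*: fixed hue/brightness/blur transforms stand in for
  site-to-site acquisition differences, and evaluation imagery is
  generated from seeds disjoint from training seeds as the analogue of
  spatially separated sampling.

These scenes are *easy* by real-world standards: no mixed-content tiles,
no shadows, clouds, roads or seasonal variation, and class-pure labels
by construction. Passing benchmarks on them establishes that the
pipeline is implemented correctly and responds in the expected
directions (CNN ≥ texture SVM; accuracy non-increasing with coarser
resolution; more training tiles not worse; wide-area maps recover the
composition), not that comparable accuracies would be obtained on real
satellite imagery.

## Problem sizes

The benchmark suite and the acceptance script run at desk scale, chosen
to exercise every code path with stable statistics: the parameter-
recovery corpus uses 500 tiles per class at 28 px with the full
30-epoch protocol; the direction sweeps (resolution, robustness,
transferability) use 256-px images, 4 training images per class,
8 epochs, and 300-tile evaluation pools, with 5 seeds in the test suite
and the CLI defaults scalable back to full-scale counts (15000-tile
corpora, 500-tile pools) through `ExperimentConfig`.

## Known limitations

* No georeferencing: GeoTIFF input is read as plain pixels (first three
  bands); overlays are written without a geotransform.
* The label grid is a deliberately coarse per-tile map, not a dense
  segmentation; an overlapped-inference majority-vote extension
  (`vote_pixel_labels`) is provided but is not part of the core
  protocol.
* Binary classification only; multi-class stacks would need a wider
  output layer and per-class palettes.
* The numpy network is CPU-only and sized for small tiles; it is not a
  general deep-learning substrate.
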