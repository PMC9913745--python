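# Methods

## Scope and data model

The package segments H&E-stained prostate-biopsy whole-slide images
into stroma, benign epithelium, and cancer. Slides are RGB images with
a per-pixel raw annotation mask in the Radboud convention
(0 background/glass, 1 stroma, 2 benign, 3/4/5 Gleason growth
patterns). All training and evaluation happens in the merged space
stroma(0)/benign(1)/cancer(2): the three Gleason patterns are pooled
into one cancer class, and raw background is an *ignore* label that is
excluded from the loss, the metrics, and all averages. Merged label
maps use 255 as the ignore/background sentinel.

Coordinates are 0-based (row, col) with a top-left origin; crops are
half-open `[origin, origin + tile)` windows. These conventions are
stated once here and used identically in tiling, stitching, and tests.

## Preprocessing

**Global threshold.** Tissue/glass separation uses one manual
threshold `T = 210` (valid range the open interval (0, 255)) on the
BT.601 luminance image (0.299 R + 0.587 G + 0.114 B, rounded half-up).
The comparison is strict, so a pixel exactly at T is background under
either polarity. Two polarities exist because the textual convention
("above T is foreground") contradicts the physics of bright glass and
dark tissue; the package defaults to `dark_is_tissue` and keeps
`bright_is_foreground` selectable. No automatic (Otsu-style)
thresholding is offered — the threshold being fixed and manual is part
of the protocol.

**Tiling.** A non-overlapping grid of 256 × 256 tiles
(stride = tile size) covers the slide; a tile is kept when its tissue
fraction is at least `min_foreground_fraction` (default 0.1, chosen
because tiles of bare glass carry no labels; the inclusion rule is
otherwise unspecified upstream and is configurable). Partial edge
tiles are discarded rather than padded — a fixed-size grid implies
full tiles only. An optional integer pre-downsample (e.g. 2 for a
20×-scanned slide analysed at 10×) is applied before tiling; pixel
spacing metadata defaults to 1.0 µm/px since the magnification chain
of the source protocol is not internally consistent and no unit
conversion can be asserted.

## Architectures

All five segmentation networks share one contract: a five-level
encoder pyramid, a decoder of exactly four up-sampling blocks
(2× nearest upsample → skip concatenation → two 3×3 conv-BN-ReLU), and
a 1×1 head producing three class scores at the input resolution. For
backbones whose deepest feature is at stride 32 the head applies one
final 2× upsample (the four decoder blocks bring stride 32 to
stride 2); the plain U-Net encoder bottoms out at stride 16 and needs
none. Decoder widths halve per block (256/128/64/32 before width
scaling) — the classic expanding-path shape; no decoder table is
prescribed upstream.

* **Plain U-Net** — double 3×3 convolutions with 2×2 max pooling,
  channels 64→1024. Batch norm is included in every conv block for
  trainability from random initialisation.
* **ResNet-34** — 7×7 stride-2 stem plus 16 basic blocks in a 3/4/6/3
  layout: 33 main-path convolutions. The three 1×1
  projection-shortcut convolutions are tallied separately by the
  census (the conventional 34-layer count also excludes them).
* **ResNeXt-50 32×4d** — 3/4/6/3 bottlenecks with grouped 3×3
  convolutions, cardinality 32 (its standard setting). Under strong
  width reduction the cardinality is clipped to the bottleneck width.
* **Inception-V3-style** — a convolutional stem plus multi-branch
  blocks mixing 1×1, 3×3 (double) and 5×5 filters with a pooled
  projection, and stride-2 reduction blocks between stages. The
  original network's asymmetric 1×7/7×1 factorisations are not
  reproduced; branches use the square filters the multi-branch design
  is usually described with. Average pooling inside blocks is a 3×3
  stride-1 zero-padded box filter.
* **EfficientNet-B2** — a 3×3 stride-2 stem, MBConv stages, and a
  final 1×1 convolution. MBConv is the mobile inverted bottleneck:
  1×1 expansion (ratio 6, or 1 in the first stage), k×k depthwise
  convolution, squeeze-excitation (ratio 0.25 of block input), 1×1
  projection, with a residual connection when shape-preserving;
  activations are SiLU. Channels follow the width schedule for
  coefficient 1.1 with divisor 8: (32, 16, 24, 48, 88, 120, 208, 352)
  and a 1408-channel head.

**EfficientNet-B2 depth.** The published description of the proposed
encoder states 22 MBConv structures between the two plain
convolutions, while the standard B2 depth schedule (and the
accompanying stage table's repeat column) sums to 23. The package
follows the 22-block description: the MBConv1 stage is kept at its
unscaled depth of 1, giving per-row repeats (1, 1, 3, 3, 4, 4, 5, 2, 1)
and exactly 22 MBConv blocks, with every stage resolution matching the
table (128, 128, 64, 32, 16, 16, 8, 8, 8 for a 256 input). The repeat
schedule is a constructor argument, so the literal 23-block table
variant remains buildable and is covered by a test.

**Freezing and the ensemble.** Encoder stages (the five down-sampling
groups) can be frozen: their parameters are excluded from optimiser
updates and from the backward sweep; the decoder is never frozen. The
three named strategies span the spectrum — freeze the whole encoder,
freeze stages 1–3, freeze nothing; the exact frozen boundaries are not
enumerated upstream, so the stage sets are configurable. The ensemble
holds three independently initialised EfficientNet-B2 U-Nets, one
strategy each. Each head's output is its per-pixel softmax probability
map; the three maps are channel-concatenated (9 channels) and fused by
a trainable 1×1 convolution — the simplest learnable combiner
consistent with a final convolution block; whether the original fusion
was learned or fixed is unstated, so learned was chosen. Heads and
fusion train jointly end-to-end.

All structural claims (block censuses, stage resolutions, parameter
counts) are produced by `summarize()` via module-tree traversal plus a
probe forward pass — never hard-coded.

## The numpy network engine

No deep-learning framework is a dependency: `wsiseg.nn` is a small
reverse-mode autodiff engine written on numpy, providing exactly the
operators the architectures need. Convolution is im2col + matmul
(grouped and depthwise paths use batched matmul/einsum); the input
gradient is computed as the transposed convolution of the
stride-dilated output gradient, so all three gradients are matmuls.
Batch norm uses eps 1e-3 and momentum 0.1 by default. Max pooling
breaks argmax ties by first index. Every operator's backward pass is
verified against central finite differences in the test suite.
Initialisation is He-normal from an explicit seeded generator, so
identical seeds give identical parameters and outputs. The engine is
float32; training a width-0.125 ensemble takes roughly 3 s per
batch-8 step at 256² on one CPU.

## Training protocol

Defaults follow the study protocol: batch size 8, at most 50 epochs,
early stopping on validation loss with patience 5 (an "improvement"
must beat the best loss by at least 1e-4 to absorb float noise), and
best-epoch weight restore. The loss is per-pixel categorical
cross-entropy over the three classes with ignored pixels contributing
exactly zero gradient (asserted by test); a soft-Dice loss is
available by flag, but cross-entropy is the default since the
evaluation surface, not the loss, is what the protocol fixes. The
optimiser and learning rate are unreported upstream; Adam at 1e-3 is
the package default. Per-epoch shuffling derives from the global seed,
making loss trajectories bit-reproducible.

## Splits

The reference split is 8100 training / 900 test patches — a 90/10
ratio; whether it was formed per slide or per patch is unstated. The
default here is *by slide* (no slide contributes to two parts, which
prevents leakage between nearly identical neighbouring tiles);
*by patch* reproduces the exact 90/10 patch counts. Early stopping
needs a validation part, whose construction is also unstated; the
default fractions (0.81, 0.09, 0.10) carve 10 % of the training share.

## Metrics

Dice and IoU are computed from pixel-area confusion counts, excluding
ignored pixels. Dataset aggregation is micro by default (areas pooled
over images before the ratio — stable when a class is rare), macro by
flag; which pooling the original tables used is unstated. The
Hausdorff distance is the undirected max–min Euclidean distance
between the ground-truth and predicted pixel sets of a class, computed
per image with a k-d tree and averaged over images where defined; a
per-image value is skipped when the class is absent from both maps and
flagged undefined when absent from exactly one. Distances are reported
in pixels; an optional physical scale factor is accepted, but no
mm conversion is asserted because the upstream unit chain cannot be
reconstructed. Undefined entries (NaN) are excluded from averages; the
average row is the arithmetic mean of the three defined class values.

## Synthetic slides

The generator emulates only what the pipeline depends on: a
near-white background (grey level 240 > T, gaussian noise σ = 3),
elliptical tissue blobs painted in three colour families — stroma pink
(230, 160, 180), benign light purple (190, 160, 210) with pale lumen
discs, cancer dark purple in three tones for raw labels 3/4/5 — with
per-pixel jitter σ = 8, and a pixel-aligned raw mask. Default slides
are 512² with 2/2/1/1/1 blobs of radius 30–80 px per raw class; later
blobs overwrite earlier ones in both image and mask. Class mean
colours are kept at pairwise RGB distance ≥ 40 (validated), so the
classes are separable by colour alone.

That separability is the point and the limitation: a network that
reaches high Dice here has demonstrated that tiling, masking, freezing,
optimisation, stitching, and scoring are wired correctly — it has not
demonstrated pathology-grade discrimination. Real slides differ in
gland/nuclear morphology, stain variation, compression artefacts, and
class imbalance, none of which are modelled.

## Scaled-down benchmark

The end-to-end acceptance run uses 20 synthetic slides (≈ 60 tiles),
a by-slide 80/10/10 split, and the three-head ensemble at width
multiplier 0.125 (≈ 0.7 M parameters), trained for at most 8 epochs.
Two adjustments are made for this few-step regime, as package choices:
the learning rate is raised to 3e-3 (an epoch is only ~6 optimiser
steps, and the upstream protocol fixes no learning rate) and batch-norm
running-average momentum to 0.3 (so evaluation-time statistics track
the few batches seen). Typical results: training mean Dice ≈ 0.97–0.99,
held-out test Dice ≈ 0.95–0.98, in about four minutes on one CPU. Full-
width networks and ImageNet-pretrained encoders (loadable through the
`load_pretrained_encoder` hook from an `.npz` of encoder weights) are
supported but not exercised by the tests, which all run from seeded
random initialisation.

## Degenerate inputs and tie-breaks

* Dice/IoU with TP = FP = FN = 0 are undefined (NaN), never 0 or 1.
* Hausdorff with an empty point set is undefined.
* A slide with no foreground tile yields an all-background prediction
  and a warning, not an error.
* Thresholding at exactly T is background under both polarities.
* Label merging rejects raw values outside {0..5}, naming the value.
* `argmax` ties in prediction resolve to the lowest class index
  (numpy convention).

## Known limitations

* The Inception-style encoder is a structural analogue, not a
  layer-faithful Inception-V3 reproduction (see above).
* The numpy engine is single-threaded BLAS-bound; full-width training
  on real WSI volumes is out of reach — the design target is
  correctness and CPU-scale reproducibility, not throughput.
* Pyramidal/multi-resolution TIFF reading is not implemented; slides
  are supplied at a single analysis resolution (with an optional
  integer downsample).
* No data augmentation and no stain normalisation are provided, as
  neither is part of the emulated protocol.
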