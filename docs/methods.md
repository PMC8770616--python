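# Methods

`tdluquant` implements an automated pipeline for quantifying age-related
involution of terminal duct lobular units (TDLUs) in breast-biopsy
histology: semantic segmentation of H&E tissue into seven classes,
morphometric feature extraction per TDLU, ordinal involution scoring
against a multi-reader consensus, and association testing of the features
with clinical attributes. Because annotated whole-slide images cannot be
redistributed, the package ships a synthetic scene generator with exact
ground truth, and every stage is developed and validated against it.

## Tissue classes and annotations

Seven integer-coded classes are used throughout: background/unannotated
(0), epithelium (1), intralobular stroma (2), extralobular stroma (3),
acinar lumen (4), adipose tissue (5), small vessel (6) and a derived
border class (7). Annotations are read from ASAP-dialect XML polygons and
rasterized with a pixel-center point-in-polygon rule on half-open
`[0, extent)` coordinates (origin top-left, x = column). Axis-aligned
integer rectangles therefore rasterize to exactly width x height pixels,
which the tests exploit. Overlap follows the anatomical nesting order
stroma < epithelium < lumen — acini are annotated as epithelial outlines
containing lumen polygons — with annotation order breaking remaining ties.

The border class is never annotated: it is carved from the inner
perimeter of every epithelial component to a depth of 3 px (1.5 um at the
0.495 um/px scan resolution) using iterated 4-connected erosion. Carving
inward (rather than dilating outward) conserves epithelium + border pixel
counts and leaves stromal geometry untouched; the erosion treats the
canvas edge as continuing tissue so image boundaries do not become
borders. The operation erodes the epithelium-or-border footprint, which
makes it idempotent. Whether the original protocol centered the border on
the outline or carved it inward is not documented; inward carving is this
package's choice and is isolated behind `build_border_class` for
sensitivity analysis.

## Segmentation network

The segmenter is a U-Net-style encoder-decoder implemented directly in
NumPy (im2col GEMM convolutions with exact manual gradients, verified
against finite differences; Adam optimization). The architecture is
conventional: 3x3 same-padding convolutions with ReLU, 2x2 max pooling,
nearest-neighbor upsampling with skip concatenation, and a 1x1
classification head over 8 logits. Defaults are depth 4 / 32 base filters
/ 512-px patches; the desk-scale experiments use depth 3 / 16 base
filters / 128-px patches, which one CPU trains in minutes.

Training details that matter:

- **Loss.** Pixelwise softmax cross-entropy with background (code 0)
  masked out: slides are exhaustively annotated only inside selected TDLU
  rectangles, so unannotated pixels must not contribute gradient.
- **Class weighting.** Inverse-square-root-frequency class weights
  (normalized to mean 1, computed from the training labels) are applied
  by default. Without them the rare classes (lumen ~2%, vessel <1%,
  border ~2% of pixels) are unstable under plain cross-entropy at this
  model scale: individual small classes collapse into their dominant
  neighbor depending on the run.
- **Augmentation.** Flips, right-angle rotations (applied identically to
  image and label), Gaussian noise (sd 0.03 on [0,1] intensities),
  Gaussian blur (sigma up to 1.2) and per-channel color scale/shift
  (±6%), image-only. Border (7) is a training class — it exists to let
  the counting step separate touching acini — but is merged into
  intralobular stroma before any Dice evaluation, which reports the six
  tissue classes.
- **Schedule.** The learning rate decays geometrically to 10% of its
  initial value across epochs; the checkpoint with the best validation
  loss is kept.

Inference tiles large images (default 256-px tiles, 32-px overlap) and
averages softmax scores before the argmax, weighting each tile by a
linear taper over its overlap margin so that pixels near a tile edge
(clipped receptive field) defer to the neighboring tile's interior
prediction. With a confidently trained network, tiled and untiled
predictions agree on >= 99.9% of pixels.

## Morphometric features

Nine features are computed per TDLU-region label map: TDLU area, acini
count, epithelial area, epithelial-to-intralobular-stroma area ratio,
vessel count, vessel area, adipose area, mean acinar size, and the count
of acini with a large lumen. Conventions:

- The border class is merged into intralobular stroma before any
  measurement; `find_acini` refuses to run on an unmerged map, since
  counting with borders in place would fragment every acinus.
- An acinus is a connected epithelial component of area **strictly
  greater than 800 px** (~196 um² at scan resolution). The threshold is
  assumed to be at scan resolution and is configurable. Connectivity
  defaults to 8 (robust to one-pixel diagonal joins in argmax output) and
  is configurable to 4; both are tested.
- TDLU area = epithelial + lumen + intralobular stroma pixels, an exact
  identity asserted on every call. Mean acinar size is the total area of
  counted components over their number, 0 when none pass.
- A lumen is "contained" in an acinus when its pixels lie in the
  topological holes of the component (hole-filling difference) — acini
  are rings around lumens. "Large lumen" means contained lumen area >=
  800 px, mirroring the acinus threshold scale; the criterion has no
  documented definition and is exposed in configuration.
- The epithelial/stromal ratio uses intralobular stroma only and is
  reported as missing (NaN) when the region has no intralobular stroma,
  never as infinity. Vessels are counted with no minimum area.
- Per-subject summaries are arithmetic means over the subject's included
  TDLUs, with missing ratios excluded pairwise.

## Synthetic scenes

A scene is one lobule: a disc of intralobular stroma holding
non-overlapping acini (epithelial annulus around a lumen disc), embedded
in extralobular stroma with adipose blobs outside the lobule and
capillary-scale vessels (25 um caliber) in and around it. The acini count
is drawn from the reader-study bins per involution level — >40 (level 0),
26–39 (levels 1–2), 10–25 (levels 3–4), <10 (level 5) — and the lobule
disc is sized from the drawn acinar area at a fixed packing fraction
(0.30), so involuted lobules are smaller, as in tissue. Placement is
rejection sampling with bounded whole-layout retries; an impossible
request (e.g., a level-0 lobule on a 256-px canvas) raises an error
naming the conflicting parameters.

Two fidelity points deserve emphasis:

- **Levels sharing a bin share the full count distribution.** The 1-vs-2
  and 3-vs-4 distinctions rest on qualitative cues (acinar packing,
  stromal density, basement-membrane thickening) that human readers can
  see but the nine features cannot. The generated morphometry therefore
  carries only bin-level information about those levels, and a model
  trained on the features cannot out-agree the reader panel on them —
  matching the structure of the real reader study. An earlier design that
  gave paired levels disjoint count sub-ranges leaked the full 6-level
  truth into the features and produced unrealistically high
  model-consensus agreement.
- **Geometry guarantees the counting rule.** Ring radii (default
  24–36 px) and per-acinus lumen fractions are drawn jointly so that the
  epithelial component still exceeds 800 px after the 3-px border carve;
  acini are placed with a >= 3 px gap so components never merge. Acini
  and vessel counts are therefore recovered exactly from the ground-truth
  map, and the generator's "true" areas are pixel counts of its own
  rendering, making the recovery tests exact rather than approximate.
  The ground-truth large-lumen flag uses the same >= 800 px contained-
  lumen rule as the feature extractor, so the two never disagree by
  construction.

Color is a fixed mean RGB per class plus Gaussian stain noise (sd 8 of
255). This is deliberately minimal — it gives the color augmentation
something to normalize while keeping classes identifiable; the palette
separates fat from lumen mainly in the blue channel, since both are
near-white in H&E. The generator does **not** emulate nuclear texture,
chromatin, real stain covariation, out-of-focus regions, duct profiles or
BBD lesions (the reader study scored only normal TDLUs). Passing
segmentation tests therefore demonstrate that the pipeline's machinery is
correct and trainable, not that the network would reach the same accuracy
on scanned slides.

Reader panels add rounded Gaussian noise (clamped to 0–5) to the true
level per reader and flag each (reader, TDLU) ungradable independently at
a configurable rate, so the "any reader ungradable" exclusion retains
(1-u)^4 of TDLUs in expectation. Clinical tables draw demographics with
realistic marginals (ages 35–74 centered at 52, menopause coupled to age,
balanced case/control) and generate each feature as mean + sd x (age
slope x (age-52) + planted standardized attribute effects + standard
Gaussian noise); planted effects and the age trend are both overridable,
and the null configuration (no effects, no age trend) is what the
calibration experiment uses.

## Scoring and statistics

Consensus of four readers is the majority vote; a 2-2 or 1-1-1-1 split
takes the ceiling of the mean. A 2-1-1 split is treated as a majority of
the unique mode — the documented tie rules enumerate only two-way and
four-way splits, so plurality-of-two is this package's completion of the
rule, with a configuration switch to route 2-1-1 to the average instead.
"Rounded up" is the exact ceiling (2.5 -> 3, 8/3 -> 3). Leave-one-reader
consensus over the remaining three uses majority-of-two, ceiling of the
mean on a three-way split.

The feature-to-score model is a 500-tree random forest (all other
parameters at library defaults, recorded in metadata), evaluated by
stratified tenfold cross-validation against the consensus: every TDLU is
predicted exactly once out-of-fold, folds are reduced with a warning if
the rarest class has fewer members than folds, and the final model is
refit on all data.

Agreement uses Cohen's kappa implemented from the weighted formulation
(kappa = 1 - sum(w O)/sum(w E), linear weights |i-j| or 0/1 unweighted)
and cross-checked against an independent reference implementation in the
tests. Both weightings are always reported: the source material is
internally inconsistent about which one its headline value uses, so
neither is asserted against it. Dice is pooled (micro) across test pairs
— intersections and mask sizes summed before the ratio — with the overall
score weighted by ground-truth pixel counts per class; mean-of-pairs
pooling would weight small regions equally and is not what "weighted
according to samples per class" describes. Empty-empty classes score 1.0
(absence correctly predicted) and are flagged. Confidence intervals are
percentile bootstrap (n = 2000) resampling the natural unit: TDLUs for
kappa, annotated regions for Dice (the resampling unit for Dice is not
documented in the protocol; regions are this package's choice).

Association analysis transforms each per-subject mean feature to van der
Waerden scores Phi^-1(r/(n+1)) (average ranks on ties, missing stays
missing) and fits OLS of the score on one attribute at a time, optionally
age-adjusted. Ordered categories are coded as ordinal trends 0/1/2
(none<partial<complete, NP<PDWA<AH, never<former<current); binaries 0/1;
risk scores standardized. ER status is analyzed among cases only, since
controls have no tumor to type. p-values are two-sided, reported to three
decimals in the heat map, and deliberately uncorrected for multiplicity
(the analysis is exploratory); missing data are handled complete-case per
cell.

## Desk-scale experiment sizes

The packaged experiments are sized for a single CPU: segmentation trains
on 40 scenes (1024² px, ~8 scenes per involution level) for 8 epochs of
8x128-px patches per scene and evaluates on 12 held-out scenes; scoring
renders 572 scenes distributed as the reader study's consensus categories
(90/46/51/68/166/151 for levels 0–5) with per-reader score noise sd 0.7;
calibration runs 1000 null tables of 120 subjects plus one 200-subject
table with a planted standardized effect of -1.0. At these sizes the
held-out weighted Dice is ~0.98-1.00, the model-consensus linear kappa ~0.78
(the noisy-consensus ceiling — consensus vs truth — is ~0.88), the null
rejection rate ~5%, and planted signs are recovered. The kappa sits near
the upper edge of the "substantial" band (0.61–0.80) and occasionally
crosses it for some seeds; that reflects genuine simulation variance at
the band edge, not a tuned quantity.

## Known limitations

- The synthetic color model makes segmentation easier than real H&E;
  Dice on these scenes is an upper bound on slide performance.
- TDLU detection/localization is out of scope: label maps are assumed to
  cover one human-selected TDLU region.
- The network is CPU-sized; training it at the default 512-px/depth-4
  configuration on real slides would require a GPU-backed reimplementation
  of the same interface.
- Gail and BBD-BC risk scores are consumed as numbers; their internal
  computation is out of scope, as is case-control risk prediction.
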