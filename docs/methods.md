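# Methods

## Problem and approach

Classifying a segmented mammographic mass as benign or malignant is hard
because the two classes share texture statistics; single-crop CNN
classifiers are brittle and sensitive to exactly how the crop was taken.
`masscontext` implements a *context-ensemble*: one CNN backbone scores
several crops (ROIs) of the same mass that differ in how much
surrounding tissue they contain, and the per-ROI predictions are fused
into a single decision. Diversity comes from the inputs, not from
training multiple networks, so the cost of the ensemble is a constant
factor at inference only.

The pipeline is: ROI extraction → (optional) contrast enhancement →
per-ROI CNN probabilities → fusion. Training fine-tunes the backbone on
an augmented set of crops and then fits the stacking meta-classifier on
the backbone's own predictions.

## ROI extraction

Two schemes produce the test-time ensemble for one mass with bounding
box `B`:

* **Scale-based (`MS1`/`MS2`/`MS3`)** — `B` is expanded by `p%` of each
  side length on each edge for `p` in a scale set ({5,10,15,20,25},
  {10,20,30,40,50}, {50,60,70,80,100}), each expanded crop resized
  (anisotropically, bilinear) to 224×224. ROIs are ordered by ascending
  scale. The notation `p:p` is read as a symmetric per-edge percentage
  expansion. Crops clamp at the image border (no padding).
* **Translation-based (`MC1`/`MC2`)** — the tight crop is isotropically
  rescaled so its *smaller* side is 256 px (no aspect distortion), then
  the four corner 224×224 windows and the center window are taken,
  each also horizontally flipped. Together with the whole rescaled crop
  resized to 224×224 this gives the 11-ROI scheme `MC2` with fixed
  order `[full, TL, TR, BL, BR, C, TLf, TRf, BLf, BRf, Cf]`. `MC1` is
  the 3-ROI subset `[full, C, Cf]`.

Two conventions here are package decisions where the method description
leaves room: the scheme's stated count of 11 equals 5 crops + 5 flips
plus *something*; we use the whole rescaled crop as the eleventh ROI
(the minimal symmetric completion), and the 3-context variant is the
full/center/center-flip subset. The ROI order is part of the contract —
stacking features are positional.

All resizes are bilinear with output dimensions rounded half-up;
everything is deterministic.

## Enhancement

For low-contrast (digitized film) sources each ROI passes through
global histogram equalization (256 bins over the ROI's own range), then
unsharp masking `x + 0.8·(x − G_σ(x))` with σ = 1 px, then a 3×3 median
filter; the result is clipped to the input range. The chain runs on the
resized 224×224 ROI by default so the kernel scales are uniform across
mass sizes (configurable). Full-field digital images with good native
contrast should run with enhancement disabled (bit-exact identity).

## Training-set augmentation

Labeled regions are few, so the training set is the union of three
augmentation families per region: sliding-window crops (a square window
of the bbox's longer side + 20 px, stepped in 10-px strides over every
placement that inscribes the whole mass and stays in the image), the 8
lossless orientation variants (rotations by 0/90/180/270° × horizontal
flip) of each window, and the 5% and 10% bbox expansions. Counts obey
closed-form formulas and the output order is deterministic. Orientations
compose with windows; scale expansions are separate additions. Rotations
are applied to the square crop rather than the whole image — equivalent
for 90° multiples.

## Backbones

The base backbone is a bottleneck ResNet-50 (groups of 3/4/6/3 blocks,
group output widths 256/512/1024/2048) whose classifier is a 2-neuron
fully connected layer. Four *density-specific* variants, one per
BI-RADS breast-density class, modify the last block of the deepest
group and fuse local and global features so that exactly **2048**
channels enter the classifier in every variant:

| variant | surgery | features into classifier |
|---|---|---|
| DI | drop final 1×1 conv, its ReLU and the shortcut; GAP ∥ GMP on the 512-ch map; projection from the first group-5 block's ReLU (1×1 conv 1024 + 7×7 max pool) | 512+512+1024 |
| DII | final conv → 1024 filters, shortcut dropped; GAP ∥ projection (1×1 conv 1024 + 7×7 max pool) | 1024+1024 |
| DIII | final conv → 512 filters, shortcut dropped; GAP ∥ GMP; projection from group-4 block-6 ReLU (1×1 conv 1024 + 14×14 max pool) | 512+512+1024 |
| DIV | final conv → 1024 filters, shortcut dropped; GAP ∥ GMP | 1024+1024 |

The architectures are expressed as declarative graph specs with channel
contracts checked both by propagation over the graph and by executing a
forward pass. Projection "conv blocks" are conv + batch norm; the
projection max pools are global over their stated grids (stride =
kernel, 1×1 output). Note the projection branches *add* parameters: DI–
DIII are slightly larger than the base model, DIV slightly smaller.

The engine underneath is a compact NumPy computational-graph library
(im2col convolution, batch norm, pooling, residual add, concatenation,
full backprop, SGD with momentum). It is CPU-only and deliberately
small; a reduced-depth `tiny` variant (two conv stages, GAP ∥ GMP head,
~2.4k parameters, 1-channel input) exists for experiments that must
train from scratch in minutes. Grayscale ROIs are standardized per-ROI
(zero mean, unit variance) and replicated across the input channels.

Fine-tuning uses SGD with momentum 0.9, learning rate 1e-4 and
mini-batches of 64, with a stratified 90:10 train/validation split,
early stopping (patience 5) and best-validation-checkpoint restore. The
1e-4 rate is a *fine-tuning* rate; the `tiny` variant trains from
random initialization and defaults to 1e-2. Epoch budget defaults to 30
(10 in the estimator, whose desk-scale runs converge faster).

## Fusion

Let `(p1_i, p2_i)` be the (benign, malignant) probabilities of ROI `i`.

* **majority vote** — label with more per-ROI argmax votes;
* **soft vote** — argmax of the per-class means;
* **max vote** — argmax of the per-class maxima;
* **stacking** — the vector `(p2_1, …, p2_n)` (malignant probability
  per ROI, ROISet order; the benign one is redundant) is standardized
  and fed to an SVM (RBF, linear or polynomial kernel; C = 1, scaled
  gamma, degree 3) or a random forest, trained on the backbone's
  predictions over the training + validation regions.

All ties resolve to malignant: the decision rule "benign iff
p_benign > p_malignant" routes exact ties to the positive class, the
right failure direction for screening. Voting rules are permutation
invariant; stacking is deliberately not.

## Metrics

With malignant positive: Sen = TP/(TP+FN), Spe = TN/(TN+FP),
Acc = (TP+TN)/N, Cohen's kappa = (Po−Pe)/(1−Pe) with Po = Acc and
Pe = [(TP+FN)(TP+FP)+(FP+TN)(FN+TN)]/N², F1 = harmonic mean of
precision and recall (a variant using sensitivity/specificity is
available behind a flag but is *not* what published tables of this
method family actually contain), AUC by the trapezoidal rule with
midrank ties. Percentages are rounded half-up to 2 decimals;
zero-denominator metrics report as undefined, never as 0.

`reconstruct_confusion` inverts printed Sen/Spe percentages and class
counts to the implied integer confusion matrix (rounding half-up).
Recomputing all metrics from that matrix reproduces a self-consistent
published row to the printed precision, which is how result tables are
audited here without any dataset.

## Synthetic phantoms

The generator emulates the *shape* of the real task, not its content: a
512×512 8-bit (optionally 16-bit) textured background — Gaussian-
filtered noise whose amplitude grows with the BI-RADS density tag —
plus one bright lesion. Benign lesions are smooth ellipses (axes 28–50
px, aspect 0.55–0.85) with a sharp margin (mask blur σ = 1); malignant
lesions are star-convex blobs (base radius 28–45 px) with 8–14 angular
spicules and a blurred margin (σ = 4). The bounding box is the tight
box of the lesion support. Classes are separable by construction along
margin sharpness, boundary roughness and eccentricity — the axes
radiologists describe — and a three-feature linear probe verifies this
independently of any CNN.

What passing tests on phantoms shows: the pipeline's plumbing,
determinism, counting, contracts, and that the ensemble machinery can
exploit a real discrimination axis end to end. What it does not show:
performance on actual mammograms, which requires the real datasets and
ImageNet-pretrained weights, both outside this package's scope.

## Problem sizes and numerical choices

The end-to-end reference run (also exercised by the test suite) uses
200 phantoms (100 per class, 70:30 split), `MC2` extraction, the `tiny`
backbone, RBF-SVM stacking, 8 epochs, and a reduced augmentation plan
(stride 20, rotations {0°, 180°} × flips, 5%/10% expansions) — chosen
so a full run fits in a few CPU-minutes while every stage still
operates at its real contract (224×224 inputs, 11-ROI stacks). With
seed 42 it reaches stacked test accuracy ≥ 0.90 and at least the
single-ROI accuracy.

Other conventions: 0-based half-open boxes; bilinear resampling with
round-half-up output sizes; float32 network arithmetic; He-normal
initialization; all randomness flows from explicit integer seeds
(NumPy `default_rng`), and repeated runs with the same seed are
bit-identical. Degenerate inputs fail loudly (empty ROI sets, windows
smaller than the bbox, single-class training sets, mismatched stack
lengths) rather than being silently corrected.

## Known limitations

* No pretrained ImageNet weights are bundled; the deep variants start
  from random initialization, so desk-scale training uses `tiny`.
* The deep backbones run on CPU at ~1 s per 224×224 forward pass —
  fine for contract probing and small studies, not for fine-tuning at
  dataset scale.
* The eleventh ROI of the translation scheme and the composition of
  the 3-context variant are package conventions (see above).
* Phantoms make no claim of anatomical realism; results on them bound
  nothing about clinical data.
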