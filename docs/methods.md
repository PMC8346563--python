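# Methods

This note documents the models, procedures, parameter choices and known
limitations of the package. It states nothing the tests or
`scripts/acceptance.py` do not themselves compute.

## The cascade

The pipeline is a two-stage cascade over fixed 224×224 patches of a
padded fundus photograph. Stage one is a linear SVM ("gate") over a
fixed-length patch feature vector; stage two is an object detector run
only on patches the gate accepts. The design assumption is cost
asymmetry: patch classification is orders of magnitude cheaper than
detection, and most patches of a screening image are lesion-free, so a
moderately accurate gate buys large savings in detector invocations and
false positives at a small cost in missed lesions. The evaluation
protocol quantifies exactly that trade: the gate's relative change of
the false-positive and false-negative rates at the exudate and image
level.

## Coordinate and padding conventions

All rectangles are 0-based, half-open `[x0, x1) × [y0, y1)`, so widths
are `x1 − x0` and edge-sharing boxes are disjoint. Padding appends black
rows/columns on the right and bottom only, to the next multiple of the
tile size; images are never resized or shifted, so ground-truth mask
coordinates remain valid in the padded frame. The black threshold for
"background" is a brightest-channel intensity ≤ 10 (of 255): clinical
photographs have near-black, not exactly-black, surrounds after
compression.

## Patch augmentation

Training patches for the detector are the positive patches (those whose
window intersects at least one ground-truth box by ≥ 1 pixel — negatives
never enter detector training) of the base grid plus three half-stride
shifted grids (offsets (112, 0), (0, 112), (112, 112), step 224, windows
fully inside the padded image), each with its three mirrored variants
(horizontal, vertical, both; ground-truth boxes are flipped alongside
the pixels). Mirroring is applied to originals *and* shifted patches:
the count identity 3 × (originals + shifted) = mirrored is asserted in
the tests and recomputed by the acceptance script (3 × 1189 = 3567;
4756 patches in total at the reference counts).

Contrast jitter (the "contrast augmentation" variant) applies
`out = clip(g·(p − μ) + μ + b·255)` with `g ~ U[0.8, 1.2]`,
`b ~ U[−0.2, 0.2]` and μ the patch mean over non-background pixels,
leaving background pixels untouched. The stated magnitude band is
"0–20 %"; a symmetric band around identity was chosen because the
augmentation's purpose is to widen the intensity distribution in both
directions, and mean-anchoring keeps the adjustment a contrast change
rather than a brightness drift. `max_frac = 0` is exactly the identity;
background pixels are fixed points for every draw — both are property
tests.

## Gate dataset and training

For each cross-validation fold, the gate's dataset holds all positive
patches of that fold's images plus exactly twice as many negatives,
sampled without replacement and stratified half from retinopathy-image
background and half from healthy images (remainder from the larger pool
when one is short) — healthy backgrounds differ subtly from
retinopathy backgrounds, so both matter. Negative candidates with more
than a third background pixels are ineligible; four all-zero "pure
black" patches are appended so heavily padded patches classify
correctly. An insufficient pool is a hard error naming the shortfall,
never a silent ratio change. Fold datasets are built from each fold's
own images so cross-validation folds stay disjoint at the image level.

Training is the classical maximum-margin linear separator (hinge loss,
penalty C = 1 by default; solver tolerance left at library defaults).
Features are not standardised: both shipped extractors emit bounded
values. A margin of exactly zero classifies *positive* — the pre-scan
should err toward sending a borderline patch to the detector, because a
gate false negative is unrecoverable downstream while a false positive
merely costs one detector call.

Two extractors satisfy the `patch → fixed vector` contract. The
production contract is the 2048-dimensional final average-pool of a
pretrained 50-layer residual network (an optional adapter requiring the
deep-learning extra; its dimension contract is importable and tested
without it). The default CPU extractor is deterministic and
hand-crafted: per-channel 16-bin histograms, gradient-magnitude
statistics, contrast-tail fractions (share of non-background pixels
exceeding the patch's background median by 10–120 intensity units), and
bright-blob morphology (component count and largest/second-largest
component area fractions at excess > 40). The tail features respond to
small bright lesions regardless of position; the blob features separate
many-small-deposits patches from single-large-structure patches such as
the optic disc, which is the dominant hard negative.

## Detection backends

The backend interface is `fit(patches_with_boxes, config)` /
`predict(model, patch)`. The configured training recipe — SGD with
momentum, mini-batch 2, learning rate 3·10⁻⁴, ten epochs, anchors
derived from training-box sizes, anchor labelling negative at max-IoU in
[0, 0.1) and positive in [0.1, 1] — is echoed in every trained model's
metadata. Anchor dimensions are width/height quantiles of the training
boxes at equally spaced probability levels (median for a single anchor),
floored at one pixel: a distribution-driven choice that adapts to lesion
scale without hand-set scales. An early-stop callback (stop after five
consecutive validation worsenings) exists but is off by default; the
final recipe is a fixed ten epochs.

The deep backend adapts torchvision's region-proposal detector and is
optional at install time. The **reference backend** is the tested
surface: per patch, the background is the median intensity of
non-background pixels; candidate regions are 8-connected components of
pixels exceeding background by δ; each is scored by its peak excess
divided by a scale, clipped to [0, 1]. "Training" is a closed-form
percentile fit pooling training patches: δ sits midway between the 95th
percentile of background excess and the 25th percentile of lesion
excess (floored at 5), and the score scale is the lesion-excess 90th
percentile, so a lesion as bright as the training upper decile scores 1.
Components below 4 px are discarded as noise. The backend's monotone
threshold knob is the score floor: raising it can only remove
detections (a property test); the structural threshold δ is fixed by
training. Detections are sorted by descending score with ties broken by
box position.

Whole-image inference pads, tiles the *base grid only* (shifted grids
are a training-time augmentation; overlapping inference tiles would
require duplicate-box merging the protocol never defines), optionally
gates, detects per retained patch, and maps boxes to image coordinates
clipped to the pre-padding extent, so detections never overlap padding.
Per-patch scores record the maximum detection score of every grid patch
(0 when gated out or detection-free) and feed the image-level rule.

## Evaluation protocol

Detections and ground truth are compared as filled rectangles. In
strict mode a ground-truth object is found iff some detection box covers
strictly more than `overlap_min` (default 20 %) of the object's box
area; the any-overlap mode (one shared pixel) serves datasets whose
expert annotations are deliberately oversized regions. The overlap
denominator is the ground-truth box area — the miss definition is
written from the ground-truth side — with intersection-over-minimum
available behind a flag. Pixel accounting: found boxes → TP, missed
boxes → FN (minus any TP overlap), unmatched detections → FP (minus
pixels already TP/FN; a matched detection's spill-over outside its
object is deliberately not punished as FP), remainder → TN. The four
counts always sum to the image pixel count, and the whole procedure is
checked against an explicit Python-set oracle on hundreds of random
scenes.

Undefined metrics (zero denominators) are reported as `None`, never as
0 or 1. Fold aggregation uses the sample standard deviation (ddof = 1;
k is small) and averages F1 across folds rather than recomputing it
from averaged sensitivity and PPV — the two differ whenever folds vary,
and a dedicated test pins the distinction. AUC is the probability that
a random positive image outscores a random negative one (ties ½),
computed via the standard library routine and cross-checked against an
exhaustive pairwise oracle.

## Synthetic data: what it does and does not emulate

The generator renders a radial orange-red gradient inside a circular
field of view on black, optional dark vessel curves and a bright optic
disc, additive Gaussian noise (σ = 4 by default), and lesions as filled
ellipses (semi-axes 3–15 px by default) whose intensity exceeds the
local background by a sampled gain, with Gaussian-softened edges in the
image while the mask keeps the exact ellipse footprint. Overlap-free
placement is enforced by default so the requested lesion count equals
the mask's component count (a flood-fill-oracle test); overlapping
lesions would merge into one component and hence one ground-truth
object, consistent with the component-based object definition. The
optic disc is deliberately bright enough to trigger the reference
detector — it supplies the non-trivial negatives that make gating
measurable.

What it does *not* emulate: texture and vessel branching realism,
haemorrhages/microaneurysms/drusen, illumination artefacts, camera
noise statistics, inter-expert disagreement. Passing tests therefore
demonstrate the correctness of the pipeline's mechanics and the
direction of the gate's effect, not clinical-grade detection accuracy;
headline scores on real datasets require real images and a pretrained
deep backbone and are out of scope here.

## Scaled-down study sizes

The end-to-end properties run on seeded synthetic datasets of 20–40
images at 672×672 (nine patches per image), with 1–4 lesions per
positive image; the acceptance study uses 40 images with lesion gains
80–120 against noise σ = 4 ("high-gain" conditions), training on 8
positive + 8 healthy images and evaluating on the held-out 28. These
sizes were chosen as the smallest at which fold construction, the 2:1
negative sampling, and both evaluation levels are all exercised with
non-degenerate statistics.

## Known limitations

- The reference detector is contrast-based; lesions darker than δ over
  their surroundings are invisible to it, and any bright compact
  structure is a candidate. It stands in for pipeline mechanics, not
  for a trained deep detector.
- The hand-crafted gate features are tuned to the synthetic image
  model's contrast structure; on real photographs the residual-network
  extractor contract is the intended feature source.
- Multi-expert consensus uses ceil(quorum·n) with a small numerical
  guard; quorums implying fewer than one expert are floored at one.
- The deep backend adapter is provided untested in CPU-only
  environments and is excluded from the default dependency set.
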