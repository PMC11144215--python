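# Methods

## Pipeline overview

The device processes one H&E whole-slide image in a fixed order:
metadata gates (tissue site must normalize to "Bladder", disease stage
to "MIBC"), image read checks, thumbnail and pen/background masks, a
non-overlapping 224×224 tile grid at 10×, per-tile quality scoring,
the score > 0.75 filter, tile embedding into an N×512 bag, attention
pooling to a slide likelihood, and thresholding (optionally into three
likelihood tiers). Every expected failure mode maps to one of six
exact user-facing messages; the strings are part of the interface and
are tested byte-for-byte.

## Tile quality control

The score formula and its threshold are fixed:
`score = 1 − 10/(10 + tissue_percent²·ln(1 + color·saturation·quantity)/100)`,
pass iff score > 0.75. The score is bounded in [0, 1), is zero whenever
there is no tissue or the quantity factor is zero, and is monotone
non-decreasing in each argument; algebraically a tile passes iff
`tissue_percent²·ln(1 + factor product) > 3000`, which the suite checks
against direct scoring.

The factor definitions are reconstructions in the spirit of the
open-source WSI filter helpers such pipelines are built on; the exact
numeric semantics of the production factors are not public, so ours are
documented choices, not claimed bit-compatible with any deployed device:

- **Pen masks** — a pixel is ink when any rule of a small per-color bank
  of relational channel tests fires (green pen: red below / green and
  blue above a threshold triple; blue and red pens analogous). Six
  triples per color, listed in `qc.py`.
- **Background mask** — all pairwise channel differences ≤ 15 (the gray
  tolerance).
- **tissue_percent** — 100 × fraction of tile pixels that are neither
  pen nor background. The quantity factor bins the *post-pen-exclusion*
  percentage: 0 → 0.0, (0,10) → 0.1, [10,80) → 0.2, [80,100] → 1.0.
- **color_factor** — `2·max(0, 1 − d̄/90°)` where d̄ is the mean circular
  hue distance of tissue pixels to the purple-pink arc [250°, 345°];
  range [0, 2], larger is more H&E-like.
- **saturation_factor** — mean HSV saturation plus mean value over
  tissue pixels; range [0, 2], near 0 for washed-out tiles.

The factor ranges were chosen so that clean, fully saturated tissue
(product ≈ 2) passes at ≥ 80% tissue while background and mostly-empty
tiles cannot (the pass condition needs a factor product > e^0.3 ≈ 0.35
even at 100% tissue). Masks are computed on a divisor-32 thumbnail and
nearest-neighbor upsampled to tile coordinates — a speed/fidelity
trade-off that is exact for the block-uniform synthetic slides and
adequate for stroke-scale artifacts; color/saturation factors always use
full-resolution tile pixels. Partial edge tiles are dropped; coordinates
are 0-based half-open pixel intervals at 10×. Slides stored at 20×/40×
are area-downsampled to 10× only when resampling is explicitly enabled;
by default the magnification error fires, which keeps the device's
behavior conservative.

## MIL model

Plain (non-gated) attention: `a = softmax(wᵀ tanh(V h))` with hidden
dimension 128, followed by a two-logit softmax head; the likelihood is
the positive-class probability. Attention weights are non-negative, sum
to one, are permutation-equivariant, and leave the likelihood invariant
under tile duplication — all asserted as properties. No post-hoc
calibration is applied to the likelihood.

The backbone contract is any callable tile → 512-vector. The bundled
backbone is a deterministic handcrafted descriptor: RGB/HSV/gradient
histograms, channel statistics, and connected-component morphology of
the hematoxylin-purple mask (component count and area statistics — the
features that separate compact solid tumor nests from dispersed nests),
mixed by a frozen Gaussian random projection into 512 dimensions. It is
linear in the descriptor, so class structure separable in descriptor
space remains separable in embedding space. A pretrained CNN with a
512-d pooled output drops into the same contract; the trainer never
back-propagates into the backbone, which is what makes a pure-NumPy
analytic-gradient implementation (attention + head only, Adam,
decoupled weight decay, dropout on the pooled embedding) sufficient and
exactly reproducible from one seed.

Defaults follow the production recipe — learning rate 1e-5, weight
decay 1e-4, dropout 0.5, class-weighted cross-entropy, one slide-bag
per optimization step, 5-fold cross-validation on an 85/15 split
stratified by label × cohort, model selection by PPV at 0.9 sensitivity
(largest qualifying threshold; ties to higher specificity then lower
index). Desk-scale runs with the frozen descriptor backbone use
learning rate 3e-3 and 120 epochs: the tiny head over fixed features
tolerates — and needs — a much larger step size than end-to-end CNN
fine-tuning, and 40 bags × 120 epochs ≈ 5k steps converges in seconds.
Epoch budget and batch construction are not externally specified
anywhere; one-bag steps and a fixed epoch count are this package's
choices.

Stain augmentation deconvolves tiles into hematoxylin/eosin/residual
optical densities (the classic H&E basis), scales each stain channel by
1 ± magnitude (default 0.05) with a small additive shift, and
reconvolves; magnitude 0 is the exact identity. Heatmaps fill each
tile's footprint with its attention weight divided by the maximum
weight, so the brightest tile is always 1.

## Synthetic slides

The generator emulates exactly what the pipeline needs to be falsifiable:
purple/pink H&E hues (stroma RGB ≈ (233, 208, 224), hue ≈ 322°; nuclei
HSV ≈ (270°, 0.5, 0.6) — both inside the QC color arc and outside the
gray tolerance), two planted tile morphologies (solid nests: 2–4
compact purple clusters of radius 32–52 px; dispersed: 40–70 scattered
4–6 px nests), near-uniform gray background, saturated red/green/blue
pen strokes, and Gaussian-blurred tissue. Composition is count-exact:
tile-kind counts are `round(fraction × n_tiles)` and cohort positives
are `round(n_slides × prevalence)` (stratified, not Bernoulli), with
per-slide and per-tile seeds hashed from the cohort seed so identical
inputs give byte-identical TIFFs. Cohort prevalence defaults to 12%,
matching the development population the device targets.

Learnability is guaranteed by construction, not assumed: the mean
connected-component area of the purple mask ("cluster compactness")
separates the two morphologies by roughly two orders of magnitude
(checked at p < 0.01 on 50 tiles per class). What the generator does
*not* model — nuclear texture, stain-vendor variation, scanner color
profiles, tissue-boundary tiles, real morphological ambiguity — bounds
what passing tests mean: they demonstrate that the pipeline recovers a
planted, separable signal end to end, not that any particular accuracy
transfers to patient slides.

The desk-scale study conditions are 60 slides of 1120×1120 px (5×5
tiles) at 40% prevalence, signal fraction 0.5, split 40 train / 20
held out; positive-slide count (24) supports the paired attention
comparison. On these conditions the trained model reaches hold-out
AUC 1.0 and places essentially all attention on the planted solid-nest
tiles (mean within-slide attention difference ≈ 0.1, Wilcoxon
p < 1e-6).

## Screening analytics

All deployment quantities are closed-form in (sensitivity, specificity,
prevalence): expected confusion cells, the test-reduction rate
`sp·(1−π) + (1−se)·π`, tier masses and per-tier prevalences by Bayes'
rule (with the mixture identity Σ fraction·prevalence = baseline checked
to 1e-9), and the cost model, which satisfies the exact conservation
with-AI cost + savings = without-AI cost. Confusion matrices are
real-valued expectations with an optional integer-rounding display mode.
Metrics with zero denominators are reported as undefined (None), never 0.

AUC uses the Mann–Whitney concordance convention (ties half credit) via
scikit-learn and is tested against an O(n²) pairwise oracle. Binomial
confidence intervals default to the Wald normal approximation (matching
typical deployment-report digits); the exact Clopper–Pearson interval is
available and recommended for small n or extreme proportions.

The two-sided exact binomial power builds the rejection region under
the null — default the *central* convention, each tail holding at most
α/2 of null mass; doubling-one-sided-p and minimum-likelihood orderings
are selectable — and sums alternative-hypothesis probabilities over the
region. For the sensitivity-validation design (n = 150, p₀ = 0.8,
p₁ = 0.9, α = 0.05) the central convention gives 0.928, i.e. 93% power
to printed precision.

## Numerical and degenerate-case choices

- Likelihood binarization is boundary-inclusive (likelihood ≥ threshold
  → positive), as is the High-tier cut; tiers partition [0, 1] and
  binarizing at the low cut equals "not Low".
- Metadata comparison trims whitespace and case-folds by default; a
  strict mode does literal comparison.
- `filter_tiles` uses strict `>` at 0.75, so a tile scoring exactly the
  threshold is dropped.
- Softmaxes subtract the maximum before exponentiation; cross-entropy
  clips probabilities at 1e-300.
- Feature standardization (training-set mean/std) is stored in the model
  checkpoint, which is a single JSON file.

## Known limitations

The handcrafted backbone is engineered for the synthetic morphologies;
on real slides a pretrained CNN backbone should replace it (the
contract is one callable). Attention training with a frozen backbone
cannot discover features the descriptor does not encode. The QC factor
constants are reconstructions; a deployment against scanner data should
re-examine the pen rule bank and the hue arc. The blur artifact is
generated but not separately scored, mirroring the device's QC design.
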