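# Methods

## Problem and model

The package treats invasive-cancer (IC) detection in whole-slide images as
per-tile binary classification by an ensemble. Tiles are squares of
`side_px` = 598 px at 0.4532 μm/px (271 μm), indexed by grid position with
0-based, half-open pixel bounding boxes. An ensemble of n base models each
maps a tile to a continuous score in [0, 1]; scores are binarized at
per-model thresholds, aggregated by majority vote, and summarised by the
agreement statistic a(x) ∈ {0, …, n} — the number of models voting for the
tile's true class.

The statistical backbone is the binomial vote model: if each of T voters is
independently correct with probability p, the probability that a strict
majority (k ≥ ⌊T/2⌋ + 1) is correct is the binomial upper tail, which
exceeds p for p > 0.5 and odd T ≥ 3 and grows toward 1 with T. The package
computes this closed form exactly (integer binomial coefficients, float
powers) and verifies it by simulation.

## Tile labeling

A tile receives annotation class c iff its center is covered by a polygon
of class c. "Covered" is closed-polygon semantics (boundary counts as
inside), delegated to shapely's vectorized `covers`; polygon holes exclude
centers inside them. Class names are matched case-insensitively after
whitespace normalisation and stored in normalised form; classes outside
the IC set are kept rather than bucketed, since the per-class confusion
breakdown needs them. The binary label is l = 1 iff the tile's class set
meets the configured IC set, default {invasive cancer, invasive lobular
cancer}; an empty class set gives l = 0.

Annotation practice sometimes additionally requires a minimum fraction of
the tile's area inside the polygon; this is exposed as
`min_area_fraction` (intersection area ≥ fraction × tile area, computed
with shapely, applied on top of the center rule) but defaults to 0 because
the center position is the primary rule. No published value exists for the
area fraction, so none is baked in. Likewise, excluding tiles that carry
artifact annotations is available (`drop_tiles_with_classes`) but off by
default.

## Partitioning

The train/test split and the N training divisions stratify on the *joint*
cross of NHG × ER × HER2 × Ki67 with "missing" as a level — the strictest
deterministic reading of "keeping the proportion of clinical features".
The test count is round(test_fraction × n), apportioned to strata by
largest remainder. Divisions are formed by shuffling each stratum with the
seed and dealing members consecutively through a single global round-robin
pointer; because each stratum occupies a contiguous run of pointer values,
both the global division sizes and any stratum's per-division counts
provably differ by at most 1. A per-stratum random multinomial would be
simpler but makes neither bound provable. All randomness comes from
explicit integer seeds; plans serialize to CSV + a JSON sidecar and
reproduce byte-for-byte.

Real cohorts may contain several WSIs per patient; nothing here groups at
patient level, because no patient linkage is modelled. A tuning subset for
early stopping of real CNNs is deliberately not carved out of divisions;
the adapter contract leaves its fraction as a free parameter.

## Score simulator

Each simulated base model has an operating threshold τ\* ∈ (0, 1)
(deliberately ≠ 0.5: softmax CNNs are not calibrated, and the calibration
stage must have something nontrivial to find), a marginal accuracy
p_correct, a concentration parameter, and a correlation ρ. Per tile: a
uniform draw decides correctness against p_correct; the score is then
placed on the correct or wrong side of τ\* at offset u ~ Beta(1, c) scaled
into the side interval (above: τ\* + (1 − τ\*)u; below: τ\*(1 − u), clamped
strictly below τ\*). Beta(1, c) has density c at 0 for every c > 0, so
score mass always abuts the threshold and the Dice-optimal threshold is
identifiable from data — the property the threshold-recovery tests rely
on. c < 1 polarizes scores toward 0/1 (confident, CNN-like; default 0.7),
c > 1 concentrates them near τ\*.

Correlation is induced by a shared-draw mixture: with probability ρ a
tile's (correctness, offset-quantile) pair is replaced by a per-tile draw
shared across models, so ρ = 0 gives conditionally independent votes (the
binomial theory's premise) and ρ → 1 collapses the ensemble to a single
voter — letting tests violate the independence assumption measurably. One
global seed expands to substreams via `SeedSequence.spawn`: child 0 for
the shared draws, child i+1 for model i.

The default family is 10 models, p_correct = 0.8, thresholds evenly spread
over 0.25–0.65, ρ = 0.

## Threshold calibration

Candidate thresholds are the midpoints between consecutive distinct scores
plus {0, 1}. Predictions, hence Dice, are piecewise constant in the
threshold with breakpoints only at observed scores, so this finite grid is
an exact search over all real thresholds; a dense-grid oracle test
confirms equivalence. Dice at every candidate is evaluated in one pass via
Dice(τ) = 2·TP(τ) / (P + Q(τ)) with sorted cumulative counts. The pooled
objective (one Dice over all out-of-division tiles jointly, not averaged
per division) is used; ties are broken toward the smallest threshold,
favoring sensitivity. Dice of the IC class only is optimised — not a
macro average — matching the single reported Dice figure of ensemble
evaluations. Calibration never touches held-out test WSIs. The degenerate
all-equal-scores input leaves candidates {0, 1}; with no positives
anywhere Dice is defined as 1.

## Voting, ties, agreement

Binarization uses ≥ at the threshold (a score exactly at τ votes 1).
Majority requires vote_sum > n/2. With even n a tie (vote_sum = n/2) is
possible; it is resolved deterministically by comparing the tile's mean
raw score to the mean of the calibrated thresholds (≥ → IC) and flagged
per tile. The binomial closed form counts only strict majorities, so its
empirical counterpart in `verify_theory` is the strict-majority rate
1[a(x) ≥ ⌊n/2⌋+1]; the tie-broken prediction accuracy is reported
separately and sits slightly above the closed form whenever resolved ties
land correctly (at p = 0.6, T = 10 the tie state holds ≈ 20 % of the
mass, so conflating the two would be a real error, not a tolerance
issue). For unlabeled tiles the reported quantity is self-agreement —
votes for the *predicted* class, in {⌈n/2⌉, …, n} — which is not the
agreement statistic and is labelled separately.

## Metrics

Accuracy, Dice, specificity and precision are derived from exact tile
confusion counts per WSI and pooled (pooled counts = summed per-WSI
counts, asserted in tests). Ratios with zero denominators (e.g. precision
on a WSI with no predicted positives) are reported as not-available
(`None` in JSON, `NA` in CSV), never imputed as 0. The ensemble/single
comparison counts a WSI as a win only on strictly greater ensemble
accuracy; ties are tallied separately. The single-model baseline is one
designated base model (default: the first) with its own calibrated
threshold; a variant trained on all training data would also be a fair
comparator, and the choice is a configuration argument
(`single_model=` / column choice), not a code path difference.

## Visualisation

The overlay draws, per tile: a square outline (true class), a filled
diamond on a greyscale ramp with level round(255·a/n) (black = 0, white =
n), and an X (predicted class); IC is `#FF8C00` orange, not-IC `#1F77B4`
blue (the named colors have no canonical hex values; these are
configurable). Glyph sizes are 90 % / 60 % / 40 % of the tile cell so all
three read when stacked. The agreement histogram splits tile counts at
each agreement level by true class. The per-class confusion table gives,
for every original annotation class, the count and percentage of its
tiles predicted IC vs not-IC plus the class total; a tile carrying several
overlapping classes contributes to every matching row, so row totals can
exceed the tile count — rows are class-conditional views, not a partition.
Every figure writes a CSV twin; numeric tests assert on tables, and the
only pixel-level test is render-twice byte identity within one
environment (PNG bytes are not expected to be stable across matplotlib
versions).

## Synthetic cohorts

The generator emulates the *structure* of annotated breast-cancer slide
cohorts: per WSI, star-convex blob polygons (16 random radii at fixed
angular steps, integer-snapped vertices) for IC (a configurable fraction
labelled invasive *lobular* cancer), DCIS, benign epithelium and artifact
classes, overlapping freely; clinical covariates drawn from realistic
marginals (NHG 1/2/3/missing at 20/45/30/5 %, ER+ 75 %, HER2+ 15 %, Ki67+
55 %, 5 % missing each). When `target_ic_fraction` is set (default 0.3,
an IC-enriched regime that keeps both classes well represented in every
division), IC blobs are added until the intended IC tile fraction reaches
the target, overshooting by at most one blob. Default study size is 10
WSIs of 30 × 30 tiles; the end-to-end demo uses 50 WSIs so that an 80/20
split yields 10 training divisions *and* a 10-WSI held-out test set.

The generator computes its own intended labels with a hand-written
even-odd ray-casting point-in-polygon routine — an implementation
independent of the shapely-based labeling path — and the round-trip test
requires exact agreement between the two on the emitted GeoJSON. Boundary
conventions differ in principle (ray casting is half-open, `covers` is
closed), but an edge passing exactly through a tile center is measure-zero
with randomized blobs and does not occur at the tested seeds.

What the synthetic cohorts do *not* emulate: H&E pixel content, spatial
correlation of model errors along tumor borders, inter-annotator
variability, patient-level clustering, and class imbalance as extreme as
production cohorts. Passing tests therefore validate the pipeline's logic
and the vote theory, not clinical performance.

## Problem sizes and numerics

Default verification sizes — 50,000 tiles for Monte-Carlo theory checks
(3 binomial-SE tolerance), 10,000 pooled tiles for threshold recovery
(|τ − τ\*| < 0.05 asserted; observed ≈ 10⁻⁴–10⁻³), 9,000 held-out tiles
for the end-to-end comparison — keep every Monte-Carlo band decisively
narrower than the effects being detected while the whole suite runs in
well under a minute of compute. Thresholds, probabilities and Dice values
are exact floats (no rounding is introduced anywhere except in file
output); the closed-form binomial tail uses exact integer coefficients.

## Known limitations

- Binary labeling only (IC vs rest); multi-class use means one binary
  ensemble per class.
- Agreement is a concordance measure over learned representations, not an
  explanation of decisions, and with correlated base models high agreement
  can overstate certainty (the ρ knob exists precisely to demonstrate
  this).
- The center rule labels a tile by a single point; tiles straddling an IC
  border carry label noise that the `min_area_fraction` knob can reduce
  but not remove.
- The real-CNN adapter is a documented contract, not executed code.
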