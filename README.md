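# tilevote

Tile-level ensemble classification for invasive-cancer (IC) detection in
whole-slide histopathology images (WSIs), built around majority voting over
independently trained base models, per-model Dice-optimal threshold
calibration, and a spatial *agreement* statistic that maps ensemble
uncertainty back onto the slide.

It is written for computational-pathology researchers who want the ensemble
machinery — data division, calibration, voting, agreement, evaluation,
visualisation — as reusable, testable components. The GPU-trained CNN base
models of a production system are replaced here by a seeded simulator with
controllable accuracy, miscalibration and inter-model correlation, so the
entire pipeline runs and is verified at desk scale; a documented adapter
contract (`basemodels.cnn_adapter_contract`) states how real CNNs plug in.

## The method

A WSI is analysed as a grid of square tiles (598 × 598 px ≈ 271 × 271 μm at
20X). Pathologist annotations are polygons with free-text classes that may
overlap; a tile inherits class *c* when its **center** falls inside a
polygon of class *c*, and its binary label is l(x) = 1 iff any of its
classes is in the IC set (by default *invasive cancer* and *invasive
lobular cancer*).

Cohort WSIs are split 80/20 into training and held-out test sets, stratified
on the joint cross of NHG grade and ER/HER2/Ki67 status, and the training
WSIs are dealt into N equal groups (default 10) preserving every stratum's
proportions to within one WSI. Each base model f_i is trained on one group
and emits a continuous score ŷ_i(x) ∈ [0, 1]. Because softmax outputs are
not guaranteed to be calibrated, each model gets its own threshold τ_i,
chosen to maximise the Dice score 2TP/(2TP+FP+FN) of

    t_i(x) = 1  if ŷ_i(x) ≥ τ_i,   else 0

over all training groups the model was *not* trained on. The ensemble
prediction is the majority of the binary votes t_i(x). For T independent
voters, each correct with probability p, the number of correct votes is
Binomial(T, p), so a strict majority is correct with probability

    p_ens = Σ_{k=⌊T/2⌋+1}^{T} C(T, k) p^k (1 − p)^(T−k),

which exceeds p whenever p > 0.5 — the quantitative reason to prefer the
ensemble. The per-tile **agreement**

    a(x) = Σ_k t_k(x)       if l(x) = 1
    a(x) = n − Σ_k t_k(x)   if l(x) = 0

counts models voting for the *true* class (0 = unanimously wrong, n =
unanimously right) and is rendered as a greyscale diamond over the slide,
alongside a square for the ground-truth class and an X for the prediction
(orange = IC, blue = not IC).

## Worked example

```bash
tilevote demo --seed 1 --out demo_out
```

generates a 50-WSI synthetic cohort (30 × 30 tiles per WSI, ~30 % IC tiles,
ten simulated base models with p_correct = 0.8 and operating thresholds
spread over 0.25–0.65), labels it from the emitted GeoJSON polygons, splits
it 80/20, calibrates each model on its nine out-of-division training groups,
and evaluates majority voting on the 10 held-out WSIs. It prints:

```
test WSIs: 10; tiles: 9000
ensemble accuracy 0.9757  dice 0.9612  specificity 0.9732  precision 0.9421
single   accuracy 0.7889  dice 0.6987  specificity 0.7857  precision 0.6225
ensemble beats single model on 10/10 WSIs (win rate 1.00, ties 0); closed-form p_ens at p=0.8, T=10: 0.9672
```

Reading: each simulated model alone is right about 79 % of the time; ten of
them voting reach 97.6 % pooled tile accuracy, close to the binomial
prediction p_ens(10, 0.8) ≈ 0.967 (slightly above it because resolved
5–5 ties can still be correct), and win on every held-out WSI. `demo_out/`
contains the partition plan, calibrated thresholds
(`thresholds.json` — the recovered τ_i sit within ~0.005 of the planted
ones), the per-tile ensemble table, per-WSI metrics, and the three
visualisations (glyph overlay, agreement histogram, per-class confusion
table) as PNG + CSV pairs.

The same pieces are callable as a library — see
`tilevote.synthetic.end_to_end_demo`, or use `wsi_labels.assign_labels`,
`partition.split_train_test` / `make_divisions`,
`calibration.calibrate_ensemble`, `ensemble.binarize` / `majority_vote` /
`agreement`, and `metrics.wsi_metrics` directly on your own tables.

## Layout

| module | role |
| --- | --- |
| `tilevote.wsi_labels` | tile grids, GeoJSON polygons, center-rule labeling |
| `tilevote.partition` | stratified 80/20 split, equal training divisions |
| `tilevote.basemodels` | base-model contract, score simulator, CNN adapter contract |
| `tilevote.calibration` | Dice score, out-of-division threshold calibration |
| `tilevote.ensemble` | binarization, majority vote, agreement, binomial theory |
| `tilevote.metrics` | per-WSI / pooled accuracy, Dice, specificity, precision |
| `tilevote.viz` | glyph overlay, agreement histogram, multi-label confusion |
| `tilevote.synthetic` | synthetic cohorts, independent geometry oracle, demo |

Design notes, parameter defaults and known limitations are documented in
[docs/methods.md](docs/methods.md).
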