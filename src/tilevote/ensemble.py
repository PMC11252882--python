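"""Vote binarization, majority aggregation, agreement, and binomial theory.

Each base model's continuous score is binarized at its calibrated threshold
(score >= tau votes 1).  The ensemble prediction is the majority vote; with
an even number of models a tied tile (exactly n/2 votes) is resolved by
comparing the tile's mean raw score against the mean of the calibrated
thresholds (>= predicts 1), a deterministic rule flagged per tile.

The *agreement* a(x) of an ensemble of n models on a labeled tile x is the
number of models voting for the true class: the vote sum when l(x) = 1, and
n minus the vote sum when l(x) = 0.  It ranges from 0 (all models wrong) to
n (unanimously right).  For unlabeled deployment the ground-truth-free
*self-agreement* -- votes for the *predicted* class -- is reported instead
and must not be confused with agreement.

If each of T independent voters is correct with probability p, the number of
correct votes is Binomial(T, p) and the probability that a strict majority
is correct is

    p_ens = sum_{k = floor(T/2)+1}^{T} C(T, k) p^k (1-p)^(T-k),

which exceeds p for any odd T >= 3 when p > 0.5 and tends to 1 as T grows.
``verify_theory`` checks this closed form against Monte-Carlo simulation.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .basemodels import SimModelSpec, simulate_scores
from .calibration import ThresholdVector

RESULT_COLUMNS = [
    "tile_id", "vote_sum", "predicted_label", "agreement", "self_agreement", "tie_flag",
]


def _taus_mapping(thresholds: ThresholdVector | Mapping[str, float]) -> dict[str, float]:
    if isinstance(thresholds, ThresholdVector):
        return thresholds.taus
    return dict(thresholds)


def binarize(
    scores: pd.DataFrame, thresholds: ThresholdVector | Mapping[str, float]
) -> pd.DataFrame:
    """Turn scores into votes: vote 1 iff score >= the model's threshold.

    A score exactly equal to the threshold votes 1.
    """
    taus = _taus_mapping(thresholds)
    missing = [m for m in scores.columns if m not in taus]
    if missing:
        raise ValueError(f"no threshold for models: {missing}")
    votes = pd.DataFrame(
        {m: (scores[m].to_numpy(dtype=float) >= taus[m]).astype(np.int8)
         for m in scores.columns},
        index=scores.index,
    )
    return votes


def majority_vote(
    votes: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    thresholds: ThresholdVector | Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Aggregate votes per tile into the ensemble prediction.

    Returns a DataFrame indexed by tile_id with vote_sum, predicted_label,
    self_agreement (votes for the predicted class) and tie_flag.  Ties
    (vote_sum == n/2, even n only) require ``scores`` and ``thresholds``
    for the mean-score tie-break.
    """
    n = votes.shape[1]
    vs = votes.to_numpy().sum(axis=1).astype(int)
    pred = (2 * vs > n).astype(int)
    tie = 2 * vs == n
    if tie.any():
        if scores is None or thresholds is None:
            raise ValueError(
                "tied tiles present; scores and thresholds are required for the "
                "mean-score tie-break"
            )
        taus = _taus_mapping(thresholds)
        mean_tau = float(np.mean([taus[m] for m in votes.columns]))
        mean_score = scores.loc[votes.index[tie], votes.columns].to_numpy().mean(axis=1)
        pred[tie] = (mean_score >= mean_tau).astype(int)
    self_agreement = np.where(pred == 1, vs, n - vs)
    return pd.DataFrame(
        {
            "vote_sum": vs,
            "predicted_label": pred,
            "self_agreement": self_agreement,
            "tie_flag": tie,
        },
        index=votes.index.rename("tile_id"),
    )


def agreement(votes: pd.DataFrame, labeled: pd.DataFrame) -> pd.Series:
    """Number of models voting for the true class of each tile.

    a(x) = vote_sum when l(x) = 1, n - vote_sum when l(x) = 0; always in
    [0, n].  Raises when any voted tile has no label (use self-agreement for
    unlabeled tiles).
    """
    n = votes.shape[1]
    lab = labeled.set_index("tile_id")["l"]
    missing = votes.index.difference(lab.index)
    if len(missing) > 0:
        raise ValueError(f"missing labels for {len(missing)} tiles")
    l = lab.loc[votes.index].to_numpy().astype(int)
    vs = votes.to_numpy().sum(axis=1).astype(int)
    a = np.where(l == 1, vs, n - vs)
    return pd.Series(a, index=votes.index.rename("tile_id"), name="agreement")


def ensemble_result(
    votes: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    thresholds: ThresholdVector | Mapping[str, float] | None = None,
    labeled: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full per-tile ensemble table; agreement included when labels given."""
    res = majority_vote(votes, scores, thresholds)
    if labeled is not None:
        res["agreement"] = agreement(votes, labeled)
    return res


def write_result(result: pd.DataFrame, path: str | Path) -> None:
    result.reset_index().to_csv(path, index=False)


def read_result(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"tile_id": str}).set_index("tile_id")


def ensemble_success_probability(n_models: int, p: float) -> float:
    """Closed-form probability that a strict majority of T voters is correct.

    ``p_ens = sum_{k=k0}^{T} C(T,k) p^k (1-p)^(T-k)`` with
    ``k0 = floor(T/2) + 1``.  For even T a tie (k = T/2) is not a success.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    k0 = n_models // 2 + 1
    return float(
        sum(
            math.comb(n_models, k) * p**k * (1.0 - p) ** (n_models - k)
            for k in range(k0, n_models + 1)
        )
    )


def verify_theory(
    specs: Sequence[SimModelSpec],
    tiles: int = 50_000,
    seed: int = 0,
) -> dict:
    """Monte-Carlo check of the binomial majority-vote theory.

    All specs must share ``p_correct`` and have ``correlation = 0`` so the
    closed form applies.  Labels are Bernoulli(1/2); votes are each model's
    score binarized at its own true threshold.  The empirical counterpart of
    the closed form is the strict-majority success rate (agreement >=
    floor(T/2)+1); the tie-broken prediction accuracy is reported separately
    because the closed form does not credit resolved ties.
    """
    ps = {s.p_correct for s in specs}
    if len(ps) != 1:
        raise ValueError("all specs must share p_correct for the matched comparison")
    if any(s.correlation != 0.0 for s in specs):
        raise ValueError("verify_theory requires correlation = 0")
    p = ps.pop()
    n = len(specs)
    if tiles < 1:
        raise ValueError("tiles must be >= 1")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 999_983]))
    labels = rng.integers(0, 2, size=tiles)
    labeled = pd.DataFrame(
        {"tile_id": [f"t{i:07d}" for i in range(tiles)], "l": labels}
    )
    scores = simulate_scores(labeled, specs, seed=seed)
    taus = {s.model_id: s.true_threshold for s in specs}
    votes = binarize(scores, taus)

    a = agreement(votes, labeled).to_numpy()
    k0 = n // 2 + 1
    strict = float(np.mean(a >= k0))
    tie_rate = float(np.mean(2 * a == n)) if n % 2 == 0 else 0.0
    pred = majority_vote(votes, scores, taus)["predicted_label"].to_numpy()
    tiebreak_acc = float(np.mean(pred == labels))

    per_model = {
        m: float(np.mean(votes[m].to_numpy() == labels)) for m in votes.columns
    }
    single_mean = float(np.mean(list(per_model.values())))
    p_theory = ensemble_success_probability(n, p)
    se_ens = math.sqrt(max(strict * (1 - strict), 1e-12) / tiles)
    se_single = math.sqrt(max(single_mean * (1 - single_mean), 1e-12) / tiles)
    return {
        "n_models": n,
        "n_tiles": tiles,
        "p_correct": p,
        "p_ens_theory": p_theory,
        "ensemble_accuracy_strict": strict,
        "ensemble_accuracy_tiebreak": tiebreak_acc,
        "tie_rate": tie_rate,
        "single_model_accuracy_mean": single_mean,
        "single_model_accuracies": per_model,
        "mc_se_ensemble": se_ens,
        "mc_se_single": se_single,
        "strict_minus_theory": strict - p_theory,
        "ensemble_gain": strict - single_mean,
    }
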