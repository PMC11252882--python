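"""Per-model binarization thresholds chosen by out-of-division Dice.

Each base model is trained on one training division, so its threshold is
calibrated on the tiles of *all other* training divisions pooled together
(never on the held-out test set).  Candidate thresholds are the midpoints
between consecutive distinct scores plus {0, 1}; because predictions -- and
hence Dice -- are piecewise constant between consecutive distinct scores,
this finite grid searches all real thresholds exactly.  Ties are broken
toward the smallest threshold, which favors sensitivity for the IC class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .partition import PartitionPlan


def dice_score(pred, truth) -> float:
    """Dice coefficient 2TP / (2TP + FP + FN), positive class = 1.

    When no positives exist in either vector (TP = FP = FN = 0) the score is
    defined as 1.0 (perfect agreement on an all-negative instance).
    """
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size < 1:
        raise ValueError("empty input")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def candidate_thresholds(scores) -> np.ndarray:
    """Midpoints of consecutive distinct sorted scores, plus 0 and 1."""
    s = np.unique(np.asarray(scores, dtype=float))
    mids = (s[:-1] + s[1:]) / 2.0 if s.size > 1 else np.empty(0)
    return np.unique(np.concatenate([[0.0], mids, [1.0]]))


def dice_curve(scores, truth) -> tuple[np.ndarray, np.ndarray]:
    """Dice of the rule ``score >= tau`` at every candidate threshold.

    Uses the identity Dice(tau) = 2 TP(tau) / (P + Q(tau)) with P the truth
    positives and Q the predicted positives, evaluated for all candidates at
    once via sorted cumulative counts.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    cands = candidate_thresholds(scores)
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    cum_pos = np.concatenate([[0], np.cumsum(truth[order])])
    p_total = int(truth.sum())
    idx = np.searchsorted(s_sorted, cands, side="left")
    q = scores.size - idx
    tp = p_total - cum_pos[idx]
    denom = p_total + q
    with np.errstate(invalid="ignore"):
        dice = np.where(denom > 0, 2.0 * tp / np.maximum(denom, 1), 1.0)
    return cands, dice


def best_threshold(scores, truth) -> tuple[float, float]:
    """Dice-optimal candidate threshold; ties go to the smallest candidate."""
    cands, dice = dice_curve(scores, truth)
    i = int(np.argmax(dice))  # first occurrence of the max = smallest tau
    return float(cands[i]), float(dice[i])


@dataclass
class ThresholdVector:
    """Calibrated threshold per model, with calibration provenance."""

    entries: dict[str, dict] = field(default_factory=dict)

    def add(self, model_id: str, tau: float, dice: float,
            divisions_excluded: Sequence[int], n_tiles: int) -> None:
        self.entries[model_id] = {
            "tau": float(tau),
            "dice": float(dice),
            "divisions_excluded": list(divisions_excluded),
            "n_tiles": int(n_tiles),
        }

    @property
    def taus(self) -> dict[str, float]:
        return {m: e["tau"] for m, e in self.entries.items()}

    def __getitem__(self, model_id: str) -> float:
        return self.entries[model_id]["tau"]

    def __contains__(self, model_id: str) -> bool:
        return model_id in self.entries

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.entries, indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "ThresholdVector":
        return cls(entries=json.loads(Path(path).read_text()))


def _pool_out_of_division(
    labeled: pd.DataFrame, plan: PartitionPlan, own_division: int
) -> pd.DataFrame:
    pool_wsis = {
        w for w, d in plan.division.items()
        if d != own_division and plan.split.get(w) == "train"
    }
    return labeled[labeled["wsi_id"].isin(pool_wsis)]


def calibrate_threshold(
    model_id: str,
    scores: pd.Series,
    labeled: pd.DataFrame,
    plan: PartitionPlan,
    own_division: int,
) -> tuple[float, float, int]:
    """Calibrate one model's threshold on its out-of-division training tiles.

    ``scores`` is the model's column of the score matrix (indexed by
    tile_id) and must cover every tile of the pooled divisions.  Returns
    (tau, pooled Dice at tau, number of pooled tiles).
    """
    pool = _pool_out_of_division(labeled, plan, own_division)
    if len(pool) == 0:
        raise ValueError(
            f"model {model_id}: no out-of-division training tiles to calibrate on"
        )
    missing = set(pool["tile_id"]) - set(scores.index)
    if missing:
        raise ValueError(
            f"model {model_id}: scores missing for {len(missing)} pooled tiles"
        )
    s = scores.loc[pool["tile_id"]].to_numpy(dtype=float)
    t = pool["l"].to_numpy().astype(int)
    tau, dice = best_threshold(s, t)
    return tau, dice, len(pool)


def calibrate_ensemble(
    scores: pd.DataFrame,
    labeled: pd.DataFrame,
    plan: PartitionPlan,
    model_divisions: Mapping[str, int] | None = None,
) -> ThresholdVector:
    """Calibrate every model column of the score matrix.

    ``model_divisions`` maps model_id to the training division the model was
    trained on; by default the i-th column is paired with division i+1
    (wrapping if there are more models than divisions).
    """
    if plan.n_divisions is None or not plan.division:
        raise ValueError("plan has no divisions; run make_divisions first")
    n_div = int(plan.n_divisions)
    if model_divisions is None:
        model_divisions = {
            m: (i % n_div) + 1 for i, m in enumerate(scores.columns)
        }
    tv = ThresholdVector()
    for model_id in scores.columns:
        own = int(model_divisions[model_id])
        tau, dice, n_tiles = calibrate_threshold(
            model_id, scores[model_id], labeled, plan, own
        )
        excluded = [own]
        tv.add(model_id, tau, dice, divisions_excluded=excluded, n_tiles=n_tiles)
    return tv
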