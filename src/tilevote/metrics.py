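"""Per-WSI and pooled performance metrics, ensemble vs single model.

The positive class is invasive cancer (l = 1).  Accuracy, Dice, specificity
and precision are computed from tile-level confusion counts per WSI and
pooled over all tiles; ratios with a zero denominator are reported as
not-available (NaN/None), never coerced to 0.  The per-WSI comparison
reports the fraction of WSIs where the ensemble's accuracy strictly exceeds
the single model's, with ties counted separately.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

METRIC_NAMES = ["accuracy", "dice", "specificity", "precision"]
REPORT_COLUMNS = ["scope", "system", "tp", "fp", "tn", "fn"] + METRIC_NAMES


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Exact tile-level confusion counts; positive class is IC (label 1)."""
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: int, denom: int) -> float | None:
    return None if denom == 0 else num / denom


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, Dice, specificity, precision; None where undefined."""
    total = c.tp + c.fp + c.tn + c.fn
    return {
        "accuracy": _ratio(c.tp + c.tn, total),
        "dice": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "precision": _ratio(c.tp, c.tp + c.fp),
    }


@dataclass
class MetricsReport:
    """Per-WSI and pooled metrics for two systems plus the win-rate summary."""

    per_wsi: pd.DataFrame  # one row per (wsi_id, system)
    pooled: pd.DataFrame   # one row per system
    n_wsis: int
    n_wins: int
    n_ties: int
    n_losses: int

    @property
    def win_rate(self) -> float:
        """Fraction of WSIs where the ensemble accuracy is strictly higher."""
        return self.n_wins / self.n_wsis if self.n_wsis else float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Flat table: per-WSI rows followed by pooled rows."""
        return pd.concat([self.per_wsi, self.pooled], ignore_index=True)[
            REPORT_COLUMNS
        ]

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")

    def write_json(self, path: str | Path) -> None:
        payload = {
            "n_wsis": self.n_wsis,
            "n_wins": self.n_wins,
            "n_ties": self.n_ties,
            "n_losses": self.n_losses,
            "win_rate": self.win_rate,
            "pooled": self.pooled.replace({np.nan: None}).to_dict(orient="records"),
            "per_wsi": self.per_wsi.replace({np.nan: None}).to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _rows_for(pred: np.ndarray, truth: np.ndarray, scope: str, system: str) -> dict:
    c = confusion_counts(pred, truth)
    row = {"scope": scope, "system": system, "tp": c.tp, "fp": c.fp,
           "tn": c.tn, "fn": c.fn}
    row.update({k: (np.nan if v is None else v) for k, v in metrics_from_counts(c).items()})
    return row


def wsi_metrics(
    ensemble_result: pd.DataFrame,
    single_result: pd.DataFrame,
    labeled: pd.DataFrame,
) -> MetricsReport:
    """Evaluate the ensemble against a single-model baseline.

    Both results are DataFrames indexed by tile_id with a
    ``predicted_label`` column over the same tiles; ``labeled`` supplies
    wsi_id and the true label l.  WSIs with zero evaluable tiles are
    excluded with a warning.  Pooled counts equal the sum of per-WSI counts.
    """
    lab = labeled.set_index("tile_id")
    tiles = ensemble_result.index
    if not tiles.equals(single_result.index):
        single_result = single_result.loc[tiles]
    missing = tiles.difference(lab.index)
    if len(missing) > 0:
        raise ValueError(f"missing labels for {len(missing)} tiles")
    truth = lab.loc[tiles, "l"].to_numpy().astype(int)
    wsi = lab.loc[tiles, "wsi_id"].to_numpy()
    ens = ensemble_result["predicted_label"].to_numpy().astype(int)
    sgl = single_result["predicted_label"].to_numpy().astype(int)

    per_rows = []
    wins = ties = losses = 0
    wsi_ids = sorted(pd.unique(wsi))
    kept = 0
    for w in wsi_ids:
        m = wsi == w
        if not m.any():
            warnings.warn(f"WSI {w} has zero tiles; excluded from metrics")
            continue
        kept += 1
        row_e = _rows_for(ens[m], truth[m], scope=str(w), system="ensemble")
        row_s = _rows_for(sgl[m], truth[m], scope=str(w), system="single")
        per_rows += [row_e, row_s]
        if row_e["accuracy"] > row_s["accuracy"]:
            wins += 1
        elif row_e["accuracy"] == row_s["accuracy"]:
            ties += 1
        else:
            losses += 1

    pooled = pd.DataFrame(
        [
            _rows_for(ens, truth, scope="pooled", system="ensemble"),
            _rows_for(sgl, truth, scope="pooled", system="single"),
        ],
        columns=REPORT_COLUMNS,
    )
    per_wsi = pd.DataFrame(per_rows, columns=REPORT_COLUMNS)
    return MetricsReport(
        per_wsi=per_wsi,
        pooled=pooled,
        n_wsis=kept,
        n_wins=wins,
        n_ties=ties,
        n_losses=losses,
    )


def single_model_result(votes: pd.DataFrame, model_id: str) -> pd.DataFrame:
    """Wrap one model's votes as an EnsembleResult-like prediction table."""
    if model_id not in votes.columns:
        raise ValueError(f"unknown model {model_id}")
    v = votes[model_id].to_numpy().astype(int)
    return pd.DataFrame(
        {"vote_sum": v, "predicted_label": v, "self_agreement": 1, "tie_flag": False},
        index=votes.index.rename("tile_id"),
    )
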