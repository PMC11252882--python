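"""Base-model contract and a simulated base-model family.

A base model maps a tile to a continuous invasive-cancer (IC) score in
[0, 1].  In the real system each base model is a CNN trained on one training
division; its softmax output is continuous but not guaranteed to be
calibrated, so each model has its own operating threshold.  The simulator
here stands in for that family: each simulated model has

* ``p_correct`` -- marginal probability that binarizing its score at its own
  operating threshold reproduces the true tile label,
* ``true_threshold`` (tau*) -- the score value separating its "votes 0" and
  "votes 1" regions; deliberately not 0.5, emulating miscalibration,
* ``concentration`` -- shape of the score distribution on each side of tau*
  (values < 1 polarize scores toward 0/1, CNN-like; values > 1 concentrate
  scores near the threshold),
* ``correlation`` (rho) -- probability that a tile's draw is replaced by a
  per-tile draw shared across models, inducing vote correlation (rho = 0
  gives conditionally independent votes).

Scores on the correct (resp. wrong) side of tau* are drawn as
``tau* + (1 - tau*) * u`` above and ``tau* * (1 - u)`` below, with
``u ~ Beta(1, concentration)`` sampled by inverse CDF from a shared or
per-model uniform.  The Beta(1, c) density is positive at 0 for every c, so
the score distribution always has mass adjacent to the operating threshold
and the Dice-optimal threshold is identifiable.

One global seed expands into per-model substreams through
``numpy.random.SeedSequence(seed).spawn``: child 0 drives the shared
(correlated) draws, child i+1 drives model i.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml


@dataclass(frozen=True)
class SimModelSpec:
    """Parameters of one simulated base model."""

    model_id: str
    p_correct: float = 0.8
    true_threshold: float = 0.5
    concentration: float = 0.7
    correlation: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_correct <= 1.0:
            raise ValueError("p_correct must be in (0, 1]")
        if not 0.0 < self.true_threshold < 1.0:
            raise ValueError("true_threshold must be in (0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be in [0, 1]")


def default_model_family(
    n_models: int = 10,
    p_correct: float = 0.8,
    correlation: float = 0.0,
    concentration: float = 0.7,
    thresholds: Sequence[float] | None = None,
) -> list[SimModelSpec]:
    """A family of ``n_models`` simulated models with spread-out operating
    thresholds (miscalibrated relative to 0.5, as softmax CNN outputs are)."""
    if thresholds is None:
        thresholds = np.linspace(0.25, 0.65, n_models)
    if len(thresholds) != n_models:
        raise ValueError("one threshold per model required")
    return [
        SimModelSpec(
            model_id=f"m{i + 1:02d}",
            p_correct=p_correct,
            true_threshold=float(t),
            concentration=concentration,
            correlation=correlation,
        )
        for i, t in enumerate(thresholds)
    ]


def simulate_scores(
    labeled: pd.DataFrame,
    specs: Sequence[SimModelSpec],
    seed: int | Sequence[int] = 0,
) -> pd.DataFrame:
    """Draw a score matrix (tiles x models) from the simulated family.

    ``labeled`` must carry ``tile_id`` and the binary label column ``l``.
    Returns a DataFrame indexed by tile_id with one column per model_id,
    all values in [0, 1]; binarizing model i's column at its
    ``true_threshold`` (score >= tau*) reproduces the label with marginal
    probability ``p_correct``.
    """
    if len(labeled) < 1:
        raise ValueError("need at least one tile")
    if len(specs) < 1:
        raise ValueError("need at least one model spec")
    ids = [s.model_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model_id in specs")
    labels = labeled["l"].to_numpy().astype(int)
    m = len(labels)

    children = np.random.SeedSequence(seed).spawn(len(specs) + 1)
    shared_rng = np.random.default_rng(children[0])
    shared_v = shared_rng.random(m)  # correctness uniform
    shared_q = shared_rng.random(m)  # score-position quantile

    cols: dict[str, np.ndarray] = {}
    for i, spec in enumerate(specs):
        rng = np.random.default_rng(
            spec.seed if spec.seed is not None else children[i + 1]
        )
        v = rng.random(m)
        q = rng.random(m)
        if spec.correlation > 0.0:
            z = rng.random(m) < spec.correlation
            v = np.where(z, shared_v, v)
            q = np.where(z, shared_q, q)
        correct = v < spec.p_correct
        # Inverse CDF of Beta(1, c): u = 1 - (1 - q)^(1/c).
        u = 1.0 - (1.0 - q) ** (1.0 / spec.concentration)
        tau = spec.true_threshold
        above = correct == (labels == 1)
        s_above = tau + (1.0 - tau) * u
        s_below = np.minimum(tau * (1.0 - u), np.nextafter(tau, 0.0))
        cols[spec.model_id] = np.where(above, s_above, s_below)

    out = pd.DataFrame(cols, index=pd.Index(labeled["tile_id"], name="tile_id"))
    validate_score_matrix(out)
    return out


def validate_score_matrix(scores: pd.DataFrame) -> None:
    """Check the score-matrix contract: no missing cells, all values in [0,1]."""
    if scores.shape[1] < 1:
        raise ValueError("score matrix needs at least one model column")
    vals = scores.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("score matrix contains missing cells")
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("scores must lie in [0, 1]")


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=True)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="tile_id", dtype={"tile_id": str})
    validate_score_matrix(df)
    return df


def write_model_specs(specs: Sequence[SimModelSpec], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump([asdict(s) for s in specs], sort_keys=False))


def read_model_specs(path: str | Path) -> list[SimModelSpec]:
    data = yaml.safe_load(Path(path).read_text())
    return [SimModelSpec(**d) for d in data]


def cnn_adapter_contract() -> dict:
    """Contract for plugging real CNN base models into the pipeline.

    This is a documentation-level contract, not executed by the test suite:
    training and inference of the real networks require GPU-scale resources
    and the restricted cohorts, so the simulated family above stands in for
    them everywhere tests run.
    """
    return {
        "architecture": "InceptionV3 (default torchvision parameters)",
        "initialization": "ImageNet pretrained weights",
        "input": "RGB tile, 598x598 px at 20X (271x271 um)",
        "output": (
            "two-class softmax; the reported score is the probability of the "
            "IC class (assumption: class index chosen so that higher = IC)"
        ),
        "loss": "cross entropy",
        "optimizer": "AdaBelief",
        "stopping": (
            "train until convergence or early stopping on a tuning set held "
            "out from the model's own training division (tuning fraction is "
            "a free parameter of the adapter)"
        ),
        "training_data": "one training division per base model",
        "calibration": (
            "after training, the operating threshold is chosen by maximizing "
            "Dice on all training divisions the model was not trained on"
        ),
        "tested": False,
    }
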