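"""Stratified train/test split and equal-size training divisions.

WSIs are split 80/20 (configurable) into training and held-out test sets,
stratified on the joint cross of the clinical covariates: Nottingham
Histological Grade (NHG 1-3) and ER / HER2 / Ki67 biomarker status, with
"missing" as its own level.  The training WSIs are then divided into N equal
groups -- one per base model -- keeping the proportion of every clinical
stratum: within each stratum the (seeded, shuffled) members are dealt
consecutively round-robin across divisions, with a global pointer carrying
over between strata.  This makes both invariants provable: global division
sizes differ by at most one, and any stratum's count differs by at most one
between any two divisions.

All randomness is driven by explicit seeds; plans are reproducible
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

CLINICAL_COLUMNS = ["wsi_id", "nhg", "er", "her2", "ki67"]
STRATUM_COLUMNS = ["nhg", "er", "her2", "ki67"]
MISSING = "missing"


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-WSI clinical covariates; unknown values are the string 'missing'."""

    wsi_id: str
    nhg: str = MISSING
    er: str = MISSING
    her2: str = MISSING
    ki67: str = MISSING


@dataclass
class PartitionPlan:
    """Train/test membership and (optionally) division assignment per WSI."""

    split: dict[str, str]
    division: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    test_fraction: float = 0.2
    n_divisions: int | None = None

    @property
    def train_ids(self) -> list[str]:
        return sorted(w for w, s in self.split.items() if s == "train")

    @property
    def test_ids(self) -> list[str]:
        return sorted(w for w, s in self.split.items() if s == "test")

    def division_members(self, d: int) -> list[str]:
        return sorted(w for w, dd in self.division.items() if dd == d)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for wsi_id in sorted(self.split):
            rows.append(
                {
                    "wsi_id": wsi_id,
                    "split": self.split[wsi_id],
                    "division": self.division.get(wsi_id, ""),
                }
            )
        return pd.DataFrame(rows, columns=["wsi_id", "split", "division"])

    def write(self, csv_path: str | Path) -> None:
        """Write the plan CSV plus a JSON sidecar with seed/N/test_fraction."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "test_fraction": self.test_fraction,
                    "n_divisions": self.n_divisions,
                },
                indent=2,
            )
        )

    @classmethod
    def read(cls, csv_path: str | Path) -> "PartitionPlan":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path, dtype={"wsi_id": str, "split": str})
        meta = {}
        sidecar = csv_path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        split = dict(zip(df["wsi_id"], df["split"]))
        division = {
            w: int(d)
            for w, d in zip(df["wsi_id"], df["division"])
            if pd.notna(d) and str(d) != ""
        }
        return cls(
            split=split,
            division=division,
            seed=int(meta.get("seed", 0)),
            test_fraction=float(meta.get("test_fraction", 0.2)),
            n_divisions=meta.get("n_divisions"),
        )


def clinical_frame(clinical: Iterable[ClinicalRecord] | pd.DataFrame) -> pd.DataFrame:
    """Coerce clinical covariates to a validated DataFrame."""
    if isinstance(clinical, pd.DataFrame):
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
        if missing_cols:
            raise ValueError(f"clinical table missing columns: {missing_cols}")
        df = clinical.loc[:, CLINICAL_COLUMNS].copy()
    else:
        df = pd.DataFrame(
            [
                {"wsi_id": r.wsi_id, "nhg": r.nhg, "er": r.er, "her2": r.her2, "ki67": r.ki67}
                for r in clinical
            ],
            columns=CLINICAL_COLUMNS,
        )
    for c in STRATUM_COLUMNS:
        df[c] = df[c].astype(str).replace({"nan": MISSING, "": MISSING})
    if df["wsi_id"].duplicated().any():
        raise ValueError("duplicate wsi_id in clinical table")
    return df.reset_index(drop=True)


def _strata(df: pd.DataFrame) -> list[tuple[tuple[str, ...], list[str]]]:
    """Group WSI ids by joint stratum, deterministically ordered."""
    groups: dict[tuple[str, ...], list[str]] = {}
    for _, row in df.iterrows():
        key = tuple(str(row[c]) for c in STRATUM_COLUMNS)
        groups.setdefault(key, []).append(str(row["wsi_id"]))
    return [(k, sorted(groups[k])) for k in sorted(groups)]


def split_train_test(
    clinical: Iterable[ClinicalRecord] | pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> PartitionPlan:
    """Stratified train/test split of WSIs.

    The total test count is round(test_fraction * n); it is apportioned to
    the joint clinical strata by largest remainder, and members are sampled
    within each stratum by a seeded shuffle.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    df = clinical_frame(clinical)
    n = len(df)
    if n < 2:
        raise ValueError("need at least 2 WSIs to split")
    n_test = int(np.floor(test_fraction * n + 0.5))
    n_test = max(1, min(n - 1, n_test))

    strata = _strata(df)
    quotas = np.array([test_fraction * len(m) for _, m in strata])
    base = np.floor(quotas).astype(int)
    sizes = np.array([len(m) for _, m in strata])
    base = np.minimum(base, sizes)
    remainder = n_test - int(base.sum())
    # Largest-remainder apportionment; ties broken by stratum order.
    frac_order = np.argsort(-(quotas - base), kind="stable")
    k = 0
    while remainder > 0 and k < len(strata) * 2:
        for s in frac_order:
            if remainder == 0:
                break
            if base[s] < sizes[s]:
                base[s] += 1
                remainder -= 1
        k += 1
    while remainder < 0:
        for s in frac_order[::-1]:
            if remainder == 0:
                break
            if base[s] > 0:
                base[s] -= 1
                remainder += 1

    rng = np.random.default_rng(seed)
    split: dict[str, str] = {}
    for (key, members), k_test in zip(strata, base):
        members = list(members)
        rng.shuffle(members)
        for w in members[:k_test]:
            split[w] = "test"
        for w in members[k_test:]:
            split[w] = "train"
    return PartitionPlan(split=split, seed=seed, test_fraction=test_fraction)


def make_divisions(
    plan: PartitionPlan,
    clinical: Iterable[ClinicalRecord] | pd.DataFrame,
    n_divisions: int,
    seed: int = 0,
) -> PartitionPlan:
    """Deal the training WSIs into ``n_divisions`` equal stratified groups.

    Within each joint stratum the members are shuffled with the seed and
    dealt consecutively to divisions through a global round-robin pointer,
    so both the global division sizes and the per-stratum counts differ by
    at most one across divisions.
    """
    df = clinical_frame(clinical)
    train = set(plan.train_ids)
    if n_divisions < 2:
        raise ValueError("n_divisions must be >= 2")
    if n_divisions > len(train):
        raise ValueError(
            f"n_divisions={n_divisions} exceeds number of training WSIs ({len(train)})"
        )
    df = df[df["wsi_id"].isin(train)]
    rng = np.random.default_rng(seed)
    division: dict[str, int] = {}
    pointer = 0
    for _, members in _strata(df):
        members = list(members)
        rng.shuffle(members)
        for w in members:
            division[w] = pointer % n_divisions + 1
            pointer += 1
    return PartitionPlan(
        split=dict(plan.split),
        division=division,
        seed=seed,
        test_fraction=plan.test_fraction,
        n_divisions=n_divisions,
    )


def read_clinical(path: str | Path) -> pd.DataFrame:
    return clinical_frame(pd.read_csv(path, dtype=str))


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    clinical_frame(df).to_csv(path, index=False)
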