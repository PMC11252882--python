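"""Synthetic whole-slide studies for end-to-end desk-scale runs.

Generates everything the pipeline consumes with no external data: tile
grids, overlapping multi-class annotation polygons (invasive cancer, DCIS,
benign, artifact blobs), per-WSI clinical covariates, and simulated
base-model score matrices.  Blobs are randomized star-convex polygons
(random radii at fixed angular steps) so the tile-center labeling rule is
exercised on ragged borders, and classes may overlap as real annotations
do.

The generator embeds its own intended per-tile labels, computed with a
hand-written even-odd ray-casting point-in-polygon test -- an independent
second geometry route, so the round trip

    generated polygons -> GeoJSON -> wsi_labels.assign_labels

is checked against a different implementation rather than against itself.

Only geometry, labels and scores are synthesized; no pixel textures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from . import calibration, ensemble, metrics, viz, wsi_labels
from .basemodels import (
    SimModelSpec,
    default_model_family,
    simulate_scores,
    write_model_specs,
    write_scores,
)
from .partition import make_divisions, split_train_test, write_clinical
from .wsi_labels import (
    DEFAULT_IC_CLASSES,
    AnnotationPolygon,
    assign_labels,
    make_grid,
    write_annotations,
    write_labeled_tiles,
    write_tiles,
)

# Realistic breast-cancer cohort marginals for the stratification covariates.
DEFAULT_NHG = {"1": 0.20, "2": 0.45, "3": 0.30, "missing": 0.05}
DEFAULT_ER = {"positive": 0.75, "negative": 0.20, "missing": 0.05}
DEFAULT_HER2 = {"positive": 0.15, "negative": 0.80, "missing": 0.05}
DEFAULT_KI67 = {"positive": 0.55, "negative": 0.40, "missing": 0.05}


@dataclass
class SyntheticStudySpec:
    """Shape and composition of one synthetic cohort."""

    n_wsis: int = 10
    grid_rows: int = 30
    grid_cols: int = 30
    side_px: float = wsi_labels.TILE_SIDE_PX
    nhg_probs: dict = field(default_factory=lambda: dict(DEFAULT_NHG))
    er_probs: dict = field(default_factory=lambda: dict(DEFAULT_ER))
    her2_probs: dict = field(default_factory=lambda: dict(DEFAULT_HER2))
    ki67_probs: dict = field(default_factory=lambda: dict(DEFAULT_KI67))
    n_ic_blobs: int = 3
    ic_radius_tiles: tuple[float, float] = (2.0, 6.0)
    lobular_fraction: float = 0.2  # IC blobs labeled "invasive lobular cancer"
    target_ic_fraction: float | None = 0.3
    n_dcis_blobs: int = 2
    dcis_radius_tiles: tuple[float, float] = (1.0, 3.0)
    n_benign_blobs: int = 2
    benign_radius_tiles: tuple[float, float] = (1.0, 4.0)
    n_artifact_blobs: int = 1
    artifact_radius_tiles: tuple[float, float] = (0.5, 2.0)
    model_specs: list[SimModelSpec] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ValueError("grid must be at least 2x2")
        for lo, hi in (self.ic_radius_tiles, self.dcis_radius_tiles,
                       self.benign_radius_tiles, self.artifact_radius_tiles):
            if not 0 < lo <= hi:
                raise ValueError("blob radius range must satisfy 0 < lo <= hi")
            if 2 * hi > min(self.grid_rows, self.grid_cols):
                raise ValueError("blob diameter exceeds the tile grid")

    def resolved_model_specs(self) -> list[SimModelSpec]:
        return self.model_specs if self.model_specs is not None else default_model_family()


@dataclass
class SyntheticStudy:
    """One generated cohort: every table the pipeline reads, in memory."""

    spec: SyntheticStudySpec
    tiles: pd.DataFrame
    annotations: list[AnnotationPolygon]
    clinical: pd.DataFrame
    intended_labels: pd.DataFrame  # labeled tile table per the generator's own rule
    scores: pd.DataFrame


# ---------------------------------------------------------------------------
# Independent geometry route: even-odd ray casting


def points_in_ring(xs: np.ndarray, ys: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Even-odd ray-casting test of points against one closed ring.

    Vectorized over points; the ring is an (k, 2) vertex array (closing
    vertex optional).  Written from scratch as an oracle independent of the
    geometry library used by the labeling module.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    ring = np.asarray(ring, dtype=float)
    if np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    inside = np.zeros(xs.shape, dtype=bool)
    k = len(ring)
    for i in range(k):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % k]
        crosses = (y1 > ys) != (y2 > ys)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (xs < np.where(crosses, x_at, np.inf))
    return inside


def points_in_polygon(
    xs: np.ndarray, ys: np.ndarray, outer: np.ndarray,
    holes: Sequence[np.ndarray] = (),
) -> np.ndarray:
    """Even-odd containment with holes: inside the outer ring, outside holes."""
    inside = points_in_ring(xs, ys, outer)
    for h in holes:
        inside &= ~points_in_ring(xs, ys, h)
    return inside


# ---------------------------------------------------------------------------
# Blob generation


def _star_blob(
    rng: np.random.Generator,
    extent_x: float,
    extent_y: float,
    radius_range_px: tuple[float, float],
    n_vertices: int = 16,
) -> np.ndarray:
    """Randomized star-convex polygon: random radii at fixed angular steps,
    vertices snapped to integer pixel coordinates."""
    lo, hi = radius_range_px
    margin = hi
    cx = rng.uniform(margin, max(extent_x - margin, margin))
    cy = rng.uniform(margin, max(extent_y - margin, margin))
    angles = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    angles = angles + rng.uniform(0, 2.0 * np.pi / n_vertices)
    radii = rng.uniform(lo, hi, size=n_vertices)
    xs = np.rint(cx + radii * np.cos(angles))
    ys = np.rint(cy + radii * np.sin(angles))
    return np.column_stack([xs, ys])


def _generate_wsi_blobs(
    spec: SyntheticStudySpec,
    rng: np.random.Generator,
    wsi_id: str,
    cx: np.ndarray,
    cy: np.ndarray,
) -> tuple[list[AnnotationPolygon], list[np.ndarray]]:
    """IC and other-class blobs for one WSI; returns polygons and the list of
    IC outer rings (for the generator's own labeling)."""
    side = spec.side_px
    ex = spec.grid_cols * side
    ey = spec.grid_rows * side
    polys: list[AnnotationPolygon] = []
    ic_rings: list[np.ndarray] = []

    def to_px(radius_tiles: tuple[float, float]) -> tuple[float, float]:
        return radius_tiles[0] * side, radius_tiles[1] * side

    def add(class_label: str, radius_tiles: tuple[float, float], is_ic: bool) -> None:
        ring = _star_blob(rng, ex, ey, to_px(radius_tiles))
        polys.append(
            AnnotationPolygon(wsi_id=wsi_id, class_label=class_label,
                              polygon=Polygon(ring))
        )
        if is_ic:
            ic_rings.append(ring)

    n_tiles = cx.size

    def ic_fraction() -> float:
        if not ic_rings:
            return 0.0
        inside = np.zeros(n_tiles, dtype=bool)
        for ring in ic_rings:
            inside |= points_in_ring(cx, cy, ring)
        return float(inside.mean())

    for b in range(spec.n_ic_blobs):
        name = ("invasive lobular cancer"
                if rng.random() < spec.lobular_fraction else "invasive cancer")
        add(name, spec.ic_radius_tiles, is_ic=True)
    if spec.target_ic_fraction is not None:
        # Keep adding IC blobs until the intended tile fraction reaches target.
        attempts = 0
        while ic_fraction() < spec.target_ic_fraction and attempts < 200:
            name = ("invasive lobular cancer"
                    if rng.random() < spec.lobular_fraction else "invasive cancer")
            add(name, spec.ic_radius_tiles, is_ic=True)
            attempts += 1

    for _ in range(spec.n_dcis_blobs):
        add("dcis", spec.dcis_radius_tiles, is_ic=False)
    for _ in range(spec.n_benign_blobs):
        add("benign epithelium", spec.benign_radius_tiles, is_ic=False)
    for _ in range(spec.n_artifact_blobs):
        add("artifact", spec.artifact_radius_tiles, is_ic=False)
    return polys, ic_rings


def _sample_categorical(rng: np.random.Generator, probs: dict, size: int) -> np.ndarray:
    levels = sorted(probs)
    p = np.array([probs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=size, p=p)


# ---------------------------------------------------------------------------
# Study generation


def generate_study(
    spec: SyntheticStudySpec, out_dir: str | Path | None = None
) -> SyntheticStudy:
    """Generate a full synthetic cohort, optionally writing all files.

    Written files (when ``out_dir`` is given): tiles.csv, clinical.csv,
    intended_labels.csv, scores.csv, model_specs.yaml, study_spec.json and
    one annotations/<wsi_id>.geojson per WSI -- exactly the formats every
    other module reads.  Fully reproducible from ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    wsi_seeds = root.spawn(spec.n_wsis + 2)
    clin_rng = np.random.default_rng(wsi_seeds[-2])

    all_tiles = []
    all_polys: list[AnnotationPolygon] = []
    intended_rows = []
    for w in range(spec.n_wsis):
        wsi_id = f"wsi{w + 1:03d}"
        rng = np.random.default_rng(wsi_seeds[w])
        tiles = make_grid(wsi_id, spec.grid_rows, spec.grid_cols, spec.side_px)
        cx = ((tiles["x0"] + tiles["x1"]) / 2.0).to_numpy()
        cy = ((tiles["y0"] + tiles["y1"]) / 2.0).to_numpy()
        polys, _ = _generate_wsi_blobs(spec, rng, wsi_id, cx, cy)

        # Generator's own labels: even-odd ray casting per class.
        label_sets = [set() for _ in range(len(tiles))]
        for p in polys:
            ring = np.asarray(p.polygon.exterior.coords)
            inside = points_in_ring(cx, cy, ring)
            for j in np.flatnonzero(inside):
                label_sets[j].add(p.class_label)
        ic = {c for c in DEFAULT_IC_CLASSES}
        lab = tiles.copy()
        lab["labels"] = [";".join(sorted(s)) for s in label_sets]
        lab["l"] = [int(bool(s & ic)) for s in label_sets]

        all_tiles.append(tiles)
        all_polys.extend(polys)
        intended_rows.append(lab)

    tiles = pd.concat(all_tiles, ignore_index=True)
    intended = pd.concat(intended_rows, ignore_index=True)

    wsi_ids = [f"wsi{w + 1:03d}" for w in range(spec.n_wsis)]
    clinical = pd.DataFrame(
        {
            "wsi_id": wsi_ids,
            "nhg": _sample_categorical(clin_rng, spec.nhg_probs, spec.n_wsis),
            "er": _sample_categorical(clin_rng, spec.er_probs, spec.n_wsis),
            "her2": _sample_categorical(clin_rng, spec.her2_probs, spec.n_wsis),
            "ki67": _sample_categorical(clin_rng, spec.ki67_probs, spec.n_wsis),
        }
    )

    specs = spec.resolved_model_specs()
    score_seed = int(wsi_seeds[-1].generate_state(1)[0] % (2**31))
    scores = simulate_scores(intended, specs, seed=score_seed)

    study = SyntheticStudy(
        spec=spec, tiles=tiles, annotations=all_polys, clinical=clinical,
        intended_labels=intended, scores=scores,
    )
    if out_dir is not None:
        _write_study(study, Path(out_dir))
    return study


def _write_study(study: SyntheticStudy, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_tiles(study.tiles, out_dir / "tiles.csv")
    write_clinical(study.clinical, out_dir / "clinical.csv")
    write_labeled_tiles(study.intended_labels, out_dir / "intended_labels.csv")
    write_scores(study.scores, out_dir / "scores.csv")
    write_model_specs(study.spec.resolved_model_specs(), out_dir / "model_specs.yaml")
    ann_dir = out_dir / "annotations"
    ann_dir.mkdir(exist_ok=True)
    by_wsi: dict[str, list[AnnotationPolygon]] = {}
    for p in study.annotations:
        by_wsi.setdefault(p.wsi_id, []).append(p)
    for wsi_id, polys in sorted(by_wsi.items()):
        write_annotations(polys, ann_dir / f"{wsi_id}.geojson")
    spec_dict = asdict(study.spec)
    spec_dict["model_specs"] = [asdict(s) for s in study.spec.resolved_model_specs()]
    (out_dir / "study_spec.json").write_text(json.dumps(spec_dict, indent=2))


# ---------------------------------------------------------------------------
# End-to-end demo


def demo_spec(seed: int = 0, n_wsis: int = 50) -> SyntheticStudySpec:
    """Default demo cohort: 50 WSIs of 30x30 tiles, ~30% IC tiles, ten
    simulated base models with p_correct = 0.8 and spread-out thresholds.
    With an 80/20 split this yields 40 training WSIs in 10 divisions and a
    10-WSI (9,000-tile) held-out test set."""
    return SyntheticStudySpec(n_wsis=n_wsis, seed=seed)


def end_to_end_demo(
    spec: SyntheticStudySpec | None = None,
    n_divisions: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
    out_dir: str | Path | None = None,
    single_model: str | None = None,
) -> dict:
    """Run the whole pipeline on a synthetic cohort.

    generate -> assign labels from GeoJSON-backed polygons -> stratified
    split and divisions -> out-of-division Dice calibration -> binarize and
    majority-vote on the held-out test tiles -> metrics and visualisations.

    Returns a dict with every intermediate object plus the metrics report;
    writes all artifacts (CSV/JSON/PNG) when ``out_dir`` is given.
    Deterministic: a fixed (spec.seed, seed) pair reproduces every output
    byte-for-byte.
    """
    if spec is None:
        spec = demo_spec(seed=seed)
    study = generate_study(spec)
    labeled = assign_labels(study.tiles, study.annotations)

    plan = split_train_test(study.clinical, test_fraction=test_fraction, seed=seed)
    plan = make_divisions(plan, study.clinical, n_divisions=n_divisions, seed=seed)

    train_tiles = labeled[labeled["wsi_id"].isin(plan.train_ids)]
    test_tiles = labeled[labeled["wsi_id"].isin(plan.test_ids)]

    thresholds = calibration.calibrate_ensemble(
        study.scores.loc[train_tiles["tile_id"]], labeled, plan
    )
    test_scores = study.scores.loc[test_tiles["tile_id"]]
    votes = ensemble.binarize(test_scores, thresholds)
    result = ensemble.ensemble_result(votes, test_scores, thresholds, labeled)

    model_ids = list(study.scores.columns)
    single_id = single_model if single_model is not None else model_ids[0]
    single = metrics.single_model_result(votes, single_id)

    report = metrics.wsi_metrics(result, single, labeled)
    theory = ensemble.ensemble_success_probability(
        len(model_ids), study.spec.resolved_model_specs()[0].p_correct
    )

    outputs: dict[str, Path] = {}
    n = len(model_ids)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_study(study, out_dir / "study")
        write_labeled_tiles(labeled, out_dir / "labeled_tiles.csv")
        plan.write(out_dir / "partition.csv")
        thresholds.write(out_dir / "thresholds.json")
        ensemble.write_result(result, out_dir / "ensemble_result.csv")
        report.write_csv(out_dir / "metrics.csv")
        report.write_json(out_dir / "metrics.json")
        first_test = plan.test_ids[0]
        wsi_tiles = labeled[labeled["wsi_id"] == first_test]
        viz.render_overlay(
            wsi_tiles, labeled, result, n, out_dir / "overlay.png"
        )
        viz.agreement_histogram(
            result, labeled, n,
            out_png=out_dir / "agreement_histogram.png",
            out_csv=out_dir / "agreement_histogram.csv",
        )
        viz.multilabel_confusion(
            labeled, result,
            out_png=out_dir / "confusion.png",
            out_csv=out_dir / "confusion.csv",
        )
        outputs = {p.name: p for p in out_dir.iterdir()}

    return {
        "study": study,
        "labeled": labeled,
        "plan": plan,
        "thresholds": thresholds,
        "votes": votes,
        "result": result,
        "single_model_id": single_id,
        "report": report,
        "p_ens_theory": theory,
        "outputs": outputs,
    }
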