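"""Tile geometry, polygon annotations, and center-rule tile labeling.

A whole-slide image (WSI) is analysed as a regular grid of square tiles
(598 x 598 px at 20X magnification, i.e. 271 x 271 um, by default).
Pathologist annotations arrive as polygons in WSI pixel coordinates, each
carrying a free-text class label; polygons of different classes may overlap,
so a single tile can carry several labels.  A tile receives a class when the
*center* of the tile lies inside (or on the boundary of) a polygon of that
class; an optional minimum tile/polygon overlap fraction can be required on
top of the center rule.  The derived binary label ``l`` is 1 when any of the
tile's classes belongs to the configured invasive-cancer (IC) class set.

Coordinates are 0-based pixels; tile bounding boxes are half-open
``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

#: Default tile side in pixels (598 px = 271 um at 20X).
TILE_SIDE_PX = 598
#: Default physical resolution, microns per pixel (271 um / 598 px).
MICRONS_PER_PX = 271.0 / 598.0
#: Classes that define the positive (invasive cancer) label.
DEFAULT_IC_CLASSES = frozenset({"invasive cancer", "invasive lobular cancer"})

TILE_COLUMNS = ["tile_id", "wsi_id", "row", "col", "x0", "y0", "x1", "y1"]
LABEL_COLUMNS = TILE_COLUMNS + ["labels", "l"]

LABEL_SEP = ";"


def normalize_class(name: str) -> str:
    """Normalise a class name: collapse whitespace, strip, casefold."""
    return re.sub(r"\s+", " ", str(name).strip()).casefold()


@dataclass(frozen=True)
class TileRecord:
    """One square tile of a WSI grid.

    ``row``/``col`` are grid indices; ``(x0, y0, x1, y1)`` is the 0-based,
    half-open pixel bounding box.  Tiles must be square.
    """

    tile_id: str
    wsi_id: str
    row: int
    col: int
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise ValueError(f"tile {self.tile_id}: negative grid index")
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"tile {self.tile_id}: empty bounding box")
        if (self.x1 - self.x0) != (self.y1 - self.y0):
            raise ValueError(f"tile {self.tile_id}: bounding box is not square")

    @property
    def side_px(self) -> float:
        return self.x1 - self.x0

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)


@dataclass(frozen=True)
class AnnotationPolygon:
    """One annotation region: a simple outer ring (holes allowed) plus a class.

    ``class_label`` is stored in normalised form (lowercase, single spaces);
    unknown classes are kept as-is rather than collapsed into an "other"
    bucket.
    """

    wsi_id: str
    class_label: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            raise TypeError("polygon must be a shapely Polygon")
        if self.polygon.is_empty:
            raise ValueError("empty polygon")


def make_grid(
    wsi_id: str,
    n_rows: int,
    n_cols: int,
    side_px: float = TILE_SIDE_PX,
) -> pd.DataFrame:
    """Build the tile table for a regular ``n_rows x n_cols`` grid."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid must be at least 1x1")
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows = rows.ravel()
    cols = cols.ravel()
    x0 = cols * side_px
    y0 = rows * side_px
    return pd.DataFrame(
        {
            "tile_id": [f"{wsi_id}_r{r:03d}c{c:03d}" for r, c in zip(rows, cols)],
            "wsi_id": wsi_id,
            "row": rows,
            "col": cols,
            "x0": x0,
            "y0": y0,
            "x1": x0 + side_px,
            "y1": y0 + side_px,
        }
    )


def tiles_frame(tiles: Iterable[TileRecord] | pd.DataFrame) -> pd.DataFrame:
    """Coerce tiles to a validated DataFrame with :data:`TILE_COLUMNS`."""
    if isinstance(tiles, pd.DataFrame):
        missing = [c for c in TILE_COLUMNS if c not in tiles.columns]
        if missing:
            raise ValueError(f"tile table missing columns: {missing}")
        df = tiles.loc[:, list(tiles.columns)].copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "tile_id": t.tile_id,
                    "wsi_id": t.wsi_id,
                    "row": t.row,
                    "col": t.col,
                    "x0": t.x0,
                    "y0": t.y0,
                    "x1": t.x1,
                    "y1": t.y1,
                }
                for t in tiles
            ],
            columns=TILE_COLUMNS,
        )
    if df["tile_id"].duplicated().any():
        raise ValueError("duplicate tile_id in tile table")
    if df.duplicated(subset=["wsi_id", "row", "col"]).any():
        raise ValueError("duplicate (wsi_id, row, col) in tile table")
    side = df["x1"] - df["x0"]
    if not np.allclose(side, df["y1"] - df["y0"]):
        raise ValueError("non-square tiles in tile table")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# GeoJSON I/O


def _feature_label(props: dict, index: int) -> str:
    cls = props.get("classification")
    if isinstance(cls, dict) and "name" in cls:
        return str(cls["name"])
    if isinstance(cls, str):
        return cls
    if "label" in props:
        return str(props["label"])
    raise ValueError(
        f"feature {index}: no 'classification'/'label' property with a class name"
    )


def read_annotations(path: str | Path, wsi_id: str | None = None) -> list[AnnotationPolygon]:
    """Read annotation polygons from a GeoJSON FeatureCollection.

    The class name is taken from ``properties.classification.name`` (QuPath
    convention), falling back to ``properties.label``.  MultiPolygons are
    expanded to one entry per member polygon, holes preserved.  The WSI id is
    taken from ``properties.wsi_id`` if present, else the ``wsi_id`` argument,
    else the file stem.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    default_wsi = wsi_id if wsi_id is not None else path.stem
    out: list[AnnotationPolygon] = []
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        label = normalize_class(_feature_label(props, i))
        geom = feat.get("geometry") or {}
        gtype = geom.get("type")
        wid = str(props.get("wsi_id", default_wsi))
        if gtype == "Polygon":
            coords_list = [geom["coordinates"]]
        elif gtype == "MultiPolygon":
            coords_list = list(geom["coordinates"])
        else:
            raise ValueError(
                f"feature {i}: unsupported geometry type {gtype!r} (expected Polygon)"
            )
        for coords in coords_list:
            poly = Polygon(coords[0], coords[1:])
            if not poly.exterior.is_simple:
                raise ValueError(f"feature {i}: self-intersecting outer ring")
            out.append(AnnotationPolygon(wsi_id=wid, class_label=label, polygon=poly))
    return out


def write_annotations(polys: Sequence[AnnotationPolygon], path: str | Path) -> None:
    """Write polygons as a GeoJSON FeatureCollection (one Feature per polygon)."""
    features = []
    for p in polys:
        rings = [list(map(list, p.polygon.exterior.coords))]
        rings += [list(map(list, r.coords)) for r in p.polygon.interiors]
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "classification": {"name": p.class_label},
                    "wsi_id": p.wsi_id,
                },
                "geometry": {"type": "Polygon", "coordinates": rings},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


# ---------------------------------------------------------------------------
# Label assignment


def assign_labels(
    tiles: Iterable[TileRecord] | pd.DataFrame,
    polys: Sequence[AnnotationPolygon],
    ic_classes: Iterable[str] = DEFAULT_IC_CLASSES,
    min_area_fraction: float = 0.0,
) -> pd.DataFrame:
    """Assign original class labels and the binary IC label to every tile.

    A tile gets class ``c`` when its center lies inside or on the boundary of
    some polygon of class ``c`` (closed-polygon ``covers`` semantics; centers
    inside holes are excluded) and, when ``min_area_fraction > 0``, the
    tile-polygon intersection covers at least that fraction of the tile area.
    ``l = 1`` iff the tile's label set intersects ``ic_classes``; tiles
    touching no polygon get an empty label set and ``l = 0``.

    Returns a labeled tile table with :data:`LABEL_COLUMNS`; ``labels`` holds
    the ";"-joined sorted class set.
    """
    if not 0.0 <= min_area_fraction <= 1.0:
        raise ValueError("min_area_fraction must be in [0, 1]")
    df = tiles_frame(tiles)
    ic = {normalize_class(c) for c in ic_classes}
    label_sets: list[set[str]] = [set() for _ in range(len(df))]

    cx = ((df["x0"] + df["x1"]) / 2.0).to_numpy()
    cy = ((df["y0"] + df["y1"]) / 2.0).to_numpy()

    by_wsi: dict[str, list[AnnotationPolygon]] = {}
    for p in polys:
        by_wsi.setdefault(p.wsi_id, []).append(p)

    for wsi_id, idx in df.groupby("wsi_id", sort=False).indices.items():
        wsi_polys = by_wsi.get(wsi_id)
        if not wsi_polys:
            continue
        pts = shapely.points(cx[idx], cy[idx])
        if min_area_fraction > 0.0:
            boxes = shapely.box(
                df["x0"].to_numpy()[idx],
                df["y0"].to_numpy()[idx],
                df["x1"].to_numpy()[idx],
                df["y1"].to_numpy()[idx],
            )
            tile_area = shapely.area(boxes)
        for p in wsi_polys:
            inside = shapely.covers(p.polygon, pts)
            if min_area_fraction > 0.0 and inside.any():
                cand = np.flatnonzero(inside)
                inter = shapely.area(shapely.intersection(p.polygon, boxes[cand]))
                ok = inter >= min_area_fraction * tile_area[cand]
                inside = np.zeros_like(inside)
                inside[cand[ok]] = True
            cls = normalize_class(p.class_label)
            for j in np.flatnonzero(inside):
                label_sets[idx[j]].add(cls)

    out = df.copy()
    out["labels"] = [LABEL_SEP.join(sorted(s)) for s in label_sets]
    out["l"] = [int(bool(s & ic)) for s in label_sets]
    return out


def labels_as_sets(labeled: pd.DataFrame) -> list[frozenset[str]]:
    """Decode the ";"-joined ``labels`` column back to per-tile class sets."""
    out = []
    for s in labeled["labels"].fillna(""):
        out.append(frozenset(p for p in str(s).split(LABEL_SEP) if p))
    return out


def drop_tiles_with_classes(labeled: pd.DataFrame, classes: Iterable[str]) -> pd.DataFrame:
    """Remove tiles carrying any of the given classes (e.g. artifact regions).

    Off by default in every pipeline; exposed for cohorts where artifact
    annotations should be excluded from training tiles.
    """
    drop = {normalize_class(c) for c in classes}
    keep = [not (s & drop) for s in labels_as_sets(labeled)]
    return labeled.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# CSV I/O


def write_tiles(df: pd.DataFrame, path: str | Path) -> None:
    tiles_frame(df).to_csv(path, index=False)


def read_tiles(path: str | Path) -> pd.DataFrame:
    return tiles_frame(pd.read_csv(path, dtype={"tile_id": str, "wsi_id": str}))


def write_labeled_tiles(labeled: pd.DataFrame, path: str | Path) -> None:
    labeled.loc[:, LABEL_COLUMNS].to_csv(path, index=False)


def read_labeled_tiles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tile_id": str, "wsi_id": str, "labels": str})
    df["labels"] = df["labels"].fillna("")
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"labeled tile table missing columns: {missing}")
    return df
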