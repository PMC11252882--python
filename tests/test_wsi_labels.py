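"""Tile labeling: GeoJSON parsing, the center rule, and its geometry oracle."""

import json

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from tilevote.synthetic import points_in_ring
from tilevote.wsi_labels import (
    AnnotationPolygon,
    assign_labels,
    labels_as_sets,
    drop_tiles_with_classes,
    make_grid,
    read_annotations,
    read_labeled_tiles,
    tiles_frame,
    write_annotations,
    write_labeled_tiles,
    TileRecord,
)


def square_poly(wsi_id, cls, x0, y0, x1, y1):
    return AnnotationPolygon(
        wsi_id=wsi_id, class_label=cls,
        polygon=Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)]),
    )


class TestGeoJSON:
    def test_single_square_feature_parses(self, tmp_path):
        fc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"classification": {"name": "Invasive  Cancer"}},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]]],
                    },
                }
            ],
        }
        p = tmp_path / "w1.geojson"
        p.write_text(json.dumps(fc))
        polys = read_annotations(p)
        assert len(polys) == 1
        assert polys[0].class_label == "invasive cancer"  # normalised
        assert polys[0].wsi_id == "w1"  # from file stem

    def test_empty_collection_gives_empty_list(self, tmp_path):
        p = tmp_path / "w1.geojson"
        p.write_text(json.dumps({"type": "FeatureCollection", "features": []}))
        assert read_annotations(p) == []

    def test_point_geometry_rejected_naming_type(self, tmp_path):
        fc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"label": "dcis"},
                    "geometry": {"type": "Point", "coordinates": [1, 2]},
                }
            ],
        }
        p = tmp_path / "w1.geojson"
        p.write_text(json.dumps(fc))
        with pytest.raises(ValueError, match="Point"):
            read_annotations(p)

    def test_missing_label_names_feature_index(self, tmp_path):
        fc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {},
                    "geometry": {"type": "Polygon",
                                 "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 0]]]},
                }
            ],
        }
        p = tmp_path / "w1.geojson"
        p.write_text(json.dumps(fc))
        with pytest.raises(ValueError, match="feature 0"):
            read_annotations(p)

    def test_write_read_round_trip(self, tmp_path):
        polys = [
            square_poly("w9", "dcis", 0, 0, 5, 5),
            AnnotationPolygon(
                wsi_id="w9", class_label="invasive cancer",
                polygon=Polygon(
                    [(0, 0), (10, 0), (10, 10), (0, 10)],
                    [[(4, 4), (6, 4), (6, 6), (4, 6)]],
                ),
            ),
        ]
        path = tmp_path / "ann.geojson"
        write_annotations(polys, path)
        back = read_annotations(path)
        assert [p.class_label for p in back] == ["dcis", "invasive cancer"]
        assert [p.wsi_id for p in back] == ["w9", "w9"]
        assert back[1].polygon.equals(polys[1].polygon)


class TestTileRecord:
    def test_center_and_side(self):
        t = TileRecord("t", "w", 0, 0, 0, 0, 598, 598)
        assert t.center == (299.0, 299.0)
        assert t.side_px == 598

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(row=-1, col=0, x0=0, y0=0, x1=1, y1=1),
            dict(row=0, col=0, x0=0, y0=0, x1=0, y1=1),
            dict(row=0, col=0, x0=0, y0=0, x1=2, y1=1),
        ],
    )
    def test_invalid_tiles_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TileRecord("t", "w", **kwargs)

    def test_duplicate_grid_position_rejected(self):
        df = make_grid("w", 2, 2, side_px=1)
        df.loc[1, ["row", "col"]] = [0, 0]
        df.loc[1, "tile_id"] = "other"
        with pytest.raises(ValueError, match="duplicate"):
            tiles_frame(df)


class TestAssignLabels:
    def test_left_half_polygon_labels_eight_tiles(self, unit_grid):
        # Polygon exactly covering the left two columns of a 4x4 unit grid.
        poly = square_poly("w1", "invasive cancer", 0, 0, 2, 4)
        lab = assign_labels(unit_grid, [poly])
        assert lab["l"].sum() == 8
        assert set(lab.loc[lab["l"] == 1, "col"]) == {0, 1}

    def test_overlapping_classes_stack_and_ic_wins(self, unit_grid):
        polys = [
            square_poly("w1", "DCIS", 0, 0, 4, 4),
            square_poly("w1", "invasive cancer", 0, 0, 1, 1),
        ]
        lab = assign_labels(unit_grid, polys)
        sets = labels_as_sets(lab)
        corner = lab.index[(lab["row"] == 0) & (lab["col"] == 0)][0]
        assert sets[corner] == {"dcis", "invasive cancer"}
        assert lab.loc[corner, "l"] == 1
        # the rest are DCIS-only: labeled but not IC
        assert lab["l"].sum() == 1
        assert all(s == {"dcis"} for i, s in enumerate(sets) if i != corner)

    def test_label_empty_set_is_zero(self, unit_grid):
        lab = assign_labels(unit_grid, [])
        assert (lab["l"] == 0).all()
        assert (lab["labels"] == "").all()

    def test_center_on_boundary_counts_inside(self):
        # Tile center at (0.5, 0.5); polygon edge passes through it.
        tiles = make_grid("w1", 1, 1, side_px=1)
        poly = square_poly("w1", "invasive cancer", 0.5, 0, 2, 2)
        lab = assign_labels(tiles, [poly])
        assert lab["l"].iloc[0] == 1

    def test_hole_excludes_center(self):
        tiles = make_grid("w1", 1, 1, side_px=1)
        donut = AnnotationPolygon(
            wsi_id="w1", class_label="invasive cancer",
            polygon=Polygon(
                [(-1, -1), (2, -1), (2, 2), (-1, 2)],
                [[(0.25, 0.25), (0.75, 0.25), (0.75, 0.75), (0.25, 0.75)]],
            ),
        )
        lab = assign_labels(tiles, [donut])
        assert lab["l"].iloc[0] == 0

    def test_min_area_fraction_filters_sliver_overlap(self):
        # Center inside, but the polygon only covers ~55% of the tile:
        # accepted at 0.5, rejected at 0.6.
        tiles = make_grid("w1", 1, 1, side_px=1)
        poly = square_poly("w1", "invasive cancer", 0, 0, 0.55, 1)
        assert assign_labels(tiles, [poly], min_area_fraction=0.5)["l"].iloc[0] == 1
        assert assign_labels(tiles, [poly], min_area_fraction=0.6)["l"].iloc[0] == 0

    def test_order_invariance(self, unit_grid):
        polys = [
            square_poly("w1", "invasive cancer", 0, 0, 2, 4),
            square_poly("w1", "dcis", 1, 1, 3, 3),
        ]
        a = assign_labels(unit_grid, polys)
        b = assign_labels(unit_grid, polys[::-1])
        shuffled = unit_grid.sample(frac=1, random_state=1)
        c = assign_labels(shuffled, polys).sort_values("tile_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(
            a.sort_values("tile_id").reset_index(drop=True), c
        )

    def test_agrees_with_ray_casting_oracle_on_random_configs(self):
        """Center rule vs an independent even-odd point-in-polygon oracle,
        >= 1000 random tile/polygon configurations."""
        rng = np.random.default_rng(42)
        checked = 0
        for trial in range(25):
            tiles = make_grid(f"w{trial}", 8, 8, side_px=1)
            k = rng.integers(5, 12)
            angles = np.sort(rng.uniform(0, 2 * np.pi, k))
            radii = rng.uniform(0.5, 4.0, k)
            ccx, ccy = rng.uniform(1, 7, 2)
            ring = np.column_stack(
                [ccx + radii * np.cos(angles), ccy + radii * np.sin(angles)]
            )
            poly = AnnotationPolygon(
                wsi_id=f"w{trial}", class_label="invasive cancer",
                polygon=Polygon(ring),
            )
            lab = assign_labels(tiles, [poly])
            cx = ((tiles["x0"] + tiles["x1"]) / 2).to_numpy()
            cy = ((tiles["y0"] + tiles["y1"]) / 2).to_numpy()
            expected = points_in_ring(cx, cy, ring).astype(int)
            np.testing.assert_array_equal(lab["l"].to_numpy(), expected)
            checked += len(tiles)
        assert checked >= 1000

    def test_shifted_polygon_counts_match_oracle(self, unit_grid):
        # Left-half polygon shifted right by 0.4 tile widths: pure center rule.
        poly = square_poly("w1", "invasive cancer", 0.4, 0, 2.4, 4)
        lab = assign_labels(unit_grid, [poly])
        cx = ((unit_grid["x0"] + unit_grid["x1"]) / 2).to_numpy()
        cy = ((unit_grid["y0"] + unit_grid["y1"]) / 2).to_numpy()
        ring = np.array([[0.4, 0], [2.4, 0], [2.4, 4], [0.4, 4]])
        assert lab["l"].sum() == points_in_ring(cx, cy, ring).sum()

    def test_drop_tiles_with_classes(self, unit_grid):
        polys = [square_poly("w1", "artifact", 0, 0, 1, 1)]
        lab = assign_labels(unit_grid, polys)
        kept = drop_tiles_with_classes(lab, ["Artifact"])
        assert len(kept) == len(unit_grid) - 1

    def test_csv_round_trip(self, unit_grid, tmp_path):
        poly = square_poly("w1", "invasive cancer", 0, 0, 2, 4)
        lab = assign_labels(unit_grid, [poly])
        path = tmp_path / "labeled.csv"
        write_labeled_tiles(lab, path)
        back = read_labeled_tiles(path)
        assert list(back["l"]) == list(lab["l"])
        assert list(back["labels"]) == list(lab["labels"])
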