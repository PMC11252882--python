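"""Agreement visualisations: glyph overlay, histogram, multi-label confusion.

The overlay renders, per tile: a square outline in the true class color, a
filled diamond whose grey level encodes agreement (black = 0 models right,
white = all n right), and an X in the predicted class color -- so ground
truth, uncertainty and prediction are readable in one glance over the tile
grid.  Orange marks invasive cancer (IC), blue marks not-IC.

The histogram counts tiles at each agreement level 0..n split by true
class; the multi-label confusion matrix breaks the binary prediction down
by *original* annotation class (a tile carrying several overlapping classes
contributes to every matching row), with per-class totals as a bar chart.
Every plot has a CSV twin so numeric checks never depend on pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.lines import Line2D
from matplotlib.patches import Polygon as MplPolygon, Rectangle

from .wsi_labels import labels_as_sets

IC_COLOR = "#FF8C00"      # orange: invasive cancer
NOT_IC_COLOR = "#1F77B4"  # blue: not invasive cancer

# Glyph sizes as fractions of the tile cell, so all three stay visible.
SQUARE_FRAC = 0.9
DIAMOND_FRAC = 0.6
X_FRAC = 0.4


@dataclass(frozen=True)
class OverlaySpec:
    ic_color: str = IC_COLOR
    not_ic_color: str = NOT_IC_COLOR
    square_frac: float = SQUARE_FRAC
    diamond_frac: float = DIAMOND_FRAC
    x_frac: float = X_FRAC


def _class_color(binary: int, spec: OverlaySpec) -> str:
    return spec.ic_color if binary == 1 else spec.not_ic_color


def render_overlay(
    tiles: pd.DataFrame,
    labeled: pd.DataFrame,
    result: pd.DataFrame,
    n_models: int,
    out: str | Path,
    background=None,
    spec: OverlaySpec = OverlaySpec(),
) -> Path:
    """Render the per-tile glyph overlay for one WSI and write a PNG.

    ``result`` must be indexed by tile_id and contain predicted_label and
    agreement.  The agreement diamond's grey level is round(255 * a / n).
    """
    wsis = tiles["wsi_id"].unique()
    if len(wsis) != 1:
        raise ValueError("render_overlay expects tiles of exactly one WSI")
    tile_set = set(tiles["tile_id"])
    if tile_set - set(result.index) or tile_set - set(labeled["tile_id"]):
        raise ValueError("result/labels do not cover the tile set")
    lab = labeled.set_index("tile_id")

    side = float(tiles["x1"].iloc[0] - tiles["x0"].iloc[0])
    width = tiles["x1"].max()
    height = tiles["y1"].max()
    fig_w = max(4.0, min(12.0, width / height * 8.0))
    fig, ax = plt.subplots(figsize=(fig_w, fig_w * height / width))
    if background is not None:
        ax.imshow(background, extent=(0, width, height, 0), origin="upper")

    for t in tiles.itertuples(index=False):
        cx = (t.x0 + t.x1) / 2.0
        cy = (t.y0 + t.y1) / 2.0
        l = int(lab.loc[t.tile_id, "l"])
        pred = int(result.loc[t.tile_id, "predicted_label"])
        a = int(result.loc[t.tile_id, "agreement"])
        grey = round(255 * a / n_models) / 255.0

        s = side * spec.square_frac
        ax.add_patch(
            Rectangle((cx - s / 2, cy - s / 2), s, s, fill=False,
                      edgecolor=_class_color(l, spec), linewidth=0.8)
        )
        d = side * spec.diamond_frac / 2.0
        ax.add_patch(
            MplPolygon(
                [(cx, cy - d), (cx + d, cy), (cx, cy + d), (cx - d, cy)],
                closed=True, facecolor=(grey, grey, grey),
                edgecolor="0.3", linewidth=0.3,
            )
        )
        xr = side * spec.x_frac / 2.0
        for dx in (-1, 1):
            ax.add_line(
                Line2D([cx - xr, cx + xr], [cy - dx * xr, cy + dx * xr],
                       color=_class_color(pred, spec), linewidth=1.0)
            )

    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)  # image convention: y down
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"{wsis[0]}: label (square), agreement 0..{n_models} (diamond), "
                 f"prediction (X)", fontsize=9)
    handles = [
        Line2D([], [], color=spec.ic_color, label="IC"),
        Line2D([], [], color=spec.not_ic_color, label="not IC"),
        Line2D([], [], marker="D", linestyle="", markerfacecolor="white",
               markeredgecolor="0.3", label=f"agreement (white = {n_models})"),
    ]
    ax.legend(handles=handles, loc="upper right", fontsize=7)
    out = Path(out)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def agreement_histogram(
    result: pd.DataFrame,
    labeled: pd.DataFrame,
    n_models: int,
    out_png: str | Path | None = None,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Counts of tiles at each agreement level 0..n, split by true class.

    Returns the table (index = agreement, columns IC / not IC); writes the
    plot and/or CSV when paths are given.  Empty input returns an empty
    table with a warning and writes no plot.
    """
    if len(result) == 0:
        warnings.warn("agreement_histogram: empty input, nothing to plot")
        return pd.DataFrame(columns=["IC", "not IC"])
    if "agreement" not in result.columns:
        raise ValueError("result has no agreement column")
    lab = labeled.set_index("tile_id")["l"].loc[result.index].to_numpy().astype(int)
    a = result["agreement"].to_numpy().astype(int)
    levels = np.arange(n_models + 1)
    table = pd.DataFrame(
        {
            "IC": [int(np.sum((a == k) & (lab == 1))) for k in levels],
            "not IC": [int(np.sum((a == k) & (lab == 0))) for k in levels],
        },
        index=pd.Index(levels, name="agreement"),
    )
    if out_csv is not None:
        table.to_csv(out_csv)
    if out_png is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        x = levels
        ax.bar(x - 0.2, table["IC"], width=0.4, color=IC_COLOR, label="IC")
        ax.bar(x + 0.2, table["not IC"], width=0.4, color=NOT_IC_COLOR,
               label="not IC")
        ax.set_xlabel("agreement (models voting for the true class)")
        ax.set_ylabel("tiles")
        ax.set_xticks(x)
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return table


def multilabel_confusion(
    labeled: pd.DataFrame,
    result: pd.DataFrame,
    out_png: str | Path | None = None,
    out_csv: str | Path | None = None,
    include_unlabeled: bool = False,
) -> pd.DataFrame:
    """Break the binary prediction down by original annotation class.

    One row per class present in the labeled table (a tile with several
    overlapping classes counts toward every matching row): counts and
    percentages predicted IC vs not-IC plus the row total.  Optionally adds
    a row for tiles with no annotation.  Rendered as an annotated heatmap
    with a per-class total bar chart when ``out_png`` is given.
    """
    sets = dict(zip(labeled["tile_id"], labels_as_sets(labeled)))
    pred = result["predicted_label"]

    classes = sorted(set().union(*sets.values())) if sets else []
    rows = []
    for c in classes:
        members = [t for t in result.index if c in sets.get(t, frozenset())]
        rows.append((c, members))
    if include_unlabeled:
        members = [t for t in result.index if not sets.get(t, frozenset())]
        rows.append(("(no annotation)", members))

    records = []
    for c, members in rows:
        total = len(members)
        n_ic = int(pred.loc[members].sum()) if total else 0
        n_not = total - n_ic
        records.append(
            {
                "class": c,
                "pred_ic": n_ic,
                "pred_not_ic": n_not,
                "pct_ic": 100.0 * n_ic / total if total else np.nan,
                "pct_not_ic": 100.0 * n_not / total if total else np.nan,
                "total": total,
            }
        )
    table = pd.DataFrame(
        records, columns=["class", "pred_ic", "pred_not_ic", "pct_ic",
                          "pct_not_ic", "total"]
    )
    if out_csv is not None:
        table.to_csv(out_csv, index=False, na_rep="NA")
    if out_png is not None and len(table) > 0:
        fig, (ax, axb) = plt.subplots(
            1, 2, figsize=(8, 1.0 + 0.6 * len(table)),
            gridspec_kw={"width_ratios": [2, 1]}, sharey=True,
        )
        pct = table[["pct_ic", "pct_not_ic"]].to_numpy(dtype=float)
        ax.imshow(np.nan_to_num(pct), cmap="Blues", vmin=0, vmax=100, aspect="auto")
        for i in range(len(table)):
            for j, (p, cnt) in enumerate(
                [(pct[i, 0], table["pred_ic"].iat[i]),
                 (pct[i, 1], table["pred_not_ic"].iat[i])]
            ):
                txt = "NA" if np.isnan(p) else f"{p:.1f}%\n({cnt})"
                ax.text(j, i, txt, ha="center", va="center", fontsize=8,
                        color="black" if (np.isnan(p) or p < 60) else "white")
        ax.set_xticks([0, 1], ["pred IC", "pred not IC"])
        ax.set_yticks(range(len(table)), table["class"])
        axb.barh(range(len(table)), table["total"], color="0.6")
        axb.set_xlabel("tiles per class")
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return table
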