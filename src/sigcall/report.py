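"""Heatmap and summary-matrix rendering with the diverging display encoding.

Cells carry a log2FC on a diverging scale clamped to [-5, +5]: dark red at
-5 (downregulation), white at 0, dark green at +5 (upregulation).
Non-significant cells are light grey, genes missing from a dataset dark
grey, and zero-read genes labelled "n.e.".  Clamping is display-only; every
rendered figure has an exact-value TSV twin carrying the unclamped numbers,
and the TSV twin — not the image — is the tested surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap, Normalize
from matplotlib.patches import Rectangle

from .activity import ExpressionMatrix

__all__ = ["HeatmapSpec", "clamp_value", "render_heatmap", "render_summary"]


@dataclass(frozen=True)
class HeatmapSpec:
    """Display encoding for expression heatmaps."""

    clamp_lo: float = -5.0
    clamp_hi: float = 5.0
    midpoint: float = 0.0
    color_low: str = "#8b0000"  # dark red
    color_high: str = "#006400"  # dark green
    color_mid: str = "#ffffff"
    nonsig_color: str = "#d3d3d3"  # light grey
    notfound_color: str = "#555555"  # dark grey
    ne_label: str = "n.e."

    def __post_init__(self) -> None:
        if not (self.clamp_lo < self.midpoint < self.clamp_hi):
            raise ValueError("require clamp_lo < midpoint < clamp_hi")

    def colormap(self) -> LinearSegmentedColormap:
        return LinearSegmentedColormap.from_list(
            "sigcall_diverging", [self.color_low, self.color_mid, self.color_high]
        )


def clamp_value(x: float, spec: HeatmapSpec = HeatmapSpec()) -> float:
    """Clamp a log2FC into the display range (display-only transform)."""
    if not math.isfinite(x):
        raise ValueError(f"cannot clamp non-finite value {x!r}")
    return min(max(x, spec.clamp_lo), spec.clamp_hi)


def render_heatmap(
    matrix: ExpressionMatrix,
    out: Union[str, Path],
    spec: HeatmapSpec = HeatmapSpec(),
) -> tuple[Path, Path]:
    """Render an expression matrix to an image plus its exact-value TSV twin.

    Returns (image path, TSV path).  The TSV carries unclamped log2FC values
    and the literal status tokens; the image applies the clamp, status
    colors, and thin separators between panels.
    """
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    img_path = out if out.suffix in (".png", ".svg") else out.with_suffix(".png")
    tsv_path = img_path.with_suffix(".tsv")

    # TSV twin: genes x models, value cells as unclamped numbers, other
    # statuses as their tokens
    value_rows = []
    for panel_label, symbol in matrix.rows:
        row: dict[str, object] = {"panel": panel_label, "gene": symbol}
        for mid in matrix.cols:
            c = matrix.cell(symbol, mid)
            row[mid] = repr(c.value) if c.value is not None else c.status
        value_rows.append(row)
    pd.DataFrame(value_rows).to_csv(tsv_path, sep="\t", index=False)

    n_rows = len(matrix.rows)
    n_cols = len(matrix.cols)
    fig_h = max(2.0, 0.22 * n_rows + 1.5)
    fig_w = max(3.0, 0.55 * n_cols + 2.5)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    cmap = spec.colormap()
    norm = Normalize(vmin=spec.clamp_lo, vmax=spec.clamp_hi)

    for r, (panel_label, symbol) in enumerate(matrix.rows):
        for c_idx, mid in enumerate(matrix.cols):
            cell = matrix.cell(symbol, mid)
            label = None
            if cell.status == "significant":
                color = cmap(norm(clamp_value(cell.value, spec)))
            elif cell.status == "non_significant":
                color = spec.nonsig_color
            elif cell.status == "not_found":
                color = spec.notfound_color
            else:  # not_expressed
                color = spec.nonsig_color
                label = spec.ne_label
            ax.add_patch(
                Rectangle((c_idx, n_rows - 1 - r), 1, 1, facecolor=color,
                          edgecolor="white", linewidth=0.3)
            )
            if label:
                ax.text(c_idx + 0.5, n_rows - 1 - r + 0.5, label,
                        ha="center", va="center", fontsize=6)

    # separators between panels
    prev = None
    for r, (panel_label, _) in enumerate(matrix.rows):
        if prev is not None and panel_label != prev:
            ax.axhline(n_rows - r, color="black", linewidth=1.2)
        prev = panel_label

    ax.set_xlim(0, n_cols)
    ax.set_ylim(0, n_rows)
    ax.set_xticks(np.arange(n_cols) + 0.5)
    ax.set_xticklabels(matrix.cols, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(n_rows) + 0.5)
    ax.set_yticklabels([sym for _, sym in reversed(matrix.rows)], fontsize=6)
    ax.set_aspect("auto")
    fig.colorbar(
        plt.cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax,
        label="log2FC (clamped for display)", shrink=0.6,
    )
    fig.tight_layout()
    fig.savefig(img_path, dpi=150)
    plt.close(fig)
    return img_path, tsv_path


#: Summary-cell fill colors follow the paper-wide growth color code:
#: green = activated (pro-growth), red = reduced; yellow covers both
#: inconclusive and no-change (merged only at render time).
SUMMARY_COLORS = {
    "activated": "#2e8b2e",
    "reduced": "#c23b22",
    "no_change": "#f5e663",
    "inconclusive": "#f5e663",
}


def render_summary(
    call_matrix: pd.DataFrame,
    out: Union[str, Path],
) -> tuple[Path, Path]:
    """Render a pathway x model call matrix plus its TSV twin.

    The TSV keeps the full "state/confidence" tokens (no-change and
    inconclusive stay distinct there); in the image both map to yellow and
    low-confidence cells get a white background ring.
    """
    if call_matrix.empty:
        raise ValueError("empty call matrix")
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    img_path = out if out.suffix in (".png", ".svg") else out.with_suffix(".png")
    tsv_path = img_path.with_suffix(".tsv")
    call_matrix.to_csv(tsv_path, sep="\t")

    n_rows, n_cols = call_matrix.shape
    fig, ax = plt.subplots(figsize=(max(3.0, 0.7 * n_cols + 2), max(2.0, 0.45 * n_rows + 1)))
    for r, pathway in enumerate(call_matrix.index):
        for c, model in enumerate(call_matrix.columns):
            token = call_matrix.iloc[r, c]
            state, _, confidence = str(token).partition("/")
            color = SUMMARY_COLORS.get(state, "#cccccc")
            y = n_rows - 1 - r
            if confidence == "low":
                ax.add_patch(Rectangle((c, y), 1, 1, facecolor="white",
                                       edgecolor="black", linewidth=0.6))
                ax.add_patch(Rectangle((c + 0.15, y + 0.15), 0.7, 0.7,
                                       facecolor=color, edgecolor="none"))
            else:
                ax.add_patch(Rectangle((c, y), 1, 1, facecolor=color,
                                       edgecolor="black", linewidth=0.6))
    ax.set_xlim(0, n_cols)
    ax.set_ylim(0, n_rows)
    ax.set_xticks(np.arange(n_cols) + 0.5)
    ax.set_xticklabels(call_matrix.columns, rotation=90, fontsize=8)
    ax.set_yticks(np.arange(n_rows) + 0.5)
    ax.set_yticklabels(list(reversed(list(call_matrix.index))), fontsize=8)
    fig.tight_layout()
    fig.savefig(img_path, dpi=150)
    plt.close(fig)
    return img_path, tsv_path
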