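"""Seriated adjacency-matrix view.

Samples run down the vertical axis, taxa across the horizontal one; each
positive cell is drawn. Rows and columns are reordered by hierarchical
clustering with optimal leaf ordering so block structure becomes visible,
and a prevalence "barcode" strip beneath the matrix shows in how many
samples each taxon occurs (darker = more).
"""
from __future__ import annotations

import colorsys
from dataclasses import dataclass
from typing import Optional
from xml.etree import ElementTree as ET

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.spatial.distance import squareform

from . import diversity
from .errors import RangeError, ValidationError
from .types import AbundanceTable

__all__ = ["SeriationResult", "seriate", "barcode", "brush", "render_matrix"]

ROW_METRICS = tuple(diversity.BETA_METRICS)
COL_METRICS = ("jaccard_presence", "correlation")
LINKAGES = ("average", "complete", "ward")

#: Distance assigned to pairs where the metric is undefined (a zero
#: vector): the metric's maximum.
_MAX_DIST = {"bray_curtis": 1.0, "jaccard": 1.0, "jensen_shannon": float(np.log(2))}


@dataclass
class SeriationResult:
    """Row/column permutations produced by a seriation method."""

    row_order: list[int]
    col_order: list[int]
    method: str

    def __post_init__(self) -> None:
        for name, order in (("row_order", self.row_order), ("col_order", self.col_order)):
            if sorted(order) != list(range(len(order))):
                raise ValidationError(f"{name} is not a permutation: {order}")

    def to_json_dict(self) -> dict:
        return {
            "rows": list(map(int, self.row_order)),
            "cols": list(map(int, self.col_order)),
            "method": self.method,
        }


def _pairwise(vectors: np.ndarray, metric: str) -> np.ndarray:
    fn = diversity.BETA_METRICS[metric]
    n = len(vectors)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = fn(vectors[i], vectors[j])
            except Exception:
                zi = vectors[i].sum() == 0
                zj = vectors[j].sum() == 0
                d = 0.0 if (zi and zj) else _MAX_DIST[metric]
            out[i, j] = out[j, i] = d
    return out


def _column_distances(counts: np.ndarray, col_metric: str) -> np.ndarray:
    if col_metric == "jaccard_presence":
        presence = (counts > 0).astype(float).T  # taxa x samples
        return _pairwise(presence, "jaccard")
    if col_metric == "correlation":
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(counts.T)
        corr = np.nan_to_num(corr, nan=0.0)
        d = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(d, 0.0)
        return (d + d.T) / 2.0
    raise ValidationError(f"col_metric must be one of {COL_METRICS}")


def _leaf_order(dist: np.ndarray, method: str, refine: bool) -> list[int]:
    n = len(dist)
    if n <= 1:
        return list(range(n))
    if n == 2:
        return [0, 1]
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method=method)
    if refine:
        Z = optimal_leaf_ordering(Z, condensed)
    return [int(i) for i in leaves_list(Z)]


def seriate(table: AbundanceTable, row_metric: str = "bray_curtis",
            col_metric: str = "jaccard_presence", linkage_method: str = "average",
            optimal: bool = True) -> SeriationResult:
    """Hierarchical-clustering seriation of rows and columns.

    Leaf orders are refined by optimal leaf ordering (minimising the sum
    of adjacent-leaf distances) unless ``optimal=False``. Deterministic:
    ties break by index order inside scipy's implementations.
    """
    if row_metric not in ROW_METRICS:
        raise ValidationError(f"row_metric must be one of {ROW_METRICS}")
    if linkage_method not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    counts = table.counts
    row_order = _leaf_order(_pairwise(counts, row_metric), linkage_method, optimal)
    col_order = _leaf_order(
        _column_distances(counts, col_metric), linkage_method, optimal
    )
    method = f"hclust[{linkage_method}]/{row_metric}+{col_metric}" + (
        "+olo" if optimal else ""
    )
    return SeriationResult(row_order=row_order, col_order=col_order, method=method)


def barcode(table: AbundanceTable, col_order: list[int]) -> np.ndarray:
    """Per-ordered-column darkness = prevalence / n_samples, in [0, 1]."""
    if sorted(col_order) != list(range(table.n_taxa)):
        raise ValidationError(f"col_order is not a permutation of 0..{table.n_taxa - 1}")
    prevalence = (table.counts > 0).sum(axis=0)
    return prevalence[np.asarray(col_order, dtype=int)] / table.n_samples


def brush(table: AbundanceTable, result: SeriationResult,
          col_range: tuple[int, int]) -> AbundanceTable:
    """Extract the sub-table of a half-open range of *ordered* columns."""
    start, end = col_range
    if not (0 <= start < end <= table.n_taxa):
        raise RangeError(
            f"column range [{start}, {end}) invalid for {table.n_taxa} taxa"
        )
    chosen = [table.taxon_ids[i] for i in result.col_order[start:end]]
    return AbundanceTable(table.data[chosen].copy())


def _cell_color(weight: float, hue: float = 210.0,
                sat_range: tuple[float, float] = (0.15, 1.0)) -> str:
    s = sat_range[0] + float(weight) * (sat_range[1] - sat_range[0])
    r, g, b = colorsys.hls_to_rgb(hue / 360.0, 0.45, min(s, 1.0))
    return "#{:02x}{:02x}{:02x}".format(round(r * 255), round(g * 255), round(b * 255))


def render_matrix(table: AbundanceTable, result: SeriationResult,
                  encoding: str = "relative_abundance", cell_size: int = 14,
                  label_space: int = 90) -> str:
    """Render the seriated matrix as an SVG document (returned as text).

    ``presence`` fills every positive cell with one fixed color;
    ``relative_abundance`` maps the within-sample relative weight to
    saturation. The prevalence barcode strip is drawn beneath the matrix.
    """
    if encoding not in ("presence", "relative_abundance"):
        raise ValidationError("encoding must be 'presence' or 'relative_abundance'")
    counts = table.counts
    row_totals = counts.sum(axis=1)
    row_totals = np.where(row_totals == 0, 1.0, row_totals)
    n_rows, n_cols = counts.shape
    bar_gap, bar_height = 6, 10
    width = label_space + n_cols * cell_size + 10
    height = n_rows * cell_size + bar_gap + bar_height + label_space + 10

    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=str(width),
        height=str(height),
        viewBox=f"0 0 {width} {height}",
    )
    ox, oy = label_space, 5

    for r, i in enumerate(result.row_order):
        label = ET.SubElement(
            svg, "text",
            {"x": str(ox - 4), "y": str(oy + r * cell_size + cell_size * 0.72),
             "text-anchor": "end", "font-size": "9", "class": "row-label"},
        )
        label.text = table.sample_ids[i]
        for c, j in enumerate(result.col_order):
            value = counts[i, j]
            if value <= 0:
                continue
            fill = (
                "#2b6cb0"
                if encoding == "presence"
                else _cell_color(value / row_totals[i])
            )
            ET.SubElement(
                svg, "rect",
                {"x": str(ox + c * cell_size), "y": str(oy + r * cell_size),
                 "width": str(cell_size - 1), "height": str(cell_size - 1),
                 "fill": fill, "class": "cell"},
            )

    bar_y = oy + n_rows * cell_size + bar_gap
    darkness = barcode(table, result.col_order)
    for c, dark in enumerate(darkness):
        ET.SubElement(
            svg, "rect",
            {"x": str(ox + c * cell_size), "y": str(bar_y),
             "width": str(cell_size - 1), "height": str(bar_height),
             "fill": "#000000", "fill-opacity": f"{dark:.6g}",
             "class": "barcode"},
        )

    for c, j in enumerate(result.col_order):
        x = ox + c * cell_size + cell_size * 0.7
        y = bar_y + bar_height + 4
        label = ET.SubElement(
            svg, "text",
            {"x": str(x), "y": str(y), "font-size": "8",
             "transform": f"rotate(90 {x} {y})", "class": "col-label"},
        )
        label.text = table.taxon_ids[j]

    return ET.tostring(svg, encoding="unicode")
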