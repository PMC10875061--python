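"""Static node-link figures (SVG).

Samples and taxa are circles (samples larger), edges straight lines drawn
beneath the nodes. Any :class:`~mbgraph.color.ColorAssignment` can drive
fills and opacities; small multiples reuse one common layout across all
panels so positions can be compared between them.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional
from xml.etree import ElementTree as ET

import numpy as np

from . import color as color_mod
from .errors import CoverageError, ValidationError
from .graph import SAMPLE, CompositionGraph
from .types import RANKS, UNASSIGNED

__all__ = ["FigureSpec", "render_nodelink", "render_small_multiples"]


@dataclass
class FigureSpec:
    """Figure geometry and styling knobs (pixels)."""

    width: float = 640.0
    height: float = 640.0
    node_radius_sample: float = 8.0
    node_radius_taxon: float = 3.5
    edge_opacity: float = 0.3
    edge_color: str = "#777777"
    margin: float = 20.0
    legend: bool = True

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("figure dimensions must be positive")
        if self.node_radius_sample <= 0 or self.node_radius_taxon <= 0:
            raise ValidationError("node radii must be positive")


def _fit_transform(positions: Mapping[str, tuple[float, float]],
                   width: float, height: float, margin: float):
    """Affine map from layout coordinates into the viewport."""
    pts = np.array(list(positions.values()), dtype=float)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.where(hi - lo < 1e-9, 1.0, hi - lo)
    scale = min((width - 2 * margin) / span[0], (height - 2 * margin) / span[1])
    mid = (lo + hi) / 2.0

    def tf(p):
        x = (p[0] - mid[0]) * scale + width / 2.0
        y = (p[1] - mid[1]) * scale + height / 2.0
        return float(x), float(y)

    return tf


def _check_coverage(graph: CompositionGraph, positions, colors) -> None:
    nodes = set(graph.node_ids)
    missing_pos = sorted(nodes - set(positions))
    if missing_pos:
        raise CoverageError(f"nodes without positions: {missing_pos}")
    missing_col = sorted(nodes - set(colors.colors))
    if missing_col:
        raise CoverageError(f"nodes without colors: {missing_col}")


def _draw_panel(parent: ET.Element, graph: CompositionGraph,
                positions: Mapping[str, tuple[float, float]], tf,
                colors: color_mod.ColorAssignment, spec: FigureSpec) -> None:
    """Edges first (beneath), then node circles."""
    edges_g = ET.SubElement(parent, "g", {"class": "edges"})
    for u, v, _ in graph.edges():
        x1, y1 = tf(positions[u])
        x2, y2 = tf(positions[v])
        op = min(
            spec.edge_opacity,
            colors.opacity.get(u, 1.0),
            colors.opacity.get(v, 1.0),
        )
        ET.SubElement(
            edges_g, "line",
            {"x1": f"{x1:.2f}", "y1": f"{y1:.2f}", "x2": f"{x2:.2f}",
             "y2": f"{y2:.2f}", "stroke": spec.edge_color,
             "stroke-opacity": f"{op:.4g}"},
        )
    nodes_g = ET.SubElement(parent, "g", {"class": "nodes"})
    for node in graph.node_ids:
        x, y = tf(positions[node])
        r = (
            spec.node_radius_sample
            if graph.node_class(node) == SAMPLE
            else spec.node_radius_taxon
        )
        ET.SubElement(
            nodes_g, "circle",
            {"cx": f"{x:.2f}", "cy": f"{y:.2f}", "r": str(r),
             "fill": colors.colors[node],
             "fill-opacity": f"{colors.opacity.get(node, 1.0):.4g}",
             "class": f"node {graph.node_class(node)}",
             "data-id": node},
        )


def _legend_group(svg: ET.Element, legend: dict, x: float, y: float) -> None:
    g = ET.SubElement(svg, "g", {"class": "legend"})
    title = ET.SubElement(g, "text", {"x": str(x), "y": str(y), "font-size": "10"})
    kind = legend.get("type", "scale")
    title.text = f"scale: {kind}"
    entries = []
    if kind == "categorical":
        entries = list(legend["categories"].items())
    elif kind == "binned":
        entries = [
            (f"{a}-{b}" if a != b else str(a), c)
            for (a, b), c in zip(legend["bins"], legend["ramp"])
        ]
    elif kind in ("saturation", "sequential"):
        lo, hi = legend["domain"]
        entries = [(f"min={lo:.4g}", None), (f"max={hi:.4g}", None)]
    for i, (label, swatch) in enumerate(entries):
        yy = y + 12 + i * 12
        if swatch:
            ET.SubElement(
                g, "rect",
                {"x": str(x), "y": str(yy - 8), "width": "9", "height": "9",
                 "fill": swatch, "class": "legend-swatch"},
            )
        t = ET.SubElement(
            g, "text", {"x": str(x + 13), "y": str(yy), "font-size": "9"}
        )
        t.text = str(label)


def render_nodelink(graph: CompositionGraph,
                    positions: Mapping[str, tuple[float, float]],
                    colors: color_mod.ColorAssignment,
                    spec: Optional[FigureSpec] = None) -> str:
    """Render the composition graph as a node-link SVG document."""
    spec = spec or FigureSpec()
    _check_coverage(graph, positions, colors)
    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=str(spec.width),
        height=str(spec.height),
        viewBox=f"0 0 {spec.width} {spec.height}",
    )
    tf = _fit_transform(positions, spec.width, spec.height, spec.margin)
    _draw_panel(svg, graph, positions, tf, colors, spec)
    if spec.legend and colors.legend:
        _legend_group(svg, colors.legend, 8.0, 14.0)
    return ET.tostring(svg, encoding="unicode")


def render_small_multiples(graph: CompositionGraph,
                           positions: Mapping[str, tuple[float, float]],
                           rank: str,
                           spec: Optional[FigureSpec] = None,
                           max_panels: int = 12) -> str:
    """One panel per taxonomy value at ``rank``, all sharing one layout.

    Values beyond ``max_panels`` are merged into an "other" panel. Within
    each panel the matching taxa are highlighted red and unrelated nodes
    faded; node coordinates are identical across panels.
    """
    spec = spec or FigureSpec(width=280.0, height=280.0,
                              node_radius_sample=4.0, node_radius_taxon=2.0)
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    values: dict[str, set[str]] = {}
    for t in graph.taxa:
        v = graph.attributes(t).get(rank, UNASSIGNED)
        if v != UNASSIGNED:
            values.setdefault(str(v), set()).add(t)
    if not values:
        raise ValidationError(f"no taxa carry an assigned {rank!r} value")

    ordered = sorted(values.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    panels: list[tuple[str, set[str]]] = ordered[:max_panels]
    if len(ordered) > max_panels:
        other = set().union(*(taxa for _, taxa in ordered[max_panels:]))
        panels.append(("other", other))

    n = len(panels)
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    pw, ph = spec.width, spec.height + 16  # room for the title
    total_w = ncols * pw
    total_h = nrows * ph
    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=str(total_w),
        height=str(total_h),
        viewBox=f"0 0 {total_w} {total_h}",
    )
    tf = _fit_transform(positions, spec.width, spec.height, spec.margin)

    for idx, (value, taxa) in enumerate(panels):
        row, col = divmod(idx, ncols)
        panel = ET.SubElement(
            svg, "g",
            {"class": "panel", "data-value": value,
             "transform": f"translate({col * pw},{row * ph + 16})"},
        )
        title = ET.SubElement(
            panel, "text",
            {"x": str(pw / 2), "y": "-4", "text-anchor": "middle",
             "font-size": "11", "class": "panel-title"},
        )
        title.text = value
        assignment = color_mod.membership_highlight(graph, taxa)
        _draw_panel(panel, graph, positions, tf, assignment, spec)
    return ET.tostring(svg, encoding="unicode")
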