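"""Color encodings for node attributes.

The catalogue follows the usual channel advice for networks: hue for
nominal attributes (categorical scale, at most 12 classes), saturation at
a fixed hue for numeric attributes (alpha diversity), a binned multi-hue
ramp for small integer domains (prevalence), and a sequential multi-hue
ramp for skewed fractions (total relative abundance).

Beta-diversity matrices are encoded by embedding the samples in three
dimensions with classical (Torgerson) multidimensional scaling and
mapping the axes into CIELAB — the perceptually uniform space in which
Euclidean distance (Delta E) approximates perceived color difference — so
similarly composed samples receive similar colors.
"""
from __future__ import annotations

import colorsys
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .errors import (
    CardinalityError,
    DegenerateInputError,
    UnknownIdentifierError,
    ValidationError,
)
from .graph import SAMPLE, TAXON, CompositionGraph
from .types import RANKS, UNASSIGNED, DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ColorAssignment",
    "HighlightState",
    "categorical_scale",
    "saturation_scale",
    "binned_multihue_scale",
    "sequential_scale",
    "classical_mds",
    "distance_to_colors",
    "highlight",
    "taxonomy_highlight",
    "lab_to_hex",
    "hex_to_lab",
]

#: Default fade opacity for de-emphasised nodes.
FADE_OPACITY = 0.15
#: Default highlight red used by the taxonomy small-multiple views.
HIGHLIGHT_RED = "#e41a1c"
#: Neutral color for nodes with no encoded value.
NEUTRAL = "#999999"

MAX_CATEGORIES = 12


@dataclass
class ColorAssignment:
    """Node -> (sRGB hex, opacity) map plus an optional legend payload."""

    colors: dict[str, str]
    opacity: dict[str, float]
    legend: Optional[dict] = None

    def __post_init__(self) -> None:
        for node, value in self.colors.items():
            if not (
                isinstance(value, str)
                and len(value) == 7
                and value[0] == "#"
                and all(c in "0123456789abcdefABCDEF" for c in value[1:])
            ):
                raise ValidationError(f"invalid hex color {value!r} for {node!r}")
        for node, value in self.opacity.items():
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"opacity {value} out of [0,1] for {node!r}")

    def to_json_dict(self) -> dict:
        return {
            node: {"color": self.colors[node], "opacity": self.opacity.get(node, 1.0)}
            for node in self.colors
        }


@dataclass
class HighlightState:
    """Hover state for a focal node: neighbors colored by their linking
    edge's relative weight, everything else faded."""

    focal_id: str
    neighbor_colors: dict[str, str]
    faded_ids: set[str]


def _hls_hex(h: float, lightness: float, s: float) -> str:
    r, g, b = colorsys.hls_to_rgb(h % 1.0, lightness, s)
    return "#{:02x}{:02x}{:02x}".format(
        round(r * 255), round(g * 255), round(b * 255)
    )


def categorical_scale(values: Mapping[str, str]) -> ColorAssignment:
    """Distinct, maximally separated hues for up to 12 categories.

    The category -> hue map depends only on the sorted category set, so it
    is stable under input reordering.
    """
    categories = sorted({str(v) for v in values.values()})
    if len(categories) > MAX_CATEGORIES:
        raise CardinalityError(
            f"{len(categories)} categories exceed the readable limit of "
            f"{MAX_CATEGORIES}; consider small multiples instead"
        )
    n = len(categories)
    palette = {c: _hls_hex(i / max(n, 1), 0.45, 0.65) for i, c in enumerate(categories)}
    return ColorAssignment(
        colors={node: palette[str(v)] for node, v in values.items()},
        opacity={node: 1.0 for node in values},
        legend={"type": "categorical", "categories": palette},
    )


def saturation_scale(values: Mapping[str, float], hue: float = 210.0,
                     sat_range: tuple[float, float] = (0.12, 1.0)) -> ColorAssignment:
    """Single-hue scale: value mapped linearly to saturation.

    Min-max normalised, so any affine transform of the values yields the
    identical assignment. Constant values collapse to mid saturation with
    a logged warning.
    """
    vals = {node: float(v) for node, v in values.items()}
    if not vals:
        raise DegenerateInputError("no values to encode")
    if not all(np.isfinite(v) for v in vals.values()):
        raise ValidationError("values must be finite")
    lo = min(vals.values())
    hi = max(vals.values())
    s0, s1 = sat_range
    if hi == lo:
        logger.warning("constant values; assigning mid saturation to all nodes")
        sats = {node: (s0 + s1) / 2.0 for node in vals}
    else:
        sats = {
            node: s0 + (v - lo) / (hi - lo) * (s1 - s0) for node, v in vals.items()
        }
    h = (hue % 360.0) / 360.0
    return ColorAssignment(
        colors={node: _hls_hex(h, 0.5, s) for node, s in sats.items()},
        opacity={node: 1.0 for node in vals},
        legend={"type": "saturation", "hue": hue, "domain": [lo, hi]},
    )


def _ramp_colors(n: int, cmap_name: str = "viridis") -> list[str]:
    import matplotlib

    cmap = matplotlib.colormaps[cmap_name]
    pts = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    return [
        "#{:02x}{:02x}{:02x}".format(*(np.array(cmap(p))[:3] * 255).round().astype(int))
        for p in pts
    ]


def binned_multihue_scale(values: Mapping[str, int], n_bins: int = 5,
                          cmap_name: str = "viridis") -> ColorAssignment:
    """Equal-width integer bins over [min, max], one ramp step per bin.

    Intended for small integer domains such as prevalence. When the domain
    holds fewer distinct integers than ``n_bins``, the bins collapse to
    the distinct values. Bin edges are reported in the legend.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be at least 2")
    vals = {node: int(v) for node, v in values.items()}
    if not vals:
        raise DegenerateInputError("no values to encode")
    lo = min(vals.values())
    hi = max(vals.values())
    domain = hi - lo + 1
    if domain <= n_bins:
        edges = [(v, v) for v in range(lo, hi + 1)]
    else:
        width = int(np.ceil(domain / n_bins))
        edges = []
        start = lo
        while start <= hi:
            edges.append((start, min(start + width - 1, hi)))
            start += width
    ramp = _ramp_colors(len(edges), cmap_name)

    def bin_of(v: int) -> int:
        for i, (a, b) in enumerate(edges):
            if a <= v <= b:
                return i
        raise AssertionError("unreachable")

    return ColorAssignment(
        colors={node: ramp[bin_of(v)] for node, v in vals.items()},
        opacity={node: 1.0 for node in vals},
        legend={"type": "binned", "bins": edges, "ramp": ramp},
    )


def sequential_scale(values: Mapping[str, float],
                     cmap_name: str = "viridis") -> ColorAssignment:
    """Continuous sequential multi-hue ramp (min-max normalised)."""
    vals = {node: float(v) for node, v in values.items()}
    if not vals:
        raise DegenerateInputError("no values to encode")
    lo = min(vals.values())
    hi = max(vals.values())
    span = hi - lo
    import matplotlib

    cmap = matplotlib.colormaps[cmap_name]

    def hexof(v: float) -> str:
        t = 0.5 if span == 0 else (v - lo) / span
        return "#{:02x}{:02x}{:02x}".format(
            *(np.array(cmap(t))[:3] * 255).round().astype(int)
        )

    return ColorAssignment(
        colors={node: hexof(v) for node, v in vals.items()},
        opacity={node: 1.0 for node in vals},
        legend={"type": "sequential", "domain": [lo, hi]},
    )


# ---------------------------------------------------------------------------
# Classical MDS and the CIELAB mapping
# ---------------------------------------------------------------------------

def classical_mds(D: DistanceMatrix, k: int = 3) -> dict[str, np.ndarray]:
    """Torgerson scaling: embed a distance matrix in k dimensions.

    Double-centers -D^2/2, eigendecomposes, and keeps the top-k
    non-negative eigenpairs scaled by sqrt(eigenvalue); negative
    eigenvalues (non-Euclidean excess) contribute zero. The sign of each
    axis is fixed so its largest-magnitude loading is positive.
    """
    n = D.n
    if n < 2:
        raise DegenerateInputError("need at least 2 points")
    if k > n - 1:
        raise ValidationError(f"k={k} must be <= n-1={n - 1}")
    d2 = D.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:k]
    coords = np.zeros((n, k))
    for axis, idx in enumerate(order):
        lam = eigval[idx]
        if lam <= 0:
            continue  # negative/zero eigenvalue: no contribution
        v = eigvec[:, idx]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, axis] = np.sqrt(lam) * v
    return {label: coords[i] for i, label in enumerate(D.labels)}


def lab_to_rgb(lab: np.ndarray) -> tuple[np.ndarray, bool]:
    """CIELAB (D65, 2 degrees) -> sRGB in [0,1]; returns (rgb, was_clamped).

    Goes through XYZ with an explicit linear-RGB stage so that
    out-of-gamut colors are *detected* (skimage's lab2rgb clips silently)
    and then clamped.
    """
    from skimage import color as skcolor
    from skimage.color.colorconv import xyz_from_rgb

    xyz = skcolor.lab2xyz(np.asarray(lab, dtype=float).reshape(1, 1, 3))[0, 0]
    linear = np.linalg.inv(xyz_from_rgb) @ xyz
    clamped = bool((linear < -1e-7).any() or (linear > 1 + 1e-7).any())
    linear = np.clip(linear, 0.0, 1.0)
    srgb = np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(linear, 1 / 2.4) - 0.055,
    )
    return np.clip(srgb, 0.0, 1.0), clamped


def lab_to_hex(lab: np.ndarray) -> tuple[str, bool]:
    """CIELAB (D65, 2 degrees) -> sRGB hex; returns (hex, was_clamped)."""
    rgb, clamped = lab_to_rgb(lab)
    return (
        "#{:02x}{:02x}{:02x}".format(*(rgb * 255).round().astype(int)),
        clamped,
    )


def hex_to_lab(hex_color: str) -> np.ndarray:
    from skimage import color as skcolor

    rgb = np.array(
        [int(hex_color[i : i + 2], 16) / 255.0 for i in (1, 3, 5)]
    ).reshape(1, 1, 3)
    return skcolor.rgb2lab(rgb)[0, 0]


#: Affine target ranges of the MDS axes in CIELAB.
_L_RANGE = (30.0, 85.0)
_AB_RANGE = (-60.0, 60.0)


def distance_to_colors(D: DistanceMatrix) -> ColorAssignment:
    """Map a beta-diversity matrix to per-sample colors via MDS -> CIELAB.

    The first (largest-eigenvalue) axis drives L* in [30, 85]; the second
    and third drive a* and b* in [-60, 60] (per-axis min-max). Samples at
    zero distance receive identical hex strings; a fully degenerate matrix
    (all pairs equal 0 spread) collapses to mid-grey.
    """
    embedding = classical_mds(D, k=min(3, D.n - 1))
    labels = D.labels
    coords = np.zeros((D.n, 3))
    raw = np.array([embedding[lab] for lab in labels])
    coords[:, : raw.shape[1]] = raw

    lab = np.zeros((D.n, 3))
    ranges = [_L_RANGE, _AB_RANGE, _AB_RANGE]
    spreads = coords.max(axis=0) - coords.min(axis=0)
    # an axis whose spread is negligible next to the dominant one carries
    # only eigendecomposition noise; collapse it to the channel midpoint
    floor = max(spreads.max(), 1e-30) * 1e-6
    for axis in range(3):
        lo = coords[:, axis].min()
        hi = coords[:, axis].max()
        a, b = ranges[axis]
        if hi - lo <= floor:
            lab[:, axis] = (a + b) / 2.0
        else:
            lab[:, axis] = a + (coords[:, axis] - lo) / (hi - lo) * (b - a)

    colors = {}
    n_clamped = 0
    for i, label in enumerate(labels):
        hex_color, was_clamped = lab_to_hex(lab[i])
        n_clamped += was_clamped
        colors[label] = hex_color
    if n_clamped:
        logger.warning("%d of %d colors fell out of the sRGB gamut and were "
                       "clamped", n_clamped, len(labels))
    # identical embedding coordinates must yield identical hex strings
    return ColorAssignment(
        colors=colors,
        opacity={label: 1.0 for label in labels},
        legend={"type": "mds_cielab", "L_range": list(_L_RANGE),
                "ab_range": list(_AB_RANGE)},
    )


# ---------------------------------------------------------------------------
# Highlight states
# ---------------------------------------------------------------------------

def highlight(graph: CompositionGraph, focal_id: str,
              hue: float = 210.0) -> HighlightState:
    """Hover highlight: color the focal node's neighbors by the relative
    weight of their connecting edge; fade everything else.

    Works symmetrically for sample and taxon focal nodes.
    """
    graph._require(focal_id)
    neighbors = graph.neighbors(focal_id)
    weights = {
        nb: graph.edge_weight_relative(focal_id, nb) for nb in neighbors
    }
    if weights:
        assignment = saturation_scale(weights, hue=hue)
        neighbor_colors = assignment.colors
    else:
        neighbor_colors = {}
    faded = set(graph.node_ids) - set(neighbors) - {focal_id}
    return HighlightState(
        focal_id=focal_id,
        neighbor_colors=neighbor_colors,
        faded_ids=faded,
    )


def membership_highlight(graph: CompositionGraph, matching_taxa: set[str],
                         legend: Optional[dict] = None) -> ColorAssignment:
    """Red highlight for a set of taxa; samples linked to at least one of
    them stay at full opacity; every other node is faded."""
    matching = set(matching_taxa)
    linked_samples = {u for u, v, _ in graph.edges() if v in matching}
    colors = {}
    opacity = {}
    for node in graph.node_ids:
        if node in matching:
            colors[node] = HIGHLIGHT_RED
            opacity[node] = 1.0
        elif node in linked_samples:
            colors[node] = NEUTRAL
            opacity[node] = 1.0
        else:
            colors[node] = NEUTRAL
            opacity[node] = FADE_OPACITY
    return ColorAssignment(colors=colors, opacity=opacity, legend=legend)


def taxonomy_highlight(graph: CompositionGraph, rank: str,
                       value: str) -> ColorAssignment:
    """Color taxa of one taxonomic group red; keep the samples containing
    them at full opacity; fade all other nodes.

    The unassigned-rank sentinel never matches a query value.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    matching = {
        t
        for t in graph.taxa
        if graph.attributes(t).get(rank, UNASSIGNED) == value
        and value != UNASSIGNED
    }
    if not matching:
        logger.warning("no taxa with %s == %r; returning an all-faded "
                       "assignment", rank, value)
    return membership_highlight(
        graph,
        matching,
        legend={"type": "taxonomy_highlight", "rank": rank, "value": value},
    )
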