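"""Force-directed layout with radial-bipartite and group-separation forces.

The simulation follows the familiar cooled, velocity-damped contract of
web force engines: a scalar temperature ``alpha`` decays geometrically
each tick; every force adds velocity increments scaled by the current
alpha; velocities are then damped and integrated into positions.

Forces:

* many-body repulsion between all node pairs (magnitude
  ``|repulsion_strength| / d`` along the separating direction, with a
  minimum-distance clamp);
* spring attraction along each sample->taxon edge toward ``link_distance``;
* centering — a rigid translation keeping the mean position at the
  configured center;
* the radial-bipartite force: samples are pulled onto a circle of radius
  ``sample_radius`` while each taxon is pulled to a radius that shrinks
  linearly with its prevalence — taxa seen in every sample sit at the
  center (the core microbiome), taxa seen in one sample at
  ``taxa_radius_max``;
* optional group-separation forces pulling each sample toward its group's
  target x (or x, y) coordinate, so cohorts (e.g. disease vs. healthy)
  occupy distinct screen regions.

The whole trajectory is deterministic given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .graph import SAMPLE, TAXON, CompositionGraph

__all__ = [
    "LayoutConfig",
    "LayoutState",
    "init_layout",
    "radial_target_radius",
    "step",
    "run_layout",
    "default_group_targets",
]

#: Default cooling chosen so alpha reaches alpha_min in ~300 ticks.
_DEFAULT_DECAY = 1.0 - 0.001 ** (1.0 / 300.0)


@dataclass
class LayoutConfig:
    """Tunable parameters of the force simulation (lengths in px)."""

    seed: int = 0
    max_ticks: int = 300
    alpha_initial: float = 1.0
    alpha_min: float = 0.001
    alpha_decay_rate: float = _DEFAULT_DECAY
    velocity_decay: float = 0.4
    repulsion_strength: float = -30.0
    min_repulsion_distance: float = 1.0
    link_distance: float = 30.0
    link_strength: float = 0.1
    center: tuple[float, float] = (0.0, 0.0)
    centering: bool = True
    radial_strength: float = 0.8
    sample_radius: float = 250.0
    taxa_radius_max: float = 200.0
    group_targets: Optional[dict] = None
    group_strength: float = 0.25
    #: "linear" maps prevalence k to r_max*(n-k)/(n-1); "rank" spaces the
    #: distinct prevalence values evenly instead
    radial_mapping: str = "linear"
    #: scale each link's spring strength by its weight_relative
    weight_scaled_links: bool = False
    #: above this node count repulsion switches to a Barnes-Hut quadtree
    exact_repulsion_limit: int = 2000
    #: Barnes-Hut opening angle (smaller = more accurate)
    approximation_theta: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_decay_rate < 1.0):
            raise ValidationError("alpha_decay_rate must lie in (0, 1)")
        if not (0.0 <= self.velocity_decay < 1.0):
            raise ValidationError("velocity_decay must lie in [0, 1)")
        if self.sample_radius <= 0:
            raise ValidationError("sample_radius must be positive")
        if self.taxa_radius_max > self.sample_radius:
            raise ValidationError("taxa_radius_max cannot exceed sample_radius")
        if self.radial_mapping not in ("linear", "rank"):
            raise ValidationError("radial_mapping must be 'linear' or 'rank'")

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["center"] = list(self.center)
        return doc


@dataclass
class LayoutState:
    """Positions/velocities of every node plus the cooling parameter."""

    positions: dict[str, tuple[float, float]]
    velocities: dict[str, tuple[float, float]]
    alpha: float
    tick_count: int = 0


def init_layout(graph: CompositionGraph, config: LayoutConfig) -> LayoutState:
    """Seeded initial state: positions uniform over the sample disk,
    zero velocities, alpha at its initial value."""
    ids = graph.node_ids
    if not ids:
        raise DegenerateInputError("cannot lay out an empty graph")
    rng = np.random.default_rng(config.seed)
    n = len(ids)
    r = config.sample_radius * np.sqrt(rng.random(n))
    theta = 2.0 * np.pi * rng.random(n)
    cx, cy = config.center
    xs = cx + r * np.cos(theta)
    ys = cy + r * np.sin(theta)
    return LayoutState(
        positions={i: (float(x), float(y)) for i, x, y in zip(ids, xs, ys)},
        velocities={i: (0.0, 0.0) for i in ids},
        alpha=config.alpha_initial,
    )


def radial_target_radius(node_class: str, prevalence: Optional[int],
                         n_samples: int, config: LayoutConfig) -> float:
    """Target radius of the radial-bipartite force.

    Samples sit on the periphery at ``sample_radius``. A taxon observed in
    ``k`` of ``n`` samples is pulled to
    ``taxa_radius_max * (n - k) / (n - 1)`` — linear in prevalence, so the
    core microbiome (k = n) collapses to the center and singleton taxa
    (k = 1) sit at ``taxa_radius_max``.
    """
    if node_class == SAMPLE:
        return config.sample_radius
    if prevalence is None:
        raise ValidationError("taxon node lacks a prevalence attribute")
    k = int(prevalence)
    if not (1 <= k <= n_samples):
        raise ValidationError(
            f"prevalence {k} outside [1, {n_samples}]"
        )
    if n_samples == 1:
        return 0.0
    return config.taxa_radius_max * (n_samples - k) / (n_samples - 1)


def default_group_targets(groups: Sequence[str], config: LayoutConfig) -> dict:
    """Default spatial targets for group-separation forces.

    Two groups: x = -+0.75 * sample_radius (left/right). Three or more:
    vertices of a regular polygon of that radius (2-D targets).
    """
    groups = sorted(set(groups))
    r = 0.75 * config.sample_radius
    cx, cy = config.center
    if len(groups) <= 2:
        xs = [-r, r][: len(groups)]
        return {g: (cx + x,) for g, x in zip(groups, xs)}
    angles = [2.0 * np.pi * i / len(groups) - np.pi / 2 for i in range(len(groups))]
    return {
        g: (cx + r * np.cos(a), cy + r * np.sin(a))
        for g, a in zip(groups, angles)
    }


class _Arrays:
    """Vectorised view of a state: id order, positions, velocities, and
    per-node force metadata resolved once per graph."""

    def __init__(self, graph: CompositionGraph, state: LayoutState,
                 config: LayoutConfig):
        self.ids = graph.node_ids
        if set(self.ids) != set(state.positions):
            raise ValidationError("state positions do not cover the graph nodes")
        index = {i: k for k, i in enumerate(self.ids)}
        self.pos = np.array([state.positions[i] for i in self.ids], dtype=float)
        self.vel = np.array([state.velocities[i] for i in self.ids], dtype=float)
        n_samples = len(graph.samples)
        rank_radius = None
        if config.radial_mapping == "rank":
            distinct = sorted(
                {graph.attributes(t)["prevalence"] for t in graph.taxa},
                reverse=True,
            )
            denom = max(len(distinct) - 1, 1)
            rank_radius = {
                p: config.taxa_radius_max * pos / denom
                for pos, p in enumerate(distinct)
            }
        self.radial_target = np.empty(len(self.ids))
        for k, i in enumerate(self.ids):
            attrs = graph.attributes(i)
            if attrs["node_class"] == SAMPLE:
                self.radial_target[k] = config.sample_radius
            elif rank_radius is not None:
                self.radial_target[k] = rank_radius[attrs["prevalence"]]
            else:
                self.radial_target[k] = radial_target_radius(
                    attrs["node_class"], attrs.get("prevalence"), n_samples,
                    config,
                )
        self.edges = np.array(
            [(index[u], index[v]) for u, v, _ in graph.edges()], dtype=int
        ).reshape(-1, 2)
        self.edge_weight = np.array(
            [d.get("weight_relative", 1.0) for _, _, d in graph.edges()],
            dtype=float,
        )
        # group force rows: (node index, target x[, target y])
        self.group_idx: list[int] = []
        self.group_xy: list[tuple] = []
        if config.group_targets:
            for i in graph.samples:
                g = graph.attributes(i).get("group")
                if g is not None and g in config.group_targets:
                    self.group_idx.append(index[i])
                    self.group_xy.append(tuple(config.group_targets[g]))


def step(graph: CompositionGraph, state: LayoutState,
         config: LayoutConfig) -> LayoutState:
    """Advance the simulation by one tick and return the new state."""
    arr = _Arrays(graph, state, config)
    alpha = state.alpha + (0.0 - state.alpha) * config.alpha_decay_rate
    pos, vel = arr.pos, arr.vel
    n = len(arr.ids)

    # --- many-body repulsion -------------------------------------------
    if config.repulsion_strength != 0.0 and n > 1:
        if n <= config.exact_repulsion_limit:
            vel += _repulsion_exact(pos, config, alpha, state.tick_count)
        else:
            vel += _repulsion_barnes_hut(pos, config, alpha, state.tick_count)

    # --- link attraction -----------------------------------------------
    if config.link_strength != 0.0 and len(arr.edges):
        src = arr.edges[:, 0]
        tgt = arr.edges[:, 1]
        delta = (pos[tgt] + vel[tgt]) - (pos[src] + vel[src])
        dist = np.linalg.norm(delta, axis=1)
        dist = np.where(dist < 1e-9, 1e-9, dist)
        coeff = (dist - config.link_distance) / dist * alpha * config.link_strength
        if config.weight_scaled_links:
            coeff = coeff * arr.edge_weight
        push = delta * coeff[:, None] * 0.5
        np.add.at(vel, src, push)
        np.subtract.at(vel, tgt, push)

    # --- radial bipartite force ----------------------------------------
    if config.radial_strength != 0.0:
        center = np.asarray(config.center, dtype=float)
        delta = pos - center
        r = np.linalg.norm(delta, axis=1)
        r = np.where(r < 1e-9, 1e-9, r)
        k = (arr.radial_target - r) * config.radial_strength * alpha
        vel += delta / r[:, None] * k[:, None]

    # --- group separation ----------------------------------------------
    if config.group_strength != 0.0 and arr.group_idx:
        for k, target in zip(arr.group_idx, arr.group_xy):
            vel[k, 0] += (target[0] - pos[k, 0]) * config.group_strength * alpha
            if len(target) > 1:
                vel[k, 1] += (target[1] - pos[k, 1]) * config.group_strength * alpha

    # --- centering: rigid translation ----------------------------------
    if config.centering:
        pos = pos + (np.asarray(config.center, dtype=float) - pos.mean(axis=0))

    vel *= 1.0 - config.velocity_decay
    pos = pos + vel

    return LayoutState(
        positions={i: (float(x), float(y)) for i, (x, y) in zip(arr.ids, pos)},
        velocities={i: (float(x), float(y)) for i, (x, y) in zip(arr.ids, vel)},
        alpha=alpha,
        tick_count=state.tick_count + 1,
    )


def _jitter(shape, seed) -> np.ndarray:
    """Deterministic sub-pixel offsets used to split coincident pairs."""
    rng = np.random.default_rng(seed)
    return (rng.random(shape) - 0.5) * 1e-6


def _repulsion_exact(pos, config, alpha, tick) -> np.ndarray:
    delta = pos[:, None, :] - pos[None, :, :]  # (n, n, 2), i minus j
    dist = np.linalg.norm(delta, axis=2)
    coincident = (dist < 1e-12) & ~np.eye(len(pos), dtype=bool)
    if coincident.any():
        jit = _jitter(pos.shape, config.seed * 1_000_003 + tick)
        delta = (pos + jit)[:, None, :] - (pos + jit)[None, :, :]
        dist = np.linalg.norm(delta, axis=2)
    np.fill_diagonal(dist, np.inf)
    dist = np.maximum(dist, config.min_repulsion_distance)
    w = (-config.repulsion_strength) * alpha / (dist * dist)
    return (delta * w[:, :, None]).sum(axis=1)


class _QuadNode:
    __slots__ = ("cx", "cy", "half", "mass", "mx", "my", "children", "point")

    def __init__(self, cx, cy, half):
        self.cx, self.cy, self.half = cx, cy, half
        self.mass = 0
        self.mx = 0.0
        self.my = 0.0
        self.children = None  # list of 4 or None
        self.point = None

    def _child_for(self, x, y):
        half = self.half / 2.0
        qi = (1 if x >= self.cx else 0) + (2 if y >= self.cy else 0)
        if self.children[qi] is None:
            ox = self.cx + (half if x >= self.cx else -half)
            oy = self.cy + (half if y >= self.cy else -half)
            self.children[qi] = _QuadNode(ox, oy, half)
        return self.children[qi]

    def insert(self, x, y, depth=0):
        self.mx = (self.mx * self.mass + x) / (self.mass + 1)
        self.my = (self.my * self.mass + y) / (self.mass + 1)
        self.mass += 1
        if self.children is None:
            if self.point is None:
                self.point = (x, y)
                return
            if depth > 48:  # identical points; keep as aggregate leaf
                return
            px, py = self.point
            self.point = None
            self.children = [None, None, None, None]
            child = self._child_for(px, py)
            child.insert(px, py, depth + 1)
        self._child_for(x, y).insert(x, y, depth + 1)


def _repulsion_barnes_hut(pos, config, alpha, tick) -> np.ndarray:
    """Approximate many-body repulsion via a Barnes-Hut quadtree.

    Cells whose width/distance ratio is below ``approximation_theta`` are
    treated as a single body at their center of mass.
    """
    jit = _jitter(pos.shape, config.seed * 1_000_003 + tick)
    pts = pos + jit
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    cx, cy = (lo + hi) / 2.0
    half = float(max(hi[0] - lo[0], hi[1] - lo[1]) / 2.0 + 1e-9)
    root = _QuadNode(float(cx), float(cy), half)
    for x, y in pts:
        root.insert(float(x), float(y))

    strength = -config.repulsion_strength
    theta2 = config.approximation_theta ** 2
    dmin2 = config.min_repulsion_distance ** 2
    out = np.zeros_like(pos)
    for k, (x, y) in enumerate(pts):
        fx = fy = 0.0
        stack = [root]
        while stack:
            node = stack.pop()
            if node is None or node.mass == 0:
                continue
            dx = x - node.mx
            dy = y - node.my
            d2 = dx * dx + dy * dy
            width = node.half * 2.0
            if node.children is not None and width * width >= theta2 * d2:
                stack.extend(node.children)
                continue
            if d2 < 1e-18:
                continue  # self-interaction (or a coincident aggregate)
            mass = node.mass
            if node.children is None and node.point is not None:
                px, py = node.point
                if abs(px - x) < 1e-12 and abs(py - y) < 1e-12:
                    mass -= 1  # leaf containing the query point itself
            if mass <= 0:
                continue
            w = strength * alpha * mass / max(d2, dmin2)
            fx += dx * w
            fy += dy * w
        out[k, 0] = fx
        out[k, 1] = fy
    return out


def run_layout(graph: CompositionGraph,
               config: Optional[LayoutConfig] = None) -> dict[str, tuple[float, float]]:
    """Iterate :func:`step` until alpha drops below ``alpha_min`` or
    ``max_ticks`` is reached; returns the final positions."""
    if config is None:
        config = LayoutConfig()
    state = init_layout(graph, config)
    while state.tick_count < config.max_ticks and state.alpha >= config.alpha_min:
        state = step(graph, state, config)
    return state.positions
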