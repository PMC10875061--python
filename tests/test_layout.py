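"""Force-simulation behaviour: determinism, radial ordering, groups."""
import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import mbgraph as mg
from mbgraph.errors import DegenerateInputError, ValidationError
from mbgraph.graph import CompositionGraph
from mbgraph.layout import (
    LayoutConfig,
    LayoutState,
    default_group_targets,
    init_layout,
    radial_target_radius,
    run_layout,
    step,
    _repulsion_barnes_hut,
    _repulsion_exact,
)


def single_node_graph():
    g = nx.DiGraph()
    g.add_node("s1", node_class="sample")
    return CompositionGraph(g)


@pytest.fixture
def ladder_graph():
    """10 samples; 10 taxa with prevalence exactly 1..10."""
    n = 10
    rows = {
        f"s{i}": {f"t{k}": (1 if i < k else 0) for k in range(1, n + 1)}
        for i in range(n)
    }
    table = mg.AbundanceTable(
        pd.DataFrame(rows).T[[f"t{k}" for k in range(1, n + 1)]]
    )
    return table, mg.build_graph(table)


def test_init_layout_deterministic_and_in_disk():
    g = single_node_graph()
    cfg = LayoutConfig(seed=5, sample_radius=50.0, taxa_radius_max=40.0)
    s1 = init_layout(g, cfg)
    s2 = init_layout(g, cfg)
    assert s1.positions == s2.positions
    assert np.hypot(*s1.positions["s1"]) <= 50.0
    assert s1.velocities["s1"] == (0.0, 0.0)
    s3 = init_layout(g, LayoutConfig(seed=6, sample_radius=50.0,
                                     taxa_radius_max=40.0))
    assert s3.positions != s1.positions


def test_radial_target_radius_mapping():
    cfg = LayoutConfig(sample_radius=100.0, taxa_radius_max=90.0)
    assert radial_target_radius("sample", None, 10, cfg) == 100.0
    assert radial_target_radius("taxon", 10, 10, cfg) == 0.0  # core -> center
    assert radial_target_radius("taxon", 1, 10, cfg) == 90.0
    assert radial_target_radius("taxon", 5, 10, cfg) == pytest.approx(50.0)
    assert radial_target_radius("taxon", 1, 1, cfg) == 0.0
    radii = [radial_target_radius("taxon", k, 10, cfg) for k in range(1, 11)]
    assert all(a > b for a, b in zip(radii, radii[1:]))  # strictly decreasing
    with pytest.raises(ValidationError):
        radial_target_radius("taxon", 0, 10, cfg)
    with pytest.raises(ValidationError):
        radial_target_radius("taxon", 11, 10, cfg)


def test_single_node_converges_to_radial_target():
    g = single_node_graph()
    cfg = LayoutConfig(seed=0, repulsion_strength=0.0, link_strength=0.0,
                       centering=False, group_strength=0.0,
                       radial_strength=0.8, sample_radius=100.0,
                       taxa_radius_max=90.0)
    pos = run_layout(g, cfg)
    assert np.hypot(*pos["s1"]) == pytest.approx(100.0, abs=0.5)


def test_two_linked_nodes_settle_at_link_distance():
    table = mg.AbundanceTable(pd.DataFrame([[5]], index=["s"], columns=["t"]))
    g = mg.build_graph(table)
    cfg = LayoutConfig(seed=1, repulsion_strength=0.0, radial_strength=0.0,
                       group_strength=0.0, link_strength=0.5,
                       link_distance=40.0, max_ticks=500)
    pos = run_layout(g, cfg)
    sep = np.hypot(pos["s"][0] - pos["t"][0], pos["s"][1] - pos["t"][1])
    assert sep == pytest.approx(40.0, rel=0.01)


def test_all_forces_disabled_is_identity():
    g = single_node_graph()
    cfg = LayoutConfig(repulsion_strength=0.0, link_strength=0.0,
                       radial_strength=0.0, group_strength=0.0,
                       centering=False)
    state = init_layout(g, cfg)
    after = step(g, state, cfg)
    assert after.positions == state.positions
    assert after.alpha < state.alpha


def test_alpha_strictly_decreasing(ladder_graph):
    _, g = ladder_graph
    cfg = LayoutConfig(seed=2)
    state = init_layout(g, cfg)
    alphas = [state.alpha]
    for _ in range(20):
        state = step(g, state, cfg)
        alphas.append(state.alpha)
    assert all(a > b > 0 for a, b in zip(alphas, alphas[1:]))


def test_run_layout_deterministic(ladder_graph):
    _, g = ladder_graph
    cfg = LayoutConfig(seed=9)
    assert run_layout(g, cfg) == run_layout(g, cfg)


def test_mirror_equivariance(ladder_graph):
    """Reflecting the initial positions about the y-axis reflects the run."""
    _, g = ladder_graph
    cfg = LayoutConfig(seed=13)
    state = init_layout(g, cfg)
    mirrored = LayoutState(
        positions={k: (-x, y) for k, (x, y) in state.positions.items()},
        velocities=dict(state.velocities),
        alpha=state.alpha,
    )
    for _ in range(60):
        state = step(g, state, cfg)
        mirrored = step(g, mirrored, cfg)
    for k in state.positions:
        assert mirrored.positions[k][0] == pytest.approx(-state.positions[k][0], abs=1e-6)
        assert mirrored.positions[k][1] == pytest.approx(state.positions[k][1], abs=1e-6)


def test_translation_equivariance(ladder_graph):
    _, g = ladder_graph
    base = run_layout(g, LayoutConfig(seed=21))
    shifted = run_layout(g, LayoutConfig(seed=21, center=(100.0, -50.0)))
    for k in base:
        assert shifted[k][0] == pytest.approx(base[k][0] + 100.0, abs=1e-6)
        assert shifted[k][1] == pytest.approx(base[k][1] - 50.0, abs=1e-6)


def test_prevalence_orders_radius(ladder_graph):
    """Core taxa end near the center, singletons at the rim (rho <= -0.9)."""
    table, g = ladder_graph
    pos = run_layout(g, LayoutConfig(seed=3))
    prev = [mg.prevalence(table, f"t{k}") for k in range(1, 11)]
    radius = [np.hypot(*pos[f"t{k}"]) for k in range(1, 11)]
    rho = spearmanr(prev, radius).statistic
    assert rho <= -0.9


def test_two_group_x_separability():
    table, taxonomy, metadata = mg.generate(mg.SyntheticSpec(seed=5))
    g = mg.build_graph(table, taxonomy=taxonomy, metadata=metadata)
    cfg = LayoutConfig(seed=7)
    groups = [g.attributes(s)["group"] for s in g.samples]
    cfg.group_targets = default_group_targets(groups, cfg)
    pos = run_layout(g, cfg)
    xs = {}
    for s in g.samples:
        xs.setdefault(g.attributes(s)["group"], []).append(pos[s][0])
    assert max(xs["group01"]) < min(xs["group02"])


def test_three_groups_form_separated_centroids():
    table, taxonomy, metadata = mg.generate(
        mg.SyntheticSpec(seed=8, n_samples=12, n_groups=3)
    )
    g = mg.build_graph(table, taxonomy=taxonomy, metadata=metadata)
    cfg = LayoutConfig(seed=15)
    groups = [g.attributes(s)["group"] for s in g.samples]
    cfg.group_targets = default_group_targets(groups, cfg)
    assert all(len(t) == 2 for t in cfg.group_targets.values())  # 2-D targets
    pos = run_layout(g, cfg)
    by_group = {}
    for s in g.samples:
        by_group.setdefault(g.attributes(s)["group"], []).append(pos[s])
    centroids = {k: np.mean(v, axis=0) for k, v in by_group.items()}
    spreads = {
        k: np.mean([np.linalg.norm(np.array(p) - centroids[k]) for p in v])
        for k, v in by_group.items()
    }
    names = sorted(centroids)
    for i in range(3):
        for j in range(i + 1, 3):
            d = np.linalg.norm(centroids[names[i]] - centroids[names[j]])
            assert d > max(spreads[names[i]], spreads[names[j]])


def test_empty_graph_rejected():
    with pytest.raises(DegenerateInputError):
        init_layout(CompositionGraph(nx.DiGraph()), LayoutConfig())


def test_coincident_nodes_do_not_crash():
    g = nx.DiGraph()
    g.add_node("a", node_class="sample")
    g.add_node("b", node_class="sample")
    cg = CompositionGraph(g)
    cfg = LayoutConfig(seed=0, link_strength=0.0, radial_strength=0.0,
                       group_strength=0.0, centering=False)
    state = LayoutState(
        positions={"a": (0.0, 0.0), "b": (0.0, 0.0)},
        velocities={"a": (0.0, 0.0), "b": (0.0, 0.0)},
        alpha=1.0,
    )
    after = step(cg, state, cfg)
    pa, pb = after.positions["a"], after.positions["b"]
    assert pa != pb  # jitter split them apart


def test_barnes_hut_approximates_exact_repulsion():
    rng = np.random.default_rng(4)
    pos = rng.normal(size=(300, 2)) * 120
    cfg = LayoutConfig()
    exact = _repulsion_exact(pos, cfg, 1.0, 0)
    approx = _repulsion_barnes_hut(pos, cfg, 1.0, 0)
    rel = np.linalg.norm(exact - approx) / np.linalg.norm(exact)
    assert rel < 0.05
    tight = LayoutConfig(approximation_theta=0.3)
    approx2 = _repulsion_barnes_hut(pos, tight, 1.0, 0)
    rel2 = np.linalg.norm(exact - approx2) / np.linalg.norm(exact)
    assert rel2 < rel  # smaller theta -> closer to exact


def test_config_validation():
    with pytest.raises(ValidationError):
        LayoutConfig(alpha_decay_rate=1.5)
    with pytest.raises(ValidationError):
        LayoutConfig(velocity_decay=1.0)
    with pytest.raises(ValidationError):
        LayoutConfig(sample_radius=100.0, taxa_radius_max=150.0)


def test_rank_radial_mapping_option(ladder_graph):
    """Rank mapping spaces distinct prevalences evenly and still orders
    radius against prevalence."""
    table, g = ladder_graph
    cfg = LayoutConfig(seed=3, radial_mapping="rank")
    pos = run_layout(g, cfg)
    prev = [mg.prevalence(table, f"t{k}") for k in range(1, 11)]
    radius = [np.hypot(*pos[f"t{k}"]) for k in range(1, 11)]
    assert spearmanr(prev, radius).statistic <= -0.9
    with pytest.raises(ValidationError):
        LayoutConfig(radial_mapping="log")


def test_weight_scaled_links_change_layout(ladder_graph):
    _, g = ladder_graph
    plain = run_layout(g, LayoutConfig(seed=4))
    scaled = run_layout(g, LayoutConfig(seed=4, weight_scaled_links=True))
    assert plain != scaled  # the option has an effect
    # and stays deterministic
    assert scaled == run_layout(g, LayoutConfig(seed=4, weight_scaled_links=True))
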