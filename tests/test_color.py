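"""Color catalogue, classical MDS, CIELAB mapping, highlight states."""
import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import mbgraph as mg
from mbgraph import color as mc
from mbgraph.errors import CardinalityError, UnknownIdentifierError, ValidationError
from mbgraph.types import DistanceMatrix


def euclidean_dm(points, labels=None):
    pts = np.asarray(points, dtype=float)
    labels = labels or [f"p{i}" for i in range(len(pts))]
    return DistanceMatrix(labels=labels, values=squareform(pdist(pts)))


# ---------------------------------------------------------------------------
# scales
# ---------------------------------------------------------------------------

def test_categorical_scale_stable_and_distinct():
    a = mc.categorical_scale({"n1": "x", "n2": "y", "n3": "x"})
    b = mc.categorical_scale({"n3": "x", "n2": "y", "n1": "x"})  # reordered
    assert a.colors == b.colors
    assert a.colors["n1"] == a.colors["n3"] != a.colors["n2"]
    with pytest.raises(CardinalityError):
        mc.categorical_scale({f"n{i}": str(i) for i in range(13)})


def _saturation(hex_color):
    import colorsys

    r, g, b = (int(hex_color[i : i + 2], 16) / 255 for i in (1, 3, 5))
    return colorsys.rgb_to_hls(r, g, b)[2]


def test_saturation_scale_monotone_and_affine_invariant():
    values = {"a": 0.0, "b": 0.4, "c": 1.0}
    asn = mc.saturation_scale(values)
    assert _saturation(asn.colors["a"]) < _saturation(asn.colors["b"]) < _saturation(
        asn.colors["c"]
    )
    shifted = mc.saturation_scale({k: 3.0 * v - 7.0 for k, v in values.items()})
    assert shifted.colors == asn.colors  # min-max normalised


def test_saturation_scale_constant_values_warns(caplog):
    with caplog.at_level("WARNING"):
        asn = mc.saturation_scale({"a": 2.0, "b": 2.0})
    assert asn.colors["a"] == asn.colors["b"]
    assert any("constant" in r.message for r in caplog.records)


def test_binned_scale_equal_width_bins():
    values = {f"n{v}": v for v in range(1, 11)}
    asn = mc.binned_multihue_scale(values, n_bins=5)
    assert asn.legend["bins"] == [(1, 2), (3, 4), (5, 6), (7, 8), (9, 10)]
    assert asn.colors["n1"] == asn.colors["n2"]
    assert asn.colors["n2"] != asn.colors["n3"]
    # monotone values traverse the ramp in order
    ramp = asn.legend["ramp"]
    seq = [ramp.index(asn.colors[f"n{v}"]) for v in range(1, 11)]
    assert seq == sorted(seq)


def test_binned_scale_small_domain_collapses():
    asn = mc.binned_multihue_scale({"a": 3, "b": 4, "c": 3}, n_bins=5)
    assert asn.legend["bins"] == [(3, 3), (4, 4)]
    single = mc.binned_multihue_scale({"a": 2, "b": 2}, n_bins=4)
    assert single.legend["bins"] == [(2, 2)]
    assert single.colors["a"] == single.colors["b"]


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------

def test_mds_recovers_euclidean_distances():
    rng = np.random.default_rng(17)
    pts = rng.normal(size=(6, 3)) * 4
    D = euclidean_dm(pts)
    emb = mc.classical_mds(D, k=3)
    coords = np.array([emb[l] for l in D.labels])
    recovered = squareform(pdist(coords))
    np.testing.assert_allclose(recovered, D.values, atol=1e-8)


def test_mds_equilateral_and_degenerate():
    D = DistanceMatrix(labels=["a", "b", "c"],
                       values=np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]))
    emb = mc.classical_mds(D, k=2)
    coords = np.array([emb[l] for l in D.labels])
    rec = squareform(pdist(coords))
    np.testing.assert_allclose(rec, D.values, atol=1e-8)
    zero = DistanceMatrix(labels=["a", "b", "c"], values=np.zeros((3, 3)))
    emb0 = mc.classical_mds(zero, k=2)
    assert all(np.allclose(v, 0) for v in emb0.values())


def test_mds_deterministic_sign_convention():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(5, 2))
    D = euclidean_dm(pts)
    e1 = mc.classical_mds(D, k=2)
    e2 = mc.classical_mds(D, k=2)
    for l in D.labels:
        np.testing.assert_array_equal(e1[l], e2[l])
    for axis in range(2):
        loadings = np.array([e1[l][axis] for l in D.labels])
        assert loadings[np.argmax(np.abs(loadings))] >= 0


def test_mds_matches_skbio_pcoa():
    """Independent oracle: scikit-bio's PCoA spans the same embedding."""
    from skbio.stats.ordination import pcoa
    from skbio import DistanceMatrix as SkbioDM

    rng = np.random.default_rng(29)
    pts = rng.normal(size=(7, 3))
    D = euclidean_dm(pts)
    ours = np.array([mc.classical_mds(D, k=3)[l] for l in D.labels])
    theirs = pcoa(SkbioDM(D.values, ids=D.labels), number_of_dimensions=3).samples.values
    # same embedding up to per-axis sign
    for axis in range(3):
        col = theirs[:, axis]
        assert np.allclose(ours[:, axis], col, atol=1e-6) or np.allclose(
            ours[:, axis], -col, atol=1e-6
        )


# ---------------------------------------------------------------------------
# CIELAB mapping
# ---------------------------------------------------------------------------

def test_lab_srgb_roundtrip_in_gamut():
    from skimage import color as skc

    rng = np.random.default_rng(5)
    n_in_gamut = 0
    for _ in range(50):
        lab = np.array([rng.uniform(30, 85), rng.uniform(-30, 30),
                        rng.uniform(-30, 30)])
        rgb, clamped = mc.lab_to_rgb(lab)
        if clamped:
            continue
        n_in_gamut += 1
        back = skc.rgb2lab(rgb.reshape(1, 1, 3))[0, 0]
        assert np.linalg.norm(back - lab) < 0.01  # continuous roundtrip
        hex_color, _ = mc.lab_to_hex(lab)
        # 8-bit hex quantisation stays well under Delta E 1
        assert np.linalg.norm(mc.hex_to_lab(hex_color) - lab) < 1.0
    assert n_in_gamut > 30


def test_lab_srgb_roundtrip_exact_hex():
    """hex -> Lab -> hex is the identity (Delta E ~ 0 for in-gamut)."""
    for hex_color in ("#336699", "#a0522d", "#00ff88", "#cccccc"):
        lab = mc.hex_to_lab(hex_color)
        back, clamped = mc.lab_to_hex(lab)
        assert not clamped
        assert back == hex_color


def test_distance_to_colors_zero_distance_identical_hex():
    # two coincident points among others
    pts = [[0, 0, 0], [0, 0, 0], [3, 0, 0], [0, 4, 0], [1, 1, 5]]
    D = euclidean_dm(pts)
    asn = mc.distance_to_colors(D)
    assert asn.colors["p0"] == asn.colors["p1"]
    assert asn.colors["p0"] != asn.colors["p2"]


def test_distance_to_colors_degenerate_all_equal():
    D = DistanceMatrix(labels=["a", "b", "c"], values=np.zeros((3, 3)))
    asn = mc.distance_to_colors(D)
    assert len(set(asn.colors.values())) == 1  # all identical mid-grey


def test_two_cluster_matrix_separates_in_lab_space():
    """Within-cluster mean Delta E < between-cluster mean Delta E."""
    rng = np.random.default_rng(31)
    a = rng.normal(size=(4, 3)) * 0.5
    b = rng.normal(size=(4, 3)) * 0.5 + np.array([8.0, 0, 0])
    D = euclidean_dm(np.vstack([a, b]))
    asn = mc.distance_to_colors(D)
    labs = {l: mc.hex_to_lab(asn.colors[l]) for l in D.labels}
    groups = {l: (0 if i < 4 else 1) for i, l in enumerate(D.labels)}
    within, between = [], []
    names = D.labels
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            de = np.linalg.norm(labs[names[i]] - labs[names[j]])
            (within if groups[names[i]] == groups[names[j]] else between).append(de)
    assert np.mean(within) < np.mean(between)


# ---------------------------------------------------------------------------
# highlight states
# ---------------------------------------------------------------------------

def test_highlight_neighbors_match_edge_scan(synthetic_graph):
    g = synthetic_graph
    rng = np.random.default_rng(2)
    nodes = g.node_ids
    for focal in rng.choice(nodes, size=10, replace=False):
        state = mc.highlight(g, focal)
        brute = {
            (v if u == focal else u)
            for u, v, _ in g.edges()
            if focal in (u, v)
        }
        assert set(state.neighbor_colors) == brute
        assert state.faded_ids == set(nodes) - brute - {focal}


def test_highlight_core_taxon_fades_nothing_linked(synthetic_graph):
    g = synthetic_graph
    state = mc.highlight(g, "core_001")  # present in every sample
    assert set(state.neighbor_colors) == set(g.samples)
    assert set(g.samples) & state.faded_ids == set()
    with pytest.raises(UnknownIdentifierError):
        mc.highlight(g, "no-such-node")


def test_taxonomy_highlight_membership(synthetic_graph):
    g = synthetic_graph
    asn = mc.taxonomy_highlight(g, "genus", "g__group01")
    red = {n for n, c in asn.colors.items() if c == mc.HIGHLIGHT_RED}
    expected = {t for t in g.taxa if g.attributes(t)["genus"] == "g__group01"}
    assert red == expected
    linked = {u for u, v, _ in g.edges() if v in expected}
    for s in g.samples:
        assert asn.opacity[s] == (1.0 if s in linked else mc.FADE_OPACITY)


def test_taxonomy_highlight_absent_value_warns(synthetic_graph, caplog):
    with caplog.at_level("WARNING"):
        asn = mc.taxonomy_highlight(synthetic_graph, "genus", "g__nothing")
    assert mc.HIGHLIGHT_RED not in asn.colors.values()
    assert any("no taxa" in r.message for r in caplog.records)


def test_taxonomy_highlight_sentinel_never_matches(synthetic_graph):
    # species rank is deliberately unassigned in the synthetic taxonomy
    asn = mc.taxonomy_highlight(synthetic_graph, "species", "")
    assert mc.HIGHLIGHT_RED not in asn.colors.values()
    with pytest.raises(ValidationError):
        mc.taxonomy_highlight(synthetic_graph, "strain", "x")
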