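"""Mutual information estimation, thresholding, DPI pruning, hub ranking."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lncstage.aracne import (
    MINetwork,
    apply_dpi,
    equal_frequency_bins,
    hub_rank,
    infer_network,
    multiedge_partner_count,
    mutual_information,
    network_delta,
)


def _net(edges, threshold=0.0):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, mi=w)
    return MINetwork(graph=g, threshold=threshold)


def test_mi_symmetry_and_self_information():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(400)
    y = rng.standard_normal(400)
    assert mutual_information(x, y) == mutual_information(y, x)
    # identity: equal-frequency binning makes the binned variable uniform,
    # so MI(x, x) = H = log2(B) exactly when B divides n
    assert mutual_information(x, x, bins=20) == pytest.approx(
        math.log2(20), abs=1e-12
    )
    n = 1024  # auto: B = floor(sqrt(n)) = 32 divides n
    x2 = rng.standard_normal(n)
    assert mutual_information(x2, x2) == pytest.approx(5.0, abs=1e-12)


def test_mi_two_by_two_histogram_matches_hand_arithmetic():
    """Joint counts (40,10,10,40) with uniform margins."""
    x = np.arange(100, dtype=float)
    # low-x: 40 low-y + 10 high-y; high-x: 10 low-y + 40 high-y
    y = np.empty(100)
    y[:40] = np.arange(40)          # low/low
    y[40:50] = 50 + np.arange(10)   # low/high
    y[50:60] = 40 + np.arange(10)   # high/low
    y[60:] = 60 + np.arange(40)     # high/high
    mi = mutual_information(x, y, bins=2)
    expected = 2 * 0.4 * math.log2(0.4 / 0.25) + 2 * 0.1 * math.log2(0.1 / 0.25)
    assert mi == pytest.approx(expected, abs=1e-12)


def test_mi_validation_and_degenerate_inputs(caplog):
    with pytest.raises(ValueError, match="equal length"):
        mutual_information([1.0] * 10, [1.0] * 9)
    with pytest.raises(ValueError, match="8 samples"):
        mutual_information([1.0] * 4, [2.0] * 4)
    with caplog.at_level("WARNING", logger="lncstage.aracne"):
        assert mutual_information([5.0] * 50, list(range(50))) == 0.0
    assert any("constant" in r.message for r in caplog.records)


def test_equal_frequency_bins_are_balanced():
    rng = np.random.default_rng(1)
    v = rng.standard_normal(120)
    b = equal_frequency_bins(v, 10)
    counts = np.bincount(b, minlength=10)
    assert (counts == 12).all()


def test_infer_network_requires_three_genes():
    data = pd.DataFrame(np.random.default_rng(0).standard_normal((50, 2)),
                        columns=["a", "b"])
    with pytest.raises(ValueError, match="3 genes"):
        infer_network(data)


def test_alpha_one_keeps_complete_graph():
    rng = np.random.default_rng(2)
    data = pd.DataFrame(rng.standard_normal((60, 5)),
                        columns=list("abcde"))
    net = infer_network(data, alpha=1.0, seed=0)
    assert net.threshold == 0.0
    assert net.graph.number_of_edges() == 10


def test_independent_matrix_false_positive_band():
    """Edge counts on independent data stay within an alpha-consistent
    band over seeds (pooled permutation null)."""
    rng_edges = []
    n_pairs = 20 * 19 // 2
    for seed in range(6):
        rng = np.random.default_rng(100 + seed)
        data = pd.DataFrame(rng.standard_normal((120, 20)),
                            columns=[f"g{i}" for i in range(20)])
        net = infer_network(data, alpha=0.05, n_perm=400, seed=seed)
        rng_edges.append(net.graph.number_of_edges())
    # binomial(190, 0.05): mean 9.5, sd ~3; allow a generous band
    assert max(rng_edges) <= 30
    assert np.mean(rng_edges) <= 20


def test_dpi_tie_protection_and_no_triangles():
    tri = _net([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
    assert apply_dpi(tri, 0.15).graph.number_of_edges() == 3
    path = _net([("a", "b", 1.0), ("b", "c", 0.5), ("c", "d", 2.0)])
    pruned = apply_dpi(path, 0.15)
    assert sorted(pruned.edges) == sorted(path.edges)


def test_dpi_removes_weak_indirect_edge():
    tri = _net([("x", "y", 2.0), ("y", "z", 1.8), ("x", "z", 0.9)])
    pruned = apply_dpi(tri, 0.15)
    assert ("x", "z") not in [(u, v) for u, v, _ in pruned.edges]
    assert pruned.graph.number_of_edges() == 2


def test_dpi_result_is_subset_of_input():
    rng = np.random.default_rng(5)
    for _ in range(50):
        g = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(1 << 30)))
        edges = [(str(u), str(v), float(rng.uniform(0.1, 2.0)))
                 for u, v in g.edges]
        net = _net(edges)
        pruned = apply_dpi(net, 0.15)
        assert set((u, v) for u, v, _ in pruned.edges) <= set(
            (u, v) for u, v, _ in net.edges
        )


def test_hub_rank_star_and_tie_breaks():
    star = _net([("hub", f"s{i}", 1.0) for i in range(5)])
    ranking = hub_rank(star)
    assert ranking[0] == ("hub", 5)
    two = _net([("a", "b", 1.0)])
    assert hub_rank(two) == [("a", 1), ("b", 1)]  # id tie-break
    weighted = _net([("a", "b", 1.0), ("c", "d", 2.0)])
    assert [g for g, _ in hub_rank(weighted)][:2] == ["c", "d"]  # MI tie-break
    assert hub_rank(_net([])) == []


def test_multiedge_partner_count_examples():
    path = _net([("a", "b", 1.0), ("b", "c", 1.0)])
    assert multiedge_partner_count(path, {"a", "b", "c"}) == 1
    empty = MINetwork(graph=nx.Graph(), threshold=0.0)
    assert multiedge_partner_count(empty, {"a"}) == 0
    with pytest.raises(ValueError, match="nonempty"):
        multiedge_partner_count(path, set())


def test_multiedge_count_matches_degree_filter_oracle():
    rng = np.random.default_rng(9)
    for _ in range(20):
        g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1 << 30)))
        net = _net([(str(u), str(v), 1.0) for u, v in g.edges])
        nodes = [str(i) for i in range(12)]
        expected = sum(1 for n in g.nodes if g.degree(n) >= 2)
        assert multiedge_partner_count(net, nodes) == expected


def test_network_delta_identity_and_partition_additivity():
    net = _net([("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)])
    d = network_delta(net, net, {"all": ["a", "b", "c", "d"]})
    assert (d["change"] == 0).all()
    parts = {"left": ["a", "b"], "right": ["c", "d"]}
    dd = network_delta(net, net, parts)
    assert dd["count_t0"].sum() == multiedge_partner_count(
        net, ["a", "b", "c", "d"]
    )
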