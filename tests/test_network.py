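"""Co-abundance edge selection and Markov Clustering."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from metaboaging import network, preprocess
from metaboaging.network import MclConfig, correlation_edges, mcl_cluster

from conftest import build_table


def _log_table(values):
    values = np.asarray(values, float)
    n = values.shape[1]
    per = n // 3
    groups = ["A"] * per + ["B"] * per + ["C"] * (n - 2 * per)
    return build_table(values, groups, scale="log10")


def test_identical_rows_give_r_one_edge():
    rng = np.random.default_rng(0)
    base = rng.normal(0, 1, 21)
    tab = _log_table([base, base, rng.normal(0, 1, 21)])
    net = correlation_edges(tab)
    assert net.has_edge("M001", "M002")
    assert net["M001"]["M002"]["r"] == pytest.approx(1.0)


def test_r_exactly_at_threshold_is_dropped():
    """The rule is strictly r > r_min."""
    # construct two rows with exact correlation 0.7
    n = 20
    x = np.arange(n, dtype=float)
    x = (x - x.mean()) / x.std()
    rng = np.random.default_rng(1)
    e = rng.normal(size=n)
    e -= e.mean()
    e -= x * (e @ x) / (x @ x)  # orthogonalize
    e /= np.linalg.norm(e) / np.sqrt(n)
    r0 = 0.7
    y = r0 * x + np.sqrt(1 - r0**2) * e
    r_check = np.corrcoef(x, y)[0, 1]
    assert r_check == pytest.approx(0.7, abs=1e-9)
    tab = _log_table([x, y, rng.normal(size=n)])
    # threshold set to the pair's exact correlation: strict > must drop it
    net = correlation_edges(tab, r_min=float(r_check), p_max=1.0)
    assert not net.has_edge("M001", "M002")


def test_anticorrelated_rows_are_dropped():
    rng = np.random.default_rng(2)
    base = rng.normal(0, 1, 21)
    tab = _log_table([base, -base + rng.normal(0, 0.3, 21), base + rng.normal(0, 0.1, 21)])
    net = correlation_edges(tab)
    r = np.corrcoef(tab.values.to_numpy())[0, 1]
    assert r < -0.7  # strongly anti-correlated ...
    assert not net.has_edge("M001", "M002")  # ... but only positive co-abundance counts
    assert net.has_edge("M001", "M003")


def test_edges_match_brute_force_double_loop():
    """Vectorized edge selection equals a naive pairwise computation."""
    rng = np.random.default_rng(3)
    X = rng.normal(0, 1, size=(30, 21))
    X[5:10] += X[0] * 1.5  # inject correlated block
    tab = _log_table(X)
    net = correlation_edges(tab, r_min=0.5, p_max=0.05)

    ids = list(tab.values.index)
    pairs, rs, ps = [], [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r, p = stats.pearsonr(X[i], X[j])
            pairs.append((ids[i], ids[j]))
            rs.append(r)
            ps.append(p)
    p_adj = multipletests(ps, method="fdr_bh")[1]
    expected = {
        pair for pair, r, q in zip(pairs, rs, p_adj) if r > 0.5 and q < 0.05
    }
    assert {tuple(sorted(e)) for e in net.edges} == {
        tuple(sorted(p)) for p in expected
    }
    for (u, v), r, q in zip(pairs, rs, p_adj):
        if (u, v) in expected:
            assert net[u][v]["r"] == pytest.approx(r, abs=1e-10)
            assert net[u][v]["p_adj"] == pytest.approx(q, abs=1e-10)


def test_constant_metabolite_excluded_but_kept_as_node():
    rng = np.random.default_rng(4)
    X = rng.normal(0, 1, size=(3, 21))
    X[1] = 5.0
    tab = _log_table(X)
    with pytest.warns(UserWarning, match="constant"):
        net = correlation_edges(tab)
    assert "M002" in net.nodes
    assert net.degree("M002") == 0


def test_correlation_requires_log_scale(three_group_table):
    with pytest.raises(ValueError, match="log"):
        correlation_edges(three_group_table)


def test_too_few_samples_is_error():
    tab = build_table(np.ones((2, 3)) + np.eye(2, 3), ["A", "A", "A"], scale="log10")
    with pytest.raises(ValueError, match="4 samples"):
        correlation_edges(tab)


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------


def test_mcl_two_disjoint_triangles():
    g = nx.disjoint_union(nx.cycle_graph(3), nx.cycle_graph(3))
    modules, converged = mcl_cluster(g)
    assert converged
    assert len(set(modules.values())) == 2
    assert modules[0] == modules[1] == modules[2]
    assert modules[3] == modules[4] == modules[5]


def test_mcl_complete_graph_single_module():
    modules, _ = mcl_cluster(nx.complete_graph(5))
    assert len(set(modules.values())) == 1


def test_mcl_bridged_cliques_split():
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    g.add_edge(0, 5)
    modules, _ = mcl_cluster(g, MclConfig(inflation=2.0))
    assert len(set(modules.values())) == 2
    assert len({modules[i] for i in range(5)}) == 1
    assert len({modules[i] for i in range(5, 10)}) == 1


def test_mcl_partition_covers_every_node():
    rng = np.random.default_rng(5)
    g = nx.gnp_random_graph(40, 0.1, seed=7)
    modules, _ = mcl_cluster(g)
    assert set(modules) == set(g.nodes)
    assert all(isinstance(m, int) for m in modules.values())


def test_mcl_isolated_nodes_are_singletons():
    g = nx.Graph()
    g.add_nodes_from(["x", "y"])
    g.add_edge("a", "b")
    modules, _ = mcl_cluster(g)
    assert modules["x"] != modules["y"]
    assert modules["a"] == modules["b"]


def test_mcl_invariant_to_relabeling():
    g = nx.les_miserables_graph()
    modules, _ = mcl_cluster(g)
    mapping = {n: f"node_{i}" for i, n in enumerate(sorted(g.nodes))}
    h = nx.relabel_nodes(g, mapping)
    modules_h, _ = mcl_cluster(h)
    # partitions agree up to module renaming
    from collections import defaultdict

    part_g = defaultdict(set)
    for n, m in modules.items():
        part_g[m].add(mapping[n])
    part_h = defaultdict(set)
    for n, m in modules_h.items():
        part_h[m].add(n)
    assert set(map(frozenset, part_g.values())) == set(map(frozenset, part_h.values()))


def test_mcl_empty_graph_is_error():
    with pytest.raises(ValueError, match="non-empty"):
        mcl_cluster(nx.Graph())
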