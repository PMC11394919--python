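"""PPI topology: centralities, hubs, MCODE modules, ORA, ROC/AUC."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rsnp_scan import centralities, mcode, ora, roc_auc, select_hubs
from rsnp_scan.network import graph_from_edges, read_gmt, roc_screen
from rsnp_scan.simulate import SimConfig, simulate_ppi


# --- brute-force oracles ---------------------------------------------------

def brute_force_centralities(graph):
    """Betweenness and stress by explicit enumeration of all shortest paths
    over unordered node pairs."""
    bet = dict.fromkeys(graph, 0.0)
    stress = dict.fromkeys(graph, 0.0)
    for s, t in itertools.combinations(graph.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in graph:
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            bet[v] += through / len(paths)
            stress[v] += through
    return bet, stress


def auc_pairwise_oracle(values, labels):
    """Mann-Whitney pairwise enumeration with half-credit for ties."""
    pos = [v for v, y in zip(values, labels) if y == 1]
    neg = [v for v, y in zip(values, labels) if y == 0]
    u = sum(1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg)
    return u / (len(pos) * len(neg))


# --- centralities ----------------------------------------------------------

def test_star_graph_closed_forms():
    g = nx.star_graph(4)  # center 0, leaves 1..4
    topo = centralities(g).set_index("node")
    assert topo.loc[0, "degree"] == 4
    assert topo.loc[0, "betweenness"] == pytest.approx(6.0)  # C(4,2)
    assert topo.loc[0, "stress"] == pytest.approx(6.0)
    for leaf in range(1, 5):
        assert topo.loc[leaf, "betweenness"] == 0.0
        assert topo.loc[leaf, "stress"] == 0.0


def test_path_graph_middle_node():
    g = nx.path_graph(3)
    topo = centralities(g).set_index("node")
    assert topo.loc[1, "betweenness"] == pytest.approx(1.0)
    assert topo.loc[1, "stress"] == pytest.approx(1.0)


def test_centralities_match_brute_force_on_random_graphs():
    """Exact equality with all-shortest-paths enumeration, graphs <= 12 nodes
    (including disconnected ones)."""
    rng = np.random.default_rng(0)
    for trial in range(25):
        n = int(rng.integers(3, 13))
        p = float(rng.uniform(0.15, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        topo = centralities(g).set_index("node")
        bet, stress = brute_force_centralities(g)
        for v in g:
            assert topo.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-9)
            assert topo.loc[v, "stress"] == pytest.approx(stress[v], abs=1e-9)


def test_centralities_invariant_under_relabeling():
    g = nx.gnp_random_graph(10, 0.4, seed=3)
    mapping = {v: f"n{(v * 7) % 10}" for v in g}
    h = nx.relabel_nodes(g, mapping)
    a = centralities(g).set_index("node")
    b = centralities(h).set_index("node")
    for v in g:
        for col in ("degree", "betweenness", "stress"):
            assert a.loc[v, col] == pytest.approx(b.loc[mapping[v], col])


# --- hub selection ---------------------------------------------------------

def test_hub_union_and_ties():
    topo = pd.DataFrame({
        "node": list(range(30)),
        "degree": list(range(30)),              # top-20: nodes 10..29
        "betweenness": list(range(29, -1, -1)),  # top-20: nodes 0..19
        "stress": [1.0] * 30,                    # all tied: everyone included
    })
    hubs = select_hubs(topo, k=20)
    assert hubs == set(range(30))
    topo2 = topo.assign(stress=topo["degree"])
    assert select_hubs(topo2, k=20) == set(range(30))  # union of two lists


def test_hub_identical_metrics_give_exactly_k():
    topo = pd.DataFrame({"node": list(range(40)), "degree": list(range(40)),
                         "betweenness": list(range(40)),
                         "stress": list(range(40))})
    assert select_hubs(topo, k=20) == set(range(20, 40))


# --- MCODE -----------------------------------------------------------------

def test_mcode_recovers_isolated_clique():
    g = nx.complete_graph(6)
    g.add_edges_from([(10, 11), (11, 12)])  # dangling path, no 2-core
    mods = mcode(g)
    assert len(mods) == 1
    assert mods[0].nodes == set(range(6))
    assert mods[0].density == pytest.approx(1.0)
    assert mods[0].mcode_score == pytest.approx(6.0)
    assert mods[0].seed in mods[0].nodes


def test_mcode_tree_has_no_modules():
    tree = nx.balanced_tree(2, 4)
    assert mcode(tree) == []


def test_mcode_empty_graph():
    assert mcode(nx.Graph()) == []


def test_mcode_two_planted_cliques_recovered_disjoint():
    rng = np.random.default_rng(1)
    g = nx.Graph()
    c1 = [f"a{i}" for i in range(8)]
    c2 = [f"b{i}" for i in range(8)]
    g.add_edges_from(itertools.combinations(c1, 2))
    g.add_edges_from(itertools.combinations(c2, 2))
    others = [f"x{i}" for i in range(30)]
    for u, v in itertools.combinations(others + c1[:1] + c2[:1], 2):
        if rng.random() < 0.05:
            g.add_edge(u, v)
    mods = mcode(g)
    found = [m.nodes for m in mods if m.mcode_score >= 4]
    assert any(set(c1) <= m for m in found)
    assert any(set(c2) <= m for m in found)
    for m1, m2 in itertools.combinations(found, 2):
        assert not (m1 & m2)


def test_mcode_on_simulated_ppi_recovers_planted_modules():
    cfg = SimConfig(seed=7, n_graph_nodes=100, n_modules=3, module_size=8,
                    background_edge_p=0.03)
    edges, true_modules = simulate_ppi(cfg)
    mods = mcode(graph_from_edges(edges))
    for planted in true_modules:
        assert any(planted <= m.nodes for m in mods)


def test_mcode_invariant_under_relabeling():
    g = nx.complete_graph(7)
    g.add_edges_from([(0, 10), (10, 11)])
    mapping = {v: f"z{v}" for v in g}
    a = mcode(g)
    b = mcode(nx.relabel_nodes(g, mapping))
    assert [{mapping[v] for v in m.nodes} for m in a] == [m.nodes for m in b]


# --- ORA -------------------------------------------------------------------

def test_ora_closed_forms():
    universe = {f"g{i}" for i in range(100)}
    module = {f"g{i}" for i in range(5)}
    term_all_in = {"all_in": module}
    res = ora(module, term_all_in, universe).iloc[0]
    # module of 5 all inside a term of 5: p = 1 / C(100, 5)
    from math import comb
    assert res["p_hyper"] == pytest.approx(1 / comb(100, 5), rel=1e-9)
    # module == term == universe
    res2 = ora(universe, {"t": universe}, universe).iloc[0]
    assert res2["p_hyper"] == pytest.approx(1.0)
    # zero overlap: upper-tail convention gives p = 1
    res3 = ora(module, {"t": {f"g{i}" for i in range(50, 60)}}, universe).iloc[0]
    assert res3["k"] == 0 and res3["p_hyper"] == pytest.approx(1.0)


def test_ora_matches_enumeration_small_universe():
    """p equals explicit hypergeometric pmf summation for N <= 40."""
    rng = np.random.default_rng(4)
    universe = [f"g{i}" for i in range(30)]
    for _ in range(20):
        module = set(rng.choice(universe, size=8, replace=False))
        term = set(rng.choice(universe, size=10, replace=False))
        p = ora(module, {"t": term}, set(universe)).iloc[0]["p_hyper"]
        k = len(module & term)
        enum = sum(stats.hypergeom.pmf(x, 30, 10, 8)
                   for x in range(k, min(10, 8) + 1))
        assert p == pytest.approx(enum, rel=1e-9)


def test_ora_bh_across_terms(small_study):
    sets = small_study.gene_sets
    module = sets["module_pathway"]
    universe = {f"G{i:04d}" for i in range(small_study.config.n_genes)}
    res = ora(module, sets, universe)
    hit = res[res["term"] == "module_pathway"].iloc[0]
    assert hit["significant"] and hit["p_adj"] < 0.05


# --- ROC / AUC -------------------------------------------------------------

@pytest.mark.parametrize("values,labels,expected", [
    ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
    ([1, 3, 2, 4], [0, 0, 1, 1], 0.75),
    ([5, 5, 5, 5], [0, 0, 1, 1], 0.5),   # all ties -> half-credit
])
def test_auc_known_values(values, labels, expected):
    assert roc_auc(values, labels).auc == pytest.approx(expected)


def test_auc_matches_pairwise_enumeration_random_inputs():
    rng = np.random.default_rng(5)
    for _ in range(50):
        n = int(rng.integers(4, 20))
        labels = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
        values = rng.integers(0, 6, size=n)  # small range forces ties
        assert roc_auc(values, labels).auc == pytest.approx(
            auc_pairwise_oracle(values, labels), rel=1e-12)


def test_auc_label_flip_complement():
    rng = np.random.default_rng(6)
    values = rng.normal(size=12)  # continuous: tie-free
    labels = np.r_[np.zeros(6, int), np.ones(6, int)]
    a = roc_auc(values, labels).auc
    b = roc_auc(values, 1 - labels).auc
    assert a + b == pytest.approx(1.0)


def test_auc_orientation_and_predictor_gate():
    values = [4, 3, 2, 1]
    labels = [0, 0, 1, 1]
    plain = roc_auc(values, labels)
    assert plain.auc == 0.0 and not plain.is_predictor
    oriented = roc_auc(values, labels, orient=True)
    assert oriented.auc == 1.0 and oriented.is_predictor
    assert not roc_auc([1, 2, 2, 1], labels).is_predictor  # auc 0.5


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([1, 2], [1, 1])


def test_roc_screen_table(small_study):
    counts = small_study.counts
    labels = small_study.condition_labels
    genes = set(counts.index[:10])
    table = roc_screen(counts, labels, genes, positive_label="disease")
    assert len(table) == 10
    assert ((table["auc"] >= 0) & (table["auc"] <= 1)).all()
    assert (table["is_predictor"] == (table["auc"] > 0.7)).all()


def test_gmt_roundtrip(tmp_path, small_study):
    from rsnp_scan.simulate import write_study
    write_study(small_study, tmp_path)
    sets = read_gmt(tmp_path / "gene_sets.gmt")
    assert sets == small_study.gene_sets
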