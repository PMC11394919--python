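"""Protein-interaction network topology, modules, ORA and ROC screening.

Hub genes are the union of the top-20 nodes by degree, unnormalised
betweenness and stress centrality (CytoNCA conventions).  Dense modules
are detected with an MCODE implementation (vertex weighting by the
highest k-core of each closed neighbourhood, greedy complex expansion,
2-core post-filter, density x size module score).  Module gene lists are
tested for over-representation against GMT gene sets with one-sided
hypergeometric tails, and per-gene ROC/AUC screening flags hub genes whose
expression separates the two phenotype groups (AUC > 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .allelic import bh_adjust

HUB_TOP_K = 20
MCODE_MAX_DEPTH = 100
MCODE_DEGREE_CUTOFF = 2
MCODE_NODE_SCORE_CUTOFF = 0.2
MCODE_SCORE_MIN = 4.0
MCODE_K_SCORE = 2
AUC_PREDICTOR_MIN = 0.7
ORA_ALPHA = 0.05


def graph_from_edges(edges: pd.DataFrame) -> nx.Graph:
    """Simple undirected graph from a two-column edge list (no self-loops)."""
    g = nx.Graph()
    g.add_edges_from(
        (a, b) for a, b in zip(edges.iloc[:, 0], edges.iloc[:, 1]) if a != b)
    return g


def _stress(graph: nx.Graph) -> dict:
    """Stress centrality: number of shortest paths through each node,
    counted over unordered source-target pairs (Brandes-style accumulation).
    """
    stress = dict.fromkeys(graph, 0.0)
    for s in graph:
        # BFS with shortest-path counts
        sigma = dict.fromkeys(graph, 0)
        dist = dict.fromkeys(graph, -1)
        preds: dict = {v: [] for v in graph}
        sigma[s] = 1
        dist[s] = 0
        order = [s]
        head = 0
        while head < len(order):
            v = order[head]
            head += 1
            for w in graph[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    order.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # paths[v] = number of shortest-path continuations from v
        paths = dict.fromkeys(graph, 0.0)
        for w in reversed(order):
            for v in preds[w]:
                paths[v] += 1.0 + paths[w]
        for v in order:
            if v != s:
                stress[v] += sigma[v] * paths[v]
    return {v: x / 2.0 for v, x in stress.items()}


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, unnormalised betweenness and stress for every node."""
    bet = nx.betweenness_centrality(graph, normalized=False)
    stress = _stress(graph)
    return (pd.DataFrame({
        "node": list(graph.nodes),
        "degree": [graph.degree(v) for v in graph.nodes],
        "betweenness": [bet[v] for v in graph.nodes],
        "stress": [stress[v] for v in graph.nodes],
    }).sort_values("node").reset_index(drop=True))


def select_hubs(topology: pd.DataFrame, k: int = HUB_TOP_K) -> set:
    """Union of the top-k nodes by each centrality; ties at rank k included."""
    hubs: set = set()
    for metric in ("degree", "betweenness", "stress"):
        vals = topology[metric].to_numpy(dtype=float)
        if len(vals) <= k:
            hubs.update(topology["node"])
            continue
        cutoff = np.sort(vals)[::-1][k - 1]
        hubs.update(topology.loc[vals >= cutoff, "node"])
    return hubs


@dataclass
class NetworkModule:
    """Dense subgraph: density = 2E/(V(V-1)); mcode_score = density * V."""

    nodes: set
    seed: object
    n_edges: int
    density: float
    mcode_score: float


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def _node_scores(graph: nx.Graph, degree_cutoff: int) -> dict:
    """MCODE vertex weighting: highest-k-core number of the closed
    neighbourhood times that core's density; low-degree nodes score 0."""
    scores = {}
    for v in graph:
        if graph.degree(v) < degree_cutoff:
            scores[v] = 0.0
            continue
        nbhd = graph.subgraph([v, *graph[v]])
        core_num = nx.core_number(nbhd)
        kmax = max(core_num.values())
        core = nbhd.subgraph([u for u, c in core_num.items() if c >= kmax])
        scores[v] = kmax * _density(core)
    return scores


def mcode(
    graph: nx.Graph,
    max_depth: int = MCODE_MAX_DEPTH,
    degree_cutoff: int = MCODE_DEGREE_CUTOFF,
    node_score_cutoff: float = MCODE_NODE_SCORE_CUTOFF,
    score_min: float = MCODE_SCORE_MIN,
    k_score: int = MCODE_K_SCORE,
) -> list[NetworkModule]:
    """Detect densely connected modules (MCODE with the standard parameters).

    Seeds descend by vertex weight; expansion includes unassigned
    neighbours scoring at least seed_score * (1 - node_score_cutoff) up to
    ``max_depth``; complexes lacking a ``k_score``-core are discarded; the
    survivors with density x size >= ``score_min`` are returned ranked by
    score.  Node sets of reported modules are pairwise disjoint and each
    contains its seed.
    """
    if graph.number_of_nodes() == 0:
        return []
    scores = _node_scores(graph, degree_cutoff)
    assigned: set = set()
    modules = []
    for seed in sorted(scores, key=lambda v: (-scores[v], str(v))):
        if seed in assigned or scores[seed] <= 0.0:
            continue
        threshold = scores[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for v in frontier:
                for u in graph[v]:
                    if u in members or u in assigned:
                        continue
                    if scores[u] >= threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        assigned |= members
        sub = graph.subgraph(members)
        if nx.k_core(sub, k=k_score).number_of_nodes() == 0:
            continue
        dens = _density(sub)
        score = dens * sub.number_of_nodes()
        if score >= score_min:
            modules.append(NetworkModule(
                nodes=set(members), seed=seed, n_edges=sub.number_of_edges(),
                density=dens, mcode_score=score))
    return sorted(modules, key=lambda m: -m.mcode_score)


def ora(
    module_genes: set,
    gene_sets: dict[str, set],
    universe: set,
    alpha: float = ORA_ALPHA,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a gene list.

    Per term: k genes of the module in the term, term size K, module size n,
    universe size N; p = P(X >= k) under Hypergeom(N, K, n), BH-adjusted
    across tested terms.  All sets are intersected with the universe first.
    """
    module = set(module_genes) & set(universe)
    n = len(module)
    N = len(universe)
    rows = []
    for term, members in gene_sets.items():
        term_set = set(members) & set(universe)
        K = len(term_set)
        k = len(module & term_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "p_hyper": p})
    out = pd.DataFrame(rows)
    if out.empty:
        out["p_adj"] = []
        out["significant"] = []
        return out
    out["p_adj"] = bh_adjust(out["p_hyper"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out.sort_values("p_hyper").reset_index(drop=True)


@dataclass
class ROCResult:
    """Per-gene AUC: Mann-Whitney U with tie half-credit over n_pos*n_neg."""

    gene: object
    auc: float
    n_pos: int
    n_neg: int
    is_predictor: bool = field(init=False)

    def __post_init__(self) -> None:
        self.is_predictor = self.auc > AUC_PREDICTOR_MIN


def roc_auc(values, labels, orient: bool = False, gene: object = None) -> ROCResult:
    """AUC of per-sample scores against binary labels (positive = 1/True).

    Equals the Mann-Whitney U statistic with half-credit for ties divided
    by n_pos * n_neg.  ``orient=True`` reflects AUC below 0.5 so the
    reported value is >= 0.5.
    """
    y = np.asarray(labels).astype(int)
    x = np.asarray(values, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, x))
    if orient and auc < 0.5:
        auc = 1.0 - auc
    return ROCResult(gene=gene, auc=auc, n_pos=n_pos, n_neg=n_neg)


def roc_screen(
    expression: pd.DataFrame,
    labels: pd.Series,
    genes: set,
    positive_label: str,
    orient: bool = False,
) -> pd.DataFrame:
    """ROC/AUC per gene of ``genes`` from a normalised expression matrix."""
    labels = labels.loc[expression.columns]
    y = (labels == positive_label).astype(int)
    rows = []
    for gene in sorted(set(genes) & set(expression.index)):
        res = roc_auc(expression.loc[gene].to_numpy(), y.to_numpy(),
                      orient=orient, gene=gene)
        rows.append({"gene": gene, "auc": res.auc, "n_pos": res.n_pos,
                     "n_neg": res.n_neg, "is_predictor": res.is_predictor})
    return pd.DataFrame(rows, columns=["gene", "auc", "n_pos", "n_neg",
                                       "is_predictor"])


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, members per line."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sets[parts[0]] = set(parts[2:])
    return sets
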