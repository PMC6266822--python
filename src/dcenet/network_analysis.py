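"""Overlap networks, community clustering, degree reports and local ORA.

The overlap network is the edge-wise intersection of two group networks,
keeping only edges correlated in the same direction in both — the
co-expression behaviour shared across conditions. Communities are found by
modularity maximization (Girvan-Newman available as an alternative);
components and communities smaller than ``min_cluster_size`` stay
"unclustered", so isolated correlated pairs never masquerade as clusters.
Over-representation analysis is a local hypergeometric test over
user-supplied GMT gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import EDGE_COLUMNS, CoexpressionNetwork, GeneSetCollection
from .io import to_networkx

UNCLUSTERED = "unclustered"


def overlap_network(net_a: CoexpressionNetwork, net_b: CoexpressionNetwork) -> CoexpressionNetwork:
    """Edges present in both networks with the same correlation sign.

    Weight is the mean of the two parent weights, support the min of the
    parent supports; nodes are the incident genes only. Commutative and
    idempotent in edge set; the result's edges are a subset of each parent's.
    """
    if net_a.n_edges == 0 or net_b.n_edges == 0:
        return CoexpressionNetwork(None, provenance=_overlap_label(net_a, net_b))
    merged = net_a.edges.merge(net_b.edges, on=["source", "target"], suffixes=("_a", "_b"))
    merged = merged[merged["sign_a"] == merged["sign_b"]]
    edges = pd.DataFrame(
        {
            "source": merged["source"],
            "target": merged["target"],
            "weight": (merged["weight_a"] + merged["weight_b"]) / 2.0,
            "support": np.minimum(merged["support_a"], merged["support_b"]),
            "sign": merged["sign_a"],
        },
        columns=list(EDGE_COLUMNS),
    )
    return CoexpressionNetwork(edges, provenance=_overlap_label(net_a, net_b))


def _overlap_label(a: CoexpressionNetwork, b: CoexpressionNetwork) -> str:
    return f"overlap({a.provenance or 'A'},{b.provenance or 'B'})"


@dataclass
class ClusterAssignment:
    """gene -> cluster id (1-based, ordered by decreasing size) or 'unclustered'."""

    labels: dict[str, object]
    min_cluster_size: int
    algorithm: str

    def cluster(self, cid: int) -> list[str]:
        return sorted(g for g, c in self.labels.items() if c == cid)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted({c for c in self.labels.values() if c != UNCLUSTERED})

    @property
    def unclustered(self) -> list[str]:
        return sorted(g for g, c in self.labels.items() if c == UNCLUSTERED)

    def sizes(self) -> dict[int, int]:
        return {c: len(self.cluster(c)) for c in self.cluster_ids}

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("gene\tcluster\n")
            for g in sorted(self.labels):
                fh.write(f"{g}\t{self.labels[g]}\n")


COMMUNITY_ALGORITHMS = ("greedy-modularity", "girvan-newman")


def community_cluster(net: CoexpressionNetwork, min_cluster_size: int = 3,
                      seed: int = 0, algorithm: str = "greedy-modularity") -> ClusterAssignment:
    """Partition a network into communities by modularity maximization.

    Connected components with fewer than ``min_cluster_size`` nodes are
    labelled 'unclustered' (isolated correlated pairs stay out of the
    clustering, as do modularity communities that end up undersized). The
    remaining graph is partitioned on its unweighted topology. Deterministic
    given the canonical node order; ``seed`` is accepted for interface
    stability but the implemented algorithms are seed-free.
    """
    if algorithm not in COMMUNITY_ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {COMMUNITY_ALGORITHMS}")
    labels: dict[str, object] = {}
    g = to_networkx(net)
    big = []
    for comp in nx.connected_components(g):
        if len(comp) < min_cluster_size:
            for node in comp:
                labels[node] = UNCLUSTERED
        else:
            big.append(comp)
    communities: list[set] = []
    if big:
        sub = g.subgraph(set().union(*big))
        # canonical copy: sorted nodes/edges for order-independent results
        h = nx.Graph()
        h.add_nodes_from(sorted(sub.nodes))
        h.add_edges_from(sorted(tuple(sorted(e)) for e in sub.edges))
        if algorithm == "greedy-modularity":
            communities = [set(c) for c in nx.community.greedy_modularity_communities(h)]
        else:
            communities = _girvan_newman_best(h)
    kept = []
    for comm in communities:
        if len(comm) >= min_cluster_size:
            kept.append(comm)
        else:
            for node in comm:
                labels[node] = UNCLUSTERED
    kept.sort(key=lambda c: (-len(c), min(c)))
    for cid, comm in enumerate(kept, start=1):
        for node in comm:
            labels[node] = cid
    return ClusterAssignment(labels=labels, min_cluster_size=min_cluster_size, algorithm=algorithm)


def _girvan_newman_best(g: nx.Graph) -> list[set]:
    """Girvan-Newman split with the highest-modularity level."""
    best = [set(g.nodes)]
    best_q = nx.community.modularity(g, best) if g.number_of_edges() else 0.0
    for level in nx.community.girvan_newman(g):
        parts = [set(c) for c in level]
        q = nx.community.modularity(g, parts)
        if q > best_q:
            best, best_q = parts, q
    return best


def degree_report(net: CoexpressionNetwork) -> pd.Series:
    """Edge count per node, sorted by decreasing degree (ties by gene id)."""
    if net.n_edges == 0 and not net.nodes:
        return pd.Series(dtype=int, name="degree")
    g = to_networkx(net)
    deg = pd.Series(dict(g.degree()), name="degree").astype(int)
    return deg.sort_index().sort_values(ascending=False, kind="mergesort")


def ora(query, universe, collection: GeneSetCollection, min_overlap: int = 2,
        p_threshold: float = 0.01, min_genes: int = 0, min_fraction: float = 0.0) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` genes in each gene set.

    For a set S: K = |S ∩ universe|, k = |S ∩ query|, n = |query|,
    N = |universe|; p = P(X >= k) for X ~ Hypergeom(N, K, n). Rows are kept
    when k >= min_overlap, the number-or-percentage gate passes
    (k >= min_genes OR k/K >= min_fraction) and p <= p_threshold.
    ``adjusted_p`` is Benjamini-Hochberg over every set tested (all sets
    intersecting the universe), not only the reported rows.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        raise ValueError(f"query gene(s) absent from universe: {sorted(stray)[:5]}")
    n, N = len(query), len(universe)
    rows = []
    for name, entry in collection:
        members = entry["genes"] & universe
        K = len(members)
        if K == 0:
            continue
        hits = members & query
        k = len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {"set_name": name, "description": entry["description"], "overlap_count": k,
             "set_size_in_universe": K, "p_value": min(p, 1.0),
             "overlap_genes": ",".join(sorted(hits))}
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "description", "overlap_count", "set_size_in_universe",
                     "p_value", "adjusted_p", "overlap_genes"]
        )
    df = pd.DataFrame(rows)
    df["adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    keep = (
        (df["overlap_count"] >= min_overlap)
        & ((df["overlap_count"] >= min_genes)
           | (df["overlap_count"] / df["set_size_in_universe"] >= min_fraction))
        & (df["p_value"] <= p_threshold)
    )
    out = df[keep].sort_values(["p_value", "set_name"]).reset_index(drop=True)
    return out[["set_name", "description", "overlap_count", "set_size_in_universe",
                "p_value", "adjusted_p", "overlap_genes"]]
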