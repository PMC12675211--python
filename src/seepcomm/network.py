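"""Co-occurrence networks: abundant-ASV filter, Spearman+BH edges, topology.

Edges connect ASV pairs whose Spearman correlation across samples passes
|rho| >= rho_min with a Benjamini-Hochberg adjusted p below p_max; the
adjustment runs over the full upper triangle of tested pairs. Topology
reports the four metrics usually quoted for microbial networks: average
degree, average clustering coefficient, average path length (over connected
pairs) and greedy-partition modularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities, modularity
from scipy import stats
from scipy.stats import false_discovery_control

from .table import CommunityTable, relative_abundance

logger = logging.getLogger(__name__)

__all__ = ["TopologySummary", "filter_abundant", "build_network", "topology"]


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_clustering: float
    average_path_length: float
    modularity: float
    n_components: int

    def to_dict(self) -> dict:
        return asdict(self)


def filter_abundant(table: CommunityTable, threshold: float = 0.005) -> CommunityTable:
    """Keep ASVs whose mean relative abundance exceeds ``threshold``.

    The comparison is strict (>), and the threshold is a fraction: the
    default 0.005 keeps ASVs above 0.5% mean relative abundance.
    """
    rel = table if table.is_relative else relative_abundance(table)
    mean_ab = rel.data.mean(axis=1)
    keep = mean_ab > threshold
    if not keep.any():
        raise ValueError(
            f"no ASV exceeds mean relative abundance {threshold}; lower the threshold"
        )
    return CommunityTable(table.data.loc[keep].copy(), table.is_relative)


def _spearman_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided p (t approximation).

    Pearson correlation of average ranks row-wise; rows with zero rank
    variance yield NaN. The p-value uses the standard
    t = r sqrt((n-2)/(1-r^2)) approximation, with p = 0 at |r| = 1.
    """
    n = X.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        pval = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    pval[np.abs(rho) >= 1.0] = 0.0
    pval[np.isnan(rho)] = np.nan
    return rho, pval


def build_network(
    table: CommunityTable,
    rho_min: float = 0.6,
    p_max: float = 0.05,
    node_annotations: pd.DataFrame | None = None,
) -> nx.Graph:
    """Spearman co-occurrence graph over the table's ASVs.

    All pairwise Spearman correlations across samples are tested on the
    table's values as given (rank-based, so any per-sample monotone
    rescaling is immaterial); BH adjustment is applied to the upper
    triangle jointly; edges with |rho| >= rho_min and p_adj < p_max are
    kept. ASVs with constant abundance have undefined correlations: their
    node stays, their edges are skipped with a warning. Deterministic —
    no randomness involved.
    """
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples for meaningful Spearman p-values")
    ids = table.taxon_ids
    X = table.counts  # taxa x samples
    constant = X.std(axis=1) == 0
    if constant.any():
        logger.warning(
            "constant ASV(s), correlations undefined: %s",
            [t for t, c in zip(ids, constant) if c],
        )
    rho, pval = _spearman_matrix(X)

    iu = np.triu_indices(len(ids), 1)
    raw_p = pval[iu]
    ok = ~np.isnan(raw_p)
    adj_p = np.full_like(raw_p, np.nan)
    if ok.any():
        adj_p[ok] = false_discovery_control(raw_p[ok], method="bh")

    g = nx.Graph()
    rel = table if table.is_relative else relative_abundance(table)
    mean_ab = rel.data.mean(axis=1)
    for t in ids:
        attrs = {"mean_rel_abund": float(mean_ab[t])}
        if node_annotations is not None and t in node_annotations.index:
            attrs.update(node_annotations.loc[t].to_dict())
        g.add_node(t, **attrs)
    for (i, j, r, p_raw, p_adj) in zip(iu[0], iu[1], rho[iu], raw_p, adj_p):
        if np.isnan(r) or np.isnan(p_adj):
            continue
        if abs(r) >= rho_min and p_adj < p_max:
            g.add_edge(ids[i], ids[j], rho=float(r), p_raw=float(p_raw), p_adj=float(p_adj))
    return g


def topology(graph: nx.Graph) -> TopologySummary:
    """The four standard topology metrics plus component count.

    Average path length is the mean shortest-path distance over *connected*
    pairs only (pair-weighted across components); a graph with no connected
    pair reports 0. Modularity uses the greedy
    Clauset-Newman-Moore partition (deterministic); an edgeless graph
    reports modularity 0.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    e = graph.number_of_edges()
    avg_degree = 2.0 * e / n
    avg_clust = float(nx.average_clustering(graph)) if n else 0.0

    total_d = 0.0
    total_pairs = 0
    components = list(nx.connected_components(graph))
    for comp in components:
        if len(comp) < 2:
            continue
        sub = graph.subgraph(comp)
        for _, dists in nx.shortest_path_length(sub):
            total_d += sum(dists.values())
        total_pairs += len(comp) * (len(comp) - 1)
    avg_path = total_d / total_pairs if total_pairs else 0.0

    if e == 0:
        q = 0.0
    else:
        partition = greedy_modularity_communities(graph)
        q = float(modularity(graph, partition))
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        average_degree=avg_degree,
        average_clustering=avg_clust,
        average_path_length=avg_path,
        modularity=q,
        n_components=len(components),
    )
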