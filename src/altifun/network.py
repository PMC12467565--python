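"""Signed co-occurrence networks and their topology report.

Construction follows the dominant convention in the soil-microbiome
literature: taxa are aggregated to a rank (genus by default), low-prevalence
taxa are dropped, pairwise Spearman correlations are computed across
samples, and an edge is kept when |rho| clears a magnitude cutoff and its
Benjamini–Hochberg-adjusted p-value clears a significance cutoff. The edge
sign records whether the pair co-varies positively (putative cooperation)
or negatively (putative competition/exclusion); weights are |rho|.

Modularity is computed on unsigned weights with Louvain community
detection, taking the best of several seeded restarts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .config import spawn_seed
from .exceptions import UsageError
from .io import OtuTable

__all__ = [
    "CoNetwork",
    "TopologyReport",
    "build_conetwork",
    "topology",
    "average_degree",
    "graph_density",
]


@dataclass
class CoNetwork:
    """Undirected signed co-occurrence graph plus construction parameters."""

    graph: nx.Graph
    rank: str
    params: dict = field(default_factory=dict)
    n_taxa_prefilter: int = 0  # taxa entering the correlation step

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class TopologyReport:
    n_nodes: int
    n_links: int
    positive_links_pct: float
    negative_links_pct: float
    average_degree: float
    average_weighted_degree: float
    graph_density: float
    modularity: float | None  # None for an empty network (undefined)

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "Nodes": self.n_nodes,
                "Links": self.n_links,
                "Positive links %": round(self.positive_links_pct, 2),
                "Negative links %": round(self.negative_links_pct, 2),
                "Average degree": round(self.average_degree, 3),
                "Average weighted degree": round(self.average_weighted_degree, 3),
                "Graph density": round(self.graph_density, 3),
                "Modularity": None if self.modularity is None else round(self.modularity, 3),
            }
        )


def average_degree(n_nodes: int, n_links: int) -> float:
    """Closed-form mean degree 2L/N of an undirected graph."""
    if n_nodes <= 0:
        raise UsageError("need at least one node")
    return 2.0 * n_links / n_nodes


def graph_density(n_nodes: int, n_links: int) -> float:
    """Closed-form density 2L/(N(N-1)) of an undirected simple graph."""
    if n_nodes <= 1:
        raise UsageError("density needs at least two nodes")
    return 2.0 * n_links / (n_nodes * (n_nodes - 1))


def build_conetwork(
    tab: OtuTable,
    rank: str = "genus",
    method: str = "spearman",
    r_cut: float = 0.6,
    p_cut: float = 0.05,
    mtc: str = "bh",
    min_prevalence: float = 1.0 / 3.0,
) -> CoNetwork:
    """Build the signed co-occurrence network at ``rank``.

    Edge (a, b) is kept iff |rho_ab| >= r_cut and the BH-adjusted p-value
    <= p_cut. Isolated nodes are dropped from the graph; the number of taxa
    that entered the correlation step is kept on the result.
    """
    if method != "spearman":
        raise UsageError(f"unsupported correlation method {method!r}")
    if mtc != "bh":
        raise UsageError(f"unsupported multiple-testing correction {mtc!r}")
    n_samples = len(tab.sample_ids)
    if n_samples < 4:
        raise UsageError("co-occurrence networks need at least 4 samples")
    lineage = tab.lineage_at(rank)
    agg = tab.counts.groupby(lineage).sum()
    agg = agg.drop(index="Unclassified", errors="ignore")
    rel = agg / tab.counts.sum(axis=0)
    prevalence = (agg > 0).sum(axis=1) / n_samples
    rel = rel.loc[prevalence >= min_prevalence]
    n_pre = rel.shape[0]
    taxa = list(rel.index)
    g = nx.Graph()
    if n_pre >= 2:
        rho, pval = spearmanr(rel.to_numpy(), axis=1)
        rho = np.atleast_2d(rho)
        pval = np.atleast_2d(pval)
        iu = np.triu_indices(n_pre, k=1)
        p_flat = pval[iu]
        p_adj = multipletests(p_flat, method="fdr_bh")[1]
        keep = (np.abs(rho[iu]) >= r_cut) & (p_adj <= p_cut)
        phylum = _phylum_of_rank(tab, rank)
        for k in np.flatnonzero(keep):
            i, j = iu[0][k], iu[1][k]
            r = float(rho[i, j])
            for t in (taxa[i], taxa[j]):
                if t not in g:
                    g.add_node(t, phylum=phylum.get(t, "Unclassified"))
            g.add_edge(
                taxa[i],
                taxa[j],
                correlation=r,
                sign=1 if r > 0 else -1,
                weight=abs(r),
                p_adjusted=float(p_adj[k]),
            )
    params = {
        "rank": rank,
        "method": method,
        "r_cut": r_cut,
        "p_cut": p_cut,
        "mtc": mtc,
        "min_prevalence": min_prevalence,
    }
    return CoNetwork(g, rank, params, n_taxa_prefilter=n_pre)


def _phylum_of_rank(tab: OtuTable, rank: str) -> dict[str, str]:
    """Map each rank-level taxon to the phylum of its member OTUs (modal)."""
    if "phylum" not in tab.taxonomy.columns:
        return {}
    df = pd.DataFrame({"r": tab.lineage_at(rank), "p": tab.taxonomy["phylum"]})
    return {
        name: sub["p"].mode().iloc[0] if len(sub) else "Unclassified"
        for name, sub in df.groupby("r")
    }


def topology(net: CoNetwork, seed: int = 0, n_restarts: int = 10) -> TopologyReport:
    """Topology summary: link counts and signs, mean (weighted) degree,
    density, and Louvain modularity on absolute weights (best of
    ``n_restarts`` seeded restarts)."""
    g = net.graph
    n, l = g.number_of_nodes(), g.number_of_edges()
    if n == 0 or l == 0:
        return TopologyReport(n, l, 0.0, 0.0, 0.0, 0.0, 0.0, None)
    signs = np.array([d["sign"] for _, _, d in g.edges(data=True)])
    pos_pct = 100.0 * (signs > 0).sum() / l
    neg_pct = 100.0 - pos_pct
    total_weight = sum(d.get("weight", 1.0) for _, _, d in g.edges(data=True))
    avg_wdeg = 2.0 * total_weight / n
    best = -np.inf
    for i in range(n_restarts):
        comms = nx.community.louvain_communities(
            g, weight="weight", seed=spawn_seed(seed, f"louvain-{i}")
        )
        q = nx.community.modularity(g, comms, weight="weight")
        best = max(best, q)
    density = graph_density(n, l) if n > 1 else 0.0
    return TopologyReport(
        n_nodes=n,
        n_links=l,
        positive_links_pct=float(pos_pct),
        negative_links_pct=float(neg_pct),
        average_degree=average_degree(n, l),
        average_weighted_degree=float(avg_wdeg),
        graph_density=float(density),
        modularity=float(best),
    )
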