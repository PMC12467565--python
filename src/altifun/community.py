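"""Relative abundance, alpha/beta diversity, ordination and ANOSIM.

Alpha diversity follows the usual amplicon conventions: bias-corrected
Chao1 and ACE (rare-abundance cutoff 10) from integer counts, Shannon
entropy in nats and the Gini–Simpson index from proportions. Community
dissimilarity is Bray–Curtis; ordination is classical PCoA (Gower double
centering) and group separation is tested with ANOSIM on midranked
distances.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio.diversity.alpha import ace as _skbio_ace
from skbio.diversity.alpha import chao1 as _skbio_chao1

from .config import substream
from .exceptions import DegenerateInputError, UsageError
from .io import OtuTable

__all__ = [
    "AbundanceTable",
    "Ordination",
    "aggregate_relative_abundance",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "anosim",
    "anosim_r",
]


@dataclass
class AbundanceTable:
    """Relative abundances aggregated at a taxonomic rank (columns sum to 1)."""

    proportions: pd.DataFrame  # taxa-at-rank × samples
    rank: str
    groups: pd.Series  # sample → group label

    def group_means(self) -> pd.DataFrame:
        """Mean proportion per taxon within each sample group."""
        return self.proportions.T.groupby(self.groups.loc[self.proportions.columns]).mean().T


@dataclass
class Ordination:
    coordinates: pd.DataFrame  # samples × axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives retained)
    proportion_explained: np.ndarray  # per retained axis, over positive eigenvalues


def aggregate_relative_abundance(tab: OtuTable, rank: str = "phylum") -> AbundanceTable:
    """Sum counts within each taxon at ``rank`` and divide by sample totals."""
    totals = tab.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DegenerateInputError(f"all-zero samples: {list(zero.index)}")
    lineage = tab.lineage_at(rank)
    grouped = tab.counts.groupby(lineage).sum()
    props = grouped / totals
    return AbundanceTable(props, rank, tab.groups.copy())


def _alpha_one(counts: np.ndarray) -> dict[str, float]:
    pos = counts[counts > 0]
    p = pos / pos.sum()
    return {
        "observed": float(len(pos)),
        "chao1": float(_skbio_chao1(counts.astype(int), bias_corrected=True)),
        "ace": float(_skbio_ace(counts.astype(int), rare_threshold=10)),
        "shannon": float(-(p * np.log(p)).sum()),
        "simpson": float(1.0 - (p**2).sum()),
    }


def alpha_diversity(tab: OtuTable) -> pd.DataFrame:
    """Per-sample observed richness, Chao1, ACE, Shannon (nats), Gini–Simpson.

    Chao1 uses the bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) so tables
    without doubletons stay finite; ACE uses the standard rare cutoff of 10.
    """
    arr = tab.counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise UsageError("alpha diversity estimators need integer counts")
    rows = {}
    for j, s in enumerate(tab.sample_ids):
        col = arr[:, j]
        if col.sum() == 0:
            raise DegenerateInputError(f"sample {s!r} has zero total count")
        rows[s] = _alpha_one(col)
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(tab) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity between samples.

    Accepts an :class:`OtuTable` or :class:`AbundanceTable` (or any
    DataFrame with samples as columns).
    """
    if isinstance(tab, OtuTable):
        mat = tab.counts
    elif isinstance(tab, AbundanceTable):
        mat = tab.proportions
    else:
        mat = tab
    if mat.shape[1] < 2:
        raise UsageError("need at least 2 samples")
    x = mat.to_numpy(dtype=float).T  # samples × taxa
    sums = x.sum(axis=1)
    if (sums == 0).sum() >= 2:
        raise DegenerateInputError("Bray–Curtis undefined between two all-zero samples")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=mat.columns, columns=mat.columns)


def _check_distance(d: pd.DataFrame) -> np.ndarray:
    a = d.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise UsageError("distance matrix must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise UsageError("distance matrix must be symmetric")
    if not np.allclose(np.diag(a), 0, atol=1e-10):
        raise UsageError("distance matrix must have a zero diagonal")
    return a


def pcoa(d: pd.DataFrame, n_axes: int | None = None) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Negative eigenvalues of the Gower-centered matrix are retained in the
    report but excluded from the coordinates; proportions explained are
    taken over the sum of positive eigenvalues.
    """
    a = _check_distance(d)
    n = a.shape[0]
    b = -0.5 * a**2
    row = b.mean(axis=1, keepdims=True)
    col = b.mean(axis=0, keepdims=True)
    g = b - row - col + b.mean()
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-10 * abs(vals).max(initial=1.0))
    n_pos = int(pos.sum())
    k = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    prop = vals[:k] / vals[pos].sum() if n_pos else np.zeros(0)
    cols = [f"PCo{i+1}" for i in range(k)]
    return Ordination(pd.DataFrame(coords, index=d.index, columns=cols), vals, prop)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def _anosim_r_from_ranks(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim_r(d: pd.DataFrame, groups) -> float:
    """ANOSIM R statistic with midranked distances (no permutation test)."""
    a = _check_distance(d)
    g = np.asarray(pd.Series(groups).loc[list(d.index)])
    iu = np.triu_indices(a.shape[0], k=1)
    ranks = rankdata(a[iu])  # midranks for ties
    within = g[iu[0]] == g[iu[1]]
    if within.all() or (~within).all():
        raise UsageError("need both within- and between-group pairs")
    return _anosim_r_from_ranks(ranks, within)


def anosim(d: pd.DataFrame, groups, n_permutations: int = 999, seed: int = 0) -> dict:
    """ANOSIM permutation test of between-group separation on a distance matrix.

    R = (mean between-group rank − mean within-group rank) / (M/4) with
    M = n(n−1)/2; the p-value is (1 + #{perm R ≥ observed R}) /
    (1 + n_permutations) under random relabeling of samples.
    """
    if n_permutations < 99:
        raise UsageError("n_permutations must be >= 99")
    a = _check_distance(d)
    g = np.asarray(pd.Series(groups).loc[list(d.index)])
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise UsageError("need at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2]
        raise UsageError(f"groups with fewer than 2 samples: {list(small)}")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks_condensed = rankdata(a[iu])
    rank_mat = np.zeros((n, n))
    rank_mat[iu] = ranks_condensed
    rank_mat = rank_mat + rank_mat.T
    within_obs = g[iu[0]] == g[iu[1]]
    r_obs = _anosim_r_from_ranks(ranks_condensed, within_obs)
    rng = substream(seed, "anosim")
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[perm]
        within = gp[iu[0]] == gp[iu[1]]
        r = _anosim_r_from_ranks(ranks_condensed, within)
        if r >= r_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return {"R": r_obs, "p": float(p), "n_permutations": n_permutations}
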