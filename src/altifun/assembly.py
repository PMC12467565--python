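"""Null-model partitioning of community assembly into five ecological processes.

The framework is the standard two-step phylogenetic/taxonomic null-model
analysis. For each pair of communities:

1. betaMNTD — the (abundance-weighted) mean phylogenetic distance from each
   taxon to its nearest relative in the other community — is compared with
   a null distribution obtained by shuffling taxon labels across the tips
   of the phylogeny. The standardized deviate is betaNTI; |betaNTI| > 2
   signals deterministic selection (heterogeneous if > +2: communities more
   phylogenetically divergent than expected; homogeneous if < −2).
2. Pairs not resolved by selection are classified with the Raup–Crick
   metric on Bray–Curtis, RC(Bray) in [−1, 1], computed against null
   communities that preserve each sample's richness and total abundance
   while drawing taxa by occurrence frequency and filling abundances from
   the regional relative-abundance pool. RC > +0.95 indicates dispersal
   limitation, RC < −0.95 homogenizing dispersal, and the residual pairs
   are attributed to drift and other processes.

betaNTI assumes phylogenetic niche conservatism: traits governing habitat
preference must be more similar among close relatives, otherwise deviation
from the tip-shuffling null carries no ecological signal.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .config import substream
from .exceptions import DegenerateInputError, UsageError
from .io import OtuTable

log = logging.getLogger(__name__)

PROCESSES = [
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift_and_others",
]

__all__ = [
    "PROCESSES",
    "AssemblyResult",
    "patristic_matrix",
    "beta_mntd",
    "beta_nti",
    "raup_crick_bray",
    "partition_processes",
]


@dataclass
class AssemblyResult:
    """Pairwise betaNTI / RC(Bray) matrices and per-group process fractions."""

    bnti: pd.DataFrame
    rc: pd.DataFrame
    fractions: pd.DataFrame  # group × process, rows sum to 1
    dominant: pd.Series  # group → "deterministic" | "stochastic"
    n_pairs: pd.Series  # group → number of classified pairs


def patristic_matrix(tree: skbio.TreeNode, taxa: list[str]) -> np.ndarray:
    """Tip-to-tip patristic distance matrix aligned to ``taxa`` order."""
    dm = tree.tip_tip_distances()
    try:
        idx = [dm.index(t) for t in taxa]
    except KeyError as exc:
        tips = set(dm.ids)
        missing = sorted(set(taxa) - tips)
        raise UsageError(f"taxa missing from tree: {missing}") from exc
    d = dm.data[np.ix_(idx, idx)]
    return np.asarray(d, dtype=float)


def _pair_list(sample_ids, pairs):
    if pairs is None:
        return list(itertools.combinations(sample_ids, 2))
    return [tuple(p) for p in pairs]


def _pair_mntd(d: np.ndarray, ia: np.ndarray, ja: np.ndarray,
               wi: np.ndarray, wj: np.ndarray) -> float:
    sub = d[np.ix_(ia, ja)]
    return 0.5 * (sub.min(axis=1) @ wi + sub.min(axis=0) @ wj)


def beta_mntd(tab: OtuTable, tree: skbio.TreeNode, weighted: bool = True) -> pd.DataFrame:
    """Between-sample mean nearest-taxon phylogenetic distance.

    For samples i, j: the mean over taxa present in i of the distance to the
    nearest taxon present in j, averaged with the reverse direction.
    ``weighted`` uses relative abundances as weights, otherwise presence
    weights 1/richness.
    """
    taxa = tab.taxon_ids
    present_any = tab.counts.sum(axis=1) > 0
    missing = sorted(
        set(np.asarray(taxa)[present_any.to_numpy()]) - {t.name for t in tree.tips()}
    )
    if missing:
        raise UsageError(f"taxa missing from tree: {missing}")
    d = patristic_matrix(tree, taxa)
    x = tab.counts.to_numpy(dtype=float)
    samples = tab.sample_ids
    n = len(samples)
    out = np.zeros((n, n))
    idx = [np.flatnonzero(x[:, k] > 0) for k in range(n)]
    w = []
    for k in range(n):
        col = x[idx[k], k]
        w.append(col / col.sum() if weighted else np.full(len(col), 1.0 / len(col)))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _pair_mntd(d, idx[i], idx[j], w[i], w[j])
    return pd.DataFrame(out, index=samples, columns=samples)


def beta_nti(
    tab: OtuTable,
    tree: skbio.TreeNode,
    n_nulls: int = 999,
    seed: int = 0,
    weighted: bool = True,
    pairs=None,
) -> pd.DataFrame:
    """Standardized deviation of betaMNTD from a tip-shuffling null.

    betaNTI(i,j) = (obs − mean_null) / sd_null over ``n_nulls`` random
    permutations of taxon labels across tree tips. Pairs whose null has
    zero spread (e.g. on a star phylogeny) are undefined and returned as
    NaN with a logged warning. ``pairs`` restricts computation to the
    listed sample pairs (others are NaN), which the per-group partition
    uses to skip between-group pairs.
    """
    if n_nulls < 99:
        raise UsageError("n_nulls must be >= 99")
    taxa = tab.taxon_ids
    n_taxa = len(taxa)
    d = patristic_matrix(tree, taxa)
    x = tab.counts.to_numpy(dtype=float)
    samples = tab.sample_ids
    pos = {s: k for k, s in enumerate(samples)}
    rng = substream(seed, "beta_nti")
    perms = np.array([rng.permutation(n_taxa) for _ in range(n_nulls)])
    idx = [np.flatnonzero(x[:, k] > 0) for k in range(len(samples))]
    weights = []
    for k in range(len(samples)):
        col = x[idx[k], k]
        weights.append(col / col.sum() if weighted else np.full(len(col), 1.0 / len(col)))
    out = pd.DataFrame(np.nan, index=samples, columns=samples)
    np.fill_diagonal(out.values, 0.0)
    n_flagged = 0
    for si, sj in _pair_list(samples, pairs):
        i, j = pos[si], pos[sj]
        ia, ja, wi, wj = idx[i], idx[j], weights[i], weights[j]
        obs = _pair_mntd(d, ia, ja, wi, wj)
        nulls = np.empty(n_nulls)
        # chunk the permutations so the (chunk, |i|, |j|) block stays small
        chunk = max(1, int(4e6 // max(1, len(ia) * len(ja))))
        for lo in range(0, n_nulls, chunk):
            p = perms[lo : lo + chunk]
            rows = p[:, ia]  # (c, |i|)
            cols = p[:, ja]  # (c, |j|)
            sub = d[rows[:, :, None], cols[:, None, :]]
            nulls[lo : lo + len(p)] = 0.5 * (
                sub.min(axis=2) @ wi + sub.min(axis=1) @ wj
            )
        sd = nulls.std(ddof=1)
        if sd < 1e-12:
            n_flagged += 1
            continue  # undefined: left NaN
        val = (obs - nulls.mean()) / sd
        out.loc[si, sj] = out.loc[sj, si] = val
    if n_flagged:
        log.warning("betaNTI undefined (zero null spread) for %d pairs", n_flagged)
    return out


def _bray(x1: np.ndarray, x2: np.ndarray) -> float:
    s = x1.sum() + x2.sum()
    return float(np.abs(x1 - x2).sum() / s) if s else np.nan


def raup_crick_bray(
    tab: OtuTable, n_nulls: int = 999, seed: int = 0, pairs=None
) -> pd.DataFrame:
    """Raup–Crick metric on Bray–Curtis against a richness- and
    abundance-preserving null.

    Null communities keep each sample's observed richness and total count;
    taxa are drawn without replacement with probability proportional to
    their occurrence frequency across samples, seeded with one individual
    each, and the remaining individuals are assigned multinomially in
    proportion to regional relative abundance. RC = 2·[P(null < obs) +
    0.5·P(null = obs)] − 1, so RC ∈ [−1, 1].
    """
    if n_nulls < 99:
        raise UsageError("n_nulls must be >= 99")
    x = tab.counts.to_numpy(dtype=float)
    samples = tab.sample_ids
    pos = {s: k for k, s in enumerate(samples)}
    n_taxa = x.shape[0]
    occ = (x > 0).sum(axis=1).astype(float)
    pool = x.sum(axis=1)
    pool_p = pool / pool.sum()
    rng = substream(seed, "raup_crick")
    out = pd.DataFrame(np.nan, index=samples, columns=samples)
    np.fill_diagonal(out.values, 0.0)
    richness = (x > 0).sum(axis=0)
    totals = x.sum(axis=0)
    log_occ = np.full(n_taxa, -np.inf)
    log_occ[occ > 0] = np.log(occ[occ > 0])

    def null_batch(n_s: int, total: int) -> np.ndarray:
        """(n_nulls, n_taxa) null count matrix for one community profile."""
        gumbel = rng.gumbel(size=(n_nulls, n_taxa))
        keys = log_occ[None, :] + gumbel
        chosen = np.argpartition(keys, -n_s, axis=1)[:, -n_s:]
        counts = np.zeros((n_nulls, n_taxa))
        extra = int(total - n_s)
        for r in range(n_nulls):
            sel = chosen[r]
            counts[r, sel] = 1.0
            if extra > 0:
                p = pool_p[sel]
                counts[r, sel] += rng.multinomial(extra, p / p.sum())
        return counts

    for si, sj in _pair_list(samples, pairs):
        i, j = pos[si], pos[sj]
        if richness[i] < 2 or richness[j] < 2:
            continue  # flagged pair: left NaN
        obs = _bray(x[:, i], x[:, j])
        n1 = null_batch(int(richness[i]), int(totals[i]))
        n2 = null_batch(int(richness[j]), int(totals[j]))
        s = n1.sum(axis=1) + n2.sum(axis=1)
        null_bc = np.abs(n1 - n2).sum(axis=1) / s
        less = (null_bc < obs - 1e-12).sum()
        equal = (np.abs(null_bc - obs) <= 1e-12).sum()
        rc = 2.0 * ((less + 0.5 * equal) / n_nulls) - 1.0
        out.loc[si, sj] = out.loc[sj, si] = rc
    return out


def partition_processes(
    bnti: pd.DataFrame,
    rc: pd.DataFrame,
    groups,
    bnti_cut: float = 2.0,
    rc_cut: float = 0.95,
) -> AssemblyResult:
    """Classify each within-group sample pair into one of five processes
    and report per-group fractions.

    A pair is heterogeneous selection if betaNTI > +cut, homogeneous
    selection if betaNTI < −cut; otherwise dispersal limitation if
    RC > +rc_cut, homogenizing dispersal if RC < −rc_cut, else drift and
    other processes. A group is "deterministic" when the two selection
    fractions sum above 0.5, else "stochastic". Pairs with undefined
    betaNTI (NaN) are excluded from the fractions with a warning.
    """
    if list(bnti.index) != list(rc.index):
        raise UsageError("betaNTI and RC matrices must share sample ids")
    g = pd.Series(groups).loc[list(bnti.index)]
    rows = {}
    npairs = {}
    n_dropped = 0
    for grp, members in g.groupby(g):
        ids = list(members.index)
        tally = dict.fromkeys(PROCESSES, 0)
        used = 0
        for a, b in itertools.combinations(ids, 2):
            v_b, v_r = bnti.loc[a, b], rc.loc[a, b]
            if np.isnan(v_b) or np.isnan(v_r):
                n_dropped += 1
                continue
            if v_b > bnti_cut:
                tally["heterogeneous_selection"] += 1
            elif v_b < -bnti_cut:
                tally["homogeneous_selection"] += 1
            elif v_r > rc_cut:
                tally["dispersal_limitation"] += 1
            elif v_r < -rc_cut:
                tally["homogenizing_dispersal"] += 1
            else:
                tally["drift_and_others"] += 1
            used += 1
        if used:
            rows[grp] = {k: v / used for k, v in tally.items()}
            npairs[grp] = used
    if n_dropped:
        log.warning("%d pairs excluded from process fractions (undefined)", n_dropped)
    if not rows:
        raise DegenerateInputError("no classifiable sample pairs in any group")
    fractions = pd.DataFrame.from_dict(rows, orient="index")[PROCESSES]
    selection = fractions["heterogeneous_selection"] + fractions["homogeneous_selection"]
    dominant = pd.Series(
        np.where(selection > 0.5, "deterministic", "stochastic"), index=fractions.index
    )
    return AssemblyResult(bnti, rc, fractions, dominant, pd.Series(npairs))
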