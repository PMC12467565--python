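"""Group comparison (one-way ANOVA with LSD letters) and redundancy analysis.

The compact-letter display follows the common greedy-insertion scheme:
groups are sorted by mean and a letter is laid over every maximal run of
groups that are mutually non-significant under pairwise LSD t-tests with
the pooled ANOVA mean square error. Groups sharing a letter are therefore
never significantly different at the chosen alpha.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, UsageError

__all__ = ["AnovaLsdResult", "RdaResult", "anova_lsd", "lsd_letters", "hellinger", "rda"]


@dataclass
class AnovaLsdResult:
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    group_means: pd.Series
    letters: pd.Series  # group → compact letter display
    pairwise_p: pd.DataFrame
    alpha: float


@dataclass
class RdaResult:
    eigenvalues: np.ndarray  # constrained axes, descending
    proportion_explained: float  # constrained / total variance
    axis_proportions: np.ndarray  # per constrained axis, over total variance
    site_scores: pd.DataFrame  # plots × axes
    species_scores: pd.DataFrame  # response columns × axes
    biplot_scores: pd.DataFrame  # explanatory variables × axes (correlations)


def anova_lsd(values, groups, alpha: float = 0.05) -> AnovaLsdResult:
    """One-way ANOVA followed by Fisher's LSD pairwise tests and letters.

    LSD t statistics use the pooled within-group mean square with N − k
    degrees of freedom.
    """
    v = pd.Series(values, dtype=float)
    g = pd.Series(groups).loc[v.index] if hasattr(groups, "loc") else pd.Series(
        list(groups), index=v.index
    )
    levels = list(dict.fromkeys(g))
    sizes = g.value_counts()
    if len(levels) < 2:
        raise UsageError("need at least 2 groups")
    if (sizes < 2).any():
        raise UsageError(f"groups with fewer than 2 replicates: "
                         f"{sorted(sizes.index[sizes < 2])}")
    n, k = len(v), len(levels)
    means = v.groupby(g).mean().loc[levels]
    sse = float(((v - means.loc[g].to_numpy()) ** 2).sum())
    ssb = float((sizes.loc[levels] * (means - v.mean()) ** 2).sum())
    df_b, df_w = k - 1, n - k
    mse = sse / df_w
    if mse == 0:
        raise DegenerateInputError("zero within-group variance everywhere; F undefined")
    f_stat = (ssb / df_b) / mse
    p_val = float(stats.f.sf(f_stat, df_b, df_w))
    pw = pd.DataFrame(1.0, index=levels, columns=levels)
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            se = np.sqrt(mse * (1 / sizes[a] + 1 / sizes[b]))
            t = (means[a] - means[b]) / se
            p = 2 * stats.t.sf(abs(t), df_w)
            pw.loc[a, b] = pw.loc[b, a] = p
    letters = lsd_letters(means, pw, alpha)
    return AnovaLsdResult(float(f_stat), (df_b, df_w), p_val, means, letters, pw, alpha)


def lsd_letters(means: pd.Series, pairwise_p: pd.DataFrame, alpha: float) -> pd.Series:
    """Compact letter display by greedy insertion over mean-sorted groups.

    A letter covers each maximal interval (in descending-mean order) whose
    members are all mutually non-significant; intervals nested in an
    earlier one are absorbed.
    """
    order = list(means.sort_values(ascending=False).index)
    m = len(order)
    nonsig = pairwise_p.loc[order, order].to_numpy() > alpha
    intervals: list[tuple[int, int]] = []
    for i in range(m):
        j = i
        while j + 1 < m and nonsig[np.ix_(range(i, j + 2), range(i, j + 2))].all():
            j += 1
        if not any(a <= i and j <= b for a, b in intervals):
            intervals.append((i, j))
    letters = {grp: "" for grp in order}
    for letter_i, (a, b) in enumerate(intervals):
        ch = chr(ord("a") + letter_i)
        for idx in range(a, b + 1):
            letters[order[idx]] += ch
    return pd.Series(letters).loc[means.index]


def hellinger(rel: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform of a plots × taxa relative-abundance matrix."""
    row_sums = rel.sum(axis=1).replace(0, np.nan)
    return np.sqrt(rel.div(row_sums, axis=0))


def rda(Y: pd.DataFrame, X: pd.DataFrame, scale_y: bool = False,
        scale_x: bool = True) -> RdaResult:
    """Redundancy analysis: constrained ordination of Y on X.

    Y and X are centered (optionally standardized); the fitted values of
    the multivariate regression of Y on X are eigen-decomposed, giving the
    constrained axes. The proportion explained is the trace ratio
    var(fitted)/var(Y); biplot scores are correlations of the explanatory
    variables with the constrained site scores.
    """
    if list(Y.index) != list(X.index):
        raise UsageError("Y and X must share plot ids in order")
    n = Y.shape[0]
    if n <= X.shape[1]:
        raise UsageError("need more plots than explanatory variables")
    yc = Y.to_numpy(dtype=float) - Y.to_numpy(dtype=float).mean(axis=0)
    xc = X.to_numpy(dtype=float) - X.to_numpy(dtype=float).mean(axis=0)
    if scale_y:
        sd = yc.std(axis=0, ddof=1)
        yc = yc / np.where(sd == 0, 1, sd)
    if scale_x:
        sd = xc.std(axis=0, ddof=1)
        if (sd == 0).any():
            cols = list(X.columns[sd == 0])
            raise UsageError(f"constant explanatory columns: {cols}")
        xc = xc / sd
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        # name a minimal set of columns that complete the collinearity
        _, r = np.linalg.qr(xc)
        dep = [X.columns[i] for i in range(xc.shape[1]) if abs(r[i, i]) < 1e-8]
        raise UsageError(f"explanatory matrix is rank deficient; collinear columns: {dep}")
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ beta
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > max(1e-12, 1e-10 * eig.max(initial=1.0))
    eig = eig[keep]
    u, s, vt = u[:, keep], s[keep], vt[keep]
    total_var = (yc**2).sum() / (n - 1)
    prop = float(eig.sum() / total_var)
    axes = [f"RDA{i+1}" for i in range(len(eig))]
    site = pd.DataFrame(u * s, index=Y.index, columns=axes)
    species = pd.DataFrame(vt.T, index=Y.columns, columns=axes)
    biplot = pd.DataFrame(index=X.columns, columns=axes, dtype=float)
    for i, ax in enumerate(axes):
        sc = site[ax].to_numpy()
        denom = np.linalg.norm(sc) * np.linalg.norm(xc, axis=0)
        biplot[ax] = (xc.T @ sc) / np.where(denom == 0, 1, denom)
    return RdaResult(eig, prop, eig / total_var, site, species, biplot)
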