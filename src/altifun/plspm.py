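"""Partial least squares path modeling (PLS-PM), mode A, centroid scheme.

Latent variables are estimated by alternating outer approximation (each
block's score is a weighted sum of its standardized manifest indicators;
mode-A weights are the correlations of each manifest with the block's
inner estimate) and inner approximation (centroid scheme: each block's
inner estimate is the sign-of-correlation-weighted sum of the scores of
the blocks it is connected to in the path diagram), iterated until the
outer weights stabilize. Path coefficients are then ordinary least squares
regressions of each endogenous block's standardized score on its
predecessors' scores, so they are standardized partial coefficients.
Bootstrap resampling of plots gives standard errors and two-sided normal
approximation p-values per path.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import substream
from .exceptions import UsageError

__all__ = ["PathModel", "plspm", "validate_path_matrix"]


@dataclass
class PathModel:
    blocks: dict[str, list[str]]
    path_matrix: pd.DataFrame  # [target, source] = 1 where source → target
    scores: pd.DataFrame  # plots × blocks, standardized
    outer_weights: dict[str, pd.Series]
    paths: pd.DataFrame  # [target, source] estimated coefficient (NaN if absent)
    path_table: pd.DataFrame  # tidy: source, target, estimate, boot_se, p
    r_squared: pd.Series  # endogenous block → R²
    communality: pd.Series  # block → mean squared loading
    gof: float
    n_iter: int
    converged: bool = True
    boot_paths: pd.DataFrame | None = field(default=None, repr=False)


def validate_path_matrix(path_matrix: pd.DataFrame, block_names: list[str]) -> pd.DataFrame:
    """Check the inner model is a DAG over the blocks; returns a 0/1 frame."""
    pm = path_matrix.reindex(index=block_names, columns=block_names).fillna(0)
    pm = (pm.astype(float) != 0).astype(int)
    # Kahn's algorithm; pm[t, s] = 1 means s → t
    indeg = pm.sum(axis=1).to_dict()
    queue = [b for b in block_names if indeg[b] == 0]
    seen = 0
    while queue:
        b = queue.pop()
        seen += 1
        for t in block_names:
            if pm.loc[t, b]:
                indeg[t] -= 1
                if indeg[t] == 0:
                    queue.append(t)
    if seen != len(block_names):
        raise UsageError("inner path matrix has a cycle")
    return pm


def _standardize(a: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise UsageError("constant manifest variable (zero variance)")
    return a / sd


def _fit_once(x_blocks, connect, tol, max_iter):
    """Core alternating algorithm on standardized per-block matrices."""
    k = len(x_blocks)
    weights = [np.ones(x.shape[1]) for x in x_blocks]
    scores = np.column_stack(
        [_norm_score(x, w) for x, w in zip(x_blocks, weights)]
    )
    for it in range(1, max_iter + 1):
        corr = np.corrcoef(scores, rowvar=False) if k > 1 else np.ones((1, 1))
        inner_w = np.sign(corr) * connect  # centroid scheme
        z = scores @ inner_w
        new_weights = []
        for j, x in enumerate(x_blocks):
            if not connect[j].any():  # isolated block keeps its weights
                new_weights.append(weights[j])
                continue
            zj = z[:, j]
            sd = zj.std(ddof=1)
            if sd == 0:
                new_weights.append(weights[j])
                continue
            w = x.T @ ((zj - zj.mean()) / sd) / (x.shape[0] - 1)  # mode A
            new_weights.append(w)
        # sign convention: each block's score correlates positively with the
        # unweighted sum of its manifests
        aligned = []
        for x, w in zip(x_blocks, new_weights):
            s = x @ w
            ref = x.sum(axis=1)
            if np.dot(s - s.mean(), ref - ref.mean()) < 0:
                w = -w
            aligned.append(w)
        new_scores = np.column_stack(
            [_norm_score(x, w) for x, w in zip(x_blocks, aligned)]
        )
        delta = max(
            np.abs(_unit(wn) - _unit(wo)).max() for wn, wo in zip(aligned, weights)
        )
        weights, scores = aligned, new_scores
        if delta < tol:
            return weights, scores, it, True
    return weights, scores, max_iter, False


def _unit(w: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(w)
    return w / n if n else w


def _norm_score(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    s = x @ w
    sd = s.std(ddof=1)
    if sd == 0:
        raise UsageError("degenerate latent score (zero variance)")
    return (s - s.mean()) / sd


def _paths_from_scores(scores: np.ndarray, pm: np.ndarray):
    k = scores.shape[1]
    paths = np.full((k, k), np.nan)
    r2 = np.full(k, np.nan)
    for t in range(k):
        preds = np.flatnonzero(pm[t])
        if len(preds) == 0:
            continue
        xp = scores[:, preds]
        beta, *_ = np.linalg.lstsq(xp, scores[:, t], rcond=None)
        paths[t, preds] = beta
        resid = scores[:, t] - xp @ beta
        r2[t] = 1.0 - resid.var(ddof=0) / scores[:, t].var(ddof=0)
    return paths, r2


def plspm(
    data: pd.DataFrame,
    blocks: dict[str, list[str]],
    path_matrix: pd.DataFrame,
    scheme: str = "centroid",
    tol: float = 1e-6,
    max_iter: int = 300,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> PathModel:
    """Fit a PLS path model.

    Parameters
    ----------
    data:
        Plot × manifest matrix containing every column named in ``blocks``.
    blocks:
        Ordered map latent-block name → list of manifest columns (each ≥ 1;
        single-indicator blocks pass through as standardized scores).
    path_matrix:
        0/1 DataFrame over block names; ``path_matrix.loc[target, source]``
        = 1 declares the directed path source → target. Must be acyclic.
    n_bootstrap:
        Number of bootstrap resamples for per-path standard errors and
        two-sided p-values (0 disables).
    """
    if scheme != "centroid":
        raise UsageError(f"unsupported inner scheme {scheme!r}")
    names = list(blocks)
    if not names:
        raise UsageError("no blocks")
    for b, cols in blocks.items():
        if len(cols) == 0:
            raise UsageError(f"block {b!r} has no manifest variables")
        missing = set(cols) - set(data.columns)
        if missing:
            raise UsageError(f"block {b!r} manifests missing from data: {sorted(missing)}")
    pm_df = validate_path_matrix(path_matrix, names)
    pm = pm_df.to_numpy()
    connect = ((pm + pm.T) > 0).astype(float)
    x_blocks = [_standardize(data[blocks[b]].to_numpy(dtype=float)) for b in names]
    weights, scores, n_iter, ok = _fit_once(x_blocks, connect, tol, max_iter)
    if not ok:
        raise UsageError(
            f"PLS-PM did not converge in {max_iter} iterations (tol={tol})"
        )
    paths, r2 = _paths_from_scores(scores, pm)
    communality = {}
    for j, b in enumerate(names):
        loadings = x_blocks[j].T @ scores[:, j] / (len(data) - 1)
        communality[b] = float((loadings**2).mean())
    endo = pm.any(axis=1)
    mean_comm = float(np.mean([communality[b] for b in names]))
    mean_r2 = float(np.nanmean(r2[endo])) if endo.any() else np.nan
    gof = float(np.sqrt(mean_comm * mean_r2)) if endo.any() else np.nan
    # ---- bootstrap ----
    boot_df = None
    rows = []
    if n_bootstrap > 0:
        rng = substream(seed, "plspm-bootstrap")
        n = len(data)
        edge_idx = [(t, s) for t in range(len(names)) for s in range(len(names)) if pm[t, s]]
        boot = np.full((n_bootstrap, len(edge_idx)), np.nan)
        for r in range(n_bootstrap):
            take = rng.integers(0, n, size=n)
            try:
                xb = [x[take] for x in x_blocks]
                xb = [_standardize(x) for x in xb]
                _, sc, _, okb = _fit_once(xb, connect, tol, max_iter)
                if not okb:
                    continue
                pb, _ = _paths_from_scores(sc, pm)
                boot[r] = [pb[t, s] for t, s in edge_idx]
            except UsageError:
                continue
        boot_df = pd.DataFrame(
            boot, columns=[f"{names[s]}->{names[t]}" for t, s in edge_idx]
        )
    for t in range(len(names)):
        for s in range(len(names)):
            if not pm[t, s]:
                continue
            est = paths[t, s]
            se = p = np.nan
            if boot_df is not None:
                col = boot_df[f"{names[s]}->{names[t]}"].dropna()
                if len(col) > 1:
                    se = float(col.std(ddof=1))
                    p = 0.0 if se == 0 else float(2 * stats.norm.sf(abs(est) / se))
            rows.append(
                {"source": names[s], "target": names[t], "estimate": float(est),
                 "boot_se": se, "p": p}
            )
    return PathModel(
        blocks=dict(blocks),
        path_matrix=pm_df,
        scores=pd.DataFrame(scores, index=data.index, columns=names),
        outer_weights={
            b: pd.Series(_unit(w), index=blocks[b]) for b, w in zip(names, weights)
        },
        paths=pd.DataFrame(paths, index=names, columns=names),
        path_table=pd.DataFrame(rows),
        r_squared=pd.Series(r2, index=names).dropna(),
        communality=pd.Series(communality),
        gof=gof,
        n_iter=n_iter,
        boot_paths=boot_df,
    )
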