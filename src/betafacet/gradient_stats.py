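"""Distance matrices and gradient statistics.

Pair-level analyses of how dissimilarity changes along the elevational
gradient: Mantel permutation tests against elevational and
environmental distance, distance–decay OLS regressions, rank-sum
comparisons between components and facets, ANOSIM for grouped
communities, and Chevan–Sutherland hierarchical partitioning of the
environmental predictors' independent effects.

All regressions and tests treat site pairs as observations, ignoring
their non-independence — the conventional practice for distance–decay
summaries; Mantel tests are the permutation-honest alternative and are
reported alongside.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomic_beta import PairwiseBetaSet


# ---------------------------------------------------------------- distances


def _check_square(d: pd.DataFrame) -> None:
    m = d.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")


def elevational_distance(meta: pd.DataFrame) -> pd.DataFrame:
    """|midpoint_i - midpoint_j| for all site pairs (meters)."""
    elev = meta["elevation_mid"].to_numpy(dtype=float)
    d = np.abs(elev[:, None] - elev[None, :])
    return pd.DataFrame(d, index=meta.index, columns=meta.index)


def environmental_distance(
    env: pd.DataFrame, variables: Sequence[str]
) -> pd.DataFrame:
    """Euclidean distance on variables standardized to mean 0, SD 1."""
    if len(variables) < 1:
        raise ValueError("need at least one variable")
    x = env[list(variables)].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    zero = [v for v, s in zip(variables, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance variable(s): {zero}")
    z = (x - x.mean(axis=0)) / sd
    d = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=-1))
    return pd.DataFrame(d, index=env.index, columns=env.index)


def per_variable_distances(
    env: pd.DataFrame, variables: Sequence[str]
) -> dict[str, pd.DataFrame]:
    return {v: environmental_distance(env, [v]) for v in variables}


def condensed(d: pd.DataFrame) -> np.ndarray:
    """Lower-triangle vector of a square symmetric matrix."""
    m = d.to_numpy(dtype=float)
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


# ------------------------------------------------------------------- Mantel


@dataclasses.dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the lower-triangle entries; the
    p-value is upper-tail, (1 + #{r_perm >= r_obs}) / (n_perm + 1),
    with permutations jointly shuffling rows and columns of ``d2``.
    Pairs where either matrix is NaN are dropped (identically for every
    permutation, so the permutation scheme stays exchangeable).
    """
    _check_square(d1)
    _check_square(d2)
    if list(d1.index) != list(d2.index):
        raise ValueError("distance matrices must share the same sites")
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    m1 = d1.to_numpy(dtype=float)
    m2 = d2.to_numpy(dtype=float)
    n = m1.shape[0]
    i, j = np.tril_indices(n, k=-1)
    valid = np.isfinite(m1) & np.isfinite(m2)
    np.fill_diagonal(valid, True)
    keep = valid[i, j]
    v1 = m1[i, j][keep]
    if v1.std() == 0:
        raise ValueError("first matrix is constant over pairs; r undefined")
    v2 = m2[i, j][keep]
    if v2.std() == 0:
        raise ValueError("second matrix is constant over pairs; r undefined")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mp = m2[np.ix_(perm, perm)]
        vp = mp[i, j][keep]
        sd = vp.std()
        r_perm = (
            float(np.corrcoef(v1, vp)[0, 1]) if sd > 0 else 0.0
        )
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm)


# ------------------------------------------------------- distance–decay OLS


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def decay_regression(
    y: np.ndarray | pd.DataFrame, dist: pd.DataFrame | np.ndarray
) -> RegressionResult:
    """OLS of pair-level dissimilarity on pair-level distance.

    Accepts either condensed (pair vector) or square inputs; pairs with
    missing dissimilarity (functional exclusions) are dropped.
    """
    yv = condensed(y) if isinstance(y, pd.DataFrame) else np.asarray(y, float)
    xv = (
        condensed(dist)
        if isinstance(dist, pd.DataFrame)
        else np.asarray(dist, float)
    )
    if yv.shape != xv.shape:
        raise ValueError("response and distance must cover the same pairs")
    keep = np.isfinite(yv) & np.isfinite(xv)
    yv, xv = yv[keep], xv[keep]
    if yv.size < 3:
        raise ValueError("need at least 3 pairs with data")
    if xv.std() == 0:
        raise ValueError("distance values are all identical")
    res = stats.linregress(xv, yv)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
        n=int(yv.size),
    )


# ---------------------------------------------------------------- rank sum


@dataclasses.dataclass(frozen=True)
class RankSumResult:
    z: float
    p: float
    direction: str  # "x > y", "y > x", or "tied"


def ranksum_compare(
    x: Sequence[float], y: Sequence[float]
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) comparison.

    z is the tie-corrected normal approximation without continuity
    correction; its sign is positive when ``x`` tends to exceed ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2  # Mann–Whitney U for x
    mu = n1 * n2 / 2
    # tie correction to the variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n1 + n2) * (n1 + n2 - 1))
    sigma2 = n1 * n2 / 12 * ((n1 + n2 + 1) - tie_term)
    if sigma2 <= 0:
        z = 0.0
    else:
        z = (u1 - mu) / np.sqrt(sigma2)
    p = 2 * stats.norm.sf(abs(z))
    direction = "x > y" if z > 0 else ("y > x" if z < 0 else "tied")
    return RankSumResult(z=float(z), p=float(min(p, 1.0)), direction=direction)


# ------------------------------------------------------------------ ANOSIM


@dataclasses.dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_perm: int


def anosim(
    d: pd.DataFrame,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities: rank-based test of between-group
    versus within-group distances, with a label-permutation p-value."""
    _check_square(d)
    groups = np.asarray(groups)
    if groups.shape[0] != d.shape[0]:
        raise ValueError("one group label per site required")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"group(s) of size 1: {small}")
    m = d.to_numpy(dtype=float)
    n = m.shape[0]
    i, j = np.tril_indices(n, k=-1)
    ranks = stats.rankdata(m[i, j])

    def r_stat(g: np.ndarray) -> float:
        between = g[i] != g[j]
        rb = ranks[between].mean()
        rw = ranks[~between].mean()
        return float((rb - rw) / (ranks.size / 2))

    r_obs = r_stat(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(groups)) >= r_obs - 1e-12:
            count += 1
    return AnosimResult(
        R=r_obs, p=float((1 + count) / (n_perm + 1)), n_perm=n_perm
    )


# ------------------------------------------- hierarchical partitioning (HP)


@dataclasses.dataclass(frozen=True)
class HierPartResult:
    independent: dict[str, float]  # I per predictor
    joint: dict[str, float]  # J per predictor (marginal R^2 - I)
    r_squared_full: float

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "predictor": k,
                "independent_effect": self.independent[k],
                "joint_effect": self.joint[k],
            }
            for k in self.independent
        ]
        return pd.DataFrame(rows)


def _ols_r2(y: np.ndarray, x: np.ndarray) -> float:
    """R^2 of an intercept-included OLS fit."""
    design = np.column_stack([np.ones(y.size), x]) if x.size else np.ones((y.size, 1))
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise ValueError("constant response")
    return float(1 - (resid**2).sum() / tss)


def hierarchical_partition(
    response: np.ndarray | pd.DataFrame,
    predictors: Mapping[str, pd.DataFrame | np.ndarray],
) -> HierPartResult:
    """Chevan–Sutherland hierarchical partitioning of OLS R².

    The independent effect of predictor i is its R² increment when
    entering the model, averaged over all orderings of predictor entry;
    the joint effect is its marginal R² minus the independent effect.
    The independent effects sum to the full-model R² exactly.
    """
    names = list(predictors)
    k = len(names)
    if k == 0:
        raise ValueError("need at least one predictor")
    if k > 12:
        raise ValueError("more than 12 predictors: 2^k enumeration refused")
    y = condensed(response) if isinstance(response, pd.DataFrame) else np.asarray(response, float)
    cols = []
    for name in names:
        p = predictors[name]
        v = condensed(p) if isinstance(p, pd.DataFrame) else np.asarray(p, float)
        if v.shape != y.shape:
            raise ValueError(f"predictor {name!r} does not match the response pairs")
        cols.append(v)
    x = np.column_stack(cols)
    keep = np.isfinite(y) & np.isfinite(x).all(axis=1)
    y, x = y[keep], x[keep]
    if y.size < k + 2:
        raise ValueError("need at least k + 2 pairs with data")
    # collinearity-to-singularity check on the full design
    full_design = np.column_stack([np.ones(y.size), x])
    if np.linalg.matrix_rank(full_design) < k + 1:
        raise ValueError(f"predictors collinear to singularity: {names}")

    from math import factorial

    r2: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, k + 1):
        for subset in itertools.combinations(range(k), size):
            r2[frozenset(subset)] = _ols_r2(y, x[:, list(subset)])
    independent = {}
    for idx, name in enumerate(names):
        total = 0.0
        others = [m for m in range(k) if m != idx]
        for size in range(0, k):
            w = factorial(size) * factorial(k - size - 1) / factorial(k)
            for subset in itertools.combinations(others, size):
                s = frozenset(subset)
                total += w * (r2[s | {idx}] - r2[s])
        independent[name] = total
    full = r2[frozenset(range(k))]
    joint = {
        name: r2[frozenset({idx})] - independent[name]
        for idx, name in enumerate(names)
    }
    return HierPartResult(independent=independent, joint=joint, r_squared_full=full)


# ----------------------------------------------------------- convenience


def mantel_table(
    beta_sets: Sequence[PairwiseBetaSet],
    dist: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel r and p for every facet x component against one distance."""
    rows = []
    rng = np.random.default_rng(seed)
    for bs in beta_sets:
        for comp in ("turnover", "nestedness", "total"):
            sub_seed = int(rng.integers(2**31))
            try:
                res = mantel(bs.component(comp), dist, n_perm=n_perm, seed=sub_seed)
                r, p = res.r, res.p
            except ValueError:
                r, p = np.nan, np.nan  # e.g. a constant component
            rows.append(
                {
                    "facet": bs.facet,
                    "component": comp,
                    "r": r,
                    "p": p,
                    "n_perm": n_perm,
                }
            )
    return pd.DataFrame(rows)
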