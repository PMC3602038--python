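"""Variety-selection statistics for multi-environment field trials.

Cadmium uptake in a randomized-block field trial is modeled as
trait ~ E + G + GxE + error, with each environment a Field x Year
combination.  Soil heterogeneity within a field confounds the genotype
effect, so plot values are first corrected by a generalized additive
model (value ~ 1 + Variety + s(row, column)) where s is a penalized
tensor-product cubic spline whose smoothing parameter is chosen by
generalized cross-validation.  Corrected values are aggregated to
genotype means per environment and scaled to unit spread per
environment; the environment-centered matrix (carrying G + GxE) is then
decomposed by SVD — the GGE biplot — and genotypes are ranked by their
projection on the average-environment axis (trait level) and their
distance from it (instability).  Pairwise variety contrasts use
Welch's t-test with t-based 95% confidence intervals and report the
relative decrease 100*(1 - meanA/meanB).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

__all__ = [
    "SpatialFit",
    "GGEResult",
    "ContrastResult",
    "fit_spatial_surface",
    "scale_by_environment",
    "gge_decompose",
    "rank_ideal_cultivars",
    "variety_contrast",
    "relative_decrease",
]


# ---------------------------------------------------------------------------
# Spatial correction


def _bspline_basis(x: np.ndarray, n_interior: int) -> np.ndarray:
    """Cubic B-spline design matrix with interior knots at quantiles.

    The interior knot count is capped at (number of unique coordinate
    values - 4) so the basis never has more functions than the data can
    distinguish along that axis; with no interior knots the basis is the
    4-dimensional cubic polynomial basis.
    """
    uniq = np.unique(x)
    n_interior = max(0, min(n_interior, len(uniq) - 4))
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        hi = lo + 1.0
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(uniq, qs)
    else:
        interior = np.array([])
    t = np.concatenate(([lo] * 4, interior, [hi] * 4))
    k = 3
    dm = BSpline.design_matrix(np.clip(x, lo, hi), t, k, extrapolate=False)
    return np.asarray(dm.todense())


def _second_diff(n: int) -> np.ndarray:
    if n < 3:
        return np.zeros((0, n))
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D


@dataclass
class SpatialFit:
    """Result of the within-field spatial correction."""

    spatial: np.ndarray          # per-plot spatial component, mean 0
    corrected: np.ndarray        # observed - spatial
    fitted: np.ndarray
    variety_effects: pd.Series   # effect per variety relative to the first
    lambda_: float
    edf: float
    gcv: float


def fit_spatial_surface(
    plots: pd.DataFrame,
    value_col: str = "value",
    variety_col: str = "variety",
    row_col: str = "row",
    col_col: str = "column",
    n_knots: int = 5,
    lambdas: Optional[Sequence[float]] = None,
) -> SpatialFit:
    """Fit value ~ 1 + Variety + s(row, column) within one environment.

    ``s`` is a tensor product of cubic B-splines (default 5 interior
    knots per dimension at coordinate quantiles, auto-capped for coarse
    grids) with a second-difference ridge penalty on the spline
    coefficients; the penalty weight is chosen by generalized
    cross-validation over a log-spaced grid.  The fitted spatial
    component is centered to mean zero (the level belongs to the
    intercept) and subtracted from the observations.
    """
    df = plots.reset_index(drop=True)
    varieties = sorted(df[variety_col].unique())
    if len(varieties) < 2:
        raise ValueError("need at least 2 varieties for spatial correction")
    y = df[value_col].to_numpy(dtype=float)
    n = len(y)

    Br = _bspline_basis(df[row_col].to_numpy(dtype=float), n_knots)
    Bc = _bspline_basis(df[col_col].to_numpy(dtype=float), n_knots)
    nr, nc = Br.shape[1], Bc.shape[1]
    # tensor product basis, row-major over (row basis, col basis)
    B = np.einsum("ij,ik->ijk", Br, Bc).reshape(n, nr * nc)

    v_codes = pd.Categorical(df[variety_col], categories=varieties).codes
    V = np.zeros((n, len(varieties) - 1))
    for i, code in enumerate(v_codes):
        if code > 0:
            V[i, code - 1] = 1.0
    X = np.hstack([np.ones((n, 1)), V, B])
    p_fixed = 1 + V.shape[1]
    p = X.shape[1]
    if n < p:
        raise ValueError(
            f"{n} plots but {p} model columns; reduce n_knots (basis {nr}x{nc})"
        )

    # second-difference penalty over the coefficient grid, both directions,
    # plus a small ridge to absorb the penalty null space
    Dr = _second_diff(nr)
    Dc = _second_diff(nc)
    P_spline = (
        np.kron(Dr.T @ Dr, np.eye(nc))
        + np.kron(np.eye(nr), Dc.T @ Dc)
        + 1e-8 * np.eye(nr * nc)
    )
    P = np.zeros((p, p))
    P[p_fixed:, p_fixed:] = P_spline

    XtX = X.T @ X
    Xty = X.T @ y
    if lambdas is None:
        lambdas = np.logspace(-8, 6, 29)
    best = None
    for lam in lambdas:
        A = XtX + lam * P
        try:
            beta = np.linalg.solve(A, Xty)
            edf = float(np.trace(np.linalg.solve(A, XtX)))
        except np.linalg.LinAlgError:
            continue
        resid = y - X @ beta
        rss = float(resid @ resid)
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, edf)
    if best is None:
        raise np.linalg.LinAlgError("spatial fit failed for every lambda")
    gcv, lam, beta, edf = best

    spatial = B @ beta[p_fixed:]
    spatial = spatial - spatial.mean()
    fitted = X @ beta
    effects = pd.Series(
        np.concatenate(([0.0], beta[1:p_fixed])), index=varieties, name="effect"
    )
    return SpatialFit(
        spatial=spatial,
        corrected=y - spatial,
        fitted=fitted,
        variety_effects=effects,
        lambda_=float(lam),
        edf=edf,
        gcv=float(gcv),
    )


# ---------------------------------------------------------------------------
# Environment scaling and GGE decomposition


def scale_by_environment(
    plots: pd.DataFrame,
    value_col: str = "corrected",
    env_col: str = "env",
    variety_col: str = "variety",
) -> pd.DataFrame:
    """Genotype x environment matrix of unit-spread trait means.

    Per environment, plot values are aggregated to genotype means and
    divided by the standard deviation (ddof=1) of those means, so every
    environment column has unit spread.  The matrix must be complete.
    """
    gem = plots.pivot_table(
        index=variety_col, columns=env_col, values=value_col, aggfunc="mean"
    )
    if gem.isna().any().any():
        raise ValueError("incomplete genotype x environment matrix")
    sds = gem.std(axis=0, ddof=1)
    if (sds < 1e-12).any():
        bad = sds.index[sds < 1e-12].tolist()
        raise ValueError(f"zero variance of genotype means in environment(s) {bad}")
    return gem / sds


@dataclass
class GGEResult:
    """Symmetric-scaling SVD of the environment-centered G x E matrix."""

    genotype_scores: pd.DataFrame    # genotypes x axes, U * sqrt(S)
    env_loadings: pd.DataFrame       # environments x axes, V * sqrt(S)
    singular_values: np.ndarray      # full spectrum
    variance_explained: np.ndarray   # percent per axis, full spectrum
    n_axes: int


def gge_decompose(gematrix: pd.DataFrame, n_axes: int = 2) -> GGEResult:
    """Environment-center the matrix and decompose it by SVD.

    Subtracting each environment's mean removes the environment main
    effect, so the singular axes carry genotype + genotype-x-environment
    signal.  Both sides are scaled by the square root of the singular
    values (symmetric biplot scaling); variance explained per axis is
    100 * s_i^2 / sum(s_j^2) over the full spectrum and sums to 100.
    """
    if gematrix.shape[0] < 2 or gematrix.shape[1] < 2:
        raise ValueError("need at least 2 genotypes and 2 environments")
    centered = gematrix - gematrix.mean(axis=0)
    U, s, Vt = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_axes > rank:
        warnings.warn(
            f"requested {n_axes} axes but rank is {rank}; truncating", stacklevel=2
        )
        n_axes = rank
    total = float(np.sum(s**2))
    ve = 100 * s**2 / total if total > 0 else np.zeros_like(s)
    k = n_axes
    axes = [f"axis{i + 1}" for i in range(k)]
    G = pd.DataFrame(
        U[:, :k] * np.sqrt(s[:k]), index=gematrix.index, columns=axes
    )
    E = pd.DataFrame(
        Vt[:k].T * np.sqrt(s[:k]), index=gematrix.columns, columns=axes
    )
    return GGEResult(
        genotype_scores=G,
        env_loadings=E,
        singular_values=s,
        variance_explained=ve,
        n_axes=k,
    )


def rank_ideal_cultivars(
    gge: GGEResult, direction: str = "low", level_rtol: float = 1e-3
) -> pd.DataFrame:
    """Rank genotypes by trait level along the average-environment axis.

    The average-environment axis is the mean of the environment loading
    vectors; each genotype's projection on it is its trait level, and
    the norm of the orthogonal remainder is its instability (its
    genotype-by-environment sensitivity).  Ranking is by level
    (ascending for ``direction='low'``, descending for ``'high'``);
    levels within ``level_rtol`` of the level range are treated as tied
    and broken by instability, so equal-performing genotypes order by
    stability rather than by floating-point noise.  The ideal cultivar
    combines extreme level with low instability.
    """
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    aea = gge.env_loadings.to_numpy().mean(axis=0)
    norm = np.linalg.norm(aea)
    if norm < 1e-12:
        raise ValueError("degenerate (zero) average-environment axis")
    unit = aea / norm
    scores = gge.genotype_scores.to_numpy()
    level = scores @ unit
    resid = scores - np.outer(level, unit)
    instability = np.linalg.norm(resid, axis=1)

    # group levels closer than the tolerance (transitively, along the sorted
    # order) so instability breaks genuine performance ties
    tol = level_rtol * max(np.ptp(level), 1e-12)
    order = np.argsort(level, kind="mergesort")
    group = np.empty(len(level), dtype=int)
    gid = 0
    for pos, idx in enumerate(order):
        if pos > 0 and level[idx] - level[order[pos - 1]] > tol:
            gid += 1
        group[idx] = gid

    out = pd.DataFrame(
        {"level": level, "instability": instability, "_group": group},
        index=gge.genotype_scores.index,
    )
    ascending = direction == "low"
    out = out.sort_values(
        by=["_group", "instability"], ascending=[ascending, True], kind="mergesort"
    )
    out = out.drop(columns="_group")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Contrasts


@dataclass
class ContrastResult:
    """Two-group comparison in the field-table format."""

    mean_a: float
    mean_b: float
    ci_a: Tuple[float, float]
    ci_b: Tuple[float, float]
    p_value: float
    relative_decrease: float  # percent, 100*(1 - mean_a/mean_b)


def _t_ci(values: np.ndarray, alpha: float = 0.05) -> Tuple[float, float]:
    m = float(np.mean(values))
    n = len(values)
    se = float(np.std(values, ddof=1)) / np.sqrt(n)
    half = stats.t.ppf(1 - alpha / 2, n - 1) * se
    return (m - half, m + half)


def relative_decrease(mean_a: float, mean_b: float) -> float:
    """Percent decrease of A relative to B: 100*(1 - mean_a/mean_b)."""
    if mean_b == 0:
        raise ZeroDivisionError("relative decrease undefined for zero reference mean")
    return 100.0 * (1.0 - mean_a / mean_b)


def variety_contrast(
    group_a: Sequence[float], group_b: Sequence[float], alpha: float = 0.05
) -> ContrastResult:
    """Welch two-sided comparison with t-based CIs and relative decrease."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    se = np.sqrt(np.var(a, ddof=1) / len(a) + np.var(b, ddof=1) / len(b))
    if se == 0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return ContrastResult(
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        ci_a=_t_ci(a, alpha),
        ci_b=_t_ci(b, alpha),
        p_value=p,
        relative_decrease=relative_decrease(float(np.mean(a)), float(np.mean(b))),
    )
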