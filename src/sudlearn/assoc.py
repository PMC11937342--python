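"""Survey-association statistics: correlations with confidence intervals,
hierarchical regression with an F-change test, commonality analysis of
regression variance, variance inflation factors, exhaustive best-subset BIC
selection, and a spline trend test on absolute prediction errors.

The regression operations run either from raw data (ordinary least squares on
standardised variables, via statsmodels) or from a printed correlation matrix
with a sample size — the latter reproduces published analyses without access
to the underlying data, and the two modes agree exactly when the matrix is
computed from the same raw data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats
import statsmodels.api as sm

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "HierarchicalRegressionResult",
    "CommonalityResult",
    "BicRanking",
    "TrendTestResult",
    "pearson_with_ci",
    "hierarchical_regression",
    "commonality",
    "vif",
    "best_subset_bic",
    "pe_trend_test",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlation with CI


@dataclass
class CorrelationResult:
    r: float
    n: int
    df: int
    ci_low: float
    ci_high: float
    p: float
    level: float = 0.95


def pearson_with_ci(
    x=None, y=None, *, r: float | None = None, n: int | None = None,
    level: float = 0.95, se_offset: int = 2,
) -> CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval.

    Either raw vectors ``x, y`` or a summary pair ``(r, n)`` may be given.
    The interval is tanh(atanh(r) +/- z * 1/sqrt(n - se_offset)); the default
    ``se_offset=2`` is this package's convention, which reproduces published
    intervals computed from rounded correlations (the textbook large-sample
    variance 1/(n-3) is available via ``se_offset=3``).  The p value comes
    from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    if r is None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        mask = ~np.isnan(x) & ~np.isnan(y)
        x, y = x[mask], y[mask]
        n = x.size
        if n < 4:
            raise ValueError("need at least 4 complete pairs")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("zero-variance input")
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        if n is None:
            raise ValueError("summary input requires both r and n")
        if not -1.0 <= r <= 1.0:
            raise ValueError("r must lie in [-1, 1]")
        if n < 4:
            raise ValueError("need n >= 4")
    n = int(n)
    df = n - 2
    if abs(r) >= 1.0 - 1e-12:
        r = float(np.sign(r))
        logger.warning("degenerate |r| = 1: returning a point interval")
        return CorrelationResult(r, n, df, r, r, 0.0, level)
    z = np.arctanh(r)
    q = stats.norm.ppf(0.5 + level / 2.0)
    se = 1.0 / np.sqrt(n - se_offset)
    lo, hi = float(np.tanh(z - q * se)), float(np.tanh(z + q * se))
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(float(r), n, df, lo, hi, p, level)


# ---------------------------------------------------------------------------
# regression helpers (raw-data and correlation-matrix modes)


@dataclass
class RegressionResult:
    """OLS summary on standardised outcome and predictors."""

    predictors: list
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: float
    adj_r2: float
    f: float
    df_model: int
    df_resid: int
    f_p: float
    vif: np.ndarray
    n: int


@dataclass
class HierarchicalRegressionResult:
    base: RegressionResult
    full: RegressionResult
    delta_r2: float
    f_change: float
    f_change_df: tuple
    f_change_p: float


def _validate_corr(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    eig = np.linalg.eigvalsh(mat)
    if eig.min() <= 1e-12:
        raise ValueError("correlation matrix is not positive definite")
    return mat


def _corr_from_raw(y, X):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    data = np.column_stack([y, X])
    if np.isnan(data).any():
        keep = ~np.isnan(data).any(axis=1)
        data = data[keep]
    n = data.shape[0]
    sds = data.std(axis=0)
    if np.any(sds == 0):
        raise ValueError("zero-variance variable in regression input")
    return np.corrcoef(data, rowvar=False), n


def _subset_r2(R: np.ndarray, idx) -> float:
    """R^2 of the standardised regression of variable 0 on predictors idx
    (indices into the correlation matrix, predictor block starting at 1)."""
    if len(idx) == 0:
        return 0.0
    idx = list(idx)
    rxx = R[np.ix_(idx, idx)]
    rxy = R[idx, 0]
    return float(rxy @ np.linalg.solve(rxx, rxy))


def _regression_from_corr(R: np.ndarray, n: int, names) -> RegressionResult:
    p = R.shape[0] - 1
    if n <= p + 1:
        raise ValueError(f"n = {n} too small for {p} predictors")
    idx = list(range(1, p + 1))
    rxx = R[np.ix_(idx, idx)]
    rxy = R[idx, 0]
    try:
        rxx_inv = np.linalg.inv(rxx)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular design among predictors {list(names)}") from exc
    beta = rxx_inv @ rxy
    r2 = float(rxy @ beta)
    df_resid = n - p - 1
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    se = np.sqrt((1.0 - r2) / df_resid * np.diag(rxx_inv))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    q = stats.t.ppf(0.975, df_resid)
    f = (r2 / p) / ((1.0 - r2) / df_resid) if p > 0 else 0.0
    f_p = float(stats.f.sf(f, p, df_resid)) if p > 0 else 1.0
    vifs = np.diag(rxx_inv).copy()
    return RegressionResult(
        list(names), beta, se, beta - q * se, beta + q * se, tvals, pvals,
        r2, adj_r2, float(f), p, df_resid, f_p, vifs, n,
    )


def hierarchical_regression(
    y=None, X_base=None, x_added=None, *,
    corr: np.ndarray | None = None, n: int | None = None, names=None,
) -> HierarchicalRegressionResult:
    """Base-vs-full nested OLS comparison on standardised variables.

    Raw mode: ``y``, base predictor matrix ``X_base``, and the added column
    ``x_added``.  Matrix mode: a correlation matrix ``corr`` ordered
    [outcome, base predictors..., added predictor] with sample size ``n``.
    F_change = dR^2 / ((1 - R^2_full) / (n - p_full - 1)) on (1, n-p_full-1).
    """
    if corr is None:
        Xb = np.asarray(X_base, dtype=float)
        if Xb.ndim == 1:
            Xb = Xb[:, None]
        xa = np.asarray(x_added, dtype=float).reshape(-1, 1)
        R, n = _corr_from_raw(y, np.column_stack([Xb, xa]))
        p_base = Xb.shape[1]
    else:
        R = _validate_corr(corr)
        if n is None:
            raise ValueError("matrix mode requires n")
        p_base = R.shape[0] - 2
    p_full = p_base + 1
    if names is None:
        names = [f"x{i + 1}" for i in range(p_full)]
    base = _regression_from_corr(R[:p_base + 1, :p_base + 1], n, names[:p_base])
    full = _regression_from_corr(R, n, names)
    delta = full.r2 - base.r2
    df2 = n - p_full - 1
    f_change = delta / ((1.0 - full.r2) / df2)
    f_p = float(stats.f.sf(f_change, 1, df2))
    return HierarchicalRegressionResult(base, full, float(delta), float(f_change),
                                        (1, df2), f_p)


# ---------------------------------------------------------------------------
# commonality analysis


@dataclass
class CommonalityResult:
    predictors: list
    components: dict          # frozenset of predictor names -> commonality coefficient
    unique: dict              # predictor -> unique variance
    total_r2: float
    adj_r2: float
    n: int

    @property
    def common_total(self) -> float:
        return self.total_r2 - sum(self.unique.values())


def commonality(
    y=None, X=None, *, corr: np.ndarray | None = None, n: int | None = None,
    names=None,
) -> CommonalityResult:
    """Partition regression R^2 into unique and common components.

    Solves the linear system tying all-subsets R^2 values to the 2^p - 1
    commonality coefficients: for every non-empty predictor set A,
    R^2(A) = sum of C(S) over subsets S intersecting A.  Components sum to
    the full-model R^2 by construction; unique_i = R^2_full - R^2_without_i.
    """
    if corr is None:
        R, n = _corr_from_raw(y, X)
    else:
        R = _validate_corr(corr)
        if n is None:
            raise ValueError("matrix mode requires n")
    p = R.shape[0] - 1
    if p < 2:
        raise ValueError("commonality analysis needs at least two predictors")
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]

    subsets = []
    for size in range(1, p + 1):
        subsets.extend(itertools.combinations(range(p), size))
    r2 = {s: _subset_r2(R, [i + 1 for i in s]) for s in subsets}
    # M[a, s] = 1 iff subset s shares a predictor with subset a
    m = len(subsets)
    M = np.zeros((m, m))
    for ai, a in enumerate(subsets):
        aset = set(a)
        for si, s in enumerate(subsets):
            if aset & set(s):
                M[ai, si] = 1.0
    coeffs = np.linalg.solve(M, np.array([r2[a] for a in subsets]))
    components = {frozenset(names[i] for i in s): float(c)
                  for s, c in zip(subsets, coeffs)}
    full = subsets[-1]
    total = r2[full]
    unique = {names[i]: float(components[frozenset([names[i]])]) for i in range(p)}
    adj = 1.0 - (1.0 - total) * (n - 1) / (n - p - 1)
    return CommonalityResult(list(names), components, unique, float(total), float(adj), n)


# ---------------------------------------------------------------------------
# VIF


def vif(X=None, *, corr: np.ndarray | None = None, names=None) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j), predictor j
    regressed on the others.  Exactly collinear designs report inf."""
    if corr is None:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("need at least two predictors")
        sds = X.std(axis=0)
        if np.any(sds == 0):
            raise ValueError("zero-variance predictor")
        R = np.corrcoef(X, rowvar=False)
    else:
        R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]
    out = np.empty(p)
    for j in range(p):
        others = [i for i in range(p) if i != j]
        rxx = R[np.ix_(others, others)]
        rxy = R[others, j]
        try:
            r2j = float(rxy @ np.linalg.solve(rxx, rxy))
        except np.linalg.LinAlgError:
            r2j = 1.0
        if r2j >= 1.0 - 1e-12:
            logger.warning("predictor %r is exactly collinear; VIF set to inf", names[j])
            out[j] = np.inf
        else:
            out[j] = 1.0 / (1.0 - r2j)
    return pd.Series(out, index=list(names), name="VIF")


# ---------------------------------------------------------------------------
# best-subset BIC


@dataclass
class BicRanking:
    table: pd.DataFrame       # one row per subset, sorted by BIC
    best_subset: tuple

    @property
    def best(self) -> pd.Series:
        return self.table.iloc[0]


def best_subset_bic(y, X, names=None) -> BicRanking:
    """Exhaustive OLS subset search ranked by BIC.

    BIC = n ln(RSS/n) + k ln(n) with k = #predictors + intercept + error
    variance.  The intercept-only model is always included; subsets with
    n <= k are skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if p > 15:
        raise ValueError("exhaustive search supports at most 15 candidates")
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]
    rows = []
    for size in range(0, p + 1):
        for subset in itertools.combinations(range(p), size):
            k = len(subset) + 2
            if n <= k:
                logger.warning("subset %s skipped: n <= k", subset)
                continue
            if subset:
                design = sm.add_constant(X[:, list(subset)])
            else:
                design = np.ones((n, 1))
            fit = sm.OLS(y, design).fit()
            rss = float(fit.ssr)
            bic = n * np.log(rss / n) + k * np.log(n)
            rows.append({
                "subset": tuple(names[i] for i in subset),
                "n_predictors": len(subset),
                "rss": rss,
                "r2": float(fit.rsquared) if subset else 0.0,
                "bic": float(bic),
            })
    table = pd.DataFrame(rows).sort_values("bic", kind="mergesort").reset_index(drop=True)
    return BicRanking(table, tuple(table.iloc[0]["subset"]))


# ---------------------------------------------------------------------------
# trend test on |PE|


@dataclass
class TrendTestResult:
    f: float
    df: tuple
    p: float
    n_obs: int


def _bspline_basis(trial: np.ndarray, df_spline: int = 4) -> np.ndarray:
    """Cubic B-spline basis with interior knots at trial quantiles."""
    degree = 3
    n_interior = max(df_spline - degree, 0)
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(trial, qs)
    else:
        interior = np.array([])
    lo, hi = trial.min(), trial.max()
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    n_basis = len(knots) - degree - 1
    basis = np.empty((trial.size, n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        basis[:, j] = interpolate.BSpline(knots, coef, degree, extrapolate=False)(trial)
    return np.nan_to_num(basis)


def pe_trend_test(sessions, params_by_subject=None, df_spline: int = 4) -> TrendTestResult:
    """Temporal trend in absolute prediction errors.

    |PE(t)| = |F(t) - U(t)| is regressed on a cubic B-spline basis of trial
    index with subject fixed intercepts; the spline block is F-tested against
    the intercepts-only model.  A smooth declining trend indicates learning.
    Constant |PE| returns F = 0, p = 1.
    """
    rows = []
    for s in sessions:
        ape = np.abs(s.F - s.U)
        for t in range(s.n_trials):
            if not np.isnan(ape[t]):
                rows.append((s.subject_id, t + 1, ape[t]))
    if len(rows) < 10:
        raise ValueError("need at least 10 trials with defined |PE|")
    df = pd.DataFrame(rows, columns=["subject", "trial", "ape"])
    if df["ape"].std() == 0:
        return TrendTestResult(0.0, (df_spline, len(df) - df_spline - 1), 1.0, len(df))
    subj_dummies = pd.get_dummies(df["subject"], drop_first=False).to_numpy(float)
    basis = _bspline_basis(df["trial"].to_numpy(float), df_spline)
    # drop one spline column: the basis sums to 1 and would be collinear
    basis = basis[:, 1:]
    y = df["ape"].to_numpy(float)
    base = sm.OLS(y, subj_dummies).fit()
    full = sm.OLS(y, np.column_stack([subj_dummies, basis])).fit()
    q = basis.shape[1]
    df_resid = int(full.df_resid)
    f = ((base.ssr - full.ssr) / q) / (full.ssr / df_resid)
    p = float(stats.f.sf(f, q, df_resid))
    return TrendTestResult(float(f), (q, df_resid), p, len(df))
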