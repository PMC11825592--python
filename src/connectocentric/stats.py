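"""Inferential layer: permutation tests, effect sizes, rank correlations,
covariate-adjusted regression, multiple-comparison control.

The group test is a two-sample permutation t-test: the observed statistic is
the pooled-variance two-sample t; the null distribution is built by randomly
reassigning group labels while preserving group sizes; the two-tailed
Monte-Carlo p-value uses add-one smoothing,

    p = (1 + #{|t_perm| >= |t_obs|}) / (n_permutations + 1),

which guarantees validity (p is never exactly 0). When the total number of
distinct label assignments C(n, n_a) does not exceed the permutation budget,
the test switches to exhaustive enumeration and reports the exact p.

Effect sizes are Cohen's d with the pooled sample standard deviation (no
small-sample correction). Rank correlations are Spearman's rho (Pearson
correlation of mid-ranks) with the t-approximation p-value; covariate
adjustment is ordinary least squares with listwise deletion; the
false-discovery rate is controlled with the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

_REL_EPS = 1e-12  # tie tolerance when comparing |t| values


@dataclass(frozen=True)
class PermutationTestResult:
    t_statistic: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None


@dataclass(frozen=True)
class RegressionResult:
    terms: tuple[str, ...]
    coefficients: tuple[float, ...]
    t_values: tuple[float, ...]
    p_values: tuple[float, ...]
    adj_r_squared: float
    f_statistic: float
    f_p_value: float
    df_model: int
    df_resid: int
    n_used: int
    n_dropped: int


def pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample t with pooled variance (equal-variance Student t)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    num = a.mean() - b.mean()
    if sp2 == 0:
        if num == 0:
            return 0.0
        raise ValueError("t statistic undefined: zero pooled variance with unequal means")
    return float(num / math.sqrt(sp2 * (1 / na + 1 / nb)))


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with pooled sample SD (ddof=1)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / math.sqrt(sp2))


def _t_from_group_sums(
    sum_a: np.ndarray,
    sumsq_a: np.ndarray,
    total_sum: float,
    total_sumsq: float,
    na: int,
    nb: int,
) -> np.ndarray:
    """Vectorized pooled t from group-A sums/sum-of-squares per permutation."""
    sum_b = total_sum - sum_a
    sumsq_b = total_sumsq - sumsq_a
    ma, mb = sum_a / na, sum_b / nb
    ss_a = sumsq_a - na * ma**2
    ss_b = sumsq_b - nb * mb**2
    sp2 = (ss_a + ss_b) / (na + nb - 2)
    num = ma - mb
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    # zero pooled variance: t is 0 if means also tie, +-inf otherwise
    bad = denom <= 0
    if np.any(bad):
        t = np.where(bad & (num == 0), 0.0, t)
        t = np.where(bad & (num != 0), np.sign(num) * np.inf, t)
    return t


def permutation_two_sample(
    a,
    b,
    n_permutations: int = 100_000,
    seed: int | None = None,
    method: str = "auto",
    chunk_size: int = 20_000,
) -> PermutationTestResult:
    """Two-sample permutation t-test (two-tailed).

    ``method`` is 'auto' (exhaustive enumeration when the number of label
    assignments C(n, n_a) <= n_permutations, Monte Carlo otherwise),
    'exhaustive', or 'montecarlo'. Monte-Carlo p-values use add-one
    smoothing; exhaustive p-values are the exact fraction of assignments
    with |t| at least the observed |t|.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values")
    na, nb = len(a), len(b)
    n = na + nb
    values = np.concatenate([a, b])
    if np.ptp(values) == 0:
        # all observations identical: exchangeable null is degenerate
        return PermutationTestResult(0.0, 1.0, n_permutations, True, seed)
    t_obs = pooled_t(a, b)
    thresh = abs(t_obs) * (1 - _REL_EPS)

    total_sum = float(values.sum())
    total_sumsq = float((values**2).sum())
    n_assignments = math.comb(n, na)
    if method not in ("auto", "exhaustive", "montecarlo"):
        raise ValueError(f"unknown method {method!r}")
    exhaustive = method == "exhaustive" or (
        method == "auto" and n_assignments <= n_permutations
    )

    if exhaustive:
        idx = np.array(list(combinations(range(n), na)), dtype=np.intp)
        picked = values[idx]
        t_all = _t_from_group_sums(
            picked.sum(axis=1),
            (picked**2).sum(axis=1),
            total_sum,
            total_sumsq,
            na,
            nb,
        )
        count = int(np.sum(np.abs(t_all) >= thresh))
        return PermutationTestResult(
            t_statistic=t_obs,
            p_value=count / n_assignments,
            n_permutations=n_assignments,
            exhaustive=True,
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    while done < n_permutations:
        m = min(chunk_size, n_permutations - done)
        idx = rng.random((m, n)).argsort(axis=1)[:, :na]
        picked = values[idx]
        t_perm = _t_from_group_sums(
            picked.sum(axis=1),
            (picked**2).sum(axis=1),
            total_sum,
            total_sumsq,
            na,
            nb,
        )
        count += int(np.sum(np.abs(t_perm) >= thresh))
        done += m
    return PermutationTestResult(
        t_statistic=t_obs,
        p_value=(1 + count) / (n_permutations + 1),
        n_permutations=n_permutations,
        exhaustive=False,
        seed=seed,
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation and its t-approximation p-value.

    rho is the Pearson correlation of mid-ranks (ties averaged); the p-value
    comes from t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d samples")
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = scipy.stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def ols_adjust(y, design: dict[str, np.ndarray] | "object") -> RegressionResult:
    """OLS of y on named regressors (intercept added), listwise deletion.

    ``design`` maps term names to 1-d numeric arrays (a pandas DataFrame
    also works). Records with a missing value in y or any regressor are
    dropped; the dropped count is reported. Raises on a rank-deficient
    design.
    """
    import pandas as pd

    frame = pd.DataFrame(dict(design) if not isinstance(design, pd.DataFrame) else design)
    frame = frame.astype(float)
    yv = np.asarray(y, dtype=float)
    if len(yv) != len(frame):
        raise ValueError("y and design have different lengths")
    keep = np.isfinite(yv) & np.isfinite(frame.to_numpy()).all(axis=1)
    n_dropped = int((~keep).sum())
    yv = yv[keep]
    frame = frame.loc[keep]
    X = sm.add_constant(frame, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if len(yv) <= X.shape[1]:
        raise ValueError("not enough observations for the number of terms")
    fit = sm.OLS(yv, X).fit()
    return RegressionResult(
        terms=tuple(X.columns),
        coefficients=tuple(float(v) for v in fit.params),
        t_values=tuple(float(v) for v in fit.tvalues),
        p_values=tuple(float(v) for v in fit.pvalues),
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_p_value=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n_used=int(len(yv)),
        n_dropped=n_dropped,
    )


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-d vector of p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-test alpha controlling family-wise error over m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
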