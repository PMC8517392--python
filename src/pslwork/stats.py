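"""Two-group clinical statistics for the cohort comparison layer.

Implements the statistical toolkit a two-group echocardiographic study
needs: pooled-variance Student's t (from raw samples or from published
group summaries), the Mann-Whitney U test with a normal approximation
(tie and continuity corrected), the Pearson chi-square test for 2x2
tables without continuity correction, Pearson correlation, ordinary
least squares with standardized coefficients, bidirectional stepwise
predictor selection, and Bland-Altman agreement.

Sign conventions: group 1 is always the reference (control) group, so
``t = (mean1 - mean2) / SE`` and a larger patient-group mean yields a
negative t.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .errors import CollinearityError, ValidationError

__all__ = [
    "TwoGroupResult",
    "RegressionResult",
    "AgreementResult",
    "t_from_summary",
    "t_from_raw",
    "mann_whitney",
    "chi_square_2x2",
    "pearson_r",
    "ols_standardized",
    "stepwise_select",
    "bland_altman",
]


@dataclass(frozen=True)
class TwoGroupResult:
    """Outcome of a two-group comparison test."""

    statistic_name: str  # "t", "Z" or "chi2"
    statistic: float
    p_value: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class RegressionResult:
    """A fitted linear model with standardized coefficients.

    ``beta`` holds standardized coefficients (SD units of predictor and
    outcome), keyed by predictor name; the intercept is fitted but not
    reported since it is zero on the standardized scale.
    """

    predictors: tuple[str, ...]
    beta: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    adj_r_squared: float
    n: int = 0
    empty: bool = field(default=False)


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement: bias and 95% limits of agreement."""

    bias: float
    loa_low: float
    loa_high: float
    n: int


def _validate_group(n: int, sd: float, label: str) -> None:
    if n < 2:
        raise ValidationError(f"group {label} needs n >= 2, got {n}")
    if not sd > 0:
        raise ValidationError(f"group {label} needs sd > 0, got {sd}")


def t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> TwoGroupResult:
    """Pooled-variance two-sample Student's t from group summaries.

    ``t = (mean1 - mean2) / sqrt(sp^2 (1/n1 + 1/n2))`` with the pooled
    variance ``sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2)`` and
    ``df = n1 + n2 - 2``.  Group 1 is the reference group.
    """
    _validate_group(n1, sd1, "1")
    _validate_group(n2, sd2, "2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TwoGroupResult("t", float(t), float(p), n1, n2)


def t_from_raw(x1: Sequence[float], x2: Sequence[float]) -> TwoGroupResult:
    """Pooled-variance Student's t from raw samples.

    Identical to :func:`t_from_summary` applied to the samples' own
    moments (ddof=1 standard deviations).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValidationError("each sample needs >= 2 values")
    return t_from_summary(
        x1.size, x1.mean(), x1.std(ddof=1), x2.size, x2.mean(), x2.std(ddof=1)
    )


def mann_whitney(x1: Sequence[float], x2: Sequence[float]) -> TwoGroupResult:
    """Mann-Whitney U with tie- and continuity-corrected normal Z.

    U counts, over all (x1, x2) pairs, the pairs where x1 wins (ties count
    half), computed via midranks.  Z standardizes U against its null mean
    ``n1 n2 / 2`` with the tie-corrected variance, applying a 0.5
    continuity correction toward the null.  The sign convention matches
    the reference-group-first layout: Z < 0 when group 1 ranks lower.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 1 or n2 < 1:
        raise ValidationError("each sample needs >= 1 value")
    pooled = np.concatenate([x1, x2])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # pairs won by group 1

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    mu_u = n1 * n2 / 2.0
    if var_u <= 0:  # all values tied: degenerate null
        z = 0.0
    else:
        diff = u1 - mu_u
        cc = 0.5 if diff != 0 else 0.0
        z = (diff - np.sign(diff) * cc) / np.sqrt(var_u)
    p = 2.0 * sps.norm.sf(abs(z))
    result = TwoGroupResult("Z", float(z), float(min(p, 1.0)), n1, n2)
    return result


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TwoGroupResult:
    """Pearson chi-square for a 2x2 table, without continuity correction.

    Table layout: rows are groups, columns are outcome categories::

        group1:  a  b
        group2:  c  d

    ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with df = 1.
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValidationError(f"counts must be non-negative integers, got {counts}")
    a, b, c, d = (int(x) for x in counts)
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValidationError(f"all table margins must be positive, got {counts}")
    n = a + b + c + d
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = sps.chi2.sf(chi2, df=1)
    return TwoGroupResult("chi2", float(chi2), float(p), a + b, c + d)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a t-based two-sided p.

    Returns ``(r, p)`` with p from the t distribution with n - 2 degrees
    of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _as_design(X, names: Sequence[str] | None):
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i+1}" for i in range(X.shape[1])]
    return X, list(names)


def ols_standardized(
    y: Sequence[float],
    X,
    names: Sequence[str] | None = None,
) -> RegressionResult:
    """OLS with an intercept, reporting standardized coefficients.

    The standardized coefficient of predictor j is the raw coefficient
    times ``sd(x_j) / sd(y)``, so for a single predictor it equals the
    Pearson correlation.  Raises :class:`CollinearityError` when the
    design matrix (with intercept) is rank deficient.
    """
    y = np.asarray(y, dtype=float)
    Xm, names = _as_design(X, names)
    n, k = Xm.shape
    if n <= k + 1:
        raise ValidationError(f"need n > p + 1 observations, got n={n}, p={k}")
    design = sm.add_constant(Xm, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("design matrix is rank deficient (collinear predictors)")
    fit = sm.OLS(y, design).fit()
    sy = y.std(ddof=1)
    sx = Xm.std(ddof=1, axis=0)
    beta = {nm: float(fit.params[j + 1] * sx[j] / sy) for j, nm in enumerate(names)}
    pvals = {nm: float(fit.pvalues[j + 1]) for j, nm in enumerate(names)}
    return RegressionResult(
        predictors=tuple(names),
        beta=beta,
        p_values=pvals,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        n=n,
    )


def stepwise_select(
    y: Sequence[float],
    X,
    names: Sequence[str] | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_iter: int = 100,
) -> RegressionResult:
    """Bidirectional stepwise selection for a linear model.

    Forward steps add the candidate with the smallest partial p-value
    below ``p_enter``; backward steps drop the included predictor with
    the largest p-value above ``p_remove``; iteration stops when the
    model is stable.  Ties break on input column order, so the procedure
    is deterministic.  If nothing enters, an empty (intercept-only) model
    is returned with ``empty=True`` and R-squared 0.
    """
    if p_enter > p_remove:
        raise ValidationError(
            f"p_enter ({p_enter}) must not exceed p_remove ({p_remove})"
        )
    y = np.asarray(y, dtype=float)
    Xm, names = _as_design(X, names)
    included: list[str] = []
    col = {nm: Xm[:, j] for j, nm in enumerate(names)}

    def fit_subset(subset: list[str]) -> RegressionResult:
        sub = np.column_stack([col[nm] for nm in subset])
        return ols_standardized(y, sub, names=subset)

    for _ in range(max_iter):
        changed = False
        # forward: best candidate by partial p-value
        candidates = [nm for nm in names if nm not in included]
        best_name, best_p = None, np.inf
        for nm in candidates:
            res = fit_subset(included + [nm])
            p = res.p_values[nm]
            if p < best_p:
                best_name, best_p = nm, p
        if best_name is not None and best_p < p_enter:
            included.append(best_name)
            changed = True
        # backward: worst included predictor
        if included:
            res = fit_subset(included)
            worst = max(included, key=lambda nm: res.p_values[nm])
            if res.p_values[worst] > p_remove:
                included.remove(worst)
                changed = True
        if not changed:
            break

    if not included:
        return RegressionResult(
            predictors=(),
            beta={},
            p_values={},
            r_squared=0.0,
            adj_r_squared=0.0,
            n=y.size,
            empty=True,
        )
    return fit_subset(included)


def bland_altman(
    m1: Sequence[float], m2: Sequence[float]
) -> AgreementResult:
    """Bland-Altman agreement between paired measurements.

    Differences are ``d = m2 - m1``; bias is their mean and the 95%
    limits of agreement are ``bias +/- 1.96 sd(d)`` (ddof=1).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.size != m2.size:
        raise ValidationError("paired measurements must have equal length")
    if m1.size < 2:
        raise ValidationError("agreement needs >= 2 pairs")
    d = m2 - m1
    bias = float(d.mean())
    spread = 1.96 * float(d.std(ddof=1))
    return AgreementResult(
        bias=bias, loa_low=bias - spread, loa_high=bias + spread, n=m1.size
    )
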