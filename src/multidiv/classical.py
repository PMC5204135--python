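"""Univariate and multivariate baselines: ANOVA, MANOVA, stepwise regression.

These are the conventional alternatives to the latent-variable model: a
one-way ANOVA per diversity metric, a MANOVA over the metric vector with
the herbivory treatment as the factor (all four classical test statistics
plus standardized canonical coefficients), and backward stepwise multiple
regression of total cover on the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AnovaResult",
    "ManovaResult",
    "StepwiseResult",
    "one_way_anova",
    "manova",
    "rank_contributions",
    "backward_stepwise_regression",
]


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df1: int
    df2: int
    p: float


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way ANOVA of ``values`` across the levels of ``groups``."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    n, g = len(values), len(levels)
    if n <= g:
        raise ValueError("need more observations than groups")
    if np.ptp(values) == 0:
        return AnovaResult(0.0, g - 1, n - g, 1.0)
    f, p = stats.f_oneway(*samples)
    return AnovaResult(float(f), g - 1, n - g, float(p))


@dataclass
class ManovaResult:
    """The four classical MANOVA statistics and canonical structure."""

    statistics: pd.DataFrame  # index: statistic name; cols: value, F, df1, df2, p, note
    canonical: pd.Series  # standardized canonical coefficients per response
    eigenvalues: np.ndarray  # of E^-1 H
    n: int
    n_groups: int
    responses: list[str]


def _manova_fs(eigs: np.ndarray, n: int, g: int, q: int) -> pd.DataFrame:
    """F approximations for Wilks, Pillai, Hotelling-Lawley and Roy.

    Rao's F for Wilks; the standard trace approximations for Pillai and
    Hotelling-Lawley; Roy's greatest root with its upper-bound F (the usual
    caveat that this F is a bound, not an approximation, is carried in the
    ``note`` column).
    """
    s = min(g - 1, q)
    m = (abs(q - (g - 1)) - 1) / 2.0
    nn = (n - g - q - 1) / 2.0
    rows = {}

    wilks = float(np.prod(1.0 / (1.0 + eigs)))
    df1 = q * (g - 1)
    denom = q**2 + (g - 1) ** 2 - 5
    t = np.sqrt((q**2 * (g - 1) ** 2 - 4) / denom) if denom > 0 else 1.0
    w = n - 1 - (q + g) / 2.0
    df2 = w * t - (q * (g - 1) - 2) / 2.0
    lam_t = wilks ** (1.0 / t)
    f = ((1 - lam_t) / lam_t) * (df2 / df1) if lam_t > 0 else np.inf
    rows["wilks"] = (wilks, f, df1, df2, stats.f.sf(f, df1, df2), "Rao's F")

    pillai = float(np.sum(eigs / (1.0 + eigs)))
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    f = (df2 / df1) * (pillai / (s - pillai)) if s - pillai > 0 else np.inf
    rows["pillai"] = (pillai, f, df1, df2, stats.f.sf(f, df1, df2), "trace approximation")

    hl = float(np.sum(eigs))
    df1 = s * (2 * m + s + 1)
    df2 = 2 * (s * nn + 1)
    f = (df2 * hl) / (s * df1) if df1 > 0 else np.inf
    rows["hotelling_lawley"] = (hl, f, df1, df2, stats.f.sf(f, df1, df2), "trace approximation")

    roy = float(eigs.max()) if eigs.size else 0.0
    r = max(q, g - 1)
    df1 = r
    df2 = n - r - 1
    f = roy * df2 / df1
    rows["roy"] = (roy, f, df1, df2, stats.f.sf(f, df1, df2), "upper-bound F")

    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["value", "F", "df1", "df2", "p", "note"]
    )
    out.index.name = "statistic"
    return out


def manova(responses: pd.DataFrame, groups) -> ManovaResult:
    """One-way MANOVA via between/within cross-product matrices.

    H is the between-group and E the within-group (error) cross-product
    matrix; all four statistics are functions of the eigenvalues of E^-1 H.
    Standardized canonical coefficients are the leading eigenvector of
    E^-1 H with each entry scaled by the error standard deviation of its
    response (sign convention: first nonzero coefficient positive).
    """
    y = responses.to_numpy(dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    n, q = y.shape
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if n <= q + g - 1:
        raise ValueError("too few observations: error matrix would be singular")
    grand = y.mean(axis=0)
    h = np.zeros((q, q))
    e = np.zeros((q, q))
    for lev in levels:
        sub = y[groups == lev]
        mean = sub.mean(axis=0)
        d = (mean - grand)[:, None]
        h += len(sub) * (d @ d.T)
        resid = sub - mean
        e += resid.T @ resid
    if np.linalg.matrix_rank(e) < q:
        corr = np.corrcoef(y.T)
        bad = [
            responses.columns[j]
            for j in range(q)
            if any(abs(corr[i, j]) > 1 - 1e-10 for i in range(j))
        ]
        raise ValueError(f"error matrix singular; collinear responses: {bad or 'unknown'}")
    einv_h = np.linalg.solve(e, h)
    eigvals, eigvecs = np.linalg.eig(einv_h)
    order = np.argsort(eigvals.real)[::-1]
    eigvals = np.clip(eigvals.real[order], 0.0, None)
    lead = eigvecs[:, order[0]].real
    nz = np.nonzero(np.abs(lead) > 1e-12)[0]
    if nz.size and lead[nz[0]] < 0:
        lead = -lead
    sd_err = np.sqrt(np.diag(e) / (n - g))
    canonical = pd.Series(lead * sd_err, index=list(responses.columns), name="std_canonical")
    stats_table = _manova_fs(eigvals[: min(q, g - 1)], n, g, q)
    return ManovaResult(
        statistics=stats_table,
        canonical=canonical,
        eigenvalues=eigvals,
        n=n,
        n_groups=g,
        responses=list(responses.columns),
    )


def rank_contributions(result: ManovaResult) -> pd.DataFrame:
    """Responses ordered by |standardized canonical coefficient|, with signs.

    Ties are broken by input column order.
    """
    coefs = result.canonical
    order = sorted(
        range(len(coefs)), key=lambda i: (-abs(coefs.iloc[i]), i)
    )
    return pd.DataFrame(
        {
            "variable": [coefs.index[i] for i in order],
            "coefficient": [coefs.iloc[i] for i in order],
            "sign": ["-" if coefs.iloc[i] < 0 else "+" for i in order],
        }
    )


@dataclass
class StepwiseResult:
    """Final model of a backward p-value elimination."""

    coefficients: pd.DataFrame  # index: term; cols: estimate, se, t, p
    retained: list[str]
    dropped: list[str]
    r_squared: float
    p_overall: float
    n: int

    @property
    def significant(self) -> bool:
        return bool(self.retained) and np.isfinite(self.p_overall) and self.p_overall < 0.05


def backward_stepwise_regression(
    y, x: pd.DataFrame, alpha: float = 0.05
) -> StepwiseResult:
    """Backward stepwise multiple regression by p-value elimination.

    Fit the full least-squares model (with intercept), then repeatedly drop
    the predictor with the largest p-value while that p exceeds ``alpha``;
    stop when every remaining predictor has p <= alpha or none remain.
    Perfectly collinear (aliased) columns are dropped up front.
    """
    y = np.asarray(y, dtype=float)
    x = x.astype(float)
    n = len(y)
    if n != len(x):
        raise ValueError("length mismatch")
    if n <= x.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    cols = list(x.columns)
    dropped: list[str] = []
    # drop aliased columns (rank deficiency of the design matrix)
    design = sm.add_constant(x[cols])
    while np.linalg.matrix_rank(design.to_numpy()) < design.shape[1] and cols:
        dropped.append(cols.pop())
        design = sm.add_constant(x[cols])
    if dropped:
        import warnings

        warnings.warn(f"dropped aliased predictors: {dropped}")

    while True:
        model = sm.OLS(y, sm.add_constant(x[cols]) if cols else np.ones((n, 1))).fit()
        if not cols:
            break
        pvals = model.pvalues.drop("const", errors="ignore")
        worst = pvals.idxmax()
        if pvals[worst] > alpha:
            cols.remove(worst)
            dropped.append(worst)
        else:
            break
    coef = pd.DataFrame(
        {
            "estimate": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        }
    )
    return StepwiseResult(
        coefficients=coef,
        retained=cols,
        dropped=dropped,
        r_squared=float(model.rsquared) if cols else 0.0,
        p_overall=float(model.f_pvalue) if cols else float("nan"),
        n=n,
    )
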