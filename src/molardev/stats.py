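"""Supporting statistical comparisons.

Logistic event-timing models (does a character's state depend on embryo age,
with strain as an extra predictor), pooled-variance Student's t-tests on
epithelium measurements, Fisher exact tests on culture outcomes, a two-sided
F test comparing variances of adult molar dimensions, and a chi-square
goodness-of-fit test against equal frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TimingModelResult",
    "fit_timing_logistic",
    "student_t",
    "fisher_exact",
    "compare_variance",
    "chisq_gof",
]


@dataclass
class TimingModelResult:
    """Logistic timing-model fit: coefficient table plus diagnostics.

    ``table`` has one row per coefficient with columns coef, se, z, p.
    ``penalized`` flags the Jeffreys-prior (Firth) fallback used when the
    outcome is completely separated along a predictor.
    """

    table: pd.DataFrame
    loglik: float
    converged: bool
    penalized: bool

    @property
    def coefficients(self) -> pd.Series:
        return self.table["coef"]


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Firth's bias-reduced (Jeffreys-prior) logistic fit via modified IRLS.

    The score is adjusted with the hat-matrix leverages, which keeps the
    estimates finite under complete separation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        W = np.clip(w, 1e-10, None)
        XtW = X.T * W
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * W
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.pinv((X.T * W) @ X)
    loglik = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    # add the Jeffreys penalty so the reported objective matches the fit
    sign, logdet = np.linalg.slogdet((X.T * W) @ X)
    loglik_pen = loglik + 0.5 * logdet
    return beta, np.sqrt(np.diag(cov)), loglik_pen


def fit_timing_logistic(present, age, strain=None) -> TimingModelResult:
    """Maximum-likelihood logit of a binary developmental state on age.

    ``present`` is the binary outcome (e.g. R2 signaling activity),
    ``age`` the continuous predictor (cdpc or weight), and ``strain`` an
    optional two-level factor added as a dummy-coded effect. Wald z tests
    per coefficient. Complete separation triggers a penalized
    (Jeffreys-prior / Firth) refit with a warning.
    """
    y = np.asarray(present, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class: the timing model is undefined")
    cols = {"intercept": np.ones(len(y)), "age": np.asarray(age, float)}
    if strain is not None:
        levels = pd.unique(pd.Series(strain))
        if len(levels) != 2:
            raise ValueError("strain must have exactly two levels")
        cols[f"strain[{levels[1]}]"] = (pd.Series(strain) == levels[1]).to_numpy(float)
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())

    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    penalized = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = np.asarray(fit.params)
        se = np.asarray(fit.bse)
        loglik = float(fit.llf)
        converged = bool(fit.mle_retvals.get("converged", True))
        if not converged or not np.isfinite(se).all():
            raise PerfectSeparationError("no finite maximum-likelihood estimate")
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        warnings.warn(
            "complete or quasi-complete separation detected; falling back to a "
            "Jeffreys-prior (Firth) penalized fit",
            stacklevel=2,
        )
        penalized = True
        beta, se, loglik = _firth_logit(X, y)
    z = beta / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    table = pd.DataFrame({"coef": beta, "se": se, "z": z, "p": p}, index=names)
    return TimingModelResult(
        table=table, loglik=loglik, converged=converged, penalized=penalized
    )


def student_t(group_a, group_b) -> tuple[float, int, float]:
    """Two-sample pooled-variance (Student's) t-test, two-sided.

    Degenerate zero-variance inputs follow the documented conventions:
    equal means -> p = 1; unequal means -> p = 0 with a warning.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    df = len(a) + len(b) - 2
    pooled_var = (
        (len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)
    ) / df
    if pooled_var == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, df, 1.0
        warnings.warn("zero pooled variance with unequal means", stacklevel=2)
        return float("inf") if np.mean(a) > np.mean(b) else float("-inf"), df, 0.0
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact test on a 2x2 count table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one. A zero margin gives
    p = 1 by convention.
    """
    t = np.asarray(table, int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("a margin of the 2x2 table is zero; p = 1 by convention",
                      stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)


def compare_variance(lengths_a, lengths_b) -> tuple[float, float]:
    """Two-sided F-ratio test on two sample variances.

    Reports the larger/smaller variance ratio and the two-sided p from the
    F distribution.
    """
    a = np.asarray(lengths_a, float)
    b = np.asarray(lengths_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero variance in a group: the F test is undefined")
    if va >= vb:
        ratio, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        ratio, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = 2.0 * sps.f.sf(ratio, dfn, dfd)
    return float(ratio), float(min(p, 1.0))


def chisq_gof(counts) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of two counts against equal frequencies.

    No continuity correction; df = 1; p from the upper chi-square tail.
    """
    c = np.asarray(counts, float)
    if c.shape != (2,) or (c < 0).any():
        raise ValueError("counts must be two non-negative integers")
    total = c.sum()
    if total == 0:
        raise ValueError("total count is zero")
    expected = total / 2.0
    chi2 = float(np.sum((c - expected) ** 2 / expected))
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, 1, p
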