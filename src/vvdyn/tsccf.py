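"""Lag-limited cross-correlation screening with global FDR correction.

The screening workflow, per subject: first-difference every series (detrending,
so that slow drifts do not manufacture spurious correlations), confirm
stationarity of the differenced series with an augmented Dickey-Fuller test,
then cross-correlate the differenced X series against each differenced Y series
at integer lags ``-max_lag .. +max_lag``.  Each coefficient gets a nominal
two-sided p-value from standard Pearson theory on the aligned overlap
(``t = r * sqrt((m - 2) / (1 - r^2))`` with ``m - 2`` degrees of freedom,
``m`` the number of overlapping pairs).  All nominal p-values across the whole
subject x variable x lag grid are pooled and corrected with the
Benjamini-Hochberg step-up rule.

Lag sign convention: the coefficient at lag ``k`` correlates ``(x_t, y_{t+k})``
— positive ``k`` means events in Y follow events in X.  By construction the
coefficient of (X, Y) at lag ``k`` equals that of (Y, X) at lag ``-k``.

The estimator is the Pearson correlation over the aligned overlap
(denominator ``m``), not the denominator-``n`` stationary CCF estimator, whose
shrinkage is material at the 12-point series lengths this screen targets; the
stationary variant is available via ``estimator="stationary"`` for
cross-checking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from .cohort import Cohort

__all__ = [
    "CCFRecord",
    "ADFResult",
    "ACFResult",
    "ScreenResult",
    "first_difference",
    "adf_stationarity_test",
    "cross_correlation",
    "ccf_pvalue",
    "autocorrelation_check",
    "bh_fdr",
    "run_ccf_screen",
    "summarize_screen",
]

logger = logging.getLogger(__name__)


def first_difference(series: np.ndarray) -> np.ndarray:
    """Replace each point by its change from the preceding point."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points to difference")
    if not np.all(np.isfinite(x)):
        raise ValueError("differencing requires a complete series (no missing values)")
    return np.diff(x)


@dataclass(frozen=True)
class ADFResult:
    statistic: float
    pvalue: float
    stationary: bool  # unit root rejected at alpha = 0.05
    used_lag: int
    n_obs: int


def adf_stationarity_test(series: np.ndarray, max_lag: int | str = "auto") -> ADFResult:
    """Augmented Dickey-Fuller test with drift (regression on a constant).

    ``max_lag="auto"`` uses no lagged-difference augmentation for series of
    length <= 14 (a dozen points cannot support it) and Schwert's rule with
    AIC selection for longer series.  The statistic is the t-ratio of the
    lagged-level coefficient; p-values come from MacKinnon's interpolated
    response surface.
    """
    x = np.asarray(series, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("ADF test is ill-posed for a constant series")
    n = x.size
    if max_lag == "auto":
        if n <= 14:
            lag, autolag = 0, None
        else:
            lag, autolag = int(12 * (n / 100.0) ** 0.25), "AIC"
    else:
        lag, autolag = int(max_lag), None
    if n < lag + 4:
        raise ValueError(f"series of length {n} too short for max_lag={lag}")
    stat, pvalue, used_lag, n_obs, *_ = adfuller(x, maxlag=lag, regression="c", autolag=autolag)
    return ADFResult(
        statistic=float(stat),
        pvalue=float(pvalue),
        stationary=bool(pvalue < 0.05),
        used_lag=int(used_lag),
        n_obs=int(n_obs),
    )


def cross_correlation(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int = 2,
    estimator: str = "pearson",
) -> list[tuple[int, float, int]]:
    """Cross-correlation at lags -max_lag..+max_lag over the aligned overlap.

    Returns (lag, coefficient, n_effective) triples; a zero-variance overlap
    yields a NaN coefficient rather than a fabricated value.  With
    ``estimator="stationary"`` the denominator-n CCF estimator (global means,
    full-series variances) is returned instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if n - max_lag < 3:
        raise ValueError(f"series of length {n} too short for max_lag={max_lag}")
    out = []
    for k in range(-max_lag, max_lag + 1):
        if k >= 0:
            xs, ys = x[: n - k], y[k:]
        else:
            xs, ys = x[-k:], y[: n + k]
        m = n - abs(k)
        if estimator == "stationary":
            denom = n * x.std(ddof=0) * y.std(ddof=0)
            coef = float(((xs - x.mean()) * (ys - y.mean())).sum() / denom) if denom > 0 else np.nan
        else:
            xc = xs - xs.mean()
            yc = ys - ys.mean()
            denom = np.sqrt((xc @ xc) * (yc @ yc))
            coef = float((xc @ yc) / denom) if denom > 0 else np.nan
        out.append((k, coef, m))
    return out


def ccf_pvalue(coefficient: float, n_effective: int) -> float:
    """Two-sided nominal p for one cross-correlation coefficient.

    Pearson theory on the overlap: ``t = r sqrt((m-2)/(1-r^2))``, ``m - 2``
    degrees of freedom.  ``|r| = 1`` gives p = 0; fewer than 4 overlapping
    pairs (or a NaN coefficient) gives NaN — undefined, to be excluded.
    """
    if n_effective < 4 or not np.isfinite(coefficient):
        return float("nan")
    r = float(coefficient)
    if not -1.0 <= r <= 1.0:
        raise ValueError("coefficient must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    df = n_effective - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


@dataclass(frozen=True)
class ACFResult:
    acf: np.ndarray          # lags 0..max_lag; lag 0 is 1 by definition
    bound: float             # white-noise band 1.96 / sqrt(n)
    flagged: bool            # any |acf(k)| > bound for k >= 1


def autocorrelation_check(series: np.ndarray, max_lag: int = 2) -> ACFResult:
    """Sample ACF with a 1.96/sqrt(n) white-noise band; flags periodicity."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < max_lag + 3:
        raise ValueError(f"series of length {n} too short for max_lag={max_lag}")
    xc = x - x.mean()
    denom = xc @ xc
    if denom == 0:
        raise ValueError("ACF is undefined for a constant series")
    acf = np.array([1.0] + [float((xc[: n - k] @ xc[k:]) / denom) for k in range(1, max_lag + 1)])
    bound = 1.96 / np.sqrt(n)
    return ACFResult(acf=acf, bound=bound, flagged=bool(np.any(np.abs(acf[1:]) > bound)))


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q-values, rejection flags).

    Rejects all sorted p_(i) with i <= k* where k* = max{i : p_(i) <= i*alpha/m};
    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = np.arange(1, m + 1) * alpha / m
    passing = np.nonzero(ranked <= crit)[0]
    reject_sorted = np.zeros(m, dtype=bool)
    if passing.size:
        reject_sorted[: passing[-1] + 1] = True
    q_sorted = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    reject = np.empty(m, dtype=bool)
    q[order] = q_sorted
    reject[order] = reject_sorted
    return q, reject


@dataclass
class CCFRecord:
    """One (subject, X, Y, lag) cross-correlation coefficient."""

    subject_id: str
    x_variable: str
    y_variable: str
    lag: int
    coefficient: float
    n_effective: int
    p_nominal: float
    q_fdr: float = float("nan")
    significant: bool = False

    @property
    def defined(self) -> bool:
        return np.isfinite(self.coefficient) and np.isfinite(self.p_nominal)


@dataclass
class ScreenResult:
    """Records plus bookkeeping from one screening run."""

    records: list[CCFRecord]
    x_variable: str
    y_variables: list[str]
    max_lag: int
    alpha: float
    fdr_pool: str
    n_subjects_screened: int
    skipped_subjects: list[str] = field(default_factory=list)
    adf_failures: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "x": [r.x_variable for r in self.records],
                "y": [r.y_variable for r in self.records],
                "lag": [r.lag for r in self.records],
                "coefficient": [r.coefficient for r in self.records],
                "n_effective": [r.n_effective for r in self.records],
                "p_nominal": [r.p_nominal for r in self.records],
                "q_fdr": [r.q_fdr for r in self.records],
                "significant": [r.significant for r in self.records],
            }
        )

    def summary(self) -> dict:
        return summarize_screen(self)


def run_ccf_screen(
    cohort: Cohort,
    x_variable: str,
    y_variables: list[str] | None = None,
    max_lag: int = 2,
    alpha: float = 0.05,
    fdr_pool: str = "all",
    stationarity_check: bool = True,
) -> ScreenResult:
    """Screen every subject's X series against every Y series over all lags.

    ``fdr_pool="all"`` applies Benjamini-Hochberg across the full grid of
    defined coefficients (the BH family is the whole grid);
    ``fdr_pool="nominal"`` applies it only to the nominally significant subset
    (p < 0.05), the two-stage reading — records outside that subset keep a NaN
    q-value.  Subjects missing any required series are skipped with a logged
    reason; ADF failures are recorded but do not abort the screen.
    """
    if fdr_pool not in ("all", "nominal"):
        raise ValueError("fdr_pool must be 'all' or 'nominal'")
    if y_variables is None:
        names: list[str] = []
        for s in cohort:
            for v in s.variables:
                if v != x_variable and v not in names:
                    names.append(v)
        y_variables = names
    if x_variable in y_variables:
        raise ValueError("x_variable must not appear among y_variables")

    records: list[CCFRecord] = []
    skipped: list[str] = []
    adf_failures: list[tuple[str, str]] = []
    n_screened = 0
    needed = [x_variable] + list(y_variables)
    for subject in cohort:
        if not subject.has_complete(needed):
            skipped.append(subject.subject_id)
            logger.warning("skipping %s: incomplete series", subject.subject_id)
            continue
        n_screened += 1
        diffed = {name: first_difference(subject.variables[name]) for name in needed}
        if stationarity_check:
            for name, d in diffed.items():
                try:
                    adf = adf_stationarity_test(d)
                except ValueError:
                    adf_failures.append((subject.subject_id, name))
                    continue
                if not adf.stationary:
                    adf_failures.append((subject.subject_id, name))
                    logger.warning(
                        "ADF did not confirm stationarity for %s/%s (p=%.3f)",
                        subject.subject_id, name, adf.pvalue,
                    )
        dx = diffed[x_variable]
        for y in y_variables:
            for lag, coef, m in cross_correlation(dx, diffed[y], max_lag=max_lag):
                records.append(
                    CCFRecord(
                        subject_id=subject.subject_id,
                        x_variable=x_variable,
                        y_variable=y,
                        lag=lag,
                        coefficient=coef,
                        n_effective=m,
                        p_nominal=ccf_pvalue(coef, m),
                    )
                )

    defined = [r for r in records if r.defined]
    if fdr_pool == "all":
        pool = defined
    else:
        pool = [r for r in defined if r.p_nominal < 0.05]
    if pool:
        q, reject = bh_fdr(np.array([r.p_nominal for r in pool]), alpha=alpha)
        for r, qi, ri in zip(pool, q, reject):
            r.q_fdr = float(qi)
            r.significant = bool(ri)
    return ScreenResult(
        records=records,
        x_variable=x_variable,
        y_variables=list(y_variables),
        max_lag=max_lag,
        alpha=alpha,
        fdr_pool=fdr_pool,
        n_subjects_screened=n_screened,
        skipped_subjects=skipped,
        adf_failures=adf_failures,
    )


def summarize_screen(result: ScreenResult) -> dict:
    """Counts, per-axis breakdowns, and 3-D lollipop coordinates."""
    records = result.records
    defined = [r for r in records if r.defined]
    retained = [r for r in records if r.significant]

    def breakdown(key) -> dict:
        out: dict = {}
        for r in retained:
            out[key(r)] = out.get(key(r), 0) + 1
        return out

    lollipop = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in retained],
            "y_variable": [r.y_variable for r in retained],
            "abs_lag": [abs(r.lag) for r in retained],
            "lag": [r.lag for r in retained],
            "coefficient": [r.coefficient for r in retained],
        }
    )
    return {
        "x_variable": result.x_variable,
        "total_coefficients": len(records),
        "n_defined": len(defined),
        "n_undefined": len(records) - len(defined),
        "n_nominal": int(sum(r.p_nominal < 0.05 for r in defined)),
        "n_fdr_retained": len(retained),
        "n_subjects_screened": result.n_subjects_screened,
        "n_subjects_skipped": len(result.skipped_subjects),
        "n_adf_failures": len(result.adf_failures),
        "per_subject": breakdown(lambda r: r.subject_id),
        "per_variable": breakdown(lambda r: r.y_variable),
        "per_lag": breakdown(lambda r: r.lag),
        "lollipop": lollipop,
    }
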