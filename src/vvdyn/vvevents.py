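"""Ventricle-volume event detection, cohort stratification, and group tests.

All analyses run on the percent-of-baseline trace: the first scan is the
baseline and entry ``t`` is ``100 * (V_t - V_0) / V_0``.  The healthy-variation
band (default +/-6 percentage points, the published scan-rescan bound) defines
"events": maximal same-sign runs of month-to-month changes whose cumulative
magnitude exceeds the threshold.  A subject is *contracting* when some window
of at least ``min_duration`` intervals is non-increasing throughout and drops
by more than the threshold — a sustained contraction with no expansions in
between.  A zero-change month does not break a contraction window; a positive
month does.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import VV, Cohort, SubjectSeries

__all__ = [
    "DEFAULT_THRESHOLD_PCT",
    "IntervalEvent",
    "VVEventProfile",
    "ThresholdEstimate",
    "StratificationResult",
    "percent_change_from_baseline",
    "estimate_normal_variation_threshold",
    "detect_interval_changes",
    "classify_contraction_status",
    "coefficient_of_variation",
    "build_event_profile",
    "stratify_cohort",
    "cohort_median_change",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "two_sample_t",
    "chi_square_2x2",
]

logger = logging.getLogger(__name__)

#: Healthy-band default: maximum intraindividual VV change observed in serial
#: scans of healthy adults, one-sided magnitude in percent of baseline.
DEFAULT_THRESHOLD_PCT = 6.0

CONTRACTING = "contracting"
NONCONTRACTING = "noncontracting"


@dataclass(frozen=True)
class IntervalEvent:
    """Maximal same-sign run of interval changes exceeding the threshold."""

    start: int
    end: int
    magnitude: float  # signed cumulative change in percentage points
    direction: str    # "expansion" | "contraction"


@dataclass
class VVEventProfile:
    subject_id: str
    pct_trace: np.ndarray
    interval_changes: np.ndarray
    events: list[IntervalEvent]
    status: str
    expansion_only: bool
    max_contraction: float  # most negative sustained drop, <= 0
    cv: float               # coefficient of variation of the raw VV, percent


@dataclass
class ThresholdEstimate:
    value: float
    source: str  # "fixed" | "estimated"
    per_subject_maxima: list[float] = field(default_factory=list)


def percent_change_from_baseline(vv_series: np.ndarray) -> np.ndarray:
    """Percent change of each scan relative to the first (baseline) scan."""
    v = np.asarray(vv_series, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 scans to form a percent trace")
    if not np.isfinite(v[0]) or v[0] <= 0:
        raise ValueError("baseline volume must be present and positive")
    return 100.0 * (v - v[0]) / v[0]


def estimate_normal_variation_threshold(healthy_cohort: Cohort | None) -> ThresholdEstimate:
    """Healthy-variation threshold: cohort max of per-subject max |%change|.

    With no healthy data the published fixed band of 6% is returned.
    """
    if healthy_cohort is None or len(healthy_cohort) == 0:
        return ThresholdEstimate(value=DEFAULT_THRESHOLD_PCT, source="fixed")
    maxima = []
    for s in healthy_cohort:
        if VV not in s.variables:
            raise ValueError(f"healthy subject {s.subject_id!r} has no VV series")
        pct = percent_change_from_baseline(s.variables[VV])
        maxima.append(float(np.nanmax(np.abs(pct))))
    value = max(maxima)
    if value == 0.0:
        warnings.warn(
            "estimated healthy-variation threshold is 0 (constant VV); "
            "a zero threshold is degenerate for event detection",
            stacklevel=2,
        )
    return ThresholdEstimate(value=value, source="estimated", per_subject_maxima=maxima)


def detect_interval_changes(pct_trace: np.ndarray, threshold: float) -> list[IntervalEvent]:
    """Above-threshold events: maximal same-sign runs of interval changes.

    A zero interval change is sign-neutral and terminates the current run.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pct = np.asarray(pct_trace, dtype=float)
    if pct.size < 2:
        raise ValueError("trace must have at least 2 points")
    deltas = np.diff(pct)
    events: list[IntervalEvent] = []
    run_start: int | None = None
    run_sign = 0

    def close_run(end: int) -> None:
        nonlocal run_start, run_sign
        if run_start is not None:
            magnitude = pct[end] - pct[run_start]
            if abs(magnitude) > threshold:
                direction = "expansion" if magnitude > 0 else "contraction"
                events.append(IntervalEvent(run_start, end, float(magnitude), direction))
        run_start, run_sign = None, 0

    for t, d in enumerate(deltas):
        sign = int(np.sign(d))
        if sign == 0:
            close_run(t)
            continue
        if sign != run_sign:
            close_run(t)
            run_start, run_sign = t, sign
    close_run(len(pct) - 1)
    return events


def classify_contraction_status(
    pct_trace: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD_PCT,
    min_duration: int = 2,
) -> tuple[str, bool, float]:
    """Classify a trace as contracting or noncontracting.

    Contracting: some window ``[t0, t1]`` with ``t1 - t0 >= min_duration``
    intervals is non-increasing throughout and drops by more than
    ``threshold`` percentage points.  ``expansion_only`` is true when the trace
    has an above-threshold expansion event but no above-threshold contraction
    event of any duration.  ``max_contraction`` is the most negative drop over
    any non-increasing window (0 for monotonically rising traces).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_duration < 1:
        raise ValueError("min_duration must be at least 1")
    pct = np.asarray(pct_trace, dtype=float)
    if pct.size < 2:
        raise ValueError("trace must have at least 2 points")

    n = pct.size
    deltas = np.diff(pct)
    contracting = False
    max_contraction = 0.0
    for t0 in range(n - 1):
        for t1 in range(t0 + 1, n):
            if deltas[t1 - 1] > 0:
                break  # window [t0, t1] no longer non-increasing
            drop = pct[t1] - pct[t0]  # <= 0
            max_contraction = min(max_contraction, drop)
            if t1 - t0 >= min_duration and -drop > threshold:
                contracting = True

    events = detect_interval_changes(pct, threshold)
    has_expansion = any(e.direction == "expansion" for e in events)
    has_contraction_event = any(e.direction == "contraction" for e in events)
    status = CONTRACTING if contracting else NONCONTRACTING
    expansion_only = has_expansion and not has_contraction_event and not contracting
    return status, expansion_only, float(max_contraction)


def coefficient_of_variation(series: np.ndarray) -> float:
    """100 * sample standard deviation (n-1 denominator) / mean."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV is undefined for zero-mean series")
    return float(100.0 * x.std(ddof=1) / mean)


def build_event_profile(
    subject: SubjectSeries,
    threshold: float = DEFAULT_THRESHOLD_PCT,
    min_duration: int = 2,
) -> VVEventProfile:
    vv = subject.variables[VV]
    pct = percent_change_from_baseline(vv)
    status, expansion_only, max_contraction = classify_contraction_status(
        pct, threshold, min_duration
    )
    return VVEventProfile(
        subject_id=subject.subject_id,
        pct_trace=pct,
        interval_changes=np.diff(pct),
        events=detect_interval_changes(pct, threshold),
        status=status,
        expansion_only=expansion_only,
        max_contraction=max_contraction,
        cv=coefficient_of_variation(vv),
    )


@dataclass
class StratificationResult:
    """Disjoint exhaustive partition of a cohort by contraction status."""

    profiles: list[VVEventProfile]
    threshold: float
    min_duration: int
    excluded: list[str] = field(default_factory=list)

    @property
    def contracting_ids(self) -> list[str]:
        return [p.subject_id for p in self.profiles if p.status == CONTRACTING]

    @property
    def noncontracting_ids(self) -> list[str]:
        return [p.subject_id for p in self.profiles if p.status == NONCONTRACTING]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [p.subject_id for p in self.profiles],
                "status": [p.status for p in self.profiles],
                "expansion_only": [p.expansion_only for p in self.profiles],
                "max_contraction": [p.max_contraction for p in self.profiles],
                "cv": [p.cv for p in self.profiles],
                "n_events": [len(p.events) for p in self.profiles],
            }
        )

    def lollipop_frame(self) -> pd.DataFrame:
        """Per-subject trace coordinates plus the max-contraction lollipop drop."""
        rows = []
        for p in self.profiles:
            for t, pct in enumerate(p.pct_trace):
                rows.append(
                    {
                        "subject_id": p.subject_id,
                        "time": t,
                        "pct_change": pct,
                        "status": p.status,
                        "max_contraction": p.max_contraction,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        n = len(self.profiles)
        any_monthly = [
            bool(np.any(np.abs(p.interval_changes) > self.threshold)) for p in self.profiles
        ]
        by_status: dict[str, list[VVEventProfile]] = {CONTRACTING: [], NONCONTRACTING: []}
        for p in self.profiles:
            by_status[p.status].append(p)
        return {
            "n_subjects": n,
            "n_contracting": len(by_status[CONTRACTING]),
            "n_noncontracting": len(by_status[NONCONTRACTING]),
            "n_any_above_threshold_monthly_change": int(np.sum(any_monthly)),
            "n_expansion_only": int(sum(p.expansion_only for p in self.profiles)),
            "cv_mean_contracting": float(np.mean([p.cv for p in by_status[CONTRACTING]]))
            if by_status[CONTRACTING] else float("nan"),
            "cv_mean_noncontracting": float(np.mean([p.cv for p in by_status[NONCONTRACTING]]))
            if by_status[NONCONTRACTING] else float("nan"),
            "threshold": self.threshold,
            "excluded": list(self.excluded),
        }


def stratify_cohort(
    cohort: Cohort,
    threshold: float = DEFAULT_THRESHOLD_PCT,
    min_duration: int = 2,
) -> StratificationResult:
    """Partition a cohort into contracting / noncontracting subjects.

    Subjects with missing VV values are excluded with a logged warning — the
    event rules need complete monthly traces.
    """
    profiles = []
    excluded = []
    for subject in cohort:
        vv = subject.variables.get(VV)
        if vv is None or not np.all(np.isfinite(vv)):
            excluded.append(subject.subject_id)
            logger.warning("excluding %s from stratification: missing VV", subject.subject_id)
            continue
        profiles.append(build_event_profile(subject, threshold, min_duration))
    return StratificationResult(
        profiles=profiles, threshold=threshold, min_duration=min_duration, excluded=excluded
    )


def cohort_median_change(baseline: np.ndarray, final: np.ndarray) -> dict:
    """Group-level VV change between two visits, under both percent definitions.

    The difference of group medians has two natural percent forms that do not
    agree in general: the difference expressed as a percent of the baseline
    median, and the median of the per-subject percent changes.  Both are
    reported rather than guessing which one a summary figure used.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(final, dtype=float)
    if b.shape != f.shape or b.size == 0:
        raise ValueError("need aligned nonempty baseline/final samples")
    med_b = float(np.median(b))
    med_f = float(np.median(f))
    return {
        "median_baseline": med_b,
        "median_final": med_f,
        "median_difference": med_f - med_b,
        "pct_of_baseline_median": 100.0 * (med_f - med_b) / med_b,
        "median_subject_pct_change": float(np.median(100.0 * (f - b) / b)),
    }


# --- group-contrast tests ----------------------------------------------------

def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray | None = None) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples (or differences directly).

    Zero differences are dropped.  For n <= 25 the p-value is exact, from the
    full sign-flip distribution of the positive-rank sum (average ranks, so
    tied magnitudes are handled); beyond that a normal approximation with tie
    correction is used.  Returns (W+, two-sided p).
    """
    d = np.asarray(x, dtype=float) - (0.0 if y is None else np.asarray(y, dtype=float))
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: signed-rank test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        # exact sign-flip distribution by convolution on doubled (integer) ranks
        scaled = np.round(2 * ranks).astype(int)
        total = scaled.sum()
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in scaled:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        counts /= 2.0**n
        w2 = int(round(2 * w_plus))
        p_low = counts[: w2 + 1].sum()
        p_high = counts[w2:].sum()
        p = min(1.0, 2.0 * min(p_low, p_high))
        return w_plus, float(p)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mu) / np.sqrt(var)
    return w_plus, float(2.0 * stats.norm.sf(abs(z)))


def mann_whitney_u(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U test, exact for small tie-free samples.

    Exact enumeration when both groups have <= 10 observations and no value is
    shared; otherwise the normal approximation with tie correction.  Returns
    (U of sample_a, two-sided p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-tailed pooled-variance Student's t test (df = nA + nB - 2)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df 1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)
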