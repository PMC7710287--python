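"""EAE timing analysis: contrast quantification, event times, and survival.

The mouse arm asks *when* each disease marker moves: the day ventricle volume
(VV) first exceeds the healthy band, the day of maximal gadolinium enhancement
(largest delta-T1 = precontrast minus postcontrast mean T1), the day of
clinical onset (first score at or above 1), and the day of maximal body-weight
loss.  Those per-animal event days are compared as time-to-event distributions
with Kaplan-Meier curves and the log-rank test, and ordinal histopathology
scores are correlated with imaging read-outs by Spearman rank correlation.

Tie rule: argmax/argmin events resolve to the earliest day — observation
schedules are coarse, and earliest is the conservative choice when asking
whether one marker precedes another.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from .cohort import VV, Cohort, SubjectSeries
from .vvevents import percent_change_from_baseline

__all__ = [
    "EAETimingRecord",
    "delta_t1",
    "extract_event_times",
    "extract_cohort_event_times",
    "kaplan_meier",
    "logrank_test",
    "paired_sign_test",
    "spearman",
    "one_way_anova",
    "compare_event_timing",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = {
    "vv_onset": ("t_vv_onset", "vv_onset_censored"),
    "dt1_max": ("t_dt1_max", "dt1_censored"),
    "clinical_onset": ("t_clinical_onset", "clinical_censored"),
    "weight_nadir": ("t_weight_nadir", "weight_censored"),
}


def delta_t1(t1_pre: float, t1_post: float) -> float:
    """Contrast-induced T1 shortening: precontrast minus postcontrast mean T1.

    Negative values are allowed — they flag absence of net enhancement.
    """
    if not (np.isfinite(t1_pre) and np.isfinite(t1_post)):
        raise ValueError("T1 values must be finite")
    if t1_pre <= 0 or t1_post <= 0:
        raise ValueError("T1 relaxation times must be positive")
    return float(t1_pre - t1_post)


@dataclass
class EAETimingRecord:
    """Per-animal event days with censoring flags (censored at the last day)."""

    animal_id: str
    t_vv_onset: float
    vv_onset_censored: bool
    t_dt1_max: float
    dt1_censored: bool
    t_clinical_onset: float
    clinical_censored: bool
    t_weight_nadir: float
    weight_censored: bool


def extract_event_times(
    animal: SubjectSeries,
    vv_threshold: float = 6.0,
    onset_score: float = 1.0,
    dt1_variable: str = "dt1_whole_brain",
) -> EAETimingRecord:
    """Extract the four marker event days from one animal's series.

    VV onset = first day the percent-of-baseline trace exceeds ``vv_threshold``;
    delta-T1 maximum and weight nadir are argmax/argmin days (earliest on
    ties); clinical onset = first day the score reaches ``onset_score``.
    Threshold events that never occur are censored at the last observed day.
    Pre-immunization baseline scans (negative days) anchor the percent trace
    but are not eligible event days.
    """
    days = animal.time
    if days.size == 0:
        raise ValueError("empty series")
    last = float(days[-1])
    post = days >= 0  # events are post-immunization by definition

    pct = percent_change_from_baseline(animal.variables[VV])
    above = np.nonzero((pct > vv_threshold) & post)[0]
    t_vv = float(days[above[0]]) if above.size else last

    dt1 = np.where(post, animal.variables[dt1_variable], -np.inf)
    t_dt1 = float(days[int(np.argmax(dt1))])  # argmax returns the earliest tie

    score = animal.variables["score"]
    onset = np.nonzero((score >= onset_score) & post)[0]
    t_clin = float(days[onset[0]]) if onset.size else last

    weight = np.where(post, animal.variables["weight"], np.inf)
    t_nadir = float(days[int(np.argmin(weight))])

    return EAETimingRecord(
        animal_id=animal.subject_id,
        t_vv_onset=t_vv,
        vv_onset_censored=not bool(above.size),
        t_dt1_max=t_dt1,
        dt1_censored=False,
        t_clinical_onset=t_clin,
        clinical_censored=not bool(onset.size),
        t_weight_nadir=t_nadir,
        weight_censored=False,
    )


def extract_cohort_event_times(cohort: Cohort, **kwargs) -> pd.DataFrame:
    """Event-time table for a whole cohort; one row per animal."""
    rows = [extract_event_times(animal, **kwargs).__dict__ for animal in cohort]
    return pd.DataFrame(rows)


def kaplan_meier(times: np.ndarray, observed: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate: columns time, survival, at_risk.

    ``observed`` is 1/True for an event, 0/False for censoring.  S(0) = 1 and
    S steps down only at event times; with no censoring this equals the
    empirical survival function.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(observed, dtype=bool)
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t < 0):
        raise ValueError("event times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
    return pd.DataFrame(
        {
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float),
        }
    )


def logrank_test(
    times_a: np.ndarray,
    observed_a: np.ndarray,
    times_b: np.ndarray,
    observed_b: np.ndarray,
) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test; returns (chi-square, two-sided p)."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(observed_a, dtype=bool)
    eb = np.asarray(observed_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank test needs at least one observed event")
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def paired_sign_test(times_a: np.ndarray, times_b: np.ndarray) -> tuple[int, float]:
    """Exact binomial sign test on paired event days (ties dropped).

    Alternative to the two-sample log-rank when both event types come from the
    same animals; returns (number of positive differences, two-sided p).
    """
    d = np.asarray(times_a, dtype=float) - np.asarray(times_b, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    k = int(np.sum(d > 0))
    p = float(stats.binomtest(k, d.size, 0.5).pvalue)
    return k, p


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    return float((rxc @ ryc) / np.sqrt((rxc @ rxc) * (ryc @ ryc)))


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation.

    rho is the Pearson correlation of average ranks.  The two-sided p-value is
    an exact permutation enumeration for n <= 8 (all n! orderings of y) and the
    usual t-approximation for larger n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman correlation is undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)
    n = x.size
    if n <= 8:
        perms = np.array(list(itertools.permutations(ry)))
        pc = perms - perms.mean(axis=1, keepdims=True)
        rxc = rx - rx.mean()
        rhos = (pc @ rxc) / np.sqrt((pc * pc).sum(axis=1) * (rxc @ rxc))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) == 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def one_way_anova(*groups: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F test across two or more groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    n_total = sum(a.size for a in arrays)
    if n_total - len(arrays) <= 0:
        raise ValueError("no within-group degrees of freedom")
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def compare_event_timing(timing: pd.DataFrame, method: str = "logrank") -> dict:
    """Pairwise timing comparisons between the four marker events.

    ``method="logrank"`` applies the two-sample log-rank to each pair of event
    types (the published comparison, though the times are paired within
    animals); ``method="paired_sign"`` applies an exact sign test instead.
    Returns ``{"a_vs_b": {"statistic": ..., "p": ...}, ...}``.
    """
    out = {}
    names = list(EVENT_COLUMNS)
    for a, b in itertools.combinations(names, 2):
        ta, ca = EVENT_COLUMNS[a]
        tb, cb = EVENT_COLUMNS[b]
        if method == "logrank":
            stat, p = logrank_test(
                timing[ta].to_numpy(), ~timing[ca].to_numpy(dtype=bool),
                timing[tb].to_numpy(), ~timing[cb].to_numpy(dtype=bool),
            )
        elif method == "paired_sign":
            stat, p = paired_sign_test(timing[ta].to_numpy(), timing[tb].to_numpy())
        else:
            raise ValueError("method must be 'logrank' or 'paired_sign'")
        out[f"{a}_vs_{b}"] = {"statistic": float(stat), "p": float(p)}
    return out
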