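"""Synthetic cohorts with the statistical structure the analyses assume.

Three generators, one per study arm:

``generate_healthy_cohort``
    Serial scans of healthy adults whose ventricle volume (VV) fluctuates
    around a fixed baseline: ``V_t = V_0 * (1 + eps_t)`` with ``eps_0 = 0`` and
    i.i.d. Gaussian ``eps_t``.  Emulates scan-rescan variability studies that
    anchor the healthy-variation band (about +/-6 percent of baseline).

``generate_ms_cohort``
    Relapsing-remitting MS patients followed monthly: VV carries a slow atrophy
    drift plus episodic piecewise-linear expansion/contraction bumps; eight MRI
    and four clinical covariates carry AR(1) noise and configurable lagged
    linear couplings to a standardized driver series.  Contrast-enhancing
    lesion (CEL) counts are Poisson with a log-link to their driver, CEL volume
    is count times log-normal lesion sizes.

``generate_eae_cohort``
    Experimental autoimmune encephalomyelitis mice scanned every other day: a
    preclinical VV peak and gadolinium-enhancement (delta-T1) peak precede
    clinical onset; body weight dips with the clinical score; an ordinal 0-3
    histopathology score rises monotonically with sacrifice day.

Every generator expands one integer seed into independent per-subject
substreams, so enlarging a cohort never perturbs already-generated subjects.
Ground truth (injected couplings, episode windows, event days) is returned on
``Cohort.ground_truth`` for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .cohort import VV, Cohort, SubjectSeries

__all__ = [
    "CouplingSpec",
    "MSCohortConfig",
    "EAECohortConfig",
    "MS_COVARIATES",
    "generate_healthy_cohort",
    "generate_ms_cohort",
    "generate_eae_cohort",
    "generate_null_cohort",
]

# 8 MRI + 4 clinical covariates carried alongside VV in the patient arm.
MS_MRI_VARIABLES = [
    "cel_count",
    "cel_volume",
    "t2_lesion_volume",
    "bh_lesion_volume",
    "adc_cc",
    "adc_bg",
    "adc_bs",
    "adc_wm",
]
MS_CLINICAL_VARIABLES = ["pasat", "hpt_dom", "hpt_ndom", "twt"]
MS_COVARIATES = MS_MRI_VARIABLES + MS_CLINICAL_VARIABLES

# Plausible clinical locations/scales for the continuous covariates
# (volumes in mm^3, ADC in 10^-3 mm^2/s, PASAT in correct answers,
# peg test and timed walk in seconds).
DEFAULT_COVARIATE_BASELINES: dict[str, tuple[float, float]] = {
    "t2_lesion_volume": (8000.0, 900.0),
    "bh_lesion_volume": (2000.0, 250.0),
    "adc_cc": (0.80, 0.03),
    "adc_bg": (0.75, 0.03),
    "adc_bs": (0.78, 0.03),
    "adc_wm": (0.72, 0.02),
    "pasat": (48.0, 3.0),
    "hpt_dom": (20.0, 1.8),
    "hpt_ndom": (22.0, 2.0),
    "twt": (6.0, 0.7),
}


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth lagged linear coupling between two generated variables.

    ``lag`` follows the screen's convention: positive lag means the target's
    events follow the driver's, i.e. ``target_t`` receives
    ``coefficient * z_driver(t - lag)``.
    """

    driver_variable: str
    target_variable: str
    lag: int
    coefficient: float

    def __post_init__(self) -> None:
        if self.driver_variable == self.target_variable:
            raise ValueError("coupling driver and target must differ")
        if not -1.0 <= self.coefficient <= 1.0:
            raise ValueError("coupling coefficient must lie in [-1, 1]")


@dataclass
class MSCohortConfig:
    """Monthly MS cohort: sizes, VV episode model, covariate couplings."""

    n_patients: int = 33
    n_timepoints: int = 13
    baseline_vv_range: tuple[float, float] = (25000.0, 42000.0)
    atrophy_drift: float = 0.0001          # fractional VV change per month
    episode_probability: float = 0.75
    episode_amplitude_range: tuple[float, float] = (0.10, 0.40)
    episode_rise_range: tuple[int, int] = (1, 3)
    episode_fall_range: tuple[int, int] = (1, 3)
    noise_sd: float = 0.015                # fractional VV noise
    couplings: list[CouplingSpec] = field(
        default_factory=lambda: [
            CouplingSpec(VV, "cel_count", lag=0, coefficient=0.6),
            CouplingSpec(VV, "t2_lesion_volume", lag=1, coefficient=0.5),
        ]
    )
    covariate_baselines: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_BASELINES)
    )
    ar_coefficient: float = 0.3
    covariate_noise_sd: float | None = None  # None -> sqrt(1 - sum coef^2) per target
    cel_base_rate: float = 2.0
    cel_log_size_mean: float = np.log(60.0)  # mm^3 per lesion
    cel_log_size_sd: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 5:
            raise ValueError("need at least 5 time points")
        if self.baseline_vv_range[0] <= 0 or self.baseline_vv_range[1] < self.baseline_vv_range[0]:
            raise ValueError("baseline VV range must be positive and ordered")
        if self.episode_amplitude_range[0] <= 0:
            raise ValueError("episode amplitudes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must lie in [0, 1)")
        max_lag = self.n_timepoints - 3
        for c in self.couplings:
            if abs(c.lag) > max_lag:
                raise ValueError(
                    f"coupling lag {c.lag} leaves no estimable overlap for "
                    f"{self.n_timepoints} time points (|lag| must be <= {max_lag})"
                )


@dataclass
class EAECohortConfig:
    """Every-other-day EAE mouse cohort with a preclinical VV / delta-T1 peak."""

    n_mice: int = 16
    schedule_days: tuple[int, ...] = tuple([-2] + list(range(0, 31, 2)))
    baseline_vv_range: tuple[float, float] = (8.0, 12.0)   # mm^3
    # VV peak: rise starts at the onset day, peaks, resolves back to baseline.
    vv_onset_day_mean: float = 6.0
    vv_onset_day_sd: float = 1.5
    vv_onset_day_min: float = 2.0
    vv_peak_day_offset: float = 6.0       # peak this many days after rise onset
    vv_amplitude_range: tuple[float, float] = (0.30, 1.00)  # fraction of baseline
    vv_resolve_day_offset: float = 16.0   # back to baseline this long after onset
    # delta-T1 peak (ms) in whole brain; cerebellum scaled up.
    dt1_peak_day_offset_mean: float = 3.0  # days after VV rise onset
    dt1_peak_day_offset_sd: float = 1.0
    dt1_peak_range: tuple[float, float] = (300.0, 600.0)
    dt1_cerebellum_factor: float = 1.6
    dt1_width_days: float = 5.0
    # clinical score: onset follows VV onset by a floored positive delay.
    clinical_delay_mean: float = 5.0
    clinical_delay_sd: float = 1.5
    clinical_delay_min: float = 2.0
    score_peak_range: tuple[float, float] = (2.0, 3.5)
    score_peak_day_offset: float = 3.0
    score_remit_day_offset: float = 12.0
    score_residual: float = 0.5
    # weight couples negatively to the clinical score.
    baseline_weight_range: tuple[float, float] = (18.0, 22.0)  # g
    weight_loss_per_score: float = 0.04   # fractional loss per score unit
    # histology sacrifice design and monotone day -> ordinal score link.
    histology_days: tuple[int, ...] = (0, 3, 5, 8, 11)
    histology_score_breaks: tuple[float, float, float] = (4.0, 7.0, 10.0)
    noise_sd: float = 0.02                # fractional VV noise
    dt1_noise_sd: float = 20.0            # ms
    weight_noise_sd: float = 0.01         # fractional
    seed: int = 0

    def __post_init__(self) -> None:
        days = np.asarray(self.schedule_days, dtype=float)
        if np.any(np.diff(days) <= 0):
            raise ValueError("schedule days must be strictly increasing")
        if days[0] >= 0:
            raise ValueError("schedule must include a baseline day before immunization (day 0)")
        if self.vv_onset_day_min <= 0:
            raise ValueError("VV onset distribution must not allow onset before day 0")
        if self.clinical_delay_mean < 0:
            raise ValueError("clinical delay must be nonnegative")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_healthy_cohort(
    n_subjects: int = 6,
    n_timepoints: int = 7,
    baseline_range: tuple[float, float] = (25000.0, 42000.0),
    fluctuation_sd: float = 0.02,
    seed: int = 0,
) -> Cohort:
    """Healthy serial-scan cohort: VV = baseline * (1 + eps_t), eps_0 = 0."""
    if fluctuation_sd < 0:
        raise ValueError("fluctuation sd must be nonnegative")
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    if baseline_range[0] <= 0 or baseline_range[1] < baseline_range[0]:
        raise ValueError("baseline range must be positive and ordered")
    subjects = []
    for i, rng in enumerate(_substreams(seed, n_subjects)):
        baseline = rng.uniform(*baseline_range)
        eps = rng.normal(0.0, fluctuation_sd, size=n_timepoints)
        eps[0] = 0.0
        subjects.append(
            SubjectSeries(
                subject_id=f"hc{i + 1:02d}",
                group="healthy",
                time=np.arange(n_timepoints, dtype=float),
                time_unit="months",
                variables={VV: baseline * (1.0 + eps)},
            )
        )
    return Cohort(subjects=subjects, ground_truth={"fluctuation_sd": fluctuation_sd})


def _episode_bump(n: int, start: int, rise: int, fall: int, amplitude: float) -> np.ndarray:
    """Piecewise-linear rise/peak/fall bump on the fractional-of-baseline scale."""
    bump = np.zeros(n)
    peak = start + rise
    end = peak + fall
    t_idx = np.arange(n)
    rising = (t_idx > start) & (t_idx <= peak)
    falling = (t_idx > peak) & (t_idx < end)
    bump[rising] = amplitude * (t_idx[rising] - start) / rise
    bump[falling] = amplitude * (end - t_idx[falling]) / fall
    return bump


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _shift(z: np.ndarray, lag: int) -> np.ndarray:
    """z(t - lag), zero-padded at the edges."""
    out = np.zeros_like(z)
    if lag == 0:
        return z.copy()
    if lag > 0:
        out[lag:] = z[:-lag]
    else:
        out[:lag] = z[-lag:]
    return out


def generate_ms_cohort(config: MSCohortConfig | None = None) -> Cohort:
    """Monthly MS cohort with episodic VV bumps and lagged covariate couplings."""
    cfg = config or MSCohortConfig()
    n_t = cfg.n_timepoints
    time = np.arange(n_t, dtype=float)
    couplings_by_target: dict[str, list[CouplingSpec]] = {}
    for c in cfg.couplings:
        couplings_by_target.setdefault(c.target_variable, []).append(c)

    subjects = []
    episodes_truth = []
    for i, rng in enumerate(_substreams(cfg.seed, cfg.n_patients)):
        sid = f"ms{i + 1:02d}"
        baseline = rng.uniform(*cfg.baseline_vv_range)
        bump = np.zeros(n_t)
        if rng.uniform() < cfg.episode_probability:
            amplitude = rng.uniform(*cfg.episode_amplitude_range)
            rise = int(rng.integers(cfg.episode_rise_range[0], cfg.episode_rise_range[1] + 1))
            fall = int(rng.integers(cfg.episode_fall_range[0], cfg.episode_fall_range[1] + 1))
            # episode must fit strictly inside the trace, after the baseline scan
            latest_start = n_t - 1 - rise - fall
            start = int(rng.integers(1, max(latest_start, 1) + 1))
            bump = _episode_bump(n_t, start, rise, fall, amplitude)
            episodes_truth.append(
                {
                    "subject_id": sid,
                    "start": start,
                    "peak": start + rise,
                    "end": start + rise + fall,
                    "amplitude": amplitude,
                }
            )
        eps = rng.normal(0.0, cfg.noise_sd, size=n_t) if cfg.noise_sd > 0 else np.zeros(n_t)
        vv = baseline * (1.0 + cfg.atrophy_drift * time + bump + eps)

        variables: dict[str, np.ndarray] = {VV: vv}
        drivers = {VV: _standardize(vv)}

        # continuous covariates: location + scale * (couplings + AR(1) noise)
        for name in MS_COVARIATES:
            if name in ("cel_count", "cel_volume"):
                continue
            loc, scale = cfg.covariate_baselines[name]
            signal = np.zeros(n_t)
            coef_sq = 0.0
            for c in couplings_by_target.get(name, []):
                signal += c.coefficient * _shift(drivers[c.driver_variable], c.lag)
                coef_sq += c.coefficient**2
            if cfg.covariate_noise_sd is not None:
                noise_amp = cfg.covariate_noise_sd
            else:
                noise_amp = np.sqrt(max(0.0, 1.0 - coef_sq))
            innov = rng.normal(0.0, 1.0, size=n_t)
            ar = np.empty(n_t)
            ar[0] = innov[0]
            for t in range(1, n_t):
                ar[t] = cfg.ar_coefficient * ar[t - 1] + innov[t] * np.sqrt(
                    1.0 - cfg.ar_coefficient**2
                )
            variables[name] = loc + scale * (signal + noise_amp * ar)

        # CEL count: Poisson, log-link to its coupled driver; volume = count x sizes.
        # Couplings to cel_volume act through the count rate (volume is derived).
        log_rate = np.full(n_t, np.log(cfg.cel_base_rate))
        cel_couplings = couplings_by_target.get("cel_count", []) + couplings_by_target.get(
            "cel_volume", []
        )
        for c in cel_couplings:
            log_rate = log_rate + c.coefficient * _shift(drivers[c.driver_variable], c.lag)
        counts = rng.poisson(np.exp(log_rate)).astype(float)
        sizes = np.array(
            [
                rng.lognormal(cfg.cel_log_size_mean, cfg.cel_log_size_sd, size=int(k)).sum()
                for k in counts
            ]
        )
        variables["cel_count"] = counts
        variables["cel_volume"] = sizes

        if cfg.missing_rate > 0:
            for name, series in variables.items():
                mask = rng.uniform(size=n_t) < cfg.missing_rate
                mask[0] = False  # keep the baseline scan
                series = series.copy()
                series[mask] = np.nan
                variables[name] = series

        subjects.append(
            SubjectSeries(
                subject_id=sid, group="ms", time=time.copy(), time_unit="months",
                variables=variables,
            )
        )
    truth = {
        "episodes": episodes_truth,
        "couplings": [asdict(c) for c in cfg.couplings],
    }
    return Cohort(subjects=subjects, ground_truth=truth)


def _linear_peak(days: np.ndarray, start: float, peak: float, end: float, amplitude: float) -> np.ndarray:
    """Rise linearly start->peak, fall peak->end, zero outside."""
    out = np.zeros_like(days, dtype=float)
    rising = (days > start) & (days <= peak)
    falling = (days > peak) & (days < end)
    if peak > start:
        out[rising] = amplitude * (days[rising] - start) / (peak - start)
    if end > peak:
        out[falling] = amplitude * (end - days[falling]) / (end - peak)
    return out


def generate_eae_cohort(config: EAECohortConfig | None = None) -> Cohort:
    """EAE mouse cohort: preclinical VV and delta-T1 peaks precede clinical onset."""
    cfg = config or EAECohortConfig()
    days = np.asarray(cfg.schedule_days, dtype=float)
    last_day = float(days[-1])
    subjects = []
    events_truth = []
    histology = []
    for i, rng in enumerate(_substreams(cfg.seed, cfg.n_mice)):
        sid = f"eae{i + 1:02d}"
        baseline_vv = rng.uniform(*cfg.baseline_vv_range)
        onset = max(rng.normal(cfg.vv_onset_day_mean, cfg.vv_onset_day_sd), cfg.vv_onset_day_min)
        amplitude = rng.uniform(*cfg.vv_amplitude_range)
        peak_day = onset + cfg.vv_peak_day_offset
        resolve_day = onset + cfg.vv_resolve_day_offset
        vv_frac = _linear_peak(days, onset, peak_day, resolve_day, amplitude)
        vv_noise = rng.normal(0.0, cfg.noise_sd, size=len(days)) if cfg.noise_sd > 0 else 0.0
        vv = baseline_vv * (1.0 + vv_frac + vv_noise)

        dt1_peak_day = onset + max(rng.normal(cfg.dt1_peak_day_offset_mean, cfg.dt1_peak_day_offset_sd), 0.5)
        dt1_amp = rng.uniform(*cfg.dt1_peak_range)
        dt1_clean = _linear_peak(
            days, dt1_peak_day - cfg.dt1_width_days, dt1_peak_day,
            dt1_peak_day + cfg.dt1_width_days, dt1_amp,
        )
        dt1_noise = rng.normal(0.0, cfg.dt1_noise_sd, size=len(days)) if cfg.dt1_noise_sd > 0 else 0.0
        dt1_wb = dt1_clean + dt1_noise
        dt1_cb = cfg.dt1_cerebellum_factor * dt1_clean + (
            rng.normal(0.0, cfg.dt1_noise_sd, size=len(days)) if cfg.dt1_noise_sd > 0 else 0.0
        )

        delay = max(rng.normal(cfg.clinical_delay_mean, cfg.clinical_delay_sd), cfg.clinical_delay_min)
        clin_onset = onset + delay
        score_peak = rng.uniform(*cfg.score_peak_range)
        score = _linear_peak(
            days, clin_onset, clin_onset + cfg.score_peak_day_offset,
            clin_onset + cfg.score_remit_day_offset,
            score_peak - cfg.score_residual,
        )
        score[days >= clin_onset + 1e-9] += cfg.score_residual
        score = np.clip(score, 0.0, 5.0)

        w0 = rng.uniform(*cfg.baseline_weight_range)
        w_noise = rng.normal(0.0, cfg.weight_noise_sd, size=len(days)) if cfg.weight_noise_sd > 0 else 0.0
        weight = w0 * (1.0 - cfg.weight_loss_per_score * score + w_noise)

        subjects.append(
            SubjectSeries(
                subject_id=sid, group="eae", time=days.copy(), time_unit="days",
                variables={
                    VV: vv,
                    "dt1_whole_brain": dt1_wb,
                    "dt1_cerebellum": dt1_cb,
                    "score": score,
                    "weight": weight,
                },
            )
        )

        # Ground truth evaluated on the noise-free trajectories at the schedule days.
        pct_clean = 100.0 * vv_frac
        above = np.where(pct_clean > 6.0)[0]
        vv_onset_day = float(days[above[0]]) if len(above) else last_day
        dt1_max_day = float(days[int(np.argmax(dt1_clean))])
        onset_idx = np.where(score >= 1.0)[0]
        clin_day = float(days[onset_idx[0]]) if len(onset_idx) else last_day
        weight_clean = w0 * (1.0 - cfg.weight_loss_per_score * score)
        nadir_day = float(days[int(np.argmin(weight_clean))])
        events_truth.append(
            {
                "subject_id": sid,
                "t_vv_onset": vv_onset_day,
                "vv_onset_censored": not len(above),
                "t_dt1_max": dt1_max_day,
                "t_clinical_onset": clin_day,
                "clinical_censored": not len(onset_idx),
                "t_weight_nadir": nadir_day,
            }
        )

        sac_day = int(cfg.histology_days[i % len(cfg.histology_days)])
        b1, b2, b3 = cfg.histology_score_breaks
        histo_score = int(np.searchsorted([b1, b2, b3], sac_day, side="right"))
        sched_idx = int(np.argmin(np.abs(days - sac_day)))
        histology.append(
            {
                "animal_id": sid,
                "sacrifice_day": sac_day,
                "score": histo_score,
                "vv_at_sacrifice": float(100.0 * (vv[sched_idx] / vv[0])),
                "dt1_at_sacrifice": float(dt1_wb[sched_idx]),
            }
        )
    truth = {"events": events_truth, "histology": histology}
    return Cohort(subjects=subjects, ground_truth=truth)


def generate_null_cohort(
    n_subjects: int = 24,
    n_variables: int = 12,
    n_timepoints: int = 13,
    seed: int = 0,
    integrated: bool = True,
) -> Cohort:
    """Cohort of mutually independent noise series for calibration studies.

    With ``integrated=True`` (default) each series is a random walk, so that
    first-differencing — the screen's detrending step — yields white noise,
    matching the stationarity-and-no-autocorrelation premise the workflow's
    ACF check enforces.  ``integrated=False`` yields i.i.d. level noise, whose
    differences are MA(1); useful for studying the nominal test's behaviour
    when that premise is violated.
    """
    names = [VV] + [f"y{j:02d}" for j in range(1, n_variables + 1)]
    subjects = []
    for i, rng in enumerate(_substreams(seed, n_subjects)):
        variables = {}
        for name in names:
            z = rng.normal(size=n_timepoints)
            series = np.cumsum(z) if integrated else z
            if name == VV:
                series = 30000.0 + 100.0 * series  # keep volumes positive
            variables[name] = series
        subjects.append(
            SubjectSeries(
                subject_id=f"n{i + 1:02d}", group="ms",
                time=np.arange(n_timepoints, dtype=float), time_unit="months",
                variables=variables,
            )
        )
    return Cohort(subjects=subjects)
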