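# Methods

This note documents the models behind `vvdyn`, the defaults and why they were
chosen, the numerical conventions, and what the synthetic cohorts do and do
not establish about real data.

## Percent-of-baseline normalization and the healthy band

All ventricle-volume (VV) analyses run on the percent-change-from-baseline
trace `p_t = 100·(V_t − V_0)/V_0`, where the baseline is the *first* scan.
There is no re-baselining: every later visit is compared with the same anchor,
which matches how serial volumetry is plotted and keeps interval changes in
percentage points of the original volume.

The healthy-variation threshold is the maximum intraindividual |p_t| observed
across a healthy serial-scan cohort. When no healthy data are supplied the
fixed published band of **6 %** is used. An estimated threshold is never
rounded; a zero estimate (constant VV) is returned with a warning because it
makes every fluctuation an "event".

## Event detection and the contraction rule

*Interval events* are maximal runs of same-sign month-to-month changes whose
cumulative magnitude exceeds the threshold. A zero-change month is
sign-neutral: it terminates the current run.

A subject is **contracting** when some window `[t0, t1]` with
`t1 − t0 ≥ min_duration` (default 2 months) is non-increasing throughout and
`p(t0) − p(t1) > threshold`. "No expansions in between" is operationalized as
non-increasing: a flat month does not break a contraction, a positive month
does. This is the most literal machine-checkable reading of a sustained
contraction; windows may start anywhere, including at the baseline scan.
`expansion_only` marks subjects with an above-threshold expansion event, no
above-threshold contraction event of any duration, and no qualifying
contraction window (without the last clause a subject could be labelled both
contracting and expansion-only through a zero-month technicality, which would
break the partition the stratified group contrasts rely on).
`max_contraction` (the lollipop coordinate) is the most negative drop over
*any* non-increasing window, regardless of duration, 0 for monotonically
rising traces.

The classifier is O(n²) in trace length (n = 13 here) and is verified in the
tests against an exhaustive all-windows search over every short grid trace.

Subjects with missing VV values are excluded from stratification with a
logged warning: the window rules need complete monthly traces, and the
original cohort design analyzed completers only.

## Group contrasts

- Wilcoxon signed-rank: zero differences dropped; for n ≤ 25 the p-value is
  exact, computed by convolving the sign-flip distribution of the
  positive-rank sum on doubled (integer) average ranks, so tied magnitudes
  are handled exactly; beyond 25, a normal approximation with tie correction
  and no continuity correction.
- Mann-Whitney U: exact enumeration (via scipy) when both groups have ≤ 10
  tie-free observations, otherwise the tie-corrected normal approximation.
- Student's t is the pooled-variance two-tailed form (df = nA + nB − 2);
  the 2×2 χ² is Pearson's, df 1, without Yates correction — the correction is
  a deliberate omission, matching the plain df-1 statistic.
- The group-level VV change is reported under *both* percent definitions —
  difference of medians as a percent of the baseline median, and the median
  of per-subject percent changes — because the two disagree in general and
  summary figures rarely say which was used.

## The cross-correlation screen

Per subject, each series is detrended by first differencing (each point
replaced by its change from the preceding point), which removes linear
trends exactly and prevents co-trending series from producing spurious
correlations. Stationarity of every differenced series is then checked with
an augmented Dickey-Fuller (ADF) regression with drift; failures are logged
and surfaced in the summary but do not abort the screen — at 12 differenced
points the ADF has modest power, and a failed confirmation is a data flag,
not a computational error.

The cross-correlation coefficient at lag k is the **Pearson correlation over
the aligned overlap** `{(x_t, y_{t+k})}` with `n_eff = n − |k|` pairs — not
the denominator-n stationary estimator, whose shrinkage toward zero is
material at these lengths and which lacks a clean finite-sample significance
theory. The stationary variant remains available (`estimator="stationary"`)
for cross-checking. Sign convention: positive lag means Y follows X; the
identity `ccf(x, y, k) = ccf(y, x, −k)` holds exactly and is tested.

Nominal p-values use the Pearson t-approximation with `n_eff − 2` degrees of
freedom. Zero-variance overlaps yield an undefined (NaN) record that is
excluded from the FDR pool and counted in the summary.

**FDR family.** By default Benjamini-Hochberg is applied across *all* defined
coefficients in the grid (the BH procedure is defined on the full family).
A two-stage mode (`fdr_pool="nominal"`) that corrects only the nominally
significant subset is provided because screening workflows are sometimes
described that way; neither mode is claimed to be "the" published
computation. The q-values are the usual step-up quantities
`q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1, cross-checked against
statsmodels.

**ADF lag order.** For differenced series of length ≤ 14 no lagged-difference
augmentation is used (12 points cannot support it); longer series use
Schwert's rule with AIC selection. P-values are MacKinnon's interpolated
surface via statsmodels, and the statistic is verified in the tests against
an independent OLS t-ratio.

**A calibration caveat.** The nominal Pearson-t theory assumes the
differenced series are (approximately) white. Differencing a series that is
*already* white induces MA(1) autocorrelation (lag-1 coefficient −0.5),
which inflates the cross-correlation tails: simulated on i.i.d. level noise,
the family-wise any-discovery rate of the screen rises to roughly 0.18. This
is exactly the failure mode the workflow's ACF check exists to catch. The
null-calibration utilities (`generate_null_cohort`, default
`integrated=True`) therefore simulate independent *random walks*, for which
differencing yields white noise and the screen's family-wise any-discovery
rate is controlled at the BH level (measured ≈ 0.05 over 500 cohorts). The
non-integrated mode is retained for studying the violated-premise behaviour.

## EAE timing

ΔT1 = precontrast − postcontrast mean T1 (ms); negative values are legal and
flag absence of net enhancement. Per-animal event days: first day the VV
percent trace exceeds the band (default +6 %), day of the ΔT1 maximum,
first day with clinical score ≥ 1, and the body-weight nadir. Argmax/argmin
ties resolve to the **earliest** day — schedules are coarse (2-day spacing)
and earliest is conservative for "marker precedes clinical onset" claims.
Threshold events that never occur are censored at the last observed day.
The pre-immunization baseline scan anchors the percent trace but is not an
eligible event day.

Event-type timing is compared with the two-sample log-rank test applied to
the per-animal event days, reproducing the published comparison even though
the two "samples" are paired within animals (a paired exact sign test is
available as `method="paired_sign"` but is off by default, as a fidelity
choice). Kaplan-Meier estimation and the log-rank statistic are delegated to
lifelines and verified against hand-computed product-limit and O−E/V values.

Spearman correlation is tie-aware (Pearson on average ranks); its p-value is
an exact permutation enumeration for n ≤ 8 and the t-approximation beyond.
One-way ANOVA is provided for the group-mean time-point contrasts as stated;
it ignores within-animal correlation across time points, and no mixed model
is substituted.

## Synthetic cohorts

The generators define the study conditions; their defaults were fixed before
any acceptance measurement and are not tuning knobs.

**Healthy arm** (6 subjects × 7 monthly scans): `V_t = V_0(1 + ε_t)` with
`ε_0 = 0` and i.i.d. `ε_t ~ N(0, σ²)`, σ = 2 %. With 36 post-baseline scans
the expected cohort maximum |p_t| is ≈ 2.9σ ≈ 5.8 %, consistent with the
±6 % scan-rescan band this arm emulates. The exceedance probability of a
single subject follows the Gaussian order statistic
`1 − P(|N| ≤ 3σ)^6`, which the tests verify by simulation.

**RRMS arm** (33 patients × 13 monthly scans): VV =
`baseline·(1 + drift·t + bump + ε_t)` with a small atrophy drift
(10⁻⁴/month), Gaussian noise (σ = 1.5 %), and, with probability 0.75 per
patient, one piecewise-linear episode (rise 1–3 months, fall 1–3 months,
amplitude 10–40 % of baseline) — the simplest shape matching a
rise-peak-return fluctuation. No quantitative episode-amplitude distribution
is available for real patients; these ranges were chosen for testability,
not as estimates. Continuous covariates are
`location + scale·(Σ couplings + AR(1) noise)`: each coupling adds
`coefficient · z(driver at t − lag)` (standardized driver, zero-padded
edges), and the AR(1) innovation sd defaults to `√(1 − Σcoef²)` so the
coefficient is approximately the induced correlation. AR coefficient 0.3,
reflecting the serial dependence of clinical scores. CEL counts are Poisson
with a log-link to their coupled driver; CEL volume is the sum of
count-many log-normal lesion sizes (couplings addressed to CEL volume act
through the count rate, since volume is derived). Default injected couplings
(VV→CEL count at lag 0, VV→T2 volume at lag +1) exist so the screen always
has a recoverable signal. A configurable missing-data rate (default 0)
masks random non-baseline cells to exercise the missing-data policy.

**EAE arm** (16 mice, days −2, 0, 2, …, 30): a piecewise-linear VV peak
(onset ≈ day 6, peak 6 days later, amplitude 30–100 % of baseline, resolved
by onset + 16 d), a triangular ΔT1 peak (≈ 3 d after VV onset, 300–600 ms,
cerebellum scaled 1.6×), a clinical score rising from onset = VV onset + a
delay floored at 2 d (so VV onset precedes clinical onset for every animal
in the noise-free limit, the ordering the timing analysis is designed to
detect), weight loss proportional to score (4 % per score unit), and an
ordinal 0–3 histology score stepping monotonically with sacrifice day.
Ground-truth event days are evaluated on the noise-free trajectories at the
schedule days, so the extractor must recover them exactly when noise is off.

Seeding: one integer seed expands into per-subject substreams
(`SeedSequence.spawn`), so enlarging a cohort never perturbs
already-generated subjects, and identical config + seed reproduces a
byte-identical serialized table.

**What passing tests show — and don't.** The generators produce the
*statistical structure the analysis assumes*: independent subjects, linear
lagged couplings, Gaussian or Poisson noise, exactly aligned complete grids.
Real volumetry has scanner drift, registration error correlated across
visits, non-linear couplings, informative missingness, and treatment
effects, none of which are modelled. Recovery and calibration results
therefore validate the *implementation* of the workflow, not the clinical
conclusions one might draw with it.

## Problem sizes and numerical conventions

The calibration studies use the design sizes of the motivating studies:
screens on 24 subjects × 12 variables × 13 time points (1440-coefficient
grid), 500 null cohorts for the family-wise FDR rate, 200 replicates for
lag recovery and EAE log-rank detection, 500 replicates for ADF size/power
at n = 100. Ties in rank tests use average ranks; argmax ties use the
earliest index; all comparisons against thresholds are strict (`>` for
event magnitudes, `≥` for score onset), matching the definitions above.
Degenerate inputs (constant series for ADF/ACF/Spearman, zero margins for
χ², all-zero differences for the signed-rank test, empty cohorts) raise
`ValueError` rather than returning placeholder numbers.

## Known limitations

- The nominal CCF p-values are anticonservative whenever the differenced
  series remain autocorrelated (see the calibration caveat above); the ACF
  check flags, but does not correct, such series.
- The log-rank comparison of event types treats paired within-animal times
  as independent samples, as in the source analysis; the provided sign test
  is the statistically cleaner alternative.
- The 6 % band is a point estimate from small healthy cohorts; the
  stratification is sensitive to it, and `estimate_normal_variation_threshold`
  exists precisely so it can be re-derived from better scan-rescan data.
- With the default 1.5 % VV noise, short (2-month) episode falls are
  sometimes broken by a single up-tick month and the subject is classified
  noncontracting; the generator's contracting fraction therefore sits
  slightly below the episode probability.
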