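# vvdyn — transient brain-ventricle-volume dynamics in neuroinflammation

Brain ventricle volume (VV) is usually treated as a slow, one-way atrophy
marker. In relapsing-remitting multiple sclerosis (RRMS), and dramatically in
its mouse model (experimental autoimmune encephalomyelitis, EAE), the
ventricles also *expand and contract transiently* on a time scale of weeks —
fluctuations plausibly driven by inflammation and CSF dysregulation rather
than neurodegeneration. `vvdyn` implements the analysis toolkit for studying
these dynamics in longitudinal MRI volumetry:

- **Event classification against a healthy band.** Monthly VV series are
  normalized to percent of the baseline scan, `p_t = 100·(V_t − V_0)/V_0`.
  Healthy scan-rescan studies bound normal intraindividual variation at about
  ±6 % of baseline; `vvdyn` detects above-threshold expansion/contraction
  events and labels a patient *contracting* when some window of ≥ 2
  consecutive months is non-increasing throughout and drops by more than the
  threshold — a sustained contraction with no expansions in between. Cohorts
  are stratified on this label and compared with the standard battery
  (Wilcoxon signed-rank with exact small-sample p, Mann-Whitney U, pooled
  *t*, Pearson χ² without continuity correction).
- **Lag-limited cross-correlation screening.** For each patient, every series
  (VV, lesion counts/volumes, regional ADC, clinical performance measures) is
  detrended by first differencing; stationarity is confirmed with an
  augmented Dickey-Fuller test; the cross-correlation function between the
  driver series and each comparison series is evaluated at lags −2…+2
  (coefficient at lag *k* correlates `(x_t, y_{t+k})`, so positive lag means
  Y follows X). Each coefficient gets a nominal p from Pearson theory on the
  aligned overlap, `t = r√((m−2)/(1−r²))`, and the whole
  subject × variable × lag grid is corrected with Benjamini-Hochberg FDR.
  For 24 patients × 12 variables × 5 lags the grid holds exactly 1440
  coefficients.
- **EAE timing analysis.** Per animal: the day VV first exceeds the band, the
  day of maximal gadolinium enhancement (ΔT1 = precontrast − postcontrast
  mean T1), clinical onset (first score ≥ 1), and the weight nadir — compared
  as time-to-event distributions with Kaplan-Meier curves and the log-rank
  test, plus Spearman correlation of ordinal histopathology scores (0–3)
  with imaging read-outs.
- **A synthetic cohort generator** for all three arms (healthy, RRMS, EAE)
  with injected ground truth — lagged couplings, episode windows, event days —
  so every stage runs, and is validated, with no external data.

## Worked example

```python
import vvdyn as v

# simulated 33-patient RRMS cohort, 13 monthly scans
ms = v.generate_ms_cohort(v.MSCohortConfig(seed=3))
strat = v.stratify_cohort(ms)                  # default ±6 % band
print(strat.summary())
# {'n_subjects': 33, 'n_contracting': 23, 'n_noncontracting': 10,
#  'n_any_above_threshold_monthly_change': 25, 'n_expansion_only': 0,
#  'cv_mean_contracting': 8.929, 'cv_mean_noncontracting': 2.817, ...}

# screen the contracting subset: VV against the other 12 series
from vvdyn.cohort import Cohort
sub = Cohort(subjects=[s for s in ms if s.subject_id in set(strat.contracting_ids)])
screen = v.run_ccf_screen(sub, "ventricle_volume")
print(screen.summary())
# total_coefficients: 1380 (23 subjects x 12 variables x 5 lags),
# n_nominal: 85, n_fdr_retained: 10; the strongest retained records are
# VV ~ CEL count / CEL volume at lag 0 (r = 0.96, 0.95), recovering the
# generator's injected coupling.

# EAE arm: marker timing
eae = v.generate_eae_cohort(v.EAECohortConfig(seed=3))
timing = v.extract_cohort_event_times(eae)
print(v.compare_event_timing(timing)["vv_onset_vs_clinical_onset"])
# {'statistic': 27.58, 'p': 1.5e-07}  — median VV onset day 8 vs clinical
# onset day 14: ventricle expansion precedes clinical signs.
```

Interpretation: 23 of 33 simulated patients show sustained contractions
beyond the healthy band (the contracting group has about 3× the VV
coefficient of variation of the noncontracting group); the FDR-corrected
screen retains 10 of 1380 coefficients, headed by the injected VV→CEL
coupling at lag 0; in the mouse arm, ventricle expansion significantly
precedes clinical onset by the log-rank test.

The same stages are available from the shell:

```bash
vvdyn simulate --arm ms --seed 3 --out ms.csv
vvdyn stratify --input ms.csv --out events.csv
vvdyn ccf-screen --input ms.csv --x ventricle_volume --out ccf.csv --summary summary.json
vvdyn run --seed 3 --outdir out/    # full pipeline + report.json
```

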