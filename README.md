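# persistkit

Treatment-persistence analysis of infliximab therapeutic drug monitoring (TDM)
from infusion-level records.

Patients with Crohn's disease or ulcerative colitis who start infliximab often
lose response over time; clinicians measure the trough serum concentration
(TDM) and, when it is low, escalate therapy by shortening the infusion
interval and/or raising the mg/kg dose. `persistkit` implements the full
observational pipeline needed to ask whether TDM-guided dose optimization is
associated with longer treatment persistence in administrative infusion
records of the kind a patient-support program collects:

- **Persistence derivation** — a patient with a gap of more than 20 weeks
  between infusions (or between the last infusion and the censoring date) is
  deemed discontinued 8 weeks (one treatment cycle) after the last infusion
  preceding the gap; otherwise right-censored. A stricter 12-week gap is
  available as a sensitivity rule. Kaplan–Meier estimation of S(t).
- **Dose-optimization detection** — escalation events between consecutive
  maintenance-phase infusions: interval decrease ≥ 11 days with posterior
  interval ≤ 46 days (low threshold) or ≤ 35 days (high), and/or dose
  increase ≥ 1.5 mg/kg with posterior level ≥ 7 mg/kg (low) or ≥ 9 mg/kg
  (high).
- **Cohort construction** — overall-population inclusion (age 18–90, first
  weight < 130 kg, initiation 2015–2018, no prior exposure in the lookback),
  then a TDM subgroup (first trough after Week 9 with a recorded result,
  before discontinuation/censoring) split into subsets A (no post-TDM
  escalation) and B (escalation within 9 weeks) among patients below a
  concentration threshold (3/5/10 µg/mL).
- **Time-dependent Cox models** — counting-process rows (start, stop] with
  exposure switching 0 → 1 at the TDM or escalation day, avoiding
  immortal-time bias; stratified by initiation year with fixed covariates
  (age group, gender, weight quartiles, region, log days-to-TDM); a
  four-model ladder (main effects, exposure×covariate interactions,
  exposure×log t, both) selects the simplest model consistent with 0.05-level
  tests, with HR read-outs at 4 and 6 weeks when proportional hazards fail.
- **Tipping-point bias analysis** — the post-exposure persistence of
  dose-optimized patients is reduced on a 25-day grid until the association
  loses significance; the median reduction (and its 8-week-cycle equivalent)
  measures robustness to unmeasured confounding.
- **Synthetic cohort generator** — a patient-support-program simulator with
  known ground truth (latent discontinuation hazards, a low-concentration /
  antibody-positive stratum, physician escalation behavior, a configurable
  true exposure hazard ratio θ), so every stage is testable without access
  to restricted patient data.

The core estimate is the stratified Cox partial likelihood with a
time-dependent exposure X(t):

λ(t | Z, X) = λ₀ₛ(t) · exp(β·X(t) + γ'Z),  HR = exp(β)

fitted by Newton–Raphson with Efron (default) or Breslow tie handling.

## Worked example

```python
from persistkit import bias, reporting
from persistkit.config import SimulationConfig
from persistkit.synthetic import simulate_cohort

cfg = SimulationConfig(n_patients=2000, seed=7)   # true exposure HR 0.36
patients, infusions, tdm, truth = simulate_cohort(cfg)

frame = reporting.subgroup_analysis_frame(patients, infusions, tdm)
fit = reporting.fit_subgroup_m1(frame)
print(fit.summary.loc["exposure", ["hr", "ci_lower", "ci_upper"]])
# hr          0.399942
# ci_lower    0.289358
# ci_upper    0.552789

tip = bias.tipping_point(frame, reporting.fit_subgroup_m1)
print(tip.tipping_median_days, tip.tipping_cycles)
# 300.0 5.4
```

The fitted hazard ratio 0.40 (95% CI 0.29–0.55) recovers the configured
θ = 0.36 within sampling error (the median estimate across replicate cohorts
sits at 0.36): dose-optimized patients discontinue at well under half the
rate of non-optimized patients with equally low troughs. The tipping point —
here a median 300-day (5.4-cycle) reduction in post-TDM persistence per
optimized patient — reports how much persistence an unmeasured confounder
would have to explain away before the association became non-significant.

The same steps run as numbered scripts:

```bash
python analysis/01_simulate_cohort.py --seed 1      # writes results/data/
python analysis/02_persistence_overall.py           # gap rules + KM rates
python analysis/03_detect_dose_optimization.py
python analysis/04_subgroup_models.py               # model ladder + HRs
python analysis/05_immortal_time_bias.py            # naive vs time-dependent
python analysis/06_tipping_point.py
```

or through the CLI (`persistkit simulate|persist|detect-do|cohort|analyze|bias|run`).

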