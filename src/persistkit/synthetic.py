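"""Synthetic patient-support-program cohort generator with known ground truth.

Each patient is simulated on their own pseudo-random stream derived from
``(seed, patient_index)``, so cohorts are extensible without disturbing
existing patients and identical config+seed yields bit-identical tables.

The generative model
--------------------
* Initiation date uniform over the configured window; induction infusions at
  the configured offsets (weeks 0/2/6 by default) then maintenance every
  8 weeks with Gaussian day-level jitter.
* A latent low-concentration stratum (immunogenicity / fast clearance): trough
  draws near the 0.035 µg/mL assay floor and usually antibody-positive; other
  patients draw from a log-normal centred near 5 µg/mL.
* TDM orders occur pre-infusion (trough by construction) at maintenance visits
  with a per-cycle probability, no earlier than the configured week.
* Physician policy: after the first recorded trough below the low-concentration
  threshold, the physician may escalate at the next infusion — shorter interval
  and/or higher mg/kg dose.  The ground-truth dose-optimization day is the
  first infusion at which the escalation is observable (the higher-dose
  infusion, or the first infusion of the shortened schedule), which is also
  the day the hazard ratio θ (``hazards.do_hr``) starts to apply.
* Discontinuation is a latent event time from a Weibull baseline hazard with
  multiplicative stratum and dose-optimization effects; the last infusion is
  the last scheduled visit strictly before it, so the observable footprint is
  the treatment gap the persistence rule detects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .records_io import INFUSION_COLUMNS, PATIENT_COLUMNS, TDM_COLUMNS

GROUND_TRUTH_COLUMNS = [
    "patient_id",
    "init_date",
    "low_stratum",
    "latent_disc_day",
    "do_day",
    "do_action",
    "first_tdm_day",
    "first_tdm_conc",
]

_PROVINCES = np.array(
    ["Ontario", "Quebec", "Alberta", "BritishColumbia", "Atlantic", "SaskatchewanManitoba"]
)
_PROVINCE_P = np.array([0.33, 0.22, 0.13, 0.12, 0.10, 0.10])


@dataclass
class _PatientResult:
    patient: tuple
    infusions: list[tuple]
    tdm: list[tuple]
    truth: tuple


def _simulate_patient(i: int, cfg: SimulationConfig) -> _PatientResult:
    rng = np.random.default_rng([cfg.seed, i])
    pid = f"P{i:05d}"
    hz = cfg.hazards
    policy = cfg.physician_policy
    tdm_cfg = cfg.tdm_ordering

    window = (cfg.initiation_end - cfg.initiation_start).days
    init_date = cfg.initiation_start + timedelta(days=int(rng.integers(0, window + 1)))
    max_day = (cfg.censor_date - init_date).days

    age = int(np.clip(round(rng.normal(40.0, 15.0)), 18, 90))
    gender = "female" if rng.random() < cfg.prob_female else "male"
    diagnosis = "CD" if rng.random() < cfg.prob_cd else "UC"
    province = str(_PROVINCES[rng.choice(len(_PROVINCES), p=_PROVINCE_P)])
    weight0 = float(np.clip(rng.normal(cfg.weight_mean_kg, cfg.weight_sd_kg), 35.0, 129.5))
    weight0 = round(weight0, 1)
    low_stratum = rng.random() < cfg.conc_model.low_fraction

    # Fixed-size pre-draws keep the stream layout stable across config tweaks.
    n_slots = len(cfg.induction_offsets_days) + max_day // 7 + 4
    jitter = rng.normal(0.0, cfg.interval_jitter_sd_days, n_slots) if cfg.interval_jitter_sd_days > 0 else np.zeros(n_slots)
    u_tdm = rng.random(n_slots)
    u_bg = rng.random(n_slots)
    w_jit = rng.normal(0.0, 1.0, n_slots)
    u_wmiss = rng.random(n_slots)
    u_strong = rng.random(n_slots)
    exp_draw = float(rng.exponential(1.0))

    offsets = list(cfg.induction_offsets_days)
    earliest_tdm_day = tdm_cfg.earliest_week * 7

    infusions: list[tuple] = []
    tdm_rows: list[tuple] = []
    interval = float(cfg.maintenance_interval_days)
    dose_level = cfg.base_dose_mg_per_kg
    mult = hz.low_conc_hr if low_stratum else 1.0
    consumed = 0.0
    first_tdm_day: int | None = None
    first_tdm_conc: float | None = None
    reacted = False  # first recorded TDM already acted upon (or declined)
    pending_do = False  # escalation decided; materializes at the next infusion
    pending_dose: float | None = None
    do_day: int | None = None
    do_action: str | None = None
    latent_disc_day: float | None = None

    def decide_escalation(action: str, strong: bool) -> None:
        # The physician reacts between visits: a shortened interval brings the
        # NEXT infusion forward, a dose increase is administered at it.  The
        # next infusion is therefore the first observably escalated one and
        # the day the hazard ratio starts to apply.
        nonlocal interval, pending_dose, pending_do, do_action
        do_action = action
        if action in ("interval", "both"):
            interval = float(
                policy.strong_interval_days if strong else policy.interval_decrease_to_days
            )
        if action in ("dose", "both"):
            pending_dose = policy.strong_dose_mg_kg if strong else policy.dose_increase_to_mg_kg
        pending_do = True

    t = 0
    k = 0
    while True:
        # --- escalation materializing at this visit -------------------------
        if pending_do and do_day is None:
            if pending_dose is not None:
                dose_level = pending_dose
                pending_dose = None
            do_day = t
            mult *= hz.do_hr
            pending_do = False

        # --- infusion administered at t ------------------------------------
        dose_mg = round(dose_level * weight0, 1)
        w_rec = round(weight0 + w_jit[k], 1) if u_wmiss[k] >= 0.10 else None
        infusions.append((pid, init_date + timedelta(days=t), dose_mg, w_rec))

        # --- TDM order (pre-infusion trough) -------------------------------
        is_maintenance = k >= len(offsets)
        if is_maintenance and t >= earliest_tdm_day and u_tdm[k] < tdm_cfg.per_cycle_prob:
            sub = np.random.default_rng([cfg.seed, i, k])
            if sub.random() < tdm_cfg.missing_result_prob:
                conc = None
                ati = "missing"
            elif low_stratum:
                conc = min(
                    float(np.exp(sub.normal(cfg.conc_model.low_log_mean, cfg.conc_model.low_log_sd))),
                    cfg.conc_model.low_ceiling,
                )
                conc = round(conc, 3)
                ati = "positive" if sub.random() < 0.7 else "missing"
            else:
                conc = round(float(np.exp(sub.normal(cfg.conc_model.normal_log_mean, cfg.conc_model.normal_log_sd))), 3)
                ati = "negative" if sub.random() < 0.5 else "missing"
            tdm_rows.append((pid, init_date + timedelta(days=t), conc, ati))
            if conc is not None and first_tdm_day is None:
                first_tdm_day = t
                first_tdm_conc = conc
                if not reacted:
                    reacted = True
                    if conc < policy.low_conc_threshold and sub.random() < policy.do_probability:
                        u = sub.random()
                        if u < policy.p_interval_only:
                            action = "interval"
                        elif u < policy.p_interval_only + policy.p_dose_only:
                            action = "dose"
                        else:
                            action = "both"
                        decide_escalation(action, sub.random() < policy.p_strong)

        # --- background (non-TDM-driven) escalation ------------------------
        if (
            is_maintenance
            and do_day is None
            and not pending_do
            and u_bg[k] < policy.background_do_prob
        ):
            decide_escalation("dose", u_strong[k] < policy.p_strong)

        # --- schedule next visit and check latent discontinuation ----------
        k += 1
        if k < len(offsets):
            t_next = offsets[k]
        else:
            t_next = t + max(7, int(round(interval + jitter[k % n_slots])))
        seg = mult * (hz.cumulative(t_next) - hz.cumulative(t))
        if consumed + seg >= exp_draw:
            latent_disc_day = hz.inverse_cumulative(hz.cumulative(t) + (exp_draw - consumed) / mult)
            break
        consumed += seg
        if t_next > max_day:
            break
        t = t_next

    disc_out = None
    if latent_disc_day is not None and latent_disc_day <= max_day:
        disc_out = int(math.ceil(latent_disc_day))

    patient = (pid, diagnosis, age, gender, province, weight0)
    truth = (
        pid,
        init_date,
        bool(low_stratum),
        disc_out,
        do_day,
        do_action,
        first_tdm_day,
        first_tdm_conc,
    )
    return _PatientResult(patient, infusions, tdm_rows, truth)


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (patients, infusions, tdm, ground_truth)."""
    cfg.validate()
    pat_rows, inf_rows, tdm_rows, truth_rows = [], [], [], []
    for i in range(cfg.n_patients):
        res = _simulate_patient(i, cfg)
        pat_rows.append(res.patient)
        inf_rows.extend(res.infusions)
        tdm_rows.extend(res.tdm)
        truth_rows.append(res.truth)

    patients = pd.DataFrame(pat_rows, columns=PATIENT_COLUMNS)
    infusions = pd.DataFrame(inf_rows, columns=INFUSION_COLUMNS)
    tdm = pd.DataFrame(tdm_rows, columns=TDM_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)
    for df, col in ((infusions, "date"), (tdm, "date"), (truth, "init_date")):
        df[col] = pd.to_datetime(df[col])
    for col in ("latent_disc_day", "do_day", "first_tdm_day"):
        truth[col] = truth[col].astype("Int64")
    if cfg.n_patients:
        patients["age_at_initiation"] = patients["age_at_initiation"].astype("Int64")
    else:
        patients = patients.astype({"age_at_initiation": "Int64"})
    return patients, infusions, tdm, truth


def simulate_null_with_immortal_time(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort in which dose optimization is causally null (θ = 1).

    Exposed patients necessarily survived until their exposure, so a naive
    ever-exposed analysis is biased toward a spurious protective effect; a
    time-dependent analysis is not.  A truly null exposure also requires the
    concentration stratum to carry no hazard effect: physicians escalate in
    response to low troughs, so a nonzero ``low_conc_hr`` would confound the
    exposure rather than isolate immortal time.  Raises
    :class:`ConfigError` unless both hazard ratios are exactly 1.

    Escalations in this cohort are forced to be dose-only.  An interval
    decrease changes the visit schedule, and the gap rule dates a
    discontinuation at last infusion + 56 days, so patients on shortened
    intervals would have their observed event dates systematically delayed —
    a measurement artifact of the outcome definition, protective-looking even
    under a null hazard, and distinct from the immortal-time mechanism this
    cohort isolates.
    """
    if cfg.hazards.do_hr != 1.0:
        raise ConfigError("hazards.do_hr: must be exactly 1 for the immortal-time null cohort")
    if cfg.hazards.low_conc_hr != 1.0:
        raise ConfigError(
            "hazards.low_conc_hr: must be exactly 1 for the immortal-time null cohort "
            "(a concentration effect would confound the trough-triggered exposure)"
        )
    from dataclasses import replace

    policy = replace(cfg.physician_policy, p_interval_only=0.0, p_dose_only=1.0)
    return simulate_cohort(cfg.replace(physician_policy=policy))
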