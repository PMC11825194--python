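"""Detection of dose-optimization events from infusion sequences.

An escalation is flagged between consecutive maintenance-phase infusions when
either criterion fires:

* interval: decrease of >= 11 days (1.57 weeks) with a posterior interval of
  <= 46 days (6.57 weeks) for the low threshold, <= 35 days (5 weeks) for the
  high threshold;
* dose level: increase of >= 1.5 mg/kg with a posterior level of >= 7 mg/kg
  (low) or >= 9 mg/kg (high).

High-threshold criteria are strictly stricter, so every high event is also a
low event.  Intervals are formed only between infusions after Week 9
post-initiation (maintenance phase), so the induction 2-week -> 4-week step-up
is never flagged.  The event is dated at the posterior infusion — the
escalation is observable only when the next infusion occurs.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd

MAINTENANCE_START_DAY = 63  # strictly after Week 9 post-initiation

# day-denominated thresholds (Fig-legend equivalents of 1.57 / 6.57 / 5 weeks)
INTERVAL_DECREASE_MIN_DAYS = 11
INTERVAL_POST_MAX_LOW_DAYS = 46
INTERVAL_POST_MAX_HIGH_DAYS = 35
DOSE_INCREASE_MIN_MG_KG = 1.5
DOSE_POST_MIN_LOW_MG_KG = 7.0
DOSE_POST_MIN_HIGH_MG_KG = 9.0


@dataclass(frozen=True)
class Thresholds:
    """Detection thresholds in integer days and mg/kg."""

    interval_decrease_min: int = INTERVAL_DECREASE_MIN_DAYS
    interval_post_max_low: int = INTERVAL_POST_MAX_LOW_DAYS
    interval_post_max_high: int = INTERVAL_POST_MAX_HIGH_DAYS
    dose_increase_min: float = DOSE_INCREASE_MIN_MG_KG
    dose_post_min_low: float = DOSE_POST_MIN_LOW_MG_KG
    dose_post_min_high: float = DOSE_POST_MIN_HIGH_MG_KG

    @classmethod
    def from_weeks(
        cls,
        interval_decrease_min_weeks: float = 1.57,
        interval_post_max_low_weeks: float = 6.57,
        interval_post_max_high_weeks: float = 5.0,
        **dose_kwargs,
    ) -> "Thresholds":
        """Build from week-denominated interval thresholds.

        Week values are converted with round-to-nearest-day (1.57 wk -> 11 d,
        6.57 wk -> 46 d, 5 wk -> 35 d), matching the published day
        equivalents.
        """
        return cls(
            interval_decrease_min=round(interval_decrease_min_weeks * 7),
            interval_post_max_low=round(interval_post_max_low_weeks * 7),
            interval_post_max_high=round(interval_post_max_high_weeks * 7),
            **dose_kwargs,
        )


@dataclass(frozen=True)
class DoseOptimizationEvent:
    patient_id: str
    date: date
    trigger: str  # interval | dose | both
    prior_interval_days: int | None
    posterior_interval_days: int | None
    prior_dose_mg_kg: float
    posterior_dose_mg_kg: float
    meets_low: bool
    meets_high: bool


EVENT_COLUMNS = [
    "patient_id",
    "date",
    "trigger",
    "prior_interval_days",
    "posterior_interval_days",
    "prior_dose_mg_kg",
    "posterior_dose_mg_kg",
    "meets_low",
    "meets_high",
]


def resolve_weights(
    weights: Sequence[float | None], fallback_weight: float | None = None
) -> list[float]:
    """Resolve per-infusion weights: event weight, else most recent prior
    recorded weight, else the first recorded weight (``fallback_weight`` is
    the patient-table first recorded weight).  Raises if none recorded."""
    vals = [None if w is None or pd.isna(w) else float(w) for w in weights]
    first = next((w for w in vals if w is not None), None)
    if first is None and fallback_weight is not None and not pd.isna(fallback_weight):
        first = float(fallback_weight)
    if first is None:
        raise ValueError("no recorded weight anywhere for patient")
    out, last = [], None
    for w in vals:
        if w is not None:
            last = w
        out.append(last if last is not None else first)
    return out


def dose_level(dose_mg: float, weight_kg: float) -> float:
    """mg/kg dose level for one infusion (weight already resolved)."""
    if dose_mg <= 0:
        raise ValueError(f"dose_mg {dose_mg} must be positive")
    if weight_kg is None or pd.isna(weight_kg) or weight_kg <= 0:
        raise ValueError(f"weight_kg {weight_kg} must be positive")
    return dose_mg / weight_kg


def dose_levels(
    dose_mg: Sequence[float],
    weights: Sequence[float | None],
    fallback_weight: float | None = None,
) -> list[float]:
    resolved = resolve_weights(weights, fallback_weight)
    return [dose_level(d, w) for d, w in zip(dose_mg, resolved)]


def detect_dose_optimizations(
    dates: Sequence[date | pd.Timestamp],
    dose_mg_kg: Sequence[float],
    patient_id: str = "",
    thresholds: Thresholds = Thresholds(),
    first_infusion_date: date | pd.Timestamp | None = None,
) -> list[DoseOptimizationEvent]:
    """Scan one patient's (date, mg/kg) sequence for escalation events.

    ``first_infusion_date`` anchors the maintenance-phase cutoff (defaults to
    the first date in the sequence).  Dose levels are rounded to 2 decimals
    before thresholding to suppress float noise from the mg/weight division.
    """
    d = [x.date() if isinstance(x, pd.Timestamp) else x for x in dates]
    if sorted(d) != d:
        order = sorted(range(len(d)), key=lambda j: d[j])
        d = [d[j] for j in order]
        dose_mg_kg = [dose_mg_kg[j] for j in order]
    if not d:
        return []
    anchor = first_infusion_date
    anchor = anchor.date() if isinstance(anchor, pd.Timestamp) else anchor
    if anchor is None:
        anchor = d[0]

    rel = [(x - anchor).days for x in d]
    found = _detect_core(rel, [float(x) for x in dose_mg_kg], thresholds)
    day_to_date = {r: x for r, x in zip(rel, d)}
    return [
        DoseOptimizationEvent(
            patient_id=patient_id,
            date=day_to_date[day],
            trigger=trigger,
            prior_interval_days=pi,
            posterior_interval_days=qi,
            prior_dose_mg_kg=pdos,
            posterior_dose_mg_kg=qdos,
            meets_low=True,
            meets_high=high,
        )
        for (day, trigger, pi, qi, pdos, qdos, high) in found
    ]


def _detect_core(
    rel_days: Sequence[int], dose_mg_kg: Sequence[float], th: Thresholds
) -> list[tuple]:
    """Detection on integer day offsets from the first infusion.

    Returns (event_day, trigger, prior_interval, posterior_interval,
    prior_dose, posterior_dose, meets_high) tuples; all events meet the low
    threshold by construction.
    """
    m_days = [r for r in rel_days if r > MAINTENANCE_START_DAY]
    m_dose = [round(x, 2) for r, x in zip(rel_days, dose_mg_kg) if r > MAINTENANCE_START_DAY]
    events: list[tuple] = []
    for j in range(1, len(m_days)):
        prior_int = (m_days[j - 1] - m_days[j - 2]) if j >= 2 else None
        post_int = m_days[j] - m_days[j - 1]
        int_low = int_high = False
        if prior_int is not None:
            decrease_ok = (prior_int - post_int) >= th.interval_decrease_min
            int_low = decrease_ok and post_int <= th.interval_post_max_low
            int_high = decrease_ok and post_int <= th.interval_post_max_high
        prior_dose, post_dose = m_dose[j - 1], m_dose[j]
        increase_ok = (post_dose - prior_dose) >= th.dose_increase_min
        dose_low = increase_ok and post_dose >= th.dose_post_min_low
        dose_high = increase_ok and post_dose >= th.dose_post_min_high
        if not (int_low or dose_low):
            continue
        trigger = "both" if (int_low and dose_low) else ("interval" if int_low else "dose")
        events.append(
            (m_days[j], trigger, prior_int, post_int, prior_dose, post_dose, bool(int_high or dose_high))
        )
    return events


def detect_all(
    infusions: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    patients: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Detect events for every patient in an infusion table (sorted per patient).

    ``patients`` supplies the first-recorded-weight fallback for patients with
    no weight on any infusion row.
    """
    inf = infusions.sort_values(["patient_id", "date"], kind="mergesort")
    w = inf.groupby("patient_id")["weight_kg"].ffill()
    w = w.groupby(inf["patient_id"]).bfill()
    if patients is not None and w.isna().any():
        fb = inf["patient_id"].map(patients.set_index("patient_id")["first_weight_kg"])
        w = w.fillna(fb)
    if w.isna().any():
        bad = inf.loc[w.isna(), "patient_id"].unique()
        raise ValueError(f"no recorded weight anywhere for patient(s) {list(bad[:5])}")
    mgkg = (inf["dose_mg"] / w).to_numpy()
    days = inf["date"].to_numpy().astype("datetime64[D]").astype(int)
    pids, starts = np.unique(inf["patient_id"].to_numpy(), return_index=True)
    order = np.argsort(starts)
    pids, starts = pids[order], starts[order]
    bounds = np.append(starts, len(inf))

    rows: list[tuple] = []
    for pid, lo, hi in zip(pids, bounds[:-1], bounds[1:]):
        d = days[lo:hi]
        rel = d - d[0]
        for (day, trigger, pi, qi, pdos, qdos, high) in _detect_core(
            rel.tolist(), mgkg[lo:hi].tolist(), thresholds
        ):
            rows.append(
                (pid, np.datetime64(int(d[0] + day), "D"), trigger, pi, qi, pdos, qdos, True, high)
            )
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df["date"] = pd.to_datetime(df["date"])
    for col in ("prior_interval_days", "posterior_interval_days"):
        df[col] = df[col].astype("Int64")
    return df


def _meets(level: str):
    if level not in ("low", "high"):
        raise ValueError(f"level {level!r} must be 'low' or 'high'")
    return "meets_high" if level == "high" else "meets_low"


def prior_do_flag(events: pd.DataFrame, tdm_date, level: str = "low") -> bool:
    """True iff any event at the given level occurred strictly before tdm_date."""
    if events.empty:
        return False
    sel = events[events[_meets(level)].astype(bool)]
    return bool((pd.to_datetime(sel["date"]) < pd.Timestamp(tdm_date)).any())


def do_within_window(
    events: pd.DataFrame, tdm_date, window_weeks: int, level: str = "low"
):
    """First event at the given level in (tdm_date, tdm_date + window_weeks*7].

    The window excludes the TDM day itself (a pre-draw same-day dose change is
    not post-TDM) and includes the right edge.  Returns (bool, date-or-None).
    """
    if events.empty:
        return False, None
    t0 = pd.Timestamp(tdm_date)
    t1 = t0 + pd.Timedelta(days=window_weeks * 7)
    sel = events[events[_meets(level)].astype(bool)]
    dates = pd.to_datetime(sel["date"])
    hit = sel[(dates > t0) & (dates <= t1)]
    if hit.empty:
        return False, None
    return True, pd.to_datetime(hit["date"]).min()
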