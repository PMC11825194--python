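"""Treatment-persistence derivation and Kaplan–Meier estimation.

Discontinuation rule: a gap of strictly more than ``gap_weeks`` (20 primary,
12 sensitivity) between consecutive infusions, or between the last infusion
and the censoring date, deems the patient discontinued as of 8 weeks (56 days,
one treatment cycle) after the last infusion preceding the gap.  Patients with
no qualifying gap are right-censored at the censoring date.

Gaps are evaluated on the full treatment history even when the index date is
later (subgroup analyses); only time after the index date contributes to the
duration.  If the 8-week offset would land after the censoring date the
patient is censored instead — a discontinuation cannot be placed after the
end of data.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

DISCONTINUATION_OFFSET_DAYS = 56  # one 8-week treatment cycle
DEFAULT_CENSOR_DATE = date(2019, 7, 31)

OUTCOME_COLUMNS = [
    "patient_id",
    "index_date",
    "duration_days",
    "discontinued",
    "discontinuation_date",
    "censor_date",
    "gap_rule_weeks",
]


@dataclass(frozen=True)
class PersistenceOutcome:
    patient_id: str
    index_date: date
    duration_days: int
    discontinued: bool
    discontinuation_date: date | None
    censor_date: date
    gap_rule_weeks: int


def _as_date(d) -> date:
    if isinstance(d, pd.Timestamp):
        return d.date()
    return d


def derive_persistence(
    infusion_dates: Sequence[date | pd.Timestamp],
    index_date: date | pd.Timestamp,
    censor_date: date | pd.Timestamp = DEFAULT_CENSOR_DATE,
    gap_weeks: int = 20,
    patient_id: str = "",
) -> PersistenceOutcome:
    """Apply the gap rule to one patient's infusion sequence.

    ``infusion_dates`` may be unsorted; dates after ``censor_date`` are
    ignored.  Requires at least one infusion on/after ``index_date`` within
    the study window.
    """
    index_date = _as_date(index_date)
    censor_date = _as_date(censor_date)
    if index_date > censor_date:
        raise ValueError(f"index_date {index_date} after censor_date {censor_date}")
    dates = sorted({_as_date(d) for d in infusion_dates if _as_date(d) <= censor_date})
    if not dates:
        raise ValueError("patient has no infusion on or before the censor date")
    if not any(d >= index_date for d in dates):
        raise ValueError("patient has no infusion on or after the index date")
    threshold = gap_weeks * 7

    disc_date: date | None = None
    for prev, nxt in zip(dates, dates[1:]):
        if (nxt - prev).days > threshold:
            disc_date = prev + timedelta(days=DISCONTINUATION_OFFSET_DAYS)
            break
    else:
        if (censor_date - dates[-1]).days > threshold:
            disc_date = dates[-1] + timedelta(days=DISCONTINUATION_OFFSET_DAYS)

    if disc_date is not None and disc_date <= censor_date:
        duration = (disc_date - index_date).days
        discontinued = True
    else:
        disc_date = None
        duration = (censor_date - index_date).days
        discontinued = False
    if duration < 0:
        raise ValueError(
            f"index_date {index_date} falls after the end of follow-up; "
            "subgroup selection should have excluded this patient"
        )
    return PersistenceOutcome(
        patient_id=patient_id,
        index_date=index_date,
        duration_days=duration,
        discontinued=discontinued,
        discontinuation_date=disc_date,
        censor_date=censor_date,
        gap_rule_weeks=gap_weeks,
    )


def derive_persistence_table(
    infusions: pd.DataFrame,
    index_dates: pd.Series | None = None,
    censor_date: date | pd.Timestamp = DEFAULT_CENSOR_DATE,
    gap_weeks: int = 20,
) -> pd.DataFrame:
    """Vectorized gap-rule application: one outcome row per patient.

    ``index_dates`` maps patient_id -> index date; by default each patient's
    first infusion is the index (overall-population analysis).  Agrees exactly
    with per-patient :func:`derive_persistence`: the first qualifying gap is
    in chronological order, and when its 8-week offset lands after the censor
    date every later qualifying gap's offset does too, so the patient is
    censored either way.
    """
    censor = pd.Timestamp(_as_date(censor_date))
    threshold = gap_weeks * 7
    inf = infusions.loc[infusions["date"] <= censor, ["patient_id", "date"]]
    inf = inf.drop_duplicates().sort_values(["patient_id", "date"], kind="mergesort")
    if inf.empty:
        return outcomes_to_table([])

    pid = inf["patient_id"].to_numpy()
    dates = inf["date"].to_numpy()
    same_next = np.empty(len(inf), dtype=bool)
    same_next[:-1] = pid[:-1] == pid[1:]
    same_next[-1] = False
    nxt = np.empty_like(dates)
    nxt[:-1] = dates[1:]
    nxt[~same_next] = np.datetime64(censor.to_datetime64())
    gap = (nxt - dates).astype("timedelta64[D]").astype(int)

    qual = gap > threshold
    firstq = (
        pd.DataFrame({"patient_id": pid[qual], "pre_gap_date": dates[qual]})
        .groupby("patient_id", sort=False)
        .first()
    )
    out = pd.DataFrame({"patient_id": pd.unique(pid)})
    first_date = pd.Series(dates).groupby(pid, sort=False).min()
    if index_dates is not None:
        out["index_date"] = pd.to_datetime(out["patient_id"].map(index_dates))
        if out["index_date"].isna().any():
            raise ValueError("index_dates missing for some patients")
        last_date = pd.Series(dates).groupby(pid, sort=False).max()
        if (out["patient_id"].map(last_date) < out["index_date"]).any():
            raise ValueError("patient has no infusion on or after the index date")
    else:
        out["index_date"] = out["patient_id"].map(first_date)
    if (out["index_date"] > censor).any():
        raise ValueError("index_date after censor_date")

    disc = pd.to_datetime(out["patient_id"].map(firstq["pre_gap_date"])) + pd.Timedelta(
        days=DISCONTINUATION_OFFSET_DAYS
    )
    discontinued = disc.notna() & (disc <= censor)
    disc = disc.where(discontinued)
    end = disc.fillna(censor)
    duration = (end - out["index_date"]).dt.days
    if (duration < 0).any():
        raise ValueError("index_date falls after the end of follow-up for some patients")
    out["duration_days"] = duration.astype(int)
    out["discontinued"] = discontinued.to_numpy()
    out["discontinuation_date"] = disc
    out["censor_date"] = censor
    out["gap_rule_weeks"] = gap_weeks
    for col in ("index_date", "discontinuation_date", "censor_date"):
        out[col] = out[col].astype("datetime64[ns]")
    return out[OUTCOME_COLUMNS]


def outcomes_to_table(outcomes: Iterable[PersistenceOutcome]) -> pd.DataFrame:
    df = pd.DataFrame([o.__dict__ for o in outcomes], columns=OUTCOME_COLUMNS)
    for col in ("index_date", "discontinuation_date", "censor_date"):
        df[col] = pd.to_datetime(df[col])
    return df


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate on the event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(durations: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan–Meier product-limit estimator with right censoring.

    Ties are handled by processing events before censorings at equal times
    (the standard convention).  Delegates to lifelines.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValueError("need at least one outcome")
    if (durations < 0).any():
        raise ValueError("negative duration")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    tbl = kmf.event_table
    times = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=tbl["at_risk"].to_numpy(dtype=float),
        events=tbl["observed"].to_numpy(dtype=float),
    )


def km_from_outcomes(outcomes: pd.DataFrame) -> KMCurve:
    return km_estimate(outcomes["duration_days"], outcomes["discontinued"])
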