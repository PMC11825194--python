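"""Cohort construction: overall-population inclusion, TDM subgroup selection,
and analysis subset (A/B) labeling.

Overall population: first infusion in the initiation window, age 18–90 at
initiation, first recorded weight < 130 kg, and no infusion during the
lookback period (prior drug exposure).

TDM subgroup: the chronologically first TDM must fall strictly after Week 9
(day 63) from the first infusion, itself carry a recorded concentration, and
occur on/before the patient's discontinuation-or-censor date; it becomes the
index date.

Subsets: within each prior-dose-optimization subpopulation, patients with a
first concentration strictly below the threshold are labeled B if a
dose-optimization at the given level occurs within the post-TDM window, else
A; at- or above-threshold patients get subset ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from . import dose_optimization as do

DEFAULT_INITIATION_START = date(2015, 1, 1)
DEFAULT_INITIATION_END = date(2018, 12, 31)
DEFAULT_LOOKBACK_START = date(2014, 5, 1)

SUBSET_COLUMNS = [
    "patient_id",
    "subpopulation",
    "conc_threshold",
    "below_threshold",
    "window_weeks",
    "subset",
    "tdm_index_date",
    "days_to_tdm",
    "do_date",
]


@dataclass(frozen=True)
class SelectionResult:
    included: pd.DataFrame
    ledger: pd.DataFrame  # columns: patient_id, rule


def _ledger(rows: list[tuple[str, str]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["patient_id", "rule"])


def select_overall(
    patients: pd.DataFrame,
    infusions: pd.DataFrame,
    initiation_start: date = DEFAULT_INITIATION_START,
    initiation_end: date = DEFAULT_INITIATION_END,
    lookback_start: date = DEFAULT_LOOKBACK_START,
) -> SelectionResult:
    """Apply overall-population inclusion rules; every exclusion is ledgered
    under the first rule it violates, so |input| = |included| + |ledger|."""
    first = infusions.groupby("patient_id")["date"].min()
    start, end = pd.Timestamp(initiation_start), pd.Timestamp(initiation_end)
    lookback = pd.Timestamp(lookback_start)

    excl: list[tuple[str, str]] = []
    keep_ids = []
    for row in patients.itertuples(index=False):
        pid = row.patient_id
        if pid not in first.index:
            excl.append((pid, "no_infusions"))
            continue
        init = first[pid]
        if init < start:
            rule = "prior_treatment_lookback" if init >= lookback else "initiation_outside_window"
            excl.append((pid, rule))
            continue
        if init > end:
            excl.append((pid, "initiation_outside_window"))
            continue
        if not (18 <= row.age_at_initiation <= 90):
            excl.append((pid, "age_out_of_range"))
            continue
        if not (row.first_weight_kg < 130):
            excl.append((pid, "weight_at_or_above_130kg"))
            continue
        keep_ids.append(pid)
    included = patients[patients["patient_id"].isin(keep_ids)].copy()
    included = included.merge(
        first.rename("initiation_date"), left_on="patient_id", right_index=True
    )
    return SelectionResult(included.reset_index(drop=True), _ledger(excl))


def select_subgroup(
    included: pd.DataFrame,
    tdm: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> SelectionResult:
    """Select the TDM subgroup from the overall population.

    ``included`` must carry ``initiation_date`` (from :func:`select_overall`);
    ``outcomes`` is the persistence table computed from initiation with the
    production gap rule.  The first TDM record must itself carry a recorded
    concentration; patients whose first record lacks one are excluded rather
    than advanced to their next TDM.
    """
    tdm = tdm.sort_values(["patient_id", "date"], kind="mergesort")
    # literal first record per patient (groupby.first() would skip missing
    # concentrations and silently advance to a later result)
    first_tdm = tdm.drop_duplicates("patient_id", keep="first")

    m = included[["patient_id", "initiation_date"]].merge(
        first_tdm, on="patient_id", how="left"
    )
    end = outcomes.set_index("patient_id")
    end_date = end["discontinuation_date"].where(end["discontinued"], end["censor_date"])
    m["end_date"] = m["patient_id"].map(end_date)
    m["days_to_tdm"] = (m["date"] - m["initiation_date"]).dt.days

    no_tdm = m["date"].isna()
    no_result = ~no_tdm & m["ifx_conc_ug_ml"].isna()
    too_early = ~no_tdm & ~no_result & (m["days_to_tdm"] <= 63)  # "after Week 9", strict
    too_late = ~no_tdm & ~no_result & ~too_early & (m["date"] > m["end_date"])
    keep = ~(no_tdm | no_result | too_early | too_late)

    excl = [
        (pid, rule)
        for mask, rule in (
            (no_tdm, "no_tdm"),
            (no_result, "first_tdm_without_result"),
            (too_early, "tdm_not_in_maintenance_phase"),
            (too_late, "tdm_after_discontinuation_or_censor"),
        )
        for pid in m.loc[mask, "patient_id"]
    ]
    sub = pd.DataFrame(
        {
            "patient_id": m.loc[keep, "patient_id"],
            "tdm_index_date": m.loc[keep, "date"],
            "first_conc_ug_ml": m.loc[keep, "ifx_conc_ug_ml"].astype(float),
            "first_ati_status": m.loc[keep, "ati_status"],
            "days_to_tdm": m.loc[keep, "days_to_tdm"].astype(int) if keep.any() else pd.Series(dtype=int),
        }
    ).reset_index(drop=True)
    return SelectionResult(sub, _ledger(excl))


def assign_subsets(
    subgroup: pd.DataFrame,
    events: pd.DataFrame,
    infusions: pd.DataFrame,
    conc_threshold: float = 3.0,
    window_weeks: int = 9,
    level: str = "low",
    exclude_no_post_tdm_treatment: bool = False,
) -> SelectionResult:
    """Label each subgroup patient with subpopulation and subset A/B/none.

    Subset B requires a dose-optimization event at the given level within
    (tdm, tdm + window]; A is below-threshold without one; ``none`` marks
    at-/above-threshold patients.  With the sensitivity flag on, patients with
    zero infusions after the TDM date are dropped before labeling.
    """
    if conc_threshold not in (3.0, 5.0, 10.0):
        import warnings

        warnings.warn(f"non-standard concentration threshold {conc_threshold}", stacklevel=2)
    post_counts = None
    if exclude_no_post_tdm_treatment:
        inf = infusions.merge(
            subgroup[["patient_id", "tdm_index_date"]], on="patient_id", how="inner"
        )
        post_counts = (
            inf[inf["date"] > inf["tdm_index_date"]].groupby("patient_id").size()
        )

    excl: list[tuple[str, str]] = []
    out = subgroup[["patient_id", "tdm_index_date", "days_to_tdm", "first_conc_ug_ml"]].copy()
    if post_counts is not None:
        dropped = ~out["patient_id"].map(post_counts).fillna(0).astype(int).gt(0)
        excl.extend((pid, "no_treatment_after_tdm") for pid in out.loc[dropped, "patient_id"])
        out = out[~dropped]

    # vectorized equivalents of prior_do_flag / do_within_window per patient
    meets = "meets_high" if level == "high" else "meets_low"
    if level not in ("low", "high"):
        raise ValueError(f"level {level!r} must be 'low' or 'high'")
    lv = events[events[meets].astype(bool)] if not events.empty else events
    m = (
        lv.merge(out[["patient_id", "tdm_index_date"]], on="patient_id", how="inner")
        if not lv.empty
        else pd.DataFrame(columns=["patient_id", "date", "tdm_index_date"])
    )
    prior_ids = set(m.loc[m["date"] < m["tdm_index_date"], "patient_id"])
    w_end = m["tdm_index_date"] + pd.Timedelta(days=window_weeks * 7)
    in_win = m[(m["date"] > m["tdm_index_date"]) & (m["date"] <= w_end)]
    first_do = in_win.groupby("patient_id")["date"].min()

    prior = out["patient_id"].isin(prior_ids)
    out["subpopulation"] = np.where(prior, f"prior_do_{level}", f"no_prior_do_{level}")
    out["conc_threshold"] = conc_threshold
    out["below_threshold"] = out["first_conc_ug_ml"] < conc_threshold
    out["window_weeks"] = window_weeks
    do_date = out["patient_id"].map(first_do)
    out["subset"] = np.where(
        ~out["below_threshold"], "none", np.where(do_date.notna(), "B", "A")
    )
    out["do_date"] = pd.to_datetime(do_date.where(out["subset"] == "B"))
    out = out[SUBSET_COLUMNS].reset_index(drop=True)
    return SelectionResult(out, _ledger(excl))


def weight_quartiles(weights: pd.Series) -> pd.Series:
    """Quartile labels Q1..Q4 computed within the analysis population."""
    q = pd.qcut(weights, 4, labels=["Q1", "Q2", "Q3", "Q4"], duplicates="drop")
    return q.astype(str)


def age_group(age: pd.Series) -> pd.Series:
    return np.where(age < 65, "18-<65", "65-90")
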