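"""Inclusion rules, subgroup selection, and subset labeling."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from persistkit import cohort, dose_optimization
from persistkit.persistence import derive_persistence_table


def _patients(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "diagnosis",
            "age_at_initiation",
            "gender",
            "province_region",
            "first_weight_kg",
        ],
    )


def _infusions(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "date", "dose_mg", "weight_kg"])
    df["date"] = pd.to_datetime(df["date"])
    return df


class TestSelectOverall:
    def setup_method(self):
        self.patients = _patients(
            [
                ("OK", "CD", 42, "female", "Ontario", 70.0),
                ("YOUNG", "CD", 17, "female", "Ontario", 70.0),
                ("OLD", "UC", 91, "male", "Quebec", 70.0),
                ("HEAVY", "CD", 42, "male", "Alberta", 130.0),
                ("ALMOST", "CD", 42, "male", "Alberta", 129.9),
                ("PRIOR", "UC", 42, "female", "Ontario", 70.0),
                ("LATE", "UC", 42, "female", "Ontario", 70.0),
                ("NOINF", "CD", 42, "female", "Ontario", 70.0),
            ]
        )
        rows = [(p, "2015-03-01", 350, 70) for p in ("OK", "YOUNG", "OLD", "HEAVY", "ALMOST")]
        rows.append(("PRIOR", "2014-11-01", 350, 70))
        rows.append(("PRIOR", "2015-03-01", 350, 70))
        rows.append(("LATE", "2019-02-01", 350, 70))
        self.infusions = _infusions(rows)

    def test_rules_and_ledger_partition_the_input(self):
        res = cohort.select_overall(self.patients, self.infusions)
        assert sorted(res.included["patient_id"]) == ["ALMOST", "OK"]
        rules = dict(zip(res.ledger["patient_id"], res.ledger["rule"]))
        assert rules == {
            "YOUNG": "age_out_of_range",
            "OLD": "age_out_of_range",
            "HEAVY": "weight_at_or_above_130kg",
            "PRIOR": "prior_treatment_lookback",
            "LATE": "initiation_outside_window",
            "NOINF": "no_infusions",
        }
        assert len(self.patients) == len(res.included) + len(res.ledger)

    def test_initiation_date_is_first_infusion(self):
        res = cohort.select_overall(self.patients, self.infusions)
        init = res.included.set_index("patient_id")["initiation_date"]
        assert init["OK"] == pd.Timestamp("2015-03-01")


class TestSelectSubgroup:
    def _inputs(self, tdm_rows):
        patients = _patients([("P1", "CD", 40, "female", "Ontario", 70.0)])
        init = date(2016, 1, 1)
        inf = _infusions(
            [("P1", init + timedelta(days=d), 350, 70) for d in (0, 14, 42, 98, 154, 210)]
        )
        sel = cohort.select_overall(patients, inf)
        outcomes = derive_persistence_table(inf)
        tdm = pd.DataFrame(tdm_rows, columns=["patient_id", "date", "ifx_conc_ug_ml", "ati_status"])
        tdm["date"] = pd.to_datetime(tdm["date"])
        return sel.included, tdm, outcomes, init

    def test_first_tdm_on_day_63_is_excluded_but_64_included(self):
        for day, expect_in in ((63, False), (64, True)):
            included, tdm, outcomes, init = self._inputs(
                [("P1", date(2016, 1, 1) + timedelta(days=day), 2.0, "negative")]
            )
            res = cohort.select_subgroup(included, tdm, outcomes)
            assert (len(res.included) == 1) is expect_in
            if expect_in:
                assert res.included.loc[0, "days_to_tdm"] == 64

    def test_first_tdm_without_result_excludes_even_with_later_result(self):
        included, tdm, outcomes, init = self._inputs(
            [
                ("P1", date(2016, 4, 8), None, "missing"),
                ("P1", date(2016, 6, 1), 2.0, "negative"),
            ]
        )
        res = cohort.select_subgroup(included, tdm, outcomes)
        assert res.included.empty
        assert list(res.ledger["rule"]) == ["first_tdm_without_result"]

    def test_tdm_after_discontinuation_is_excluded(self):
        # last infusion day 210, censored-by-gap: discontinued at 210 + 56 = day 266
        included, tdm, outcomes, init = self._inputs(
            [("P1", date(2016, 1, 1) + timedelta(days=300), 2.0, "negative")]
        )
        res = cohort.select_subgroup(included, tdm, outcomes)
        assert res.included.empty
        assert list(res.ledger["rule"]) == ["tdm_after_discontinuation_or_censor"]


class TestAssignSubsets:
    def _subgroup(self):
        return pd.DataFrame(
            {
                "patient_id": ["A1", "B1", "HIGHCONC", "NOTREAT"],
                "tdm_index_date": pd.to_datetime(["2016-05-01"] * 4),
                "first_conc_ug_ml": [2.5, 2.5, 3.0, 2.5],
                "first_ati_status": ["negative"] * 4,
                "days_to_tdm": [120] * 4,
            }
        )

    def _events(self):
        df = pd.DataFrame(
            {
                "patient_id": ["B1"],
                "date": pd.to_datetime(["2016-06-10"]),  # TDM + 40 d
                "trigger": ["dose"],
                "prior_interval_days": [56],
                "posterior_interval_days": [56],
                "prior_dose_mg_kg": [5.0],
                "posterior_dose_mg_kg": [7.5],
                "meets_low": [True],
                "meets_high": [False],
            }
        )
        return df

    def _infusions(self):
        rows = []
        for pid in ("A1", "B1", "HIGHCONC"):
            rows.append((pid, "2016-06-10", 350, 70))
        rows.append(("NOTREAT", "2016-04-01", 350, 70))
        return _infusions(rows)

    def test_worked_examples(self):
        res = cohort.assign_subsets(
            self._subgroup(), self._events(), self._infusions(), 3.0, 9, "low"
        )
        out = res.included.set_index("patient_id")
        assert out.loc["B1", "subset"] == "B" and out.loc["B1", "subpopulation"] == "no_prior_do_low"
        assert out.loc["A1", "subset"] == "A"
        assert out.loc["HIGHCONC", "subset"] == "none"  # 3.0 at threshold 3 is not below
        assert not out.loc["HIGHCONC", "below_threshold"]
        assert pd.notna(out.loc["B1", "do_date"]) and pd.isna(out.loc["A1", "do_date"])

    def test_exclude_no_post_tdm_treatment_drops_before_labeling(self):
        res = cohort.assign_subsets(
            self._subgroup(), self._events(), self._infusions(), 3.0, 9, "low",
            exclude_no_post_tdm_treatment=True,
        )
        assert "NOTREAT" not in set(res.included["patient_id"])
        assert list(res.ledger["rule"]) == ["no_treatment_after_tdm"]

    def test_prior_do_moves_patient_to_prior_subpopulation(self):
        events = self._events()
        events.loc[0, "date"] = pd.Timestamp("2016-04-01")  # before the TDM
        res = cohort.assign_subsets(self._subgroup(), events, self._infusions(), 3.0, 9, "low")
        out = res.included.set_index("patient_id")
        assert out.loc["B1", "subpopulation"] == "prior_do_low"
        assert out.loc["B1", "subset"] == "A"  # no within-window event anymore


class TestPartitionInvariants:
    def test_partition_and_counting_consistency_on_synthetic_cohort(self, small_cohort):
        patients, infusions, tdm, _ = small_cohort
        sel = cohort.select_overall(patients, infusions)
        inf = infusions[infusions["patient_id"].isin(sel.included["patient_id"])]
        outcomes = derive_persistence_table(inf)
        events = dose_optimization.detect_all(inf, patients=patients)
        sub = cohort.select_subgroup(sel.included, tdm, outcomes)
        assert len(sel.included) == len(sub.included) + len(sub.ledger)
        for level in ("low", "high"):
            res = cohort.assign_subsets(sub.included, events, inf, 3.0, 9, level)
            out = res.included
            assert len(out) == len(sub.included)
            assert set(out["subpopulation"]) <= {f"no_prior_do_{level}", f"prior_do_{level}"}
            below = out["below_threshold"]
            assert (out.loc[~below, "subset"] == "none").all()
            assert set(out.loc[below, "subset"]) <= {"A", "B"}
            n_a = (out["subset"] == "A").sum()
            n_b = (out["subset"] == "B").sum()
            assert n_a + n_b == int(below.sum())

    def test_vectorized_labels_agree_with_scalar_flag_operations(self, small_cohort):
        patients, infusions, tdm, _ = small_cohort
        sel = cohort.select_overall(patients, infusions)
        inf = infusions[infusions["patient_id"].isin(sel.included["patient_id"])]
        outcomes = derive_persistence_table(inf)
        events = dose_optimization.detect_all(inf, patients=patients)
        sub = cohort.select_subgroup(sel.included, tdm, outcomes)
        out = cohort.assign_subsets(sub.included, events, inf, 3.0, 9, "low").included
        by_pid = dict(tuple(events.groupby("patient_id")))
        empty = events.iloc[0:0]
        for row in out.itertuples(index=False):
            ev = by_pid.get(row.patient_id, empty)
            prior = dose_optimization.prior_do_flag(ev, row.tdm_index_date, "low")
            assert row.subpopulation == ("prior_do_low" if prior else "no_prior_do_low")
            hit, when = dose_optimization.do_within_window(ev, row.tdm_index_date, 9, "low")
            if row.below_threshold:
                assert row.subset == ("B" if hit else "A")
                if hit:
                    assert row.do_date == when
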