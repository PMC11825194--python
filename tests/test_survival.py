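"""Counting-process construction and Cox fitting against independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from persistkit import reporting, survival
from persistkit.config import SimulationConfig
from persistkit.synthetic import simulate_cohort


# ---------------------------------------------------------------------------
# independent brute-force partial likelihood (straightforward, unoptimized)
# ---------------------------------------------------------------------------

def neg_log_partial_likelihood(beta, X, start, stop, event, strata, ties):
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    for s in np.unique(strata):
        rows = np.flatnonzero(strata == s)
        for t in np.unique(stop[rows][event[rows]]):
            at_risk = rows[(start[rows] < t) & (t <= stop[rows])]
            deaths = rows[(stop[rows] == t) & event[rows]]
            eta = X[at_risk] @ beta
            eta_d = X[deaths] @ beta
            d = len(deaths)
            total += eta_d.sum()
            if ties == "breslow":
                total -= d * np.log(np.exp(eta).sum())
            else:
                w_all = np.exp(eta).sum()
                w_d = np.exp(eta_d).sum()
                for ell in range(d):
                    total -= np.log(w_all - (ell / d) * w_d)
    return -total


def brute_force_fit(df, cols, strata_col=None, ties="efron"):
    X = df[cols].to_numpy(dtype=float)
    start = df["start"].to_numpy(dtype=float)
    stop = df["stop"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=bool)
    strata = df[strata_col].to_numpy() if strata_col else np.zeros(len(df))
    res = optimize.minimize(
        neg_log_partial_likelihood,
        np.zeros(len(cols)),
        args=(X, start, stop, event, strata, ties),
        method="BFGS",
        options={"gtol": 1e-10},
    )
    return res.x, -res.fun


def random_instance(rng, n, with_strata=False, tie_prone=True):
    stop = rng.integers(1, 12 if tie_prone else 1000, size=n).astype(float)
    start = np.where(rng.random(n) < 0.4, stop * rng.random(n) * 0.8, 0.0).round(1)
    start = np.minimum(start, stop - 0.5)
    event = rng.random(n) < 0.7
    df = pd.DataFrame(
        {
            "patient_id": [f"S{i}" for i in range(n)],
            "start": start,
            "stop": stop,
            "event": event,
            "x1": rng.normal(size=n).round(2),
            "x2": (rng.random(n) < 0.5).astype(float),
            "stratum": rng.integers(0, 2, size=n) if with_strata else 0,
        }
    )
    # ensure estimability: at least 2 events and variation in both columns
    if df["event"].sum() < 2 or df["x2"].nunique() < 2:
        return random_instance(rng, n, with_strata, tie_prone)
    return df


class TestCountingProcess:
    def _frame(self, duration, event, exposure_day):
        return pd.DataFrame(
            {
                "patient_id": ["P1"],
                "duration_days": [duration],
                "discontinued": [event],
                "exposure_day": [exposure_day],
                "stratum": [2016],
            }
        )

    def test_exposed_subject_splits_at_exposure_day(self):
        rows = survival.build_counting_process(self._frame(100.0, True, 30.0))
        assert len(rows) == 2
        pre, post = rows.iloc[0], rows.iloc[1]
        assert (pre["start"], pre["stop"], pre["event"], pre["exposure"]) == (0.0, 30.0, False, 0)
        assert (post["start"], post["stop"], post["event"], post["exposure"]) == (30.0, 100.0, True, 1)

    def test_unexposed_subject_is_one_row(self):
        rows = survival.build_counting_process(self._frame(100.0, False, np.nan))
        assert len(rows) == 1 and rows.loc[0, "exposure"] == 0 and not rows.loc[0, "event"]

    def test_exposure_at_end_of_follow_up_stays_unexposed(self):
        rows = survival.build_counting_process(self._frame(100.0, True, 100.0))
        assert len(rows) == 1 and rows.loc[0, "exposure"] == 0 and bool(rows.loc[0, "event"])

    def test_preconditions(self):
        with pytest.raises(ValueError, match="exposure_day"):
            survival.build_counting_process(self._frame(100.0, True, 0.0))
        with pytest.raises(ValueError, match="duration"):
            survival.build_counting_process(self._frame(0.0, True, np.nan))

    def test_rows_tile_follow_up_with_single_terminal_event(self, small_cohort):
        patients, infusions, tdm, _ = small_cohort
        frame = reporting.overall_analysis_frame(patients, infusions, tdm)
        rows = survival.build_counting_process(
            frame[["patient_id", "duration_days", "discontinued", "exposure_day", "stratum"]]
        )
        durations = frame.set_index("patient_id")["duration_days"]
        for pid, grp in rows.groupby("patient_id"):
            grp = grp.sort_values("start")
            assert grp.iloc[0]["start"] == 0.0
            assert np.all(grp["stop"].to_numpy()[:-1] == grp["start"].to_numpy()[1:])
            assert grp.iloc[-1]["stop"] == durations[pid]
            assert not grp["event"].to_numpy()[:-1].any()
            assert (grp["exposure"].diff().dropna() >= 0).all()  # 0 -> 1 at most once


class TestFitAgainstOracles:
    def test_six_subject_toy_matches_brute_force(self):
        df = pd.DataFrame(
            {
                "patient_id": list("ABCDEF"),
                "start": [0.0] * 6,
                "stop": [2.0, 3.0, 3.0, 5.0, 7.0, 9.0],
                "event": [True, True, True, False, True, False],
                "x1": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
            }
        )
        for ties in ("efron", "breslow"):
            fit = survival.fit_cox(df, ["x1"], ties=ties)
            b, ll = brute_force_fit(df, ["x1"], ties=ties)
            assert abs(fit.params["x1"] - b[0]) < 1e-6
            assert abs(fit.loglik - ll) < 1e-8

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    @pytest.mark.parametrize("with_strata", [False, True])
    def test_small_random_instances_match_brute_force(self, ties, with_strata):
        rng = np.random.default_rng(hash((ties, with_strata)) % 2**31)
        for _ in range(8):
            df = random_instance(rng, 10, with_strata=with_strata)
            try:
                fit = survival.fit_cox(
                    df, ["x1", "x2"], strata="stratum" if with_strata else None, ties=ties
                )
            except (ValueError, survival.CoxConvergenceError):
                continue  # inestimable draw (e.g. separation); oracle would diverge too
            if max(abs(fit.params)) > 3:
                continue
            b, _ = brute_force_fit(df, ["x1", "x2"], "stratum" if with_strata else None, ties)
            if np.max(np.abs(b)) > 3:
                continue  # monotone likelihood: both optimizers drift, neither optimum exists
            assert np.max(np.abs(fit.params.to_numpy() - b)) < 1e-5

    def test_matches_lifelines_on_a_simulated_subgroup(self):
        # a cohort large enough that no covariate cell is quasi-separated,
        # so both fitters sit at a well-identified interior optimum
        patients, infusions, tdm, _ = simulate_cohort(SimulationConfig(n_patients=800, seed=5))
        frame = reporting.subgroup_analysis_frame(patients, infusions, tdm)
        cols = ["patient_id", "duration_days", "discontinued", "exposure_day", "stratum"]
        rows = survival.build_counting_process(frame[cols + reporting.SUBGROUP_COVARIATES])
        covs = ["exposure"] + reporting.SUBGROUP_COVARIATES
        fit = survival.fit_cox(rows, covs, strata="stratum")

        from lifelines import CoxTimeVaryingFitter

        enc, _ = survival.encode_design(rows, covs)
        ll_df = pd.concat(
            [rows[["patient_id", "start", "stop", "event", "stratum"]].reset_index(drop=True),
             enc.reset_index(drop=True)],
            axis=1,
        )
        ctv = CoxTimeVaryingFitter()
        ctv.fit(ll_df, id_col="patient_id", start_col="start", stop_col="stop",
                event_col="event", strata=["stratum"])
        diff = np.abs(fit.params.to_numpy() - ctv.params_.reindex(fit.params.index).to_numpy())
        assert np.max(diff) < 1e-8

    def test_all_zero_exposure_is_dropped_with_valid_remaining_fit(self):
        rng = np.random.default_rng(2)
        df = random_instance(rng, 40)
        df["exposure"] = 0
        with pytest.warns(UserWarning, match="dropped constant"):
            fit = survival.fit_cox(df, ["exposure", "x1", "x2"])
        assert "exposure" in fit.dropped
        assert set(fit.summary.index) == {"x1", "x2"}

    def test_collinear_columns_raise(self):
        rng = np.random.default_rng(3)
        df = random_instance(rng, 30)
        df["x3"] = 2.0 * df["x1"]
        with pytest.raises(ValueError, match="collinear"):
            survival.fit_cox(df, ["x1", "x3"])

    def test_no_events_raise(self):
        rng = np.random.default_rng(4)
        df = random_instance(rng, 10)
        df["event"] = False
        with pytest.raises(ValueError, match="no events"):
            survival.fit_cox(df, ["x1"])


class TestTimeInteraction:
    def test_episode_splitting_preserves_the_partial_likelihood(self):
        rng = np.random.default_rng(6)
        df = random_instance(rng, 60, tie_prone=False)
        df["exposure"] = (rng.random(60) < 0.5).astype(int)
        fit0 = survival.fit_cox(df, ["exposure", "x1"])
        split, tname = survival.split_at_event_times(df, base_col="exposure")
        fit1 = survival.fit_cox(split, ["exposure", "x1"])
        assert abs(fit0.loglik - fit1.loglik) < 1e-9
        assert np.max(np.abs(fit0.params.to_numpy() - fit1.params.to_numpy())) < 1e-9

    def test_hr_at_time_arithmetic_identity(self):
        summary = pd.DataFrame(
            {"coef": [-1.0, 0.1], "se": [0.1, 0.01]},
            index=pd.Index(["exposure", "exposure:log_t"], name="term"),
        )
        for col in ("hr", "ci_lower", "ci_upper", "z", "p"):
            summary[col] = np.nan
        fit = survival.ModelFit(
            model_id="M3", summary=summary,
            cov=pd.DataFrame(np.zeros((2, 2)), index=summary.index, columns=summary.index),
            loglik=0.0, loglik_null=0.0, n_events=1, n_rows=1, ties="efron", converged=True,
        )
        hr, lo, hi = survival.hr_at_time(fit, 4.0)
        assert hr == pytest.approx(np.exp(-1.0 + 0.1 * np.log(28.0)))
        assert lo == hi == pytest.approx(hr)  # zero covariance collapses the CI

    def test_zero_interaction_gives_equal_fixed_time_hrs(self):
        rng = np.random.default_rng(7)
        df = random_instance(rng, 80, tie_prone=False)
        df["exposure"] = (rng.random(80) < 0.5).astype(int)
        split, tname = survival.split_at_event_times(df, base_col="exposure")
        fit = survival.fit_cox(split, ["exposure", "x1", tname])
        if abs(fit.params[tname]) < 1e-12:  # only in the exact-zero case
            hr4 = survival.hr_at_time(fit, 4.0)[0]
            hr6 = survival.hr_at_time(fit, 6.0)[0]
            assert hr4 == pytest.approx(hr6)


def _simulate_subjects(rng, n, log_hr_fn):
    """Subject-level survival with exposure applied from day 1 and a possibly
    time-varying exposure log-hazard ratio; daily discrete hazard 0.01."""
    exposure = (rng.random(n) < 0.5).astype(float)
    days = np.arange(1, 400)
    base = 0.012
    dur = np.empty(n)
    ev = np.empty(n, dtype=bool)
    for i in range(n):
        h = base * np.exp(exposure[i] * log_hr_fn(days))
        u = rng.random(len(days))
        hit = np.nonzero(u < h)[0]
        if hit.size:
            dur[i] = days[hit[0]]
            ev[i] = True
        else:
            dur[i] = 399.0
            ev[i] = False
    return pd.DataFrame(
        {
            "patient_id": [f"S{i}" for i in range(n)],
            "duration_days": dur,
            "discontinued": ev,
            "exposure_day": np.where(exposure > 0, 1.0, np.nan),
            "x1": rng.normal(size=n).round(2),
            "stratum": 0,
        }
    )


class TestModelLadder:
    def test_constant_effect_selects_main_effects_model(self):
        rng = np.random.default_rng(10)
        subjects = _simulate_subjects(rng, 500, lambda t: -0.7 * np.ones_like(t, dtype=float))
        rows = survival.build_counting_process(subjects)
        ladder = survival.model_ladder(rows, ["exposure", "x1"], strata="stratum")
        assert ladder.selected_id == "M1"
        assert not ladder.ph_violated

    def test_decaying_effect_selects_time_interaction_model(self):
        rng = np.random.default_rng(12)
        subjects = _simulate_subjects(rng, 600, lambda t: -2.0 + 0.45 * np.log(t))
        rows = survival.build_counting_process(subjects)
        ladder = survival.model_ladder(rows, ["exposure", "x1"], strata="stratum")
        assert ladder.ph_violated
        assert ladder.selected_id in ("M3", "M4")
        assert ladder.selected.ph_test_p is not None and ladder.selected.ph_test_p < 0.05
        hr4 = survival.hr_at_time(ladder.fits["M3"], 4.0)[0]
        hr6 = survival.hr_at_time(ladder.fits["M3"], 6.0)[0]
        assert hr6 > hr4  # effect attenuates with time by construction
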