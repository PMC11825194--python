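"""End-to-end pipeline assembly, baseline tables, and run manifests.

The analysis surface mirrors the study design: the overall population
(exposure = any TDM use, index = initiation) and the TDM subgroup (exposure =
post-TDM dose optimization within a window, index = first TDM), each analyzed
with the stratified time-dependent Cox ladder, with the tipping-point bias
analysis available per subgroup cell.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import bias as bias_mod
from . import cohort, dose_optimization, persistence, records_io, survival
from .config import ConfigError, SimulationConfig
from .synthetic import simulate_cohort

SUBGROUP_COVARIATES = [
    "age_group",
    "gender",
    "weight_quartile",
    "province_region",
    "log_days_to_tdm",
]
OVERALL_COVARIATES = ["age_group", "gender", "weight_quartile", "province_region"]


# ---------------------------------------------------------------------------
# analysis-frame assembly
# ---------------------------------------------------------------------------

def _with_covariates(frame: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    out = frame.merge(
        patients[
            ["patient_id", "age_at_initiation", "gender", "province_region", "first_weight_kg"]
        ],
        on="patient_id",
        how="left",
    )
    out["age_group"] = cohort.age_group(out["age_at_initiation"])
    out["weight_quartile"] = cohort.weight_quartiles(out["first_weight_kg"])
    return out.drop(columns=["age_at_initiation", "first_weight_kg"])


def overall_analysis_frame(
    patients: pd.DataFrame,
    infusions: pd.DataFrame,
    tdm: pd.DataFrame,
    gap_weeks: int = 20,
    censor_date: date = persistence.DEFAULT_CENSOR_DATE,
) -> pd.DataFrame:
    """Subject-level frame for the overall analysis: exposure day = first TDM.

    Returns one row per included patient with duration, event indicator,
    exposure day (days from initiation to first TDM, if any), fixed
    covariates, and the initiation-year stratum.
    """
    sel = cohort.select_overall(patients, infusions)
    inf = infusions[infusions["patient_id"].isin(sel.included["patient_id"])]
    outcomes = persistence.derive_persistence_table(inf, censor_date=censor_date, gap_weeks=gap_weeks)
    frame = outcomes[["patient_id", "index_date", "duration_days", "discontinued"]].copy()
    # TDM *use* counts regardless of whether a result was recorded
    first_tdm = tdm.groupby("patient_id")["date"].min()
    frame = frame.merge(first_tdm.rename("first_tdm_date"), on="patient_id", how="left")
    exp_day = (frame["first_tdm_date"] - frame["index_date"]).dt.days.astype(float)
    # a TDM on/before the index day cannot define post-index exposure
    exp_day[exp_day <= 0] = np.nan
    frame["exposure_day"] = exp_day
    frame["stratum"] = frame["index_date"].dt.year
    frame = _with_covariates(frame, patients)
    return frame[frame["duration_days"] > 0].reset_index(drop=True)


def do_exposure_frame(
    patients: pd.DataFrame,
    infusions: pd.DataFrame,
    gap_weeks: int = 20,
    censor_date: date = persistence.DEFAULT_CENSOR_DATE,
    level: str = "low",
) -> pd.DataFrame:
    """Subject-level frame over the whole included population with exposure =
    first detected dose-optimization event (days from initiation).

    This is the cohort used to demonstrate immortal-time bias: the exposure
    can be coded naively (ever-exposed) or time-dependently from the same
    frame.
    """
    sel = cohort.select_overall(patients, infusions)
    inf = infusions[infusions["patient_id"].isin(sel.included["patient_id"])]
    outcomes = persistence.derive_persistence_table(inf, censor_date=censor_date, gap_weeks=gap_weeks)
    events = dose_optimization.detect_all(inf, patients=patients)
    if level == "high" and not events.empty:
        events = events[events["meets_high"]]
    first_ev = events.groupby("patient_id")["date"].min() if not events.empty else pd.Series(dtype="datetime64[ns]")
    frame = outcomes[["patient_id", "index_date", "duration_days", "discontinued"]].copy()
    exp_day = (frame["patient_id"].map(first_ev) - frame["index_date"]).dt.days.astype(float)
    exp_day[exp_day <= 0] = np.nan
    frame["exposure_day"] = exp_day
    frame["stratum"] = frame["index_date"].dt.year
    frame = _with_covariates(frame, patients)
    return frame[frame["duration_days"] > 0].reset_index(drop=True)


def ground_truth_frame(
    truth: pd.DataFrame, censor_date: date = persistence.DEFAULT_CENSOR_DATE
) -> pd.DataFrame:
    """Subject-level frame built from the generator's latent ground truth:
    outcome = latent discontinuation day, exposure = true dose-optimization
    day.

    Bypasses the gap-rule outcome measurement entirely, which is the right
    reference when validating the Cox machinery itself: the observed endpoint
    dates every discontinuation at last infusion + 56 days, a convention that
    adds visit-locked event-free time and is studied separately.
    """
    max_day = (pd.Timestamp(censor_date) - truth["init_date"]).dt.days.astype(float)
    frame = pd.DataFrame(
        {
            "patient_id": truth["patient_id"],
            "duration_days": truth["latent_disc_day"].astype(float).fillna(max_day),
            "discontinued": truth["latent_disc_day"].notna(),
            "exposure_day": truth["do_day"].astype(float),
            "stratum": truth["init_date"].dt.year,
        }
    )
    frame.loc[frame["exposure_day"] <= 0, "exposure_day"] = np.nan
    return frame[frame["duration_days"] > 0].reset_index(drop=True)


def subgroup_analysis_frame(
    patients: pd.DataFrame,
    infusions: pd.DataFrame,
    tdm: pd.DataFrame,
    conc_threshold: float = 3.0,
    window_weeks: int = 9,
    level: str = "low",
    gap_weeks: int = 20,
    censor_date: date = persistence.DEFAULT_CENSOR_DATE,
    exclude_no_post_tdm_treatment: bool = False,
    subpopulation_prior_do: bool = False,
) -> pd.DataFrame:
    """Subject-level frame for one subgroup analysis cell.

    Restricted to the requested prior-dose-optimization subpopulation and to
    patients below the concentration threshold (subsets A/B); exposure day is
    the within-window dose-optimization date relative to the first-TDM index.
    """
    sel = cohort.select_overall(patients, infusions)
    inf = infusions[infusions["patient_id"].isin(sel.included["patient_id"])]
    outcomes = persistence.derive_persistence_table(inf, censor_date=censor_date, gap_weeks=gap_weeks)
    events = dose_optimization.detect_all(inf, patients=patients)
    sub = cohort.select_subgroup(sel.included, tdm, outcomes)
    labels = cohort.assign_subsets(
        sub.included,
        events,
        inf,
        conc_threshold=conc_threshold,
        window_weeks=window_weeks,
        level=level,
        exclude_no_post_tdm_treatment=exclude_no_post_tdm_treatment,
    ).included

    want = ("prior" if subpopulation_prior_do else "no_prior") + f"_do_{level}"
    labels = labels[(labels["subpopulation"] == want) & labels["below_threshold"]]
    out = outcomes.set_index("patient_id")
    frame = labels[["patient_id", "subset", "tdm_index_date", "days_to_tdm", "do_date"]].copy()
    end = out.loc[frame["patient_id"]]
    end_date = end["discontinuation_date"].where(end["discontinued"], end["censor_date"])
    frame["duration_days"] = (end_date.to_numpy() - frame["tdm_index_date"].to_numpy()).astype(
        "timedelta64[D]"
    ).astype(float)
    frame["discontinued"] = end["discontinued"].to_numpy()
    frame["exposure_day"] = (
        (frame["do_date"] - frame["tdm_index_date"]).dt.days.astype(float)
    )
    frame["log_days_to_tdm"] = np.log(frame["days_to_tdm"].astype(float))
    init_year = out.loc[frame["patient_id"], "index_date"].dt.year.to_numpy()
    frame["stratum"] = init_year
    frame = _with_covariates(frame, patients)
    return frame[frame["duration_days"] > 0].reset_index(drop=True)


def fit_subgroup_m1(
    frame: pd.DataFrame, ties: str = "efron", covariates: list[str] | None = None
) -> survival.ModelFit:
    """Main-effects time-dependent Cox fit on a subgroup subject frame."""
    rows = survival.build_counting_process(frame[
        ["patient_id", "duration_days", "discontinued", "exposure_day", "stratum"]
        + (covariates or SUBGROUP_COVARIATES)
    ])
    return survival.fit_cox(
        rows, ["exposure"] + (covariates or SUBGROUP_COVARIATES), strata="stratum", ties=ties
    )


# ---------------------------------------------------------------------------
# baseline descriptive table
# ---------------------------------------------------------------------------

def baseline_table(
    population: pd.DataFrame,
    group_col: str,
    continuous: list[str] = (),
    categorical: list[str] = (),
) -> pd.DataFrame:
    """Descriptive statistics by group with two-sample comparisons.

    Continuous variables: per-group n/mean/SD and a pooled two-sample t-test;
    categorical variables: per-level counts/percentages and a chi-square test.
    Degenerate comparisons (an empty group, a single-level factor) are skipped
    with a note.
    """
    groups = [g for g, _ in population.groupby(group_col)]
    rows = []
    two_groups = len(groups) == 2 and all(
        (population[group_col] == g).sum() > 0 for g in groups
    )
    for var in continuous:
        row = {"variable": var, "level": "mean (SD)", "test": "t-test", "p_value": np.nan, "note": ""}
        samples = []
        for g in groups:
            x = population.loc[population[group_col] == g, var].dropna()
            row[f"{g}"] = f"{x.mean():.2f} ({x.std(ddof=1):.2f})" if len(x) else ""
            samples.append(x)
        if two_groups and all(len(x) > 1 for x in samples):
            row["p_value"] = float(stats.ttest_ind(samples[0], samples[1], equal_var=True).pvalue)
        else:
            row["note"] = "comparison skipped: empty or singleton group"
        rows.append(row)
    for var in categorical:
        tab = pd.crosstab(population[var], population[group_col])
        p = np.nan
        note = ""
        if tab.shape[0] < 2 or tab.shape[1] < 2 or (tab.sum(axis=0) == 0).any():
            note = "chi-square skipped: degenerate table"
        else:
            p = float(stats.chi2_contingency(tab.to_numpy()).pvalue)
        for i, (lv, counts) in enumerate(tab.iterrows()):
            row = {
                "variable": var,
                "level": str(lv),
                "test": "chi-square",
                "p_value": p if i == 0 else np.nan,
                "note": note if i == 0 else "",
            }
            for g in groups:
                n = counts.get(g, 0)
                tot = int(tab[g].sum())
                row[f"{g}"] = f"{n} ({100.0 * n / tot:.1f}%)" if tot else "0"
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    out_dir: Path
    simulate: SimulationConfig | None = None
    patients_path: Path | None = None
    infusions_path: Path | None = None
    tdm_path: Path | None = None
    gap_rule_weeks: int = 20
    conc_thresholds: tuple[float, ...] = (3.0,)
    window_weeks: tuple[int, ...] = (9,)
    levels: tuple[str, ...] = ("low",)
    exclude_no_post_tdm: bool = False
    alpha: float = 0.05
    run_bias: bool = True
    bias_step_days: float = 25.0
    censor_date: date = persistence.DEFAULT_CENSOR_DATE

    def validate(self) -> None:
        if not self.conc_thresholds:
            raise ConfigError("conc_thresholds: must not be empty")
        if not self.window_weeks:
            raise ConfigError("window_weeks: must not be empty")
        if not self.levels:
            raise ConfigError("levels: must not be empty")
        if self.gap_rule_weeks not in (20, 12):
            raise ConfigError("gap_rule_weeks: must be 20 or 12")
        if self.simulate is None and not (
            self.patients_path and self.infusions_path and self.tdm_path
        ):
            raise ConfigError("inputs: provide simulate config or all three input paths")

    def to_jsonable(self) -> dict:
        d = {
            "gap_rule_weeks": self.gap_rule_weeks,
            "conc_thresholds": list(self.conc_thresholds),
            "window_weeks": list(self.window_weeks),
            "levels": list(self.levels),
            "exclude_no_post_tdm": self.exclude_no_post_tdm,
            "alpha": self.alpha,
            "run_bias": self.run_bias,
            "bias_step_days": self.bias_step_days,
            "censor_date": self.censor_date.isoformat(),
            "simulate": None if self.simulate is None else _dataclass_dict(self.simulate),
            "inputs": [str(p) for p in (self.patients_path, self.infusions_path, self.tdm_path) if p],
        }
        return d


def _dataclass_dict(obj) -> dict:
    from dataclasses import asdict

    def default(o):
        if isinstance(o, date):
            return o.isoformat()
        raise TypeError(o)

    return json.loads(json.dumps(asdict(obj), default=default))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every enumerated analysis cell and write artifacts plus a manifest.

    A stage error halts its cell and is recorded in the manifest; other cells
    proceed.  Outputs are deterministic given (config, seed): wall-clock
    timings go to the run log, never the manifest.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    files: list[Path] = []
    t_start = time.perf_counter()

    def save(df: pd.DataFrame, name: str) -> Path:
        path = records_io.write_analysis_table(df, out_dir / name)
        files.append(path)
        return path

    if config.simulate is not None:
        patients, infusions, tdm, truth = simulate_cohort(config.simulate)
        save(patients, "patients.csv")
        save(infusions, "infusions.csv")
        save(tdm, "tdm.csv")
        save(truth, "ground_truth.csv")
        log_lines.append(f"simulated cohort n={config.simulate.n_patients} seed={config.simulate.seed}")
    else:
        patients, infusions, tdm = records_io.read_tables(
            config.patients_path, config.infusions_path, config.tdm_path
        )
        log_lines.append("loaded input tables")

    sel = cohort.select_overall(patients, infusions)
    save(sel.ledger, "overall_exclusions.csv")
    inf = infusions[infusions["patient_id"].isin(sel.included["patient_id"])]
    outcomes = persistence.derive_persistence_table(
        inf, censor_date=config.censor_date, gap_weeks=config.gap_rule_weeks
    )
    save(outcomes, "persistence_overall.csv")
    curve = persistence.km_from_outcomes(outcomes)
    save(
        pd.DataFrame(
            {
                "time_days": curve.times,
                "survival": curve.survival,
                "at_risk": curve.at_risk,
                "events": curve.events,
            }
        ),
        "km_overall.csv",
    )
    events = dose_optimization.detect_all(inf, patients=patients)
    save(events, "dose_optimization_events.csv")

    frame_overall = overall_analysis_frame(
        patients, infusions, tdm, config.gap_rule_weeks, config.censor_date
    )
    base = frame_overall.copy()
    base["tdm_group"] = np.where(np.isnan(base["exposure_day"]), "no_tdm", "tdm")
    save(
        baseline_table(
            base,
            "tdm_group",
            continuous=["duration_days"],
            categorical=["age_group", "gender", "province_region", "weight_quartile"],
        ),
        "baseline_overall.csv",
    )

    cells = []
    for thr in config.conc_thresholds:
        for win in config.window_weeks:
            for level in config.levels:
                cell_id = f"thr{thr:g}_win{win}_{level}"
                cell: dict = {"id": cell_id, "status": "ok", "warnings": []}
                t0 = time.perf_counter()
                try:
                    frame = subgroup_analysis_frame(
                        patients,
                        infusions,
                        tdm,
                        conc_threshold=thr,
                        window_weeks=win,
                        level=level,
                        gap_weeks=config.gap_rule_weeks,
                        censor_date=config.censor_date,
                        exclude_no_post_tdm_treatment=config.exclude_no_post_tdm,
                    )
                    save(frame, f"subgroup_frame_{cell_id}.csv")
                    rows = survival.build_counting_process(
                        frame[
                            ["patient_id", "duration_days", "discontinued", "exposure_day", "stratum"]
                            + SUBGROUP_COVARIATES
                        ]
                    )
                    save(rows, f"counting_process_{cell_id}.csv")
                    ladder = survival.model_ladder(
                        rows,
                        ["exposure"] + SUBGROUP_COVARIATES,
                        strata="stratum",
                        alpha=config.alpha,
                    )
                    report = {
                        "selected": ladder.selected_id,
                        "interaction_p": ladder.interaction_p,
                        "ph_p": ladder.ph_p,
                        "ph_violated": ladder.ph_violated,
                        "models": {
                            mid: {
                                "loglik": fit.loglik,
                                "n_events": fit.n_events,
                                "terms": fit.summary.reset_index().to_dict("records"),
                            }
                            for mid, fit in ladder.fits.items()
                        },
                        "errors": ladder.errors,
                    }
                    path = out_dir / f"ladder_{cell_id}.json"
                    path.write_text(json.dumps(report, indent=2, default=float))
                    files.append(path)
                    hr, lo, hi = ladder.selected.hazard_ratio("exposure")
                    cell["exposure_hr"] = hr
                    cell["exposure_ci"] = [lo, hi]
                    cell["selected_model"] = ladder.selected_id
                    if ladder.selected_id != "M1":
                        m1hr, m1lo, m1hi = ladder.fits["M1"].hazard_ratio("exposure")
                        cell["m1_exposure_hr"] = m1hr
                        cell["m1_exposure_ci"] = [m1lo, m1hi]
                    if ladder.ph_violated and "M3" in ladder.fits:
                        cell["hr_at_weeks"] = {
                            str(wk): survival.hr_at_time(ladder.fits["M3"], wk)
                            for wk in (4, 6)
                        }
                    for fit in ladder.fits.values():
                        cell["warnings"].extend(fit.warnings)

                    if config.run_bias:
                        def refit(subjects: pd.DataFrame) -> survival.ModelFit:
                            return fit_subgroup_m1(subjects)

                        tip = bias_mod.tipping_point(
                            frame,
                            refit,
                            step_days=config.bias_step_days,
                            alpha=config.alpha,
                        )
                        path = out_dir / f"tipping_point_{cell_id}.json"
                        path.write_text(json.dumps(tip.as_dict(), indent=2))
                        files.append(path)
                        cell["tipping_median_days"] = tip.tipping_median_days
                        cell["tipping_cycles"] = tip.tipping_cycles
                except Exception as exc:
                    cell["status"] = "error"
                    cell["error"] = str(exc)
                log_lines.append(f"cell {cell_id}: {cell['status']} ({time.perf_counter() - t0:.2f}s)")
                cells.append(cell)

    import lifelines
    import scipy

    from . import __version__

    cfg_json = json.dumps(config.to_jsonable(), sort_keys=True)
    manifest = {
        "config": config.to_jsonable(),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": None if config.simulate is None else config.simulate.seed,
        "versions": {
            "persistkit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "lifelines": lifelines.__version__,
        },
        "cells": cells,
        "files": {p.name: _sha256(p) for p in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log_lines.append(f"total {time.perf_counter() - t_start:.2f}s")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    if any(c["status"] != "ok" for c in cells):
        manifest["status"] = "error"
    else:
        manifest["status"] = "ok"
    return manifest
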