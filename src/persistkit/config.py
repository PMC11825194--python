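"""Simulation and pipeline configuration objects.

Defaults encode the study conditions the generator emulates: initiation between
2015-01-01 and 2018-12-31, administrative censoring on 2019-07-31, induction at
weeks 0/2/6 then 5 mg/kg every 8 weeks, and a serum-concentration mixture with
a low-concentration / antibody-positive stratum near the assay floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from datetime import date
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """An invalid configuration field; the message names the field."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{name}: {msg}")


@dataclass(frozen=True)
class ConcentrationModel:
    """Log-normal mixture for trough serum infliximab concentration (µg/mL).

    ``low_fraction`` of patients sit in a low-concentration stratum whose draws
    are clipped at the 0.035 µg/mL assay floor (the regime in which antibodies
    to infliximab are typically evaluated); the rest draw from a log-normal
    with median ``exp(normal_log_mean)``.
    """

    low_fraction: float = 0.20
    low_log_mean: float = -4.2  # median ~0.015 µg/mL
    low_log_sd: float = 0.6
    low_ceiling: float = 0.035
    normal_log_mean: float = 1.609  # median ~5 µg/mL
    normal_log_sd: float = 0.8

    def validate(self) -> None:
        _check(0.0 <= self.low_fraction <= 1.0, "conc_model.low_fraction", "must be in [0,1]")
        _check(self.low_log_sd > 0, "conc_model.low_log_sd", "must be > 0")
        _check(self.normal_log_sd > 0, "conc_model.normal_log_sd", "must be > 0")
        _check(self.low_ceiling > 0, "conc_model.low_ceiling", "must be > 0")


@dataclass(frozen=True)
class TDMOrderingModel:
    """Physician TDM ordering: per-maintenance-cycle order probability and the
    earliest week (post-initiation) at which a trough draw is taken."""

    per_cycle_prob: float = 0.25
    earliest_week: int = 10
    missing_result_prob: float = 0.05

    def validate(self) -> None:
        _check(0.0 <= self.per_cycle_prob <= 1.0, "tdm_ordering.per_cycle_prob", "must be in [0,1]")
        _check(self.earliest_week >= 0, "tdm_ordering.earliest_week", "must be >= 0")
        _check(
            0.0 <= self.missing_result_prob <= 1.0,
            "tdm_ordering.missing_result_prob",
            "must be in [0,1]",
        )


@dataclass(frozen=True)
class PhysicianPolicy:
    """Dose-optimization behavior after a low first TDM result.

    With probability ``do_probability`` the physician escalates at the next
    infusion following a first trough below ``low_conc_threshold``: the
    interval is shortened to ``interval_decrease_to_days`` and/or the dose
    level raised to ``dose_increase_to_mg_kg`` (mix given by ``p_interval_only``
    / ``p_dose_only`` / remainder = both).  ``background_do_prob`` is a small
    per-cycle rate of escalation unrelated to TDM.
    """

    do_probability: float = 0.6
    low_conc_threshold: float = 3.0
    interval_decrease_to_days: int = 42
    dose_increase_to_mg_kg: float = 7.5
    p_interval_only: float = 0.25
    p_dose_only: float = 0.50
    background_do_prob: float = 0.01
    # strong escalations (q4w / monograph-ceiling 10 mg/kg) meet the high
    # detection threshold; chosen instead of the standard magnitudes with
    # probability p_strong
    strong_interval_days: int = 28
    strong_dose_mg_kg: float = 10.0
    p_strong: float = 0.25

    def validate(self) -> None:
        for nm in ("do_probability", "p_interval_only", "p_dose_only", "background_do_prob", "p_strong"):
            _check(0.0 <= getattr(self, nm) <= 1.0, f"physician_policy.{nm}", "must be in [0,1]")
        _check(self.strong_interval_days > 0, "physician_policy.strong_interval_days", "must be > 0")
        _check(self.strong_dose_mg_kg > 0, "physician_policy.strong_dose_mg_kg", "must be > 0")
        _check(
            self.p_interval_only + self.p_dose_only <= 1.0,
            "physician_policy.p_interval_only",
            "p_interval_only + p_dose_only must be <= 1",
        )
        _check(self.low_conc_threshold > 0, "physician_policy.low_conc_threshold", "must be > 0")
        _check(self.interval_decrease_to_days > 0, "physician_policy.interval_decrease_to_days", "must be > 0")
        _check(self.dose_increase_to_mg_kg > 0, "physician_policy.dose_increase_to_mg_kg", "must be > 0")


@dataclass(frozen=True)
class HazardModel:
    """Discontinuation hazard: Weibull baseline (shape 1 = exponential) with
    multiplicative effects of the low-concentration stratum and, from the day
    of a dose-optimization event, the true hazard ratio ``do_hr`` (θ)."""

    baseline_scale_days: float = 1250.0  # exponential rate 8e-4/day at shape 1
    shape: float = 1.0
    low_conc_hr: float = 1.5
    do_hr: float = 0.36

    def validate(self) -> None:
        _check(self.baseline_scale_days > 0, "hazards.baseline_scale_days", "must be > 0")
        _check(self.shape > 0, "hazards.shape", "must be > 0")
        _check(self.low_conc_hr > 0, "hazards.low_conc_hr", "must be > 0")
        _check(self.do_hr > 0, "hazards.do_hr", "must be > 0")

    def cumulative(self, t_days: float) -> float:
        return (max(t_days, 0.0) / self.baseline_scale_days) ** self.shape

    def inverse_cumulative(self, h: float) -> float:
        return self.baseline_scale_days * h ** (1.0 / self.shape)


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of the synthetic patient-support-program cohort."""

    n_patients: int = 1000
    seed: int = 0
    initiation_start: date = date(2015, 1, 1)
    initiation_end: date = date(2018, 12, 31)
    censor_date: date = date(2019, 7, 31)
    maintenance_interval_days: int = 56
    interval_jitter_sd_days: float = 2.5
    induction_offsets_days: tuple[int, ...] = (0, 14, 42)
    base_dose_mg_per_kg: float = 5.0
    weight_mean_kg: float = 74.5
    weight_sd_kg: float = 17.9
    prob_cd: float = 0.59
    prob_female: float = 0.53
    conc_model: ConcentrationModel = field(default_factory=ConcentrationModel)
    tdm_ordering: TDMOrderingModel = field(default_factory=TDMOrderingModel)
    physician_policy: PhysicianPolicy = field(default_factory=PhysicianPolicy)
    hazards: HazardModel = field(default_factory=HazardModel)

    def validate(self) -> None:
        _check(self.n_patients >= 0, "n_patients", "must be >= 0")
        _check(self.seed >= 0, "seed", "must be >= 0")
        _check(self.initiation_start <= self.initiation_end, "initiation_start", "must precede initiation_end")
        _check(self.initiation_end <= self.censor_date, "initiation_end", "must not exceed censor_date")
        _check(self.maintenance_interval_days > 0, "maintenance_interval_days", "must be > 0")
        _check(self.interval_jitter_sd_days >= 0, "interval_jitter_sd_days", "must be >= 0")
        _check(
            tuple(sorted(self.induction_offsets_days)) == tuple(self.induction_offsets_days)
            and len(self.induction_offsets_days) >= 1
            and self.induction_offsets_days[0] == 0,
            "induction_offsets_days",
            "must be increasing and start at 0",
        )
        _check(self.base_dose_mg_per_kg > 0, "base_dose_mg_per_kg", "must be > 0")
        _check(self.weight_mean_kg > 0, "weight_mean_kg", "must be > 0")
        _check(self.weight_sd_kg >= 0, "weight_sd_kg", "must be >= 0")
        _check(0.0 <= self.prob_cd <= 1.0, "prob_cd", "must be in [0,1]")
        _check(0.0 <= self.prob_female <= 1.0, "prob_female", "must be in [0,1]")
        self.conc_model.validate()
        self.tdm_ordering.validate()
        self.physician_policy.validate()
        self.hazards.validate()

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        from dataclasses import replace

        return replace(self, **kwargs)


def _from_mapping(cls, data: dict[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown field(s) {sorted(unknown)} for {cls.__name__}")
    return cls(**data)


_NESTED = {
    "conc_model": ConcentrationModel,
    "tdm_ordering": TDMOrderingModel,
    "physician_policy": PhysicianPolicy,
    "hazards": HazardModel,
}
_DATES = ("initiation_start", "initiation_end", "censor_date")


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file: top level must be a mapping")
    data: dict[str, Any] = {}
    for key, val in raw.items():
        if key in _NESTED:
            if not isinstance(val, dict):
                raise ConfigError(f"{key}: must be a mapping")
            data[key] = _from_mapping(_NESTED[key], val)
        elif key in _DATES:
            data[key] = val if isinstance(val, date) else date.fromisoformat(str(val))
        elif key == "induction_offsets_days":
            data[key] = tuple(int(v) for v in val)
        else:
            data[key] = val
    cfg = _from_mapping(SimulationConfig, data)
    cfg.validate()
    return cfg
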