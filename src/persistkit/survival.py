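"""Counting-process construction and stratified Cox proportional-hazards fits.

Exposure (TDM use in the overall analysis, post-TDM dose optimization in the
subgroup analyses) enters as a right-continuous time-dependent 0/1 indicator:
each subject's follow-up [0, duration] is tiled into (start, stop] rows split
at the exposure day, which avoids immortal-time bias.  Models are stratified
by year of treatment initiation, with fixed covariates (age group, gender,
weight quartiles, province/region and, in subgroup analyses, log days to TDM).

The fitter maximizes the stratified partial likelihood by Newton–Raphson with
Efron (default) or Breslow handling of tied event times.  The four-model
ladder adds exposure x covariate interactions (M2), an exposure x log(time)
term probing the proportional-hazards assumption (M3), or both (M4), and
selects the simplest model consistent with 0.05-level tests; no multiplicity
adjustment is applied.  When the PH assumption is violated the exposure
hazard ratio is read out at fixed times (4 and 6 weeks) from the
time-interaction model via the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Z975 = 1.959963984540054


class CoxConvergenceError(RuntimeError):
    """Newton iterations failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message} (log-likelihood trace: {trace})")
        self.trace = trace


# ---------------------------------------------------------------------------
# counting-process construction
# ---------------------------------------------------------------------------

def build_counting_process(
    subjects: pd.DataFrame,
    exposure_day_col: str = "exposure_day",
    duration_col: str = "duration_days",
    event_col: str = "discontinued",
    keep_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Tile each subject's follow-up into (start, stop] rows with a 0/1
    time-dependent ``exposure`` column.

    One row if unexposed or if the exposure day is at/after the end of
    follow-up (exposure must precede risk-set contribution); otherwise two
    rows split at the exposure day with the event only on the final row.
    """
    dur = subjects[duration_col].to_numpy(dtype=float)
    if (dur <= 0).any():
        bad = subjects.loc[dur <= 0, "patient_id"].tolist()
        raise ValueError(f"non-positive follow-up duration for patient(s) {bad[:5]}")
    exp_day = subjects[exposure_day_col].to_numpy(dtype=float)
    if ((exp_day <= 0) & ~np.isnan(exp_day)).any():
        raise ValueError("exposure_day must be positive when present")
    event = subjects[event_col].to_numpy(dtype=bool)
    keep_cols = keep_cols or [
        c
        for c in subjects.columns
        if c not in (exposure_day_col, duration_col, event_col)
    ]

    split = ~np.isnan(exp_day) & (exp_day < dur)
    base = subjects[keep_cols].reset_index(drop=True)

    pre = base.copy()
    pre["start"] = 0.0
    pre["stop"] = np.where(split, exp_day, dur)
    pre["event"] = np.where(split, False, event)
    pre["exposure"] = 0

    post = base.loc[split].copy()
    post["start"] = exp_day[split]
    post["stop"] = dur[split]
    post["event"] = event[split]
    post["exposure"] = 1

    out = pd.concat([pre, post], ignore_index=True)
    sort_key = "patient_id" if "patient_id" in out.columns else keep_cols[0]
    out = out.sort_values([sort_key, "start"], kind="mergesort").reset_index(drop=True)
    out["event"] = out["event"].astype(bool)
    return out


def build_ever_exposed(
    subjects: pd.DataFrame,
    exposure_day_col: str = "exposure_day",
    duration_col: str = "duration_days",
    event_col: str = "discontinued",
    keep_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Naive ever-exposed coding (one row per subject, exposure fixed at its
    eventual value).  Deliberately subject to immortal-time bias; used only to
    demonstrate that bias against the time-dependent coding."""
    exp_day = subjects[exposure_day_col].to_numpy(dtype=float)
    dur = subjects[duration_col].to_numpy(dtype=float)
    keep_cols = keep_cols or [
        c
        for c in subjects.columns
        if c not in (exposure_day_col, duration_col, event_col)
    ]
    out = subjects[keep_cols].reset_index(drop=True).copy()
    out["start"] = 0.0
    out["stop"] = dur
    out["event"] = subjects[event_col].to_numpy(dtype=bool)
    out["exposure"] = (~np.isnan(exp_day) & (exp_day <= dur)).astype(int)
    return out


# ---------------------------------------------------------------------------
# design-matrix encoding
# ---------------------------------------------------------------------------

def encode_design(df: pd.DataFrame, covariates: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Encode covariates to numeric columns (categoricals to 0/1 dummies with
    the lexicographically first level as reference).  Returns (frame, columns)."""
    parts, cols = [], []
    for c in covariates:
        s = df[c]
        if s.dtype == bool:
            parts.append(s.astype(float).rename(c))
            cols.append(c)
        elif pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
            cols.append(c)
        else:
            levels = sorted(s.astype(str).unique())
            for lv in levels[1:]:
                name = f"{c}[{lv}]"
                parts.append((s.astype(str) == lv).astype(float).rename(name))
                cols.append(name)
    out = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)
    return out, cols


# ---------------------------------------------------------------------------
# partial-likelihood machinery
# ---------------------------------------------------------------------------

@dataclass
class _StratumSchedule:
    steps: list[tuple[np.ndarray, np.ndarray, np.ndarray]]  # (add, remove, deaths)


def _prepare_schedules(
    start: np.ndarray, stop: np.ndarray, event: np.ndarray, strata: np.ndarray
) -> list[_StratumSchedule]:
    schedules = []
    for s in np.unique(strata):
        rows = np.flatnonzero(strata == s)
        st, sp, ev = start[rows], stop[rows], event[rows]
        ev_times = np.unique(sp[ev])[::-1]
        if ev_times.size == 0:
            continue
        by_stop = rows[np.argsort(sp, kind="mergesort")[::-1]]
        by_start = rows[np.argsort(st, kind="mergesort")[::-1]]
        sp_sorted = stop[by_stop]
        st_sorted = start[by_start]
        ia = ir = 0
        steps = []
        for t in ev_times:
            na = np.searchsorted(-sp_sorted, -t, side="right")
            nr = np.searchsorted(-st_sorted, -t, side="right")
            add = by_stop[ia:na]
            rem = by_start[ir:nr]
            ia, ir = na, nr
            deaths = rows[(sp == t) & ev]
            steps.append((add, rem, deaths))
        schedules.append(_StratumSchedule(steps))
    return schedules


def _loglik_grad_hess(
    beta: np.ndarray,
    X: np.ndarray,
    schedules: list[_StratumSchedule],
    ties: str,
    want_derivs: bool = True,
):
    p = X.shape[1]
    eta = X @ beta
    eta -= eta.max() if eta.size else 0.0  # guard overflow; constant shift cancels
    w = np.exp(eta)
    ll = 0.0
    g = np.zeros(p)
    H = np.zeros((p, p))
    for sched in schedules:
        S0 = 0.0
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        for add, rem, D in sched.steps:
            if add.size:
                wa, Xa = w[add], X[add]
                S0 += wa.sum()
                S1 += wa @ Xa
                S2 += Xa.T @ (wa[:, None] * Xa)
            if rem.size:
                wr, Xr = w[rem], X[rem]
                S0 -= wr.sum()
                S1 -= wr @ Xr
                S2 -= Xr.T @ (wr[:, None] * Xr)
            d = D.size
            XD, wD = X[D], w[D]
            ll += eta[D].sum()
            g += XD.sum(axis=0)
            if ties == "breslow":
                ll -= d * np.log(S0)
                Z1 = S1 / S0
                g -= d * Z1
                if want_derivs:
                    H -= d * (S2 / S0 - np.outer(Z1, Z1))
            else:  # efron
                S0D = wD.sum()
                S1D = wD @ XD
                S2D = XD.T @ (wD[:, None] * XD) if want_derivs else None
                for ell in range(d):
                    f = ell / d
                    den = S0 - f * S0D
                    Z1 = (S1 - f * S1D) / den
                    ll -= np.log(den)
                    g -= Z1
                    if want_derivs:
                        H -= (S2 - f * S2D) / den - np.outer(Z1, Z1)
    return ll, g, H


@dataclass
class ModelFit:
    """A fitted Cox model: per-term coefficients, HRs with 95% CIs, Wald
    p-values, covariance, and bookkeeping for the model ladder."""

    model_id: str
    summary: pd.DataFrame
    cov: pd.DataFrame
    loglik: float
    loglik_null: float
    n_events: int
    n_rows: int
    ties: str
    converged: bool
    dropped: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    ph_test_p: float | None = None
    selected: bool = False

    @property
    def params(self) -> pd.Series:
        return self.summary["coef"]

    def hazard_ratio(self, term: str) -> tuple[float, float, float]:
        row = self.summary.loc[term]
        return float(row["hr"]), float(row["ci_lower"]), float(row["ci_upper"])

    def p_value(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])


def fit_cox(
    data: pd.DataFrame,
    covariates: list[str],
    strata: str | None = None,
    ties: str = "efron",
    start_col: str = "start",
    stop_col: str = "stop",
    event_col: str = "event",
    model_id: str = "M1",
    max_iter: int = 60,
    tol: float = 1e-10,
) -> ModelFit:
    """Fit a stratified Cox model on counting-process rows.

    Covariates with no variation in the data (e.g., an all-zero exposure
    column) are dropped with a warning rather than failing the fit; exact
    collinearity raises.  Non-convergence raises
    :class:`CoxConvergenceError` with the log-likelihood trace; runaway
    coefficients are flagged as possible monotone likelihood (complete
    separation).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties {ties!r} must be 'efron' or 'breslow'")
    Xdf, cols = encode_design(data, covariates)
    warns: list[str] = []
    dropped = [c for c in cols if Xdf[c].nunique() <= 1]
    if dropped:
        warns.append(f"dropped constant term(s): {dropped}")
        warnings.warn(warns[-1], stacklevel=2)
        cols = [c for c in cols if c not in dropped]
    if not cols:
        raise ValueError("no estimable covariates remain")
    X = Xdf[cols].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(cols):
        raise ValueError(f"collinear covariate columns among {cols}")
    center = X.mean(axis=0)
    Xc = X - center

    start = data[start_col].to_numpy(dtype=float)
    stop = data[stop_col].to_numpy(dtype=float)
    event = data[event_col].to_numpy(dtype=bool)
    if (stop <= start).any():
        raise ValueError("every row must satisfy stop > start")
    strata_vals = (
        data[strata].to_numpy() if strata is not None else np.zeros(len(data), dtype=int)
    )
    schedules = _prepare_schedules(start, stop, event, strata_vals)
    if not schedules:
        raise ValueError("no events in any stratum")

    p = len(cols)
    beta = np.zeros(p)
    ll, gvec, H = _loglik_grad_hess(beta, Xc, schedules, ties)
    ll_null = ll
    trace = [ll]
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(gvec)) < 1e-7:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, gvec)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(f"singular information matrix: {exc}", trace) from exc
        # step-halving line search; the bound tolerates float noise at the optimum
        scale = 1.0
        accept = False
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, H_new = _loglik_grad_hess(cand, Xc, schedules, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-9 * (1.0 + abs(ll)):
                accept = True
                break
            scale *= 0.5
        if not accept:
            if np.max(np.abs(gvec)) < 1e-5:  # flat to machine precision
                converged = True
                break
            raise CoxConvergenceError("step-halving failed to improve likelihood", trace)
        beta, delta = cand, ll_new - ll
        ll, gvec, H = ll_new, g_new, H_new
        trace.append(ll)
        if abs(delta) < tol and np.max(np.abs(gvec)) < 1e-6:
            converged = True
            break
    if not converged:
        if np.max(np.abs(gvec)) < 1e-5:
            converged = True
        else:
            raise CoxConvergenceError("Newton iterations did not converge", trace)
    if np.max(np.abs(beta)) > 15:
        warns.append(
            "coefficient magnitude > 15: possible monotone likelihood (complete separation)"
        )
        warnings.warn(warns[-1], stacklevel=2)

    cov = np.linalg.inv(-H)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # a quasi-separated dummy can overflow its CI
        summary = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_lower": np.exp(beta - Z975 * se),
                "ci_upper": np.exp(beta + Z975 * se),
                "z": z,
                "p": pvals,
            },
            index=pd.Index(cols, name="term"),
        )
    return ModelFit(
        model_id=model_id,
        summary=summary,
        cov=pd.DataFrame(cov, index=cols, columns=cols),
        loglik=float(ll),
        loglik_null=float(ll_null),
        n_events=int(event.sum()),
        n_rows=len(data),
        ties=ties,
        converged=converged,
        dropped=dropped,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# time interaction (exposure x log t) via episode splitting at event times
# ---------------------------------------------------------------------------

def split_at_event_times(
    data: pd.DataFrame,
    base_col: str = "exposure",
    strata: str | None = None,
    start_col: str = "start",
    stop_col: str = "stop",
    event_col: str = "event",
) -> tuple[pd.DataFrame, str]:
    """Split rows at the event times of their stratum and attach the
    deterministic time-varying column ``base:log_t`` = base x log(t days).

    The split is exact for the partial likelihood: each sub-row covers one
    event time, at which the interaction covariate is constant.  Censored
    tail pieces covering no event time contribute nothing and are dropped.
    """
    start = data[start_col].to_numpy(dtype=float)
    stop = data[stop_col].to_numpy(dtype=float)
    event = data[event_col].to_numpy(dtype=bool)
    strata_vals = (
        data[strata].to_numpy() if strata is not None else np.zeros(len(data), dtype=int)
    )
    pieces = []
    for s in np.unique(strata_vals):
        rows = np.flatnonzero(strata_vals == s)
        ev = np.unique(stop[rows][event[rows]])
        if ev.size == 0:
            continue
        lo = np.searchsorted(ev, start[rows], side="right")
        hi = np.searchsorted(ev, stop[rows], side="right")
        counts = hi - lo
        keep = counts > 0
        rows, lo, counts = rows[keep], lo[keep], counts[keep]
        total = int(counts.sum())
        rep = np.repeat(rows, counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        ev_idx = np.repeat(lo, counts) + within
        piece_stop = ev[ev_idx]
        piece_start = np.where(within == 0, start[rep], ev[np.maximum(ev_idx - 1, 0)])
        piece_event = event[rep] & (piece_stop == stop[rep])
        sub = data.iloc[rep].copy()
        sub[start_col] = piece_start
        sub[stop_col] = piece_stop
        sub[event_col] = piece_event
        pieces.append(sub)
    if not pieces:
        raise ValueError("no events: cannot build time-interaction data")
    out = pd.concat(pieces, ignore_index=True)
    name = f"{base_col}:log_t"
    out[name] = out[base_col].astype(float) * np.log(out[stop_col].to_numpy(dtype=float))
    return out, name


def hr_at_time(
    fit: ModelFit,
    t_weeks: float,
    exposure_term: str = "exposure",
    interaction_term: str = "exposure:log_t",
) -> tuple[float, float, float]:
    """Exposure HR and 95% CI at a fixed time from a time-interaction model.

    HR(t) = exp(b_exposure + b_interaction * log(t days)); the CI comes from
    the delta method on the linear combination.
    """
    if interaction_term not in fit.summary.index:
        raise ValueError(f"fit has no {interaction_term!r} term")
    if exposure_term not in fit.cov.index or interaction_term not in fit.cov.columns:
        raise ValueError("missing covariance for the exposure/interaction terms")
    lt = np.log(t_weeks * 7.0)
    b = fit.params[exposure_term] + fit.params[interaction_term] * lt
    var = (
        fit.cov.loc[exposure_term, exposure_term]
        + lt**2 * fit.cov.loc[interaction_term, interaction_term]
        + 2 * lt * fit.cov.loc[exposure_term, interaction_term]
    )
    se = float(np.sqrt(var))
    return float(np.exp(b)), float(np.exp(b - Z975 * se)), float(np.exp(b + Z975 * se))


# ---------------------------------------------------------------------------
# four-model ladder
# ---------------------------------------------------------------------------

@dataclass
class LadderReport:
    fits: dict[str, ModelFit]
    errors: dict[str, str]
    selected_id: str
    interaction_p: float | None
    ph_p: float | None
    ph_violated: bool
    alpha: float

    @property
    def selected(self) -> ModelFit:
        return self.fits[self.selected_id]


def _lr_test(full: ModelFit, reduced: ModelFit) -> float:
    k = len(full.summary) - len(reduced.summary)
    if k <= 0:
        return 1.0
    lr = 2.0 * (full.loglik - reduced.loglik)
    return float(stats.chi2.sf(max(lr, 0.0), k))


def model_ladder(
    data: pd.DataFrame,
    covariates: list[str],
    exposure_col: str = "exposure",
    strata: str | None = None,
    alpha: float = 0.05,
    ties: str = "efron",
) -> LadderReport:
    """Fit the M1–M4 ladder and select the simplest consistent model.

    M1: main effects.  M2: + exposure x covariate interactions (retained only
    if jointly significant by likelihood ratio at ``alpha``).  M3: + exposure
    x log(time); a significant term declares the proportional-hazards
    assumption violated for the exposure.  M4: both.  Fit errors propagate
    per model; the ladder continues with the remaining models.
    """
    enc, enc_cols = encode_design(data, [c for c in covariates if c != exposure_col])
    base = data[[c for c in (strata, "start", "stop", "event", exposure_col) if c]].copy()
    base = pd.concat([base.reset_index(drop=True), enc.reset_index(drop=True)], axis=1)
    inter_cols = []
    for c in enc_cols:
        name = f"{exposure_col}:{c}"
        base[name] = base[exposure_col].astype(float) * base[c]
        inter_cols.append(name)

    main_cols = [exposure_col] + enc_cols
    fits: dict[str, ModelFit] = {}
    errors: dict[str, str] = {}

    def try_fit(mid: str, df: pd.DataFrame, cols: list[str]) -> ModelFit | None:
        try:
            fit = fit_cox(df, cols, strata=strata, ties=ties, model_id=mid)
            fits[mid] = fit
            return fit
        except (ValueError, CoxConvergenceError) as exc:
            errors[mid] = str(exc)
            return None

    m1 = try_fit("M1", base, main_cols)
    if m1 is None:
        raise CoxConvergenceError(f"M1 failed: {errors['M1']}", [])
    try_fit("M2", base, main_cols + inter_cols)

    split_df, tname = split_at_event_times(base, base_col=exposure_col, strata=strata)
    try_fit("M3", split_df, main_cols + [tname])
    try_fit("M4", split_df, main_cols + inter_cols + [tname])

    interaction_p = _lr_test(fits["M2"], fits["M1"]) if "M2" in fits else None
    ph_p = fits["M3"].p_value(tname) if "M3" in fits else None
    for mid in ("M3", "M4"):
        if mid in fits:
            fits[mid].ph_test_p = fits[mid].p_value(tname)

    interactions_sig = interaction_p is not None and interaction_p < alpha
    ph_violated = ph_p is not None and ph_p < alpha
    if interactions_sig and ph_violated and "M4" in fits:
        selected = "M4"
    elif interactions_sig and "M2" in fits:
        selected = "M2"
    elif ph_violated and "M3" in fits:
        selected = "M3"
    else:
        selected = "M1"
    fits[selected].selected = True
    return LadderReport(
        fits=fits,
        errors=errors,
        selected_id=selected,
        interaction_p=interaction_p,
        ph_p=ph_p,
        ph_violated=ph_violated,
        alpha=alpha,
    )
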