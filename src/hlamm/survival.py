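"""Time-to-event analysis: event curves, log-rank, Cox models, discrimination
and calibration.

Kaplan-Meier estimation, log-rank tests and Cox proportional-hazards fits
(Efron tie handling) are delegated to lifelines behind this module's
surface; time-varying covariates (a DSA or rejection episode switching a
0/1 flag at its event time) are expanded into counting-process intervals
before fitting. Time-dependent discrimination uses the
inverse-probability-of-censoring-weighted (IPCW) cumulative/dynamic AUC
with the censoring distribution estimated by Kaplan-Meier; a naive
estimator that simply drops subjects censored before the horizon is
reported alongside. Calibration at a fixed horizon uses leave-one-out
refits with bootstrap percentile bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)


@dataclass
class SurvivalFit:
    """Hazard ratios with 95% CIs and p-values from a proportional-hazards fit."""

    summary: pd.DataFrame  # index: covariate; columns: coef, hr, hr_lo, hr_hi, p
    n_events: int
    n_at_risk: int
    label: str
    fitter: object = None


@dataclass
class DiscriminationResult:
    """AUC(t) at each evaluation time."""

    times: np.ndarray
    auc_t: np.ndarray
    estimator: str


def cumulative_event_curve(
    durations, events, groups=None, alpha: float = 0.05
) -> dict:
    """1 - Kaplan-Meier per group, with Greenwood confidence bands.

    Returns {group: DataFrame(time, cum_event, ci_lo, ci_hi)}.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValueError("empty group: no subjects to estimate a curve from")
    if groups is None:
        groups = np.zeros(durations.size, dtype=int)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter(alpha=alpha)
        kmf.fit(durations[mask], events[mask])
        surv = kmf.survival_function_.iloc[:, 0]
        ci = kmf.confidence_interval_
        out[g] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "cum_event": 1.0 - surv.to_numpy(),
                "ci_lo": 1.0 - ci.iloc[:, 1].to_numpy(),  # upper survival -> lower event
                "ci_hi": 1.0 - ci.iloc[:, 0].to_numpy(),
            }
        ).reset_index(drop=True)
    return out


def logrank(durations, events, groups) -> tuple:
    """k-group log-rank test; returns (chi-square statistic, p-value)."""
    groups = np.asarray(groups)
    if pd.unique(groups).size < 2:
        raise ValueError("log-rank needs at least two groups")
    res = multivariate_logrank_test(
        np.asarray(durations, dtype=float), groups, np.asarray(events, dtype=bool)
    )
    return float(res.test_statistic), float(res.p_value)


def expand_time_varying(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    time_varying: Mapping[str, str],
    id_col: str = "pair_id",
) -> pd.DataFrame:
    """Counting-process expansion of 0->1 time-varying covariates.

    ``time_varying`` maps new covariate names to columns holding the switch
    time (NaN = never). Each subject becomes one or two (start, stop]
    intervals; the outcome event is recorded on the final interval only.
    """
    rows = []
    for _, row in data.iterrows():
        stop = float(row[duration_col])
        switch_times = []
        for name, col in time_varying.items():
            t = row[col]
            if pd.notna(t) and 0.0 < float(t) < stop:
                switch_times.append(float(t))
        cuts = sorted(set(switch_times))
        bounds = [0.0] + cuts + [stop]
        for k in range(len(bounds) - 1):
            start, end = bounds[k], bounds[k + 1]
            interval = dict(row)
            interval["start"] = start
            interval["stop"] = end
            for name, col in time_varying.items():
                t = row[col]
                interval[name] = int(pd.notna(t) and float(t) <= start)
            interval[event_col] = bool(row[event_col]) and (k == len(bounds) - 2)
            rows.append(interval)
    return pd.DataFrame(rows)


def fit_ph_model(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    time_varying: Optional[Mapping[str, str]] = None,
    label: str = "cox",
    id_col: str = "pair_id",
    penalizer: float = 0.0,
) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron ties), optionally with 0->1
    time-varying covariates expanded to counting-process form.

    Raises on non-convergence; complete separation surfaces as a lifelines
    convergence error with diagnostics attached.
    """
    data = data.dropna(subset=[duration_col] + list(covariates)).copy()
    data[event_col] = data[event_col].astype(bool)
    if time_varying:
        long = expand_time_varying(data, duration_col, event_col, time_varying, id_col)
        cols = [id_col, "start", "stop", event_col] + list(covariates) + list(time_varying)
        ctv = CoxTimeVaryingFitter(penalizer=penalizer)
        ctv.fit(
            long[cols].astype({event_col: int}),
            id_col=id_col,
            start_col="start",
            stop_col="stop",
            event_col=event_col,
        )
        raw = ctv.summary
        fitter = ctv
    else:
        cph = CoxPHFitter(penalizer=penalizer)
        cph.fit(
            data[[duration_col, event_col] + list(covariates)],
            duration_col=duration_col,
            event_col=event_col,
        )
        raw = cph.summary
        fitter = cph
    summary = pd.DataFrame(
        {
            "coef": raw["coef"],
            "hr": raw["exp(coef)"],
            "hr_lo": np.exp(raw["coef lower 95%"]),
            "hr_hi": np.exp(raw["coef upper 95%"]),
            "p": raw["p"],
        }
    )
    return SurvivalFit(
        summary=summary,
        n_events=int(data[event_col].sum()),
        n_at_risk=len(data),
        label=label,
        fitter=fitter,
    )


# -- time-dependent discrimination ----------------------------------------


def _censoring_survival(durations: np.ndarray, events: np.ndarray) -> KaplanMeierFitter:
    kmf = KaplanMeierFitter()
    kmf.fit(durations, ~events)
    return kmf


def time_dependent_auc(
    risk_scores,
    durations,
    events,
    eval_times: Sequence[float],
    estimator: str = "ipcw",
) -> DiscriminationResult:
    """Cumulative/dynamic AUC(t): cases are events by t, controls survive past t.

    ``ipcw`` weights cases by 1/G(T-), G the Kaplan-Meier of the censoring
    distribution (the constant control weight 1/G(t) cancels); with no
    censoring this reduces exactly to the Mann-Whitney AUC of scores
    against the event-by-t label. ``naive`` drops censored-before-t
    subjects and uses unit weights. Evaluation times beyond the last
    observed time yield NaN (flagged).
    """
    scores = np.asarray(risk_scores, dtype=float)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    eval_times = np.asarray(eval_times, dtype=float)

    if estimator == "ipcw":
        g = _censoring_survival(durations, events)
        g_at = g.predict((durations - 1e-9).clip(min=0.0)).to_numpy(dtype=float)
        case_weights = np.where(g_at > 0, 1.0 / np.where(g_at > 0, g_at, 1.0), 0.0)
    elif estimator == "naive":
        case_weights = np.ones_like(durations)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    auc_t = np.full(eval_times.size, np.nan)
    t_max = durations.max()
    for k, t in enumerate(eval_times):
        if t > t_max:
            logger.warning("evaluation time %.3g beyond last observed time: AUC undefined", t)
            continue
        cases = (durations <= t) & events
        controls = durations > t
        if not cases.any() or not controls.any():
            continue
        w = case_weights[cases]
        diff = scores[cases][:, None] - scores[controls][None, :]
        psi = (diff > 0) + 0.5 * (diff == 0)
        auc_t[k] = (w[:, None] * psi).sum() / (w.sum() * controls.sum())
    return DiscriminationResult(times=eval_times, auc_t=auc_t, estimator=estimator)


# -- calibration -----------------------------------------------------------


def _predicted_risk(cph: CoxPHFitter, rows: pd.DataFrame, horizon: float) -> np.ndarray:
    surv = cph.predict_survival_function(rows, times=[horizon])
    return 1.0 - surv.iloc[0].to_numpy(dtype=float)


def calibration_curve(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    horizon: float,
    n_boot: int = 200,
    n_groups: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted vs observed event risk at a horizon, leave-one-out validated.

    Each subject's predicted risk comes from a Cox model fitted without
    that subject. Subjects are grouped into ``n_groups`` quantile bins of
    predicted risk; observed risk per bin is 1 - KM at the horizon.
    Percentile bands over ``n_boot`` bootstrap refits (each resample fits
    once and re-evaluates the binned observed-vs-predicted curve).

    Returns a DataFrame (group, predicted, observed, obs_lo, obs_hi, n)
    with the calibration slope (OLS of observed on predicted across bins)
    in ``df.attrs["slope"]``.
    """
    if horizon > data[duration_col].max():
        raise ValueError("calibration horizon beyond observed follow-up")
    df = data.dropna(subset=[duration_col] + list(covariates)).reset_index(drop=True)
    n = len(df)
    covariates = [c for c in covariates if df[c].nunique() > 1]  # constants carry no risk signal
    cols = [duration_col, event_col] + list(covariates)

    predicted = np.empty(n)
    if not covariates:
        # degenerate model: everyone gets the marginal Kaplan-Meier risk
        kmf = KaplanMeierFitter()
        kmf.fit(df[duration_col], df[event_col])
        predicted[:] = 1.0 - float(kmf.predict(horizon))
    for i in range(n) if covariates else []:
        train = df.loc[df.index != i, cols]
        # a covariate can become constant once subject i is held out
        usable = [c for c in covariates if train[c].nunique() > 1]
        if not usable:
            kmf = KaplanMeierFitter()
            kmf.fit(train[duration_col], train[event_col])
            predicted[i] = 1.0 - float(kmf.predict(horizon))
            continue
        fold_cols = [duration_col, event_col] + usable
        try:
            cph = CoxPHFitter()
            cph.fit(train[fold_cols], duration_col=duration_col, event_col=event_col)
        except Exception:  # near-singular fold: stabilise with a small ridge
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(train[fold_cols], duration_col=duration_col, event_col=event_col)
        predicted[i] = _predicted_risk(cph, df.loc[[i], usable], horizon)[0]

    def binned_observed(pred: np.ndarray, frame: pd.DataFrame) -> pd.DataFrame:
        if np.unique(pred).size == 1:  # constant predictions: one marginal group
            bins = pd.Series(0, index=frame.index)
        else:
            bins = pd.Series(
                pd.qcut(pred, q=min(n_groups, np.unique(pred).size), labels=False, duplicates="drop"),
                index=frame.index,
            )
        rows = []
        for g, idx in bins.groupby(bins).groups.items():
            sub = frame.loc[idx]
            kmf = KaplanMeierFitter()
            kmf.fit(sub[duration_col], sub[event_col])
            observed = 1.0 - float(kmf.predict(horizon))
            rows.append(
                {"group": int(g), "predicted": float(pred[frame.index.get_indexer(idx)].mean()),
                 "observed": observed, "n": len(idx)}
            )
        return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)

    curve = binned_observed(predicted, df)

    rng = np.random.default_rng(seed)
    boot_obs = {g: [] for g in curve["group"]}
    for _ in range(int(n_boot)):
        idx = rng.integers(0, n, size=n)
        sample = df.iloc[idx].reset_index(drop=True)
        if covariates:
            try:
                cph = CoxPHFitter()
                cph.fit(sample[cols], duration_col=duration_col, event_col=event_col)
            except Exception:  # degenerate resample: skip
                continue
            pred_b = _predicted_risk(cph, sample[covariates], horizon)
        else:
            kmf_b = KaplanMeierFitter()
            kmf_b.fit(sample[duration_col], sample[event_col])
            pred_b = np.full(n, 1.0 - float(kmf_b.predict(horizon)))
        curve_b = binned_observed(pred_b, sample)
        for row in curve_b.itertuples(index=False):
            if row.group in boot_obs:
                boot_obs[row.group].append(row.observed)
    lo, hi = [], []
    for g in curve["group"]:
        draws = boot_obs[g]
        if draws:
            lo.append(float(np.percentile(draws, 2.5)))
            hi.append(float(np.percentile(draws, 97.5)))
        else:
            lo.append(np.nan)
            hi.append(np.nan)
    curve["obs_lo"] = lo
    curve["obs_hi"] = hi

    x, y = curve["predicted"].to_numpy(), curve["observed"].to_numpy()
    if np.std(x) > 0:
        slope = float(np.polyfit(x, y, 1)[0])
    else:
        slope = np.nan
    curve.attrs["slope"] = slope
    return curve
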