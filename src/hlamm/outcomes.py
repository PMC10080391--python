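"""Censoring-aware outcome derivation from longitudinal registry records.

Turns raw antibody tests, eGFR series, calcineurin-inhibitor (CNI) levels
and biopsy events into per-patient event times:

* locus-specific de-novo DSA — first positive test against a mismatched
  donor molecule, earliest over molecules within a locus;
* eGFR50 — persistent 50% reduction from the month-3 baseline eGFR,
  confirmed by a second qualifying value six months later;
* late TCMR (>6 months post-transplant) and ABMR;
* CNI adherence surrogates: intra-patient variability (IPV, mean absolute
  deviation / mean x 100, high if >25%) and the count of levels above
  5 ng/ml. Ciclosporin levels are divided by 10 to approximate tacrolimus.

All event times are right-censored at last follow-up or death.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WEEK_YEARS = 7.0 / 365.25


@dataclass
class OutcomeConfig:
    """Clinical constants of the outcome definitions."""

    ipv_threshold_pct: float = 25.0
    cni_threshold_ng_ml: float = 5.0
    ciclosporin_divisor: float = 10.0
    cni_start_years: float = 0.5  # levels from month 6 onward
    late_tcmr_cutoff_years: float = 0.5  # late = strictly > 6 months
    egfr_baseline_years: float = 0.25  # baseline eGFR at month 3
    egfr_baseline_window_weeks: float = 6.0
    egfr50_fraction: float = 0.5
    egfr50_confirm_spacing_years: float = 0.5  # two results six months apart
    egfr50_confirm_tolerance_weeks: float = 6.0
    calibration_n_boot: int = 200  # leave-one-out validation, 200 bootstraps


def derive_dsa_events(
    antibody_records: pd.DataFrame,
    mismatched_molecules: pd.DataFrame,
    last_followup: float,
) -> pd.DataFrame:
    """Per-locus first de-novo DSA time for one patient.

    ``antibody_records``: columns time_years, specificity, positive.
    ``mismatched_molecules``: columns locus, molecule (the donor's
    mismatched molecules; chain names of a DQ heterodimer also match).
    A positive specificity matching no mismatched donor molecule is not
    donor-specific and is ignored (logged). Loci with no event are censored
    at ``last_followup`` (event=False).
    """
    by_target: dict = {}
    for row in mismatched_molecules.itertuples(index=False):
        by_target.setdefault(row.molecule, (row.locus, row.molecule))
        for chain in str(row.molecule).split("~"):
            by_target.setdefault(chain, (row.locus, row.molecule))

    first_time: dict = {}
    positives = antibody_records[antibody_records["positive"].astype(bool)]
    for row in positives.itertuples(index=False):
        hit = by_target.get(row.specificity)
        if hit is None:
            logger.info("antibody vs %s matches no donor mismatch: not donor-specific", row.specificity)
            continue
        locus = hit[0]
        t = float(row.time_years)
        if t > last_followup:
            continue
        if locus not in first_time or t < first_time[locus][0]:
            first_time[locus] = (t, hit[1])

    rows = []
    for locus in sorted(set(mismatched_molecules["locus"])):
        if locus in first_time:
            t, molecule = first_time[locus]
            rows.append({"locus": locus, "time_years": t, "event": True, "molecule": molecule})
        else:
            rows.append({"locus": locus, "time_years": last_followup, "event": False, "molecule": None})
    return pd.DataFrame(rows, columns=["locus", "time_years", "event", "molecule"])


def derive_molecule_dsa(
    antibody_records: pd.DataFrame,
    mismatched_molecules: pd.DataFrame,
    last_followup: float,
) -> pd.DataFrame:
    """First DSA time per individual mismatched donor molecule (or censored)."""
    positives = antibody_records[antibody_records["positive"].astype(bool)]
    rows = []
    for row in mismatched_molecules.itertuples(index=False):
        targets = {row.molecule} | set(str(row.molecule).split("~"))
        hits = positives[positives["specificity"].isin(targets)]
        hits = hits[hits["time_years"].astype(float) <= last_followup]
        if hits.empty:
            rows.append({"locus": row.locus, "molecule": row.molecule, "dsa": False, "dsa_time": None})
        else:
            rows.append(
                {
                    "locus": row.locus,
                    "molecule": row.molecule,
                    "dsa": True,
                    "dsa_time": float(hits["time_years"].astype(float).min()),
                }
            )
    return pd.DataFrame(rows, columns=["locus", "molecule", "dsa", "dsa_time"])


def derive_egfr50(
    egfr_series: pd.DataFrame,
    config: Optional[OutcomeConfig] = None,
    last_followup: Optional[float] = None,
) -> Tuple[Optional[float], bool, Optional[float]]:
    """(event_time, event, baseline) for the persistent-eGFR-decline outcome.

    Baseline is the measurement nearest month 3 within +/- 6 weeks; an event
    is the first measurement at or below half the baseline whose confirming
    measurement six months later (+/- 6 weeks) is also at or below half.
    The event time is the first qualifying measurement. Missing baseline
    returns (None, False, None) — the patient is excluded upstream.
    """
    config = config or OutcomeConfig()
    series = egfr_series.sort_values("time_years").reset_index(drop=True)
    times = series["time_years"].to_numpy(dtype=float)
    values = series["egfr"].to_numpy(dtype=float)

    window = config.egfr_baseline_window_weeks * WEEK_YEARS
    offsets = np.abs(times - config.egfr_baseline_years)
    in_window = offsets <= window
    if not in_window.any():
        logger.info("no eGFR measurement within the month-3 baseline window")
        return None, False, None
    baseline = float(values[in_window][np.argmin(offsets[in_window])])

    half = config.egfr50_fraction * baseline
    spacing = config.egfr50_confirm_spacing_years
    tol = config.egfr50_confirm_tolerance_weeks * WEEK_YEARS
    for i in range(len(times)):
        if values[i] > half:
            continue
        lo, hi = times[i] + spacing - tol, times[i] + spacing + tol
        confirm = (times >= lo) & (times <= hi) & (values <= half)
        if confirm.any():
            return float(times[i]), True, baseline
    censor = float(last_followup) if last_followup is not None else float(times[-1])
    return censor, False, baseline


def convert_cni_levels(cni_series: pd.DataFrame, config: Optional[OutcomeConfig] = None) -> np.ndarray:
    """Levels on the tacrolimus scale (ciclosporin divided by 10)."""
    config = config or OutcomeConfig()
    levels = cni_series["level"].to_numpy(dtype=float).copy()
    if "drug" in cni_series.columns:
        ciclo = cni_series["drug"].astype(str).str.lower().eq("ciclosporin").to_numpy()
        levels[ciclo] = levels[ciclo] / config.ciclosporin_divisor
    return levels


def compute_ipv(
    cni_series: pd.DataFrame, config: Optional[OutcomeConfig] = None
) -> Tuple[Optional[float], Optional[str]]:
    """Intra-patient variability of CNI levels, percent, and high/low category.

    IPV = 100 * mean(|x - mean(x)|) / mean(x) over levels from month 6
    onward; high iff strictly above 25%. Scale-invariant, so the
    ciclosporin conversion cannot change a patient's category. Needs >= 2
    measurements (else undefined, logged).
    """
    config = config or OutcomeConfig()
    series = cni_series[cni_series["time_years"].astype(float) >= config.cni_start_years]
    levels = convert_cni_levels(series, config)
    if levels.size < 2:
        logger.info("IPV undefined: %d CNI measurement(s)", levels.size)
        return None, None
    mean = levels.mean()
    ipv = 100.0 * np.abs(levels - mean).mean() / mean
    return float(ipv), ("high" if ipv > config.ipv_threshold_pct else "low")


def cni_above_threshold(
    cni_series: pd.DataFrame, config: Optional[OutcomeConfig] = None
) -> Tuple[int, Optional[float]]:
    """Count and fraction of converted CNI levels strictly above 5 ng/ml."""
    config = config or OutcomeConfig()
    levels = convert_cni_levels(cni_series, config)
    if levels.size == 0:
        return 0, None
    count = int((levels > config.cni_threshold_ng_ml).sum())
    return count, count / levels.size


def derive_rejection_events(
    biopsy_events: pd.DataFrame,
    last_followup: float,
    config: Optional[OutcomeConfig] = None,
) -> dict:
    """Late TCMR (>6 months) and ABMR event times for one patient.

    Returns {'tcmr_time', 'tcmr_event', 'abmr_time', 'abmr_event'};
    rejection episodes at or before 6 months do not count as late TCMR.
    """
    config = config or OutcomeConfig()
    out = {}
    for kind, prefix in (("TCMR", "tcmr"), ("ABMR", "abmr")):
        events = biopsy_events[biopsy_events["type"] == kind]
        times = events["time_years"].astype(float)
        if kind == "TCMR":
            times = times[times > config.late_tcmr_cutoff_years]
        times = times[times <= last_followup]
        if times.empty:
            out[f"{prefix}_time"] = last_followup
            out[f"{prefix}_event"] = False
        else:
            out[f"{prefix}_time"] = float(times.min())
            out[f"{prefix}_event"] = True
    return out


def derive_outcomes(
    pair_ids: Sequence[str],
    followup: pd.DataFrame,
    antibody: pd.DataFrame,
    mismatched_molecules: pd.DataFrame,
    egfr: pd.DataFrame,
    cni: pd.DataFrame,
    biopsy: pd.DataFrame,
    config: Optional[OutcomeConfig] = None,
) -> pd.DataFrame:
    """Assemble one outcome row per patient from the longitudinal tables.

    ``followup`` needs columns pair_id, last_followup_years (death already
    folded into last follow-up by the registry extract). Input tables are
    keyed by pair_id. Patients with no month-3 eGFR baseline carry NA
    eGFR50 columns (excluded from eGFR50 models, logged).
    """
    config = config or OutcomeConfig()
    fu = dict(zip(followup["pair_id"], followup["last_followup_years"].astype(float)))
    rows = []
    for pair_id in pair_ids:
        last = fu[pair_id]
        row: dict = {"pair_id": pair_id, "last_followup_years": last}

        mols = mismatched_molecules[mismatched_molecules["pair_id"] == pair_id]
        ab = antibody[antibody["pair_id"] == pair_id]
        dsa = derive_dsa_events(ab, mols[["locus", "molecule"]], last)
        for locus_row in dsa.itertuples(index=False):
            row[f"dsa_{locus_row.locus}_time"] = locus_row.time_years
            row[f"dsa_{locus_row.locus}_event"] = locus_row.event
        any_event = dsa[dsa["event"]]
        row["dsa_any_time"] = (
            float(any_event["time_years"].min()) if not any_event.empty else last
        )
        row["dsa_any_event"] = not any_event.empty

        series = egfr[egfr["pair_id"] == pair_id]
        if series.empty:
            row.update({"egfr50_time": None, "egfr50_event": False, "baseline_egfr": None})
        else:
            t, event, baseline = derive_egfr50(series, config, last)
            row.update({"egfr50_time": t, "egfr50_event": event, "baseline_egfr": baseline})

        levels = cni[cni["pair_id"] == pair_id]
        ipv, ipv_cat = compute_ipv(levels, config)
        count, frac = cni_above_threshold(levels, config)
        row.update(
            {"cni_ipv_pct": ipv, "cni_ipv_category": ipv_cat,
             "cni_above5_count": count, "cni_above5_fraction": frac}
        )

        row.update(derive_rejection_events(biopsy[biopsy["pair_id"] == pair_id], last, config))
        rows.append(row)
    return pd.DataFrame(rows)
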