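"""End-to-end pipeline: simulate -> impute -> score -> thresholds ->
stratify -> outcomes -> survival.

Each stage is a pure function of (input files, config, seed) and writes its
outputs to the working directory; ``run_pipeline`` chains them and records
a manifest (config hash, per-stage seeds and row counts). Floating-point
outputs are written with 10 significant digits so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import hla, imputation, outcomes, single_molecule, stratification, survival
from .predictors import MockBindingPredictor
from .scoring import (
    SCORING_LOCI,
    Ems3DTable,
    Molecule,
    MismatchRecord,
    MismatchScoreSet,
    ScoringConfig,
    antigen_mismatches,
    records_to_frame,
    score_pair,
)
from .synthetic import (
    SimulationConfig,
    generate_allele_universe,
    generate_cohort,
    generate_ems3d_table,
    generate_haplotype_table,
    genotypes_from_pairs,
    split_typings_from_pairs,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

DEFAULT_SURVIVAL = {
    "covariates": ["baseline_egfr", "recipient_age", "donor_age", "graft_number"],
    "eval_times": [1.0, 2.0, 3.0, 4.0],
    "horizon": 4.0,
    "n_boot": 200,
    "calibration_groups": 5,
}

_SECTIONS = {"seed", "population", "simulate", "scoring", "outcomes", "survival"}


class ConfigError(ValueError):
    """Pipeline configuration does not validate against the schema."""


def validate_config(config: Mapping) -> dict:
    """Normalise and validate a pipeline config before any stage runs."""
    unknown = set(config) - _SECTIONS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    out = {
        "seed": int(config.get("seed", 0)),
        "population": str(config.get("population", "EUR")),
        "simulate": dict(config.get("simulate", {})),
        "scoring": dict(config.get("scoring", {})),
        "outcomes": dict(config.get("outcomes", {})),
        "survival": {**DEFAULT_SURVIVAL, **dict(config.get("survival", {}))},
    }
    for section, cls in (
        ("simulate", SimulationConfig),
        ("scoring", ScoringConfig),
        ("outcomes", outcomes.OutcomeConfig),
    ):
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(out[section]) - valid
        if bad:
            raise ConfigError(f"unknown {section} config keys: {sorted(bad)}")
    bad = set(out["survival"]) - set(DEFAULT_SURVIVAL)
    if bad:
        raise ConfigError(f"unknown survival config keys: {sorted(bad)}")
    return out


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return len(df)


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.blake2b(f"{seed}|{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


# -- stages ----------------------------------------------------------------


def stage_simulate(config: dict, workdir: Path) -> dict:
    sim = SimulationConfig(seed=config["seed"], **config["simulate"])
    store = generate_allele_universe(sim)
    haplotypes = generate_haplotype_table(store, sim, population=config["population"])
    ems3d = generate_ems3d_table(store, sim)
    predictor = MockBindingPredictor(seed=_stage_seed(config["seed"], "predictor"))
    scoring_config = ScoringConfig(**config["scoring"])
    cohort = generate_cohort(store, haplotypes, ems3d, sim, predictor, scoring_config)

    store.write(workdir / "alleles.fasta", workdir / "serology.tsv")
    hla.write_haplotype_table(haplotypes, workdir / "haplotypes.tsv")
    ems3d.write(workdir / "ems3d.tsv")
    counts = {}
    for name in (
        "pairs", "covariates", "followup", "antibody",
        "egfr", "cni", "biopsy", "truth_molecules", "truth_patients",
    ):
        counts[name] = _write(getattr(cohort, name), workdir / f"{name}.csv")
    return {"stage": "simulate", "rows": counts}


def _load_store(workdir: Path) -> hla.AlleleSequenceStore:
    return hla.load_allele_store(workdir / "alleles.fasta", workdir / "serology.tsv")


def stage_impute(config: dict, workdir: Path) -> dict:
    store = _load_store(workdir)
    haplotypes = hla.load_haplotype_table(workdir / "haplotypes.tsv", config["population"])
    pairs = pd.read_csv(workdir / "pairs.csv")
    truth = {who: genotypes_from_pairs(pairs, who) for who in ("donor", "recipient")}
    typings = {who: split_typings_from_pairs(pairs, who) for who in ("donor", "recipient")}

    geno_rows, log_rows = [], []
    excluded = 0
    for pair_id in pairs["pair_id"]:
        row = {"pair_id": pair_id}
        ok = True
        for who in ("donor", "recipient"):
            try:
                candidates = imputation.compatible_haplotype_pairs(
                    typings[who][pair_id], haplotypes, store
                )
            except imputation.UntypeableError as err:
                logger.warning("%s %s untypeable: %s", pair_id, who, err)
                ok = False
                excluded += 1
                log_rows.append(
                    {"pair_id": pair_id, "person": who, "n_candidates": 0,
                     "top_probability": np.nan, "correct": False}
                )
                continue
            h1, h2, prob = candidates[0]
            genotype = hla.Genotype.from_haplotypes(h1, h2)
            correct = genotype == truth[who][pair_id]
            log_rows.append(
                {"pair_id": pair_id, "person": who, "n_candidates": len(candidates),
                 "top_probability": prob, "correct": correct}
            )
            for loc in hla.LOCI:
                a, b = sorted(genotype.pair(loc))
                row[f"{who}_{loc}_1"], row[f"{who}_{loc}_2"] = a, b
        if ok:
            geno_rows.append(row)
    _write(pd.DataFrame(geno_rows), workdir / "imputed_genotypes.csv")
    _write(pd.DataFrame(log_rows), workdir / "imputation_log.csv")
    return {"stage": "impute", "rows": {"imputed_genotypes": len(geno_rows)},
            "excluded_untypeable": excluded}


def stage_score(config: dict, workdir: Path) -> dict:
    store = _load_store(workdir)
    ems3d = Ems3DTable.from_path(workdir / "ems3d.tsv")
    predictor = MockBindingPredictor(seed=_stage_seed(config["seed"], "predictor"))
    scoring_config = ScoringConfig(**config["scoring"])
    imputed = pd.read_csv(workdir / "imputed_genotypes.csv")
    antibody = pd.read_csv(workdir / "antibody.csv")
    followup = pd.read_csv(workdir / "followup.csv")
    fu = dict(zip(followup["pair_id"], followup["last_followup_years"]))

    donors = genotypes_from_pairs(imputed, "donor")
    recipients = genotypes_from_pairs(imputed, "recipient")
    all_records, ant_rows = [], []
    for pair_id in imputed["pair_id"]:
        donor, recipient = donors[pair_id], recipients[pair_id]
        records = score_pair(pair_id, donor, recipient, store, ems3d, predictor, scoring_config)
        mols = pd.DataFrame(
            [{"locus": r.locus, "molecule": r.molecule.name} for r in records],
            columns=["locus", "molecule"],
        )
        ab = antibody[antibody["pair_id"] == pair_id]
        mol_dsa = outcomes.derive_molecule_dsa(ab, mols, fu[pair_id]) if len(mols) else None
        if mol_dsa is not None:
            lookup = {
                (r.locus, r.molecule): (r.dsa, r.dsa_time)
                for r in mol_dsa.itertuples(index=False)
            }
            for record in records:
                dsa, t = lookup[(record.locus, record.molecule.name)]
                record.dsa = bool(dsa)
                record.dsa_time = t if dsa else None
        all_records.extend(records)
        for locus in SCORING_LOCI:
            ant_rows.append(
                {"pair_id": pair_id, "locus": locus,
                 "antMM": antigen_mismatches(donor, recipient, locus, store)}
            )
    _write(records_to_frame(all_records), workdir / "scores.csv")
    _write(pd.DataFrame(ant_rows), workdir / "antigen_counts.csv")
    from .scoring import locus_score_sums

    _write(locus_score_sums(all_records), workdir / "score_sums.csv")
    return {"stage": "score", "rows": {"scores": len(all_records)}}


def records_from_frame(df: pd.DataFrame) -> list:
    """Rebuild mismatch records from a scores table (inverse of records_to_frame)."""
    records = []
    for row in df.itertuples(index=False):
        chains = tuple(str(row.molecule).split("~"))
        records.append(
            MismatchRecord(
                pair_id=row.pair_id,
                locus=row.locus,
                molecule=Molecule(row.locus, row.molecule, chains),
                scores=MismatchScoreSet(
                    int(row.antMM), int(row.AAMS), float(row.EMS3D),
                    int(row.netMHC), int(row.netMHC1k),
                ),
                dsa=bool(row.dsa),
                dsa_time=None if pd.isna(row.dsa_time) else float(row.dsa_time),
            )
        )
    return records


def stage_thresholds(config: dict, workdir: Path) -> dict:
    records = records_from_frame(pd.read_csv(workdir / "scores.csv"))
    thresholds = single_molecule.derive_thresholds(records)
    _write(thresholds, workdir / "thresholds.csv")
    roc_rows = []
    for locus in SCORING_LOCI:
        data = single_molecule.build_single_molecule_dataset(records, locus)
        if data.empty or data["dsa"].nunique() < 2:
            continue
        for method in single_molecule.METHODS:
            roc = single_molecule.roc_auc(data[method].to_numpy(), data["dsa"].to_numpy(dtype=bool))
            curve = roc.curve.copy()
            curve.insert(0, "locus", locus)
            curve.insert(1, "method", method)
            roc_rows.append(curve)
    _write(
        pd.concat(roc_rows, ignore_index=True) if roc_rows else pd.DataFrame(),
        workdir / "roc_points.csv",
    )
    corr_rows = []
    for locus in SCORING_LOCI:
        try:
            r, p = single_molecule.score_correlation_matrix(records, locus)
        except ValueError:
            continue
        for m1 in r.index:
            for m2 in r.columns:
                corr_rows.append(
                    {"locus": locus, "method1": m1, "method2": m2,
                     "pearson_r": r.loc[m1, m2], "p_value": p.loc[m1, m2]}
                )
    _write(pd.DataFrame(corr_rows), workdir / "correlations.csv")
    return {"stage": "thresholds", "rows": {"thresholds": len(thresholds)}}


def stage_stratify(config: dict, workdir: Path) -> dict:
    records = records_from_frame(pd.read_csv(workdir / "scores.csv"))
    thresholds = pd.read_csv(workdir / "thresholds.csv")
    antigen_counts = pd.read_csv(workdir / "antigen_counts.csv")
    pair_ids = sorted(antigen_counts["pair_id"].unique())
    profiles = stratification.build_risk_profiles(
        records, thresholds, antigen_counts, all_pair_ids=pair_ids
    )
    _write(profiles, workdir / "profiles.csv")
    targeting = stratification.highest_score_targeting(records)
    _write(targeting, workdir / "targeting.csv")
    return {"stage": "stratify", "rows": {"profiles": len(profiles)}}


def stage_outcomes(config: dict, workdir: Path) -> dict:
    cfg = outcomes.OutcomeConfig(**config["outcomes"])
    scores = pd.read_csv(workdir / "scores.csv")
    followup = pd.read_csv(workdir / "followup.csv")
    table = outcomes.derive_outcomes(
        pair_ids=sorted(followup["pair_id"]),
        followup=followup,
        antibody=pd.read_csv(workdir / "antibody.csv"),
        mismatched_molecules=scores[["pair_id", "locus", "molecule"]],
        egfr=pd.read_csv(workdir / "egfr.csv"),
        cni=pd.read_csv(workdir / "cni.csv"),
        biopsy=pd.read_csv(workdir / "biopsy.csv"),
        config=cfg,
    )
    _write(table, workdir / "outcomes.csv")
    return {"stage": "outcomes", "rows": {"outcomes": len(table)}}


def _dq_ems3d_groups(profiles: pd.DataFrame) -> pd.DataFrame:
    dq = profiles[(profiles["locus"] == "DQ") & (profiles["method"] == "EMS3D")]
    return dq[["pair_id", "category", "dq_stratum"]].rename(
        columns={"category": "dq_ems3d_category"}
    )


def stage_survival(config: dict, workdir: Path) -> dict:
    cfg = config["survival"]
    profiles = pd.read_csv(workdir / "profiles.csv")
    outcome_table = pd.read_csv(workdir / "outcomes.csv")
    covariates = pd.read_csv(workdir / "covariates.csv")
    data = outcome_table.merge(covariates, on="pair_id").merge(
        _dq_ems3d_groups(profiles), on="pair_id", how="left"
    )
    data["dq_ems3d_category"] = data["dq_ems3d_category"].fillna("matched")

    # DSA-free survival by EMS3D risk category, per locus
    km_rows, logrank_rows = [], []
    for locus in SCORING_LOCI:
        col_t, col_e = f"dsa_{locus}_time", f"dsa_{locus}_event"
        if col_t not in outcome_table.columns:
            continue
        strata = profiles[(profiles["locus"] == locus) & (profiles["method"] == "EMS3D")]
        merged = outcome_table.merge(
            strata[["pair_id", "category"]], on="pair_id", how="inner"
        ).dropna(subset=[col_t])
        if merged.empty or merged["category"].nunique() < 2:
            continue
        curves = survival.cumulative_event_curve(
            merged[col_t], merged[col_e].astype(bool), merged["category"]
        )
        for group, curve in sorted(curves.items()):
            curve = curve.copy()
            curve.insert(0, "locus", locus)
            curve.insert(1, "category", group)
            km_rows.append(curve)
        stat, p = survival.logrank(
            merged[col_t], merged[col_e].astype(bool), merged["category"]
        )
        logrank_rows.append({"locus": locus, "comparison": "all", "chi2": stat, "p": p})
        hl = merged[merged["category"].isin(["high", "low"])]
        if hl["category"].nunique() == 2:
            stat, p = survival.logrank(hl[col_t], hl[col_e].astype(bool), hl["category"])
            logrank_rows.append(
                {"locus": locus, "comparison": "high_vs_low", "chi2": stat, "p": p}
            )
    _write(
        pd.concat(km_rows, ignore_index=True) if km_rows else pd.DataFrame(),
        workdir / "km_curves.csv",
    )
    _write(pd.DataFrame(logrank_rows), workdir / "logrank.csv")

    # eGFR50 time-zero Cox: DQ EMS3D high vs low (matched folded into low)
    model = data.dropna(subset=["egfr50_time", "baseline_egfr"]).copy()
    model["dq_high"] = (model["dq_ems3d_category"] == "high").astype(int)
    covs = [
        c for c in ["dq_high"] + list(cfg["covariates"])
        if model[c].nunique() > 1  # constant columns break the partial likelihood
    ]
    try:
        fit = survival.fit_ph_model(
            model, "egfr50_time", "egfr50_event", covs, label="egfr50_time_zero"
        )
    except Exception:  # sparse events: stabilise with a small ridge
        fit = survival.fit_ph_model(
            model, "egfr50_time", "egfr50_event", covs,
            label="egfr50_time_zero_ridge", penalizer=0.1,
        )
    summary = fit.summary.reset_index(names="covariate")
    summary.insert(0, "model", fit.label)
    rows = [summary]

    # time-varying rejection episodes added to the time-zero model
    tv_model = model.copy()
    tv_model["tcmr_switch"] = np.where(tv_model["tcmr_event"].astype(bool), tv_model["tcmr_time"], np.nan)
    tv_model["abmr_switch"] = np.where(tv_model["abmr_event"].astype(bool), tv_model["abmr_time"], np.nan)
    time_varying = {
        name: col
        for name, col in (("tcmr", "tcmr_switch"), ("abmr", "abmr_switch"))
        # a switch identifies its effect only if it fires before some follow-up end
        if (tv_model[col] < tv_model["egfr50_time"]).any()
    }
    tv_summary = None
    if time_varying:
        try:
            tv_fit = survival.fit_ph_model(
                tv_model, "egfr50_time", "egfr50_event", covs,
                time_varying=time_varying,
                label="egfr50_time_varying",
            )
        except Exception:  # separation in a sparse cohort: stabilise with ridge
            tv_fit = survival.fit_ph_model(
                tv_model, "egfr50_time", "egfr50_event", covs,
                time_varying=time_varying,
                label="egfr50_time_varying_ridge",
                penalizer=0.1,
            )
        tv_summary = tv_fit.summary.reset_index(names="covariate")
        tv_summary.insert(0, "model", tv_fit.label)
        rows.append(tv_summary)
    _write(pd.concat(rows, ignore_index=True), workdir / "cox_fits.csv")

    # discrimination: time-dependent AUC of the time-zero linear predictor
    risk = fit.fitter.predict_partial_hazard(model[covs]).to_numpy(dtype=float)
    eval_times = [t for t in cfg["eval_times"] if t <= model["egfr50_time"].max()]
    auc_rows = []
    for estimator in ("ipcw", "naive"):
        res = survival.time_dependent_auc(
            risk, model["egfr50_time"], model["egfr50_event"].astype(bool),
            eval_times, estimator=estimator,
        )
        for t, a in zip(res.times, res.auc_t):
            auc_rows.append({"estimator": estimator, "time": t, "auc": a})
    _write(pd.DataFrame(auc_rows), workdir / "td_auc.csv")

    calib = survival.calibration_curve(
        model, "egfr50_time", "egfr50_event", covs,
        horizon=min(cfg["horizon"], float(model["egfr50_time"].max())),
        n_boot=int(cfg["n_boot"]),
        n_groups=int(cfg["calibration_groups"]),
        seed=_stage_seed(config["seed"], "calibration"),
    )
    calib = calib.assign(slope=calib.attrs.get("slope"))
    _write(calib, workdir / "calibration.csv")
    return {
        "stage": "survival",
        "rows": {
            "cox_fits": sum(len(r) for r in rows),
            "td_auc": len(auc_rows),
        },
        "n_events_egfr50": fit.n_events,
    }


STAGES = (
    ("simulate", stage_simulate),
    ("impute", stage_impute),
    ("score", stage_score),
    ("thresholds", stage_thresholds),
    ("stratify", stage_stratify),
    ("outcomes", stage_outcomes),
    ("survival", stage_survival),
)


def run_pipeline(config: Mapping, workdir) -> dict:
    """Run every stage in order; returns (and writes) the run manifest."""
    config = validate_config(config)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": config["seed"],
        "stages": [],
    }
    manifest_path = workdir / "manifest.json"
    for name, stage in STAGES:
        try:
            info = stage(config, workdir)
        except Exception as err:
            manifest["failed_stage"] = name
            manifest["error"] = str(err)
            manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
            raise
        manifest["stages"].append(info)
        logger.info("stage %s complete", name)
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
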