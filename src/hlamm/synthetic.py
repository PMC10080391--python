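"""Synthetic allele universes, haplotype tables, EMS3D tables and cohorts.

The generator emulates the structure of a paediatric kidney-transplant
registry cohort so every pipeline stage is exercisable without external
data: multi-locus genotypes drawn from a haplotype frequency table,
per-molecule DSA event times whose hazard increases with the molecular
mismatch score, eGFR trajectories with persistent-decline events whose
hazard depends on the patient's DQ molecular risk group, censoring, CNI
level series, and biopsy-proven rejection events. Split-level typings are
emitted alongside the true allelic genotypes so imputation accuracy is
directly measurable.

Default parameters target the marginals of the study cohort this pipeline
is designed for: roughly one third of patients developing de-novo DSA,
~15% reaching the eGFR50 endpoint, and a median follow-up around 4.5
years. Event times are exponential (constant hazard) by default for
analytic tractability; a Weibull shape parameter is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .hla import (
    AMINO_ACIDS,
    LOCI,
    AlleleSequenceStore,
    Genotype,
    Haplotype,
    HLAAllele,
)
from .predictors import MockBindingPredictor
from .scoring import (
    SCORING_LOCI,
    Ems3DTable,
    Molecule,
    MismatchRecord,
    ScoringConfig,
    aams,
    molecule_aligned_sequence,
    score_pair,
)

_DEFAULT_SEQ_LENGTH = {
    "A": 180, "B": 180, "C": 180,
    "DRB1": 190, "DRB345": 190, "DQA1": 180, "DQB1": 190,
}
_SPLIT_PREFIX = {"A": "A", "B": "B", "C": "Cw", "DRB1": "DR", "DQB1": "DQ"}
_ALLELE_PREFIX = {loc: loc for loc in LOCI}
_ALLELE_PREFIX["DRB345"] = "DRB3"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort (defaults emulate the study conditions)."""

    seed: int = 0
    n_patients: int = 177
    alleles_per_locus: int = 8
    sequence_length: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_SEQ_LENGTH))
    polymorphic_fraction: float = 0.15
    haplotype_count: int = 20
    # DSA process: per-molecule hazard = baseline * exp(slope * EMS3D score)
    dsa_baseline_hazard: float = 0.00018  # events / year at score 0
    dsa_log_hazard_slope: float = 7.0  # per unit EMS3D
    weibull_shape: float = 1.0  # 1.0 = exponential
    # eGFR50 process by DQ molecular risk group (events / year)
    egfr50_hazard_by_risk_group: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.013, "high": 0.0455}
    )
    # log-hazard effects of baseline covariates on eGFR50 (centred internally):
    # age, donor age, baseline eGFR and re-transplantation predict decline
    egfr50_covariate_log_hr: Mapping[str, float] = field(
        default_factory=lambda: {
            "recipient_age": 0.08, "donor_age": 0.035,
            "baseline_egfr": -0.04, "graft_number": 0.7,
        }
    )
    dq_risk_threshold: float = 0.6  # generator's true high/low EMS3D cut
    censoring_rate: float = 0.02  # events / year of random dropout
    followup_max: float = 6.0  # years
    target_score_correlations: Mapping[str, float] = field(
        default_factory=lambda: {"EMS3D_AAMS": 0.7}
    )
    ems3d_max: float = 1.2
    cni_mean: float = 6.0  # ng/ml, tacrolimus scale
    cni_sd: float = 1.5  # typical within-patient SD
    ciclosporin_fraction: float = 0.02
    tcmr_hazard: float = 0.03
    abmr_hazard: float = 0.012
    egfr_baseline_mean: float = 75.0  # ml/min/1.73m2
    egfr_baseline_sd: float = 12.0
    egfr_noise_sd: float = 4.0


def _rng(config: SimulationConfig, *stream) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *stream])


# -- allele universe -------------------------------------------------------


def _mutate(seq: list, positions: Sequence[int], prob: float, rng) -> list:
    out = list(seq)
    for pos in positions:
        if rng.random() < prob:
            current = out[pos]
            choices = [aa for aa in AMINO_ACIDS if aa != current]
            out[pos] = choices[rng.integers(len(choices))]
    return out


def generate_allele_universe(config: SimulationConfig) -> AlleleSequenceStore:
    """Random aligned allele universe with serological splits.

    Per locus: alleles are mutations of a locus consensus restricted to a
    ``polymorphic_fraction`` of positions; splits group 2-4 sequence-similar
    alleles (each split has its own sub-consensus). DQA1 and DRB3/4/5 carry
    no serological splits, mirroring real typing practice.
    """
    rng = _rng(config, 1)
    store = AlleleSequenceStore()
    for locus in LOCI:
        length = config.sequence_length[locus]
        consensus = [AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length)]
        n_poly = int(round(config.polymorphic_fraction * length))
        poly_positions = sorted(rng.choice(length, size=n_poly, replace=False)) if n_poly else []
        n_splits = max(1, round(config.alleles_per_locus / 2.5))
        split_consensus = [
            _mutate(consensus, poly_positions, 0.5, rng) for _ in range(n_splits)
        ]
        for k in range(config.alleles_per_locus):
            split_idx = k % n_splits
            seq = _mutate(split_consensus[split_idx], poly_positions, 0.3, rng)
            name = f"{_ALLELE_PREFIX[locus]}*{split_idx + 1:02d}:{k // n_splits + 1:02d}"
            split = None
            if locus in _SPLIT_PREFIX:
                split = f"{_SPLIT_PREFIX[locus]}{split_idx + 1}"
            store.add_allele(HLAAllele(locus, name, "".join(seq), split))
            if split is not None:
                store.set_split(name, split)
    return store


def generate_haplotype_table(
    store: AlleleSequenceStore, config: SimulationConfig, population: str = "EUR"
) -> list:
    """Random haplotypes with Dirichlet frequencies summing to 1."""
    rng = _rng(config, 2)
    haplotypes = []
    seen = set()
    guard = 0
    while len(haplotypes) < config.haplotype_count:
        alleles = tuple(
            (loc, store.alleles_at(loc)[rng.integers(config.alleles_per_locus)].name)
            for loc in LOCI
        )
        key = tuple(name for _, name in alleles)
        guard += 1
        if key in seen and guard < 100 * config.haplotype_count:
            continue
        seen.add(key)
        haplotypes.append(alleles)
    # skewed frequencies: a few common haplotypes dominate, as in real tables
    freqs = rng.dirichlet(np.full(len(haplotypes), 0.5))
    return [
        Haplotype(alleles, population, float(f)) for alleles, f in zip(haplotypes, freqs)
    ]


# -- EMS3D table -----------------------------------------------------------


def _locus_molecules(store: AlleleSequenceStore, locus: str) -> list:
    """All molecules the allele universe can form at a scoring locus."""
    if locus == "DQ":
        from .hla import heterodimer_name

        return [
            Molecule("DQ", heterodimer_name(a.name, b.name), (a.name, b.name))
            for a in store.alleles_at("DQA1")
            for b in store.alleles_at("DQB1")
        ]
    allele_locus = {"A": "A", "B": "B", "DR": "DRB1"}[locus]
    return [Molecule(locus, a.name, (a.name,)) for a in store.alleles_at(allele_locus)]


def generate_ems3d_table(
    store: AlleleSequenceStore,
    config: SimulationConfig,
    loci: Sequence[str] = SCORING_LOCI,
) -> Ems3DTable:
    """Pairwise electrostatic scores correlated with AAMS at the target r.

    score(d, r) is a linear blend of the standardised AAMS(d, {r}) and
    Gaussian noise (linear rescaling to [0, ems3d_max] preserves the
    Pearson correlation), with self-pairs forced to exactly 0.
    """
    rng = _rng(config, 3)
    target_r = float(config.target_score_correlations.get("EMS3D_AAMS", 0.7))
    target_r = min(max(target_r, -1.0), 1.0)
    scores: dict = {}
    for locus in loci:
        molecules = _locus_molecules(store, locus)
        seqs = {m.name: molecule_aligned_sequence(m, store) for m in molecules}
        # engineer the correlation over mismatched (non-self) pairs only:
        # the diagonal's zeros would otherwise inflate the AAMS variance and
        # attenuate the achieved r on the pairs the analysis actually uses
        pairs = [(d, r) for d in molecules for r in molecules if d.name != r.name]
        raw = np.array([float(aams(seqs[d.name], [seqs[r.name]])) for d, r in pairs])
        sd = raw.std()
        z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
        noise = rng.standard_normal(raw.size)
        blend = target_r * z + np.sqrt(max(0.0, 1 - target_r**2)) * noise
        span = blend.max() - blend.min()
        scaled = (
            (blend - blend.min()) / span * config.ems3d_max
            if span > 0
            else np.zeros_like(blend)
        )
        for (d, r), value in zip(pairs, scaled):
            scores[(d.name, r.name)] = float(value)
        for m in molecules:
            scores[(m.name, m.name)] = 0.0
    return Ems3DTable(scores)


# -- cohort ----------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """All tables a pipeline run consumes, plus the generating truth."""

    pairs: pd.DataFrame  # true allelic genotypes + split typings
    covariates: pd.DataFrame
    followup: pd.DataFrame
    antibody: pd.DataFrame
    egfr: pd.DataFrame
    cni: pd.DataFrame
    biopsy: pd.DataFrame
    truth_molecules: pd.DataFrame
    truth_patients: pd.DataFrame
    records: list  # scored MismatchRecords with attached DSA outcomes


def _split_typing(genotype: Genotype, store: AlleleSequenceStore) -> dict:
    typing = {}
    for typed, allele_locus in (("A", "A"), ("B", "B"), ("DR", "DRB1"), ("DQ", "DQB1")):
        splits = tuple(sorted(store.split_of(a) for a in genotype.pair(allele_locus)))
        typing[typed] = splits
    return typing


def _event_time(rng, hazard: float, shape: float) -> float:
    if hazard <= 0:
        return np.inf
    if shape == 1.0:
        return float(rng.exponential(1.0 / hazard))
    # Weibull with scale chosen so the hazard integrates like the exponential at t=1
    u = rng.random()
    return float((-np.log(1 - u)) ** (1.0 / shape) / hazard)


def generate_cohort(
    store: AlleleSequenceStore,
    haplotypes: Sequence[Haplotype],
    ems3d_table: Ems3DTable,
    config: SimulationConfig,
    predictor=None,
    scoring_config: Optional[ScoringConfig] = None,
) -> SyntheticCohort:
    """Full synthetic cohort with molecule-level DSA and patient-level outcomes.

    Donor and recipient genotypes are two haplotypes each, drawn by
    frequency. Each mismatched donor molecule gets a latent DSA time with
    log-hazard ``log(baseline) + slope * EMS3D``; the molecule-level
    assumption of the single-molecule method is therefore literally true in
    the generated data. eGFR50 events follow the patient's DQ molecular
    risk group (max EMS3D vs the configured true threshold).
    """
    rng = _rng(config, 4)
    predictor = predictor or MockBindingPredictor(seed=config.seed)
    scoring_config = scoring_config or ScoringConfig()
    freqs = np.array([h.frequency for h in haplotypes])
    freqs = freqs / freqs.sum()

    pair_rows, cov_rows, fu_rows = [], [], []
    ab_rows, egfr_rows, cni_rows, biopsy_rows = [], [], [], []
    truth_mol_rows, truth_pat_rows = [], []
    all_records: list = []

    hazards = dict(config.egfr50_hazard_by_risk_group)
    for i in range(config.n_patients):
        pair_id = f"P{i + 1:04d}"
        idx = rng.choice(len(haplotypes), size=4, p=freqs)
        recipient = Genotype.from_haplotypes(haplotypes[idx[0]], haplotypes[idx[1]])
        donor = Genotype.from_haplotypes(haplotypes[idx[2]], haplotypes[idx[3]])

        row = {"pair_id": pair_id}
        for who, g in (("donor", donor), ("recipient", recipient)):
            for loc in LOCI:
                a, b = g.pair(loc)
                row[f"{who}_{loc}_1"], row[f"{who}_{loc}_2"] = a, b
            for typed, splits in _split_typing(g, store).items():
                row[f"{who}_{typed}_split_1"], row[f"{who}_{typed}_split_2"] = splits
        pair_rows.append(row)

        # follow-up: administrative window plus random dropout
        lf = config.followup_max * rng.uniform(0.55, 1.0)
        if config.censoring_rate > 0:
            lf = min(lf, float(rng.exponential(1.0 / config.censoring_rate)))
        lf = max(lf, 0.6)  # registry entries have at least some follow-up
        fu_rows.append({"pair_id": pair_id, "last_followup_years": lf})

        cov = {
            "pair_id": pair_id,
            "recipient_age": float(rng.uniform(1, 18)),
            "donor_age": float(rng.uniform(20, 55)),
            "recipient_ethnicity": int(rng.random() < 0.95),
            "graft_number": 1 + int(rng.random() < 0.08),
            "cold_ischaemia_hours": float(np.clip(rng.normal(12, 4), 1, 30)),
            "pra_pct": float(rng.choice([0, 5, 30, 90], p=[0.82, 0.11, 0.05, 0.02])),
        }
        cov_rows.append(cov)

        records = score_pair(
            pair_id, donor, recipient, store, ems3d_table, predictor, scoring_config
        )
        dq_scores = [r.scores.EMS3D for r in records if r.locus == "DQ"]
        dq_max = max(dq_scores) if dq_scores else 0.0
        risk_group = "high" if dq_max >= config.dq_risk_threshold else "low"

        for record in records:
            hazard = config.dsa_baseline_hazard * np.exp(
                config.dsa_log_hazard_slope * record.scores.EMS3D
            )
            t = _event_time(rng, hazard, config.weibull_shape)
            observed = t <= lf
            if observed:
                record.dsa = True
                record.dsa_time = t
                ab_rows.append(
                    {
                        "pair_id": pair_id,
                        "time_years": t,
                        "specificity": record.molecule.name,
                        "positive": True,
                    }
                )
            truth_mol_rows.append(
                {
                    "pair_id": pair_id,
                    "locus": record.locus,
                    "molecule": record.molecule.name,
                    "ems3d": record.scores.EMS3D,
                    "dsa_latent_time": t if np.isfinite(t) else np.nan,
                    "dsa_observed": observed,
                }
            )
        all_records.extend(records)

        # eGFR series with a persistent-decline event driven by risk group
        # and baseline covariates (proportional hazards on the latent time)
        baseline_true = float(np.clip(rng.normal(config.egfr_baseline_mean, config.egfr_baseline_sd), 30, 140))
        centres = {"recipient_age": 9.5, "donor_age": 37.5, "baseline_egfr": config.egfr_baseline_mean, "graft_number": 1.0}
        values = {**cov, "baseline_egfr": baseline_true}
        lp = sum(
            beta * (values[name] - centres.get(name, 0.0))
            for name, beta in config.egfr50_covariate_log_hr.items()
        )
        hazard = hazards[risk_group] * float(np.exp(lp))
        te = 0.25 + _event_time(rng, hazard, config.weibull_shape)
        visits = [0.25, 0.5] + list(np.arange(1.0, lf + 1e-9, 0.5))
        visits = [v for v in visits if v <= lf]
        baseline_meas = None
        for v in visits:
            if v >= te:
                value = 0.40 * (baseline_meas or baseline_true) + rng.normal(0, 2.0)
                value = min(value, 0.46 * (baseline_meas or baseline_true))
            else:
                value = baseline_true + rng.normal(0, config.egfr_noise_sd)
                ref = baseline_meas or baseline_true
                value = max(value, 0.60 * ref)
            if baseline_meas is None:
                baseline_meas = value  # first visit is the month-3 baseline
            egfr_rows.append({"pair_id": pair_id, "time_years": v, "egfr": float(value)})

        # CNI level series (tacrolimus scale; rare ciclosporin stored x10)
        drug = "ciclosporin" if rng.random() < config.ciclosporin_fraction else "tacrolimus"
        pmean = float(np.clip(rng.normal(config.cni_mean, 0.8), 3.0, 10.0))
        psd = float(abs(rng.normal(config.cni_sd, 0.6))) + 0.2
        for v in np.arange(0.5, lf + 1e-9, 0.5):
            level = float(np.clip(rng.normal(pmean, psd), 0.5, None))
            if drug == "ciclosporin":
                level *= 10.0
            cni_rows.append(
                {"pair_id": pair_id, "time_years": float(v), "drug": drug, "level": level}
            )

        for kind, hz in (("TCMR", config.tcmr_hazard), ("ABMR", config.abmr_hazard)):
            t = _event_time(rng, hz, config.weibull_shape)
            if t <= lf:
                biopsy_rows.append({"pair_id": pair_id, "time_years": t, "type": kind})

        truth_pat_rows.append(
            {
                "pair_id": pair_id,
                "dq_max_ems3d": dq_max,
                "dq_risk_group": risk_group,
                "egfr50_latent_time": te,
                "baseline_egfr_true": baseline_true,
            }
        )

    return SyntheticCohort(
        pairs=pd.DataFrame(pair_rows),
        covariates=pd.DataFrame(cov_rows),
        followup=pd.DataFrame(fu_rows),
        antibody=pd.DataFrame(ab_rows, columns=["pair_id", "time_years", "specificity", "positive"]),
        egfr=pd.DataFrame(egfr_rows, columns=["pair_id", "time_years", "egfr"]),
        cni=pd.DataFrame(cni_rows, columns=["pair_id", "time_years", "drug", "level"]),
        biopsy=pd.DataFrame(biopsy_rows, columns=["pair_id", "time_years", "type"]),
        truth_molecules=pd.DataFrame(truth_mol_rows),
        truth_patients=pd.DataFrame(truth_pat_rows),
        records=all_records,
    )


def genotypes_from_pairs(pairs: pd.DataFrame, who: str) -> dict:
    """Reconstruct phased genotypes from a pairs table (``who`` in donor/recipient)."""
    out = {}
    for row in pairs.itertuples(index=False):
        d = row._asdict()
        out[d["pair_id"]] = Genotype(
            {loc: (d[f"{who}_{loc}_1"], d[f"{who}_{loc}_2"]) for loc in LOCI}
        )
    return out


def split_typings_from_pairs(pairs: pd.DataFrame, who: str) -> dict:
    out = {}
    for row in pairs.itertuples(index=False):
        d = row._asdict()
        out[d["pair_id"]] = {
            typed: (d[f"{who}_{typed}_split_1"], d[f"{who}_{typed}_split_2"])
            for typed in ("A", "B", "DR", "DQ")
        }
    return out


# -- lightweight cohorts for statistical checks ----------------------------


def generate_group_survival_data(
    n: int,
    hazard_ratio: float,
    baseline_hazard: float = 0.05,
    high_fraction: float = 0.35,
    followup_max: float = 5.5,
    seed: int = 0,
    covariates: int = 0,
) -> pd.DataFrame:
    """Two-group exponential survival data with a known hazard ratio.

    Optional independent noise covariates are appended (true coefficient 0)
    for adjusted-model checks. Columns: time, event, high, x0..x{k-1}.
    """
    rng = np.random.default_rng(seed)
    high = rng.random(n) < high_fraction
    hazard = baseline_hazard * np.where(high, hazard_ratio, 1.0)
    t = rng.exponential(1.0 / hazard)
    censor = followup_max * rng.uniform(0.55, 1.0, size=n)
    time = np.minimum(t, censor)
    data = {"time": time, "event": t <= censor, "high": high.astype(int)}
    for k in range(covariates):
        data[f"x{k}"] = rng.standard_normal(n)
    return pd.DataFrame(data)


def generate_score_survival_data(
    n: int,
    slope: float,
    baseline_hazard: float = 0.05,
    followup_max: float = 5.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-molecule exponential DSA times with log-hazard linear in the score."""
    rng = np.random.default_rng(seed)
    score = rng.uniform(0, 1.2, size=n)
    hazard = baseline_hazard * np.exp(slope * score)
    t = rng.exponential(1.0 / hazard)
    censor = followup_max * rng.uniform(0.55, 1.0, size=n)
    return pd.DataFrame(
        {"score": score, "time": np.minimum(t, censor), "event": t <= censor}
    )


def generate_cox_data(
    n: int,
    betas: Sequence[float] = (0.8, -0.5),
    baseline_hazard: float = 0.08,
    followup_max: float = 6.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Well-specified Cox data: standard-normal covariates, exponential times."""
    rng = np.random.default_rng(seed)
    betas = np.asarray(betas, dtype=float)
    x = rng.standard_normal((n, betas.size))
    hazard = baseline_hazard * np.exp(x @ betas)
    t = rng.exponential(1.0 / hazard)
    censor = followup_max * rng.uniform(0.5, 1.0, size=n)
    df = pd.DataFrame(x, columns=[f"x{k}" for k in range(betas.size)])
    df["time"] = np.minimum(t, censor)
    df["event"] = t <= censor
    return df
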