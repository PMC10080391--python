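"""Per-mismatched-molecule HLA scoring.

For every donor HLA molecule absent from the recipient at the allelic level,
four scores quantify the donor-recipient difference:

* **antMM** — serological split mismatch (the traditional antigen count);
* **AAMS** — amino-acid mismatch score: alignment positions where the donor
  residue is absent from the recipient's residue repertoire at that position;
* **EMS3D** — electrostatic mismatch score, consumed from a precomputed
  pairwise donor-vs-comparator table and aggregated over the recipient's
  molecules (minimum by default: the donor scored against its most
  electrostatically similar recipient molecule);
* **netMHC / netMHC1k** — counts of unique predicted 9-mer binding cores
  among donor-unique 15-mers presented by recipient class II molecules,
  at (affinity <= 500 nM and rank < 2%) / (affinity <= 1000 nM) respectively.

Scoring loci are A, B, DQ and DR. The DQ molecule is the cis alpha-beta
heterodimer (DQA1 sequence concatenated with DQB1); DR is scored on the
DRB1 beta chain, with DRB3/4/5 contributing as presenters and as class II
comparator sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .hla import (
    CLASS_I_LOCI,
    CLASS_II_LOCI,
    GAP,
    AlleleSequenceStore,
    Genotype,
    concatenated_dq_sequence,
    dq_heterodimers,
    heterodimer_name,
)

logger = logging.getLogger(__name__)

#: Loci at which mismatched molecules are scored.
SCORING_LOCI = ("A", "B", "DQ", "DR")
#: The store locus whose alleles define molecules / antigens per scoring locus.
_MOLECULE_LOCUS = {"A": "A", "B": "B", "DR": "DRB1"}
_ANTIGEN_LOCUS = {"A": "A", "B": "B", "DR": "DRB1", "DQ": "DQB1"}
CLASS_OF_LOCUS = {"A": "I", "B": "I", "DQ": "II", "DR": "II"}

METHODS = ("AAMS", "EMS3D", "netMHC", "netMHC1k")


@dataclass(frozen=True)
class Molecule:
    """One donor or recipient HLA molecule: a single allele or DQ heterodimer."""

    locus: str  # scoring locus: A, B, DQ or DR
    name: str
    chains: tuple  # underlying allele names (1, or 2 for DQ)


@dataclass
class MismatchScoreSet:
    """The four molecular scores plus the antigen-mismatch contribution."""

    antMM_contribution: int
    AAMS: int
    EMS3D: float
    netMHC: int
    netMHC1k: int

    def __getitem__(self, method: str):
        return getattr(self, method)


@dataclass
class MismatchRecord:
    """One mismatched donor molecule in one transplant pair, with scores and outcome."""

    pair_id: str
    locus: str
    molecule: Molecule
    scores: MismatchScoreSet
    dsa: bool = False
    dsa_time: Optional[float] = None


@dataclass
class ScoringConfig:
    """Tunable conventions of the scoring stage (defaults follow the study design)."""

    ems3d_aggregation: str = "min"  # or "mean"
    aams_comparator_scope: str = "locus"  # or "class"
    peptide_comparator_scope: str = "class"  # or "locus"
    pool_cores_across_presenters: bool = True
    netmhc_affinity_nm: float = 500.0
    netmhc_rank_pct: float = 2.0
    netmhc1k_affinity_nm: float = 1000.0
    peptide_length: int = 15


class Ems3DTable:
    """Pairwise (donor molecule, comparator molecule) -> electrostatic score."""

    def __init__(self, scores: dict):
        self._scores = dict(scores)

    def score(self, donor: str, comparator: str) -> float:
        try:
            return self._scores[(donor, comparator)]
        except KeyError:
            raise KeyError(f"EMS3D table has no entry for ({donor}, {comparator})") from None

    def __len__(self) -> int:
        return len(self._scores)

    def items(self):
        return self._scores.items()

    @classmethod
    def from_path(cls, path) -> "Ems3DTable":
        df = pd.read_csv(path, sep="\t", dtype={"donor_molecule": str, "comparator_molecule": str})
        needed = {"donor_molecule", "comparator_molecule", "score"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"EMS3D table missing columns: {sorted(missing)}")
        return cls(
            {
                (r.donor_molecule, r.comparator_molecule): float(r.score)
                for r in df.itertuples(index=False)
            }
        )

    def write(self, path) -> None:
        rows = sorted(self._scores.items())
        pd.DataFrame(
            [(d, c, s) for (d, c), s in rows],
            columns=["donor_molecule", "comparator_molecule", "score"],
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


# -- molecules and antigen mismatch ---------------------------------------


def molecules_of(genotype: Genotype, locus: str, store: AlleleSequenceStore) -> list:
    """The distinct molecules a genotype carries at a scoring locus."""
    if locus == "DQ":
        return [
            Molecule("DQ", heterodimer_name(a, b), (a, b)) for a, b in dq_heterodimers(genotype)
        ]
    allele_locus = _MOLECULE_LOCUS[locus]
    return [Molecule(locus, name, (name,)) for name in genotype.unique_alleles(allele_locus)]


def molecule_aligned_sequence(molecule: Molecule, store: AlleleSequenceStore) -> str:
    if molecule.locus == "DQ":
        return concatenated_dq_sequence(store, *molecule.chains)
    return store.aligned(molecule.chains[0])


def mismatched_donor_molecules(
    donor: Genotype, recipient: Genotype, locus: str, store: AlleleSequenceStore
) -> list:
    """Donor molecules at a locus absent from the recipient (allelic level)."""
    recipient_names = {m.name for m in molecules_of(recipient, locus, store)}
    return [m for m in molecules_of(donor, locus, store) if m.name not in recipient_names]


def antigen_mismatches(
    donor: Genotype, recipient: Genotype, locus: str, store: AlleleSequenceStore
) -> int:
    """Serological split mismatch count at a locus (0, 1 or 2).

    Unique donor splits absent from the recipient's splits; a homozygous
    donor antigen counts once.
    """
    allele_locus = _ANTIGEN_LOCUS[locus]
    donor_splits = {store.split_of(a) for a in donor.pair(allele_locus)}
    recipient_splits = {store.split_of(a) for a in recipient.pair(allele_locus)}
    return len(donor_splits - recipient_splits)


def molecule_split(molecule: Molecule, store: AlleleSequenceStore) -> str:
    """Serological split of a molecule (DQ: the beta-chain split)."""
    chain = molecule.chains[-1] if molecule.locus == "DQ" else molecule.chains[0]
    return store.split_of(chain)


# -- AAMS ------------------------------------------------------------------


def aams(donor_seq: str, recipient_comparators: Sequence[str]) -> int:
    """Amino-acid mismatch score of a donor sequence against comparators.

    Counts alignment positions where the donor residue is absent from the
    set of residues the comparator sequences carry at that position. Gap
    symbols participate as ordinary residues (a gap-vs-residue difference
    is a mismatch).
    """
    if not recipient_comparators:
        raise ValueError("need at least one recipient comparator sequence")
    n = len(donor_seq)
    for comp in recipient_comparators:
        if len(comp) != n:
            raise ValueError(
                f"comparator length {len(comp)} differs from donor length {n}"
            )
    count = 0
    for pos in range(n):
        residue = donor_seq[pos]
        if all(comp[pos] != residue for comp in recipient_comparators):
            count += 1
    return count


# -- EMS3D -----------------------------------------------------------------


def ems3d_score(
    donor_molecule: Molecule,
    recipient_comparators: Sequence[Molecule],
    table: Ems3DTable,
    aggregation: str = "min",
) -> float:
    """Aggregate pairwise electrostatic scores of donor vs recipient molecules.

    ``min`` (default) scores the donor against its most electrostatically
    similar recipient molecule; ``mean`` averages over comparators.
    """
    values = [table.score(donor_molecule.name, comp.name) for comp in recipient_comparators]
    if not values:
        raise ValueError("need at least one recipient comparator molecule")
    if aggregation == "min":
        return min(values)
    if aggregation == "mean":
        return sum(values) / len(values)
    raise ValueError(f"unknown EMS3D aggregation {aggregation!r}")


# -- peptides and binding cores -------------------------------------------


def _windows(seq: str, k: int) -> list:
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def donor_unique_15mers(
    donor_seqs: Sequence[str], recipient_seqs: Iterable[str], k: int = 15
) -> set:
    """Contiguous donor ``k``-mers absent from every recipient sequence.

    Sequences are ungapped before windowing. ``donor_seqs`` may hold more
    than one chain (DQ heterodimer): each chain is windowed separately, so
    no artificial junction-spanning peptides are produced. A chain shorter
    than ``k`` contributes nothing (logged).
    """
    recipient_kmers = set()
    for seq in recipient_seqs:
        recipient_kmers.update(_windows(seq.replace(GAP, ""), k))
    unique = set()
    for seq in donor_seqs:
        ungapped = seq.replace(GAP, "")
        if len(ungapped) < k:
            logger.info("donor chain of length %d < %d: no peptides", len(ungapped), k)
            continue
        unique.update(w for w in _windows(ungapped, k) if w not in recipient_kmers)
    return unique


def count_unique_cores(
    peptides: Iterable[str],
    presenters: Sequence[str],
    predictor,
    mode: str,
    config: Optional[ScoringConfig] = None,
) -> int:
    """Number of distinct predicted 9-mer cores passing a binding filter.

    ``netMHC1k``: affinity <= 1000 nM. ``netMHC``: affinity <= 500 nM and
    rank < 2%. Cores are pooled across presenters by default (a core passing
    with any presenter counts once); with pooling disabled the per-presenter
    unique counts are summed.
    """
    config = config or ScoringConfig()
    if mode == "netMHC":
        passes = lambda p: (
            p.affinity_nm <= config.netmhc_affinity_nm and p.rank_pct < config.netmhc_rank_pct
        )
    elif mode == "netMHC1k":
        passes = lambda p: p.affinity_nm <= config.netmhc1k_affinity_nm
    else:
        raise ValueError(f"unknown mode {mode!r}")

    peptides = sorted(set(peptides))
    if config.pool_cores_across_presenters:
        cores = set()
        for presenter in presenters:
            for pep in peptides:
                pred = predictor.predict(pep, presenter)
                if passes(pred):
                    cores.add(pred.core9)
        return len(cores)
    total = 0
    for presenter in presenters:
        cores = {
            pred.core9
            for pep in peptides
            if passes(pred := predictor.predict(pep, presenter))
        }
        total += len(cores)
    return total


def class_ii_presenters(recipient: Genotype, store: AlleleSequenceStore) -> list:
    """Recipient presenting molecules: DRB1, DRB3/4/5 alleles and DQ heterodimers."""
    presenters = list(recipient.unique_alleles("DRB1"))
    presenters += list(recipient.unique_alleles("DRB345"))
    presenters += [heterodimer_name(a, b) for a, b in dq_heterodimers(recipient)]
    return sorted(set(presenters))


def _recipient_peptide_comparators(
    recipient: Genotype, locus: str, store: AlleleSequenceStore, scope: str
) -> list:
    """Ungapped recipient sequences a donor peptide must be absent from."""
    if scope == "class":
        loci = CLASS_I_LOCI if CLASS_OF_LOCUS[locus] == "I" else CLASS_II_LOCI
    elif scope == "locus":
        loci = {"A": ("A",), "B": ("B",), "DQ": ("DQA1", "DQB1"), "DR": ("DRB1",)}[locus]
    else:
        raise ValueError(f"unknown peptide comparator scope {scope!r}")
    seqs = []
    for loc in loci:
        if loc not in recipient.loci:
            continue
        for name in recipient.unique_alleles(loc):
            seqs.append(store.get(name).seq)
    return sorted(set(seqs))


def _aams_comparator_seqs(
    recipient: Genotype, donor_molecule: Molecule, store: AlleleSequenceStore, scope: str
) -> list:
    if donor_molecule.locus == "DQ":
        return [
            concatenated_dq_sequence(store, a, b) for a, b in dq_heterodimers(recipient)
        ]
    if scope == "locus":
        loci = (_MOLECULE_LOCUS[donor_molecule.locus],)
    else:  # class-wide: every same-class recipient allele with a matching alignment
        loci = CLASS_I_LOCI if CLASS_OF_LOCUS[donor_molecule.locus] == "I" else CLASS_II_LOCI
    donor_len = len(molecule_aligned_sequence(donor_molecule, store))
    seqs = []
    for loc in loci:
        if loc not in recipient.loci:
            continue
        for name in recipient.unique_alleles(loc):
            aligned = store.aligned(name)
            if len(aligned) == donor_len:
                seqs.append(aligned)
    if not seqs:
        raise ValueError(
            f"no recipient comparator with alignment length {donor_len} for "
            f"{donor_molecule.name} (scope={scope})"
        )
    return seqs


# -- orchestration ---------------------------------------------------------


def score_molecule(
    donor_molecule: Molecule,
    donor: Genotype,
    recipient: Genotype,
    store: AlleleSequenceStore,
    ems3d_table: Ems3DTable,
    predictor,
    config: Optional[ScoringConfig] = None,
) -> MismatchScoreSet:
    """All four molecular scores (plus antMM contribution) for one donor molecule."""
    config = config or ScoringConfig()
    locus = donor_molecule.locus

    recipient_molecules = molecules_of(recipient, locus, store)
    recipient_splits = {molecule_split(m, store) for m in recipient_molecules}
    ant_contribution = int(molecule_split(donor_molecule, store) not in recipient_splits)

    donor_aligned = molecule_aligned_sequence(donor_molecule, store)
    aams_score = aams(
        donor_aligned,
        _aams_comparator_seqs(recipient, donor_molecule, store, config.aams_comparator_scope),
    )
    ems = ems3d_score(
        donor_molecule, recipient_molecules, ems3d_table, config.ems3d_aggregation
    )

    donor_chain_seqs = [store.get(c).seq for c in donor_molecule.chains]
    peptides = donor_unique_15mers(
        donor_chain_seqs,
        _recipient_peptide_comparators(
            recipient, locus, store, config.peptide_comparator_scope
        ),
        k=config.peptide_length,
    )
    presenters = class_ii_presenters(recipient, store)
    net = count_unique_cores(peptides, presenters, predictor, "netMHC", config)
    net1k = count_unique_cores(peptides, presenters, predictor, "netMHC1k", config)

    return MismatchScoreSet(ant_contribution, aams_score, ems, net, net1k)


def score_pair(
    pair_id: str,
    donor: Genotype,
    recipient: Genotype,
    store: AlleleSequenceStore,
    ems3d_table: Ems3DTable,
    predictor,
    config: Optional[ScoringConfig] = None,
) -> list:
    """One :class:`MismatchRecord` per mismatched donor molecule per scoring locus."""
    config = config or ScoringConfig()
    records = []
    for locus in SCORING_LOCI:
        for molecule in mismatched_donor_molecules(donor, recipient, locus, store):
            scores = score_molecule(
                molecule, donor, recipient, store, ems3d_table, predictor, config
            )
            records.append(MismatchRecord(pair_id, locus, molecule, scores))
    return records


def records_to_frame(records: Sequence[MismatchRecord]) -> pd.DataFrame:
    """Flatten mismatch records into a tidy per-molecule table."""
    rows = []
    for r in records:
        rows.append(
            {
                "pair_id": r.pair_id,
                "locus": r.locus,
                "molecule": r.molecule.name,
                "antMM": r.scores.antMM_contribution,
                "AAMS": r.scores.AAMS,
                "EMS3D": r.scores.EMS3D,
                "netMHC": r.scores.netMHC,
                "netMHC1k": r.scores.netMHC1k,
                "dsa": r.dsa,
                "dsa_time": r.dsa_time,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "locus", "molecule", "antMM",
            "AAMS", "EMS3D", "netMHC", "netMHC1k", "dsa", "dsa_time",
        ],
    )


def locus_score_sums(records: Sequence[MismatchRecord]) -> pd.DataFrame:
    """Per-pair score sums for class I, class II, HLA-DQ and HLA-DR.

    Individual molecular mismatch scores are summed within each grouping;
    these sums feed the rejection models.
    """
    df = records_to_frame(records)
    if df.empty:
        return pd.DataFrame(
            columns=["pair_id", "group"] + list(METHODS) + ["antMM"]
        )
    group_of = {"A": "class_I", "B": "class_I", "DQ": "class_II", "DR": "class_II"}
    frames = []
    for label, loci in (
        ("class_I", ("A", "B")),
        ("class_II", ("DQ", "DR")),
        ("DQ", ("DQ",)),
        ("DR", ("DR",)),
        ("A", ("A",)),
        ("B", ("B",)),
    ):
        sub = df[df["locus"].isin(loci)]
        agg = sub.groupby("pair_id")[list(METHODS) + ["antMM"]].sum().reset_index()
        agg.insert(1, "group", label)
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)
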