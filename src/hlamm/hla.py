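"""Core HLA domain types: alleles, genotypes, haplotypes and the aligned-sequence store.

The store holds aligned extracellular amino-acid sequences for a universe of
HLA alleles, one alignment per locus (all alleles of a locus share the same
alignment length), plus the allele -> serological split map used for
antigen-level (split) matching and for haplotype-pair imputation.

File formats are deliberately plain: FASTA with ``LOCUS*NAME`` headers for
sequences, tab-separated tables for serology and haplotype frequencies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Loci tracked by the store. DRB3, DRB4 and DRB5 are folded into a single
#: DRB345 locus (they occupy the same chromosomal slot on a haplotype).
LOCI = ("A", "B", "C", "DRB1", "DRB345", "DQA1", "DQB1")
CLASS_I_LOCI = ("A", "B", "C")
CLASS_II_LOCI = ("DRB1", "DRB345", "DQA1", "DQB1")

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: DQ alpha/beta chains are concatenated in this fixed order when the DQ
#: heterodimer is treated as a single molecule.
DQ_CHAIN_ORDER = ("DQA1", "DQB1")


class FormatError(ValueError):
    """Malformed input file (ragged alignment, bad frequency, missing column)."""


def locus_of(allele_name: str) -> str:
    """Locus for an allele name such as ``A*02:01`` or ``DRB4*01:03``.

    DRB3/DRB4/DRB5 map to the combined ``DRB345`` locus.
    """
    prefix, _, _ = allele_name.partition("*")
    if not prefix or "*" not in allele_name:
        raise FormatError(f"allele name {allele_name!r} lacks a LOCUS* prefix")
    if prefix in ("DRB3", "DRB4", "DRB5"):
        return "DRB345"
    if prefix not in LOCI:
        raise FormatError(f"unknown locus {prefix!r} in allele {allele_name!r}")
    return prefix


@dataclass(frozen=True)
class HLAAllele:
    """One two-field HLA allele with its aligned extracellular sequence."""

    locus: str
    name: str
    aligned_seq: str
    split: Optional[str] = None

    @property
    def seq(self) -> str:
        """Ungapped amino-acid sequence (gap columns removed)."""
        return self.aligned_seq.replace(GAP, "")


@dataclass(frozen=True)
class Haplotype:
    """One multi-locus haplotype with its population frequency."""

    alleles: tuple  # ((locus, allele_name), ...) in LOCI order
    population: str
    frequency: float

    def allele(self, locus: str) -> str:
        for loc, name in self.alleles:
            if loc == locus:
                return name
        raise KeyError(locus)

    @property
    def key(self) -> tuple:
        """Lexicographic sort key (allele names in locus order)."""
        return tuple(name for _, name in self.alleles)


class Genotype:
    """Per-locus pair of allele names, phase-aware when built from haplotypes.

    The pair at each locus is stored as an ordered tuple; when the genotype
    comes from a haplotype pair the first element of every locus tuple
    belongs to the same haplotype, which preserves the cis pairing used to
    assemble DQ alpha-beta heterodimers. Equality and the public accessors
    treat the pair as unordered.
    """

    def __init__(self, alleles: Mapping[str, Sequence[str]]):
        self.alleles = {loc: tuple(pair) for loc, pair in alleles.items()}
        for loc, pair in self.alleles.items():
            if len(pair) != 2:
                raise ValueError(f"locus {loc}: genotype needs exactly 2 alleles, got {pair}")

    @classmethod
    def from_haplotypes(cls, h1: Haplotype, h2: Haplotype) -> "Genotype":
        return cls({loc: (h1.allele(loc), h2.allele(loc)) for loc, _ in h1.alleles})

    def pair(self, locus: str) -> tuple:
        return self.alleles[locus]

    def unique_alleles(self, locus: str) -> tuple:
        """Distinct allele names at a locus (1 if homozygous), sorted."""
        return tuple(sorted(set(self.alleles[locus])))

    @property
    def loci(self) -> tuple:
        return tuple(self.alleles)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        if set(self.alleles) != set(other.alleles):
            return False
        return all(
            sorted(self.alleles[loc]) == sorted(other.alleles[loc]) for loc in self.alleles
        )

    def __repr__(self) -> str:
        inner = ", ".join(f"{loc}: {a}/{b}" for loc, (a, b) in self.alleles.items())
        return f"Genotype({inner})"


class AlleleSequenceStore:
    """Aligned sequences and serology for a universe of HLA alleles.

    Alleles are indexed by name (the locus is implicit in the name); all
    alleles of a locus must share one alignment length, validated on insert.
    """

    def __init__(self):
        self._alleles: dict = {}
        self._serology: dict = {}
        self.alignment_length: dict = {}

    # -- construction -----------------------------------------------------

    def add_allele(self, allele: HLAAllele) -> None:
        expected = self.alignment_length.get(allele.locus)
        if expected is not None and len(allele.aligned_seq) != expected:
            raise FormatError(
                f"ragged alignment at locus {allele.locus}: {allele.name} has "
                f"length {len(allele.aligned_seq)}, expected {expected}"
            )
        existing = self._alleles.get(allele.name)
        if existing is not None:
            if existing.aligned_seq == allele.aligned_seq:
                warnings.warn(f"duplicate allele {allele.name} ignored (identical sequence)")
                return
            raise FormatError(f"allele {allele.name} listed twice with different sequences")
        self.alignment_length.setdefault(allele.locus, len(allele.aligned_seq))
        self._alleles[allele.name] = allele

    def set_split(self, allele_name: str, split: str) -> None:
        self._serology[allele_name] = split
        existing = self._alleles.get(allele_name)
        if existing is not None and existing.split != split:
            self._alleles[allele_name] = HLAAllele(
                existing.locus, existing.name, existing.aligned_seq, split
            )

    # -- lookups ----------------------------------------------------------

    def __contains__(self, allele_name: str) -> bool:
        return allele_name in self._alleles

    def __len__(self) -> int:
        return len(self._alleles)

    def get(self, allele_name: str) -> HLAAllele:
        try:
            return self._alleles[allele_name]
        except KeyError:
            raise KeyError(f"allele {allele_name!r} not in sequence store") from None

    def aligned(self, allele_name: str) -> str:
        return self.get(allele_name).aligned_seq

    def split_of(self, allele_name: str) -> str:
        split = self._serology.get(allele_name)
        if split is None:
            allele = self._alleles.get(allele_name)
            if allele is not None and allele.split is not None:
                return allele.split
            raise KeyError(f"no serological split mapped for allele {allele_name!r}")
        return split

    def has_split(self, allele_name: str) -> bool:
        return allele_name in self._serology or (
            allele_name in self._alleles and self._alleles[allele_name].split is not None
        )

    def alleles_at(self, locus: str) -> list:
        return sorted(
            (a for a in self._alleles.values() if a.locus == locus), key=lambda a: a.name
        )

    @property
    def loci(self) -> tuple:
        return tuple(loc for loc in LOCI if loc in self.alignment_length)

    # -- round-trip I/O ---------------------------------------------------

    def write(self, seq_path, serology_path) -> None:
        records = [
            SeqRecord(Seq(a.aligned_seq), id=a.name, description="")
            for a in sorted(self._alleles.values(), key=lambda a: (a.locus, a.name))
        ]
        SeqIO.write(records, str(seq_path), "fasta")
        rows = sorted(self._serology.items())
        pd.DataFrame(rows, columns=["allele", "split"]).to_csv(
            serology_path, sep="\t", index=False
        )


def load_allele_store(seq_path, serology_path=None) -> AlleleSequenceStore:
    """Load an :class:`AlleleSequenceStore` from FASTA sequences + serology TSV.

    FASTA headers carry the allele name (``LOCUS*NAME``); the serology table
    has columns ``allele`` and ``split``. An allele in the serology map with
    no sequence is retained for split-only use (with a warning).
    """
    store = AlleleSequenceStore()
    for record in SeqIO.parse(str(seq_path), "fasta"):
        name = record.id
        store.add_allele(HLAAllele(locus_of(name), name, str(record.seq).upper()))
    if serology_path is not None:
        sero = pd.read_csv(serology_path, sep="\t", dtype=str)
        missing = {"allele", "split"} - set(sero.columns)
        if missing:
            raise FormatError(f"serology table missing columns: {sorted(missing)}")
        for allele, split in zip(sero["allele"], sero["split"]):
            if allele not in store:
                warnings.warn(
                    f"serology map lists allele {allele} with no sequence; kept for split-only use"
                )
            store.set_split(allele, split)
    return store


def load_haplotype_table(path, population: str, tol: float = 1e-6) -> list:
    """Read an NMDP-style haplotype frequency TSV for one population.

    Columns: one per locus in :data:`LOCI`, plus ``population`` and
    ``frequency``. Frequencies must lie in [0, 1] and sum to at most
    1 + ``tol`` within the selected population.
    """
    df = pd.read_csv(path, sep="\t", dtype={"population": str})
    needed = set(LOCI) | {"population", "frequency"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"haplotype table missing columns: {sorted(missing)}")
    sel = df[df["population"] == population]
    if sel.empty:
        raise FormatError(f"no haplotypes for population {population!r}")
    freqs = sel["frequency"].astype(float)
    if (freqs < 0).any() or (freqs > 1).any():
        bad = freqs[(freqs < 0) | (freqs > 1)].iloc[0]
        raise FormatError(f"haplotype frequency {bad} outside [0, 1]")
    if freqs.sum() > 1 + tol:
        raise FormatError(f"haplotype frequencies sum to {freqs.sum():.6f} > 1")
    haplotypes = []
    for _, row in sel.iterrows():
        alleles = tuple((loc, str(row[loc])) for loc in LOCI)
        haplotypes.append(Haplotype(alleles, population, float(row["frequency"])))
    return haplotypes


def write_haplotype_table(haplotypes: Iterable[Haplotype], path) -> None:
    rows = []
    for h in haplotypes:
        row = {loc: name for loc, name in h.alleles}
        row["population"] = h.population
        row["frequency"] = h.frequency
        rows.append(row)
    pd.DataFrame(rows, columns=list(LOCI) + ["population", "frequency"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def heterodimer_name(dqa1: str, dqb1: str) -> str:
    """Canonical name of a DQ alpha-beta heterodimer, always alpha then beta."""
    if locus_of(dqa1) != "DQA1" or locus_of(dqb1) != "DQB1":
        raise ValueError(f"heterodimer needs (DQA1, DQB1) chains, got ({dqa1}, {dqb1})")
    return f"{dqa1}~{dqb1}"


def concatenated_dq_sequence(store: AlleleSequenceStore, dqa1: str, dqb1: str) -> str:
    """Aligned DQA1 sequence concatenated with the aligned DQB1 sequence.

    The chain order is fixed (alpha then beta) so identical heterodimers
    always yield identical concatenations.
    """
    if locus_of(dqa1) != "DQA1":
        raise ValueError(f"{dqa1} is not a DQA1 allele")
    if locus_of(dqb1) != "DQB1":
        raise ValueError(f"{dqb1} is not a DQB1 allele")
    return store.aligned(dqa1) + store.aligned(dqb1)


def dq_heterodimers(genotype: Genotype) -> list:
    """The (up to two) cis DQ heterodimers of a phased genotype.

    Chains inherited on the same haplotype pair together; a genotype
    homozygous for the pairing yields a single heterodimer.
    """
    dqa = genotype.pair("DQA1")
    dqb = genotype.pair("DQB1")
    pairs = {(dqa[0], dqb[0]), (dqa[1], dqb[1])}
    return sorted(pairs)
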