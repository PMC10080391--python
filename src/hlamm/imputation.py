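"""Allelic imputation from split-serotype typing via haplotype frequencies.

Registry HLA typing is usually reported at the serological split level
(e.g. A2, A24, DR15, DQ6). Two-field allelic genotypes are recovered by
enumerating haplotype pairs from a population frequency table whose implied
split-level typing matches the observed one, and assigning the
maximum-probability pair. Under Hardy-Weinberg the probability of an
unordered pair is ``2 f1 f2`` for distinct haplotypes and ``f**2`` for a
homozygous pair.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .hla import AlleleSequenceStore, Genotype, Haplotype

logger = logging.getLogger(__name__)

#: Serologically typed loci and the store locus carrying their splits.
#: DR and DQ serology are defined by the beta chains.
TYPING_LOCUS = {
    "A": "A",
    "B": "B",
    "C": "C",
    "DR": "DRB1",
    "DRB1": "DRB1",
    "DQ": "DQB1",
    "DQB1": "DQB1",
}


class UntypeableError(ValueError):
    """No haplotype pair in the table reproduces the observed split typing."""

    def __init__(self, loci):
        self.loci = tuple(loci)
        super().__init__(
            f"no compatible haplotype pair; unmatched at loci: {', '.join(self.loci)}"
        )


def _normalise_typing(split_typing: Mapping[str, Sequence[str]]) -> dict:
    """Map typing loci onto store loci and expand single splits to homozygous."""
    out = {}
    for loc, splits in split_typing.items():
        store_locus = TYPING_LOCUS.get(loc)
        if store_locus is None:
            raise ValueError(f"unknown typing locus {loc!r}")
        splits = tuple(splits) if not isinstance(splits, str) else (splits,)
        if len(splits) == 1:  # single antigen = split-level homozygote
            splits = (splits[0], splits[0])
        if len(splits) != 2:
            raise ValueError(f"locus {loc}: expected 1 or 2 splits, got {splits}")
        out[store_locus] = tuple(sorted(splits))
    return out


def _haplotype_splits(h: Haplotype, store: AlleleSequenceStore, loci) -> dict:
    return {loc: store.split_of(h.allele(loc)) for loc in loci}


def compatible_haplotype_pairs(
    split_typing: Mapping[str, Sequence[str]],
    table: Sequence[Haplotype],
    store: AlleleSequenceStore,
) -> list:
    """All unordered haplotype pairs compatible with a split-level typing.

    A pair is compatible when, at every typed locus, the multiset of splits
    implied by its two haplotypes equals the typed split pair. Returns
    ``(h1, h2, probability)`` triples sorted by descending probability, ties
    broken lexicographically by allele names.

    Raises
    ------
    UntypeableError
        If no pair is compatible; the error lists the loci that no pair
        could match.
    """
    if not table:
        raise ValueError("empty haplotype table")
    typing = _normalise_typing(split_typing)
    loci = tuple(typing)
    hap_splits = [_haplotype_splits(h, store, loci) for h in table]

    results = []
    best_unmatched = set(loci)
    n = len(table)
    for i in range(n):
        for j in range(i, n):
            unmatched = [
                loc
                for loc in loci
                if tuple(sorted((hap_splits[i][loc], hap_splits[j][loc]))) != typing[loc]
            ]
            if unmatched:
                if len(unmatched) < len(best_unmatched):
                    best_unmatched = set(unmatched)
                continue
            f1, f2 = table[i].frequency, table[j].frequency
            prob = f1 * f1 if i == j else 2.0 * f1 * f2
            h1, h2 = sorted((table[i], table[j]), key=lambda h: h.key)
            results.append((h1, h2, prob))
    if not results:
        raise UntypeableError(sorted(best_unmatched))
    results.sort(key=lambda t: (-t[2], t[0].key, t[1].key))
    return results


def impute_genotype(
    split_typing: Mapping[str, Sequence[str]],
    table: Sequence[Haplotype],
    store: AlleleSequenceStore,
) -> Genotype:
    """Genotype of the maximum-probability compatible haplotype pair.

    Ties in probability are broken lexicographically by haplotype allele
    names, so the result is deterministic given the table.
    """
    pairs = compatible_haplotype_pairs(split_typing, table, store)
    h1, h2, _ = pairs[0]
    return Genotype.from_haplotypes(h1, h2)


def is_allelic_typing(typing: Mapping[str, Sequence[str]]) -> bool:
    """True if every typed value is already a two-field allele name."""
    return all(
        "*" in v
        for values in typing.values()
        for v in ((values,) if isinstance(values, str) else values)
    )


def genotype_from_allelic_typing(
    typing: Mapping[str, Sequence[str]], store: AlleleSequenceStore
) -> Genotype:
    """Pass-through for typings already at two-field allelic resolution."""
    alleles = {}
    for loc, values in typing.items():
        values = (values,) if isinstance(values, str) else tuple(values)
        if len(values) == 1:
            values = (values[0], values[0])
        for v in values:
            store.get(v)  # total lookup: fail fast on unknown alleles
        alleles[loc] = values
    return Genotype(alleles)
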