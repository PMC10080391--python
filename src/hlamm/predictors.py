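"""Peptide-binding predictor interface and a deterministic mock.

Class II binding predictions (9-mer core, affinity in nM, percentage rank)
are consumed behind a small callable contract so the scoring stage is
agnostic to where predictions come from: a tabular export of an external
neural-network predictor, or the seeded mock used for simulation and
testing. The mock is fully deterministic in (peptide, presenter, seed):

* the 9-mer core is the window maximising a presenter-specific positional
  weight table (ties resolved to the leftmost window);
* affinity is a keyed-hash uniform draw mapped log-uniformly onto
  (1, 50000) nM;
* percentage rank is the empirical percentile of that affinity against a
  fixed presenter-specific reference distribution of 10,000 seeded random
  peptide affinities, so rank is strictly monotone in affinity within a
  presenter.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hla import AMINO_ACIDS

PEPTIDE_LENGTH = 15
CORE_LENGTH = 9
AFFINITY_MAX_NM = 50000.0


@dataclass(frozen=True)
class BindingPrediction:
    """Predicted presentation of one 15-mer by one class II molecule."""

    peptide: str
    presenter: str
    core9: str
    affinity_nm: float
    rank_pct: float

    def __post_init__(self):
        if self.core9 not in self.peptide:
            raise ValueError("core9 must be a contiguous substring of the peptide")


def _hash_uniform(*parts) -> float:
    """Deterministic uniform in [0, 1) keyed on the given parts."""
    digest = hashlib.blake2b("|".join(map(str, parts)).encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") / 2**64


class MockBindingPredictor:
    """Deterministic stand-in class II binding predictor (see module docstring)."""

    def __init__(self, seed: int = 0, reference_size: int = 10000):
        self.seed = int(seed)
        self.reference_size = int(reference_size)
        self._weights: dict = {}
        self._reference: dict = {}
        self._cache: dict = {}
        self._aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    def _presenter_rng(self, tag: str, presenter: str) -> np.random.Generator:
        digest = hashlib.blake2b(
            f"{tag}|{presenter}|{self.seed}".encode(), digest_size=8
        ).digest()
        return np.random.default_rng(int.from_bytes(digest, "big"))

    def _weight_table(self, presenter: str) -> np.ndarray:
        table = self._weights.get(presenter)
        if table is None:
            rng = self._presenter_rng("weights", presenter)
            table = rng.random((CORE_LENGTH, len(AMINO_ACIDS)))
            self._weights[presenter] = table
        return table

    def _reference_affinities(self, presenter: str) -> np.ndarray:
        ref = self._reference.get(presenter)
        if ref is None:
            rng = self._presenter_rng("reference", presenter)
            u = rng.random(self.reference_size)
            ref = np.sort(AFFINITY_MAX_NM**u)
            self._reference[presenter] = ref
        return ref

    def _core(self, peptide: str, presenter: str) -> str:
        w = self._weight_table(presenter)
        best, best_score = None, -np.inf
        for start in range(PEPTIDE_LENGTH - CORE_LENGTH + 1):
            window = peptide[start : start + CORE_LENGTH]
            score = sum(w[i, self._aa_index[aa]] for i, aa in enumerate(window))
            if score > best_score:  # strict: ties keep the leftmost window
                best, best_score = window, score
        return best

    def predict(self, peptide: str, presenter: str) -> BindingPrediction:
        if len(peptide) != PEPTIDE_LENGTH:
            raise ValueError(f"peptide must be length {PEPTIDE_LENGTH}, got {len(peptide)}")
        key = (peptide, presenter)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        affinity = AFFINITY_MAX_NM ** _hash_uniform("affinity", peptide, presenter, self.seed)
        ref = self._reference_affinities(presenter)
        rank = 100.0 * np.searchsorted(ref, affinity, side="left") / ref.size
        pred = BindingPrediction(peptide, presenter, self._core(peptide, presenter), affinity, rank)
        self._cache[key] = pred
        return pred

    __call__ = predict


class TabularPredictor:
    """Adapter over a tabular export of an external class II predictor.

    Expects columns ``peptide``, ``presenter``, ``core``, ``affinity_nm``,
    ``rank_pct`` (tab-separated when read from a path). Lookups are exact;
    a missing (peptide, presenter) combination raises ``KeyError``.
    """

    def __init__(self, table: pd.DataFrame):
        needed = {"peptide", "presenter", "core", "affinity_nm", "rank_pct"}
        missing = needed - set(table.columns)
        if missing:
            raise ValueError(f"prediction table missing columns: {sorted(missing)}")
        self._table = {
            (row.peptide, row.presenter): BindingPrediction(
                row.peptide, row.presenter, row.core, float(row.affinity_nm), float(row.rank_pct)
            )
            for row in table.itertuples(index=False)
        }

    @classmethod
    def from_path(cls, path) -> "TabularPredictor":
        return cls(pd.read_csv(path, sep="\t", dtype={"peptide": str, "presenter": str}))

    def predict(self, peptide: str, presenter: str) -> BindingPrediction:
        try:
            return self._table[(peptide, presenter)]
        except KeyError:
            raise KeyError(f"no prediction for peptide {peptide!r} with {presenter!r}") from None

    __call__ = predict
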