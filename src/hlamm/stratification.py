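"""Patient-level risk stratification from per-molecule scores.

A patient's representative score at a locus is the maximum over their
mismatched donor molecules (patients with two mismatches are represented by
the higher-scoring one). Against the locus x method Youden threshold this
yields three categories: ``matched`` (no allelic mismatch), ``low``
(score below the threshold) and ``high`` (score at or above it). For
HLA-DQ, crossing the antigen mismatch count (0/1/2) with the low/high
molecular category gives six strata.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .scoring import METHODS, MismatchRecord, records_to_frame

MATCHED = "matched"
LOW = "low"
HIGH = "high"

#: Stratum index for (antigen mismatch count, molecular category):
#: 1 - 0MM/low, 2 - 1MM/low, 3 - 2MM/low, 4 - 0MM/high, 5 - 1MM/high, 6 - 2MM/high.
_DQ_STRATA = {
    (0, LOW): 1, (1, LOW): 2, (2, LOW): 3,
    (0, HIGH): 4, (1, HIGH): 5, (2, HIGH): 6,
}


def patient_locus_score(
    records: Sequence[MismatchRecord], pair_id: str, locus: str, method: str
) -> Optional[float]:
    """Representative (maximum) score for one patient at one locus; None if matched."""
    scores = [
        r.scores[method] for r in records if r.pair_id == pair_id and r.locus == locus
    ]
    return max(scores) if scores else None


def risk_category(
    score: Optional[float], threshold: float, boundary: str = "ge"
) -> str:
    """matched / low / high against a Youden threshold.

    ``ge`` (default): high iff score >= threshold. ``gt``: high iff
    score > threshold (the alternative boundary convention).
    """
    if score is None:
        return MATCHED
    if boundary == "ge":
        return HIGH if score >= threshold else LOW
    if boundary == "gt":
        return HIGH if score > threshold else LOW
    raise ValueError(f"unknown boundary convention {boundary!r}")


def dq_stratum(ant_mm: int, category: str) -> int:
    """Six-way DQ stratum from antigen mismatch count and molecular category.

    Antigen-matched patients can still carry a molecular mismatch (split
    identity does not imply allelic identity), which is what populates the
    0MM/high stratum. A fully matched (allelic) patient is molecular low
    risk by definition; passing ``matched`` with a nonzero antigen count or
    ``high`` is inconsistent and raises.
    """
    if ant_mm not in (0, 1, 2):
        raise ValueError(f"antigen mismatch count must be 0, 1 or 2, got {ant_mm}")
    if category == MATCHED:
        if ant_mm != 0:
            raise ValueError("allelically matched patient cannot have antigen mismatches")
        category = LOW
    if category not in (LOW, HIGH):
        raise ValueError(f"unknown category {category!r}")
    return _DQ_STRATA[(ant_mm, category)]


def build_risk_profiles(
    records: Sequence[MismatchRecord],
    thresholds: pd.DataFrame,
    antigen_counts: Optional[pd.DataFrame] = None,
    all_pair_ids: Optional[Sequence[str]] = None,
    boundary: str = "ge",
) -> pd.DataFrame:
    """Per patient x locus x method representative score and risk category.

    ``thresholds`` is the locus x method table from the single-molecule
    analysis. ``antigen_counts`` (columns pair_id, locus, antMM), when
    given, adds the six-way DQ stratum for methods with a DQ threshold.
    ``all_pair_ids`` lets fully matched patients (no mismatch records at
    all) appear as ``matched`` rows.
    """
    df = records_to_frame(records)
    pair_ids = sorted(set(df["pair_id"]) | set(all_pair_ids or []))
    thr = {
        (row.locus, row.method): row.threshold for row in thresholds.itertuples(index=False)
    }
    ant = {}
    if antigen_counts is not None:
        ant = {
            (row.pair_id, row.locus): int(row.antMM)
            for row in antigen_counts.itertuples(index=False)
        }
    rows = []
    loci = sorted({locus for locus, _ in thr})
    methods = sorted({method for _, method in thr})
    for pair_id in pair_ids:
        for locus in loci:
            sub = df[(df["pair_id"] == pair_id) & (df["locus"] == locus)]
            for method in methods:
                if (locus, method) not in thr:
                    continue
                score = sub[method].max() if not sub.empty else None
                category = risk_category(
                    None if sub.empty else float(score), thr[(locus, method)], boundary
                )
                row = {
                    "pair_id": pair_id,
                    "locus": locus,
                    "method": method,
                    "representative_score": None if sub.empty else float(score),
                    "category": category,
                }
                if locus == "DQ" and (pair_id, "DQ") in ant:
                    row["dq_stratum"] = dq_stratum(ant[(pair_id, "DQ")], category)
                rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty and "dq_stratum" not in out.columns:
        out["dq_stratum"] = pd.NA
    return out


def highest_score_targeting(
    records: Sequence[MismatchRecord], methods: Sequence[str] = METHODS
) -> pd.DataFrame:
    """Among two-mismatch/one-DSA (2MM1DSA) patients, does the DSA hit the top score?

    For each locus x method: patients with exactly two mismatched molecules
    at that locus and DSA against exactly one of them; counts how often the
    DSA-targeted molecule carries the (weakly) highest score. Score ties
    count as targeting the highest.
    """
    df = records_to_frame(records)
    rows = []
    for method in methods:
        for locus, group in df.groupby("locus"):
            n_total = n_highest = 0
            for _, pair_group in group.groupby("pair_id"):
                if len(pair_group) != 2 or pair_group["dsa"].sum() != 1:
                    continue
                n_total += 1
                target = pair_group[pair_group["dsa"]][method].iloc[0]
                other = pair_group[~pair_group["dsa"]][method].iloc[0]
                if target >= other:
                    n_highest += 1
            rows.append(
                {
                    "locus": locus,
                    "method": method,
                    "n_targeting_highest": n_highest,
                    "n_total_2mm1dsa": n_total,
                }
            )
    return pd.DataFrame(
        rows, columns=["locus", "method", "n_targeting_highest", "n_total_2mm1dsa"]
    )
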