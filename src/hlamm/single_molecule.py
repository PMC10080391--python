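"""The single-molecule method: per-molecule ROC analysis of mismatch scores.

Every mismatched donor molecule contributes one observation (score,
molecule-specific DSA yes/no), independent of which patient it belongs to.
ROC analysis of each scoring method against molecule-specific DSA yields a
Youden-index threshold per locus x method that separates low- from
high-risk molecular mismatches; correlated AUCs are compared with the
paired DeLong test.

AUC is the Mann-Whitney (rank) statistic with tie correction; its variance
and the covariance between paired AUCs use the DeLong structural-components
formulation, giving Wald confidence intervals and a two-sided z-test for
the AUC difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import METHODS, MismatchRecord, records_to_frame


class DegenerateLabelsError(ValueError):
    """ROC analysis needs both a positive and a negative class."""


@dataclass
class ROCResult:
    """ROC curve, AUC with a DeLong 95% CI, and class sizes."""

    auc: float
    ci95: Tuple[float, float]
    curve: pd.DataFrame  # columns: threshold, sensitivity, specificity
    n_pos: int
    n_neg: int


@dataclass
class RiskThreshold:
    """Youden-derived cut separating low from high molecular risk.

    Classification convention: score >= threshold is called high risk.
    """

    locus: Optional[str]
    method: Optional[str]
    threshold: float
    youden_j: float


@dataclass
class DeLongResult:
    auc1: float
    auc2: float
    delta: float
    z: float
    p_value: float


def _check_labels(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise DegenerateLabelsError("degenerate labels: need both classes present")


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative).

    psi(x, y) = 1 if x > y, 1/2 if x == y, 0 otherwise; V10_i is the mean of
    psi over negatives, V01_j the mean over positives. AUC is the mean of
    either vector.
    """
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0)


def mann_whitney_auc(scores, labels) -> float:
    """Tie-corrected rank AUC: P(score_pos > score_neg) + 1/2 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_labels(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_curve_points(scores, labels, candidates: str = "observed") -> pd.DataFrame:
    """Sensitivity/specificity at each candidate threshold (score >= t positive).

    ``observed`` uses the unique observed score values as candidates (so a
    reported cut is an attainable score); ``midpoints`` uses midpoints of
    consecutive unique scores plus one threshold above the maximum.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    uniq = np.unique(scores)
    if candidates == "observed":
        thresholds = uniq
    elif candidates == "midpoints":
        mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.array([])
        thresholds = np.concatenate([[uniq[0] - 1], mids, [uniq[-1] + 1]])
    else:
        raise ValueError(f"unknown candidate convention {candidates!r}")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    rows = []
    for t in thresholds:
        called = scores >= t
        sens = (called & labels).sum() / n_pos if n_pos else np.nan
        spec = (~called & ~labels).sum() / n_neg if n_neg else np.nan
        rows.append((t, sens, spec))
    return pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])


def roc_auc(scores, labels, candidates: str = "observed") -> ROCResult:
    """Mann-Whitney AUC with DeLong 95% CI and the full threshold curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_labels(labels)
    auc = mann_whitney_auc(scores, labels)
    v10, v01 = _delong_components(scores[labels], scores[~labels])
    var = (
        (np.var(v10, ddof=1) / v10.size if v10.size > 1 else 0.0)
        + (np.var(v01, ddof=1) / v01.size if v01.size > 1 else 0.0)
    )
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    curve = roc_curve_points(scores, labels, candidates)
    return ROCResult(
        auc=auc,
        ci95=(max(0.0, auc - half), min(1.0, auc + half)),
        curve=curve,
        n_pos=int(labels.sum()),
        n_neg=int(labels.size - labels.sum()),
    )


def youden_threshold(
    roc: ROCResult, locus: Optional[str] = None, method: Optional[str] = None
) -> RiskThreshold:
    """Threshold maximising J = sensitivity + specificity - 1.

    Ties in J are broken toward the lower threshold (the more sensitive
    cut).
    """
    curve = roc.curve
    j = curve["sensitivity"] + curve["specificity"] - 1.0
    order = np.lexsort((curve["threshold"].to_numpy(), -j.to_numpy()))
    best = order[0]
    return RiskThreshold(
        locus=locus,
        method=method,
        threshold=float(curve["threshold"].iloc[best]),
        youden_j=float(j.iloc[best]),
    )


def delong_test(scores1, scores2, labels) -> DeLongResult:
    """Paired DeLong comparison of two correlated AUCs on identical labels."""
    scores1 = np.asarray(scores1, dtype=float)
    scores2 = np.asarray(scores2, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_labels(labels)
    v10_1, v01_1 = _delong_components(scores1[labels], scores1[~labels])
    v10_2, v01_2 = _delong_components(scores2[labels], scores2[~labels])
    auc1, auc2 = v10_1.mean(), v10_2.mean()
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc1 - auc2
    if delta == 0:  # identical ROC (incl. monotone transforms): no evidence
        return DeLongResult(auc1=auc1, auc2=auc2, delta=0.0, z=0.0, p_value=1.0)
    z = delta / np.sqrt(var_delta) if var_delta > 0 else np.inf * np.sign(delta)
    p = float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(auc1=auc1, auc2=auc2, delta=delta, z=float(z), p_value=min(p, 1.0))


# -- dataset assembly over mismatch records --------------------------------


def build_single_molecule_dataset(
    records: Sequence[MismatchRecord], locus: Optional[str] = None
) -> pd.DataFrame:
    """One row per mismatched donor molecule with its scores and DSA flag.

    A patient with two mismatches at a locus contributes two rows; allelic
    matches contribute none (they produce no mismatch records).
    """
    df = records_to_frame(records)
    if locus is not None:
        df = df[df["locus"] == locus].reset_index(drop=True)
    return df[["pair_id", "locus", "molecule", "antMM"] + list(METHODS) + ["dsa"]]


def derive_thresholds(
    records: Sequence[MismatchRecord],
    loci: Sequence[str] = ("A", "B", "DQ", "DR"),
    methods: Sequence[str] = METHODS,
    candidates: str = "observed",
) -> pd.DataFrame:
    """Youden threshold per locus x method from the single-molecule datasets."""
    rows = []
    for locus in loci:
        data = build_single_molecule_dataset(records, locus)
        if data.empty or data["dsa"].nunique() < 2:
            continue
        labels = data["dsa"].to_numpy(dtype=bool)
        for method in methods:
            roc = roc_auc(data[method].to_numpy(), labels, candidates)
            thr = youden_threshold(roc, locus, method)
            rows.append(
                {
                    "locus": locus,
                    "method": method,
                    "threshold": thr.threshold,
                    "youden_j": thr.youden_j,
                    "auc": roc.auc,
                    "auc_lo": roc.ci95[0],
                    "auc_hi": roc.ci95[1],
                    "n_pos": roc.n_pos,
                    "n_neg": roc.n_neg,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "locus", "method", "threshold", "youden_j",
            "auc", "auc_lo", "auc_hi", "n_pos", "n_neg",
        ],
    )


def score_correlation_matrix(
    records: Sequence[MismatchRecord], locus: Optional[str] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r (and p-values) among scoring methods over molecules.

    Allelic matches are excluded by construction (they yield no records).
    A zero-variance score leaves its correlations undefined (NaN).
    """
    data = build_single_molecule_dataset(records, locus)
    if len(data) < 3:
        raise ValueError("need at least 3 mismatched molecules for correlations")
    methods = list(METHODS)
    r = pd.DataFrame(np.nan, index=methods, columns=methods)
    p = pd.DataFrame(np.nan, index=methods, columns=methods)
    for i, m1 in enumerate(methods):
        for m2 in methods[i:]:
            x = data[m1].to_numpy(dtype=float)
            y = data[m2].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r.loc[m1, m2] = r.loc[m2, m1] = res.statistic
            p.loc[m1, m2] = p.loc[m2, m1] = res.pvalue
    return r, p
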