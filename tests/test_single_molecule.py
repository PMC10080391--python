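"""ROC/AUC, Youden thresholds, DeLong comparisons and score correlations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hlamm.scoring import METHODS, records_to_frame
from hlamm.single_molecule import (
    DegenerateLabelsError,
    build_single_molecule_dataset,
    delong_test,
    derive_thresholds,
    mann_whitney_auc,
    roc_auc,
    score_correlation_matrix,
    youden_threshold,
)


def auc_oracle(scores, labels):
    """Brute-force pairwise counting: (concordant + ties/2) / (n_pos * n_neg)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_oracle(scores, labels):
    """Exhaustive search over observed values plus +/- infinity candidates."""
    best_j, best_t = -np.inf, None
    candidates = sorted(set(scores))
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    for t in candidates:
        called = scores >= t
        sens = (called & labels).sum() / labels.sum()
        spec = (~called & ~labels).sum() / (~labels).sum()
        j = sens + spec - 1
        if j > best_j or (j == best_j and t < best_t):
            best_j, best_t = j, t
    return best_t, best_j


def test_auc_degenerate_cases():
    assert mann_whitney_auc([1, 1, 1, 1], [0, 0, 1, 1]) == pytest.approx(0.5)
    assert mann_whitney_auc([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(1.0)
    with pytest.raises(DegenerateLabelsError):
        mann_whitney_auc([1, 2], [1, 1])


@pytest.mark.parametrize("seed", range(5))
def test_auc_equals_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 10, size=50).astype(float)  # heavy ties
    labels = rng.random(50) < 0.4
    if labels.all() or not labels.any():
        labels[0] = not labels[0]
    assert mann_whitney_auc(scores, labels) == pytest.approx(
        auc_oracle(scores, labels), abs=1e-12
    )


def test_auc_against_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(1)
    scores = rng.normal(size=200)
    labels = rng.random(200) < 0.3
    assert mann_whitney_auc(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12
    )


@given(st.integers(0, 10**6))
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=40)
    labels = rng.random(40) < 0.5
    if labels.all() or not labels.any():
        labels[0] = not labels[0]
    a = mann_whitney_auc(scores, labels)
    b = mann_whitney_auc(np.exp(2 * scores), labels)
    assert a == pytest.approx(b, abs=1e-12)


def test_youden_worked_example():
    roc = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
    thr = youden_threshold(roc)
    assert thr.threshold == 3
    assert thr.youden_j == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(10))
def test_youden_equals_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 80))
    scores = np.round(rng.normal(size=n), 1)
    labels = rng.random(n) < 0.4
    if labels.all() or not labels.any():
        labels[0] = not labels[0]
    roc = roc_auc(scores, labels)
    thr = youden_threshold(roc)
    t_oracle, j_oracle = youden_oracle(scores, labels)
    assert thr.youden_j == pytest.approx(j_oracle, abs=1e-12)
    assert thr.threshold == pytest.approx(t_oracle)


def test_youden_null_scores_give_small_j():
    rng = np.random.default_rng(0)
    # null: scores independent of labels; J should sit below the null 95th pct
    n = 400
    j_values = []
    for _ in range(100):
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.5
        thr = youden_threshold(roc_auc(scores, labels))
        j_values.append(thr.youden_j)
    assert np.median(j_values) < 0.2


def test_roc_curve_shape_and_ci():
    rng = np.random.default_rng(2)
    scores = np.concatenate([rng.normal(1, 1, 60), rng.normal(0, 1, 120)])
    labels = np.array([True] * 60 + [False] * 120)
    roc = roc_auc(scores, labels)
    assert roc.n_pos == 60 and roc.n_neg == 120
    sens = roc.curve.sort_values("threshold")["sensitivity"].to_numpy()
    assert (np.diff(sens) <= 1e-12).all()  # non-increasing in threshold
    assert roc.ci95[0] <= roc.auc <= roc.ci95[1]
    # curve trapezoid area equals the rank AUC
    spec = roc.curve.sort_values("threshold")["specificity"].to_numpy()
    fpr = 1 - spec
    area = -np.trapezoid(np.append(sens, 0.0), np.append(fpr, 0.0))
    assert area == pytest.approx(roc.auc, abs=1e-9)


def test_delong_identical_and_monotone():
    rng = np.random.default_rng(3)
    scores = rng.normal(size=100)
    labels = rng.random(100) < 0.5
    res = delong_test(scores, scores, labels)
    assert res.p_value == 1.0 and res.delta == 0.0
    res2 = delong_test(scores, np.exp(scores), labels)
    assert res2.delta == pytest.approx(0.0, abs=1e-12)
    assert res2.p_value == 1.0


def test_delong_agrees_with_paired_bootstrap():
    """Binormal paired scores, n=200: DeLong p within 0.05 of a 2000-rep bootstrap."""
    rng = np.random.default_rng(4)
    n = 200
    labels = np.array([True] * 80 + [False] * 120)
    latent = rng.normal(size=n) + 0.9 * labels
    s1 = latent + rng.normal(scale=0.6, size=n)
    s2 = 0.8 * latent + rng.normal(scale=0.8, size=n)
    res = delong_test(s1, s2, labels)

    deltas = np.empty(2000)
    for b in range(2000):
        idx = rng.integers(0, n, size=n)
        lb = labels[idx]
        if lb.all() or not lb.any():
            deltas[b] = np.nan
            continue
        deltas[b] = mann_whitney_auc(s1[idx], lb) - mann_whitney_auc(s2[idx], lb)
    deltas = deltas[~np.isnan(deltas)]
    observed = res.auc1 - res.auc2
    # two-sided bootstrap p: is zero inside the resampling distribution?
    p_boot = 2 * min((deltas <= 0).mean(), (deltas >= 0).mean())
    assert abs(res.p_value - min(p_boot, 1.0)) < 0.05
    assert np.sign(observed) == np.sign(np.median(deltas))


def test_dataset_rows_and_flags(cohort):
    records = cohort.records
    data = build_single_molecule_dataset(records, "DQ")
    dq_records = [r for r in records if r.locus == "DQ"]
    assert len(data) == len(dq_records)
    assert data["dsa"].sum() == sum(r.dsa for r in dq_records)
    per_pair = data.groupby("pair_id").size()
    assert per_pair.max() <= 2  # at most two mismatched DQ molecules per pair


def test_thresholds_table_structure(cohort):
    thresholds = derive_thresholds(cohort.records)
    assert set(thresholds["method"]) <= set(METHODS)
    assert ((thresholds["youden_j"] >= -1e-12) & (thresholds["youden_j"] <= 1)).all()
    assert ((thresholds["auc"] >= 0) & (thresholds["auc"] <= 1)).all()
    # thresholds are observed score values of their own dataset
    for row in thresholds.itertuples(index=False):
        data = build_single_molecule_dataset(cohort.records, row.locus)
        assert row.threshold in set(data[row.method].astype(float))


def test_correlation_matrix_properties(cohort):
    r, p = score_correlation_matrix(cohort.records, "DQ")
    for m in METHODS:
        assert r.loc[m, m] == pytest.approx(1.0)
    assert np.allclose(r.to_numpy(), r.to_numpy().T, equal_nan=True)
    assert ((p.fillna(0.5) >= 0) & (p.fillna(0.5) <= 1)).all().all()


def test_correlation_anticorrelated_and_constant():
    from hlamm.scoring import MismatchRecord, MismatchScoreSet, Molecule

    records = []
    for i, (a, e) in enumerate([(1, 9.0), (2, 8.0), (3, 7.0), (4, 6.0)]):
        records.append(
            MismatchRecord(
                f"P{i}", "A", Molecule("A", f"A*{i}", (f"A*{i}",)),
                MismatchScoreSet(1, a, e, 5, 5),
            )
        )
    r, p = score_correlation_matrix(records)
    assert r.loc["AAMS", "EMS3D"] == pytest.approx(-1.0)
    assert np.isnan(r.loc["AAMS", "netMHC"])  # zero-variance score -> missing
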