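"""Folds, metrics, DeLong comparison, ensemble weighting, nested CV and
cross-cohort transfer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ragnet import (accuracy, auc_rank, compare_auc,
                    cross_cohort_transfer, cross_validated_ensemble,
                    ensemble_predict, fit_weight, make_folds, nested_select_k)
from ragnet.predictor import delong_variance


def pair_count_auc(scores, labels):
    """Brute-force concordant-pair fraction with ties counted 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = wins = 0.0
    for p in pos:
        for q in neg:
            total += 1
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / total


# ---------------------------------------------------------------------------
# make_folds
# ---------------------------------------------------------------------------

def test_balanced_folds_have_equal_class_counts():
    y = np.array([0, 1] * 50)
    folds = make_folds(y, n_folds=10, seed=1)
    for f in range(1, 11):
        sel = folds == f
        assert sel.sum() == 10
        assert y[sel].sum() == 5


def test_fold_plan_deterministic_under_seed():
    y = np.array([0] * 40 + [1] * 60)
    np.testing.assert_array_equal(make_folds(y, seed=9), make_folds(y, seed=9))


def test_unbalanced_fold_proportions_within_one_sample():
    y = np.array([1] * 61 + [0] * 39)
    folds = make_folds(y, n_folds=10, seed=2)
    for f in range(1, 11):
        n_pos = int(y[folds == f].sum())
        assert n_pos in (6, 7)  # 61/10 -> 6 or 7 positives (counting oracle)


def test_too_few_class_members_for_folds():
    with pytest.raises(ValueError, match="folds"):
        make_folds(np.array([0] * 50 + [1] * 5), n_folds=10)


# ---------------------------------------------------------------------------
# accuracy / auc_rank
# ---------------------------------------------------------------------------

def test_accuracy_examples_and_count_oracle():
    assert accuracy([1, 0, 1], [1, 0, 1]) == 1.0
    pred = [1, 1, 1, 0, 0, 0, 0, 0, 1, 1]
    y = [1, 1, 1, 1, 1, 0, 0, 1, 0, 0]
    # TP=3, TN=2 -> 0.5
    assert accuracy(pred, y) == 0.5
    rng = np.random.default_rng(3)
    p = rng.integers(0, 2, 40)
    t = rng.integers(0, 2, 40)
    tp = int(((p == 1) & (t == 1)).sum())
    tn = int(((p == 0) & (t == 0)).sum())
    assert accuracy(p, t) == (tp + tn) / 40


def test_auc_separation_and_ties():
    assert auc_rank([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert auc_rank([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_auc_matches_pair_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 25
    y = np.zeros(n, int)
    y[: rng.integers(1, n)] = 1
    rng.shuffle(y)
    s = np.round(rng.normal(size=n), 1)  # rounding forces some ties
    assert auc_rank(s, y) == pytest.approx(pair_count_auc(s, y), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 50)
    y[0], y[1] = 0, 1
    s = rng.normal(size=50)
    assert auc_rank(s, y) == pytest.approx(auc_rank(np.exp(3 * s), y))


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        auc_rank([0.1, 0.2], [1, 1])


# ---------------------------------------------------------------------------
# compare_auc
# ---------------------------------------------------------------------------

def test_identical_scores_give_p_one():
    s = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
    y = np.array([0, 0, 1, 1, 1, 0])
    assert compare_auc(s, s, y).pvalue == 1.0


def test_delong_variance_matches_hand_structural_components():
    """3 positives / 3 negatives hand example: V10/V01 computed directly
    from the pairwise indicator definition."""
    s = np.array([0.9, 0.7, 0.3, 0.8, 0.4, 0.2])
    y = np.array([1, 1, 1, 0, 0, 0])
    pos, neg = s[y == 1], s[y == 0]
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)          # per-positive components
    v01 = psi.mean(axis=0)          # per-negative components
    expected = v10.var(ddof=1) / 3 + v01.var(ddof=1) / 3
    assert delong_variance(s, y) == pytest.approx(expected, abs=1e-12)


def test_degenerate_variance_raises():
    # perfect separation in both arms but different scores: zero variance
    y = np.array([1, 1, 0, 0])
    a = np.array([1.0, 1.0, 0.0, 0.0])
    b = np.array([0.9, 0.9, 0.1, 0.1])
    with pytest.raises(ValueError, match="degenerate"):
        compare_auc(a, b, y)


def test_bootstrap_alternative_runs():
    rng = np.random.default_rng(5)
    y = np.array([0, 1] * 30)
    a = y + rng.normal(0, 1.0, 60)
    b = y + rng.normal(0, 1.5, 60)
    res = compare_auc(a, b, y, method="bootstrap", n_boot=200, seed=1)
    assert 0.0 < res.pvalue <= 1.0


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

def test_ensemble_endpoints_and_paper_style_weight():
    p_snp = np.array([1.0, 0.2])
    p_clin = np.array([0.0, 0.6])
    np.testing.assert_array_equal(ensemble_predict(p_snp, p_clin, 0.0), p_clin)
    np.testing.assert_array_equal(ensemble_predict(p_snp, p_clin, 1.0), p_snp)
    # a 0.27 genetic weight: confident genetic call alone stays below 0.5
    out = ensemble_predict(np.array([1.0]), np.array([0.0]), 0.27)
    assert out[0] == pytest.approx(0.27)
    assert out[0] < 0.5


def test_fit_weight_equals_exhaustive_grid_search_oracle():
    rng = np.random.default_rng(6)
    y = rng.integers(0, 2, 40)
    p_snp = np.clip(y * 0.5 + rng.uniform(0, 0.6, 40), 0, 1)
    p_clin = np.clip(y * 0.3 + rng.uniform(0, 0.8, 40), 0, 1)
    grid = np.round(np.arange(0, 1.01, 0.01), 2)
    w_star, table = fit_weight(p_snp, p_clin, y, grid)
    best_acc = -1.0
    best_w = None
    for w in grid:  # independent exhaustive search
        acc = np.mean(((w * p_snp + (1 - w) * p_clin) >= 0.5) == y)
        if acc > best_acc:
            best_acc, best_w = acc, float(w)
    assert w_star == best_w
    assert table["accuracy"].max() == pytest.approx(best_acc)


def test_mismatched_arms_rejected():
    with pytest.raises(ValueError):
        ensemble_predict(np.zeros(3), np.zeros(4), 0.5)


# ---------------------------------------------------------------------------
# nested CV and full ensemble
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cv_result(small_data, small_bundle, small_network):
    return cross_validated_ensemble(
        small_data, small_bundle, small_network, k_grid=[5, 10, 15, 20],
        strategy="network_score", n_pcs=5, seed=11)


def test_cv_selects_k_from_grid_with_valid_probabilities(cv_result,
                                                         small_data):
    assert cv_result.k_star in (5, 10, 15, 20)
    assert ((cv_result.p_snp >= 0) & (cv_result.p_snp <= 1)).all()
    assert ((cv_result.p_final >= 0) & (cv_result.p_final <= 1)).all()
    assert len(cv_result.fold_snp_sets) == 10
    assert cv_result.acc_curve.shape[0] == 4


def test_cv_mean_accuracy_is_mean_of_fold_accuracies(cv_result):
    assert cv_result.mean_accuracy == pytest.approx(
        cv_result.fold_accuracies.mean())


def test_cv_detects_signal_on_simulated_cohort(cv_result):
    # strong causal + clinical effects: must beat chance comfortably
    assert cv_result.mean_accuracy > 0.6
    assert cv_result.auc > 0.6


def test_cv_deterministic_under_seed(small_data, small_bundle, small_network):
    a = cross_validated_ensemble(small_data, small_bundle, small_network,
                                 k_grid=[5, 10], n_pcs=3, seed=4)
    b = cross_validated_ensemble(small_data, small_bundle, small_network,
                                 k_grid=[5, 10], n_pcs=3, seed=4)
    assert a.k_star == b.k_star and a.w_star == b.w_star
    np.testing.assert_array_equal(a.p_final, b.p_final)
    assert a.fold_snp_sets == b.fold_snp_sets


def test_training_partition_missing_a_class_raises(small_data, small_bundle,
                                                   small_network):
    fold_ids = np.ones(len(small_data.y), dtype=int)
    fold_ids[small_data.y == 1] = 2  # fold 2 training set has no cases
    with pytest.raises(ValueError, match="lost a class"):
        nested_select_k(small_data, small_bundle, small_network, fold_ids,
                        [5], "network_score", n_pcs=2)


# ---------------------------------------------------------------------------
# cross-cohort transfer
# ---------------------------------------------------------------------------

def test_transfer_identity_cohort_finds_all_and_beats_chance(small_data):
    snps = list(small_data.genotypes.variant_ids[:30]) \
        + sorted(set(small_data.genotypes.variant_ids)
                 & set())  # keep explicit list form
    report = cross_cohort_transfer(snps, small_data, seed=11)
    assert report.missing == []
    assert len(report.found) == 30
    assert report.fold_accuracies is not None


def test_transfer_reports_missing_ids_exactly(small_data):
    snps = list(small_data.genotypes.variant_ids[:5]) + ["rsX1", "rsX2"]
    report = cross_cohort_transfer(snps, small_data, seed=0)
    assert report.missing == ["rsX1", "rsX2"]
    assert len(report.found) == 5


def test_transfer_refuses_with_zero_overlap(small_data):
    report = cross_cohort_transfer(["nope1", "nope2"], small_data)
    assert report.refused
    assert report.mean_accuracy is None
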