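"""Outcome classing, variant QC, HWE exactness, PCA and association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from ragnet import (GenotypeMatrix, classify_progression, compute_pcs,
                    hwe_exact_p, logistic_assoc, qc_filter)
from ragnet.qc_assoc import hwe_chisq_p


def _matrix(dosage, positions=None):
    dosage = np.asarray(dosage, dtype=float)
    n, v = dosage.shape
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n)],
        variant_ids=[f"v{j}" for j in range(v)],
        positions=positions if positions is not None else np.arange(v) * 1000,
        ref=["A"] * v, alt=["G"] * v, dosage=dosage)


def hwe_enumeration_oracle(n_hom1, n_het, n_hom2):
    """Direct enumeration over all heterozygote counts with the observed
    allele counts, using exact log-multinomial conditional probabilities."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    probs = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom1 = (n_a - het) // 2
        hom2 = n - het - hom1
        logp = (gammaln(n + 1) - gammaln(hom1 + 1) - gammaln(het + 1)
                - gammaln(hom2 + 1) + het * np.log(2)
                + gammaln(n_a + 1) + gammaln(2 * n - n_a + 1)
                - gammaln(2 * n + 1))
        probs[het] = np.exp(logp)
    p_obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


# ---------------------------------------------------------------------------
# classify_progression
# ---------------------------------------------------------------------------

def test_two_xray_rate_arithmetic():
    labels = classify_progression([10, 0, 5], [20, 3, 5], [2, 1, 1])
    assert labels.rate[0] == 5.0
    assert labels.rate[1] == 3.0


def test_one_xray_rate_arithmetic():
    labels = classify_progression(total_shs=[30, 10, 2],
                                  disease_years=[10, 5, 1], mode="one_xray")
    assert labels.rate[0] == 3.0


def test_tertile_labels_on_explicit_rate_vector():
    """Rates 1..9: the bottom three are no-progression, top three severe,
    middle three excluded (quantile oracle on the explicit vector)."""
    base = np.zeros(9)
    follow = np.arange(1.0, 10.0)
    labels = classify_progression(base, follow, np.ones(9))
    by_rate = {r: l for r, l in zip(labels.rate, labels.label)}
    assert all(by_rate[r] == "no_progression" for r in (1, 2, 3))
    assert all(by_rate[r] == "severe" for r in (7, 8, 9))
    assert all(by_rate[r] == "excluded" for r in (4, 5, 6))


def test_nonpositive_interval_excluded_with_error_record():
    labels = classify_progression([0] * 5, [1, 2, 3, 4, 5], [1, 1, 1, 1, 0])
    assert labels.label[4] == "excluded"
    assert labels.errors and labels.errors[0][0] == 4


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def test_hwe_degenerate_and_equilibrium_cases():
    assert hwe_exact_p(0, 0, 50) == 1.0
    assert hwe_exact_p(25, 50, 25) == pytest.approx(
        hwe_enumeration_oracle(25, 50, 25))
    # heavy heterozygote deficit is extreme under the exact test
    assert hwe_exact_p(40, 20, 40) == pytest.approx(
        hwe_enumeration_oracle(40, 20, 40))
    assert hwe_exact_p(40, 20, 40) < 1e-8


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
def test_hwe_matches_enumeration_oracle(a, b, c):
    if a + b + c == 0:
        return
    assert hwe_exact_p(a, b, c) == pytest.approx(
        hwe_enumeration_oracle(a, b, c), rel=1e-9)


def test_hwe_chisq_agrees_in_large_balanced_samples():
    # same qualitative decision as exact test away from sparse cells
    assert hwe_chisq_p(250, 500, 250) == pytest.approx(1.0)
    assert hwe_chisq_p(400, 200, 400) < 1e-10


# ---------------------------------------------------------------------------
# qc_filter
# ---------------------------------------------------------------------------

def test_qc_maf_threshold_is_inclusive():
    # 1000 samples, 10 alt alleles -> MAF exactly 0.005
    dosage = np.zeros((1000, 1))
    dosage[:10, 0] = 1.0
    _, report = qc_filter(_matrix(dosage), maf_min=0.005, hwe_min=0.0)
    assert report.table["maf"].iloc[0] == pytest.approx(0.005)
    assert bool(report.table["pass_flag"].iloc[0])


def test_qc_filters_call_rate_and_hwe():
    rng = np.random.default_rng(0)
    good = rng.binomial(2, 0.3, size=(200, 1)).astype(float)
    sparse = good.copy()
    sparse[:20] = np.nan                      # call rate 0.9
    bad_hwe = np.concatenate([np.zeros(100), np.full(100, 2.0)])[:, None]
    g = _matrix(np.hstack([good, sparse, bad_hwe]))
    kept, report = qc_filter(g, maf_min=0.01, callrate_min=0.95,
                             hwe_min=5e-7)
    assert list(kept.variant_ids) == ["v0"]
    assert report.table["pass_flag"].tolist() == [True, False, False]


def test_qc_is_idempotent(small_cohort):
    g1, _ = qc_filter(small_cohort.genotypes)
    g2, _ = qc_filter(g1)
    np.testing.assert_array_equal(g1.dosage, g2.dosage)
    assert list(g1.variant_ids) == list(g2.variant_ids)


def test_qc_removing_everything_warns():
    dosage = np.zeros((50, 2))  # monomorphic, MAF 0
    with pytest.warns(UserWarning, match="every variant"):
        kept, _ = qc_filter(_matrix(dosage), maf_min=0.05)
    assert kept.n_variants == 0


# ---------------------------------------------------------------------------
# compute_pcs
# ---------------------------------------------------------------------------

def test_pcs_duplicated_samples_coincide_and_loadings_orthogonal():
    rng = np.random.default_rng(1)
    dosage = rng.binomial(2, 0.4, size=(20, 50)).astype(float)
    dosage[1] = dosage[0]
    res = compute_pcs(_matrix(dosage), n_pcs=5)
    np.testing.assert_allclose(res.coords[0], res.coords[1], atol=1e-8)
    # sample coordinates U*S have orthogonal columns by construction
    gram = res.coords.T @ res.coords
    np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)


def test_pc1_variance_matches_dense_eigendecomposition():
    rng = np.random.default_rng(2)
    dosage = rng.binomial(2, 0.3, size=(20, 50)).astype(float)
    res = compute_pcs(_matrix(dosage), n_pcs=5)
    X = (dosage - dosage.mean(0)) / dosage.std(0)
    evals = np.linalg.eigvalsh(X @ X.T)[::-1]
    expected = evals[0] / evals[evals > 1e-9].sum()
    assert res.explained_variance_ratio[0] == pytest.approx(expected, rel=1e-8)


def test_pcs_truncate_beyond_rank_with_warning():
    dosage = np.random.default_rng(3).binomial(2, 0.4, (5, 40)).astype(float)
    with pytest.warns(UserWarning, match="truncating"):
        res = compute_pcs(_matrix(dosage), n_pcs=10)
    assert res.coords.shape[1] <= 5


# ---------------------------------------------------------------------------
# logistic_assoc
# ---------------------------------------------------------------------------

def test_constant_genotype_is_flagged():
    rng = np.random.default_rng(4)
    dosage = np.hstack([np.full((100, 1), 1.0),
                        rng.binomial(2, 0.4, (100, 1)).astype(float)])
    y = rng.integers(0, 2, 100)
    res = logistic_assoc(_matrix(dosage), y)
    assert not res.table["converged"].iloc[0]
    assert "v0" not in res.significant
    assert res.table["converged"].iloc[1]


def test_single_variant_fit_matches_statsmodels_oracle():
    """Printed 2x3 genotype-by-outcome table; log-odds vs an independent
    maximum-likelihood fit within 1e-6."""
    import statsmodels.api as sm

    # cases: 10/30/20 copies 0/1/2; controls: 30/20/10
    dosage = np.concatenate([
        np.repeat([0.0, 1.0, 2.0], [10, 30, 20]),
        np.repeat([0.0, 1.0, 2.0], [30, 20, 10]),
    ])[:, None]
    y = np.concatenate([np.ones(60), np.zeros(60)])
    res = logistic_assoc(_matrix(dosage), y)
    fit = sm.Logit(y, sm.add_constant(dosage)).fit(disp=0)
    assert res.table["beta"].iloc[0] == pytest.approx(fit.params[1], abs=1e-6)
    assert res.table["se"].iloc[0] == pytest.approx(fit.bse[1], abs=1e-6)
    assert res.table["p"].iloc[0] == pytest.approx(fit.pvalues[1], rel=1e-6)


def test_association_with_covariates_matches_statsmodels(small_data):
    import statsmodels.api as sm

    g = small_data.genotypes.subset(variants=np.arange(5))
    res = logistic_assoc(g, small_data.y, covariates=small_data.clinical)
    Z = np.column_stack([np.ones(g.n_samples),
                         small_data.clinical.to_numpy(float)])
    for j in range(5):
        d = g.dosage[:, j]
        ok = ~np.isnan(d)
        fit = sm.Logit(small_data.y[ok],
                       np.column_stack([Z[ok], d[ok]])).fit(disp=0)
        assert res.table["p"].iloc[j] == pytest.approx(fit.pvalues[-1],
                                                       rel=1e-5)


def test_association_invariant_to_sample_and_variant_order(small_data):
    g = small_data.genotypes.subset(variants=np.arange(40))
    base = logistic_assoc(g, small_data.y, covariates=small_data.clinical)
    rng = np.random.default_rng(7)
    sp = rng.permutation(g.n_samples)
    vp = rng.permutation(40)
    g2 = g.subset(samples=sp, variants=vp)
    perm = logistic_assoc(g2, small_data.y[sp],
                          covariates=small_data.clinical.iloc[sp]
                          .reset_index(drop=True))
    a = base.table.set_index("variant_id")["p"]
    b = perm.table.set_index("variant_id")["p"]
    np.testing.assert_allclose(a.loc[b.index], b, rtol=1e-6)


def test_pure_noise_covariate_barely_moves_pvalues(small_data):
    g = small_data.genotypes.subset(variants=np.arange(60))
    base = logistic_assoc(g, small_data.y)
    noise = pd.DataFrame(
        {"noise": np.random.default_rng(8).normal(size=g.n_samples)})
    noisy = logistic_assoc(g, small_data.y, covariates=noise)
    shift = np.abs(-np.log10(base.table["p"]) + np.log10(noisy.table["p"]))
    assert np.nanmedian(shift) < 0.2
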