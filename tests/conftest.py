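import pandas as pd
import pytest

from ragnet import (AnnotationBundle, CohortData, SimulationConfig,
                    classify_progression, simulate_annotations,
                    simulate_cohort, simulate_network_priors)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_samples=180, n_variants=300, n_genes=80,
                            n_causal_snps=5, causal_odds_ratio=2.5, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_config, small_cohort):
    return simulate_annotations(small_config, small_cohort)


@pytest.fixture(scope="session")
def small_network(small_config, small_bundle, small_cohort):
    return simulate_network_priors(small_config, small_bundle, small_cohort)


@pytest.fixture(scope="session")
def small_data(small_cohort):
    labels = classify_progression(small_cohort.shs_baseline,
                                  small_cohort.shs_followup,
                                  small_cohort.xray_interval_years)
    keep, y = labels.binary()
    return CohortData(
        genotypes=small_cohort.genotypes.subset(samples=keep),
        y=y,
        clinical=small_cohort.clinical.iloc[keep].reset_index(drop=True),
    )


@pytest.fixture()
def toy_bundle():
    """Hand-built annotation bundle on a 100 kb toy genome.

    Gene layout: GA (+ strand, body [10000, 15000)), GB (- strand, body
    [30000, 34000)), GC (+ strand, [50000, 58000)); one enhancer linked to
    GA and GC, one miRNA targeting GB, eQTL links, and a small LD table.
    """
    genes = pd.DataFrame({
        "gene": ["GA", "GB", "GC"],
        "start": [10000, 30000, 50000],
        "end": [15000, 34000, 58000],
        "strand": ["+", "-", "+"],
    })
    enhancers = pd.DataFrame({
        "enhancer_id": ["E1"], "start": [70000], "end": [70500],
    })
    enh_links = pd.DataFrame({
        "enhancer_id": ["E1", "E1"], "gene": ["GA", "GC"],
    })
    mirna = pd.DataFrame({
        "mirna_id": ["M1"], "start": [80000], "end": [80100],
    })
    mir_links = pd.DataFrame({"mirna_id": ["M1"], "gene": ["GB"]})
    eqtl = pd.DataFrame({
        "snp": ["snp_eqtl", "snp_eqtl_ns"],
        "gene": ["GC", "GA"],
        "tissue": ["PBMC", "PBMC"],
        "significant": [True, False],
    })
    ld = pd.DataFrame({
        "snp_a": ["snp_idx", "snp_idx", "snp_a3"],
        "snp_b": ["snp_proxy_hi", "snp_proxy_lo", "snp_b3"],
        "r2": [0.95, 0.80, 0.9],
    })
    return AnnotationBundle(
        gene_intervals=genes, enhancer_intervals=enhancers,
        enhancer_gene_links=enh_links, mirna_intervals=mirna,
        mirna_target_links=mir_links, eqtl_links=eqtl, ld_proxies=ld)
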