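"""Seeded synthetic cohorts, annotation tables and disease-network priors.

The generator emulates the statistical structure the pipeline assumes: a
biallelic genotype matrix at configurable MAF/missingness regimes, a
radiographic-progression phenotype driven jointly by a small set of causal
SNPs and six clinical covariates, LD proxies with controlled r², functional
annotation tracks guaranteeing every causal SNP maps to at least one gene,
and a scale-free gene network whose causal genes sit near disease-prior
genes.  Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .disease_network import DiseaseNetwork
from .qc_assoc import GenotypeMatrix
from .snp2gene import AnnotationBundle, map_snp_to_genes

EVIDENCE_CYCLE = ("gene_body", "promoter", "enhancer", "mirna_target", "eqtl")
CLINICAL_COLUMNS = ("baseline_shs", "disease_duration", "haq",
                    "anti_ccp", "bmi", "esr")
EQTL_TISSUES = ("PBMC", "monocyte", "CD4_T", "lymphoblastoid")


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    ``causal_odds_ratio`` is the per-allele odds ratio of each causal SNP on
    the progression liability; ``clinical_effects`` are the liability
    coefficients of the six standardized clinical covariates in the order
    (baseline SHS, disease duration, HAQ, anti-CCP positivity, BMI, ESR).
    ``fraction_unmapped`` controls how many non-causal variants receive no
    functional annotation at all.
    """

    n_samples: int = 240
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    n_genes: int = 300
    n_causal_snps: int = 10
    causal_odds_ratio: float = 1.8
    clinical_effects: tuple[float, ...] = (0.4, 0.2, 0.3, 0.6, -0.1, 0.3)
    network_degree_param: float = 2.0
    prior_disease_count: int = 8
    seed: int = 0
    # secondary structure knobs
    proxies_per_causal: int = 2
    proxy_r2: float = 0.9
    n_decoy_ld_pairs: int = 5
    fraction_unmapped: float = 0.5
    liability_noise_sd: float = 1.0
    variant_spacing: int = 1000

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_variants", "n_genes", "n_causal_snps",
                     "prior_disease_count"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must lie in [0, 1)")
        if self.n_causal_snps > self.n_variants:
            raise InvalidConfigError("n_causal_snps exceeds n_variants")
        if len(self.clinical_effects) != 6:
            raise InvalidConfigError("clinical_effects must have 6 entries")
        if self.causal_odds_ratio <= 0:
            raise InvalidConfigError("causal_odds_ratio must be positive")
        if self.network_degree_param <= 0:
            raise InvalidConfigError("network_degree_param must be positive")
        if self.n_genes <= self.n_causal_snps:
            raise InvalidConfigError("n_genes must exceed n_causal_snps")


@dataclass
class CohortFixture:
    """A simulated cohort with genotypes, SHS trajectories and covariates."""

    genotypes: GenotypeMatrix
    shs_baseline: np.ndarray
    shs_followup: np.ndarray
    xray_interval_years: np.ndarray
    disease_duration_years: np.ndarray
    clinical: pd.DataFrame
    causal_variant_ids: set[str]
    ld_pairs: list[tuple[str, str]] = field(default_factory=list)
    liability: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.causal_variant_ids <= set(self.genotypes.variant_ids):
            raise ValueError("causal ids must be a subset of variant ids")
        if (self.shs_followup < 0).any() or (self.shs_baseline < 0).any():
            raise ValueError("SHS scores must be nonnegative")


def simulate_cohort(config: SimulationConfig) -> CohortFixture:
    """Draw genotypes, clinical covariates and SHS trajectories.

    Genotypes are binomial(2, MAF) per variant with independent missingness.
    A latent liability sums the causal per-allele log-odds, the clinical
    linear predictor and Gaussian noise; the yearly SHS progression rate is
    a monotone (exponential) function of the standardized liability, so a
    larger liability always means faster joint damage.  LD proxies of causal
    variants are injected by copying the causal genotype column with
    controlled resampling noise calibrated to the target r².
    """
    rng = np.random.default_rng(config.seed)
    n, V = config.n_samples, config.n_variants
    genome_length = V * config.variant_spacing
    positions = np.sort(rng.choice(genome_length, size=V, replace=False))
    variant_ids = np.array([f"rs{i + 1:06d}" for i in range(V)], dtype=object)
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=V)
    dosage = rng.binomial(2, mafs[None, :], size=(n, V)).astype(float)

    causal_idx = np.sort(rng.choice(V, size=config.n_causal_snps, replace=False))
    taken = set(causal_idx.tolist())
    ld_pairs: list[tuple[str, str]] = []

    def _copy_with_noise(src_idx: int, dst_idx: int, keep_prob: float) -> None:
        col = dosage[:, src_idx].copy()
        redraw = rng.random(n) >= keep_prob
        col[redraw] = rng.binomial(2, mafs[src_idx], size=int(redraw.sum()))
        dosage[:, dst_idx] = col
        mafs[dst_idx] = mafs[src_idx]

    free = [i for i in range(V) if i not in taken]
    rng.shuffle(free)
    keep_prob = float(np.sqrt(config.proxy_r2))  # dosage corr ~ keep_prob
    for ci in causal_idx:
        for _ in range(config.proxies_per_causal):
            if not free:
                break
            pi = free.pop()
            taken.add(pi)
            _copy_with_noise(ci, pi, keep_prob)
            ld_pairs.append((variant_ids[ci], variant_ids[pi]))
    # weak decoy pairs that must stay below any sensible r² threshold
    for _ in range(config.n_decoy_ld_pairs):
        if len(free) < 2:
            break
        a, b = free.pop(), free.pop()
        _copy_with_noise(a, b, 0.4)
        ld_pairs.append((variant_ids[a], variant_ids[b]))

    # clinical covariates: anti-CCP Bernoulli, the rest plausible continuous
    clinical = pd.DataFrame({
        "baseline_shs": np.round(rng.gamma(2.0, 4.0, size=n), 1),
        "disease_duration": np.round(rng.gamma(2.0, 2.0, size=n) + 0.5, 2),
        "haq": np.round(rng.uniform(0.0, 3.0, size=n), 2),
        "anti_ccp": rng.binomial(1, 0.7, size=n).astype(float),
        "bmi": np.round(rng.normal(23.0, 3.0, size=n), 1),
        "esr": np.round(rng.gamma(2.0, 15.0, size=n), 1),
    })

    log_or = np.log(config.causal_odds_ratio)
    centered = dosage[:, causal_idx] - 2.0 * mafs[causal_idx]
    genetic = log_or * centered.sum(axis=1)
    z = (clinical - clinical.mean()) / clinical.std(ddof=0).replace(0.0, 1.0)
    clin_score = z.to_numpy() @ np.asarray(config.clinical_effects, dtype=float)
    liability = genetic + clin_score + rng.normal(0.0, config.liability_noise_sd, n)

    sd = liability.std()
    lz = (liability - liability.mean()) / sd if sd > 0 else np.zeros(n)
    rate = np.exp(np.log(3.0) + 0.8 * lz)  # yearly SHS rate, median ~3
    interval = rng.uniform(1.5, 4.0, size=n)
    shs_baseline = clinical["baseline_shs"].to_numpy()
    shs_followup = shs_baseline + rate * interval

    if config.missing_rate > 0:
        dosage[rng.random((n, V)) < config.missing_rate] = np.nan

    genotypes = GenotypeMatrix(
        sample_ids=np.array([f"S{i + 1:04d}" for i in range(n)], dtype=object),
        variant_ids=variant_ids,
        positions=positions,
        ref=np.full(V, "A", dtype=object),
        alt=np.full(V, "G", dtype=object),
        dosage=dosage,
    )
    return CohortFixture(
        genotypes=genotypes,
        shs_baseline=shs_baseline,
        shs_followup=shs_followup,
        xray_interval_years=interval,
        disease_duration_years=clinical["disease_duration"].to_numpy(),
        clinical=clinical,
        causal_variant_ids=set(variant_ids[causal_idx]),
        ld_pairs=ld_pairs,
        liability=liability,
    )


def _empirical_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
        return 0.0
    return float(np.corrcoef(a[ok], b[ok])[0, 1] ** 2)


def simulate_annotations(config: SimulationConfig,
                         cohort: CohortFixture) -> AnnotationBundle:
    """Generate annotation tracks so every causal SNP maps to >= 1 gene.

    Causal and a (1 - fraction_unmapped) share of non-causal variants are
    anchored to genes through a rotating evidence source (gene body,
    promoter, enhancer, miRNA target, eQTL).  Intervals (and the 2 kb
    promoter windows genes imply) are constrained never to cover a variant
    designated unmapped — an anchor that cannot fit between its unmapped
    neighbours falls back to a position-free eQTL link — so the unmapped
    fraction is a guarantee, not an expectation.  Leftover gene budget is
    placed in a gene-only zone beyond the variant region.  The LD-proxy
    table reports the empirical r² of the injected proxy and decoy pairs.
    """
    from .snp2gene import PROMOTER_BP

    rng = np.random.default_rng(config.seed + 104729)
    g = cohort.genotypes
    pos_of = dict(zip(g.variant_ids, g.positions))
    region_end = config.n_variants * config.variant_spacing
    filler_zone = (region_end + PROMOTER_BP + 1, region_end + 60_000)

    causal = sorted(cohort.causal_variant_ids)
    noncausal = [v for v in g.variant_ids if v not in cohort.causal_variant_ids]
    n_mapped = int(round((1.0 - config.fraction_unmapped) * len(noncausal)))
    mapped_j = rng.choice(len(noncausal), size=n_mapped, replace=False)
    mapped_noncausal = [noncausal[int(j)] for j in sorted(mapped_j)]
    unmapped = sorted(
        int(pos_of[v]) for v in noncausal
        if v not in set(mapped_noncausal))

    def _avoid_bounds(pos: int) -> tuple[int, int]:
        """Open interval between the nearest unmapped-variant neighbours."""
        i = np.searchsorted(unmapped, pos)
        lo = unmapped[i - 1] if i > 0 else -(10 ** 9)
        hi = unmapped[i] if i < len(unmapped) else 10 ** 9
        return lo, hi

    genes: list[tuple[str, int, int, str]] = []
    enh_rows: list[tuple[str, int, int]] = []
    enh_links: list[tuple[str, str]] = []
    mir_rows: list[tuple[str, int, int]] = []
    mir_links: list[tuple[str, str]] = []
    eqtl_rows: list[tuple[str, str, str, bool]] = []

    def _new_gene(start: int, end: int, strand: str) -> str:
        name = f"G{len(genes) + 1:04d}"
        genes.append((name, max(0, start), end, strand))
        return name

    def _filler_gene() -> str:
        start = int(rng.integers(*filler_zone))
        return _new_gene(start, start + int(rng.integers(2000, 15000)),
                         "+" if rng.random() < 0.5 else "-")

    def _link_target_gene() -> str:
        if len(genes) < config.n_genes and (not genes or rng.random() < 0.5):
            return _filler_gene()
        return genes[int(rng.integers(0, len(genes)))][0]

    def _eqtl_anchor(vid: str) -> None:
        tissue = EQTL_TISSUES[int(rng.integers(0, len(EQTL_TISSUES)))]
        eqtl_rows.append((vid, _link_target_gene(), tissue, True))

    def _anchor(vid: str, source: str) -> None:
        pos = int(pos_of[vid])
        lo, hi = _avoid_bounds(pos)  # created intervals must stay in (lo, hi)
        if source == "gene_body" and len(genes) < config.n_genes:
            # promoter spill: '+' gene needs 2 kb clear below its start
            if pos - lo > PROMOTER_BP + 1:
                start = int(rng.integers(max(lo + PROMOTER_BP + 1, pos - 1500),
                                         pos + 1))
                end = int(rng.integers(pos + 1, min(hi, pos + 1500) + 1))
                _new_gene(start, end, "+")
                return
            if hi - pos > PROMOTER_BP + 1:
                start = int(rng.integers(max(lo + 1, pos - 1500), pos + 1))
                end = int(rng.integers(pos + 1,
                                       min(hi - PROMOTER_BP, pos + 1500) + 1))
                _new_gene(start, end, "-")
                return
            source = "enhancer"
        if source == "promoter" and len(genes) < config.n_genes:
            # '+' gene whose [TSS-2000, TSS) window covers pos
            tss_lo = max(pos + 1, lo + PROMOTER_BP + 1)
            tss_hi = min(pos + PROMOTER_BP, hi - 2)
            if tss_lo <= tss_hi:
                tss = int(rng.integers(tss_lo, tss_hi + 1))
                end = int(rng.integers(tss + 1, min(hi, tss + 12_000)))
                _new_gene(tss, end, "+")
                return
            source = "enhancer"
        if source == "enhancer":
            eid = f"E{len(enh_rows) + 1:04d}"
            enh_rows.append((eid, max(lo + 1, pos - 400), min(hi, pos + 400)))
            enh_links.append((eid, _link_target_gene()))
        elif source == "mirna_target":
            mid = f"MIR{len(mir_rows) + 1:04d}"
            mir_rows.append((mid, max(lo + 1, pos - 80), min(hi, pos + 80)))
            mir_links.append((mid, _link_target_gene()))
        else:
            _eqtl_anchor(vid)

    for i, vid in enumerate(causal):
        _anchor(vid, EVIDENCE_CYCLE[i % len(EVIDENCE_CYCLE)])
    for vid in mapped_noncausal:
        _anchor(vid, EVIDENCE_CYCLE[int(rng.integers(0, len(EVIDENCE_CYCLE)))])

    while len(genes) < config.n_genes:
        _filler_gene()

    gene_df = pd.DataFrame(genes, columns=["gene", "start", "end", "strand"])
    # a few pre-thresholded-out eQTL rows the mapper must ignore
    for _ in range(min(10, len(noncausal))):
        vid = noncausal[int(rng.integers(0, len(noncausal)))]
        eqtl_rows.append((vid, genes[int(rng.integers(0, len(genes)))][0],
                          EQTL_TISSUES[0], False))

    ld_rows = [(a, b, _empirical_r2(
        g.dosage[:, np.flatnonzero(g.variant_ids == a)[0]],
        g.dosage[:, np.flatnonzero(g.variant_ids == b)[0]]))
        for a, b in cohort.ld_pairs]

    return AnnotationBundle(
        gene_intervals=gene_df,
        enhancer_intervals=pd.DataFrame(enh_rows,
                                        columns=["enhancer_id", "start", "end"]),
        enhancer_gene_links=pd.DataFrame(enh_links,
                                         columns=["enhancer_id", "gene"]),
        mirna_intervals=pd.DataFrame(mir_rows,
                                     columns=["mirna_id", "start", "end"]),
        mirna_target_links=pd.DataFrame(mir_links, columns=["mirna_id", "gene"]),
        eqtl_links=pd.DataFrame(eqtl_rows,
                                columns=["snp", "gene", "tissue", "significant"]),
        ld_proxies=pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2"]),
    )


def simulate_network_priors(
    config: SimulationConfig,
    bundle: AnnotationBundle,
    cohort: CohortFixture | None = None,
    r2_min: float = 0.8,
) -> DiseaseNetwork:
    """Scale-free gene network with GDA/DS priors near the causal genes.

    Uses preferential attachment for the interaction graph.  When the cohort
    is supplied, its causal variants are mapped through the bundle and each
    causal gene is guaranteed a disease-prior gene within two hops (itself
    or a neighbour receives a GDA entry).
    """
    rng = np.random.default_rng(config.seed + 224737)
    gene_list = list(bundle.gene_intervals["gene"])
    n = len(gene_list)
    m = max(1, int(round(config.network_degree_param)))
    graph = nx.barabasi_albert_graph(n, m, seed=int(config.seed % (2**31)))
    W = np.zeros((n, n))
    for u, v in graph.edges():
        w = float(rng.uniform(0.5, 1.0))
        W[u, v] = W[v, u] = w

    diseases = ["RA"] + [f"D{i:02d}" for i in range(1, config.prior_disease_count)]
    other_ds = np.round(rng.uniform(0.1, 0.9, size=len(diseases) - 1), 3)
    ds = pd.DataFrame({
        "disease": diseases,
        "score": [1.0] + [float(x) for x in other_ds],
    })

    gda_rows: list[tuple[str, str, float]] = []
    n_prior = max(1, n // 10)
    prior_idx = rng.choice(n, size=n_prior, replace=False)
    for gi in prior_idx:
        k_dis = min(len(diseases), int(rng.integers(1, 3)))
        for d in rng.choice(diseases, size=k_dis, replace=False):
            gda_rows.append((gene_list[gi], str(d),
                             float(np.round(rng.uniform(0.3, 1.0), 3))))

    if cohort is not None:
        # causal genes sit next to high-GDA target-disease genes: the gene
        # itself or a direct neighbour always carries a strong prior
        causal = sorted(cohort.causal_variant_ids)
        pos_of = dict(zip(cohort.genotypes.variant_ids,
                          cohort.genotypes.positions))
        cmap = map_snp_to_genes(causal, pos_of, bundle, r2_min=r2_min)
        causal_genes = sorted({gn for s in causal for gn in cmap.genes(s)})
        index_of = {gn: i for i, gn in enumerate(gene_list)}
        for gn in causal_genes:
            gi = index_of[gn]
            nbrs = list(graph.neighbors(gi))
            pick = gn if (not nbrs or rng.random() < 0.5) \
                else gene_list[nbrs[int(rng.integers(0, len(nbrs)))]]
            gda_rows.append((pick, "RA",
                             float(np.round(rng.uniform(0.6, 1.0), 3))))

    gda = pd.DataFrame(gda_rows, columns=["gene", "disease", "score"])
    gda = gda.drop_duplicates(subset=["gene", "disease"], keep="last")
    return DiseaseNetwork(genes=gene_list, adjacency=W, gda=gda, ds=ds,
                         target_disease="RA")
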