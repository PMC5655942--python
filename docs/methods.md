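# Methods

`ragnet` predicts severe radiographic progression in rheumatoid arthritis
(RA) from genome-wide SNP data plus six clinical covariates. Its premise is
that at cohort sizes of a few hundred patients, per-SNP association
p-values are too noisy to select a stable predictive SNP set, whereas
biological evidence — which genes a SNP touches, and how close those genes
sit to known disease genes in an interaction network — is sample-independent
and therefore both more stable across training subsets and more likely to
tag truly relevant loci. The pipeline implements that idea end to end and
evaluates it against a plain p-value-ranking baseline under nested
cross-validation.

## Outcome definition

Radiographic damage is quantified by the Sharp/van der Heijde score (SHS).
With two hand X-rays per patient the yearly progression rate is
(SHS_followup − SHS_baseline) / interval in years; with a single X-ray the
estimated rate is total SHS / disease duration. Patients are split at the
1/3 and 2/3 empirical quantiles of the rate: the low tertile is labelled
*no progression* (class 0), the high tertile *severe progression* (class 1),
and the middle tertile is excluded from analysis. Membership is by quantile
interval (rate ≤ q1 → low, rate ≥ q2 → high); with heavily tied rates a
tertile can hold more than a third of the cohort, which is reported, not
hidden. Samples with non-positive denominators are excluded with a
per-sample error record.

## Variant QC and association scan

Variants pass QC when MAF ≥ 0.005 (inclusive), per-variant call rate ≥ 0.95
(inclusive) and Hardy–Weinberg exact p > 5×10⁻⁷ (strict). The HWE test is
an exact enumeration of the conditional heterozygote distribution given the
allele counts (two-sided: sum of probabilities no larger than the observed
outcome's); an exact test rather than chi-square because the threshold sits
at an extreme tail where the chi-square approximation is unreliable. A
chi-square variant is available as an option.

Association is a per-variant additive logistic regression of severe vs. no
progression, adjusted for the six clinical covariates (baseline SHS,
disease duration, HAQ, anti-CCP positivity, BMI, ESR) and the top ten
genotype principal components, with a Wald test on the genotype term and a
strict p < 0.05 significance filter. The fits are Newton/IRLS iterations
vectorized across all variants simultaneously (shared covariate block plus
one genotype column per variant), which is what makes re-running the scan
inside every cross-validation fold affordable. Samples with a missing
genotype get zero IRLS weight for that variant (per-variant complete-case);
samples with missing covariates are dropped globally with logged counts.
Constant-genotype columns, separated fits (|β| ≥ 15) and non-converged fits
are flagged and never enter the significant set. Wald p-values are
asymptotic; at n ≈ 200 they are mildly conservative in the far-from-0.05
range, which matters only for distribution-level uniformity checks, not for
the 0.05 rejection rate (calibrated to within ±0.01 at that n).

PCA mean-imputes missing dosages per variant, standardizes, and takes the
thin SVD; no LD pruning by default. Samples beyond 6 SD on any top-10 PC
are flagged for reporting only.

## SNP-to-gene mapping

Each significant SNP is expanded to its LD proxy set — itself plus every
partner with r² strictly above 0.8 in the proxy table (symmetrized, no
transitive closure) — and the union of the following evidence is collected
over the set:

- **gene body**: the position lies in a gene interval (0-based half-open);
- **promoter**: the position lies in the 2 kb window upstream of the TSS —
  [TSS−2000, TSS) on the + strand and the mirrored window [end, end+2000)
  on the − strand;
- **enhancer**: the position lies in an enhancer interval; the enhancer's
  linked genes are attached;
- **miRNA target**: the position lies in a miRNA gene region; the miRNA's
  target genes are attached;
- **eQTL**: a pre-thresholded significant eQTL link exists for the SNP.

Evidence sources are recorded per (SNP, gene) pair but never weighted;
proxy-derived and direct mappings count identically. An unmappable SNP
keeps an empty gene set and a zero reprioritization score.

## Disease network prior and propagation

Gene–disease association scores GDA(v, d) ∈ [0, 1] and disease-similarity
scores DS(d, target) ∈ [0, 1] (target disease at 1) seed a prior per gene

    Y(v) = max_d GDA(v, d) · DS(d, target),

zero for genes without any association. The interaction network W
(symmetric, nonnegative, no self-loops; unit weights if the edge list has
no weight column) is degree-normalized as W′ᵢⱼ = Wᵢⱼ/√(DᵢDⱼ), whose
spectral radius is ≤ 1. The prior is then diffused by iterating

    F ← α W′ F + (1 − α) Y,   F₀ = Y,

to the fixed point F = (1 − α)(I − αW′)⁻¹Y. F is nonnegative, bounded below
by (1 − α)Y elementwise, monotone in Y, and reduces to Y as α → 0. Defaults:
α = 0.5, tolerance 1e−9 on the max-abs update, max 10,000 iterations
(non-convergence raises, carrying the residual); a built-in sensitivity
report recomputes F over α ∈ {0.3, 0.5, 0.7, 0.9}. The propagation restart
parameter is a genuine free choice — no principled value is singled out by
the problem — hence the default mid-range value and the sensitivity report.
An optional logistic squashing of Y before propagation is available behind
a flag but off by default; the literal max-product prior is propagated.

## Reprioritization and selection

A SNP's score is Σ F(g) over its deduplicated mapped genes; genes absent
from the score vector contribute 0 with a log entry. Ranking strategies:
`network_score` (descending score, ties by ascending association p, then
SNP id) and the baseline `gwas_p` (ascending p, ties by id). Zero-score
SNPs stay rankable so any top-k is well-defined. The candidate k grid is
10, 15, 20, … (configurable cap), i.e. growing from ten in steps of five.

Selection stability across training sets is summarized by the overlap
ratio: the mean pairwise Jaccard index |A∩B|/|A∪B| over all unordered
pairs of per-fold selected sets. Jaccard is one of several defensible
definitions of "overlap ratio"; comparisons with externally reported
overlap numbers should check the definition first.

## Nested cross-validation and the ensemble

Samples are split into ten stratified folds (per-fold class counts within
one of proportionality, deterministic under the seed). For each fold the
*entire* upstream pipeline — PCA, association scan, significance filter,
mapping, ranking — is recomputed on the nine training folds only; for each
k in the grid an RBF-kernel SVM on the top-k SNP dosages (training-fold
mean imputation and standardization) is scored on the held-out fold. k* is
the grid value maximizing mean held-out accuracy, ties resolved to the
smallest k (parsimony). Network gene scores F involve no sample data and
are computed once.

Two probability arms: the genetic arm above, and a clinical arm (RBF SVM on
the six standardized covariates). SVM hyperparameters are C = 1 and
gamma = 1/(n_features · variance); probabilities come from Platt-style
sigmoid calibration fitted by internal cross-validation within the training
partition only. The ensemble is p = w·p_SNP + (1−w)·p_clin with w chosen on
the pooled held-out probabilities over a [0, 1] grid (step 0.01, ties to
the smaller w, endpoints included — so the ensemble can never be worse than
either single arm on the pooled criterion). Decision threshold 0.5.

Metrics: accuracy (TP+TN)/N; rank-based AUC
(ΣRank(pos) − #pos(#pos+1)/2)/(#pos·#neg) with midranks for ties — the
Mann–Whitney normalization, the unique one for which perfect separation
gives 1 and pure ties give 1/2. AUC differences between paired models are
tested with DeLong's structural-components method (two-sided normal
reference; identical score vectors return p = 1; a degenerate variance
raises with a diagnostic); a paired bootstrap is available behind a flag.

Cross-cohort transfer intersects a selected SNP set with a second cohort's
variants, reports found/missing ids, and cross-validates the genetic arm
alone on the overlap (covariate-free association is supported for cohorts
with limited clinical data). The primary replication mode is re-running the
whole selection pipeline on the second cohort.

## Synthetic data generator

No patient-level cohort is shipped; the generator emulates the statistical
structure the pipeline assumes, with everything deterministic under the
config seed:

- **Genotypes**: one linear chromosome, 0-based positions; per-variant MAF
  uniform in `maf_range`, dosages binomial(2, MAF), independent missingness
  at `missing_rate`. LD proxies are injected by copying causal columns with
  resampling noise calibrated so dosage correlation ≈ √r²; decoy pairs with
  low r² exercise the strict threshold. The proxy table reports empirical r².
- **Phenotype**: a latent liability sums per-allele causal log-odds
  (`causal_odds_ratio`, default 1.8 per allele), the standardized clinical
  linear predictor (`clinical_effects`, defaults of magnitude 0.1–0.6 with
  anti-CCP strongest, consistent with its clinical role), and unit Gaussian
  noise. The yearly SHS rate is exp-linear in the standardized liability
  (median ≈ 3 SHS units/year), so follow-up SHS is always ≥ baseline and
  higher liability always means faster progression.
- **Clinical covariates**: anti-CCP Bernoulli(0.7); the others continuous
  with plausible location/scale (e.g. BMI ~ N(23, 3), ESR ~ gamma). They are
  *not* calibrated to any real cohort's distributions.
- **Annotations**: causal variants and a (1 − `fraction_unmapped`) share of
  non-causal variants are anchored to genes through a rotating evidence
  source. Anchor intervals — including the 2 kb promoter windows genes imply
  — are confined between the nearest designated-unmapped variants (falling
  back to position-free eQTL links when the gap is too tight), and filler
  genes live beyond the variant region, so the unmapped fraction is a hard
  guarantee. A consequence is that synthetic gene bodies rarely span
  multiple variants.
- **Network and priors**: preferential-attachment graph (Barabási–Albert,
  m = round(`network_degree_param`)) with uniform(0.5, 1) edge weights;
  ~10% of genes carry background GDA entries (0.3–1.0) over
  `prior_disease_count` diseases; each causal gene, or one of its direct
  neighbours, additionally carries a high (0.6–1.0) target-disease prior —
  the "causal genes sit near disease-prior genes" condition the method is
  designed to exploit.

What the generator does **not** emulate: population structure and
stratification, realistic LD beyond the injected pairs, imputation
uncertainty, sex chromosomes, genotyping batch effects, real annotation
database dialects, and clinical covariate correlations. Passing tests
therefore certify the machinery (correct propagation, leak-free CV,
calibrated tests, recoverable network-proximal signal) — not performance on
real cohorts.

## Numerical choices and degenerate inputs

- Propagation: tol 1e−9 (max-abs update), max_iter 10,000; reaches ~1e−9
  residual in tens of iterations at α = 0.5.
- IRLS: max 40 Newton iterations, step damping above norm 10 (stabilizes
  quasi-separated fits), convergence at max-abs step < 1e−8; standard
  errors from the final observed information.
- HWE exact test: log-space enumeration with a 1e−12 relative slack when
  comparing outcome probabilities, guarding float ties.
- Tie-breaks: k* → smallest k; w* → smallest w; ranking ties → ascending p
  then lexical SNP id; all sorts are stable (mergesort).
- Degenerate inputs: monomorphic variants (HWE p = 1, flagged in
  association), all-missing variants (fail QC), empty significant sets
  (fold falls back to the majority class), single-class SVM training sets
  (prevalence output), zero-overlap transfer (explicit refusal).

## Problem sizes

The shipped demonstration and the reproduction script use a synthetic
cohort of 240 patients (≈160 after tertile exclusion), 2,000 variants, 300
genes and 10 causal SNPs, with k ∈ {10, 15, …, 150}; the test suite uses
smaller cohorts (120–240 samples, 120–300 variants) chosen so the full
pipeline stays interactive on a single CPU while every stage still carries
signal. All sizes are configuration, not code.

## Known limitations

- Overlap-ratio values depend on the Jaccard definition (above).
- The nested CV selects k by accuracy only; AUC-based selection is not
  implemented.
- DeLong's test is asymptotic; for very small folds use the bootstrap flag.
- The generator's LD injection gives controlled pairwise r² but no extended
  haplotype structure, so proxy expansion is exercised only on pairs.
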