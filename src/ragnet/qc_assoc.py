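"""Variant QC, outcome classing, principal components and per-SNP association.

The association scan is a covariate-adjusted additive logistic regression per
variant (no-progression = 0, severe progression = 1), fitted by Newton/IRLS
vectorized across variants, with a Wald test on the genotype term.  QC keeps
variants with MAF >= maf_min, call rate >= callrate_min and Hardy-Weinberg
exact p > hwe_min.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = np.nan


class QcError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Samples x variants additive-coded genotypes with variant metadata.

    ``dosage`` holds minor/alt allele counts in {0, 1, 2} with ``nan`` for
    missing calls; shape is ``(n_samples, n_variants)``.  Positions are
    0-based on a single linear chromosome.
    """

    sample_ids: np.ndarray
    variant_ids: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, v = self.dosage.shape
        if len(self.sample_ids) != n or len(self.variant_ids) != v:
            raise QcError("dosage shape inconsistent with sample/variant ids")
        if len(self.positions) != v:
            raise QcError("positions inconsistent with variant ids")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise QcError("dosage values must be in {0, 1, 2} or missing")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        af = self.allele_freq()
        return np.minimum(af, 1.0 - af)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def genotype_counts(self) -> np.ndarray:
        """Per-variant (n_hom_ref, n_het, n_hom_alt) counts, shape (V, 3)."""
        d = self.dosage
        return np.stack(
            [np.nansum(d == k, axis=0) for k in (0.0, 1.0, 2.0)], axis=1
        ).astype(int)

    def subset(self, samples: np.ndarray | None = None,
               variants: np.ndarray | None = None) -> "GenotypeMatrix":
        s = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        v = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        return GenotypeMatrix(
            sample_ids=self.sample_ids[s],
            variant_ids=self.variant_ids[v],
            positions=self.positions[v],
            ref=np.asarray(self.ref, dtype=object)[v],
            alt=np.asarray(self.alt, dtype=object)[v],
            dosage=self.dosage[np.ix_(s, v)],
            chrom=self.chrom,
        )


# ---------------------------------------------------------------------------
# Radiographic outcome classing
# ---------------------------------------------------------------------------

@dataclass
class ProgressionLabels:
    """Per-sample yearly joint-damage rate and tertile-based class.

    Samples in the low tertile of the yearly rate are labelled
    ``no_progression``, the high tertile ``severe``, the middle tertile
    ``excluded``.  Samples with invalid denominators are excluded too and
    listed in ``errors``.
    """

    rate: np.ndarray
    tertile: np.ndarray        # 'low' | 'middle' | 'high' | 'invalid'
    label: np.ndarray          # 'no_progression' | 'severe' | 'excluded'
    cutpoints: tuple[float, float]
    errors: list[tuple[int, str]] = field(default_factory=list)

    def binary(self) -> tuple[np.ndarray, np.ndarray]:
        """(indices of analysed samples, 0/1 outcome) with severe = 1."""
        keep = np.flatnonzero(self.label != "excluded")
        return keep, (self.label[keep] == "severe").astype(int)


def classify_progression(
    shs_baseline: Sequence[float] | None = None,
    shs_followup: Sequence[float] | None = None,
    interval_years: Sequence[float] | None = None,
    total_shs: Sequence[float] | None = None,
    disease_years: Sequence[float] | None = None,
    mode: Literal["two_xray", "one_xray"] = "two_xray",
) -> ProgressionLabels:
    """Class samples by yearly radiographic damage rate tertiles.

    ``two_xray`` mode uses (follow-up SHS - baseline SHS) / interval years;
    ``one_xray`` mode uses the estimated rate total SHS / disease years.
    Tertile cut points are the 1/3 and 2/3 empirical quantiles of the valid
    rates; membership is by quantile interval (rate <= q1 -> low,
    rate >= q2 -> high).
    """
    errors: list[tuple[int, str]] = []
    if mode == "two_xray":
        base = np.asarray(shs_baseline, dtype=float)
        follow = np.asarray(shs_followup, dtype=float)
        years = np.asarray(interval_years, dtype=float)
        rate = np.full(base.shape, np.nan)
        for i in range(len(base)):
            if not years[i] > 0:
                errors.append((i, f"nonpositive X-ray interval {years[i]}"))
            else:
                rate[i] = (follow[i] - base[i]) / years[i]
    elif mode == "one_xray":
        total = np.asarray(total_shs, dtype=float)
        years = np.asarray(disease_years, dtype=float)
        rate = np.full(total.shape, np.nan)
        for i in range(len(total)):
            if not years[i] > 0:
                errors.append((i, f"nonpositive disease duration {years[i]}"))
            else:
                rate[i] = total[i] / years[i]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    valid = ~np.isnan(rate)
    if valid.sum() < 3:
        raise QcError("need at least 3 valid samples to form tertiles")
    q1, q2 = np.quantile(rate[valid], [1.0 / 3.0, 2.0 / 3.0])

    tertile = np.full(rate.shape, "invalid", dtype=object)
    tertile[valid & (rate <= q1)] = "low"
    tertile[valid & (rate >= q2)] = "high"
    tertile[valid & (rate > q1) & (rate < q2)] = "middle"

    label = np.full(rate.shape, "excluded", dtype=object)
    label[tertile == "low"] = "no_progression"
    label[tertile == "high"] = "severe"
    return ProgressionLabels(rate=rate, tertile=tertile, label=label,
                             cutpoints=(float(q1), float(q2)), errors=errors)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic variant.

    Sums, over all heterozygote counts consistent with the observed allele
    counts, the conditional probabilities that are no larger than the
    probability of the observed heterozygote count (Wigginton-style
    enumeration).  Monomorphic variants return 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no genotyped samples")
    n_rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    if n_rare == 0:
        return 1.0

    # Heterozygote counts share the parity of the rare-allele count.
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    # Unnormalized log conditional probability of each het count given the
    # allele counts: P(het) ∝ n_rare! n_common! n! 2^het /
    #                        (hom_rare! het! hom_common! (2n)!)
    hom_rare = (n_rare - het_values) // 2
    hom_common = n - het_values - hom_rare
    from scipy.special import gammaln

    logp = (het_values * np.log(2.0)
            - gammaln(hom_rare + 1) - gammaln(het_values + 1)
            - gammaln(hom_common + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[het_values == n_het][0]
    # 1e-12 relative slack guards against float noise on equal-probability ties
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chisq_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """1-df chi-square Hardy-Weinberg p-value (optional alternative)."""
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no genotyped samples")
    p = (2 * n_hom1 + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    chi2 = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

@dataclass
class VariantQcReport:
    table: pd.DataFrame  # variant_id, maf, call_rate, hwe_p, pass_flag

    @property
    def n_pass(self) -> int:
        return int(self.table["pass_flag"].sum())


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.005,
    callrate_min: float = 0.95,
    hwe_min: float = 5e-7,
    hwe_test: Literal["exact", "chisq"] = "exact",
) -> tuple[GenotypeMatrix, VariantQcReport]:
    """Filter variants on MAF, call rate and Hardy-Weinberg equilibrium.

    Keeps variants with MAF >= ``maf_min`` (inclusive), call rate >=
    ``callrate_min`` (inclusive) and HWE p > ``hwe_min`` (strict).  Variants
    with no called genotypes have undefined HWE and fail QC.
    """
    if g.n_variants == 0:
        raise QcError("empty genotype matrix")
    maf = g.maf()
    cr = g.call_rate()
    counts = g.genotype_counts()
    test = hwe_exact_p if hwe_test == "exact" else hwe_chisq_p
    hwe = np.array([
        test(*row) if row.sum() > 0 else np.nan for row in counts
    ])
    pass_flag = (
        (maf >= maf_min) & (cr >= callrate_min)
        & ~np.isnan(hwe) & (hwe > hwe_min) & ~np.isnan(maf)
    )
    report = VariantQcReport(pd.DataFrame({
        "variant_id": g.variant_ids,
        "maf": maf,
        "call_rate": cr,
        "hwe_p": hwe,
        "pass_flag": pass_flag,
    }))
    kept = np.flatnonzero(pass_flag)
    if kept.size == 0:
        warnings.warn("QC removed every variant; returning an empty matrix",
                      stacklevel=2)
        logger.warning("qc_filter: 0/%d variants pass", g.n_variants)
    else:
        logger.info("qc_filter: %d/%d variants pass", kept.size, g.n_variants)
    if kept.size == 0:
        empty = GenotypeMatrix(
            sample_ids=g.sample_ids,
            variant_ids=np.array([], dtype=object),
            positions=np.array([], dtype=np.int64),
            ref=np.array([], dtype=object),
            alt=np.array([], dtype=object),
            dosage=np.empty((g.n_samples, 0)),
            chrom=g.chrom,
        )
        return empty, report
    return g.subset(variants=kept), report


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------

@dataclass
class PcResult:
    coords: np.ndarray               # (n_samples, n_pcs)
    explained_variance_ratio: np.ndarray
    outlier_flags: np.ndarray        # samples beyond 6 SD on any top-10 PC


def impute_dosage_mean(dosage: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean of observed calls."""
    out = dosage.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(out, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(out))
    out[idx] = means[idx[1]]
    return out


def compute_pcs(g: GenotypeMatrix, n_pcs: int = 10) -> PcResult:
    """Top principal components of the standardized genotype matrix.

    Missing dosages are mean-imputed per variant; variants are centred and
    scaled to unit variance (zero-variance variants dropped).  Sample
    coordinates are U·S from the thin SVD, so loadings are orthonormal.
    Samples beyond 6 SD on any of the top 10 PCs are flagged (report only).
    """
    X = impute_dosage_mean(g.dosage)
    sd = X.std(axis=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    rank = min(X.shape)
    if n_pcs > rank:
        warnings.warn(f"n_pcs={n_pcs} exceeds rank {rank}; truncating",
                      stacklevel=2)
        n_pcs = rank
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :n_pcs] * S[:n_pcs]
    evr = (S ** 2) / (S ** 2).sum()
    top = coords[:, : min(10, n_pcs)]
    sd_top = top.std(axis=0)
    sd_top[sd_top == 0] = 1.0
    flags = (np.abs(top - top.mean(axis=0)) > 6 * sd_top).any(axis=1)
    return PcResult(coords=coords, explained_variance_ratio=evr[:n_pcs],
                    outlier_flags=flags)


# ---------------------------------------------------------------------------
# Per-SNP logistic association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    table: pd.DataFrame        # variant_id, beta, se, p, converged
    covariates: list[str]
    p_threshold: float

    @property
    def significant(self) -> list[str]:
        """Variant ids with converged fits and p strictly below threshold."""
        t = self.table
        keep = t["converged"] & (t["p"] < self.p_threshold)
        return list(t.loc[keep, "variant_id"])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _batched_logistic_wald(
    G: np.ndarray, Z: np.ndarray, y: np.ndarray, mask: np.ndarray,
    max_iter: int = 40, tol: float = 1e-8, beta_cap: float = 15.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton/IRLS logistic fits for every variant at once.

    G: (n, V) dosages with missing set to 0 and excluded via ``mask``;
    Z: (n, q) shared covariate design (first column intercept); y: (n,) 0/1.
    Returns (beta_g, se_g, converged) over the V genotype terms.  Samples
    missing a genotype get zero IRLS weight, i.e. per-variant complete-case.
    """
    n, V = G.shape
    q = Z.shape[1]
    p = q + 1
    X = np.empty((V, n, p))
    X[:, :, :q] = Z[None, :, :]
    X[:, :, q] = G.T
    beta = np.zeros((V, p))
    converged = np.zeros(V, dtype=bool)
    active = np.ones(V, dtype=bool)
    maskT = mask.T.astype(float)  # (V, n)
    yv = y[None, :].astype(float)

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Xa = X[idx]
        eta = np.einsum("vnp,vp->vn", Xa, beta[idx])
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu) * maskT[idx] + 1e-12
        grad = np.einsum("vnp,vn->vp", Xa, (yv - mu) * maskT[idx])
        H = np.einsum("vnp,vn,vnq->vpq", Xa, w, Xa)
        try:
            step = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("vpq,vq->vp", np.linalg.pinv(H), grad)
        # Damp huge steps (quasi-separation) to keep the iteration stable
        norm = np.maximum(np.abs(step).max(axis=1, keepdims=True), 1e-300)
        step = np.where(norm > 10.0, step * (10.0 / norm), step)
        beta[idx] += step
        done = np.abs(step).max(axis=1) < tol
        converged[idx[done]] = True
        active[idx] = ~done

    # Standard errors from the final observed information
    eta = np.einsum("vnp,vp->vn", X, beta)
    mu = _sigmoid(eta)
    w = mu * (1.0 - mu) * maskT + 1e-12
    H = np.einsum("vnp,vn,vnq->vpq", X, w, X)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se = np.sqrt(np.maximum(cov[:, q, q], 0.0))
    ok = converged & (np.abs(beta[:, q]) < beta_cap) & np.isfinite(se) & (se > 0)
    return beta[:, q], se, ok


def logistic_assoc(
    g: GenotypeMatrix,
    y: np.ndarray,
    covariates: pd.DataFrame | None = None,
    pcs: np.ndarray | None = None,
    p_threshold: float = 0.05,
) -> AssociationResult:
    """Additive logistic association of each variant with the binary outcome.

    Fits ``logit P(severe) = b0 + covariates + PCs + b_g * dosage`` per
    variant and reports the Wald p-value on the genotype term.  Samples with
    any missing covariate are dropped (complete-case, counts logged); samples
    missing a genotype are dropped for that variant only.  Constant-genotype,
    separated or non-converged fits are flagged and never enter the
    significant set.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    cov_names: list[str] = []
    blocks = [np.ones((g.n_samples, 1))]
    if covariates is not None:
        cov_names += list(covariates.columns)
        blocks.append(np.asarray(covariates, dtype=float))
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        cov_names += [f"PC{i+1}" for i in range(pcs.shape[1])]
        blocks.append(pcs)
    Z = np.hstack(blocks)

    complete = ~np.isnan(Z).any(axis=1) & ~np.isnan(y)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("logistic_assoc: dropping %d samples with incomplete "
                    "covariates or labels", n_drop)
    Z, y = Z[complete], y[complete]
    D = g.dosage[complete]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes required after complete-case")

    mask = ~np.isnan(D)
    G = np.where(mask, D, 0.0)
    # constant genotype among non-missing calls -> no information, flag
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gvar = np.nanvar(np.where(mask, D, np.nan), axis=0)
    informative = np.nan_to_num(gvar) > 0

    beta = np.full(g.n_variants, np.nan)
    se = np.full(g.n_variants, np.nan)
    ok = np.zeros(g.n_variants, dtype=bool)
    idx = np.flatnonzero(informative)
    if idx.size:
        b, s, o = _batched_logistic_wald(G[:, idx], Z, y, mask[:, idx])
        beta[idx], se[idx], ok[idx] = b, s, o

    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.where(ok, pvals, np.nan)
    table = pd.DataFrame({
        "variant_id": g.variant_ids,
        "beta": beta,
        "se": se,
        "p": pvals,
        "converged": ok,
    })
    return AssociationResult(table=table, covariates=cov_names,
                             p_threshold=p_threshold)
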