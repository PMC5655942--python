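"""Nested cross-validated SNP selection, SVM arms and probability ensemble.

Ten stratified folds; within each training partition the whole upstream
pipeline (association scan, SNP-to-gene mapping, network scoring, ranking)
is recomputed so the held-out fold never influences feature selection.  The
genetic arm is an RBF-kernel SVM on the top-k SNP dosages, the clinical arm
an RBF SVM on six clinical covariates; the final probability is the weighted
sum w * p_snp + (1 - w) * p_clin with w chosen on pooled held-out
predictions.  Evaluation uses accuracy (TP + TN) / N and the rank-based
(Mann-Whitney) AUC, with a paired DeLong test for AUC differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import prioritize, snp2gene
from .disease_network import CorrelationScores, DiseaseNetwork, propagate, assign_prior, normalize_adjacency
from .qc_assoc import GenotypeMatrix, compute_pcs, logistic_assoc
from .snp2gene import AnnotationBundle

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """Analysis-ready cohort: genotypes, binary outcome, clinical features.

    ``y`` is 0 for no progression and 1 for severe progression.  ``clinical``
    (optional) holds the six covariates; when absent, association runs
    covariate-free and only the genetic arm is available.
    """

    genotypes: GenotypeMatrix
    y: np.ndarray
    clinical: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.y) != self.genotypes.n_samples:
            raise ValueError("labels length mismatch")
        if self.clinical is not None and len(self.clinical) != len(self.y):
            raise ValueError("clinical table length mismatch")


@dataclass
class KSelectionResult:
    k_star: int
    acc_curve: pd.DataFrame          # k, mean_accuracy, fold accuracies
    fold_snp_sets: list[set[str]]    # top-k* per training fold
    fold_rankings: list[list[str]]
    p_snp: np.ndarray                # held-out genetic-arm probabilities
    strategy: str


@dataclass
class CvEnsembleResult:
    fold_ids: np.ndarray
    k_star: int
    w_star: float
    acc_curve: pd.DataFrame
    fold_snp_sets: list[set[str]]
    p_snp: np.ndarray
    p_clin: np.ndarray | None
    p_final: np.ndarray
    fold_accuracies: np.ndarray
    mean_accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    overlap: float
    strategy: str


# ---------------------------------------------------------------------------
# Folds and metrics
# ---------------------------------------------------------------------------

def make_folds(labels: Sequence[int], n_folds: int = 10,
               seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (1..n_folds), deterministic under seed."""
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_ids = np.zeros(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y), start=1):
        fold_ids[test_idx] = f
    return fold_ids


def accuracy(predictions: Sequence[int], labels: Sequence[int]) -> float:
    """(TP + TN) / N over aligned binary vectors."""
    p = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if p.size == 0 or p.shape != y.shape:
        raise ValueError("empty or misaligned inputs")
    return float((p == y).mean())


def auc_rank(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC: (sum of positive midranks - m(m+1)/2) / (m * n).

    Equivalent to the Mann-Whitney U normalization, i.e. the fraction of
    (positive, negative) pairs ranked concordantly with ties counted 1/2;
    invariant under any strictly monotone transform of the scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)  # midranks for ties
    return float((ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n))


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison
# ---------------------------------------------------------------------------

def _delong_components(scores: np.ndarray,
                       y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and its structural components V10 (per positive), V01 (per neg)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    auc = psi.mean()
    return float(auc), psi.mean(axis=1), psi.mean(axis=0)


@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    z: float
    pvalue: float
    method: str = "delong"


def delong_variance(scores: Sequence[float], labels: Sequence[int]) -> float:
    """DeLong variance estimate of a single AUC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    auc, v10, v01 = _delong_components(s, y)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def compare_auc(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> AucComparison:
    """Paired test for the difference of two correlated AUCs.

    DeLong's method (default) estimates the covariance of the two empirical
    AUCs from their structural components and refers the standardized
    difference to a normal.  Identical score vectors give p = 1; a zero
    variance of the difference with unequal scores is an error.  A paired
    bootstrap alternative is available with ``method='bootstrap'``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("paired scores must align with labels")
    auc_a, va10, va01 = _delong_components(a, y)
    auc_b, vb10, vb01 = _delong_components(b, y)
    if np.array_equal(a, b):
        return AucComparison(auc_a, auc_b, 0.0, 1.0, method)

    if method == "delong":
        m, n = len(va10), len(va01)
        s10 = np.cov(np.stack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
        s01 = np.cov(np.stack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
        cov = s10 / m + s01 / n
        var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
        if var_diff <= 0:
            raise ValueError(
                f"degenerate DeLong variance ({var_diff:.3e}); AUCs "
                f"{auc_a:.4f} vs {auc_b:.4f} cannot be compared")
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = 2.0 * stats.norm.sf(abs(z))
        return AucComparison(auc_a, auc_b, float(z), float(p), "delong")
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx_all = np.arange(len(y))
        diffs = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.choice(idx_all, size=len(y), replace=True)
            if len(np.unique(y[idx])) < 2:
                diffs[i] = 0.0
                continue
            diffs[i] = auc_rank(a[idx], y[idx]) - auc_rank(b[idx], y[idx])
        observed = auc_a - auc_b
        p = 2.0 * min((diffs - diffs.mean() >= abs(observed)).mean(),
                      (diffs - diffs.mean() <= -abs(observed)).mean())
        p = float(min(1.0, max(p, 1.0 / n_boot)))
        return AucComparison(auc_a, auc_b, float("nan"), p, "bootstrap")
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Classifier arms
# ---------------------------------------------------------------------------

def _svm_arm(X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray,
             seed: int = 0) -> np.ndarray:
    """RBF-SVM probability of the severe class on held-out samples.

    C = 1, gamma = 1 / (n_features * var); Platt-style sigmoid calibration
    is fitted by internal cross-validation inside the training data only.
    Degenerate training sets (single class, or a class too small to
    calibrate) fall back to the class prevalence.
    """
    counts = np.bincount(np.asarray(y_train, dtype=int), minlength=2)
    if counts.min() < 2:
        return np.full(len(X_test), float(np.mean(y_train)))
    inner_cv = int(min(5, counts.min()))
    model = make_pipeline(
        StandardScaler(),
        CalibratedClassifierCV(
            SVC(kernel="rbf", C=1.0, gamma="scale"),
            method="sigmoid", cv=inner_cv, ensemble=False),
    )
    model.fit(X_train, y_train)
    cls = list(model.classes_)
    return model.predict_proba(X_test)[:, cls.index(1)]


def _snp_features(dosage: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages using training-fold means only."""
    out = dosage.copy()
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(out[train_idx], axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    ij = np.where(np.isnan(out))
    out[ij] = means[ij[1]]
    return out


# ---------------------------------------------------------------------------
# Nested selection of the SNP count k
# ---------------------------------------------------------------------------

def network_gene_scores(network: DiseaseNetwork, alpha: float = 0.5,
                        tol: float = 1e-9,
                        max_iter: int = 10_000) -> CorrelationScores:
    """Propagated disease correlation scores for every network gene."""
    prior = assign_prior(network.gda, network.ds, network.target_disease,
                         genes=network.genes)
    return propagate(normalize_adjacency(network.adjacency), prior,
                     alpha=alpha, tol=tol, max_iter=max_iter)


def nested_select_k(
    data: CohortData,
    bundle: AnnotationBundle,
    network: DiseaseNetwork,
    fold_ids: np.ndarray,
    k_grid: Sequence[int],
    strategy: str = "network_score",
    *,
    p_threshold: float = 0.05,
    r2_min: float = 0.8,
    alpha: float = 0.5,
    n_pcs: int = 10,
    seed: int = 0,
    gene_scores: CorrelationScores | None = None,
) -> KSelectionResult:
    """Choose the SNP count k by nested tenfold cross-validation.

    For every fold, the per-SNP association scan, SNP-to-gene mapping,
    network scoring and ranking run on the nine training folds only; an
    RBF-SVM on the top-k SNP dosages is evaluated on the held-out fold for
    each k in the grid.  k* maximizes the mean held-out accuracy (ties to
    the smallest k).  Held-out genetic-arm probabilities at k* are returned
    for the ensemble stage.
    """
    k_grid = sorted(int(k) for k in k_grid)
    g = data.genotypes
    y = data.y
    folds = sorted(set(fold_ids.tolist()))
    if gene_scores is None:
        gene_scores = network_gene_scores(network, alpha=alpha)
    positions = dict(zip(g.variant_ids, g.positions))
    vindex = {v: i for i, v in enumerate(g.variant_ids)}

    accs = np.full((len(folds), len(k_grid)), np.nan)
    prob_store: dict[tuple[int, int], np.ndarray] = {}
    rankings: list[list[str]] = []

    for fi, f in enumerate(folds):
        train = np.flatnonzero(fold_ids != f)
        test = np.flatnonzero(fold_ids == f)
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"training partition of fold {f} lost a class")
        g_train = g.subset(samples=train)
        cov = data.clinical.iloc[train] if data.clinical is not None else None
        n_pcs_eff = min(n_pcs, len(train) - 1, g.n_variants)
        pcs = compute_pcs(g_train, n_pcs_eff).coords if n_pcs_eff > 0 else None
        assoc = logistic_assoc(g_train, y[train], covariates=cov, pcs=pcs,
                               p_threshold=p_threshold)
        sig = assoc.significant
        logger.info("fold %d: %d significant SNPs", f, len(sig))
        if not sig:
            rankings.append([])
            prevalence = float(y[train].mean())
            for ki in range(len(k_grid)):
                pred = np.full(len(test), int(prevalence >= 0.5))
                accs[fi, ki] = accuracy(pred, y[test])
                prob_store[(fi, ki)] = np.full(len(test), prevalence)
            continue
        mapping = snp2gene.map_snp_to_genes(sig, positions, bundle,
                                            r2_min=r2_min)
        pvals = dict(zip(assoc.table["variant_id"], assoc.table["p"]))
        scored = prioritize.score_snps(mapping, gene_scores, pvals)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            ranking = prioritize.rank_and_select(
                scored, min(max(k_grid), len(scored)), strategy)
        rankings.append(ranking)

        for ki, k in enumerate(k_grid):
            top = ranking[: min(k, len(ranking))]
            cols = np.array([vindex[v] for v in top])
            X = _snp_features(g.dosage[:, cols], train)
            p_test = _svm_arm(X[train], y[train], X[test],
                              seed=seed + 1000 * f + ki)
            accs[fi, ki] = accuracy((p_test >= 0.5).astype(int), y[test])
            prob_store[(fi, ki)] = p_test

    mean_acc = np.nanmean(accs, axis=0)
    ki_star = int(np.argmax(mean_acc))  # first max -> smallest k on ties
    k_star = k_grid[ki_star]

    p_snp = np.full(len(y), np.nan)
    for fi, f in enumerate(folds):
        test = np.flatnonzero(fold_ids == f)
        p_snp[test] = prob_store[(fi, ki_star)]

    curve = pd.DataFrame({"k": k_grid, "mean_accuracy": mean_acc})
    for fi, f in enumerate(folds):
        curve[f"fold_{f}"] = accs[fi]
    fold_sets = [set(r[: min(k_star, len(r))]) for r in rankings]
    return KSelectionResult(k_star=k_star, acc_curve=curve,
                            fold_snp_sets=fold_sets, fold_rankings=rankings,
                            p_snp=p_snp, strategy=strategy)


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

def ensemble_predict(p_snp: np.ndarray, p_clin: np.ndarray,
                     w: float) -> np.ndarray:
    """Weighted probability sum p_final = w * p_snp + (1 - w) * p_clin."""
    p_snp = np.asarray(p_snp, dtype=float)
    p_clin = np.asarray(p_clin, dtype=float)
    if p_snp.shape != p_clin.shape:
        raise ValueError("arm probability vectors must align")
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    for p in (p_snp, p_clin):
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
    return w * p_snp + (1.0 - w) * p_clin


def fit_weight(
    p_snp: np.ndarray,
    p_clin: np.ndarray,
    labels: Sequence[int],
    w_grid: Sequence[float] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Grid-search the ensemble weight on pooled held-out probabilities.

    Maximizes accuracy at the 0.5 decision threshold; ties resolve to the
    smallest w.  Returns (w*, accuracy-by-weight table).
    """
    y = np.asarray(labels, dtype=int)
    if w_grid is None:
        w_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    w_grid = sorted(float(w) for w in w_grid)
    rows = []
    for w in w_grid:
        pred = (ensemble_predict(p_snp, p_clin, w) >= 0.5).astype(int)
        rows.append((w, accuracy(pred, y)))
    table = pd.DataFrame(rows, columns=["w", "accuracy"])
    w_star = float(table.loc[table["accuracy"].idxmax(), "w"])  # first max
    return w_star, table


def _threshold_metrics(p: np.ndarray, y: np.ndarray,
                       thr: float = 0.5) -> tuple[float, float, float]:
    pred = (p >= thr).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    return sens, spec, ppv


def cross_validated_ensemble(
    data: CohortData,
    bundle: AnnotationBundle,
    network: DiseaseNetwork,
    k_grid: Sequence[int],
    strategy: str = "network_score",
    *,
    n_folds: int = 10,
    p_threshold: float = 0.05,
    r2_min: float = 0.8,
    alpha: float = 0.5,
    n_pcs: int = 10,
    w_grid: Sequence[float] | None = None,
    seed: int = 0,
    gene_scores: CorrelationScores | None = None,
) -> CvEnsembleResult:
    """Full genetic + clinical ensemble under nested cross-validation.

    Runs the nested k selection for the genetic arm, trains the clinical arm
    per fold, fits the ensemble weight on pooled held-out probabilities, and
    reports per-fold accuracy, rank AUC, sensitivity/specificity/PPV at the
    0.5 threshold, and the fold-overlap (mean pairwise Jaccard) of the
    selected SNP sets.  Without a clinical table the genetic arm alone is
    evaluated (w = 1).
    """
    fold_ids = make_folds(data.y, n_folds=n_folds, seed=seed)
    sel = nested_select_k(data, bundle, network, fold_ids, k_grid, strategy,
                          p_threshold=p_threshold, r2_min=r2_min, alpha=alpha,
                          n_pcs=n_pcs, seed=seed, gene_scores=gene_scores)
    y = data.y
    if data.clinical is not None:
        p_clin = np.full(len(y), np.nan)
        Xc = data.clinical.to_numpy(dtype=float)
        for f in sorted(set(fold_ids.tolist())):
            train = np.flatnonzero(fold_ids != f)
            test = np.flatnonzero(fold_ids == f)
            p_clin[test] = _svm_arm(Xc[train], y[train], Xc[test],
                                    seed=seed + 77 * f)
        w_star, _ = fit_weight(sel.p_snp, p_clin, y, w_grid)
        p_final = ensemble_predict(sel.p_snp, p_clin, w_star)
    else:
        p_clin = None
        w_star = 1.0
        p_final = sel.p_snp

    fold_accs = np.array([
        accuracy((p_final[fold_ids == f] >= 0.5).astype(int), y[fold_ids == f])
        for f in sorted(set(fold_ids.tolist()))
    ])
    sens, spec, ppv = _threshold_metrics(p_final, y)
    nonempty = [s for s in sel.fold_snp_sets]
    overlap = prioritize.overlap_ratio(nonempty) if len(nonempty) >= 2 else float("nan")
    return CvEnsembleResult(
        fold_ids=fold_ids, k_star=sel.k_star, w_star=w_star,
        acc_curve=sel.acc_curve, fold_snp_sets=sel.fold_snp_sets,
        p_snp=sel.p_snp, p_clin=p_clin, p_final=p_final,
        fold_accuracies=fold_accs, mean_accuracy=float(fold_accs.mean()),
        auc=auc_rank(p_final, y), sensitivity=sens, specificity=spec,
        ppv=ppv, overlap=overlap, strategy=strategy)


# ---------------------------------------------------------------------------
# Cross-cohort transfer
# ---------------------------------------------------------------------------

@dataclass
class TransferReport:
    found: list[str]
    missing: list[str]
    fold_accuracies: np.ndarray | None
    mean_accuracy: float | None
    auc: float | None
    refused: bool = False


def cross_cohort_transfer(
    selected_snps: Sequence[str],
    cohort_b: CohortData,
    n_folds: int = 10,
    seed: int = 0,
) -> TransferReport:
    """Evaluate a fixed SNP set on an independent cohort (genetic arm only).

    Intersects the selected SNP ids with cohort B's variants, reports found
    and missing ids, and cross-validates an RBF-SVM on the found SNPs within
    cohort B.  An empty intersection refuses to build a model.  The primary
    replication mode — re-running the whole selection pipeline on cohort B —
    is ``cross_validated_ensemble`` on that cohort.
    """
    have = set(cohort_b.genotypes.variant_ids)
    found = [s for s in selected_snps if s in have]
    missing = [s for s in selected_snps if s not in have]
    if not found:
        logger.warning("cross_cohort_transfer: no overlapping SNPs; refusing")
        return TransferReport(found=[], missing=missing, fold_accuracies=None,
                              mean_accuracy=None, auc=None, refused=True)
    vindex = {v: i for i, v in enumerate(cohort_b.genotypes.variant_ids)}
    cols = np.array([vindex[v] for v in found])
    y = cohort_b.y
    fold_ids = make_folds(y, n_folds=n_folds, seed=seed)
    p = np.full(len(y), np.nan)
    for f in sorted(set(fold_ids.tolist())):
        train = np.flatnonzero(fold_ids != f)
        test = np.flatnonzero(fold_ids == f)
        X = _snp_features(cohort_b.genotypes.dosage[:, cols], train)
        p[test] = _svm_arm(X[train], y[train], X[test], seed=seed + 31 * f)
    fold_accs = np.array([
        accuracy((p[fold_ids == f] >= 0.5).astype(int), y[fold_ids == f])
        for f in sorted(set(fold_ids.tolist()))
    ])
    return TransferReport(found=found, missing=missing,
                          fold_accuracies=fold_accs,
                          mean_accuracy=float(fold_accs.mean()),
                          auc=auc_rank(p, y))
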