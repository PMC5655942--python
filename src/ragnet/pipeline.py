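"""End-to-end orchestration: simulate/load -> QC -> association -> mapping ->
network scoring -> prioritization -> nested CV -> ensemble -> report.

Every run directory contains the serialized config, a config hash stamped
into each artifact header, per-stage outputs, and a deterministic
``metrics.json`` so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, prioritize, snp2gene
from .disease_network import DiseaseNetwork
from .predictor import (CohortData, compare_auc, cross_validated_ensemble,
                        network_gene_scores)
from .qc_assoc import classify_progression, compute_pcs, logistic_assoc, qc_filter
from .snp2gene import AnnotationBundle
from .synthetic_data import (CohortFixture, SimulationConfig,
                             simulate_annotations, simulate_cohort,
                             simulate_network_priors)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All thresholds, grids and input locations for one pipeline run."""

    seed: int = 0
    # inputs: either a simulation block or paths to on-disk inputs
    simulate: dict = field(default_factory=dict)
    vcf: str | None = None
    phenotype: str | None = None
    bundle_dir: str | None = None
    network_dir: str | None = None
    # thresholds
    maf_min: float = 0.005
    callrate_min: float = 0.95
    hwe_min: float = 5e-7
    p_threshold: float = 0.05
    r2_min: float = 0.8
    alpha: float = 0.5
    n_pcs: int = 10
    n_folds: int = 10
    k_grid: tuple[int, int, int] = (10, 150, 5)   # start, stop, step
    w_step: float = 0.01
    outcome_mode: str = "two_xray"
    strategies: tuple[str, ...] = ("network_score", "gwas_p")

    def __post_init__(self) -> None:
        for s in self.strategies:
            if s not in ("network_score", "gwas_p"):
                raise ValueError(f"unknown strategy {s!r}")
        start, stop, step = self.k_grid
        if not (start > 0 and stop >= start and step > 0):
            raise ValueError("invalid k_grid")
        if self.simulate == {} and self.vcf is None:
            raise ValueError("config needs a 'simulate' block or input paths")

    def k_values(self) -> list[int]:
        start, stop, step = self.k_grid
        return list(range(start, stop + 1, step))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_grid"] = list(d["k_grid"])
        d["strategies"] = list(d["strategies"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "k_grid" in raw:
            raw["k_grid"] = tuple(raw["k_grid"])
        if "strategies" in raw:
            raw["strategies"] = tuple(raw["strategies"])
        return cls(**raw)


def _json_default(o):
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write artifacts + metrics under ``out_dir``.

    Returns the metrics dictionary that is also serialized (deterministic,
    sorted keys) to ``metrics.json``.  A stage failure raises
    ``PipelineStageError`` naming the stage, with earlier artifacts kept.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config.config_hash()}"
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    stage = "inputs"
    try:
        cohort, bundle, network = _load_inputs(config, out, tag)

        stage = "outcome"
        labels = classify_progression(
            shs_baseline=cohort.shs_baseline,
            shs_followup=cohort.shs_followup,
            interval_years=cohort.xray_interval_years,
            total_shs=cohort.shs_followup,
            disease_years=cohort.disease_duration_years,
            mode=config.outcome_mode,
        )
        keep, y = labels.binary()
        logger.info("outcome: %d/%d samples analysed (%d severe)",
                    len(keep), len(labels.rate), int(y.sum()))

        stage = "qc"
        g_all = cohort.genotypes.subset(samples=keep)
        g_qc, qc_report = qc_filter(g_all, config.maf_min,
                                    config.callrate_min, config.hwe_min)
        io.write_tsv(qc_report.table, out / "qc_report.tsv", tag)
        logger.info("qc: %d/%d variants pass", qc_report.n_pass,
                    g_all.n_variants)

        clinical = cohort.clinical.iloc[keep].reset_index(drop=True)
        data = CohortData(genotypes=g_qc, y=y, clinical=clinical)

        stage = "association"
        n_pcs_eff = min(config.n_pcs, g_qc.n_samples - 1, g_qc.n_variants)
        pcs = compute_pcs(g_qc, n_pcs_eff)
        assoc = logistic_assoc(g_qc, y, covariates=clinical, pcs=pcs.coords,
                               p_threshold=config.p_threshold)
        io.write_tsv(assoc.table, out / "assoc.tsv", tag)
        sig = assoc.significant
        logger.info("association: %d/%d significant at p<%g", len(sig),
                    g_qc.n_variants, config.p_threshold)

        stage = "mapping"
        positions = dict(zip(g_qc.variant_ids, g_qc.positions))
        mapping = snp2gene.map_snp_to_genes(sig, positions, bundle,
                                            r2_min=config.r2_min)
        io.write_tsv(mapping.table, out / "snp_gene_map.tsv", tag)
        n_mapped = mapping.table["snp"].nunique()
        logger.info("mapping: %d/%d significant SNPs mapped to >=1 gene",
                    n_mapped, len(sig))

        stage = "network_score"
        scores = network_gene_scores(network, alpha=config.alpha)
        io.write_tsv(scores.scores.rename("F").reset_index()
                     .rename(columns={"index": "gene"}),
                     out / "gene_scores.tsv", tag)

        stage = "prioritize"
        pvals = dict(zip(assoc.table["variant_id"], assoc.table["p"]))
        scored = prioritize.score_snps(mapping, scores, pvals)
        for strat in config.strategies:
            ranked = prioritize.rank_table(scored, strat)
            io.write_tsv(ranked, out / f"ranked_{strat}.tsv", tag)

        stage = "cv_ensemble"
        w_grid = np.round(np.arange(0.0, 1.0 + 1e-9, config.w_step), 6)
        results = {}
        for strat in config.strategies:
            res = cross_validated_ensemble(
                data, bundle, network, config.k_values(), strat,
                n_folds=config.n_folds, p_threshold=config.p_threshold,
                r2_min=config.r2_min, alpha=config.alpha,
                n_pcs=config.n_pcs, w_grid=w_grid, seed=config.seed,
                gene_scores=scores)
            results[strat] = res
            io.write_tsv(res.acc_curve, out / f"accuracy_curve_{strat}.tsv",
                         tag)
            probs = pd.DataFrame({
                "sample_id": data.genotypes.sample_ids,
                "fold": res.fold_ids,
                "label": data.y,
                "p_snp": res.p_snp,
                "p_clin": res.p_clin if res.p_clin is not None else np.nan,
                "p_final": res.p_final,
            })
            io.write_tsv(probs, out / f"heldout_probs_{strat}.tsv", tag)
            full_rank = prioritize.rank_and_select(scored, res.k_star, strat)
            io.write_tsv(pd.DataFrame({"snp": full_rank}),
                         out / f"selected_snps_{strat}.tsv", tag)
            roc = _roc_points(res.p_final, data.y)
            io.write_tsv(roc, out / f"roc_{strat}.tsv", tag)

        stage = "report"
        metrics: dict = {
            "config_hash": config.config_hash(),
            "n_samples_analysed": int(len(y)),
            "n_variants_qc": int(g_qc.n_variants),
            "n_significant": int(len(sig)),
            "n_mapped": int(n_mapped),
        }
        for strat, res in results.items():
            metrics[strat] = {
                "k_star": int(res.k_star),
                "w_star": float(res.w_star),
                "mean_accuracy": round(res.mean_accuracy, 10),
                "auc": round(res.auc, 10),
                "sensitivity": round(res.sensitivity, 10),
                "specificity": round(res.specificity, 10),
                "ppv": round(res.ppv, 10),
                "fold_overlap": round(res.overlap, 10),
            }
        strats = list(config.strategies)
        if len(strats) >= 2:
            comp = {}
            for i in range(len(strats)):
                for j in range(i + 1, len(strats)):
                    a, b = strats[i], strats[j]
                    try:
                        c = compare_auc(results[a].p_final,
                                        results[b].p_final, data.y)
                        comp[f"{a}_vs_{b}"] = {
                            "auc_a": round(c.auc_a, 10),
                            "auc_b": round(c.auc_b, 10),
                            "pvalue": round(c.pvalue, 12),
                        }
                    except ValueError as exc:
                        comp[f"{a}_vs_{b}"] = {"error": str(exc)}
            metrics["auc_comparisons"] = comp
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True,
                      default=_json_default)
            fh.write("\n")
        return metrics
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc


def _roc_points(p: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    order = np.argsort(-p, kind="mergesort")
    tp = np.cumsum(y[order] == 1)
    fp = np.cumsum(y[order] == 0)
    m, n = int((y == 1).sum()), int((y == 0).sum())
    return pd.DataFrame({
        "threshold": p[order],
        "tpr": tp / max(m, 1),
        "fpr": fp / max(n, 1),
    })


def _load_inputs(config: RunConfig, out: Path,
                 tag: str) -> tuple[CohortFixture, AnnotationBundle,
                                    DiseaseNetwork]:
    if config.simulate:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        if "clinical_effects" in sim:
            sim["clinical_effects"] = tuple(sim["clinical_effects"])
        sim_cfg = SimulationConfig(**sim)
        cohort = simulate_cohort(sim_cfg)
        bundle = simulate_annotations(sim_cfg, cohort)
        network = simulate_network_priors(sim_cfg, bundle, cohort,
                                          r2_min=config.r2_min)
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        io.write_vcf(cohort.genotypes, inputs / "genotypes.vcf", tag)
        io.write_phenotype(cohort, inputs / "phenotype.tsv", tag)
        io.write_bundle(bundle, inputs / "annotations", tag)
        io.write_network(network, inputs / "network", tag)
        return cohort, bundle, network

    g = io.read_vcf(config.vcf)
    pheno = io.read_tsv(config.phenotype)
    pheno = pheno.set_index("sample_id").loc[list(g.sample_ids)].reset_index()
    clinical = io.clinical_from_phenotype(pheno)
    cohort = CohortFixture(
        genotypes=g,
        shs_baseline=pheno["shs_baseline"].to_numpy(float),
        shs_followup=pheno["shs_followup"].to_numpy(float),
        xray_interval_years=pheno["xray_interval_years"].to_numpy(float),
        disease_duration_years=pheno["disease_duration"].to_numpy(float),
        clinical=clinical,
        causal_variant_ids=set(),
    )
    bundle = io.read_bundle(config.bundle_dir)
    network = io.read_network(config.network_dir)
    return cohort, bundle, network
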