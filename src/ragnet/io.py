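"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (written as plain VCF 4.2 text, read back with
cyvcf2); interval tracks as BED (0-based half-open); link tables, priors and
edge lists as TSV.  Writers accept an optional header comment (used by the
pipeline to stamp the run-config hash into every artifact); readers skip
``#``-prefixed comment lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .disease_network import DiseaseNetwork
from .qc_assoc import GenotypeMatrix
from .snp2gene import AnnotationBundle

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path,
              header_comment: str | None = None) -> None:
    path = Path(path)
    max_pos = int(g.positions.max(initial=0)) + 2
    lines = ["##fileformat=VCFv4.2"]
    if header_comment:
        lines.append(f"##comment={header_comment}")
    lines.append(f"##contig=<ID={g.chrom},length={max_pos}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in g.sample_ids))
    for j in range(g.n_variants):
        gts = "\t".join(
            _GT_CODE.get(g.dosage[i, j], "./.")
            if not np.isnan(g.dosage[i, j]) else "./."
            for i in range(g.n_samples)
        )
        # VCF positions are 1-based
        lines.append(f"{g.chrom}\t{g.positions[j] + 1}\t{g.variant_ids[j]}\t"
                     f"{g.ref[j]}\t{g.alt[j]}\t.\tPASS\t.\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.array(vcf.samples, dtype=object)
    ids, pos, ref, alt, rows = [], [], [], [], []
    chrom = "chr1"
    for var in vcf:
        chrom = var.CHROM
        ids.append(var.ID)
        pos.append(var.POS - 1)  # back to 0-based
        ref.append(var.REF)
        alt.append(var.ALT[0] if var.ALT else ".")
        gt = var.gt_types.astype(float)  # 0/1/2 alt copies, 3 = missing
        gt[gt == 3] = np.nan
        rows.append(gt)
    dosage = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(sample_ids=samples, variant_ids=np.array(ids, dtype=object),
                          positions=np.array(pos, dtype=np.int64),
                          ref=np.array(ref, dtype=object),
                          alt=np.array(alt, dtype=object),
                          dosage=dosage, chrom=chrom)


def write_tsv(df: pd.DataFrame, path: str | Path,
              header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bed(df: pd.DataFrame, path: str | Path, name_col: str,
              chrom: str = "chr1", strand_col: str | None = None,
              header_comment: str | None = None) -> None:
    """Write intervals as BED6 (score 0, strand '.' unless given)."""
    bed = pd.DataFrame({
        "chrom": chrom,
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
        "name": df[name_col],
        "score": 0,
        "strand": df[strand_col] if strand_col else ".",
    })
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        bed.to_csv(fh, sep="\t", index=False, header=False)


def read_bed(path: str | Path, name_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", name_col, "score",
                            "strand"])
    return df[[name_col, "start", "end", "strand"]]


# ---------------------------------------------------------------------------
# Phenotype + clinical table
# ---------------------------------------------------------------------------

PHENO_COLUMNS = ["sample_id", "shs_baseline", "shs_followup",
                 "xray_interval_years", "disease_duration", "haq",
                 "anti_ccp", "bmi", "esr"]


def write_phenotype(cohort, path: str | Path,
                    header_comment: str | None = None) -> None:
    df = pd.DataFrame({
        "sample_id": cohort.genotypes.sample_ids,
        "shs_baseline": cohort.shs_baseline,
        "shs_followup": cohort.shs_followup,
        "xray_interval_years": cohort.xray_interval_years,
        "disease_duration": cohort.clinical["disease_duration"],
        "haq": cohort.clinical["haq"],
        "anti_ccp": cohort.clinical["anti_ccp"],
        "bmi": cohort.clinical["bmi"],
        "esr": cohort.clinical["esr"],
    })
    write_tsv(df, path, header_comment)


def clinical_from_phenotype(pheno: pd.DataFrame) -> pd.DataFrame:
    """Six clinical features in canonical column order."""
    return pd.DataFrame({
        "baseline_shs": pheno["shs_baseline"],
        "disease_duration": pheno["disease_duration"],
        "haq": pheno["haq"],
        "anti_ccp": pheno["anti_ccp"],
        "bmi": pheno["bmi"],
        "esr": pheno["esr"],
    })


# ---------------------------------------------------------------------------
# Annotation bundle and disease network directories
# ---------------------------------------------------------------------------

def write_bundle(bundle: AnnotationBundle, out_dir: str | Path,
                 header_comment: str | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_bed(bundle.gene_intervals, out / "genes.bed", "gene",
              strand_col="strand", header_comment=header_comment)
    write_bed(bundle.enhancer_intervals, out / "enhancers.bed", "enhancer_id",
              header_comment=header_comment)
    write_bed(bundle.mirna_intervals, out / "mirna.bed", "mirna_id",
              header_comment=header_comment)
    write_tsv(bundle.enhancer_gene_links, out / "enhancer_gene_links.tsv",
              header_comment)
    write_tsv(bundle.mirna_target_links, out / "mirna_target_links.tsv",
              header_comment)
    write_tsv(bundle.eqtl_links, out / "eqtl_links.tsv", header_comment)
    write_tsv(bundle.ld_proxies, out / "ld_proxies.tsv", header_comment)


def read_bundle(in_dir: str | Path) -> AnnotationBundle:
    d = Path(in_dir)
    genes = read_bed(d / "genes.bed", "gene")
    enh = read_bed(d / "enhancers.bed", "enhancer_id")[
        ["enhancer_id", "start", "end"]]
    mir = read_bed(d / "mirna.bed", "mirna_id")[["mirna_id", "start", "end"]]
    return AnnotationBundle(
        gene_intervals=genes[["gene", "start", "end", "strand"]],
        enhancer_intervals=enh,
        enhancer_gene_links=read_tsv(d / "enhancer_gene_links.tsv"),
        mirna_intervals=mir,
        mirna_target_links=read_tsv(d / "mirna_target_links.tsv"),
        eqtl_links=read_tsv(d / "eqtl_links.tsv"),
        ld_proxies=read_tsv(d / "ld_proxies.tsv"),
    )


def write_network(net: DiseaseNetwork, out_dir: str | Path,
                  header_comment: str | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    idx = np.triu_indices_from(net.adjacency, k=1)
    nz = net.adjacency[idx] > 0
    edges = pd.DataFrame({
        "gene_a": [net.genes[i] for i in idx[0][nz]],
        "gene_b": [net.genes[j] for j in idx[1][nz]],
        "weight": net.adjacency[idx][nz],
    })
    write_tsv(edges, out / "edges.tsv", header_comment)
    write_tsv(pd.DataFrame({"gene": net.genes}), out / "genes.tsv",
              header_comment)
    write_tsv(net.gda, out / "gda.tsv", header_comment)
    write_tsv(net.ds, out / "ds.tsv", header_comment)


def read_network(in_dir: str | Path,
                 target_disease: str = "RA") -> DiseaseNetwork:
    """Load a network directory; edge lists without a weight column get 1.0."""
    d = Path(in_dir)
    genes = list(read_tsv(d / "genes.tsv")["gene"])
    index = {g: i for i, g in enumerate(genes)}
    edges = read_tsv(d / "edges.tsv")
    if "weight" not in edges.columns:
        edges["weight"] = 1.0
    W = np.zeros((len(genes), len(genes)))
    for row in edges.itertuples(index=False):
        i, j = index[row.gene_a], index[row.gene_b]
        W[i, j] = W[j, i] = float(row.weight)
    return DiseaseNetwork(genes=genes, adjacency=W,
                          gda=read_tsv(d / "gda.tsv"),
                          ds=read_tsv(d / "ds.tsv"),
                          target_disease=target_disease)
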