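"""Functional SNP-to-gene mapping with LD proxy expansion.

Each significant SNP, together with its strong-LD proxies (r² strictly above
the threshold), is mapped to the union of: genes whose body or promoter
contains the position, genes linked to a containing enhancer, target genes of
a containing miRNA, and genes with a significant eQTL link to the SNP.  The
evidence source is recorded per (SNP, gene) pair but not weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

EVIDENCE_SOURCES = ("gene_body", "promoter", "enhancer", "mirna_target", "eqtl")

PROMOTER_BP = 2000  # promoter window: 2 kb upstream of the TSS


@dataclass
class AnnotationBundle:
    """Interval tracks and link tables defining each SNP's related genes.

    All intervals are 0-based half-open on a single linear chromosome.
    ``gene_intervals``: gene, start, end, strand ('+'/'-'); the TSS is
    ``start`` on '+' genes and ``end`` on '-' genes.  ``eqtl_links`` rows are
    pre-thresholded (boolean ``significant``).  ``ld_proxies`` holds
    (snp_a, snp_b, r2) pairs and is symmetrized on load.
    """

    gene_intervals: pd.DataFrame
    enhancer_intervals: pd.DataFrame       # enhancer_id, start, end
    enhancer_gene_links: pd.DataFrame      # enhancer_id, gene
    mirna_intervals: pd.DataFrame          # mirna_id, start, end
    mirna_target_links: pd.DataFrame       # mirna_id, gene
    eqtl_links: pd.DataFrame               # snp, gene, tissue, significant
    ld_proxies: pd.DataFrame               # snp_a, snp_b, r2

    def __post_init__(self) -> None:
        r2 = self.ld_proxies["r2"].to_numpy(dtype=float) if len(self.ld_proxies) else []
        if len(self.ld_proxies) and ((self.ld_proxies["r2"] < 0).any()
                                     or (self.ld_proxies["r2"] > 1).any()):
            raise ValueError("r2 values must lie in [0, 1]")
        known = set(self.gene_intervals["gene"])
        for df, col in ((self.enhancer_gene_links, "gene"),
                        (self.mirna_target_links, "gene"),
                        (self.eqtl_links, "gene")):
            unknown = set(df[col]) - known
            if unknown:
                raise ValueError(f"link table references unknown genes: "
                                 f"{sorted(unknown)[:5]}")

    def promoter_intervals(self) -> pd.DataFrame:
        """Promoter windows derived from gene intervals.

        '+' strand: [TSS - 2000, TSS); '-' strand: [TSS, TSS + 2000) with
        the TSS at the right edge of the gene body.  Starts clip at 0.
        """
        rows = []
        for g in self.gene_intervals.itertuples(index=False):
            if g.strand == "+":
                rows.append((g.gene, max(0, g.start - PROMOTER_BP), g.start))
            else:
                rows.append((g.gene, g.end, g.end + PROMOTER_BP))
        return pd.DataFrame(rows, columns=["gene", "start", "end"])


@dataclass
class SnpGeneMap:
    """Per-SNP sets of related genes with their evidence source."""

    table: pd.DataFrame  # snp, gene, source, via_proxy
    snps: list[str] = field(default_factory=list)

    def genes(self, snp: str) -> set[str]:
        t = self.table
        return set(t.loc[t["snp"] == snp, "gene"])

    def gene_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {s: set() for s in self.snps}
        for row in self.table.itertuples(index=False):
            out.setdefault(row.snp, set()).add(row.gene)
        return out


def expand_ld_proxies(
    snps: Sequence[str],
    ld_proxies: pd.DataFrame,
    r2_min: float = 0.8,
) -> dict[str, set[str]]:
    """Proxy set per SNP: itself plus partners with r² strictly above r2_min.

    The pair table is symmetrized; no transitive closure is applied.  A SNP
    absent from the table keeps only itself.
    """
    partners: dict[str, set[str]] = {s: {s} for s in snps}
    if len(ld_proxies):
        strong = ld_proxies[ld_proxies["r2"] > r2_min]
        for row in strong.itertuples(index=False):
            if row.snp_a in partners:
                partners[row.snp_a].add(row.snp_b)
            if row.snp_b in partners:
                partners[row.snp_b].add(row.snp_a)
    return partners


def _build_tree(df: pd.DataFrame, id_col: str) -> IntervalTree:
    tree = IntervalTree()
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end > start:
            tree.addi(start, end, getattr(row, id_col))
    return tree


def map_snp_to_genes(
    snps: Iterable[str],
    positions: Mapping[str, int],
    bundle: AnnotationBundle,
    r2_min: float = 0.8,
) -> SnpGeneMap:
    """Map each SNP (plus its LD proxies) to its set of related genes.

    Evidence per (SNP, gene) pair is the union over the SNP itself and each
    proxy of gene-body/promoter containment, enhancer linkage, miRNA-target
    linkage and significant eQTL links.  Unmappable SNPs keep an empty set.
    Proxies whose position is unknown contribute only their eQTL links.
    """
    snps = list(snps)
    gene_tree = _build_tree(bundle.gene_intervals, "gene")
    promoter_tree = _build_tree(bundle.promoter_intervals(), "gene")
    enhancer_tree = _build_tree(bundle.enhancer_intervals, "enhancer_id")
    mirna_tree = _build_tree(bundle.mirna_intervals, "mirna_id")

    enh2genes: dict[str, set[str]] = {}
    for row in bundle.enhancer_gene_links.itertuples(index=False):
        enh2genes.setdefault(row.enhancer_id, set()).add(row.gene)
    mir2genes: dict[str, set[str]] = {}
    for row in bundle.mirna_target_links.itertuples(index=False):
        mir2genes.setdefault(row.mirna_id, set()).add(row.gene)
    eqtl = bundle.eqtl_links
    eqtl = eqtl[eqtl["significant"].astype(bool)] if len(eqtl) else eqtl
    snp2eqtl: dict[str, set[str]] = {}
    for row in eqtl.itertuples(index=False):
        snp2eqtl.setdefault(row.snp, set()).add(row.gene)

    proxies = expand_ld_proxies(snps, bundle.ld_proxies, r2_min)
    records: list[tuple[str, str, str, bool]] = []
    for snp in snps:
        seen: set[tuple[str, str]] = set()
        # the SNP itself first, so direct evidence wins over proxy evidence
        for q in [snp] + sorted(proxies[snp] - {snp}):
            via_proxy = q != snp
            hits: list[tuple[str, str]] = []
            pos = positions.get(q)
            if pos is not None:
                pos = int(pos)
                hits += [(iv.data, "gene_body") for iv in gene_tree.at(pos)]
                hits += [(iv.data, "promoter") for iv in promoter_tree.at(pos)]
                for iv in enhancer_tree.at(pos):
                    hits += [(g, "enhancer") for g in enh2genes.get(iv.data, ())]
                for iv in mirna_tree.at(pos):
                    hits += [(g, "mirna_target") for g in mir2genes.get(iv.data, ())]
            hits += [(g, "eqtl") for g in snp2eqtl.get(q, ())]
            for gene, source in hits:
                if (gene, source) not in seen:
                    seen.add((gene, source))
                    records.append((snp, gene, source, via_proxy))
    table = pd.DataFrame(records, columns=["snp", "gene", "source", "via_proxy"])
    return SnpGeneMap(table=table, snps=snps)
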