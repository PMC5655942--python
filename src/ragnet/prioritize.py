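"""SNP reprioritization by summed network disease-correlation scores.

A SNP's reprioritization score is the sum of the propagated disease
correlation scores F(g) over its deduplicated set of related genes, so SNPs
whose functional neighbourhood sits close to disease-prior genes rise in the
ranking even when their raw association p-values are unremarkable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

import pandas as pd

from .disease_network import CorrelationScores
from .snp2gene import SnpGeneMap

logger = logging.getLogger(__name__)

Strategy = Literal["network_score", "gwas_p"]


@dataclass
class SnpScoreTable:
    """Per-SNP association p-value, mapped genes and network score."""

    table: pd.DataFrame  # snp, p, score, n_genes, genes (';'-joined)

    def __len__(self) -> int:
        return len(self.table)


def score_snps(
    snp_gene_map: SnpGeneMap,
    scores: CorrelationScores,
    pvalues: Mapping[str, float],
) -> SnpScoreTable:
    """Sum F(gene) over each SNP's deduplicated related-gene set.

    Genes missing from the score vector contribute 0 (logged).  SNPs with an
    empty gene set keep score 0 and remain rankable by p-value.
    """
    known = set(scores.scores.index)
    missing: set[str] = set()
    rows = []
    gene_sets = snp_gene_map.gene_sets()
    for snp in snp_gene_map.snps:
        genes = gene_sets.get(snp, set())
        missing |= genes - known
        total = sum(scores[g] for g in genes)
        rows.append((snp, float(pvalues.get(snp, float("nan"))), total,
                     len(genes), ";".join(sorted(genes))))
    if missing:
        logger.info("score_snps: %d mapped genes absent from score vector, "
                    "treated as F=0", len(missing))
    return SnpScoreTable(pd.DataFrame(
        rows, columns=["snp", "p", "score", "n_genes", "genes"]))


def rank_and_select(
    table: SnpScoreTable,
    k: int,
    strategy: Strategy = "network_score",
) -> list[str]:
    """Ordered top-k SNPs under the chosen ranking strategy.

    ``network_score``: descending score, ties by ascending p, then SNP id.
    ``gwas_p``: ascending p, ties by SNP id.  If k exceeds the table size the
    whole ranking is returned with a warning.
    """
    t = table.table
    if k > len(t):
        import warnings
        warnings.warn(f"k={k} exceeds table size {len(t)}; truncating",
                      stacklevel=2)
        k = len(t)
    if strategy == "network_score":
        ranked = t.sort_values(["score", "p", "snp"],
                               ascending=[False, True, True],
                               kind="mergesort")
    elif strategy == "gwas_p":
        ranked = t.sort_values(["p", "snp"], ascending=[True, True],
                               kind="mergesort")
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return list(ranked["snp"].iloc[:k])


def rank_table(table: SnpScoreTable,
               strategy: Strategy = "network_score") -> pd.DataFrame:
    """Full ranking with an explicit 1-based rank column."""
    order = rank_and_select(table, len(table), strategy)
    out = table.table.set_index("snp").loc[order].reset_index()
    out["rank"] = range(1, len(out) + 1)
    return out


def overlap_ratio(sets: Sequence[set[str]]) -> float:
    """Mean pairwise Jaccard index over the given SNP sets.

    Pairs in which either set is empty contribute 0 (logged).  Measures the
    stability of top-k selection across cross-validation training sets.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    vals = []
    for a, b in combinations(sets, 2):
        if not a or not b:
            logger.info("overlap_ratio: empty set in pair, contributes 0")
            vals.append(0.0)
        else:
            vals.append(len(a & b) / len(a | b))
    return float(sum(vals) / len(vals))
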