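"""Single-category genomic feature annotation with deterministic precedence.

Categories: Promoter > 5' UTR > 3' UTR > Exon > Intron > Downstream >
Distal Intergenic.  Intervals are annotated by their midpoint; the
promoter is [TSS - flank, TSS + flank) and downstream extends past the
gene's 3' end, both strand-aware.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import GeneModel, GenomeCoordinate

CATEGORIES = [
    "Promoter",
    "5' UTR",
    "3' UTR",
    "Exon",
    "Intron",
    "Downstream",
    "Distal Intergenic",
]


@dataclass
class FeatureAnnotation:
    query_id: str
    category: str
    nearest_gene: str | None
    distance_to_tss: int | None


def _contains(intervals, x: int) -> bool:
    return any(s <= x < e for s, e in intervals)


def annotate_position(
    contig: str,
    pos: int,
    gene_models: list[GeneModel],
    promoter_flank: int = 3_000,
    downstream_flank: int = 3_000,
    query_id: str = "",
) -> FeatureAnnotation:
    genes_here = [g for g in gene_models if g.contig == contig]
    nearest, nearest_dist = None, None
    for g in genes_here:
        d = pos - g.tss if g.strand == "+" else g.tss - pos
        if nearest is None or abs(d) < abs(nearest_dist):
            nearest, nearest_dist = g.gene_id, d

    def category() -> str:
        for g in genes_here:
            if g.tss - promoter_flank <= pos < g.tss + promoter_flank:
                return "Promoter"
        for g in genes_here:
            if _contains(g.utr5, pos):
                return "5' UTR"
        for g in genes_here:
            if _contains(g.utr3, pos):
                return "3' UTR"
        for g in genes_here:
            if _contains(g.exons, pos):
                return "Exon"
        for g in genes_here:
            if g.start <= pos < g.end:
                return "Intron"
        for g in genes_here:
            if g.strand == "+" and g.end <= pos < g.end + downstream_flank:
                return "Downstream"
            if g.strand == "-" and g.start - downstream_flank <= pos < g.start:
                return "Downstream"
        return "Distal Intergenic"

    return FeatureAnnotation(
        query_id=query_id,
        category=category(),
        nearest_gene=nearest,
        distance_to_tss=nearest_dist,
    )


def annotate(
    queries,
    gene_models: list[GeneModel],
    promoter_flank: int = 3_000,
    downstream_flank: int = 3_000,
) -> pd.DataFrame:
    """Annotate point queries or intervals (by midpoint).

    ``queries`` is an iterable of (query_id, contig, pos) triples or of
    GenomeCoordinate objects.
    """
    if not gene_models:
        warnings.warn("empty gene model: every query becomes Distal Intergenic")
    rows = []
    for q in queries:
        if isinstance(q, GenomeCoordinate):
            qid, contig, pos = f"{q.contig}:{q.start}-{q.end}", q.contig, q.midpoint
        else:
            qid, contig, pos = q
        ann = annotate_position(
            contig, int(pos), gene_models,
            promoter_flank=promoter_flank,
            downstream_flank=downstream_flank,
            query_id=str(qid),
        )
        rows.append(
            {
                "query_id": ann.query_id,
                "contig": contig,
                "pos": int(pos),
                "category": ann.category,
                "nearest_gene": ann.nearest_gene,
                "distance_to_tss": ann.distance_to_tss,
            }
        )
    return pd.DataFrame(
        rows, columns=["query_id", "contig", "pos", "category", "nearest_gene", "distance_to_tss"]
    )


def category_fractions(annotations: pd.DataFrame) -> pd.Series:
    """Percentage of queries per category (sums to 100)."""
    counts = annotations["category"].value_counts()
    return counts / counts.sum() * 100.0
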