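"""Fixed-allele differences between lines, CpG-loss / novel-CpG context
calls against the reference, and the 1/16-expectancy enrichment table.

A CpG-SNP (CpG loss) is a SNP sitting on the C of a reference CpG (or,
by strand complement, on the G); a novel CpG is a SNP whose alternate
allele is C immediately 5' of a reference G where the reference base is
not C.  G-side CpG gains are deliberately not counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GenotypeTable, ReferenceGenome

CPG_EXPECTANCY = 1.0 / 16.0  # chance a uniform random dinucleotide is CpG


class CpGContext(str, Enum):
    CPG_LOSS = "CpG_loss"
    NOVEL_CPG = "novel_CpG"
    OTHER = "other"


@dataclass
class CpGContextCall:
    contig: str
    pos: int
    ref: str
    alt: str
    context: CpGContext
    strand_of_cpg: str  # '+', '-' or 'n/a'
    change_type: str
    edge_flagged: bool = False


def fixed_allele_differences(table: GenotypeTable) -> np.ndarray:
    """Mask of loci with differentially fixed alleles between the lines.

    A locus qualifies iff every non-missing call in one line is
    homozygous for one allele, every non-missing call in the other line
    is homozygous for the opposite allele, and both lines have at least
    one non-missing call.
    """
    la, lb = table.group_labels
    ma, mb = table.group_mask(la), table.group_mask(lb)
    out = np.zeros(table.n_loci, dtype=bool)
    for mask_first, mask_second in ((ma, mb),):
        da = table.dosage[mask_first]
        db = table.dosage[mask_second]
        called_a, called_b = da >= 0, db >= 0
        n_a, n_b = called_a.sum(axis=0), called_b.sum(axis=0)
        a_all_ref = ((da == 0) | ~called_a).all(axis=0)
        a_all_alt = ((da == 2) | ~called_a).all(axis=0)
        b_all_ref = ((db == 0) | ~called_b).all(axis=0)
        b_all_alt = ((db == 2) | ~called_b).all(axis=0)
        opposite = (a_all_ref & b_all_alt) | (a_all_alt & b_all_ref)
        out |= opposite & (n_a > 0) & (n_b > 0)
    return out


def call_cpg_loss(genome: ReferenceGenome, contig: str, pos: int, ref: str, alt: str) -> CpGContextCall:
    """CpG-loss call for one biallelic SNP.

    Plus strand: ref C with 3' neighbour G, alt != C.  Minus strand
    (complement case): ref G with 5' neighbour C, alt != G.
    """
    clen = genome.contig_length(contig)
    change = f"{ref}→{alt}"
    if pos + 1 >= clen or pos - 1 < 0:
        return CpGContextCall(contig, pos, ref, alt, CpGContext.OTHER, "n/a", change, edge_flagged=True)
    base = genome.base(contig, pos)
    nxt = genome.base(contig, pos + 1)
    prv = genome.base(contig, pos - 1)
    if base == "C" and nxt == "G" and ref == "C" and alt != "C":
        return CpGContextCall(contig, pos, ref, alt, CpGContext.CPG_LOSS, "+", change)
    if base == "G" and prv == "C" and ref == "G" and alt != "G":
        return CpGContextCall(contig, pos, ref, alt, CpGContext.CPG_LOSS, "-", change)
    return CpGContextCall(contig, pos, ref, alt, CpGContext.OTHER, "n/a", change)


def call_novel_cpg(genome: ReferenceGenome, contig: str, pos: int, ref: str, alt: str) -> CpGContextCall:
    """Novel-CpG call: alt C, reference 3' neighbour G, reference base != C."""
    clen = genome.contig_length(contig)
    change = f"{ref}→{alt}"
    if pos + 1 >= clen:
        return CpGContextCall(contig, pos, ref, alt, CpGContext.OTHER, "n/a", change, edge_flagged=True)
    nxt = genome.base(contig, pos + 1)
    if alt == "C" and ref != "C" and nxt == "G":
        return CpGContextCall(contig, pos, ref, alt, CpGContext.NOVEL_CPG, "+", change)
    return CpGContextCall(contig, pos, ref, alt, CpGContext.OTHER, "n/a", change)


def call_contexts(genome: ReferenceGenome, table: GenotypeTable) -> pd.DataFrame:
    """Per-locus CpG context over a genotype table.

    CpG_loss takes precedence; by construction the two contexts are
    mutually exclusive (a loss needs ref C or G of a CpG; a gain needs
    alt C with ref not C).
    """
    rows = []
    for j in range(table.n_loci):
        contig, pos = str(table.contig[j]), int(table.pos[j])
        ref, alt = str(table.ref[j]), str(table.alt[j])
        loss = call_cpg_loss(genome, contig, pos, ref, alt)
        if loss.context is CpGContext.CPG_LOSS:
            call = loss
        else:
            gain = call_novel_cpg(genome, contig, pos, ref, alt)
            call = gain if gain.context is CpGContext.NOVEL_CPG else loss
        rows.append(
            {
                "contig": contig,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "context": call.context.value,
                "strand_of_cpg": call.strand_of_cpg,
                "change_type": call.change_type,
                "edge_flagged": call.edge_flagged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["contig", "pos", "ref", "alt", "context", "strand_of_cpg", "change_type", "edge_flagged"],
    )


def most_frequent_allele_by_line(table: GenotypeTable, locus_index: int) -> dict[str, str | None]:
    """Dosage-weighted most frequent base per line; ties go to the ref."""
    out: dict[str, str | None] = {}
    for label in table.group_labels:
        freq = table.alt_freq(table.group_mask(label))[locus_index]
        if not np.isfinite(freq):
            out[label] = None
        elif freq > 0.5:
            out[label] = str(table.alt[locus_index])
        else:
            out[label] = str(table.ref[locus_index])
    return out


def enrichment_table(
    is_cpg: np.ndarray, categories: np.ndarray, expectancy: float = CPG_EXPECTANCY
) -> pd.DataFrame:
    """Observed vs expected CpG-SNPs per feature category, plus a total row.

    expected = n * expectancy; fold = observed / expected; chi2 is a 1-df
    goodness-of-fit test on the two-cell (CpG vs non-CpG) table.
    """
    is_cpg = np.asarray(is_cpg, dtype=bool)
    categories = np.asarray(categories, dtype=object)
    if is_cpg.shape != categories.shape:
        raise ValueError("is_cpg and categories must align")

    def row(name, mask):
        n = int(mask.sum())
        obs = int(is_cpg[mask].sum())
        exp = n * expectancy
        if n == 0:
            return {"category": name, "n_snps": 0, "expected_cpg": 0.0,
                    "observed_cpg": 0, "fold": np.nan, "chi2": np.nan, "p": np.nan}
        chi2 = (obs - exp) ** 2 / exp + ((n - obs) - (n - exp)) ** 2 / (n - exp)
        return {
            "category": name,
            "n_snps": n,
            "expected_cpg": exp,
            "observed_cpg": obs,
            "fold": obs / exp,
            "chi2": chi2,
            "p": float(stats.chi2.sf(chi2, df=1)),
        }

    rows = [row(cat, categories == cat) for cat in dict.fromkeys(categories)]
    rows.append(row("Total", np.ones_like(is_cpg, dtype=bool)))
    return pd.DataFrame(rows)
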