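"""Per-SNP Weir-Cockerham Fst, windowed Tajima's D, SNP-window matching,
and the ten-category selection-signature classification.

The classifier applies the criteria in their stated order with
first-match-wins; a slightly negative Fst estimate is clamped to 0 for
classification only (the raw value is retained in output).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .genomic_io import GenotypeTable


class SelectionClass(str, Enum):
    FIXED_ALLELE = "FixedAllele"
    POSITIVE_SELECTION = "PositiveSelection"
    BALANCING_SELECTION = "BalancingSelection"
    HIGH_FST_NEUTRAL_TAJIMA = "HighFstNeutralTajima"
    NEGATIVE_SELECTION = "NegativeSelection"
    POSSIBLE_STRUCTURE_EXPANSION = "PossiblePopulationStructureExpansion"
    NEUTRAL = "Neutral"
    NON_SELECTED = "NonSelected"
    HIGH_FST_NO_TAJIMA = "HighFstNoTajimaData"
    SHARED_NEUTRALITY = "SharedNeutrality"


def wc_fst(table: GenotypeTable, min_calls: int = 2) -> tuple[np.ndarray, float]:
    """Weir & Cockerham (1984) two-population Fst from genotype counts.

    Returns (per-locus fst, global fst).  Per-locus fst is NaN when either
    group has fewer than ``min_calls`` non-missing diploid calls, and 0 by
    convention at loci monomorphic overall.  The global estimate is
    sum(a) / sum(a + b + c) over loci with defined components.
    """
    la, lb = table.group_labels
    masks = [table.group_mask(la), table.group_mask(lb)]
    r = 2
    n_i = np.stack([(table.dosage[m] >= 0).sum(axis=0) for m in masks])  # (2, L)
    p_i = np.stack([table.alt_freq(m) for m in masks])
    # observed heterozygote frequency per group
    h_i = np.stack(
        [
            np.where(
                n_i[k] > 0,
                (table.dosage[masks[k]] == 1).sum(axis=0) / np.maximum(n_i[k], 1),
                np.nan,
            )
            for k in range(2)
        ]
    )

    valid = (n_i >= min_calls).all(axis=0)
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        denom = a + b + c
        fst = np.where(np.abs(denom) > 0, a / np.where(np.abs(denom) > 0, denom, 1.0), 0.0)
    mono = (pbar <= 0) | (pbar >= 1)
    fst = np.where(mono, 0.0, fst)
    fst = np.where(valid, fst, np.nan)

    use = valid & ~mono & np.isfinite(denom)
    global_fst = float(a[use].sum() / denom[use].sum()) if use.any() else float("nan")
    return fst, global_fst


def _tajima_constants(n: int) -> dict:
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "e1": e1, "e2": e2}


def tajima_d_windows(table: GenotypeTable, window_bp: int = 10_000) -> pd.DataFrame:
    """Tajima's D per non-overlapping genomic window over pooled samples.

    Genotypes are treated as 2n chromosomes; per-site pi uses the
    unbiased estimator 2p(1-p) * 2n/(2n-1) with the site's own call
    count, and the window constants use the rounded mean chromosome
    count over the window's loci.  D is NaN where S = 0.
    """
    called = table.dosage >= 0
    n_l = called.sum(axis=0)
    alt = np.where(called, table.dosage, 0).sum(axis=0)
    rows = []
    order = np.lexsort((table.pos, table.contig.astype(str)))
    contigs = table.contig[order]
    pos = table.pos[order]
    n_l, alt = n_l[order], alt[order]
    for contig in dict.fromkeys(contigs):
        m = contigs == contig
        cpos, cn, calt = pos[m], n_l[m], alt[m]
        if not len(cpos):
            continue
        for wstart in range(0, int(cpos.max()) + 1, window_bp):
            wend = wstart + window_bp
            inw = (cpos >= wstart) & (cpos < wend)
            if not inw.any():
                continue
            wn, walt = cn[inw], calt[inw]
            chroms = 2 * wn
            usable = chroms >= 2
            wn, walt, chroms = wn[usable], walt[usable], chroms[usable]
            if not len(wn):
                continue
            poly = (walt > 0) & (walt < chroms)
            S = int(poly.sum())
            n_chrom = int(round(chroms.mean()))
            if S == 0 or n_chrom < 4:
                rows.append(
                    {"contig": contig, "start": wstart, "end": wend,
                     "n_chromosomes": n_chrom, "S": S, "pi": 0.0, "D": np.nan}
                )
                continue
            p = walt / chroms
            pi = float((2 * p * (1 - p) * chroms / (chroms - 1))[poly].sum())
            k = _tajima_constants(n_chrom)
            var = k["e1"] * S + k["e2"] * S * (S - 1)
            D = (pi - S / k["a1"]) / np.sqrt(var) if var > 0 else np.nan
            rows.append(
                {"contig": contig, "start": wstart, "end": wend,
                 "n_chromosomes": n_chrom, "S": S, "pi": pi, "D": float(D)}
            )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "n_chromosomes", "S", "pi", "D"])


def attach_tajima(table: GenotypeTable, windows: pd.DataFrame) -> np.ndarray:
    """Per-SNP mean of D over all half-open windows containing the SNP.

    NaN when no containing window has a defined D.
    """
    out = np.full(table.n_loci, np.nan)
    if not len(windows):
        return out
    for contig, sub in windows.groupby("contig", sort=False):
        m = np.asarray(table.contig == contig)
        if not m.any():
            continue
        snp_pos = table.pos[m]
        sums = np.zeros(len(snp_pos))
        counts = np.zeros(len(snp_pos))
        for w in sub.itertuples():
            if not np.isfinite(w.D):
                continue
            inw = (snp_pos >= w.start) & (snp_pos < w.end)
            sums[inw] += w.D
            counts[inw] += 1
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out[np.flatnonzero(m)] = vals
    return out


def classify_selection(
    fst: float, tajima_d_mean: float | None, d_tol: float = 1e-9, fst_tol: float = 1e-9
) -> SelectionClass:
    """Classify one locus from (Fst, mean Tajima's D), first match wins.

    |D| <= d_tol is treated as D = 0; Fst within fst_tol of 1 counts as
    fixed; a negative estimate is clamped to 0.
    """
    if fst is None or not np.isfinite(fst):
        raise ValueError("fst must be present for classification")
    f = min(max(float(fst), 0.0), 1.0)
    d = tajima_d_mean
    has_d = d is not None and np.isfinite(d)
    if has_d and abs(d) <= d_tol:
        d = 0.0
    if f >= 1.0 - fst_tol:
        return SelectionClass.FIXED_ALLELE
    if f > 0.25 and has_d and d < 0:
        return SelectionClass.POSITIVE_SELECTION
    if f > 0.25 and has_d and d > 0:
        return SelectionClass.BALANCING_SELECTION
    if f > 0.25 and has_d and d == 0:
        return SelectionClass.HIGH_FST_NEUTRAL_TAJIMA
    if f < 0.05 and has_d and d < 0:
        return SelectionClass.NEGATIVE_SELECTION
    if f < 0.05 and has_d and d > 0:
        return SelectionClass.POSSIBLE_STRUCTURE_EXPANSION
    if 0.05 <= f <= 0.25:
        return SelectionClass.NEUTRAL
    if f < 0.05 and not has_d:
        return SelectionClass.NON_SELECTED
    if f >= 0.05 and not has_d:
        return SelectionClass.HIGH_FST_NO_TAJIMA
    return SelectionClass.SHARED_NEUTRALITY


def run_popgen(table: GenotypeTable, window_bp: int = 10_000) -> pd.DataFrame:
    """Fst + windowed D + per-SNP classification in one frame.

    Loci where Fst is undefined (too few calls in a group) are reported
    with class ``unclassified``.
    """
    fst, global_fst = wc_fst(table)
    windows = tajima_d_windows(table, window_bp=window_bp)
    d_mean = attach_tajima(table, windows)
    classes = [
        classify_selection(f, d).value if np.isfinite(f) else "unclassified"
        for f, d in zip(fst, d_mean)
    ]
    df = pd.DataFrame(
        {
            "contig": table.contig,
            "pos": table.pos,
            "fst": fst,
            "tajima_d_mean": d_mean,
            "selection_class": classes,
        }
    )
    df.attrs["global_fst"] = global_fst
    return df
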