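"""Genotype QC filters, allele-based association with permutation, BH-FDR,
and pairwise-LD summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GenotypeTable


@dataclass
class FilterReport:
    n_samples_in: int = 0
    n_samples_dropped: int = 0
    n_loci_in: int = 0
    n_loci_dropped_callrate: int = 0
    n_loci_dropped_maf: int = 0

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.n_samples_dropped

    @property
    def n_loci_out(self) -> int:
        return self.n_loci_in - self.n_loci_dropped_callrate - self.n_loci_dropped_maf


def filter_genotypes(
    table: GenotypeTable,
    min_maf: float = 0.02,
    min_sample_callrate: float = 0.20,
    min_locus_callrate: float = 0.70,
) -> tuple[GenotypeTable, FilterReport]:
    """Drop low-call-rate samples first, then low-call-rate/low-MAF loci.

    All thresholds are inclusive ("at least"): a locus at MAF exactly
    ``min_maf`` is retained.
    """
    report = FilterReport(n_samples_in=table.n_samples, n_loci_in=table.n_loci)
    called = table.dosage >= 0
    sample_rate = called.mean(axis=1) if table.n_loci else np.ones(table.n_samples)
    keep_samples = sample_rate >= min_sample_callrate
    report.n_samples_dropped = int((~keep_samples).sum())
    if not keep_samples.any():
        raise ValueError(f"all samples removed by call-rate filter: {report}")
    table = table.subset_samples(keep_samples)

    called = table.dosage >= 0
    locus_rate = called.mean(axis=0)
    keep_rate = locus_rate >= min_locus_callrate
    report.n_loci_dropped_callrate = int((~keep_rate).sum())

    alt = np.where(called, table.dosage, 0).sum(axis=0)
    tot = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    maf = np.minimum(freq, 1 - freq)
    keep_maf = maf >= min_maf
    report.n_loci_dropped_maf = int((keep_rate & ~keep_maf).sum())

    keep = keep_rate & keep_maf
    if not keep.any():
        raise ValueError(f"all loci removed by filters: {report}")
    return table.subset_loci(keep), report


def _counts_2x2(table: GenotypeTable) -> tuple[np.ndarray, ...]:
    """Per-locus allele counts: (alt_a, ref_a, alt_b, ref_b)."""
    la, lb = table.group_labels
    alt_a, ref_a = table.allele_counts(table.group_mask(la))
    alt_b, ref_b = table.allele_counts(table.group_mask(lb))
    return alt_a, ref_a, alt_b, ref_b


def _chi2_from_counts(alt_a, ref_a, alt_b, ref_b) -> np.ndarray:
    """Pearson chi-squared (1 df, no continuity correction) per 2x2 table.

    Degenerate tables (a zero row or column margin) give chi2 = 0.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (alt_a, ref_a, alt_b, ref_b))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    return chi2


def allelic_association(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus 2x2 allele-count chi-squared association between groups.

    Each non-missing diploid call contributes two alleles.  Monomorphic
    loci get chi2 = 0, p = 1.
    """
    alt_a, ref_a, alt_b, ref_b = _counts_2x2(table)
    chi2 = _chi2_from_counts(alt_a, ref_a, alt_b, ref_b)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(chi2 <= 0, 1.0, p)
    return pd.DataFrame(
        {
            "contig": table.contig,
            "pos": table.pos,
            "ref": table.ref,
            "alt": table.alt,
            "alt_a": alt_a,
            "ref_a": ref_a,
            "alt_b": alt_b,
            "ref_b": ref_b,
            "chi2": chi2,
            "p": p,
        }
    )


def permutation_pvalues(table: GenotypeTable, n_perm: int, seed: int) -> np.ndarray:
    """Empirical per-locus p by joint permutation of group labels.

    p = (1 + #{permuted chi2 >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    la, _ = table.group_labels
    mask_a = table.group_mask(la)
    n_a = int(mask_a.sum())
    called = table.dosage >= 0
    dos0 = np.where(called, table.dosage, 0).astype(np.int64)

    def chi2_for(mask):
        alt_a = dos0[mask].sum(axis=0)
        calls_a = called[mask].sum(axis=0)
        alt_b = dos0[~mask].sum(axis=0)
        calls_b = called[~mask].sum(axis=0)
        return _chi2_from_counts(alt_a, 2 * calls_a - alt_a, alt_b, 2 * calls_b - alt_b)

    observed = chi2_for(mask_a)
    exceed = np.zeros(table.n_loci, dtype=np.int64)
    idx = np.arange(table.n_samples)
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        m = np.zeros(table.n_samples, dtype=bool)
        m[perm[:n_a]] = True
        exceed += chi2_for(m) >= observed - 1e-12
    return (1 + exceed) / (1 + n_perm)


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, significant mask)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= alpha


@dataclass
class LdSummary:
    n_pairs: int
    mean: float
    median: float
    q25: float
    q75: float


def ld_summary(table: GenotypeTable, max_pairs: int = 50_000, seed: int = 0) -> LdSummary:
    """Distribution of pairwise r^2 computed on allele dosages.

    r^2 is the squared Pearson correlation of dosages over samples with
    complete calls at both loci (composite LD; genotypes are unphased).
    Pairs are subsampled deterministically when the total exceeds
    ``max_pairs``.
    """
    if table.n_loci < 2:
        raise ValueError("need at least two loci for LD")
    rng = np.random.default_rng(seed)
    n = table.n_loci
    total = n * (n - 1) // 2
    if total <= max_pairs:
        ii, jj = np.triu_indices(n, k=1)
    else:
        ii = rng.integers(0, n, size=max_pairs)
        jj = rng.integers(0, n, size=max_pairs)
        ok = ii != jj
        ii, jj = ii[ok], jj[ok]
    vals = []
    D = table.dosage
    for a, b in zip(ii, jj):
        x, y = D[:, a].astype(float), D[:, b].astype(float)
        ok = (x >= 0) & (y >= 0)
        if ok.sum() < 3:
            continue
        x, y = x[ok], y[ok]
        if x.std() == 0 or y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        vals.append(r * r)
    vals = np.asarray(vals)
    if not len(vals):
        raise ValueError("no informative locus pairs")
    return LdSummary(
        n_pairs=len(vals),
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        q25=float(np.percentile(vals, 25)),
        q75=float(np.percentile(vals, 75)),
    )


def run_association(
    table: GenotypeTable,
    alpha: float = 0.05,
    n_perm: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Association + optional permutation + BH-FDR in one frame."""
    res = allelic_association(table)
    if n_perm:
        res["p_perm"] = permutation_pvalues(table, n_perm, seed)
    q, sig = bh_fdr(res["p"].to_numpy(), alpha=alpha)
    res["q"] = q
    res["significant"] = sig
    return res
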