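"""MeDIP-seq windowed differential methylation.

Pipeline: stacked-read Poisson filter -> 100-bp read extension -> 300-bp
window counts with CpG coupling factors -> CpG-dependent normalisation to
relative methylation scores (rms) -> per-window Welch test on log rms ->
merging of adjacent significant windows with a 1-bp gap tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .genomic_io import IntervalSet, ReferenceGenome

RMS_LOG_OFFSET = 0.1


def stacked_read_cap(lam: float, p: float = 0.001) -> int:
    """Largest stack height k with P(X >= k) >= p under Poisson(lam).

    Stacks taller than the cap are truncated to it; the cap never drops
    below 1.
    """
    k = 1
    while stats.poisson.sf(k - 1, lam) >= p:
        k += 1
        if k > 10_000_000:  # pragma: no cover
            break
    return max(k - 1, 1)


def stacked_read_filter(
    reads: IntervalSet, genome: ReferenceGenome, p: float = 0.001
) -> tuple[IntervalSet, int]:
    """Truncate PCR-like stacks of identical reads per (contig, start, strand).

    lam is the genome-wide mean number of reads per available start
    position (total reads / genome length).  Returns the filtered reads
    and the number removed.
    """
    df = reads.df
    if not len(df):
        return reads, 0
    lam = len(df) / genome.total_length
    cap = stacked_read_cap(lam, p=p)
    key = df.groupby(["contig", "start", "strand"], dropna=False).cumcount()
    keep = key < cap
    return IntervalSet(df[keep], kind=reads.kind), int((~keep).sum())


def extend_reads(reads: IntervalSet, genome: ReferenceGenome, target: int = 100) -> IntervalSet:
    """Extend reads shorter than ``target`` 3'-ward to that length.

    Plus-strand reads grow their end, minus-strand reads their start;
    extension is clipped at contig bounds.  Longer reads are untouched.
    """
    df = reads.df.copy()
    lengths = df["end"] - df["start"]
    short = lengths < target
    plus = df["strand"].fillna("+") != "-"
    clens = df["contig"].map(lambda c: genome.contig_length(c))
    df.loc[short & plus, "end"] = np.minimum(
        df.loc[short & plus, "start"] + target, clens[short & plus]
    )
    df.loc[short & ~plus, "start"] = np.maximum(df.loc[short & ~plus, "end"] - target, 0)
    return IntervalSet(df, kind=reads.kind)


def window_counts(
    reads_by_sample: dict[str, IntervalSet],
    genome: ReferenceGenome,
    window_bp: int = 300,
) -> pd.DataFrame:
    """Window x sample count matrix with per-window CpG coupling factors.

    A read increments every window its interval overlaps.  Returns a
    frame with contig/start/end/cpg_count plus one column per sample.
    """
    tiles = genome.tile(window_bp)
    tiles["cpg_count"] = [
        genome.cpg_count(r.contig, r.start, r.end) for r in tiles.itertuples()
    ]
    offsets = {}
    running = 0
    for contig in genome.contigs:
        offsets[contig] = running
        running += int(np.ceil(genome.contig_length(contig) / window_bp))
    n_windows = running
    for sample, ivs in reads_by_sample.items():
        counts = np.zeros(n_windows, dtype=np.int64)
        for contig, sub in ivs.df.groupby("contig", sort=False):
            if contig not in offsets:
                continue
            clen = genome.contig_length(contig)
            last = (clen - 1) // window_bp
            first_w = np.clip(sub["start"].to_numpy() // window_bp, 0, last)
            last_w = np.clip((sub["end"].to_numpy() - 1) // window_bp, 0, last)
            block = counts[offsets[contig] : offsets[contig] + last + 1]
            k = 0
            while True:  # a read spans at most a few windows
                active = first_w + k <= last_w
                if not active.any():
                    break
                block += np.bincount(first_w[active] + k, minlength=last + 1)
                k += 1
        tiles[sample] = counts[: len(tiles)]
    return tiles


def sample_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in ("contig", "start", "end", "cpg_count")]


def coupling_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """CpG-dependent normalisation to relative methylation scores.

    Per sample: counts -> counts-per-million; the expected CPM at each
    integer CpG-coupling level is the mean CPM over windows sharing that
    level, smoothed monotone-increasing by isotonic regression;
    rms = CPM / expected(CF).  Missing CF levels are interpolated by the
    isotonic fit; the expectation is floored to keep rms finite.
    """
    cf = matrix["cpg_count"].to_numpy(dtype=float)
    out = matrix[["contig", "start", "end", "cpg_count"]].copy()
    for sample in sample_columns(matrix):
        counts = matrix[sample].to_numpy(dtype=float)
        total = counts.sum()
        cpm = counts / total * 1e6 if total > 0 else counts
        levels, inverse = np.unique(cf, return_inverse=True)
        level_mean = np.bincount(inverse, weights=cpm) / np.bincount(inverse)
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        iso.fit(levels, level_mean)
        expected = iso.predict(cf)
        floor = max(cpm.mean() * 1e-3, 1e-9)
        expected = np.maximum(expected, floor)
        out[sample] = cpm / expected
    return out


def differential_windows(
    matrix: pd.DataFrame,
    rms: pd.DataFrame,
    groups: dict[str, str],
    min_row_sum: int = 10,
) -> pd.DataFrame:
    """Welch two-sample test on log2(rms + 0.1) per window.

    Windows whose total raw count across all samples is below
    ``min_row_sum`` are dropped before testing.  log2fc is the difference
    of group means (second group label minus first).
    """
    samples = sample_columns(matrix)
    labels = sorted(set(groups[s] for s in samples))
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    ga = [s for s in samples if groups[s] == labels[0]]
    gb = [s for s in samples if groups[s] == labels[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need >=2 samples per group")

    total = matrix[samples].sum(axis=1)
    keep = total >= min_row_sum
    sub = rms[keep]
    la = np.log2(sub[ga].to_numpy(dtype=float) + RMS_LOG_OFFSET)
    lb = np.log2(sub[gb].to_numpy(dtype=float) + RMS_LOG_OFFSET)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # zero-variance windows raise precision warnings; they are given
        # explicit p-values below
        _warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    mean_diff = lb.mean(axis=1) - la.mean(axis=1)
    # zero variance in both groups: p=1 when means agree, ~0 otherwise
    var_zero = (la.std(axis=1) == 0) & (lb.std(axis=1) == 0)
    p = np.where(var_zero & (mean_diff == 0), 1.0, p)
    p = np.where(var_zero & (mean_diff != 0), np.finfo(float).tiny, p)
    out = sub[["contig", "start", "end", "cpg_count"]].copy()
    out["log2fc"] = mean_diff  # positive = higher in second group (B)
    out["p"] = p
    out["group_a"] = labels[0]
    out["group_b"] = labels[1]
    return out.reset_index(drop=True)


@dataclass
class Dmr:
    contig: str
    start: int
    end: int
    n_windows: int
    log2fc: float
    p: float
    direction: str  # hyper_in_B / hypo_in_B
    n_cpgs: int


def merge_dmrs(
    diff: pd.DataFrame,
    alpha: float = 0.05,
    max_gap: int = 1,
    genome: ReferenceGenome | None = None,
) -> list[Dmr]:
    """Merge same-direction significant windows with gaps <= max_gap bp.

    n_cpgs is recomputed on the merged span when a genome is attached;
    the merged p is the minimum member p and log2fc the member mean.
    """
    sig = diff[diff["p"] <= alpha].copy()
    if not len(sig):
        return []
    sig = sig.sort_values(["contig", "start"]).reset_index(drop=True)
    dmrs: list[Dmr] = []
    run: list[pd.Series] = []

    def close(run):
        if not run:
            return
        block = pd.DataFrame(run)
        contig = str(block.iloc[0]["contig"])
        start, end = int(block.iloc[0]["start"]), int(block.iloc[-1]["end"])
        lfc = float(block["log2fc"].mean())
        n_cpgs = genome.cpg_count(contig, start, end) if genome is not None else int(block["cpg_count"].sum())
        dmrs.append(
            Dmr(
                contig=contig,
                start=start,
                end=end,
                n_windows=len(block),
                log2fc=lfc,
                p=float(block["p"].min()),
                direction="hyper_in_B" if lfc > 0 else "hypo_in_B",
                n_cpgs=n_cpgs,
            )
        )

    for _, row in sig.iterrows():
        if run and (
            row["contig"] != run[-1]["contig"]
            or row["start"] - run[-1]["end"] > max_gap
            or np.sign(row["log2fc"]) != np.sign(run[-1]["log2fc"])
        ):
            close(run)
            run = []
        run.append(row)
    close(run)
    return dmrs


def direction_summary(dmrs) -> dict:
    """Counts and percentages of hypo/hyper (in the second group) DMRs.

    Accepts Dmr objects or anything with a ``direction`` attribute/key.
    """
    def direction_of(d):
        return d.direction if hasattr(d, "direction") else d["direction"]

    n = len(dmrs)
    hypo = sum(1 for d in dmrs if direction_of(d) == "hypo_in_B")
    hyper = n - hypo
    return {
        "n_total": n,
        "n_hypo_in_B": hypo,
        "n_hyper_in_B": hyper,
        "pct_hypo_in_B": 100.0 * hypo / n if n else float("nan"),
        "pct_hyper_in_B": 100.0 * hyper / n if n else float("nan"),
    }


def cpg_enrichment_score(regions: IntervalSet, genome: ReferenceGenome) -> dict:
    """CpG enrichment of a region set relative to the genome.

    relH-like: (CpG per bp in regions) / (CpG per bp genome-wide).
    GoGe-like: observed/expected CpG inside regions divided by the
    genome's observed/expected, where expected = (#C * #G) / length.
    """
    span = regions.total_span()
    if span <= 0:
        raise ValueError("zero-length region set")
    cpg_in = 0
    c_in = g_in = 0
    for r in regions.df.itertuples():
        seq = genome.fetch(r.contig, r.start, r.end)
        cpg_in += seq.count("CG")
        c_in += seq.count("C")
        g_in += seq.count("G")
    genome_cpg = genome.cpg_count_total()
    genome_len = genome.total_length
    genome_c = sum(s.count("C") for s in genome.contigs.values())
    genome_g = sum(s.count("G") for s in genome.contigs.values())

    relh_regions = cpg_in / span
    relh_genome = genome_cpg / genome_len
    goge_regions = cpg_in / max(c_in * g_in / span, 1e-12)
    goge_genome = genome_cpg / max(genome_c * genome_g / genome_len, 1e-12)
    return {
        "relh_score": relh_regions / relh_genome if relh_genome > 0 else float("nan"),
        "goge_score": goge_regions / goge_genome if goge_genome > 0 else float("nan"),
        "cpg_in_regions": cpg_in,
        "region_span": span,
    }


def dmrs_to_frame(dmrs: list[Dmr]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": d.contig,
                "start": d.start,
                "end": d.end,
                "n_windows": d.n_windows,
                "log2fc": d.log2fc,
                "p": d.p,
                "direction": d.direction,
                "n_cpgs": d.n_cpgs,
            }
            for d in dmrs
        ],
        columns=["contig", "start", "end", "n_windows", "log2fc", "p", "direction", "n_cpgs"],
    )


def dmrs_to_intervals(dmrs: list[Dmr]) -> IntervalSet:
    return IntervalSet.from_records(
        [(d.contig, d.start, d.end, d.direction) for d in dmrs], kind="generic"
    )
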