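"""Copy-number detection from two pooled libraries of read intervals.

Implements the window-size recommendation and the Gaussian-approximation
ratio test for Poisson window counts (Geary-Hinkley transformation),
Bonferroni thresholding, merging of adjacent significant windows, and
gain/loss / top-call labelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import IntervalSet, ReferenceGenome

# defaults of the published CNV-seq recommendation
DEFAULT_LOG2_THRESHOLD = 0.6
DEFAULT_P_THRESHOLD = 0.001
DEFAULT_ENLARGEMENT = 1.5
TOP_FOLD = 8.0


def recommend_window(
    genome_length: int,
    n_reads_a: float,
    n_reads_b: float,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    enlargement: float = DEFAULT_ENLARGEMENT,
) -> int:
    """Best window size for detecting a +-log2_threshold copy ratio.

    Minimum window at which a true per-base ratio of 2**(+-log2_threshold)
    reaches significance p_threshold under the Gaussian approximation of
    the Poisson count ratio, taken as the larger of the gain/loss windows
    and multiplied by the enlargement factor.
    """
    if genome_length <= 0 or n_reads_a <= 0 or n_reads_b <= 0:
        raise ValueError("genome length and read counts must be positive")
    z = stats.norm.ppf(1 - p_threshold / 2)

    def min_window(rho: float) -> float:
        return (
            genome_length
            * z**2
            * (rho**2 * n_reads_a / n_reads_b + 1)
            / (n_reads_a * (rho - 1) ** 2)
        )

    w = max(min_window(2.0**log2_threshold), min_window(2.0**-log2_threshold))
    return int(round(w * enlargement))


def window_counts_from_reads(
    reads_a: IntervalSet, reads_b: IntervalSet, genome: ReferenceGenome, window_bp: int
) -> pd.DataFrame:
    """Per-window read-start counts for the two pooled libraries."""
    tiles = genome.tile(window_bp)
    tiles["count_a"] = 0
    tiles["count_b"] = 0
    for col, reads in (("count_a", reads_a), ("count_b", reads_b)):
        for contig, sub in reads.df.groupby("contig", sort=False):
            m = tiles["contig"] == contig
            if not m.any():
                continue
            clen = genome.contig_length(contig)
            idx = np.minimum(sub["start"].to_numpy() // window_bp, (clen - 1) // window_bp)
            counts = np.bincount(idx, minlength=int(m.sum()))
            tiles.loc[m, col] = counts[: int(m.sum())]
    return tiles


def window_log2_test(
    windows: pd.DataFrame,
    n_reads_a: float,
    n_reads_b: float,
    genome_length: int,
    window_bp: int,
) -> pd.DataFrame:
    """Library-size-normalised log2 ratio and Geary-Hinkley p per window.

    t = (lam_b * r - lam_a) / sqrt(lam_b * r^2 + lam_a) with r the raw
    count ratio and lam the expected counts under no copy difference;
    t is standard normal under H0.  Zero counts are floored at 0.5 for
    the ratio and flagged.
    """
    df = windows.copy()
    a = df["count_a"].to_numpy(dtype=float)
    b = df["count_b"].to_numpy(dtype=float)
    flagged = (a <= 0) | (b <= 0)
    af = np.maximum(a, 0.5)
    bf = np.maximum(b, 0.5)
    widths = (df["end"] - df["start"]).to_numpy(dtype=float)
    lam_a = n_reads_a * widths / genome_length
    lam_b = n_reads_b * widths / genome_length
    r = af / bf
    t = (lam_b * r - lam_a) / np.sqrt(lam_b * r**2 + lam_a)
    p = np.minimum(2 * stats.norm.sf(np.abs(t)), 1.0)
    df["log2_ratio"] = np.log2((af / n_reads_a) / (bf / n_reads_b))
    df["t"] = t
    df["p"] = p
    df["zero_flagged"] = flagged
    return df


@dataclass
class CnvCall:
    contig: str
    start: int
    end: int
    n_windows: int
    mean_log2_ratio: float
    direction: str  # gain_in_A / gain_in_B
    is_top: bool


def call_cnvs(windows: pd.DataFrame, alpha: float = 0.05) -> list[CnvCall]:
    """Merge adjacent same-direction Bonferroni-significant windows.

    Threshold = alpha / number of tested windows.  ``is_top`` marks calls
    whose mean fold change over unflagged member windows is >= 8x in
    either direction; fully flagged calls are never top.
    """
    n = len(windows)
    if n == 0:
        return []
    threshold = alpha / n
    sig = windows[windows["p"] < threshold].copy()
    if not len(sig):
        return []
    sig = sig.sort_values(["contig", "start"]).reset_index(drop=True)
    calls: list[CnvCall] = []
    run: list[pd.Series] = []

    def close(run):
        if not run:
            return
        block = pd.DataFrame(run)
        unflagged = block[~block["zero_flagged"]]
        mean_l2 = float(block["log2_ratio"].mean())
        is_top = bool(len(unflagged)) and abs(float(unflagged["log2_ratio"].mean())) >= np.log2(TOP_FOLD)
        calls.append(
            CnvCall(
                contig=str(block.iloc[0]["contig"]),
                start=int(block.iloc[0]["start"]),
                end=int(block.iloc[-1]["end"]),
                n_windows=len(block),
                mean_log2_ratio=mean_l2,
                direction="gain_in_A" if mean_l2 > 0 else "gain_in_B",
                is_top=is_top,
            )
        )

    for _, row in sig.iterrows():
        if run and (
            row["contig"] != run[-1]["contig"]
            or row["start"] != run[-1]["end"]
            or np.sign(row["log2_ratio"]) != np.sign(run[-1]["log2_ratio"])
        ):
            close(run)
            run = []
        run.append(row)
    close(run)
    return calls


def gain_loss_summary(calls: list[CnvCall]) -> tuple[float, float]:
    """(fraction gains in A, fraction losses in A) over the call set."""
    if not calls:
        raise ValueError("empty call set")
    gains = sum(1 for c in calls if c.direction == "gain_in_A")
    return gains / len(calls), 1 - gains / len(calls)


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": c.contig,
                "start": c.start,
                "end": c.end,
                "n_windows": c.n_windows,
                "mean_log2_ratio": c.mean_log2_ratio,
                "direction": c.direction,
                "is_top": c.is_top,
            }
            for c in calls
        ],
        columns=["contig", "start", "end", "n_windows", "mean_log2_ratio", "direction", "is_top"],
    )


def calls_to_intervals(calls: list[CnvCall]) -> IntervalSet:
    return IntervalSet.from_records(
        [(c.contig, c.start, c.end, c.direction) for c in calls], kind="generic"
    )
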