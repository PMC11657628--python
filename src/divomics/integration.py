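"""Cross-omic interval integration: pairwise hypergeometric overlap tests,
multiway Venn counts, DMR-in-CNV confounding flags, and repeat-class
overlap profiles.

All overlap counting is any-overlap (>= 1 bp) on half-open intervals, so
abutting features do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import IntervalSet


@dataclass
class OverlapResult:
    name_a: str
    name_b: str
    n_a: int
    n_b: int
    n_overlap: int
    universe_n: int
    p_hypergeometric: float
    counted_set: str  # which set's elements were counted


def default_universe(set_a: IntervalSet, set_b: IntervalSet, genome_length: int) -> int:
    """Genome length divided by the mean feature width of both sets' union."""
    widths = np.concatenate(
        [
            (set_a.df["end"] - set_a.df["start"]).to_numpy(),
            (set_b.df["end"] - set_b.df["start"]).to_numpy(),
        ]
    )
    if not len(widths):
        raise ValueError("both sets empty")
    return max(int(round(genome_length / widths.mean())), len(set_a) + len(set_b))


def pairwise_overlap_test(
    set_a: IntervalSet,
    set_b: IntervalSet,
    universe_n: int,
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapResult:
    """Upper-tail hypergeometric test of interval overlap.

    The overlap count is the number of elements of the smaller set that
    intersect at least one element of the other; p = P(X >= n_overlap)
    for X ~ Hypergeom(universe_n, n_a, n_b).
    """
    n_a, n_b = len(set_a), len(set_b)
    if universe_n < max(n_a, n_b):
        raise ValueError(f"universe {universe_n} smaller than a set ({n_a}, {n_b})")
    if n_a <= n_b:
        k = set_a.count_overlapping(set_b)
        counted = name_a
    else:
        k = set_b.count_overlapping(set_a)
        counted = name_b
    p = float(stats.hypergeom.sf(k - 1, universe_n, n_a, n_b))
    return OverlapResult(
        name_a=name_a,
        name_b=name_b,
        n_a=n_a,
        n_b=n_b,
        n_overlap=k,
        universe_n=universe_n,
        p_hypergeometric=min(max(p, np.finfo(float).tiny), 1.0),
        counted_set=counted,
    )


class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def multiway_venn(sets: dict[str, IntervalSet]) -> dict[tuple[str, ...], int]:
    """Connected-component Venn counts for 2-4 interval sets.

    Features overlapping across sets are chained into components; each
    component contributes one count to the cell named by the sets its
    members come from, so a feature chain spanning all sets is counted
    once in the full-intersection cell.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("multiway_venn supports 2-4 sets")
    # global node index per (set, element)
    offsets, total = {}, 0
    for name in names:
        offsets[name] = total
        total += len(sets[name])
    dsu = _DisjointSet(total)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            a, b = sets[na], sets[nb]
            for ai in range(len(a)):
                row = a.df.iloc[ai]
                probe = IntervalSet.from_records(
                    [(row["contig"], int(row["start"]), int(row["end"]))]
                )
                hits = b.overlaps_any(probe)
                for bi in np.flatnonzero(hits):
                    dsu.union(offsets[na] + ai, offsets[nb] + int(bi))
    member_sets: dict[int, set[str]] = {}
    for name in names:
        for i in range(len(sets[name])):
            root = dsu.find(offsets[name] + i)
            member_sets.setdefault(root, set()).add(name)
    cells: dict[tuple[str, ...], int] = {}
    for members in member_sets.values():
        key = tuple(n for n in names if n in members)
        cells[key] = cells.get(key, 0) + 1
    return cells


def flag_dmr_in_cnv(dmrs: IntervalSet, cnvs: IntervalSet) -> np.ndarray:
    """Mask of DMRs whose span intersects any CNV call."""
    return dmrs.overlaps_any(cnvs)


@dataclass
class RepeatOverlapProfile:
    table: pd.DataFrame  # class, n_query, frac_query, plus per-background fracs/folds


def repeat_profile(
    queries: IntervalSet,
    repeats: IntervalSet,
    background_sets: dict[str, IntervalSet] | None = None,
    known_classes: list[str] | None = None,
) -> RepeatOverlapProfile:
    """Per-repeat-class overlap frequency of a query set, with folds
    against one or more background interval sets.

    Unknown repeat-class labels are grouped under "Other"; a query
    overlapping several classes is counted once per class.
    """
    classes = repeats.df["name"].astype(str)
    if known_classes is not None:
        classes = classes.where(classes.isin(known_classes), "Other")
    rows = []
    for rclass in sorted(classes.unique()):
        sub = repeats.subset((classes == rclass).to_numpy())
        row = {
            "class": rclass,
            "n_query": int(queries.overlaps_any(sub).sum()),
            "frac_query": float(queries.overlaps_any(sub).mean()) if len(queries) else float("nan"),
        }
        if background_sets:
            for bg_name, bg in background_sets.items():
                frac_bg = float(bg.overlaps_any(sub).mean()) if len(bg) else float("nan")
                row[f"frac_{bg_name}"] = frac_bg
                row[f"fold_vs_{bg_name}"] = (
                    row["frac_query"] / frac_bg if frac_bg and np.isfinite(frac_bg) else float("nan")
                )
        rows.append(row)
    return RepeatOverlapProfile(table=pd.DataFrame(rows))


def overlap_results_to_frame(results: list[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_a": r.name_a,
                "set_b": r.name_b,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "n_overlap": r.n_overlap,
                "universe_n": r.universe_n,
                "p_hypergeometric": r.p_hypergeometric,
                "counted_set": r.counted_set,
            }
            for r in results
        ]
    )
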