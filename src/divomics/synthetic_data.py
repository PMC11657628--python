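"""Synthetic two-line multi-omic dataset generator with a truth manifest.

Produces an internally consistent genome, gene models, two-line diploid
genotypes (Balding-Nichols divergence model), per-sample MeDIP read
intervals coupled to CpG density, pooled input read depth with planted
copy-ratio segments, repeats and QTL intervals.  Every output is fully
determined by the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomic_io import (
    GeneModel,
    GenotypeTable,
    IntervalSet,
    ReferenceGenome,
    write_bed,
    write_fasta,
    write_gff3,
    write_group_map,
    write_vcf,
)

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimulationConfig:
    seed: int = 1
    n_contigs: int = 5
    contig_length: int = 200_000
    gc_fraction: float = 0.42
    cpg_depletion: float = 0.8  # fraction of background CpGs swapped away
    n_genes: int = 40
    promoter_flank: int = 3_000
    island_halfwidth: int = 500
    island_cpg_rate: float = 0.05  # planted CG per dinucleotide in island cores
    n_samples_line_a: int = 10
    n_samples_line_b: int = 7
    n_loci: int = 5_000
    fraction_fixed: float = 0.002
    fraction_high_fst: float = 0.05
    fraction_cpg_loss: float = 0.05
    fraction_novel_cpg: float = 0.04
    fst_high: float = 0.30
    fst_background: float = 0.045
    missing_rate: float = 0.05
    n_dmr: int = 30
    dmr_log2fc: float = 1.0
    window_bp: int = 300
    medip_depth: float = 40.0  # per-sample count scale before CpG coupling
    medip_dispersion: float = 0.2
    coupling_k: float = 10.0
    read_length: int = 50
    n_cnv_segments: int = 12
    cnv_ratios: tuple = (0.5, 2.0, 3.0, 8.0)
    cnv_segment_length: int = 4_000
    n_input_reads: int = 1_000_000  # per line
    repeat_classes: dict = field(
        default_factory=lambda: {
            "LINE": 0.07,
            "LTR": 0.03,
            "SINE": 0.02,
            "Simple_repeat": 0.02,
        }
    )
    n_qtl: int = 5
    qtl_length_min: int = 50_000
    qtl_length_max: int = 100_000

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction",
            "cpg_depletion",
            "fraction_fixed",
            "fraction_high_fst",
            "fraction_cpg_loss",
            "fraction_novel_cpg",
            "fst_high",
            "fst_background",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_fixed + self.fraction_high_fst >= 1.0:
            raise ValueError("fraction_fixed + fraction_high_fst must be < 1")

    @property
    def genome_length(self) -> int:
        return self.n_contigs * self.contig_length

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "cnv_ratios" in data:
            data["cnv_ratios"] = tuple(data["cnv_ratios"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["cnv_ratios"] = list(data["cnv_ratios"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TruthManifest:
    """Machine-readable record of every planted feature."""

    locus_class: list[str] = field(default_factory=list)  # fixed/high_fst/neutral
    cpg_loss_flags: list[bool] = field(default_factory=list)
    novel_cpg_flags: list[bool] = field(default_factory=list)
    dmrs: list[dict] = field(default_factory=list)  # contig,start,end,direction,log2fc
    cnv_segments: list[dict] = field(default_factory=list)  # contig,start,end,ratio
    islands: list[dict] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _place_nonoverlapping(rng, contig_length, lengths, margin=0, max_tries=10_000):
    """Greedy placement of interval lengths on one contig without overlap."""
    placed: list[tuple[int, int]] = []
    for L in lengths:
        for _ in range(max_tries):
            s = int(rng.integers(margin, contig_length - L - margin))
            iv = (s, s + L)
            if all(iv[1] + margin <= a or b + margin <= iv[0] for a, b in placed):
                placed.append(iv)
                break
        else:
            raise RuntimeError("could not place interval without overlap")
    return placed


def simulate_genome(config: SimulationConfig, rng=None):
    """Genome + gene models + repeats + QTLs.

    The background is CpG-depleted by swapping a fraction of CG
    dinucleotides to GC (composition-preserving); promoter cores carry
    planted CpG islands so that CpG density inside the promoter flank is
    at least twice the genome background.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base_p = np.array(
        [
            (1 - config.gc_fraction) / 2,
            config.gc_fraction / 2,
            config.gc_fraction / 2,
            (1 - config.gc_fraction) / 2,
        ]
    )
    contig_names = [f"chr{i + 1}" for i in range(config.n_contigs)]
    seqs = {
        name: rng.choice(4, size=config.contig_length, p=base_p)
        for name in contig_names
    }

    # genes: round-robin over contigs, greedy non-overlapping placement
    mean_span = 6_000
    if config.n_genes * mean_span > config.genome_length:
        raise ValueError("gene span budget exceeds genome length")
    genes: list[GeneModel] = []
    per_contig = [config.n_genes // config.n_contigs] * config.n_contigs
    for i in range(config.n_genes % config.n_contigs):
        per_contig[i] += 1
    gidx = 0
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for name, n_here in zip(contig_names, per_contig):
        lengths = rng.integers(3_000, 9_000, size=n_here)
        spans = _place_nonoverlapping(
            rng, config.contig_length, lengths, margin=config.promoter_flank + 500
        )
        gene_spans[name] = spans
        for s, e in spans:
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 6))
            cuts = np.sort(rng.choice(np.arange(s + 100, e - 100), size=2 * n_exons - 2, replace=False))
            bounds = np.concatenate([[s], cuts, [e]])
            exons = [
                (int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_exons)
            ]
            exons = [(a, b) for a, b in exons if b > a]
            first, last = exons[0], exons[-1]
            utr5, utr3 = [], []
            if first[1] - first[0] > 60 and last[1] - last[0] > 60:
                if strand == "+":
                    utr5 = [(first[0], first[0] + 30)]
                    utr3 = [(last[1] - 30, last[1])]
                else:
                    utr5 = [(last[1] - 30, last[1])]
                    utr3 = [(first[0], first[0] + 30)]
            genes.append(
                GeneModel(
                    gene_id=f"gene{gidx:04d}",
                    contig=name,
                    strand=strand,
                    exons=exons,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
            gidx += 1

    # CpG islands at promoter cores
    islands = []
    for g in genes:
        lo = max(0, g.tss - config.island_halfwidth)
        hi = min(config.contig_length - 1, g.tss + config.island_halfwidth)
        islands.append({"contig": g.contig, "start": int(lo), "end": int(hi)})

    island_mask = {name: np.zeros(config.contig_length, dtype=bool) for name in contig_names}
    for isl in islands:
        island_mask[isl["contig"]][isl["start"] : isl["end"]] = True
    flank_mask = {name: np.zeros(config.contig_length, dtype=bool) for name in contig_names}
    for g in genes:
        lo = max(0, g.tss - config.promoter_flank)
        hi = min(config.contig_length, g.tss + config.promoter_flank)
        flank_mask[g.contig][lo:hi] = True

    # deplete background CpGs sparing promoter flanks; C->G (or G->C when
    # the left neighbour is a C) preserves composition and cannot recreate
    # a CpG against the untouched neighbour
    for name in contig_names:
        seq = seqs[name]
        is_cg = (seq[:-1] == 1) & (seq[1:] == 2)
        cand = np.flatnonzero(is_cg & ~flank_mask[name][:-1])
        cand = cand[(cand > 0) & (cand + 2 < len(seq))]
        kill = cand[rng.random(len(cand)) < config.cpg_depletion]
        left_not_c = seq[kill - 1] != 1
        right_not_g = seq[kill + 2] != 2
        c_to_g = kill[left_not_c]
        g_to_c = kill[~left_not_c & right_not_g] + 1
        seq[c_to_g] = 2
        seq[g_to_c] = 1

    # plant extra CpGs in island cores
    for name in contig_names:
        seq = seqs[name]
        core = np.flatnonzero(island_mask[name][:-1])
        plant = core[rng.random(len(core)) < config.island_cpg_rate / 2]
        # avoid immediately adjacent plants clobbering each other
        keep = np.concatenate([[True], np.diff(plant) > 1]) if len(plant) else np.array([], dtype=bool)
        plant = plant[keep]
        seq[plant], seq[plant + 1] = 1, 2

    genome = ReferenceGenome(
        {name: "".join(BASES[seqs[name]]) for name in contig_names}
    )

    # repeats: per class, place intervals until the genome fraction is met
    repeat_rows = []
    for rclass, frac in config.repeat_classes.items():
        target = frac * config.genome_length
        covered = 0
        while covered < target:
            L = int(rng.integers(200, 2_000))
            name = contig_names[int(rng.integers(config.n_contigs))]
            s = int(rng.integers(0, config.contig_length - L))
            repeat_rows.append((name, s, s + L, rclass))
            covered += L
    repeats = IntervalSet.from_records(repeat_rows, kind="repeat")

    qtl_rows = []
    for i in range(config.n_qtl):
        L = int(rng.integers(config.qtl_length_min, config.qtl_length_max + 1))
        L = min(L, config.contig_length - 2)
        name = contig_names[int(rng.integers(config.n_contigs))]
        s = int(rng.integers(0, config.contig_length - L))
        qtl_rows.append((name, s, s + L, f"QTL_FP{i + 1}"))
    qtls = IntervalSet.from_records(qtl_rows, kind="qtl")

    truth_genes = [
        {
            "gene_id": g.gene_id,
            "contig": g.contig,
            "strand": g.strand,
            "tss": g.tss,
            "start": g.start,
            "end": g.end,
        }
        for g in genes
    ]
    return genome, genes, repeats, qtls, islands, truth_genes


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _candidate_positions(genome: ReferenceGenome):
    """Index CpG-loss-capable and novel-CpG-capable positions per contig."""
    loss, gain = {}, {}
    for name, seq in genome.contigs.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        c, g = ord("C"), ord("G")
        is_cg = (arr[:-1] == c) & (arr[1:] == g)
        loss[name] = np.flatnonzero(is_cg)  # the C of a reference CpG
        # ref base != C with 3' neighbour G: alt C creates a CpG
        gain[name] = np.flatnonzero((arr[:-1] != c) & (arr[1:] == g))
    return loss, gain


def simulate_genotypes(config: SimulationConfig, genome: ReferenceGenome, rng=None):
    """Two-line diploid genotypes under the Balding-Nichols model.

    Per-line allele frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) around an
    ancestral p ~ U(0.05, 0.95), with F the background or elevated
    divergence parameter.  Fixed-differential loci are hard-set to
    opposite homozygotes before missingness.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_a, n_b = config.n_samples_line_a, config.n_samples_line_b
    n_loci = config.n_loci
    contig_names = list(genome.contigs)

    n_fixed = round(config.fraction_fixed * n_loci)
    n_high = round(config.fraction_high_fst * n_loci)
    n_loss = round(config.fraction_cpg_loss * n_loci)
    n_gain = round(config.fraction_novel_cpg * n_loci)

    loss_cand, gain_cand = _candidate_positions(genome)

    # choose locus positions: planted CpG-loss sites, planted novel-CpG
    # sites, then uniform background, all distinct
    chosen: set[tuple[str, int]] = set()

    def draw(cands_by_contig, n):
        out = []
        while len(out) < n:
            name = contig_names[int(rng.integers(len(contig_names)))]
            cands = cands_by_contig[name]
            if not len(cands):
                continue
            p = int(cands[int(rng.integers(len(cands)))])
            if 0 < p < genome.contig_length(name) - 1 and (name, p) not in chosen:
                chosen.add((name, p))
                out.append((name, p))
        return out

    loss_sites = draw(loss_cand, n_loss)
    gain_sites = draw(gain_cand, n_gain)
    background = draw(
        {name: np.arange(1, genome.contig_length(name) - 1) for name in contig_names},
        n_loci - n_loss - n_gain,
    )

    loci = []
    for name, p in loss_sites:
        ref = genome.base(name, p)  # C by construction
        alt = ["T", "A", "G"][int(rng.integers(3))]
        loci.append((name, p, ref, alt, True, False))
    for name, p in gain_sites:
        ref = genome.base(name, p)  # != C, 3' neighbour G
        # a G whose 5' neighbour is C is a CpG loss, which takes precedence
        is_loss = ref == "G" and genome.base(name, p - 1) == "C"
        loci.append((name, p, ref, "C", is_loss, not is_loss))
    for name, p in background:
        ref = genome.base(name, p)
        others = [b for b in "ACGT" if b != ref]
        alt = others[int(rng.integers(3))]
        # background loci can satisfy a CpG context by chance; the truth
        # manifest records the realised context, not just deliberate plants
        prv, nxt = genome.base(name, p - 1), genome.base(name, p + 1)
        is_loss = (ref == "C" and nxt == "G") or (ref == "G" and prv == "C")
        is_gain = not is_loss and alt == "C" and ref != "C" and nxt == "G"
        loci.append((name, p, ref, alt, is_loss, is_gain))
    order = sorted(range(len(loci)), key=lambda i: (loci[i][0], loci[i][1]))
    loci = [loci[i] for i in order]

    classes = np.array(["neutral"] * n_loci, dtype=object)
    special = rng.choice(n_loci, size=n_fixed + n_high, replace=False)
    classes[special[:n_fixed]] = "fixed"
    classes[special[n_fixed:]] = "high_fst"

    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    dosage = np.zeros((n_a + n_b, n_loci), dtype=np.int8)
    for j in range(n_loci):
        if classes[j] == "fixed":
            flip = rng.random() < 0.5
            dosage[:n_a, j] = 2 if flip else 0
            dosage[n_a:, j] = 0 if flip else 2
            continue
        F = config.fst_high if classes[j] == "high_fst" else config.fst_background
        if F <= 0:
            pa = pb = p_anc[j]
        else:
            a = p_anc[j] * (1 - F) / F
            b = (1 - p_anc[j]) * (1 - F) / F
            pa, pb = rng.beta(a, b, size=2)
        dosage[:n_a, j] = rng.binomial(2, pa, size=n_a)
        dosage[n_a:, j] = rng.binomial(2, pb, size=n_b)

    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = -1

    table = GenotypeTable(
        sample_ids=[f"A{i + 1:02d}" for i in range(n_a)]
        + [f"B{i + 1:02d}" for i in range(n_b)],
        groups=["A"] * n_a + ["B"] * n_b,
        contig=np.array([l[0] for l in loci], dtype=object),
        pos=np.array([l[1] for l in loci], dtype=np.int64),
        ref=np.array([l[2] for l in loci], dtype=object),
        alt=np.array([l[3] for l in loci], dtype=object),
        dosage=dosage,
    )
    truth = {
        "locus_class": list(classes),
        "cpg_loss_flags": [bool(l[4]) for l in loci],
        "novel_cpg_flags": [bool(l[5]) for l in loci],
    }
    return table, truth


def coupling_function(cf, k: float):
    """Saturating CpG-coupling curve f(c) = c / (c + k)."""
    cf = np.asarray(cf, dtype=float)
    return cf / (cf + k)


def plant_dmrs(config: SimulationConfig, genome: ReferenceGenome, rng=None):
    """Choose non-overlapping DMR spans (1-3 windows) in CpG-rich windows."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    tiles = genome.tile(config.window_bp)
    cf = np.array(
        [genome.cpg_count(r.contig, r.start, r.end) for r in tiles.itertuples()]
    )
    rich = np.flatnonzero(cf >= max(8, int(np.median(cf)) + 2))
    taken = np.zeros(len(tiles), dtype=bool)
    dmrs = []
    tries = 0
    while len(dmrs) < config.n_dmr and tries < 50_000:
        tries += 1
        i = int(rich[int(rng.integers(len(rich)))])
        span = int(rng.integers(1, 4))
        idx = np.arange(i, min(i + span, len(tiles)))
        sub = tiles.iloc[idx]
        if sub["contig"].nunique() != 1 or taken[idx].any():
            continue
        # keep a one-window buffer so planted DMRs never merge together
        lo, hi = max(0, idx[0] - 1), min(len(tiles), idx[-1] + 2)
        if taken[lo:hi].any():
            continue
        taken[lo:hi] = True
        direction = "hyper_in_A" if rng.random() < 0.5 else "hyper_in_B"
        dmrs.append(
            {
                "contig": sub.iloc[0]["contig"],
                "start": int(sub.iloc[0]["start"]),
                "end": int(sub.iloc[-1]["end"]),
                "direction": direction,
                "log2fc": float(config.dmr_log2fc),
                "window_indices": [int(x) for x in idx],
            }
        )
    if len(dmrs) < config.n_dmr:
        raise RuntimeError("could not place requested DMRs in CpG-rich windows")
    return dmrs, tiles, cf


def simulate_medip(config: SimulationConfig, genome: ReferenceGenome, dmr_truth, rng=None):
    """Per-sample MeDIP read intervals.

    Window mean = size_factor * depth * f(CF) shifted by +-log2fc/2 for
    planted DMR windows; counts ~ NegativeBinomial(mean, dispersion);
    each count is realised as fixed-length reads uniform in the window.
    Returns {sample_id: IntervalSet} plus the group map.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    tiles = genome.tile(config.window_bp)
    cf = np.array(
        [genome.cpg_count(r.contig, r.start, r.end) for r in tiles.itertuples()]
    )
    base_mean = config.medip_depth * coupling_function(cf, config.coupling_k)

    shift_a = np.zeros(len(tiles))
    shift_b = np.zeros(len(tiles))
    for d in dmr_truth:
        idx = np.asarray(d["window_indices"], dtype=int)
        half = d["log2fc"] / 2.0
        if d["direction"] == "hyper_in_A":
            shift_a[idx] += half
            shift_b[idx] -= half
        else:
            shift_a[idx] -= half
            shift_b[idx] += half

    samples = [f"A{i + 1:02d}" for i in range(config.n_samples_line_a)] + [
        f"B{i + 1:02d}" for i in range(config.n_samples_line_b)
    ]
    groups = {s: ("A" if s.startswith("A") else "B") for s in samples}
    phi = config.medip_dispersion
    reads: dict[str, IntervalSet] = {}
    starts_all = tiles["start"].to_numpy()
    ends_all = tiles["end"].to_numpy()
    contigs_all = tiles["contig"].to_numpy()
    lo_all = starts_all
    hi_all = np.maximum(lo_all + 1, ends_all - config.read_length)
    for s in samples:
        size_factor = rng.lognormal(0.0, 0.1)
        shift = shift_a if groups[s] == "A" else shift_b
        mean = size_factor * base_mean * np.power(2.0, shift)
        if phi < 1e-8:
            counts = rng.poisson(mean)
        else:
            n_param = 1.0 / phi
            p_param = n_param / (n_param + mean)
            counts = np.where(mean > 0, rng.negative_binomial(n_param, np.clip(p_param, 1e-12, 1.0)), 0)
        widx = np.repeat(np.arange(len(counts)), counts)
        rstarts = lo_all[widx] + rng.integers(0, hi_all[widx] - lo_all[widx])
        df = pd.DataFrame(
            {
                "contig": contigs_all[widx],
                "start": rstarts,
                "end": rstarts + config.read_length,
                "name": ".",
                "score": np.nan,
                "strand": np.where(rng.random(len(widx)) < 0.5, "+", "-"),
                "sample": s,
            }
        )
        reads[s] = IntervalSet(df, kind="reads")
    return reads, groups


def plant_cnv_segments(config: SimulationConfig, genome: ReferenceGenome, rng=None):
    """Non-overlapping copy-ratio segments; ratio = line A over line B."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    contig_names = list(genome.contigs)
    segments = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_names}
    tries = 0
    while len(segments) < config.n_cnv_segments and tries < 50_000:
        tries += 1
        name = contig_names[int(rng.integers(len(contig_names)))]
        L = int(config.cnv_segment_length * rng.uniform(0.7, 1.3))
        s = int(rng.integers(0, genome.contig_length(name) - L))
        if any(s < b and a < s + L for a, b in placed[name]):
            continue
        ratio = float(config.cnv_ratios[int(rng.integers(len(config.cnv_ratios)))])
        if rng.random() < 0.5:  # balance gains between the lines
            ratio = 1.0 / ratio
        placed[name].append((s, s + L))
        segments.append({"contig": name, "start": s, "end": s + L, "ratio": ratio})
    if len(segments) < config.n_cnv_segments:
        raise RuntimeError("could not place CNV segments without overlap")
    for c in placed:  # guaranteed by construction, but keep the contract hard
        ivs = sorted(placed[c])
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if b1 > a2:
                raise ValueError("overlapping planted CNV segments")
    return segments


def simulate_input_depth(config: SimulationConfig, genome: ReferenceGenome, cnv_truth, rng=None):
    """Two pooled input read sets with planted copy-ratio segments.

    Per 100-bp tile, expected count is proportional to library size x tile
    length x per-line copy weight; counts are Poisson and reads are placed
    uniformly.  Returns {line: IntervalSet}.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 5)
    ivs = sorted(
        (d["contig"], d["start"], d["end"]) for d in cnv_truth
    )
    for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
        if c1 == c2 and e1 > s2:
            raise ValueError("overlapping planted CNV segments")

    tile_bp = 100
    tiles = genome.tile(tile_bp)
    starts = tiles["start"].to_numpy()
    ends = tiles["end"].to_numpy()
    contigs = tiles["contig"].to_numpy()
    weight_a = np.ones(len(tiles))
    weight_b = np.ones(len(tiles))
    for seg in cnv_truth:
        m = (contigs == seg["contig"]) & (starts >= seg["start"]) & (ends <= seg["end"])
        r = seg["ratio"]
        if r >= 1.0:
            weight_a[m] = r
        else:
            weight_b[m] = 1.0 / r
    lengths = (ends - starts).astype(float)
    out = {}
    for line, weight in (("A", weight_a), ("B", weight_b)):
        w = weight * lengths
        lam = config.n_input_reads * w / w.sum()
        counts = rng.poisson(lam)
        tidx = np.repeat(np.arange(len(counts)), counts)
        rstarts = starts[tidx] + rng.integers(0, np.maximum(ends[tidx] - starts[tidx], 1))
        df = pd.DataFrame(
            {
                "contig": contigs[tidx],
                "start": rstarts,
                "end": rstarts + config.read_length,
            }
        )
        out[line] = IntervalSet(df, kind="reads")
    return out


def simulate_all(config: SimulationConfig):
    """Run every generator with a single master seed; returns a dict."""
    genome, genes, repeats, qtls, islands, truth_genes = simulate_genome(config)
    table, geno_truth = simulate_genotypes(config, genome)
    dmr_truth, _, _ = plant_dmrs(config, genome)
    reads, groups = simulate_medip(config, genome, dmr_truth)
    cnv_truth = plant_cnv_segments(config, genome)
    depth = simulate_input_depth(config, genome, cnv_truth)
    truth = TruthManifest(
        locus_class=geno_truth["locus_class"],
        cpg_loss_flags=geno_truth["cpg_loss_flags"],
        novel_cpg_flags=geno_truth["novel_cpg_flags"],
        dmrs=dmr_truth,
        cnv_segments=cnv_truth,
        islands=islands,
        genes=truth_genes,
    )
    return {
        "genome": genome,
        "genes": genes,
        "repeats": repeats,
        "qtls": qtls,
        "genotypes": table,
        "medip_reads": reads,
        "medip_groups": groups,
        "input_depth": depth,
        "truth": truth,
    }


def write_dataset(data: dict, outdir) -> None:
    """Persist a simulated dataset as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(data["genome"], outdir / "genome.fa")
    write_gff3(data["genes"], outdir / "genes.gff3")
    write_bed(data["repeats"], outdir / "repeats.bed")
    write_bed(data["qtls"], outdir / "qtl.bed")
    write_vcf(data["genotypes"], outdir / "genotypes.vcf")
    table = data["genotypes"]
    write_group_map(dict(zip(table.sample_ids, table.groups)), outdir / "groups.tsv")
    for sample, ivs in data["medip_reads"].items():
        write_bed(ivs, outdir / f"reads_{sample}.bed")
    for line, ivs in data["input_depth"].items():
        write_bed(ivs, outdir / f"input_{line}.bed")
    data["truth"].to_json(outdir / "truth.json")
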