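"""Readers/writers for the on-disk formats and the shared coordinate types.

Every module in this package uses 0-based, half-open coordinates.  VCF is
1-based on disk and is converted at the read/write boundary; BED and GFF3
exon math follow their native conventions and are normalised on load.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand", "sample"]


@dataclass(frozen=True, order=True)
class GenomeCoordinate:
    """A 0-based half-open genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomeCoordinate") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


class ReferenceGenome:
    """Named contigs of upper-case nucleotide sequence over {A,C,G,T,N}."""

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ValueError("genome has no contigs")
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            if not seq:
                raise ValueError(f"empty sequence for contig {name!r}")
            self.contigs[name] = seq.upper()

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def contig_length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][max(start, 0) : end]

    def base(self, contig: str, pos: int) -> str:
        return self.contigs[contig][pos]

    def cpg_count(self, contig: str, start: int, end: int) -> int:
        """Number of CG dinucleotides fully inside [start, end)."""
        return self.fetch(contig, start, end).count("CG")

    def cpg_count_total(self) -> int:
        return sum(s.count("CG") for s in self.contigs.values())

    def tile(self, window_bp: int) -> pd.DataFrame:
        """Tile every contig into adjacent windows of ``window_bp``.

        The last window of a contig may be shorter.  Returns a frame with
        contig/start/end columns in contig order.
        """
        rows = []
        for contig, seq in self.contigs.items():
            starts = np.arange(0, len(seq), window_bp)
            ends = np.minimum(starts + window_bp, len(seq))
            rows.append(pd.DataFrame({"contig": contig, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)


def read_fasta(path) -> ReferenceGenome:
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name {record.id!r} in {path}")
        seq = str(record.seq).strip().upper()
        if not seq:
            raise ValueError(f"empty sequence for contig {record.id!r} in {path}")
        contigs[record.id] = seq
    if not contigs:
        raise ValueError(f"no sequences found in {path}")
    return ReferenceGenome(contigs)


def write_fasta(genome: ReferenceGenome, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass
class GeneModel:
    """Gene structure: sorted non-overlapping exons plus optional UTRs."""

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """0-based position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1


def read_gff3(path) -> list[GeneModel]:
    """Parse gene/exon/UTR records from a GFF3 file into gene models."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            iv = (int(start) - 1, int(end))
            if ftype == "gene":
                gid = attr.get("ID", attr.get("gene_id", ""))
                genes.setdefault(
                    gid, {"contig": contig, "strand": strand, "exons": [], "utr5": [], "utr3": []}
                )
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                parent = attr.get("Parent", "")
                rec = genes.setdefault(
                    parent,
                    {"contig": contig, "strand": strand, "exons": [], "utr5": [], "utr3": []},
                )
                key = {"exon": "exons", "five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}[ftype]
                rec[key].append(iv)
    return [
        GeneModel(gene_id=gid, contig=rec["contig"], strand=rec["strand"],
                  exons=rec["exons"], utr5=rec["utr5"], utr3=rec["utr3"])
        for gid, rec in genes.items()
        if rec["exons"]
    ]


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tdivomics\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.contig}\tdivomics\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
                )
            for s, e in g.utr5:
                fh.write(
                    f"{g.contig}\tdivomics\tfive_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
                )
            for s, e in g.utr3:
                fh.write(
                    f"{g.contig}\tdivomics\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
                )


class IntervalSet:
    """Named, typed genomic intervals with overlap queries.

    Backed by a DataFrame sorted by (contig, start, end).  For
    ``kind="repeat"`` the ``name`` column carries the repeat class; for
    ``kind="reads"`` the ``strand`` and ``sample`` columns are meaningful.
    """

    def __init__(self, df: pd.DataFrame, kind: str = "generic"):
        df = df.copy()
        for col in BED_COLUMNS:
            if col not in df.columns:
                df[col] = None
        if len(df) and (df["end"] <= df["start"]).any():
            bad = df.index[(df["end"] <= df["start"])][0]
            raise ValueError(f"interval end <= start at row {bad}")
        self.df = (
            df[BED_COLUMNS]
            .sort_values(["contig", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.df["start"] = self.df["start"].astype(np.int64)
        self.df["end"] = self.df["end"].astype(np.int64)
        self.kind = kind

    @classmethod
    def from_records(cls, records, kind: str = "generic") -> "IntervalSet":
        """Build from (contig, start, end[, name[, strand[, sample]]]) tuples."""
        rows = []
        for rec in records:
            row = dict(zip(["contig", "start", "end", "name", "strand", "sample"], rec))
            rows.append(row)
        df = pd.DataFrame(rows, columns=["contig", "start", "end", "name", "strand", "sample"])
        return cls(df, kind=kind)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self.df[["contig", "start", "end"]]
        b = other.df[["contig", "start", "end"]]
        return a.equals(b)

    def coordinates(self) -> list[GenomeCoordinate]:
        return [
            GenomeCoordinate(r.contig, int(r.start), int(r.end))
            for r in self.df.itertuples()
        ]

    def total_span(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def subset(self, mask) -> "IntervalSet":
        return IntervalSet(self.df[np.asarray(mask)], kind=self.kind)

    def _per_contig(self):
        for contig, sub in self.df.groupby("contig", sort=False):
            yield contig, sub["start"].to_numpy(), sub["end"].to_numpy()

    def overlaps_any(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per interval of self: intersects >=1 interval of other.

        Half-open semantics: abutting intervals do not overlap.
        """
        out = np.zeros(len(self.df), dtype=bool)
        other_by_contig = {
            c: (s, np.maximum.accumulate(e)) for c, s, e in other._per_contig()
        }
        for contig, sub in self.df.groupby("contig", sort=False):
            if contig not in other_by_contig:
                continue
            ostarts, ocummax_ends = other_by_contig[contig]
            qs = sub["start"].to_numpy()
            qe = sub["end"].to_numpy()
            # candidate others start before the query end
            idx = np.searchsorted(ostarts, qe, side="left")
            hit = np.zeros(len(sub), dtype=bool)
            nz = idx > 0
            hit[nz] = ocummax_ends[idx[nz] - 1] > qs[nz]
            out[sub.index] = hit
        return out

    def count_overlapping(self, other: "IntervalSet") -> int:
        return int(self.overlaps_any(other).sum())


def read_bed(path, kind: str = "generic", genome: ReferenceGenome | None = None) -> IntervalSet:
    """Read a BED3+ file.  Coordinates stay 0-based half-open.

    For ``kind="repeat"`` column 4 is the repeat class (stored as name);
    for ``kind="reads"`` column 6 is the strand and column 7 the sample id.
    Intervals running past the end of an attached genome's contig are
    clipped with a warning.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                first = line
                break
    if not first:
        return IntervalSet(pd.DataFrame(columns=BED_COLUMNS), kind=kind)
    n_fields = min(len(first.rstrip("\n").split("\t")), 7)
    if n_fields < 3:
        raise ValueError(f"{path}: fewer than 3 BED columns")
    raw = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=BED_COLUMNS[:n_fields],
        usecols=range(n_fields),
        dtype={"contig": str, "name": str, "strand": str, "sample": str},
        engine="c",
        skip_blank_lines=True,
    )
    for col in BED_COLUMNS[n_fields:]:
        raw[col] = None
    raw = raw[~raw["contig"].isin(["track", "browser"])].reset_index(drop=True)
    if raw.empty:
        return IntervalSet(pd.DataFrame(columns=BED_COLUMNS), kind=kind)
    starts = pd.to_numeric(raw["start"], errors="coerce")
    ends = pd.to_numeric(raw["end"], errors="coerce")
    bad = starts.isna() | ends.isna()
    if bad.any():
        raise ValueError(f"{path}:{int(bad.idxmax()) + 1}: malformed BED coordinates")
    raw["start"], raw["end"] = starts.astype(np.int64), ends.astype(np.int64)
    inverted = raw["end"] <= raw["start"]
    if inverted.any():
        lineno = int(inverted.idxmax()) + 1
        raise ValueError(
            f"{path}:{lineno}: end <= start "
            f"({int(raw['start'][inverted.idxmax()])} >= {int(raw['end'][inverted.idxmax()])})"
        )
    if genome is not None:
        for contig in raw["contig"].unique():
            if contig not in genome.contigs:
                continue
            clen = genome.contig_length(contig)
            over = (raw["contig"] == contig) & (raw["end"] > clen)
            if over.any():
                warnings.warn(f"{path}: {int(over.sum())} interval(s) clipped to end of {contig}")
                raw.loc[over, "end"] = clen
        raw = raw[raw["end"] > raw["start"]]
    raw["score"] = pd.to_numeric(raw["score"], errors="coerce")
    return IntervalSet(raw, kind=kind)


def write_bed(intervals: IntervalSet, path) -> None:
    """Emit sorted BED; trailing all-empty columns are dropped."""
    df = intervals.df
    ncols = 3
    for i, col in enumerate(BED_COLUMNS[3:], start=4):
        if df[col].notna().any():
            ncols = i
    out = df[BED_COLUMNS[:ncols]].copy()
    if ncols > 4:
        score = out["score"].map(lambda v: "." if pd.isna(v) else f"{v:g}")
        out["score"] = score
    for col in ("name", "strand", "sample"):
        if col in out.columns:
            out[col] = out[col].fillna(".")
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class GenotypeTable:
    """Samples x biallelic loci with group labels and alt-dosage calls.

    ``dosage`` is (n_samples, n_loci) int8 with values {0, 1, 2} and -1
    for missing.  Positions are 0-based.
    """

    sample_ids: list[str]
    groups: list[str]
    contig: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    n_skipped_multiallelic: int = 0

    def __post_init__(self) -> None:
        self.contig = np.asarray(self.contig, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.sample_ids)}, {len(self.pos)})"
            )
        labels = sorted(set(self.groups))
        if len(labels) != 2:
            raise ValueError(f"need exactly two groups, got {labels}")
        self.group_labels: tuple[str, str] = (labels[0], labels[1])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    def group_mask(self, label: str) -> np.ndarray:
        return np.array([g == label for g in self.groups], dtype=bool)

    def missing(self) -> np.ndarray:
        return self.dosage < 0

    def allele_counts(self, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(alt, ref) allele counts per locus over the masked samples."""
        d = self.dosage[mask]
        called = d >= 0
        alt = np.where(called, d, 0).sum(axis=0)
        ref = 2 * called.sum(axis=0) - alt
        return alt.astype(np.int64), ref.astype(np.int64)

    def alt_freq(self, mask: np.ndarray) -> np.ndarray:
        alt, ref = self.allele_counts(mask)
        tot = alt + ref
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def subset_loci(self, mask) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            sample_ids=self.sample_ids,
            groups=self.groups,
            contig=self.contig[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            dosage=self.dosage[:, mask],
        )

    def subset_samples(self, mask) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            groups=[g for g, m in zip(self.groups, mask) if m],
            contig=self.contig,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[mask],
        )


def read_vcf(path, group_map: dict[str, str]) -> GenotypeTable:
    """Read biallelic SNPs from a VCF into a GenotypeTable.

    1-based POS becomes 0-based.  Multi-allelic and non-SNP records are
    skipped and counted.  Half-missing diploid calls (e.g. ``0/.``) are
    treated as fully missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in group_map:
            raise ValueError(f"sample {s!r} in VCF absent from group map")
    contigs, pos, refs, alts, rows = [], [], [], [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        dos = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            dos[i] = a + b if (a >= 0 and b >= 0) else -1
        contigs.append(v.CHROM)
        pos.append(v.POS - 1)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(dos)
    vcf.close()
    if skipped:
        log.info("skipped %d multi-allelic/non-SNP records", skipped)
    dosage = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeTable(
        sample_ids=samples,
        groups=[group_map[s] for s in samples],
        contig=np.array(contigs, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosage=dosage,
        n_skipped_multiallelic=skipped,
    )


def write_vcf(table: GenotypeTable, path) -> None:
    """Write a minimal GT-only VCF v4.2; internal 0-based start -> POS."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in dict.fromkeys(table.contig):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        order = np.lexsort((table.pos, table.contig.astype(str)))
        for j in order:
            calls = "\t".join(gt_of[int(d)] for d in table.dosage[:, j])
            fh.write(
                f"{table.contig[j]}\t{table.pos[j] + 1}\t.\t{table.ref[j]}\t"
                f"{table.alt[j]}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_group_map(path) -> dict[str, str]:
    """Two-column TSV: sample id, group label."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, group = line.split("\t")[:2]
            out[sample] = group
    return out


def write_group_map(group_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, group in group_map.items():
            fh.write(f"{sample}\t{group}\n")


def read_window_tsv(path) -> pd.DataFrame:
    """Window count matrix: contig, start, end, then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != ["contig", "start", "end"]:
        raise ValueError("window TSV must start with contig/start/end columns")
    return df


def write_window_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
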