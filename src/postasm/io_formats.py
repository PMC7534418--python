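"""Domain types and readers/writers for the on-disk formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere.  GFF3 and VCF use
1-based closed coordinates on disk; the conversion happens at the I/O
boundary and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "AssemblyGap",
    "RepeatFeature",
    "SVRecord",
    "KmerHistogram",
    "Transcript",
    "GeneModel",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "find_assembly_gaps",
    "read_gene_gff3",
    "write_gene_gff3",
    "read_sv_vcf",
    "write_sv_vcf",
    "read_kmer_histogram",
    "write_kmer_histogram",
    "read_repeat_table",
    "write_repeat_table",
    "read_bed",
    "write_bed",
]

STRANDS = ("+", "-", ".")

# Full IUPAC nucleotide alphabet, both cases (softmasking is significant).
_IUPAC = set("ACGTURYSWKMBDHVN")
_IUPAC |= {c.lower() for c in _IUPAC}

SV_TYPES = ("DEL", "DUP", "INV")
GENOTYPES = ("0/0", "0/1", "1/1", "./.")
MISSING_GT = "./."


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open span on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AssemblyGap:
    """Maximal run of N characters within an assembled sequence."""

    interval: GenomicInterval
    run_base: str = "N"

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class RepeatFeature:
    """Annotated repeat with a hierarchical class/family label."""

    interval: GenomicInterval
    class_name: str
    family_name: str = ""

    def __post_init__(self) -> None:
        if not self.class_name:
            raise ValueError("class_name must be non-empty")

    @property
    def label(self) -> str:
        if self.family_name:
            return f"{self.class_name}/{self.family_name}"
        return self.class_name


@dataclass(frozen=True)
class SVRecord:
    """One structural-variant call with evidence fields and genotypes.

    ``pos``/``end`` follow the VCF convention (1-based, closed); use
    :meth:`interval` for internal coordinates.
    """

    id: str
    sv_type: str
    chrom: str
    pos: int
    end: int
    precise: bool
    pe: int
    sr: int
    mapq: int
    filter_status: str
    genotypes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.end < self.pos:
            raise ValueError(f"end {self.end} < pos {self.pos}")
        for name in ("pe", "sr", "mapq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for gt in self.genotypes:
            if gt not in GENOTYPES:
                raise ValueError(f"unknown genotype {gt!r}")

    @property
    def length(self) -> int:
        return self.end - self.pos

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos - 1, self.end)


@dataclass(frozen=True)
class KmerHistogram:
    """k-mer multiplicity spectrum: ordered (multiplicity, count) bins."""

    k: int
    bins: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev = 0
        for m, c in self.bins:
            if m <= prev:
                raise ValueError("multiplicities must be strictly increasing and >= 1")
            if c < 0:
                raise ValueError("counts must be non-negative")
            prev = m

    @property
    def multiplicities(self) -> tuple[int, ...]:
        return tuple(m for m, _ in self.bins)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(c for _, c in self.bins)


@dataclass(frozen=True)
class Transcript:
    """One isoform: ordered exons on a single chromosome/strand plus an AED score."""

    id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    aed: float

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        if not (0.0 <= self.aed <= 1.0):
            raise ValueError(f"AED must be in [0, 1], got {self.aed}")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError("exons must share one chromosome")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError("exons must be sorted and non-overlapping")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """MAKER-style gene: union span over one or more isoforms."""

    gene_id: str
    span: GenomicInterval
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError("gene must have at least one transcript")
        for tx in self.transcripts:
            for exon in tx.exons:
                if exon.chrom != self.span.chrom or not (
                    self.span.start <= exon.start and exon.end <= self.span.end
                ):
                    raise ValueError(
                        f"exon {exon} of {tx.id} outside gene span {self.span}"
                    )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly softmasked) FASTA into name -> sequence, case preserved."""
    records: dict[str, str] = {}
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise FormatError(f"duplicate FASTA record name {rec.id!r}")
            seq = str(rec.seq)
            if not seq:
                raise FormatError(f"empty FASTA record {rec.id!r}")
            bad = set(seq) - _IUPAC
            if bad:
                raise FormatError(
                    f"non-nucleotide character(s) {sorted(bad)} in record {rec.id!r}"
                )
            records[rec.id] = seq
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences wrapped to ``width`` columns, preserving case."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_N_RUN = re.compile(r"[Nn]+")


def find_assembly_gaps(
    sequence: str, min_len: int = 1, chrom: str = "seq"
) -> list[AssemblyGap]:
    """Maximal runs of N (case-insensitive) of length >= ``min_len``, sorted."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    gaps = []
    for match in _N_RUN.finditer(sequence):
        if match.end() - match.start() >= min_len:
            gaps.append(
                AssemblyGap(GenomicInterval(chrom, match.start(), match.end()))
            )
    return gaps


# ---------------------------------------------------------------------------
# GFF3 (gene/mRNA/exon subset, MAKER dialect with per-mRNA AED attribute)


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().rstrip(";").split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_gene_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a gene/mRNA/exon GFF3 with an ``_AED`` attribute on each mRNA.

    GFF3 coordinates (1-based closed) are converted to internal 0-based
    half-open at this boundary.
    """
    gene_rows: dict[str, tuple[str, int, int, str]] = {}
    mrna_rows: dict[str, tuple[str, str, float]] = {}  # id -> (gene, chrom, aed)
    mrna_spans: dict[str, tuple[int, int, str]] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 GFF3 columns")
            chrom, _source, ftype, start, end, _score, strand, _phase, attr_text = fields
            start0, end0 = int(start) - 1, int(end)
            attrs = _parse_gff_attributes(attr_text)
            if ftype == "gene":
                gid = attrs["ID"]
                gene_rows[gid] = (chrom, start0, end0, strand)
                gene_order.append(gid)
            elif ftype == "mRNA":
                mid = attrs["ID"]
                parent = attrs.get("Parent")
                if parent is None or parent not in gene_rows:
                    raise FormatError(f"line {lineno}: mRNA {mid!r} has no parent gene")
                aed = float(attrs.get("_AED", attrs.get("AED", "nan")))
                if not (0.0 <= aed <= 1.0):
                    raise FormatError(
                        f"line {lineno}: AED {aed} outside [0, 1] for {mid!r}"
                    )
                mrna_rows[mid] = (parent, chrom, aed)
                mrna_spans[mid] = (start0, end0, strand)
                exons.setdefault(mid, [])
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None or parent not in mrna_rows:
                    raise FormatError(f"line {lineno}: exon has no parent mRNA")
                mstart, mend, strand_m = mrna_spans[parent]
                if start0 < mstart or end0 > mend:
                    raise FormatError(
                        f"line {lineno}: exon [{start0}, {end0}) outside mRNA span"
                    )
                exons[parent].append(
                    GenomicInterval(chrom, start0, end0, strand_m)
                )

    by_gene: dict[str, list[Transcript]] = {gid: [] for gid in gene_rows}
    for mid, (gid, chrom, aed) in mrna_rows.items():
        tx_exons = tuple(sorted(exons[mid], key=lambda e: e.start))
        by_gene[gid].append(Transcript(mid, gid, tx_exons, aed))

    genes = []
    for gid in gene_order:
        chrom, start0, end0, strand = gene_rows[gid]
        txs = tuple(sorted(by_gene[gid], key=lambda t: t.id))
        if not txs:
            continue
        genes.append(
            GeneModel(gid, GenomicInterval(chrom, start0, end0, strand), txs)
        )
    return genes


def write_gene_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models back out as gene/mRNA/exon GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            g = gene.span
            fh.write(
                f"{g.chrom}\tpostasm\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={gene.gene_id}\n"
            )
            for tx in gene.transcripts:
                s = tx.span
                fh.write(
                    f"{s.chrom}\tpostasm\tmRNA\t{s.start + 1}\t{s.end}\t.\t"
                    f"{s.strand}\t.\tID={tx.id};Parent={gene.gene_id};_AED={tx.aed:g}\n"
                )
                for i, exon in enumerate(tx.exons, 1):
                    fh.write(
                        f"{exon.chrom}\tpostasm\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                        f"{exon.strand}\t.\tID={tx.id}:exon:{i};Parent={tx.id}\n"
                    )


# ---------------------------------------------------------------------------
# SV VCF (Delly v0.8 dialect)

_VCF_COLUMNS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"


def _parse_info(text: str) -> dict[str, str | bool]:
    info: dict[str, str | bool] = {}
    for part in text.split(";"):
        if not part:
            continue
        if "=" in part:
            key, value = part.split("=", 1)
            info[key] = value
        else:
            info[part] = True
    return info


def read_sv_vcf(path: str | Path) -> tuple[list[SVRecord], list[str]]:
    """Parse a Delly-dialect SV VCF; returns records and ordered sample names."""
    records: list[SVRecord] = []
    samples: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                samples = cols[9:]
                continue
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise FormatError(
                    f"line {lineno}: {len(fields) - 9} sample columns, "
                    f"header declares {len(samples)}"
                )
            chrom, pos, vid, _ref, _alt, _qual, filt, info_text, fmt = fields[:9]
            info = _parse_info(info_text)
            for key in ("SVTYPE", "END"):
                if key not in info:
                    raise FormatError(f"line {lineno}: missing INFO key {key}")
            sv_type = str(info["SVTYPE"])
            if sv_type not in SV_TYPES:
                raise FormatError(f"line {lineno}: unknown SVTYPE {sv_type!r}")
            fmt_keys = fmt.split(":")
            if "GT" not in fmt_keys:
                raise FormatError(f"line {lineno}: FORMAT lacks GT")
            gt_idx = fmt_keys.index("GT")
            gts = []
            for sample_text in fields[9:]:
                gt = sample_text.split(":")[gt_idx].replace("|", "/")
                gts.append(gt if gt in GENOTYPES else MISSING_GT)
            records.append(
                SVRecord(
                    id=vid,
                    sv_type=sv_type,
                    chrom=chrom,
                    pos=int(pos),
                    end=int(info["END"]),
                    precise="PRECISE" in info,
                    pe=int(str(info.get("PE", 0))),
                    sr=int(str(info.get("SR", 0))),
                    mapq=int(str(info.get("MAPQ", 0))),
                    filter_status=filt,
                    genotypes=tuple(gts),
                )
            )
    return records, samples


def write_sv_vcf(
    records: Sequence[SVRecord],
    samples: Sequence[str],
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=LowQual,Description="Low quality call">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=PE,Number=1,Type=Integer,Description="Paired-end support">\n')
        fh.write('##INFO=<ID=SR,Number=1,Type=Integer,Description="Split-read support">\n')
        fh.write('##INFO=<ID=MAPQ,Number=1,Type=Integer,Description="Median mapping quality">\n')
        fh.write('##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Precise breakpoints">\n')
        fh.write('##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoints">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        header = _VCF_COLUMNS
        if samples:
            header += "\t" + "\t".join(samples)
        fh.write(header + "\n")
        for rec in records:
            flag = "PRECISE" if rec.precise else "IMPRECISE"
            info = (
                f"{flag};SVTYPE={rec.sv_type};END={rec.end};"
                f"PE={rec.pe};SR={rec.sr};MAPQ={rec.mapq}"
            )
            row = [
                rec.chrom,
                str(rec.pos),
                rec.id,
                "N",
                f"<{rec.sv_type}>",
                ".",
                rec.filter_status,
                info,
                "GT",
                *rec.genotypes,
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# k-mer histogram (two-column whitespace-delimited text)


def read_kmer_histogram(path: str | Path, k: int = 21) -> KmerHistogram:
    bins: list[tuple[int, int]] = []
    seen: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise FormatError(f"line {lineno}: expected two columns")
            try:
                m, c = int(tokens[0]), int(tokens[1])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer token") from exc
            if m in seen:
                raise FormatError(f"line {lineno}: duplicate multiplicity {m}")
            seen.add(m)
            bins.append((m, c))
    bins.sort()
    return KmerHistogram(k=k, bins=tuple(bins))


def write_kmer_histogram(hist: KmerHistogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m, c in hist.bins:
            fh.write(f"{m} {c}\n")


# ---------------------------------------------------------------------------
# BED-like repeat table: chrom, start, end, class/family, strand


def read_repeat_table(path: str | Path) -> list[RepeatFeature]:
    features: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"line {lineno}: expected 5 columns")
            chrom, start, end, label, strand = fields[:5]
            start_i, end_i = int(start), int(end)
            if start_i >= end_i:
                raise FormatError(f"line {lineno}: start >= end")
            if strand not in STRANDS:
                raise FormatError(f"line {lineno}: malformed strand {strand!r}")
            if "/" in label:
                class_name, family_name = label.split("/", 1)
            else:
                class_name, family_name = label, ""
            features.append(
                RepeatFeature(
                    GenomicInterval(chrom, start_i, end_i, strand),
                    class_name,
                    family_name,
                )
            )
    return features


def write_repeat_table(features: Sequence[RepeatFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for feat in features:
            iv = feat.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{feat.label}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Plain BED (used for gap tracks)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
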