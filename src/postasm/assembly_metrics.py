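"""Contig/scaffold summary statistics: gap splitting, NX, masked fraction."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import find_assembly_gaps

__all__ = [
    "AssemblyRow",
    "AssemblySummary",
    "split_into_contigs",
    "nx",
    "masked_fraction",
    "summarize_assembly",
    "aggregate_rows",
    "percent_of",
    "ratio_per_unit",
]

DEFAULT_MIN_GAP_LEN = 10  # gap census threshold: N-runs longer than 10 bp


@dataclass(frozen=True)
class AssemblyRow:
    name: str
    total_length: int
    contig_count: int
    contig_n50: int
    gap_count: int
    masked_fraction: float


@dataclass(frozen=True)
class AssemblySummary:
    rows: tuple[AssemblyRow, ...]
    totals: AssemblyRow


_GAP_SPLIT_CACHE: dict[int, re.Pattern] = {}


def split_into_contigs(sequence: str, min_gap_len: int = DEFAULT_MIN_GAP_LEN) -> list[int]:
    """Lengths of maximal non-gap segments between N-runs of length >= min_gap_len."""
    if min_gap_len < 1:
        raise ValueError("min_gap_len must be >= 1")
    pattern = _GAP_SPLIT_CACHE.get(min_gap_len)
    if pattern is None:
        pattern = re.compile(r"[Nn]{%d,}" % min_gap_len)
        _GAP_SPLIT_CACHE[min_gap_len] = pattern
    return [len(seg) for seg in pattern.split(sequence) if seg]


def nx(lengths: Sequence[int], x: float = 50) -> int:
    """Smallest L such that segments of length >= L cover at least x% of the total."""
    if not lengths:
        raise ValueError("empty length list")
    if not (0 < x <= 100):
        raise ValueError("x must be in (0, 100]")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    target = arr.sum() * (x / 100.0)
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(cum, target))
    return int(arr[min(idx, len(arr) - 1)])


def masked_fraction(sequence: str, include_n: bool = True) -> float:
    """Lowercase (softmasked) base count over total; Ns stay in the denominator
    by default."""
    if not sequence:
        raise ValueError("empty sequence")
    lower = sum(1 for c in sequence if c.islower())
    denom = len(sequence)
    if not include_n:
        denom -= sequence.count("N") + sequence.count("n")
        if denom == 0:
            raise ValueError("sequence is all N")
    return lower / denom


def aggregate_rows(rows: Sequence[AssemblyRow], name: str = "All") -> AssemblyRow:
    """Totals row: sums for counts/lengths, pooled N50 and masked fraction."""
    if not rows:
        raise ValueError("no rows to aggregate")
    total_length = sum(r.total_length for r in rows)
    masked_bases = sum(r.masked_fraction * r.total_length for r in rows)
    return AssemblyRow(
        name=name,
        total_length=total_length,
        contig_count=sum(r.contig_count for r in rows),
        contig_n50=max(r.contig_n50 for r in rows),
        gap_count=sum(r.gap_count for r in rows),
        masked_fraction=masked_bases / total_length if total_length else 0.0,
    )


def summarize_assembly(
    sequences: Mapping[str, str], min_gap_len: int = DEFAULT_MIN_GAP_LEN
) -> AssemblySummary:
    rows = []
    all_contigs: list[int] = []
    for name, seq in sequences.items():
        contigs = split_into_contigs(seq, min_gap_len)
        all_contigs.extend(contigs)
        gaps = find_assembly_gaps(seq, min_len=min_gap_len, chrom=name)
        rows.append(
            AssemblyRow(
                name=name,
                total_length=len(seq),
                contig_count=len(contigs),
                contig_n50=nx(contigs, 50) if contigs else 0,
                gap_count=len(gaps),
                masked_fraction=masked_fraction(seq),
            )
        )
    totals = aggregate_rows(rows)
    if all_contigs:
        totals = AssemblyRow(
            name=totals.name,
            total_length=totals.total_length,
            contig_count=totals.contig_count,
            contig_n50=nx(all_contigs, 50),
            gap_count=totals.gap_count,
            masked_fraction=totals.masked_fraction,
        )
    return AssemblySummary(rows=tuple(rows), totals=totals)


def percent_of(part: float, whole: float, ndigits: int = 2) -> float:
    """part / whole as a percentage, rounded to ``ndigits``."""
    if whole == 0:
        raise ZeroDivisionError("whole must be non-zero")
    return round(100.0 * part / whole, ndigits)


def ratio_per_unit(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Plain quotient rounded to ``ndigits`` (e.g. transcripts per gene)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be non-zero")
    return round(numerator / denominator, ndigits)
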