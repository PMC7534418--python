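"""Structural-variant curation, population allele frequencies, and the
deletion-length vs TE-length density comparison.

The curation chain keeps calls that are precise (split-read resolved), shorter
than 5 Mb (strict), FILTER = PASS, mapping quality strictly above zero, and
supported by at least five paired-end reads (inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import MISSING_GT, SVRecord

__all__ = [
    "SVFilterConfig",
    "VariantStats",
    "TypeSummary",
    "PopulationSVSummary",
    "sv_length",
    "passes_filters",
    "minor_allele_frequency",
    "summarize_population",
    "deletion_te_length_overlap",
]

_ALT_COUNT = {"0/0": 0, "0/1": 1, "1/1": 2}


@dataclass(frozen=True)
class SVFilterConfig:
    max_length: int = 5_000_000  # exclusive: length must be < max_length
    min_pe: int = 5  # inclusive
    require_precise: bool = True
    require_pass: bool = True
    min_mapq_exclusive: int = 0  # mapq must be strictly greater
    pe_includes_sr: bool = False  # option: count PE+SR toward min_pe

    def __post_init__(self) -> None:
        if min(self.max_length, self.min_pe, self.min_mapq_exclusive) < 0:
            raise ValueError("thresholds must be >= 0")


def sv_length(record: SVRecord) -> int:
    """end - pos for all variant types; zero-length records are degenerate."""
    length = record.end - record.pos
    if length == 0:
        warnings.warn(f"degenerate zero-length SV {record.id}", stacklevel=2)
    return length


def passes_filters(
    record: SVRecord, config: SVFilterConfig = SVFilterConfig()
) -> tuple[bool, list[str]]:
    """Apply the curation chain; returns (passed, list of violated rules)."""
    reasons = []
    if config.require_precise and not record.precise:
        reasons.append("imprecise")
    if record.precise and record.sr == 0:
        warnings.warn(
            f"{record.id}: PRECISE flag without split-read support", stacklevel=2
        )
    if sv_length(record) >= config.max_length:
        reasons.append("max_length")
    if config.require_pass and record.filter_status != "PASS":
        reasons.append("filter")
    if record.mapq <= config.min_mapq_exclusive:
        reasons.append("mapq")
    support = record.pe + (record.sr if config.pe_includes_sr else 0)
    if support < config.min_pe:
        reasons.append("min_pe")
    return (not reasons), reasons


def minor_allele_frequency(
    genotypes: Sequence[str], carrier_based: bool = False
) -> tuple[float, int]:
    """Folded allele frequency over called diploid genotypes.

    Missing calls are excluded.  With ``carrier_based`` the frequency is the
    fraction of called samples carrying at least one alternate allele (folded
    the same way).  Returns (MAF, called-sample count).
    """
    called = [g for g in genotypes if g != MISSING_GT]
    if not called:
        raise ValueError("all genotypes missing")
    if carrier_based:
        freq = sum(1 for g in called if _ALT_COUNT[g] > 0) / len(called)
    else:
        freq = sum(_ALT_COUNT[g] for g in called) / (2 * len(called))
    return min(freq, 1.0 - freq), len(called)


@dataclass(frozen=True)
class VariantStats:
    record: SVRecord
    length: int
    maf: float
    called: int


@dataclass(frozen=True)
class TypeSummary:
    sv_type: str
    count: int
    median_length: float
    maf_pass_count: int  # variants with MAF >= threshold


@dataclass(frozen=True)
class PopulationSVSummary:
    per_type: tuple[TypeSummary, ...]
    variants: tuple[VariantStats, ...]
    maf_threshold: float
    filter_config: SVFilterConfig


def summarize_population(
    records: Sequence[SVRecord],
    config: SVFilterConfig = SVFilterConfig(),
    maf_threshold: float = 0.01,
) -> PopulationSVSummary:
    """Type-wise counts, median lengths and MAF-thresholded counts over the
    filter-passing records.  Even-sized medians are midpoint averages."""
    passing: list[VariantStats] = []
    for rec in records:
        ok, _ = passes_filters(rec, config)
        if not ok:
            continue
        maf, called = minor_allele_frequency(rec.genotypes)
        passing.append(VariantStats(rec, sv_length(rec), maf, called))

    per_type = []
    for sv_type in ("DEL", "DUP", "INV"):
        rows = [v for v in passing if v.record.sv_type == sv_type]
        if rows:
            median = float(np.median([v.length for v in rows]))
            n_maf = sum(1 for v in rows if v.maf >= maf_threshold)
        else:
            median, n_maf = float("nan"), 0
        per_type.append(TypeSummary(sv_type, len(rows), median, n_maf))
    return PopulationSVSummary(
        per_type=tuple(per_type),
        variants=tuple(passing),
        maf_threshold=maf_threshold,
        filter_config=config,
    )


def deletion_te_length_overlap(
    del_lengths: Sequence[int],
    te_lengths: Sequence[int],
    bin_width: int = 500,
    range_max: int = 10_000,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Histogram-overlap coefficient between two length samples.

    Both samples are binned on the shared grid [0, range_max) with the given
    bin width, each histogram normalized to unit mass over that range, and the
    overlap is the sum of per-bin minima.  Returns (overlap, bin_edges,
    deletion_density, te_density).
    """
    if not len(del_lengths) or not len(te_lengths):
        raise ValueError("both length samples must be non-empty")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    edges = np.arange(0, range_max + bin_width, bin_width)
    d_counts, _ = np.histogram(del_lengths, bins=edges)
    t_counts, _ = np.histogram(te_lengths, bins=edges)
    d_total, t_total = d_counts.sum(), t_counts.sum()
    d_density = d_counts / d_total if d_total else d_counts.astype(float)
    t_density = t_counts / t_total if t_total else t_counts.astype(float)
    overlap = float(np.minimum(d_density, t_density).sum())
    return overlap, edges, d_density, t_density
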