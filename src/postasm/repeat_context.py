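"""Genic context and strand concordance of repeat annotations, plus windowed
coverage tracks.

A repeat is *genic* when it overlaps any gene span by at least one base
(introns and UTRs included); strand relation is taken from the leftmost
overlapping gene when several overlap.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneModel, GenomicInterval, RepeatFeature

__all__ = [
    "RepeatContextCall",
    "ClassContext",
    "ContextComposition",
    "GeneIndex",
    "classify_repeat",
    "classify_repeats",
    "context_composition",
    "class_count_ratio",
    "window_coverage",
    "merge_intervals",
]

GENIC = "genic"
NON_GENIC = "non-genic"


@dataclass(frozen=True)
class RepeatContextCall:
    repeat: RepeatFeature
    context: str  # genic | non-genic
    strand_relation: str  # same | different | unstranded


class GeneIndex:
    """Per-chromosome gene spans, sorted by start, queryable for overlap."""

    def __init__(self, genes: Iterable[GeneModel | GenomicInterval]):
        spans: dict[str, list[GenomicInterval]] = defaultdict(list)
        for g in genes:
            span = g.span if isinstance(g, GeneModel) else g
            spans[span.chrom].append(span)
        self._spans = {c: sorted(v, key=lambda s: (s.start, s.end)) for c, v in spans.items()}
        self._starts = {
            c: np.array([s.start for s in v]) for c, v in self._spans.items()
        }
        self._ends = {c: np.array([s.end for s in v]) for c, v in self._spans.items()}

    def overlapping(self, iv: GenomicInterval) -> list[GenomicInterval]:
        """All gene spans overlapping ``iv``, in coordinate order."""
        if iv.chrom not in self._spans:
            return []
        starts = self._starts[iv.chrom]
        ends = self._ends[iv.chrom]
        mask = (starts < iv.end) & (ends > iv.start)
        return [self._spans[iv.chrom][i] for i in np.nonzero(mask)[0]]


def classify_repeat(repeat: RepeatFeature, genes: GeneIndex) -> RepeatContextCall:
    hits = genes.overlapping(repeat.interval)
    if not hits:
        return RepeatContextCall(repeat, NON_GENIC, "unstranded")
    gene = hits[0]  # leftmost by coordinate on ties
    r_strand, g_strand = repeat.interval.strand, gene.strand
    if r_strand == "." or g_strand == ".":
        relation = "unstranded"
    elif r_strand == g_strand:
        relation = "same"
    else:
        relation = "different"
    return RepeatContextCall(repeat, GENIC, relation)


def classify_repeats(
    repeats: Sequence[RepeatFeature], genes: GeneIndex | Iterable[GeneModel]
) -> list[RepeatContextCall]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [classify_repeat(r, index) for r in repeats]


@dataclass(frozen=True)
class ClassContext:
    class_name: str
    genic_count: int
    non_genic_count: int
    genic_share: float | None  # share among genic elements
    non_genic_share: float | None
    fold_difference: float | None  # non-genic share / genic share
    same_strand: int
    different_strand: int

    @property
    def strand_ratio(self) -> float | None:
        if self.different_strand == 0:
            return None
        return self.same_strand / self.different_strand


@dataclass(frozen=True)
class ContextComposition:
    per_class: tuple[ClassContext, ...]
    genic_total: int
    non_genic_total: int
    multi_gene_overlaps: int  # repeats overlapping >1 gene (tie-break applied)


def context_composition(
    repeats: Sequence[RepeatFeature],
    genes: GeneIndex | Iterable[GeneModel],
) -> ContextComposition:
    """Per-class shares within the genic and non-genic contexts, fold
    differences, and same:different strand tallies among genic elements."""
    if not repeats:
        raise ValueError("empty repeat set")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    genic: dict[str, int] = defaultdict(int)
    non_genic: dict[str, int] = defaultdict(int)
    same: dict[str, int] = defaultdict(int)
    diff: dict[str, int] = defaultdict(int)
    multi = 0
    for rep in repeats:
        hits = index.overlapping(rep.interval)
        if len(hits) > 1:
            multi += 1
        call = classify_repeat(rep, index)
        if call.context == GENIC:
            genic[rep.class_name] += 1
            if call.strand_relation == "same":
                same[rep.class_name] += 1
            elif call.strand_relation == "different":
                diff[rep.class_name] += 1
        else:
            non_genic[rep.class_name] += 1

    genic_total = sum(genic.values())
    non_genic_total = sum(non_genic.values())
    classes = sorted(set(genic) | set(non_genic))
    rows = []
    for cls in classes:
        g, n = genic[cls], non_genic[cls]
        g_share = g / genic_total if genic_total else None
        n_share = n / non_genic_total if non_genic_total else None
        fold = None
        if g_share and n_share is not None:
            fold = n_share / g_share
        rows.append(
            ClassContext(
                class_name=cls,
                genic_count=g,
                non_genic_count=n,
                genic_share=g_share,
                non_genic_share=n_share,
                fold_difference=fold,
                same_strand=same[cls],
                different_strand=diff[cls],
            )
        )
    return ContextComposition(
        per_class=tuple(rows),
        genic_total=genic_total,
        non_genic_total=non_genic_total,
        multi_gene_overlaps=multi,
    )


def class_count_ratio(
    repeats: Sequence[RepeatFeature], class_a: str, class_b: str
) -> tuple[float, str]:
    """count(class_a) / count(class_b) plus a nearest-integer "n:1" rendering.

    Labels match either the top-level class or the full class/family label.
    """

    def count(label: str) -> int:
        return sum(
            1 for r in repeats if r.class_name == label or r.label == label
        )

    a, b = count(class_a), count(class_b)
    if b == 0:
        raise ZeroDivisionError(f"no elements of class {class_b!r}")
    ratio = a / b
    return ratio, f"{round(ratio):d}:1"


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> dict[str, np.ndarray]:
    """Merge overlapping/adjacent intervals; per-chrom (n, 2) start/end arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out: list[list[int]] = []
        for start, end in pairs:
            if out and start <= out[-1][1]:
                out[-1][1] = max(out[-1][1], end)
            else:
                out.append([start, end])
        merged[chrom] = np.array(out, dtype=np.int64)
    return merged


def covered_bases(
    merged: Mapping[str, np.ndarray], chrom: str, start: int, end: int
) -> int:
    """Bases of [start, end) covered by a merged interval set."""
    if chrom not in merged or end <= start:
        return 0
    arr = merged[chrom]
    lo = np.clip(arr[:, 0], start, end)
    hi = np.clip(arr[:, 1], start, end)
    return int(np.maximum(0, hi - lo).sum())


def window_coverage(
    features: Iterable[GenomicInterval | RepeatFeature],
    chrom_lengths: Mapping[str, int],
    window: int,
) -> list[tuple[str, int, int, float]]:
    """Covered fraction per non-overlapping window; the final partial window is
    normalized by its own width.  Returns (chrom, start, end, fraction) rows."""
    if window < 1:
        raise ValueError("window must be >= 1")
    ivs = [f.interval if isinstance(f, RepeatFeature) else f for f in features]
    merged = merge_intervals(ivs)
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, window):
            end = min(start + window, length)
            frac = covered_bases(merged, chrom, start, end) / (end - start)
            rows.append((chrom, start, end, frac))
    return rows
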