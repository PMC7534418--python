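"""Permutation test comparing gap-flank sequence content against shuffled gaps.

For each flank distance, the observed statistic is the unweighted mean over
all valid flank windows; gap coordinates are then shuffled uniformly over the
chromosomes (lengths preserved, placements non-overlapping) and the same
statistic recomputed.  The p-value is the proportion of permuted means that
are *strictly greater* than the observed mean; ties do not count as exceeding,
so a zero-variance permutation distribution yields p = 0 and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AssemblyGap, GenomicInterval, RepeatFeature
from .repeat_context import merge_intervals

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "GenomeStats",
    "flank_windows",
    "mean_flank_statistic",
    "shuffle_gaps",
    "permutation_test",
]

DEFAULT_DISTANCES = (50, 100, 500, 1000, 1500)
STATISTICS = ("repeat_fraction", "gc_fraction")


@dataclass(frozen=True)
class PermutationConfig:
    n_perm: int = 1000
    distances: tuple[int, ...] = DEFAULT_DISTANCES
    statistics: tuple[str, ...] = STATISTICS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if any(d <= 0 for d in self.distances):
            raise ValueError("distances must be > 0")
        for stat in self.statistics:
            if stat not in STATISTICS:
                raise ValueError(f"unknown statistic {stat!r}")


@dataclass(frozen=True)
class PermutationResult:
    distance: int
    statistic: str
    observed: float
    permuted: tuple[float, ...]
    p_value: float
    degenerate: bool  # permutation distribution has zero variance

    def render_p(self) -> str:
        if self.p_value == 0.0:
            return f"< {1.0 / len(self.permuted):g}"
        return f"{self.p_value:g}"


class GenomeStats:
    """Per-chromosome prefix sums for O(1) window GC and repeat coverage."""

    def __init__(
        self,
        sequences: Mapping[str, str],
        repeats: Iterable[GenomicInterval | RepeatFeature] = (),
    ):
        self.chrom_lengths = {name: len(seq) for name, seq in sequences.items()}
        self._gc: dict[str, np.ndarray] = {}
        self._acgt: dict[str, np.ndarray] = {}
        self._rep: dict[str, np.ndarray] = {}
        merged = merge_intervals(
            f.interval if isinstance(f, RepeatFeature) else f for f in repeats
        )
        for name, seq in sequences.items():
            arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
            is_gc = (arr == b"G") | (arr == b"C")
            is_acgt = is_gc | (arr == b"A") | (arr == b"T")
            cover = np.zeros(len(seq), dtype=bool)
            for start, end in merged.get(name, ()):
                cover[start:end] = True
            self._gc[name] = np.concatenate([[0], np.cumsum(is_gc, dtype=np.int64)])
            self._acgt[name] = np.concatenate([[0], np.cumsum(is_acgt, dtype=np.int64)])
            self._rep[name] = np.concatenate([[0], np.cumsum(cover, dtype=np.int64)])

    def window_statistic(self, iv: GenomicInterval, statistic: str) -> float:
        if statistic == "repeat_fraction":
            pre = self._rep[iv.chrom]
            return (pre[iv.end] - pre[iv.start]) / iv.length
        if statistic == "gc_fraction":
            gc = self._gc[iv.chrom]
            acgt = self._acgt[iv.chrom]
            denom = acgt[iv.end] - acgt[iv.start]
            if denom == 0:
                return float("nan")
            return (gc[iv.end] - gc[iv.start]) / denom
        raise ValueError(f"unknown statistic {statistic!r}")


def flank_windows(
    gap: AssemblyGap | GenomicInterval, distance: int, chrom_length: int
) -> list[GenomicInterval]:
    """Left and right windows of width ``distance`` abutting the gap.

    Windows extending past either chromosome end are discarded (not truncated)
    so every retained window has identical width.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    iv = gap.interval if isinstance(gap, AssemblyGap) else gap
    windows = []
    if iv.start - distance >= 0:
        windows.append(GenomicInterval(iv.chrom, iv.start - distance, iv.start))
    if iv.end + distance <= chrom_length:
        windows.append(GenomicInterval(iv.chrom, iv.end, iv.end + distance))
    return windows


def mean_flank_statistic(
    gaps: Sequence[AssemblyGap | GenomicInterval],
    stats: GenomeStats,
    distance: int,
    statistic: str,
) -> float:
    """Unweighted mean of the per-window statistic over all valid flank windows."""
    values = []
    for gap in gaps:
        iv = gap.interval if isinstance(gap, AssemblyGap) else gap
        for window in flank_windows(iv, distance, stats.chrom_lengths[iv.chrom]):
            v = stats.window_statistic(window, statistic)
            if not np.isnan(v):
                values.append(v)
    if not values:
        raise ValueError("no valid flank windows")
    return float(np.mean(values))


class ShuffleError(RuntimeError):
    """Non-overlapping placement failed within the retry budget."""


def shuffle_gaps(
    gaps: Sequence[AssemblyGap | GenomicInterval],
    chrom_lengths: Mapping[str, int],
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> list[GenomicInterval]:
    """Re-place each gap uniformly on the genome, preserving its length.

    The chromosome is drawn with probability proportional to its length and
    the offset uniformly over feasible positions; placed gaps are pairwise
    non-overlapping.  Shuffled gaps may coincide with original gap positions.
    """
    names = list(chrom_lengths)
    sizes = np.array([chrom_lengths[n] for n in names], dtype=float)
    probs = sizes / sizes.sum()
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    out = []
    for gap in gaps:
        iv = gap.interval if isinstance(gap, AssemblyGap) else gap
        length = iv.length
        for attempt in range(max_tries):
            ci = int(rng.choice(len(names), p=probs))
            chrom = names[ci]
            limit = int(sizes[ci]) - length
            if limit < 0:
                continue
            start = int(rng.integers(0, limit + 1))
            end = start + length
            if all(e <= start or end <= s for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                out.append(GenomicInterval(chrom, start, end))
                break
        else:
            raise ShuffleError(f"could not place a gap of length {length}")
    return out


def permutation_test(
    sequences: Mapping[str, str],
    gaps: Sequence[AssemblyGap | GenomicInterval],
    repeats: Iterable[GenomicInterval | RepeatFeature],
    config: PermutationConfig,
    stats: GenomeStats | None = None,
) -> list[PermutationResult]:
    """Observed vs shuffled mean flank statistic for each distance/statistic."""
    if not gaps:
        raise ValueError("no gaps supplied")
    if stats is None:
        stats = GenomeStats(sequences, repeats)
    rng = np.random.default_rng(config.seed)
    shuffles = [
        shuffle_gaps(gaps, stats.chrom_lengths, rng) for _ in range(config.n_perm)
    ]
    results = []
    for statistic in config.statistics:
        for distance in config.distances:
            observed = mean_flank_statistic(gaps, stats, distance, statistic)
            permuted = np.array(
                [
                    mean_flank_statistic(s, stats, distance, statistic)
                    for s in shuffles
                ]
            )
            p = float((permuted > observed).sum()) / config.n_perm
            results.append(
                PermutationResult(
                    distance=distance,
                    statistic=statistic,
                    observed=observed,
                    permuted=tuple(float(v) for v in permuted),
                    p_value=p,
                    degenerate=bool(np.ptp(permuted) == 0.0),
                )
            )
    return results
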