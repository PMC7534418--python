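"""Peak-based haploid genome-size estimation from a k-mer multiplicity spectrum.

The estimator locates the error/coverage trough, takes the homozygous peak as
the count argmax above it, and divides the included k-mer mass by the peak
multiplicity.  No heterozygous-peak mixture model is fitted; the estimate is
validated by parameter recovery on simulated spectra and the simplification is
recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import KmerHistogram

__all__ = ["GenomeSizeEstimate", "NoCoveragePeakError", "find_error_threshold", "estimate_genome_size"]


class NoCoveragePeakError(ValueError):
    """Histogram has no error trough followed by a coverage peak."""


@dataclass(frozen=True)
class GenomeSizeEstimate:
    genome_size: float
    error_threshold: int
    hom_peak: int
    included_kmer_mass: int
    method: str = "haploid-peak (no heterozygous mixture fit)"

    def __post_init__(self) -> None:
        if self.error_threshold > self.hom_peak:
            raise ValueError("error_threshold must be <= hom_peak")
        if self.genome_size <= 0:
            raise ValueError("genome_size must be > 0")


def _smoothed_counts(hist: KmerHistogram, smooth: int) -> np.ndarray:
    counts = np.asarray(hist.counts, dtype=float)
    if smooth and smooth > 1 and len(counts) > 1:
        # edge-replicating pad avoids spurious rises at the array boundary
        kernel = np.ones(smooth) / smooth
        padded = np.pad(counts, (smooth // 2, smooth - 1 - smooth // 2), mode="edge")
        counts = np.convolve(padded, kernel, mode="valid")
    return counts


def find_error_threshold(hist: KmerHistogram, smooth: int = 0) -> int:
    """Multiplicity of the first local minimum scanning upward from m = 1.

    Everything below the returned multiplicity is treated as sequencing-error
    k-mer mass.  If counts rise from the very first bin (or there is a single
    bin) there is no error mass and the first multiplicity is returned.  A
    monotonically decreasing spectrum has no coverage peak and raises.
    """
    if not hist.bins:
        raise ValueError("histogram is empty")
    counts = _smoothed_counts(hist, smooth)
    mult = hist.multiplicities
    if len(counts) == 1:
        return mult[0]
    # first index where counts rise marks the end of the error slope
    rises = np.nonzero(np.diff(counts) > 0)[0]
    if rises.size == 0:
        raise NoCoveragePeakError(
            "monotone decreasing spectrum: no coverage peak above the error slope"
        )
    return mult[int(rises[0])]


def estimate_genome_size(
    hist: KmerHistogram,
    smooth: int = 0,
    error_threshold: int | None = None,
) -> GenomeSizeEstimate:
    """Estimate genome size as (included k-mer mass) / (homozygous peak depth).

    Mass is summed over multiplicities >= the error threshold; the homozygous
    peak is the count argmax over the same range.
    """
    if error_threshold is None:
        error_threshold = find_error_threshold(hist, smooth=smooth)
    mult = np.asarray(hist.multiplicities)
    counts = np.asarray(hist.counts, dtype=np.int64)
    keep = mult >= error_threshold
    if not keep.any():
        raise NoCoveragePeakError("error threshold excludes the whole spectrum")
    kept_mult = mult[keep]
    kept_counts = counts[keep]
    smoothed = _smoothed_counts(hist, smooth)[keep]
    hom_peak = int(kept_mult[int(np.argmax(smoothed))])
    mass = int((kept_mult.astype(np.int64) * kept_counts).sum())
    if mass <= 0:
        raise NoCoveragePeakError("no k-mer mass above the error threshold")
    return GenomeSizeEstimate(
        genome_size=mass / hom_peak,
        error_threshold=int(error_threshold),
        hom_peak=hom_peak,
        included_kmer_mass=mass,
    )
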