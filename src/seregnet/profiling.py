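"""Binned, depth-normalized signal profiles and region occupancy scores.

Reads are consumed as single representative positions (e.g. fragment
midpoints from a BED of placements); all scores are reads-per-million so
duplicating the whole library leaves every number unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import InsufficientDataError, NormalizationError
from .io import GenomicInterval

__all__ = [
    "ReadPlacement",
    "SignalProfile",
    "profile_around_centers",
    "region_occupancy_score",
    "relative_occupancy",
]


@dataclass(frozen=True)
class ReadPlacement:
    chrom: str
    position: int

    def __post_init__(self):
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclass
class SignalProfile:
    """Mean reads-per-million per offset bin around peak centers."""

    bin_edges: np.ndarray   # left edges of offset bins, -halfwidth .. +halfwidth
    bin_scores: np.ndarray  # one score per bin, averaged over centers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.bin_edges, "score": self.bin_scores})


def _as_arrays(reads) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(reads, pd.DataFrame):
        return reads["chrom"].to_numpy(), reads["position"].to_numpy(dtype=np.int64)
    chroms = np.array([r.chrom for r in reads])
    pos = np.array([r.position for r in reads], dtype=np.int64)
    return chroms, pos


def profile_around_centers(
    reads,
    centers: Sequence[tuple[str, int]],
    config: PipelineConfig,
) -> SignalProfile:
    """Average read density in 100-bp bins over ±3 kb around each center.

    For each center, reads with offset in ``[-halfwidth, +halfwidth)`` are
    tallied into bins of ``profile_bin`` bp (half-open; +halfwidth itself
    excluded).  Bin counts are summed over centers, divided by the total
    read count in millions, then averaged over the number of centers.

    ``reads`` is either a DataFrame with ``chrom``/``position`` columns or
    an iterable of :class:`ReadPlacement`.
    """
    chroms, pos = _as_arrays(reads)
    n_reads = len(pos)
    if n_reads == 0:
        raise NormalizationError("zero reads: depth normalization undefined")
    if len(centers) == 0:
        raise InsufficientDataError("no centers to profile")
    hw, width = config.profile_halfwidth, config.profile_bin
    n_bins = 2 * hw // width
    counts = np.zeros(n_bins, dtype=np.int64)

    by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(chroms):
        by_chrom[str(c)] = np.sort(pos[chroms == c])
    for chrom, center in centers:
        arr = by_chrom.get(chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr, center - hw, side="left")
        hi = np.searchsorted(arr, center + hw, side="left")
        offsets = arr[lo:hi] - (center - hw)
        counts += np.bincount(offsets // width, minlength=n_bins)[:n_bins]
    scores = counts / (n_reads / 1e6) / len(centers)
    edges = np.arange(-hw, hw, width)
    return SignalProfile(edges, scores)


def region_occupancy_score(reads, region: GenomicInterval) -> float:
    """Reads-per-million falling inside ``[start, end)`` of the region."""
    chroms, pos = _as_arrays(reads)
    n_reads = len(pos)
    if n_reads == 0:
        raise NormalizationError("zero reads: depth normalization undefined")
    inside = (chroms == region.chrom) & (pos >= region.start) & (pos < region.end)
    return float(inside.sum() / (n_reads / 1e6))


def relative_occupancy(score_a: float, score_b: float, pseudocount: float = 1.0) -> float:
    """log2 of the pseudocounted occupancy ratio; exactly antisymmetric."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return float(np.log2((score_a + pseudocount) / (score_b + pseudocount)))
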