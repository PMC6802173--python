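"""Super-enhancer calling: TSS exclusion, stitching, rank-curve elbow cutoff.

The procedure mirrors ROSE-style SE identification: peaks fully contained
in a TSS exclusion zone are dropped, the survivors are stitched into
regions whenever the gap between neighbouring peak intervals is at most
the stitching distance (12.5 kb by default), regions are ranked by total
signal, and the elbow of the unit-scaled ascending rank curve — the point
where the tangent slope reaches 1, found as argmax(x − y) — separates
super-enhancers (strictly above the cutoff signal) from typical enhancers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateCurveError, EmptyInputError, InsufficientDataError
from .io import GeneModel, GenomicInterval, Peak, PeakSet, collapse_to_genes

logger = logging.getLogger(__name__)

__all__ = [
    "StitchedRegion",
    "SECallResult",
    "exclude_tss_peaks",
    "stitch_peaks",
    "rank_and_cutoff",
    "associate_se_genes",
    "call_superenhancers",
]


@dataclass
class StitchedRegion:
    """A maximal run of peaks whose consecutive gaps are <= stitch_distance.

    ``total_signal`` is the sum of constituent peak signal scores and
    ``interval`` spans exactly min(start)..max(end) of the constituents.
    ``rank`` (1-based, ascending total signal) is filled by
    :func:`rank_and_cutoff`.
    """

    interval: GenomicInterval
    constituents: list[Peak] = field(default_factory=list)
    rank: int = 0

    @property
    def total_signal(self) -> float:
        return float(sum(p.signal for p in self.constituents))


@dataclass
class SECallResult:
    """Regions sorted by ascending total signal with the elbow partition."""

    regions: list[StitchedRegion]
    cutoff_signal: float
    cutoff_rank: int  # 1-based rank position of the argmax(x - y) point

    @property
    def superenhancers(self) -> list[StitchedRegion]:
        return [r for r in self.regions if r.total_signal > self.cutoff_signal]

    @property
    def typical(self) -> list[StitchedRegion]:
        return [r for r in self.regions if r.total_signal <= self.cutoff_signal]


def exclude_tss_peaks(
    peaks: PeakSet, genes: Iterable[GeneModel], tss_exclusion: int
) -> PeakSet:
    """Remove peaks fully contained in ``[tss - z, tss + z)`` of any TSS.

    Partial overlaps are retained; ``tss_exclusion=0`` is the identity
    (an empty zone contains nothing).
    """
    if tss_exclusion < 0:
        raise ValueError("tss_exclusion must be >= 0")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)  # type: ignore[attr-defined]
    tss_by_chrom = {c: np.array(sorted(v)) for c, v in tss_by_chrom.items()}

    kept: list[Peak] = []
    removed = 0
    for p in peaks:
        sites = tss_by_chrom.get(p.chrom)
        # containment [start,end) in [t-z, t+z)  <=>  t in [end - z, start + z]
        if sites is not None and tss_exclusion > 0:
            lo, hi = p.end - tss_exclusion, p.start + tss_exclusion
            i = np.searchsorted(sites, lo, side="left")
            if i < len(sites) and sites[i] <= hi:
                removed += 1
                continue
        kept.append(p)
    logger.info("TSS exclusion removed %d of %d peaks", removed, len(peaks))
    return peaks.replace_peaks(kept)


def stitch_peaks(peaks: PeakSet, stitch_distance: int) -> list[StitchedRegion]:
    """Single-linkage merge of peaks whose interval gap is <= stitch_distance.

    The gap is measured between interval ends (end of the earlier peak to
    start of the later), so overlapping peaks always merge.  Output regions
    are disjoint, sorted by (chrom, start), pairwise separated by more than
    the stitch distance, and independent of input order.
    """
    if len(peaks) == 0:
        raise EmptyInputError("cannot stitch an empty peak set")
    ordered = sorted(peaks.peaks, key=lambda p: (p.chrom, p.start, p.end, p.signal))
    regions: list[StitchedRegion] = []
    cur: list[Peak] = [ordered[0]]
    cur_end = ordered[0].end
    for p in ordered[1:]:
        if p.chrom == cur[0].chrom and p.start - cur_end <= stitch_distance:
            cur.append(p)
            cur_end = max(cur_end, p.end)
        else:
            regions.append(_close_region(cur))
            cur = [p]
            cur_end = p.end
    regions.append(_close_region(cur))
    return regions


def _close_region(constituents: list[Peak]) -> StitchedRegion:
    start = min(p.start for p in constituents)
    end = max(p.end for p in constituents)
    return StitchedRegion(GenomicInterval(constituents[0].chrom, start, end), constituents)


def rank_and_cutoff(regions: Sequence[StitchedRegion]) -> SECallResult:
    """Rank regions by ascending total signal and place the elbow cutoff.

    Both axes of the rank curve are rescaled to [0, 1]; the cutoff index is
    ``argmax(x - y)``, the discrete point where the tangent slope of a
    convex ascending curve passes 1.  Regions with total signal strictly
    above the cutoff region's signal are super-enhancers, so a boundary tie
    stays typical.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 regions.
    DegenerateCurveError
        All total signals identical (no elbow exists).
    """
    regs = sorted(
        regions,
        key=lambda r: (r.total_signal, r.interval.chrom, r.interval.start),
    )
    n = len(regs)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 regions to place a cutoff, got {n}")
    sig = np.array([r.total_signal for r in regs], dtype=float)
    if sig[-1] == sig[0]:
        raise DegenerateCurveError("all region signals equal; rank curve has no elbow")
    x = np.arange(n, dtype=float) / (n - 1)
    y = (sig - sig[0]) / (sig[-1] - sig[0])
    cut = int(np.argmax(x - y))
    for i, r in enumerate(regs):
        r.rank = i + 1
    result = SECallResult(regs, cutoff_signal=float(sig[cut]), cutoff_rank=cut + 1)
    logger.info(
        "ranked %d regions; cutoff signal %.4g at rank %d; %d super-enhancers",
        n, result.cutoff_signal, result.cutoff_rank, len(result.superenhancers),
    )
    return result


def associate_se_genes(
    result: SECallResult,
    genes: Iterable[GeneModel],
    network_window: int,
    superenhancers_only: bool = True,
) -> dict[GenomicInterval, frozenset[str]]:
    """Associate each SE with genes whose extended span intersects it.

    A gene's extended span is its body widened by ``network_window`` on
    both sides.  When no extended span intersects an SE, the gene with
    minimal distance between the SE midpoint and its TSS on the same
    chromosome is assigned (ties broken by symbol).  SEs on chromosomes
    without genes are logged and excluded.
    """
    gene_models = collapse_to_genes(genes)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)

    targets = result.superenhancers if superenhancers_only else result.regions
    mapping: dict[GenomicInterval, frozenset[str]] = {}
    for region in targets:
        iv = region.interval
        candidates = by_chrom.get(iv.chrom)
        if not candidates:
            logger.warning("no genes on %s; SE %s left unassigned", iv.chrom, iv)
            continue
        hits = {
            g.symbol
            for g in candidates
            if g.tx_start - network_window < iv.end
            and iv.start < g.tx_end + network_window
        }
        if not hits:
            mid = (iv.start + iv.end) // 2
            nearest = min(candidates, key=lambda g: (abs(g.tss - mid), g.symbol))
            hits = {nearest.symbol}
        mapping[iv] = frozenset(hits)
    return mapping


def call_superenhancers(
    peaks: PeakSet,
    genes: Iterable[GeneModel],
    stitch_distance: int = 12_500,
    tss_exclusion: int = 2_500,
) -> SECallResult:
    """Convenience wrapper: TSS exclusion, stitching, elbow cutoff in one call."""
    gene_list = list(genes)
    filtered = exclude_tss_peaks(peaks, gene_list, tss_exclusion)
    regions = stitch_peaks(filtered, stitch_distance)
    return rank_and_cutoff(regions)
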