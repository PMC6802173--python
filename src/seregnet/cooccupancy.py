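"""Multi-factor co-occupancy: union binding sites, binary occupancy matrix,
pairwise Pearson correlations with clustering order, factors-per-region counts.

Two peaks overlap when their centers lie within a 500-bp window (strict
distance < window) on the same chromosome; chained overlaps merge into one
union site (single linkage), so the site universe is the transitive closure
of the pairwise relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, InsufficientDataError
from .io import GenomicInterval, Peak, PeakSet

__all__ = [
    "UnionSite",
    "OccupancyMatrix",
    "CorrelationResult",
    "centers_overlap",
    "build_union_sites",
    "pairwise_correlation",
    "count_factors_per_region",
]


@dataclass(frozen=True)
class UnionSite:
    """One cluster of mutually (transitively) overlapping peak centers.

    ``anchor`` is the lower median of the member centers; ``interval``
    spans min member start to max member end.
    """

    interval: GenomicInterval
    anchor: int
    members: tuple[tuple[str, Peak], ...]  # (factor, peak) pairs

    def factors(self) -> frozenset[str]:
        return frozenset(f for f, _ in self.members)


@dataclass
class OccupancyMatrix:
    """Binary sites × factors indicator of which factor binds each union site."""

    sites: list[UnionSite]
    factors: list[str]
    values: np.ndarray  # shape (n_sites, n_factors), dtype int8

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{s.interval.chrom}:{s.interval.start}-{s.interval.end}" for s in self.sites]
        return pd.DataFrame(self.values, index=idx, columns=self.factors)


@dataclass
class CorrelationResult:
    table: pd.DataFrame        # factor x factor Pearson r, NaN where undefined
    order: list[str]           # dendrogram leaf order (constant factors excluded)


def centers_overlap(a: Peak, b: Peak, overlap_window: int) -> bool:
    """True iff the two peak centers are within the window on one chromosome."""
    return a.chrom == b.chrom and abs(a.center - b.center) < overlap_window


def build_union_sites(
    peaksets: Sequence[PeakSet], overlap_window: int
) -> OccupancyMatrix:
    """Single-linkage clustering of all peaks from all factors into union sites.

    Invariant to the order of peak sets and of peaks within a set.  Each
    cluster becomes a :class:`UnionSite`; the matrix entry (site, factor)
    is 1 iff the factor contributed at least one peak to the cluster.
    """
    if len(peaksets) < 2:
        raise ConfigurationError("need >= 2 peak sets for a co-occupancy matrix")
    factors = [ps.factor for ps in peaksets]
    if len(set(factors)) != len(factors):
        raise ConfigurationError("factor names must be unique across peak sets")

    entries = [
        (p.chrom, p.center, p.start, p.end, ps.factor, p)
        for ps in peaksets
        for p in ps
    ]
    entries.sort(key=lambda e: (e[0], e[1], e[2], e[3], e[4]))

    sites: list[UnionSite] = []
    cluster: list[tuple[str, int, int, int, str, Peak]] = []

    def close(cl):
        centers = [e[1] for e in cl]
        anchor = sorted(centers)[(len(centers) - 1) // 2]  # lower median
        iv = GenomicInterval(cl[0][0], min(e[2] for e in cl), max(e[3] for e in cl))
        sites.append(UnionSite(iv, anchor, tuple((e[4], e[5]) for e in cl)))

    for e in entries:
        if cluster and (e[0] != cluster[-1][0] or e[1] - cluster[-1][1] >= overlap_window):
            close(cluster)
            cluster = []
        cluster.append(e)
    if cluster:
        close(cluster)

    fidx = {f: j for j, f in enumerate(factors)}
    values = np.zeros((len(sites), len(factors)), dtype=np.int8)
    for i, s in enumerate(sites):
        for f, _ in s.members:
            values[i, fidx[f]] = 1
    return OccupancyMatrix(sites, factors, values)


def _binary_pearson(values: np.ndarray) -> np.ndarray:
    """Column-pairwise Pearson r; NaN for constant columns, diagonal forced to 1."""
    x = values.astype(float)
    xc = x - x.mean(axis=0)
    norms = np.linalg.norm(xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ xc) / np.outer(norms, norms)
    r[norms == 0, :] = np.nan
    r[:, norms == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0, out=r)
    return r


def pairwise_correlation(
    matrix: OccupancyMatrix, method: str = "global"
) -> CorrelationResult:
    """Factor × factor Pearson correlation of binary occupancy columns.

    ``method="global"`` (default) correlates columns over the full union-site
    universe.  ``method="pairwise"`` rebuilds a two-factor universe per pair
    from the member peaks, mirroring the original per-pair overlap design.
    Constant columns have undefined r (reported NaN) and are excluded from
    the average-linkage (1 − r) clustering that supplies the display order.
    """
    if len(matrix.sites) < 2:
        raise InsufficientDataError("need >= 2 union sites for correlations")
    factors = matrix.factors
    if method == "global":
        r = _binary_pearson(matrix.values)
    elif method == "pairwise":
        n = len(factors)
        r = np.full((n, n), np.nan)
        np.fill_diagonal(r, 1.0)
        per_factor = _peaksets_from_matrix(matrix)
        for i in range(n):
            for j in range(i + 1, n):
                sub = build_union_sites(
                    [per_factor[factors[i]], per_factor[factors[j]]],
                    overlap_window=_infer_window(matrix),
                )
                rr = _binary_pearson(sub.values)
                r[i, j] = r[j, i] = rr[0, 1]
    else:
        raise ConfigurationError(f"unknown correlation method {method!r}")

    table = pd.DataFrame(r, index=factors, columns=factors)

    defined = [f for f in factors if not np.isnan(table.loc[f].drop(f)).all()]
    order = list(defined)
    if len(defined) > 2:
        sub = table.loc[defined, defined].to_numpy()
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        z = linkage(squareform(dist, checks=False), method="average")
        order = [defined[i] for i in leaves_list(z)]
    return CorrelationResult(table, order)


def _peaksets_from_matrix(matrix: OccupancyMatrix) -> dict[str, PeakSet]:
    out: dict[str, list[Peak]] = {f: [] for f in matrix.factors}
    for s in matrix.sites:
        for f, p in s.members:
            out[f].append(p)
    return {f: PeakSet(f, "", ps) for f, ps in out.items()}


def _infer_window(matrix: OccupancyMatrix) -> int:
    # the original window is not stored on the matrix; use the field default
    return 500


def count_factors_per_region(
    regions: Iterable[GenomicInterval], peaksets: Sequence[PeakSet]
) -> dict[GenomicInterval, int]:
    """Distinct factors with at least one peak center inside each region."""
    centers = {
        ps.factor: sorted((p.chrom, p.center) for p in ps) for ps in peaksets
    }
    out: dict[GenomicInterval, int] = {}
    for region in regions:
        n = 0
        for factor, pts in centers.items():
            if any(c == region.chrom and region.start <= pos < region.end for c, pos in pts):
                n += 1
        out[region] = n
    return out
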