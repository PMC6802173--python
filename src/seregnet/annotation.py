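"""Peak-to-gene assignment: feature hierarchy, enhancer counts, target genes.

All assignments are decided by the peak *center* (a point), never by
interval overlap.  Feature precedence is
promoter > upstream > intron > exon > intergenic: a promoter is ±2 kb of a
TSS, an upstream element 2–20 kb 5' of the TSS on the gene's strand, and
introns/exons partition the gene body.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable

from .config import PipelineConfig
from .errors import UnassignableError
from .io import GeneModel, Peak, PeakSet, collapse_to_genes

__all__ = [
    "Feature",
    "FeatureCall",
    "classify_peak_feature",
    "classify_peakset",
    "map_enhancers_to_genes",
    "assign_target_gene",
]


class Feature(IntEnum):
    """Genomic features ordered by precedence (lower value wins)."""

    PROMOTER = 0
    UPSTREAM = 1
    INTRON = 2
    EXON = 3
    INTERGENIC = 4

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


@dataclass(frozen=True)
class FeatureCall:
    peak: Peak
    feature: Feature
    gene: GeneModel | None  # None only for intergenic


def _gene_feature(center: int, g: GeneModel, cfg: PipelineConfig) -> Feature | None:
    """Best feature of one gene for a peak center, or None if unrelated."""
    if abs(center - g.tss) <= cfg.promoter_halfwidth:
        return Feature.PROMOTER
    upstream_offset = g.tss - center if g.strand == "+" else center - g.tss
    if cfg.promoter_halfwidth < upstream_offset <= cfg.upstream_max:
        return Feature.UPSTREAM
    if g.tx_start <= center < g.tx_end:
        in_exon = any(e.start <= center < e.end for e in g.exons)
        return Feature.EXON if in_exon else Feature.INTRON
    return None


def classify_peak_feature(
    peak: Peak, genes: Iterable[GeneModel], config: PipelineConfig
) -> FeatureCall:
    """Highest-precedence feature of the peak center across all genes.

    Gene ties at equal precedence are broken by TSS proximity, then symbol.
    """
    center = peak.center
    best: tuple[Feature, int, str, GeneModel] | None = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        feat = _gene_feature(center, g, config)
        if feat is None:
            continue
        key = (feat, abs(center - g.tss), g.symbol, g)
        if best is None or key[:3] < best[:3]:
            best = key
    if best is None:
        return FeatureCall(peak, Feature.INTERGENIC, None)
    return FeatureCall(peak, best[0], best[3])


def classify_peakset(
    peaks: PeakSet, genes: Iterable[GeneModel], config: PipelineConfig
) -> list[FeatureCall]:
    gene_list = list(genes)
    return [classify_peak_feature(p, gene_list, config) for p in peaks]


def map_enhancers_to_genes(
    peaks: PeakSet, genes: Iterable[GeneModel], config: PipelineConfig
) -> dict[str, int]:
    """Per-gene enhancer count: centers within 20 kb 5' of the TSS or the body.

    Strand-aware and many-to-many (one enhancer may count for several
    genes); every gene appears in the result, zero included.
    """
    gene_models = collapse_to_genes(genes)
    counts = {g.symbol: 0 for g in gene_models}
    for g in gene_models:
        if g.strand == "+":
            lo, hi = g.tx_start - config.upstream_max, g.tx_end
        else:
            lo, hi = g.tx_start, g.tx_end + config.upstream_max
        for p in peaks:
            if p.chrom == g.chrom and lo <= p.center < hi:
                counts[g.symbol] += 1
    return counts


def assign_target_gene(
    peak: Peak, genes: Iterable[GeneModel], config: PipelineConfig
) -> list[str]:
    """Target gene(s) of a binding site under the ±window + gene-body rule.

    Returns every gene whose body extended by ``config.network_window`` on
    both sides contains the peak center; when none does, the nearest gene
    by |center − TSS| is assigned (ties: smaller distance to the gene-body
    boundary, then lexicographic symbol).
    """
    center = peak.center
    w = config.network_window
    on_chrom = [g for g in collapse_to_genes(genes) if g.chrom == peak.chrom]
    if not on_chrom:
        raise UnassignableError(f"no gene on chromosome {peak.chrom!r}")
    hits = sorted(
        g.symbol for g in on_chrom if g.tx_start - w <= center < g.tx_end + w
    )
    if hits:
        return hits

    def body_distance(g: GeneModel) -> int:
        if g.tx_start <= center < g.tx_end:
            return 0
        return min(abs(center - g.tx_start), abs(center - (g.tx_end - 1)))

    nearest = min(on_chrom, key=lambda g: (abs(center - g.tss), body_distance(g), g.symbol))
    return [nearest.symbol]
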