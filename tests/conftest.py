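"""Shared fixtures: tiny gene annotations and peak builders."""

import numpy as np
import pytest

from seregnet.config import PipelineConfig
from seregnet.io import GeneModel, GenomicInterval, Peak, PeakSet


@pytest.fixture
def config():
    return PipelineConfig()


def make_peak(chrom, start, end, signal=1.0, factor="p300", state="TSC", name=""):
    return Peak(GenomicInterval(chrom, start, end), signal, factor, state, name)


def make_gene(symbol, chrom, strand, start, end, exons=None, tx_name=None):
    if exons is None:
        third = (end - start) // 3
        exons = [(start, start + third), (end - third, end)]
    return GeneModel(
        symbol=symbol,
        tx_name=tx_name or f"tx_{symbol}",
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=end,
        exons=tuple(GenomicInterval(chrom, s, e) for s, e in exons),
    )


@pytest.fixture
def plus_gene():
    # + strand gene on chr1 spanning [100_000, 130_000), TSS at 100_000
    return make_gene("GeneA", "chr1", "+", 100_000, 130_000)


@pytest.fixture
def minus_gene():
    # - strand gene on chr1 spanning [200_000, 230_000), TSS at 229_999
    return make_gene("GeneB", "chr1", "-", 200_000, 230_000)


def random_peakset(rng, n, chroms=("chr1", "chr2"), span=1_000_000,
                   max_width=2_000, factor="p300"):
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        width = int(rng.integers(100, max_width))
        peaks.append(
            make_peak(chrom, start, start + width, float(rng.exponential(5.0)),
                      factor=factor, name=f"p{i}")
        )
    return PeakSet(factor, "TSC", peaks)
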