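"""Super-enhancer calling: TSS exclusion, stitching vs a closure oracle,
elbow cutoff vs exhaustive evaluation, and SE-gene association."""

import numpy as np
import pytest

from seregnet.errors import DegenerateCurveError, EmptyInputError, InsufficientDataError
from seregnet.io import GenomicInterval, PeakSet
from seregnet.se_calling import (
    StitchedRegion,
    associate_se_genes,
    exclude_tss_peaks,
    rank_and_cutoff,
    stitch_peaks,
)

from conftest import make_gene, make_peak, random_peakset


def stitch_oracle(peaks, stitch_distance):
    """O(n^2) transitive closure of the pairwise gap relation (union-find)."""
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    plist = list(peaks)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = plist[i], plist[j]
            if a.chrom != b.chrom:
                continue
            earlier, later = (a, b) if (a.start, a.end) <= (b.start, b.end) else (b, a)
            if later.start - earlier.end <= stitch_distance:
                union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(plist[i])
    return sorted(
        (g[0].chrom, min(p.start for p in g), max(p.end for p in g),
         round(sum(p.signal for p in g), 6))
        for g in groups.values()
    )


def regions_as_tuples(regions):
    return sorted(
        (r.interval.chrom, r.interval.start, r.interval.end, round(r.total_signal, 6))
        for r in regions
    )


def elbow_oracle_se_count(signals):
    """Exhaustive argmax(x - y) over all points of the scaled ascending curve."""
    s = sorted(signals)
    n = len(s)
    best_i, best_v = 0, -np.inf
    for i in range(n):
        v = i / (n - 1) - (s[i] - s[0]) / (s[-1] - s[0])
        if v > best_v:
            best_i, best_v = i, v
    cutoff = s[best_i]
    return sum(1 for x in s if x > cutoff), cutoff


class TestTssExclusion:
    def test_fully_contained_peak_removed(self):
        gene = make_gene("A", "chr1", "+", 50_000, 80_000)  # TSS 50_000
        ps = PeakSet("p300", "TSC", [
            make_peak("chr1", 48_000, 52_000),  # inside [47500, 52500)
            make_peak("chr1", 46_000, 49_000),  # sticks out on the left
        ])
        out = exclude_tss_peaks(ps, [gene], 2_500)
        assert [(p.start, p.end) for p in out] == [(46_000, 49_000)]

    def test_zero_exclusion_is_identity(self):
        gene = make_gene("A", "chr1", "+", 50_000, 80_000)
        ps = PeakSet("p300", "TSC", [make_peak("chr1", 49_999, 50_001)])
        assert exclude_tss_peaks(ps, [gene], 0).peaks == ps.peaks

    def test_minus_strand_tss_zone(self):
        gene = make_gene("A", "chr1", "-", 10_000, 20_000)  # TSS 19_999
        ps = PeakSet("p300", "TSC", [make_peak("chr1", 19_000, 21_000)])
        assert len(exclude_tss_peaks(ps, [gene], 2_500)) == 0


class TestStitching:
    def test_gap_within_distance_merges(self):
        ps = PeakSet("f", "s", [make_peak("chr1", 1_000, 1_600, 2.0),
                                make_peak("chr1", 10_000, 10_600, 3.0)])
        (r,) = stitch_peaks(ps, 12_500)
        assert (r.interval.start, r.interval.end) == (1_000, 10_600)
        assert r.total_signal == 5.0

    def test_gap_beyond_distance_splits(self):
        ps = PeakSet("f", "s", [make_peak("chr1", 0, 500), make_peak("chr1", 20_000, 20_500)])
        assert len(stitch_peaks(ps, 12_500)) == 2

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            stitch_peaks(PeakSet("f", "s", []), 12_500)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ps = random_peakset(rng, 50, span=400_000)
        got = regions_as_tuples(stitch_peaks(ps, 12_500))
        assert got == stitch_oracle(ps, 12_500)

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(42)
        ps = random_peakset(rng, 60, span=500_000)
        regions = stitch_peaks(ps, 12_500)
        refed = PeakSet("f", "s", [
            make_peak(r.interval.chrom, r.interval.start, r.interval.end, r.total_signal)
            for r in regions
        ])
        again = stitch_peaks(refed, 12_500)
        assert regions_as_tuples(again) == regions_as_tuples(regions)

        perm = rng.permutation(len(ps.peaks))
        shuffled = PeakSet("f", "s", [ps.peaks[i] for i in perm])
        assert regions_as_tuples(stitch_peaks(shuffled, 12_500)) == regions_as_tuples(regions)

    def test_signal_conservation_through_exclusion_and_stitching(self):
        rng = np.random.default_rng(3)
        ps = random_peakset(rng, 80, span=600_000)
        genes = [make_gene("A", "chr1", "+", 100_000, 120_000)]
        surviving = exclude_tss_peaks(ps, genes, 2_500)
        regions = stitch_peaks(surviving, 12_500)
        assert sum(r.total_signal for r in regions) == pytest.approx(
            sum(p.signal for p in surviving)
        )


def _regions_from_signals(signals):
    # well-separated singleton regions carrying the given signals
    return [
        StitchedRegion(
            GenomicInterval("chr1", 100_000 * i + 1, 100_000 * i + 500),
            [make_peak("chr1", 100_000 * i + 1, 100_000 * i + 500, s)],
        )
        for i, s in enumerate(signals)
    ]


class TestElbowCutoff:
    def test_worked_example_two_superenhancers(self):
        res = rank_and_cutoff(_regions_from_signals([1] * 8 + [40, 60]))
        assert len(res.superenhancers) == 2
        assert res.cutoff_signal == 1.0
        assert sorted(r.total_signal for r in res.superenhancers) == [40, 60]

    def test_constant_signals_have_no_elbow(self):
        with pytest.raises(DegenerateCurveError):
            rank_and_cutoff(_regions_from_signals([5.0] * 6))

    def test_too_few_regions(self):
        with pytest.raises(InsufficientDataError):
            rank_and_cutoff(_regions_from_signals([1, 2]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_argmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        signals = np.concatenate(
            [rng.exponential(5.0, 40), rng.exponential(200.0, 5)]
        ).tolist()
        res = rank_and_cutoff(_regions_from_signals(signals))
        n_se, cutoff = elbow_oracle_se_count(signals)
        assert len(res.superenhancers) == n_se
        assert res.cutoff_signal == pytest.approx(cutoff)

    @pytest.mark.parametrize("seed", range(10))
    def test_appending_weaker_region_never_drops_ses(self, seed):
        rng = np.random.default_rng(seed)
        signals = np.concatenate(
            [rng.exponential(5.0, 30), rng.exponential(100.0, 4)]
        ).tolist()
        before = len(rank_and_cutoff(_regions_from_signals(signals)).superenhancers)
        extended = signals + [min(signals) / 2]
        after = len(rank_and_cutoff(_regions_from_signals(extended)).superenhancers)
        assert after >= before

    def test_ranks_are_ascending_and_partition_is_clean(self):
        res = rank_and_cutoff(_regions_from_signals([3, 1, 2, 50, 40]))
        assert [r.rank for r in res.regions] == [1, 2, 3, 4, 5]
        se = {r.rank for r in res.superenhancers}
        ty = {r.rank for r in res.typical}
        assert se | ty == {1, 2, 3, 4, 5} and not se & ty
        assert min(r.total_signal for r in res.superenhancers) > max(
            r.total_signal for r in res.typical
        )


class TestSEGeneAssociation:
    def _result(self, signals):
        return rank_and_cutoff(_regions_from_signals(signals))

    def test_extended_span_intersection(self):
        res = self._result([1, 1, 1, 100])
        se = res.superenhancers[0].interval  # chr1:[300001, 300500)
        near = make_gene("Near", "chr1", "+", se.end + 10_000, se.end + 40_000)
        far = make_gene("Far", "chr1", "+", se.end + 50_000, se.end + 80_000)
        mapping = associate_se_genes(res, [near, far], 20_000)
        assert mapping[se] == frozenset({"Near"})

    def test_nearest_tss_fallback(self):
        res = self._result([1, 1, 1, 100])
        se = res.superenhancers[0].interval
        a = make_gene("A", "chr1", "+", se.end + 100_000, se.end + 130_000)
        b = make_gene("B", "chr1", "+", se.end + 300_000, se.end + 330_000)
        mapping = associate_se_genes(res, [a, b], 20_000)
        assert mapping[se] == frozenset({"A"})

    def test_spanning_two_genes_keeps_both(self):
        res = self._result([1, 1, 1, 100])
        se = res.superenhancers[0].interval
        left = make_gene("L", "chr1", "+", max(se.start - 15_000, 0) , se.start + 100)
        right = make_gene("R", "chr1", "+", se.end - 100, se.end + 15_000)
        mapping = associate_se_genes(res, [left, right], 20_000)
        assert mapping[se] == frozenset({"L", "R"})

    def test_geneless_chromosome_is_excluded(self, caplog):
        res = self._result([1, 1, 1, 100])
        other = make_gene("X", "chr9", "+", 0, 30_000)
        with caplog.at_level("WARNING"):
            mapping = associate_se_genes(res, [other], 20_000)
        assert mapping == {} and "unassigned" in caplog.text
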