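"""Union binding sites, binary occupancy matrix, correlations, SE counts."""

import numpy as np
import pytest

from seregnet.cooccupancy import (
    build_union_sites,
    centers_overlap,
    count_factors_per_region,
    pairwise_correlation,
)
from seregnet.errors import ConfigurationError, InsufficientDataError
from seregnet.io import GenomicInterval, PeakSet

from conftest import make_peak


def union_oracle(peaksets, window):
    """Transitive closure of the pairwise center-overlap relation (union-find)."""
    entries = [(ps.factor, p) for ps in peaksets for p in ps]
    n = len(entries)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = entries[i][1], entries[j][1]
            if a.chrom == b.chrom and abs(a.center - b.center) < window:
                parent[find(i)] = find(j)
    groups = {}
    for i, (factor, p) in enumerate(entries):
        groups.setdefault(find(i), []).append((factor, p))
    return sorted(
        (g[0][1].chrom,
         min(p.start for _, p in g), max(p.end for _, p in g),
         tuple(sorted({f for f, _ in g})))
        for g in groups.values()
    )


def matrix_as_tuples(matrix):
    return sorted(
        (s.interval.chrom, s.interval.start, s.interval.end, tuple(sorted(s.factors())))
        for s in matrix.sites
    )


class TestCentersOverlap:
    @pytest.mark.parametrize(
        "c1, c2, expected", [(100, 550, True), (100, 700, False), (100, 100, True),
                             (100, 599, True), (100, 600, False)]
    )
    def test_window_is_strict_distance(self, c1, c2, expected):
        a = make_peak("chr1", c1 - 50, c1 + 50)
        b = make_peak("chr1", c2 - 50, c2 + 50)
        assert centers_overlap(a, b, 500) is expected

    def test_different_chromosomes_never_overlap(self):
        a = make_peak("chr1", 0, 200)
        b = make_peak("chr2", 0, 200)
        assert not centers_overlap(a, b, 500)


class TestUnionSites:
    def test_identical_peak_lists_give_all_ones(self):
        peaks = [make_peak("chr1", i * 10_000, i * 10_000 + 400) for i in range(5)]
        m = build_union_sites(
            [PeakSet("A", "", peaks), PeakSet("B", "", list(peaks))], 500
        )
        assert m.values.shape == (5, 2) and m.values.all()

    def test_disjoint_chromosomes_share_no_sites(self):
        a = PeakSet("A", "", [make_peak("chr1", 0, 400)])
        b = PeakSet("B", "", [make_peak("chr2", 0, 400)])
        m = build_union_sites([a, b], 500)
        assert sorted(map(tuple, m.values.tolist())) == [[0, 1], [1, 0]] or \
               sorted(map(tuple, m.values.tolist())) == [(0, 1), (1, 0)]

    def test_chained_overlaps_merge_transitively(self):
        # A~B and B~C within 500 bp but A-C distance 800: one union site
        a = PeakSet("A", "", [make_peak("chr1", 800, 1200)])   # center 1000
        b = PeakSet("B", "", [make_peak("chr1", 1200, 1600)])  # center 1400
        c = PeakSet("C", "", [make_peak("chr1", 1600, 2000)])  # center 1800
        m = build_union_sites([a, b, c], 500)
        assert len(m.sites) == 1 and m.values.tolist() == [[1, 1, 1]]
        assert m.sites[0].anchor == 1400  # lower median of member centers

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_closure_oracle_on_random_factors(self, seed):
        rng = np.random.default_rng(seed)
        sets = [
            PeakSet(f"TF{k}", "", [
                make_peak("chr1", s, s + 300, factor=f"TF{k}")
                for s in rng.integers(0, 40_000, 30).tolist()
            ])
            for k in range(3)
        ]
        m = build_union_sites(sets, 500)
        assert matrix_as_tuples(m) == union_oracle(sets, 500)

    def test_invariant_to_peakset_and_peak_order(self):
        rng = np.random.default_rng(9)
        sets = [
            PeakSet(f"TF{k}", "", [
                make_peak("chr1", s, s + 300)
                for s in rng.integers(0, 30_000, 20).tolist()
            ])
            for k in range(3)
        ]
        m1 = build_union_sites(sets, 500)
        shuffled = [
            PeakSet(ps.factor, ps.cell_state,
                    [ps.peaks[i] for i in rng.permutation(len(ps.peaks))])
            for ps in reversed(sets)
        ]
        m2 = build_union_sites(shuffled, 500)
        assert matrix_as_tuples(m1) == matrix_as_tuples(m2)

    def test_every_row_has_a_binder_and_column_sums_match(self):
        rng = np.random.default_rng(2)
        sets = [
            PeakSet(f"TF{k}", "", [
                make_peak("chr1", s, s + 300)
                for s in rng.integers(0, 50_000, 25).tolist()
            ])
            for k in range(2)
        ]
        m = build_union_sites(sets, 500)
        assert (m.values.sum(axis=1) >= 1).all()
        for j, f in enumerate(m.factors):
            participating = sum(1 for s in m.sites if f in s.factors())
            assert m.values[:, j].sum() == participating

    def test_single_peakset_rejected(self):
        with pytest.raises(ConfigurationError):
            build_union_sites([PeakSet("A", "", [make_peak("chr1", 0, 100)])], 500)


class TestPairwiseCorrelation:
    def test_identical_sets_correlate_perfectly(self):
        peaks = [make_peak("chr1", i * 10_000, i * 10_000 + 400) for i in range(6)]
        extra = PeakSet("C", "", [make_peak("chr1", 1_000_000, 1_000_400)])
        m = build_union_sites(
            [PeakSet("A", "", peaks), PeakSet("B", "", list(peaks)), extra], 500
        )
        r = pairwise_correlation(m).table
        assert r.loc["A", "B"] == pytest.approx(1.0)
        assert r.loc["A", "A"] == 1.0

    def test_complementary_factors_anticorrelate(self):
        # TF1 binds sites 1-2, TF2 binds sites 3-4: columns [1,1,0,0] vs [0,0,1,1]
        a = PeakSet("TF1", "", [make_peak("chr1", i * 10_000, i * 10_000 + 400)
                                for i in range(2)])
        b = PeakSet("TF2", "", [make_peak("chr1", i * 10_000, i * 10_000 + 400)
                                for i in range(2, 4)])
        m = build_union_sites([a, b], 500)
        assert pairwise_correlation(m).table.loc["TF1", "TF2"] == pytest.approx(-1.0)

    def test_constant_column_reported_missing_not_zero(self):
        # factor bound everywhere has zero variance: r undefined
        peaks = [make_peak("chr1", i * 10_000, i * 10_000 + 400) for i in range(4)]
        a = PeakSet("A", "", peaks)
        b = PeakSet("B", "", list(peaks))
        c = PeakSet("C", "", peaks[:2])
        m = build_union_sites([a, b, c], 500)
        r = pairwise_correlation(m).table
        assert np.isnan(r.loc["A", "C"])  # A constant across the union universe

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(4)
        sets = [
            PeakSet(f"TF{k}", "", [
                make_peak("chr1", s, s + 300)
                for s in rng.integers(0, 60_000, 25).tolist()
            ])
            for k in range(4)
        ]
        res = pairwise_correlation(build_union_sites(sets, 500))
        r = res.table.to_numpy()
        assert np.allclose(r, r.T, equal_nan=True)
        defined = r[~np.isnan(r)]
        assert ((defined >= -1) & (defined <= 1)).all()
        assert set(res.order) <= set(res.table.columns)

    def test_high_cooccupancy_pair_outranks_low(self):
        from seregnet.synthetic import generate_tf_peaksets

        wins = 0
        for seed in range(20):
            sets, _ = generate_tf_peaksets(
                n_factors=3, shared_sites=300,
                cooccupancy_rate=[0.9, 0.9, 0.1],
                private_sites_per_factor=50, seed=seed,
            )
            r = pairwise_correlation(build_union_sites(sets, 500)).table
            wins += r.iloc[0, 1] > r.iloc[0, 2]
        assert wins >= 19

    def test_too_few_sites_rejected(self):
        a = PeakSet("A", "", [make_peak("chr1", 0, 400)])
        b = PeakSet("B", "", [make_peak("chr1", 100, 500)])
        m = build_union_sites([a, b], 500)
        with pytest.raises(InsufficientDataError):
            pairwise_correlation(m)


class TestFactorsPerRegion:
    def test_counts_distinct_factors_only(self):
        region = GenomicInterval("chr1", 0, 13_000)
        many = [PeakSet(f"TF{k}", "", [make_peak("chr1", 1_000 * k, 1_000 * k + 200)])
                for k in range(12)]
        single = PeakSet("solo", "", [make_peak("chr1", 100, 300),
                                      make_peak("chr1", 2_000, 2_200)])
        assert count_factors_per_region([region], many)[region] == 12
        assert count_factors_per_region([region], [single, PeakSet("empty", "", [])])[region] == 1

    def test_empty_region_counts_zero(self):
        region = GenomicInterval("chr5", 0, 1_000)
        sets = [PeakSet("A", "", [make_peak("chr1", 0, 200)])]
        assert count_factors_per_region([region], sets)[region] == 0
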