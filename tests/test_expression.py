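"""Moving-average enhancer counts, time-course classes, dysregulation screen."""

import numpy as np
import pandas as pd
import pytest

from seregnet.errors import ConfigurationError, DegenerateProfilesError
from seregnet.expression import (
    CaseControlDataset,
    archetype_templates,
    classify_timecourse,
    crossdataset_dysregulated,
    moving_average_enhancer_counts,
    relative_timecourse,
)
from seregnet.synthetic import (
    generate_case_control_datasets,
    generate_timecourse_expression,
)


def table(values, genes=None, cols=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = cols or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cols)


class TestMovingAverage:
    def test_window_mean_arithmetic(self):
        # ratios force rank order g0 > g1 > g2 > g3; counts 1,2,3,4 in rank order
        a = table([[16], [8], [4], [2]])
        b = table([[1], [1], [1], [1]])
        counts = {"g0": 1, "g1": 2, "g2": 3, "g3": 4}
        out = moving_average_enhancer_counts(a, b, counts, window=3)
        assert out["mean_count"].tolist() == [2.0, 3.0]
        assert out["rank"].tolist() == [1, 2]

    def test_constant_counts_give_constant_series(self):
        rng = np.random.default_rng(0)
        a = table(rng.uniform(1, 100, (20, 2)))
        b = table(rng.uniform(1, 100, (20, 2)))
        counts = {g: 7 for g in a.index}
        out = moving_average_enhancer_counts(a, b, counts, window=5)
        assert np.allclose(out["mean_count"], 7.0)
        assert len(out) == 16

    def test_window_larger_than_universe_rejected(self):
        a, b = table([[1], [2]]), table([[1], [2]])
        with pytest.raises(ConfigurationError):
            moving_average_enhancer_counts(a, b, {"g0": 1, "g1": 2}, window=3)

    def test_depends_only_on_ranked_count_sequence(self):
        """Relabeling genes while preserving (ratio rank, count) pairs is a no-op."""
        rng = np.random.default_rng(1)
        vals = np.sort(rng.uniform(1, 50, 10))[::-1]
        a = table(vals[:, None], genes=[f"g{i}" for i in range(10)])
        b = table(np.ones((10, 1)), genes=list(a.index))
        counts = {f"g{i}": i for i in range(10)}
        out1 = moving_average_enhancer_counts(a, b, counts, window=4)
        renamed = {f"g{i}": f"x{i:02d}" for i in range(10)}
        a2, b2 = a.rename(index=renamed), b.rename(index=renamed)
        counts2 = {renamed[g]: c for g, c in counts.items()}
        out2 = moving_average_enhancer_counts(a2, b2, counts2, window=4)
        assert out1["mean_count"].tolist() == out2["mean_count"].tolist()

    def test_enhancer_dosage_tracks_relative_expression(self):
        """Counts rising with true relative expression -> windowed means fall
        along the descending ranking (negative rank correlation)."""
        from scipy.stats import spearmanr
        from seregnet.synthetic import generate_condition_pair

        rhos = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            counts = {f"g{i:03d}": int(c) for i, c in enumerate(rng.integers(0, 30, 200))}
            a, b = generate_condition_pair(counts, seed=seed, noise_sd=0.1)
            out = moving_average_enhancer_counts(a, b, counts, window=50)
            rho, _ = spearmanr(out["rank"], out["mean_count"])
            rhos.append(rho)
        assert all(r < -0.9 for r in rhos)


class TestRelativeTimecourse:
    def test_flat_profile_maps_to_ones(self):
        out = relative_timecourse(table([[2, 2, 2, 2]]))
        assert out.iloc[0].tolist() == [1, 1, 1, 1]

    def test_zero_mean_gene_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = relative_timecourse(table([[0, 4], [0, 0]]))
        assert out.index.tolist() == ["g0"]
        assert out.iloc[0].tolist() == [0.0, 2.0]
        assert "all-zero" in caplog.text

    def test_rows_average_to_one(self):
        rng = np.random.default_rng(0)
        out = relative_timecourse(table(rng.uniform(0.1, 100, (50, 7))))
        assert np.allclose(out.mean(axis=1), 1.0, atol=1e-9)


class TestClassifyTimecourse:
    def test_pure_archetypes_recover_their_labels(self):
        templates = archetype_templates(7)
        rows = [100 * 2.0 ** templates[c] for c in (1, 2, 3, 4)]
        expr = table(rows, genes=["bi", "down", "up", "flat"])
        classing = classify_timecourse(expr, 4)
        assert classing.class_of == {"bi": 1, "down": 2, "up": 3, "flat": 4}

    def test_single_class_groups_everything(self):
        rng = np.random.default_rng(0)
        expr = table(rng.uniform(1, 50, (6, 5)))
        classing = classify_timecourse(expr, 1)
        assert set(classing.class_of.values()) == {1}

    def test_identical_profiles_raise_named_error(self):
        expr = table([[5, 5, 5, 5]] * 4, genes=["a", "b", "c", "d"])
        with pytest.raises(DegenerateProfilesError, match="a, b"):
            classify_timecourse(expr, 4)

    def test_generator_truth_recovery_at_moderate_noise(self):
        hits, total = 0, 0
        for seed in range(5):
            expr, truth = generate_timecourse_expression(
                n_genes_per_class=30, n_timepoints=7, noise_sd=0.1, seed=seed
            )
            classing = classify_timecourse(expr, 4)
            for g, c in classing.class_of.items():
                hits += c == truth.class_labels[g]
                total += 1
        assert hits / total >= 0.95


class TestCrossdatasetScreen:
    def _datasets(self):
        return generate_case_control_datasets(
            n_datasets=5, n_genes=400, n_planted_up=10, n_planted_down=10,
            effect_log2fc=2.0, noise_sd=0.2, seed=0,
        )

    def test_threshold_rule_and_direction(self):
        datasets, truth = self._datasets()
        result = crossdataset_dysregulated(
            datasets, set(truth.dysregulated_genes), None, 0.10, 3
        )
        assert set(result.index) == set(truth.dysregulated_genes)
        for g, row in result.iterrows():
            assert row["direction"] == truth.dysregulated_genes[g]

    def test_gene_extreme_in_too_few_datasets_not_selected(self):
        datasets, truth = self._datasets()
        result = crossdataset_dysregulated(
            datasets, set(truth.dysregulated_genes), None, 0.10, 5
        )
        hits5 = set(result.index)
        result3 = crossdataset_dysregulated(
            datasets, set(truth.dysregulated_genes), None, 0.10, 3
        )
        assert hits5 <= set(result3.index)  # raising min_hits never adds genes

    def test_wider_extremes_never_remove_genes(self):
        datasets, truth = self._datasets()
        narrow = crossdataset_dysregulated(
            datasets, set(truth.dysregulated_genes), None, 0.05, 3
        )
        wide = crossdataset_dysregulated(
            datasets, set(truth.dysregulated_genes), None, 0.15, 3
        )
        assert set(narrow.index) <= set(wide.index)

    def test_ortholog_mapping_restricts_candidates(self):
        datasets, truth = self._datasets()
        planted = sorted(truth.dysregulated_genes)
        orthologs = {f"m_{g}": g for g in planted[:5]}
        result = crossdataset_dysregulated(
            datasets, {f"m_{g}" for g in planted[:5]}, orthologs, 0.10, 3
        )
        assert set(result.index) <= set(planted[:5])

    def test_background_gene_never_qualifies_when_not_se_associated(self):
        datasets, truth = self._datasets()
        result = crossdataset_dysregulated(
            datasets, set(truth.dysregulated_genes), None, 0.10, 3
        )
        background = set(datasets[0].expression.index) - set(truth.dysregulated_genes)
        assert not (set(result.index) & background)

    def test_fewer_datasets_than_min_hits_rejected(self):
        datasets, truth = self._datasets()
        with pytest.raises(ConfigurationError):
            crossdataset_dysregulated(datasets[:2], set(), None, 0.10, 3)
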