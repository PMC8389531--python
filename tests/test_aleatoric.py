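"""Empirical cdfs, probability boxes, shape statistics and the three views."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from uqmd.aleatoric import (
    ecdf,
    ensemble_vs_parametric,
    pbox,
    pbox_interval,
    per_seed_intervals,
    shape_report,
    shape_stats,
    skewness_region,
)

from conftest import table_from_matrix


class TestEcdf:
    def test_single_sample(self):
        F = ecdf([1.0])
        assert F(0.9) == 0.0 and F(1.0) == 1.0

    def test_midpoint(self):
        assert ecdf([1, 2, 3, 4])(2.5) == 0.5

    def test_ties_counted_with_multiplicity(self):
        assert ecdf([2, 2, 3])(2) == pytest.approx(2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf([])

    def test_inverse_is_generalized_left_continuous(self):
        F = ecdf([1, 2, 3, 4])
        assert F.inverse(0.5) == 2.0  # min{x : F(x) >= 0.5}
        assert F.inverse(0.51) == 3.0
        assert F.inverse(1.0) == 4.0


class TestPBox:
    def test_identical_seeds_degenerate_envelope(self):
        E = np.tile(np.array([[0.0], [1.0], [2.0]]), (1, 4))
        box = pbox(table_from_matrix(E))
        for x in [-0.5, 0.0, 0.7, 1.0, 2.5]:
            assert box.lower(x) == box.upper(x)

    def test_disjoint_seeds(self):
        E = np.array([[0.0, 10.0], [1.0, 11.0]])
        box = pbox(table_from_matrix(E))
        assert box.upper(1.0) == 1.0
        assert box.lower(9.9) == 0.0
        assert box.lower(10.0) == 0.5

    def test_translation_property(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=30)
        delta = 0.7
        E = np.column_stack([base, base + delta])
        box = pbox(table_from_matrix(E))
        lo, hi, width = pbox_interval(box, 0.9)
        F = ecdf(base)
        single = F.inverse(0.95) - F.inverse(0.05)
        assert width == pytest.approx(single + delta, abs=1e-12)

    def test_envelope_dominates_members(self):
        rng = np.random.default_rng(7)
        E = rng.normal(size=(40, 8)) + rng.normal(scale=0.5, size=8)
        box = pbox(table_from_matrix(E))
        probes = rng.uniform(E.min() - 1, E.max() + 1, size=1000)
        lo = box.lower(probes)
        hi = box.upper(probes)
        for F in box.per_seed_cdfs.values():
            vals = F(probes)
            assert np.all(lo <= vals + 1e-15) and np.all(vals <= hi + 1e-15)

    def test_interval_monotone_in_level(self):
        rng = np.random.default_rng(8)
        E = rng.normal(size=(50, 5))
        box = pbox(table_from_matrix(E))
        widths = [pbox_interval(box, lv)[2] for lv in (0.5, 0.8, 0.9, 0.95)]
        assert all(b >= a for a, b in zip(widths, widths[1:]))

    def test_envelope_interval_is_conservative(self):
        rng = np.random.default_rng(9)
        E = rng.normal(size=(60, 10)) + 0.8 * rng.normal(size=10)
        box = pbox(table_from_matrix(E))
        _, _, width = pbox_interval(box, 0.95)
        indiv = per_seed_intervals(box, 0.95)["width"]
        assert width >= indiv.max()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=10_000),
        st.integers(min_value=2, max_value=25),
        st.integers(min_value=2, max_value=10),
    )
    def test_envelope_dominance_fuzzed(self, seed, n_cfg, n_seed):
        rng = np.random.default_rng(seed)
        E = rng.normal(size=(n_cfg, n_seed)) + 2 * rng.normal(size=n_seed)
        box = pbox(table_from_matrix(E))
        probes = rng.uniform(E.min() - 1, E.max() + 1, size=200)
        lo, hi = box.lower(probes), box.upper(probes)
        for F in box.per_seed_cdfs.values():
            v = F(probes)
            assert np.all(lo <= v) and np.all(v <= hi)

    def test_ragged_table_rejected(self):
        t = table_from_matrix(np.zeros((3, 4)))
        frame = t.frame.drop(index=[0])  # remove one (config, seed) row
        from uqmd.tables import EvaluationTable

        with pytest.raises(ValueError):
            pbox(EvaluationTable(frame))

    def test_single_configuration_rejected(self):
        with pytest.raises(ValueError):
            pbox(table_from_matrix(np.zeros((1, 4))))


class TestShapeStats:
    def test_gaussian_reference_values(self):
        rng = np.random.default_rng(10)
        entry = shape_stats(rng.normal(size=200_000), n_boot=10, seed=1)
        assert entry.skewness == pytest.approx(0.0, abs=0.05)
        assert entry.excess_kurtosis == pytest.approx(0.0, abs=0.05)
        assert entry.region == "A"

    def test_symmetric_two_point_sample(self):
        entry = shape_stats([-1.0, -1.0, 1.0, 1.0], n_boot=50, seed=2)
        assert entry.skewness == pytest.approx(0.0)
        assert entry.region == "A"

    def test_exponential_is_highly_skewed(self):
        rng = np.random.default_rng(11)
        entry = shape_stats(rng.exponential(size=200_000), n_boot=10, seed=3)
        assert entry.skewness == pytest.approx(2.0, abs=0.1)
        assert entry.region == "C"

    def test_zero_variance_flagged(self):
        entry = shape_stats([3.0, 3.0, 3.0], n_boot=10, seed=4)
        assert entry.defined is False
        assert entry.region == "undefined"

    def test_bootstrap_ci_contains_point_estimate(self):
        rng = np.random.default_rng(12)
        hits = 0
        n_cases = 100
        for k in range(n_cases):
            x = rng.normal(size=25) + rng.exponential(size=25)
            e = shape_stats(x, n_boot=300, seed=k)
            hits += e.skew_ci[0] <= e.skewness <= e.skew_ci[1]
        assert hits >= 0.99 * n_cases

    def test_bias_corrected_variant_available(self):
        x = np.random.default_rng(13).exponential(size=50)
        biased = shape_stats(x, n_boot=5, seed=0, bias=True)
        corrected = shape_stats(x, n_boot=5, seed=0, bias=False)
        assert biased.skewness != corrected.skewness
        assert corrected.skewness == pytest.approx(
            stats.skew(x, bias=False)
        )

    @pytest.mark.parametrize(
        "skew,region",
        [(0.0, "A"), (0.49, "A"), (0.5, "B"), (-0.8, "B"), (1.0, "B"), (-1.2, "C")],
    )
    def test_region_thresholds(self, skew, region):
        assert skewness_region(skew) == region


class TestShapeReport:
    def test_per_configuration_entries(self, mock_table):
        rep = shape_report(mock_table, n_boot=50, seed=0)
        assert len(rep.entries) == mock_table.n_configs
        assert set(rep.entries["region"]) <= {"A", "B", "C", "undefined"}

    def test_reproducible_given_seed(self, mock_table):
        a = shape_report(mock_table, n_boot=50, seed=5).entries
        b = shape_report(mock_table, n_boot=50, seed=5).entries
        assert a.equals(b)


class TestThreeViews:
    def test_sizes(self):
        E = np.random.default_rng(14).normal(size=(63, 25))
        raw, per_seed, per_config = ensemble_vs_parametric(table_from_matrix(E))
        assert raw.size == 1575
        assert per_seed.size == 25
        assert per_config.size == 63

    def test_seed_only_energy_has_zero_epistemic_variance(self):
        seed_effect = np.arange(5, dtype=float)
        E = np.tile(seed_effect, (10, 1))
        _, per_seed, per_config = ensemble_vs_parametric(table_from_matrix(E))
        assert np.var(per_config) == 0.0
        assert np.var(per_seed) > 0.0

    def test_config_only_energy_has_zero_aleatoric_variance(self):
        cfg_effect = np.arange(10, dtype=float).reshape(-1, 1)
        E = np.tile(cfg_effect, (1, 5))
        _, per_seed, per_config = ensemble_vs_parametric(table_from_matrix(E))
        assert np.var(per_seed) == 0.0
        assert np.var(per_config) > 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_averaging_reduces_variance(self, seed):
        rng = np.random.default_rng(seed)
        E = rng.normal(size=(20, 12)) + rng.normal(size=(20, 1)) + rng.normal(size=12)
        raw, per_seed, per_config = ensemble_vs_parametric(table_from_matrix(E))
        assert np.var(raw) >= np.var(per_config) - 1e-12
        assert np.var(raw) >= np.var(per_seed) - 1e-12
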