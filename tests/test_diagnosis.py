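"""Set-level diagnosis: bootstrap CI, threshold rule, Wilson intervals, cross-matrix."""

import numpy as np
import pytest

from pascdx.errors import ConfigurationError, InsufficientDataError
from pascdx.diagnosis import (
    bootstrap_proportion,
    cross_disease_matrix,
    determine_threshold,
    proportion_flagged,
    wilson_interval,
)
from pascdx.modeling import ModelSpec, train_final
from pascdx.synth import SynthConfig, generate_disease_tables

from conftest import make_table

FAST_LR = ModelSpec(family="LR", grid={"clf__C": [1.0]}, seed=0)


class TestProportionFlagged:
    def test_separable_positives_nearly_all_flagged(self, separable_table):
        model = train_final(separable_table, FAST_LR, seed=0)
        pos = separable_table.select_rows(separable_table.labels == 1)
        p, flags = proportion_flagged(model, pos)
        assert p == flags.mean() >= 0.95

    def test_empty_set_rejected(self, separable_table):
        model = train_final(separable_table, FAST_LR, seed=0)
        with pytest.raises(InsufficientDataError):
            proportion_flagged(model, np.empty((0, 10)))


class TestBootstrapProportion:
    def test_degenerate_flags_zero_width(self):
        diag = bootstrap_proportion(np.ones(30, bool), n_boot=100, seed=0)
        assert diag.ci_low == diag.ci_high == diag.proportion == 1.0
        diag0 = bootstrap_proportion(np.zeros(30, bool), n_boot=100, seed=0)
        assert diag0.ci_low == diag0.ci_high == 0.0

    def test_deterministic_given_seed(self):
        flags = np.random.default_rng(0).integers(0, 2, 50).astype(bool)
        a = bootstrap_proportion(flags, seed=9)
        b = bootstrap_proportion(flags, seed=9)
        assert np.array_equal(a.bootstrap_values, b.bootstrap_values)

    def test_replicate_count_and_bounds(self):
        flags = np.random.default_rng(1).integers(0, 2, 80).astype(bool)
        diag = bootstrap_proportion(flags, n_boot=500, confidence=0.95, seed=2)
        assert diag.bootstrap_values.size == 500
        assert diag.ci_low <= np.median(diag.bootstrap_values) <= diag.ci_high
        assert 0 <= diag.ci_low <= diag.ci_high <= 1

    def test_n_boot_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            bootstrap_proportion(np.ones(5, bool), n_boot=1)

    def test_ci_width_shrinks_as_sqrt_n(self):
        """Percentile-CI width scales ~ 1/sqrt(n) in the metabolite-set size."""
        rng = np.random.default_rng(3)
        widths = {}
        for n in (25, 100, 400):
            w = []
            for rep in range(40):
                flags = rng.random(n) < 0.5
                d = bootstrap_proportion(flags, n_boot=300, seed=rep)
                w.append(d.ci_high - d.ci_low)
            widths[n] = np.mean(w)
        assert widths[100] / widths[25] == pytest.approx(0.5, rel=0.25)
        assert widths[400] / widths[100] == pytest.approx(0.5, rel=0.25)


class TestDetermineThreshold:
    def test_degenerate_clouds(self):
        ref = np.full(500, 0.95)
        comp = np.full(500, 0.80)
        result = determine_threshold(ref, comp)
        assert result.separable
        assert result.confidence_level == pytest.approx(0.95)
        assert result.threshold == pytest.approx(0.875)

    def test_identical_clouds_non_separable(self):
        cloud = np.random.default_rng(0).normal(0.8, 0.05, 500)
        result = determine_threshold(cloud, cloud.copy())
        assert not result.separable
        assert np.isnan(result.threshold)

    def test_reversed_medians_non_separable(self):
        rng = np.random.default_rng(1)
        low = rng.normal(0.6, 0.02, 500)
        high = rng.normal(0.9, 0.02, 500)
        assert not determine_threshold(low, high).separable

    def test_matches_exhaustive_scan_oracle(self):
        """Overlapping normal clouds: first-disjoint confidence equals a
        brute-force scan over the same grid, within one step."""
        rng = np.random.default_rng(42)
        ref = rng.normal(0.9, 0.05, 500)
        comp = rng.normal(0.7, 0.05, 500)
        result = determine_threshold(ref, comp, c_step=0.001)
        assert result.separable

        oracle_c = None
        for i in range(951):
            c = 0.95 - i * 0.001
            if c <= 0:
                break
            r_lo = np.percentile(ref, 100 * (1 - c) / 2)
            c_hi = np.percentile(comp, 100 * (1 + c) / 2)
            if c_hi < r_lo:
                oracle_c = c
                break
        assert oracle_c is not None
        assert result.confidence_level == pytest.approx(oracle_c, abs=0.001)
        assert result.gap_low < result.threshold < result.gap_high

    def test_monotone_in_gap(self):
        """Widening the gap between clouds never lowers the achievable confidence."""
        rng = np.random.default_rng(5)
        base = rng.normal(0.0, 0.05, 500)
        levels = []
        for gap in (0.05, 0.1, 0.2, 0.3, 0.4):
            # same cloud shape, centers separated by `gap`
            res = determine_threshold(base + 0.7 + gap / 2, base + 0.7 - gap / 2)
            levels.append(res.confidence_level if res.separable else 0.0)
        assert all(b >= a for a, b in zip(levels, levels[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            determine_threshold(np.array([]), np.array([0.5]))


class TestWilson:
    def test_frozen_example(self):
        lo, hi = wilson_interval(9, 10)
        assert lo == pytest.approx(0.596, abs=5e-4)
        assert hi == pytest.approx(0.982, abs=5e-4)

    def test_boundaries(self):
        assert wilson_interval(0, 10)[0] == 0.0
        assert wilson_interval(10, 10)[1] == 1.0

    def test_matches_statsmodels_closed_form(self):
        from statsmodels.stats.proportion import proportion_confint

        for n in range(1, 51):
            for k in range(n + 1):
                lo, hi = wilson_interval(k, n)
                ref_lo, ref_hi = proportion_confint(k, n, alpha=0.05, method="wilson")
                assert lo == pytest.approx(ref_lo, abs=1e-10)
                assert hi == pytest.approx(ref_hi, abs=1e-10)
                assert lo <= k / n <= hi

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            wilson_interval(5, 0)
        with pytest.raises(ConfigurationError):
            wilson_interval(11, 10)


class TestCrossDiseaseMatrix:
    def test_twin_diseases_mutually_confused(self):
        """overlap=1 with identical shift: each model flags the other's
        positives at a rate close to its own."""
        cfg = SynthConfig(n_descriptors=30, n_informative=8, descriptor_shift=1.5,
                          overlap=1.0, seed=10)
        tables = generate_disease_tables(cfg, n_diseases=2, n_positive=60)
        mat = cross_disease_matrix(tables, FAST_LR, seed=0)
        p = mat.proportions
        assert p.loc["disease_A", "disease_B"] >= 0.8
        assert p.loc["disease_B", "disease_A"] >= 0.8

    def test_disjoint_signatures_diagonal_dominates(self):
        cfg = SynthConfig(n_descriptors=30, n_informative=8, descriptor_shift=2.0,
                          overlap=0.0, seed=11)
        tables = generate_disease_tables(cfg, n_diseases=2, n_positive=60)
        mat = cross_disease_matrix(tables, FAST_LR, seed=0)
        p = mat.proportions
        assert p.loc["disease_A", "disease_A"] > p.loc["disease_A", "disease_B"]
        assert p.loc["disease_B", "disease_B"] > p.loc["disease_B", "disease_A"]
        # Wilson intervals contain their point proportions
        for row in p.index:
            for col in p.columns:
                assert mat.ci_low.loc[row, col] <= p.loc[row, col] <= mat.ci_high.loc[row, col]

    def test_single_disease_rejected(self, small_table):
        with pytest.raises(ConfigurationError):
            cross_disease_matrix({"only": small_table}, FAST_LR, seed=0)

    def test_mismatched_columns_rejected(self, small_table):
        other = make_table(n_descriptors=5, seed=3)
        with pytest.raises(ConfigurationError):
            cross_disease_matrix({"a": small_table, "b": other}, FAST_LR, seed=0)
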