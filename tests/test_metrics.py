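import numpy as np
import pytest
from hypothesis import given, strategies as st

from rhythmforge import (
    DegenerateDistributionError,
    InvalidParameterError,
    InvalidSequenceError,
    build_bins,
    differential_entropy,
    generate_isochronous,
    generate_poisson,
    intervals,
    kde_density,
    on_integer_fraction,
    rhythm_ratios,
    sequence_metrics,
)
from rhythmforge.metrics import DEFAULT_TARGETS


class TestIntervals:
    def test_basic_differences(self):
        np.testing.assert_allclose(intervals(np.array([0.0, 250.0, 500.0])), [250.0, 250.0])

    def test_length_and_telescoping(self, rng):
        times = np.cumsum(rng.exponential(10.0, size=50))
        iv = intervals(times)
        assert iv.size == times.size - 1
        assert iv.sum() == pytest.approx(times[-1] - times[0])

    def test_rejects_bad_sequences(self):
        with pytest.raises(InvalidSequenceError):
            intervals(np.array([5.0]))
        with pytest.raises(InvalidSequenceError):
            intervals(np.array([0.0, 2.0, 2.0]))


class TestRhythmRatios:
    def test_two_to_one_ratio(self):
        assert rhythm_ratios(np.array([200.0, 100.0]))[0] == pytest.approx(2.0 / 3.0)

    def test_isochrony_gives_half(self):
        np.testing.assert_allclose(rhythm_ratios(np.full(20, 137.0)), 0.5)

    @given(
        st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=2, max_size=40)
    )
    def test_reversal_symmetry(self, durations):
        # algebraic identity: ratios of the reversed sequence are 1 - r, reversed
        iv = np.asarray(durations)
        forward = rhythm_ratios(iv)
        backward = rhythm_ratios(iv[::-1])
        np.testing.assert_allclose(backward, (1.0 - forward)[::-1], rtol=1e-9)

    def test_values_strictly_inside_unit_interval(self, rng):
        r = rhythm_ratios(rng.exponential(5.0, size=1000))
        assert np.all((r > 0) & (r < 1))

    def test_needs_two_intervals(self):
        with pytest.raises(InvalidSequenceError):
            rhythm_ratios(np.array([100.0]))


class TestKdeDensity:
    def test_uniform_sample_flat(self, rng):
        dens = kde_density(rng.uniform(size=20_000), np.linspace(0.1, 0.9, 33))
        np.testing.assert_allclose(dens, 1.0, atol=0.1)

    def test_bimodal_modes_recovered(self, rng):
        sample = np.concatenate(
            [rng.normal(1 / 3, 0.02, 3000), rng.normal(2 / 3, 0.02, 3000)]
        )
        grid = np.linspace(0, 1, 512)
        dens = kde_density(sample, grid)
        lo = grid[np.argmax(dens * (grid < 0.5))]
        hi = grid[np.argmax(dens * (grid > 0.5))]
        assert lo == pytest.approx(1 / 3, abs=0.03)
        assert hi == pytest.approx(2 / 3, abs=0.03)

    def test_integrates_to_one(self, rng):
        grid = np.linspace(-0.5, 1.5, 2001)
        dens = kde_density(rng.uniform(size=5000), grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.02)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            kde_density(np.full(100, 0.5))


class TestIntegerRatioBins:
    def test_default_targets(self):
        bins = build_bins()
        np.testing.assert_allclose(bins.targets, DEFAULT_TARGETS)

    def test_midpoint_boundary_and_central_half(self):
        bins = build_bins((0.5, 0.6))
        i = bins.targets.index(0.5)
        assert bins.segments[i][1] == pytest.approx(0.55)   # midpoint boundary
        assert bins.on_bins[i][1] == pytest.approx(0.525)   # central half
        assert bins.on_bins[i][0] == pytest.approx(0.475)   # mirrored outer side

    def test_bins_disjoint_ordered_and_tiling(self):
        bins = build_bins()
        for (lo_s, hi_s), (lo_o, hi_o) in zip(bins.segments, bins.on_bins):
            assert lo_s < lo_o < hi_o < hi_s
        for left, right in zip(bins.segments[:-1], bins.segments[1:]):
            assert left[1] == pytest.approx(right[0])  # segments tile without overlap

    def test_inverse_ratios_kept_separate(self):
        bins = build_bins()
        i12 = bins.targets.index(1.0 / 3.0)
        i21 = bins.targets.index(2.0 / 3.0)
        assert bins.segments[i12][1] < bins.segments[i21][0]

    def test_needs_two_targets(self):
        with pytest.raises(InvalidParameterError):
            build_bins((0.5,))


class TestOnIntegerFraction:
    def test_all_on_target_scores_one(self):
        r = np.full(500, 0.5)
        assert on_integer_fraction(r, 0.5) == pytest.approx(1.0)

    def test_uniform_scores_half(self, rng):
        # inverse-width weighting makes a flat density score 0.5 in every bin
        r = rng.uniform(size=200_000)
        for target in DEFAULT_TARGETS:
            assert on_integer_fraction(r, target) == pytest.approx(0.5, abs=0.05)

    def test_isochronous_sequence_scores_one_at_unison(self):
        seq = generate_isochronous(4.0, 200)
        r = rhythm_ratios(intervals(seq))
        assert on_integer_fraction(r, 0.5) == pytest.approx(1.0)

    def test_undefined_when_bins_empty(self):
        r = np.full(100, 0.95)  # outside every bin of the 3:1 category
        assert np.isnan(on_integer_fraction(r, 0.75))

    def test_unknown_target_rejected(self):
        with pytest.raises(InvalidParameterError):
            on_integer_fraction(np.array([0.5]), 0.47)

    def test_time_unit_invariance(self, rng):
        times = np.cumsum(rng.exponential(10.0, size=2000))
        for scale in (1.0, 1000.0):
            r = rhythm_ratios(intervals(times * scale))
            frac = on_integer_fraction(r, 0.5)
        assert frac == on_integer_fraction(rhythm_ratios(intervals(times)), 0.5)


class TestDifferentialEntropy:
    def test_uniform_near_zero(self, rng):
        est = differential_entropy(rng.uniform(size=10_000))
        assert abs(est) < 0.05

    def test_scaled_uniform_matches_log_width(self, rng):
        # closed form: H(Uniform(0, c)) = ln c
        est = differential_entropy(rng.uniform(0.0, 0.5, size=10_000))
        assert est == pytest.approx(np.log(0.5), abs=0.05)

    def test_degenerate_sample_minus_infinity(self):
        assert differential_entropy(np.full(200, 0.5)) == -np.inf

    def test_isochronous_sequence_minus_infinity(self):
        seq = generate_isochronous(11.0, 300, start=3.0)
        assert differential_entropy(rhythm_ratios(intervals(seq))) == -np.inf

    def test_too_few_ratios_rejected(self):
        with pytest.raises(InvalidSequenceError):
            differential_entropy(np.linspace(0.1, 0.9, 9))

    def test_concentration_lowers_entropy(self, rng):
        # mean-preserving concentration: tighter samples score lower
        wide = rng.uniform(size=5000)
        for width in (0.5, 0.1, 0.02):
            narrow = 0.5 + width * (rng.uniform(size=5000) - 0.5)
            assert differential_entropy(narrow) < differential_entropy(wide)

    def test_never_exceeds_uniform_bound(self, rng):
        # uniform maximizes entropy on (0,1); allow 3 SEs of estimator noise
        for seed in range(5):
            r = np.random.default_rng(seed).uniform(size=2000)
            assert differential_entropy(r) < 0.0 + 3 * 0.05


class TestSequenceMetrics:
    def test_poisson_summary_row(self):
        seq = generate_poisson(5.0, 5000, seed=3)
        row = sequence_metrics(seq)
        assert row["n_intervals"] == 5000
        assert abs(row["entropy"]) < 0.1
        for key in ("frac_1_3", "frac_1_2", "frac_2_3", "frac_1_1",
                    "frac_3_2", "frac_2_1", "frac_3_1"):
            assert row[key] == pytest.approx(0.5, abs=0.15)
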