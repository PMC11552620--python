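import numpy as np
import pytest

from polykmer import (
    EstimationError,
    FitComponent,
    FitConfig,
    KmerHistogram,
    detect_error_cutoff,
    estimate_genome_size,
    estimate_initial_chet,
    expected_G_oracle,
    fill_missing,
    fit_component,
    region_size,
    repeat_size,
    scale_counts,
    simulate_histogram,
    subtract_component,
    unscale_counts,
    MixtureSpec,
)

NO_SMOOTH = FitConfig(smoothing_window=1)


def _hist(freqs, start=1):
    freqs = np.asarray(freqs, dtype=float)
    return KmerHistogram(np.arange(start, start + freqs.size), freqs)


class TestErrorCutoff:
    def test_first_valley_between_error_spike_and_peak(self):
        hist = _hist([10000, 2000, 400, 120, 300, 900, 1200])
        assert detect_error_cutoff(hist, NO_SMOOTH) == 4

    def test_monotone_spectrum_returns_one_with_warning(self):
        hist = _hist([10, 20, 30, 40, 50, 60])
        with pytest.warns(UserWarning, match="no error peak"):
            assert detect_error_cutoff(hist, NO_SMOOTH) == 1

    def test_sparse_spikes_keep_all_signal(self, delta_histogram):
        # zero-padded spectrum: the flat stretch before the first peak is the
        # valley, so neither signal spike may be excluded
        cutoff = detect_error_cutoff(delta_histogram.dense(), FitConfig())
        assert 1 < cutoff <= 25

    def test_too_short_histogram_rejected(self):
        with pytest.raises(EstimationError):
            detect_error_cutoff(_hist([1, 2]), NO_SMOOTH)


class TestInitialChet:
    def test_windowed_argmax_finds_first_peak(self, delta_histogram):
        dense = delta_histogram.dense()
        assert estimate_initial_chet(dense, C=60, error_cutoff=2, config=NO_SMOOTH) == 25

    def test_homozygous_spectrum_falls_back_to_peak_division(self):
        # fully homozygous diploid: single peak at 50, nothing near 25
        freqs = np.zeros(60)
        freqs[49] = 8e5
        hist = _hist(freqs)
        with pytest.warns(UserWarning, match="homozygous-like"):
            est = estimate_initial_chet(hist, C=60, error_cutoff=2, config=NO_SMOOTH)
        assert est == pytest.approx(25.0)

    def test_poisson_mixture_estimate_close_to_truth(self):
        spec = MixtureSpec(
            p=2, c_het=30, distinct_kmers=(100_000, 100_000), seed=11
        )
        hist, _ = simulate_histogram(spec)
        est = estimate_initial_chet(hist.dense(), C=75, error_cutoff=2, config=FitConfig())
        assert abs(est - 30) <= 2

    def test_empty_interval_is_an_error(self):
        hist = _hist([100, 50, 10])
        with pytest.raises(EstimationError, match="re-check"):
            estimate_initial_chet(hist, C=300, error_cutoff=1, config=NO_SMOOTH)


class TestScaleFill:
    def test_max_normalization_within_window(self):
        hist = KmerHistogram(np.array([48, 50, 52]), np.array([100.0, 400.0, 200.0]))
        scaled, factor = scale_counts(hist, (48, 52))
        assert factor == 400
        assert scaled.frequencies.tolist() == [0.25, 1.0, 0.5]

    def test_single_bin_window(self):
        hist = KmerHistogram(np.array([50]), np.array([7.0]))
        scaled, factor = scale_counts(hist, (49, 51))
        assert factor == 7 and scaled.frequencies[0] == 1.0

    def test_scale_unscale_is_identity(self):
        rng = np.random.default_rng(1)
        hist = _hist(rng.uniform(0.5, 1e6, size=30))
        scaled, factor = scale_counts(hist, (10, 20))
        back = unscale_counts(scaled, (10, 20), factor)
        np.testing.assert_allclose(back.frequencies, hist.frequencies, rtol=1e-15)

    def test_all_zero_window_is_an_error(self):
        hist = _hist([0, 0, 0, 5])
        with pytest.raises(EstimationError):
            scale_counts(hist, (1, 3))

    @pytest.mark.parametrize(
        "present, window, expected",
        [
            ([(10, 100), (12, 300)], (10, 12), [(11, 200.0)]),
            ([(10, 100), (14, 500)], (10, 14), [(11, 200.0), (12, 300.0), (13, 400.0)]),
        ],
    )
    def test_linear_interpolation_of_missing_bins(self, present, window, expected):
        cov, freq = zip(*present)
        hist = KmerHistogram(np.array(cov), np.array(freq, dtype=float))
        filled = fill_missing(hist, window)
        for c, f in expected:
            idx = np.searchsorted(filled.coverages, c)
            assert filled.coverages[idx] == c
            assert filled.frequencies[idx] == pytest.approx(f)

    def test_fill_is_identity_on_gapless_window(self):
        hist = _hist([5.0, 6.0, 7.0, 8.0], start=10)
        filled = fill_missing(hist, (10, 13))
        np.testing.assert_array_equal(filled.coverages, hist.coverages)
        np.testing.assert_array_equal(filled.frequencies, hist.frequencies)

    def test_fill_needs_two_present_bins(self):
        hist = KmerHistogram(np.array([10]), np.array([5.0]))
        with pytest.raises(EstimationError):
            fill_missing(hist, (9, 11))


class TestFitComponent:
    def test_exact_gaussian_recovered(self):
        grid = np.arange(1, 101, dtype=float)
        a, mu, sigma = 1234.0, 50.0, 3.0
        freqs = a * np.exp(-0.5 * ((grid - mu) / sigma) ** 2)
        comp = fit_component(_hist(freqs), i=2, C_het=25, config=FitConfig())
        assert comp.converged
        assert comp.mean == pytest.approx(mu, rel=1e-6)
        assert comp.sd == pytest.approx(sigma, rel=1e-6)
        assert comp.amplitude == pytest.approx(a, rel=1e-6)

    def test_all_zero_window_yields_flat_component(self):
        comp = fit_component(_hist(np.zeros(100)), i=2, C_het=25)
        assert not comp.converged
        assert comp.amplitude == 0
        assert not comp.fitted_curve.any()

    def test_poisson_peak_mean_recovered_within_one(self):
        rng = np.random.default_rng(5)
        draws = rng.poisson(50, size=100_000)
        freqs = np.bincount(draws, minlength=120)[1:120]
        comp = fit_component(_hist(freqs.astype(float)), i=2, C_het=25)
        assert abs(comp.mean - 50) <= 1

    def test_curve_is_nonnegative_everywhere(self):
        rng = np.random.default_rng(6)
        comp = fit_component(_hist(rng.uniform(0, 100, 80)), i=1, C_het=40)
        assert (comp.fitted_curve >= 0).all()


class TestSubtract:
    def test_exact_cancellation(self):
        freqs = np.linspace(1, 10, 20)
        hist = _hist(freqs)
        comp = FitComponent(1, 10.0, 2.0, 1.0, freqs.copy(), True, (5, 15))
        out, loss = subtract_component(hist, comp)
        assert not out.frequencies.any()
        assert loss == 0

    def test_zero_curve_leaves_residual_unchanged(self):
        hist = _hist([3.0, 4.0, 5.0])
        comp = FitComponent(1, 2.0, 1.0, 0.0, np.zeros(3), False, (1, 3))
        out, loss = subtract_component(hist, comp)
        np.testing.assert_array_equal(out.frequencies, hist.frequencies)
        assert loss == 0

    def test_oversubtraction_floors_at_zero_and_records_loss(self):
        hist = KmerHistogram(np.array([4]), np.array([5.0]))
        comp = FitComponent(1, 4.0, 1.0, 7.0, np.array([7.0]), True, (3, 5))
        out, loss = subtract_component(hist, comp)
        assert out.frequencies[0] == 0
        assert loss == pytest.approx(4 * 2.0)  # instances, not frequency

    def test_grid_mismatch_is_an_error(self):
        hist = _hist([1.0, 2.0])
        comp = FitComponent(1, 1.0, 1.0, 1.0, np.zeros(3), True, (1, 3))
        with pytest.raises(EstimationError):
            subtract_component(hist, comp)


class TestSizes:
    def test_delta_component_algebra(self):
        # a spike of N k-mers at coverage i*C_het contributes N*i/p bases
        curve = np.zeros(100)
        curve[49] = 8e5  # coverage 50 = 2 * 25
        comp = FitComponent(2, 50.0, 1.0, 8e5, curve, True, (37.5, 62.5))
        assert region_size(comp, p=2, C_het=25) == pytest.approx(8e5)

    def test_flat_component_has_zero_size(self):
        comp = FitComponent(1, 25.0, 1.0, 0.0, np.zeros(50), False, (12.5, 37.5))
        assert region_size(comp, p=2, C_het=25) == 0

    def test_gaussian_component_mass_matches_quadrature(self):
        # unit-area Gaussian of N distinct k-mers at mu: sum(c*f) ~ N*mu
        grid = np.arange(1, 201, dtype=float)
        n, mu, sigma = 1e6, 50.0, 3.0
        curve = n / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((grid - mu) / sigma) ** 2)
        comp = FitComponent(2, mu, sigma, curve.max(), curve, True, (37.5, 62.5))
        assert region_size(comp, p=2, C_het=25) == pytest.approx(1e6, rel=5e-3)

    def test_repeat_size_of_zero_residual(self):
        assert repeat_size(_hist(np.zeros(10)), 2, 25, 1) == 0

    def test_repeat_size_single_bin(self):
        hist = KmerHistogram(np.array([500]), np.array([1000.0]))
        assert repeat_size(hist, 2, 25, 1) == pytest.approx(1e4)

    def test_above_last_window_policy_ignores_mid_spectrum_residual(self):
        freqs = np.zeros(400)
        freqs[59] = 100.0   # inside the fitted range for p=2, C_het=25
        freqs[299] = 100.0  # beyond the last window
        hist = _hist(freqs)
        cfg = FitConfig(repeat_min_coverage_policy="above_last_window")
        got = repeat_size(hist, 2, 25, 1, cfg)
        assert got == pytest.approx(100 * 300 / 50)


class TestEstimateGenomeSize:
    def test_delta_spectrum_closed_form(self, delta_histogram):
        report = estimate_genome_size(delta_histogram, p=2, C=60)
        assert report.c_het == pytest.approx(25, rel=1e-3)
        assert report.region_sizes[0] == pytest.approx(2e5, rel=1e-3)
        assert report.region_sizes[1] == pytest.approx(8e5, rel=1e-3)
        assert report.repeat_size == pytest.approx(0, abs=1e3)
        assert report.genome_size == pytest.approx(1e6, rel=1e-3)
        assert report.full_size == pytest.approx(2e6, rel=1e-3)

    def test_haploid_single_peak(self):
        # for p=1 the first-peak bracket degenerates: the only peak IS C_het
        freqs = np.zeros(80)
        freqs[49] = 1e6
        report = estimate_genome_size(_hist(freqs), p=1, C=75)
        assert report.c_het == pytest.approx(50, rel=1e-3)
        assert report.genome_size == pytest.approx(1e6, rel=1e-3)

    def test_poisson_tetraploid_recovers_oracle(self):
        spec = MixtureSpec(
            p=4,
            c_het=25,
            distinct_kmers=(200_000, 100_000, 100_000, 600_000),
            repeat_kmers=50_000,
            repeat_multiplier=12,
            seed=42,
        )
        hist, truth = simulate_histogram(spec)
        report = estimate_genome_size(hist, p=4, C=2.5 * 25)
        assert report.c_het == pytest.approx(25, rel=0.02)
        assert report.genome_size == pytest.approx(expected_G_oracle(spec), rel=0.05)

    def test_report_sums_are_exact_by_construction(self):
        spec = MixtureSpec(p=2, c_het=30, distinct_kmers=(150_000, 300_000), seed=9)
        hist, _ = simulate_histogram(spec)
        report = estimate_genome_size(hist, p=2, C=75)
        assert report.genome_size == sum(report.region_sizes) + report.repeat_size
        assert report.full_size == report.genome_size * report.ploidy
        assert all(g >= 0 for g in report.region_sizes)

    def test_instance_conservation(self):
        spec = MixtureSpec(
            p=4, c_het=30, distinct_kmers=(150_000, 100_000, 50_000, 400_000), seed=13
        )
        hist, _ = simulate_histogram(spec)
        report = estimate_genome_size(hist, p=4, C=75)
        fitted = sum(c.instances for c in report.components)
        lhs = fitted + report.residual_instances
        rhs = report.observed_instances + report.floored_loss
        assert lhs == pytest.approx(rhs, rel=1e-9)
        assert report.floored_loss <= 0.01 * report.observed_instances

    def test_homozygous_spectrum_warns_and_matches_closed_form(self):
        freqs = np.zeros(80)
        freqs[49] = 1e6  # all k-mers shared by both homologs
        report = estimate_genome_size(_hist(freqs), p=2, C=60)
        assert any("homozygous" in w for w in report.warnings)
        closed_form = 50 * 1e6 / (2 * report.c_het)
        assert report.genome_size == pytest.approx(closed_form, rel=0.05)

    def test_aggregate_bin_excluded_by_default(self):
        freqs = np.zeros(100)
        freqs[24] = 4e5
        freqs[49] = 8e5
        freqs[99] = 1e8  # counter ceiling artifact
        hist = KmerHistogram(np.arange(1, 101), freqs, aggregate_last_bin=True)
        report = estimate_genome_size(hist, p=2, C=60)
        assert report.genome_size == pytest.approx(1e6, rel=1e-2)

    def test_invalid_ploidy_rejected(self, delta_histogram):
        with pytest.raises(ValueError):
            estimate_genome_size(delta_histogram, p=0, C=60)
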