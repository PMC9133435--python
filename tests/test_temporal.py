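"""Energy/median-frequency time-courses, trends and the energy crossover."""

import numpy as np
import pytest

from semgspec import decompose, spectral, synthetic, temporal
from semgspec.containers import SpectraMatrix
from semgspec.exceptions import InvalidInputError

GRID = spectral.band_grid()


def default_contributions(seed=7, n=2):
    truth = synthetic.make_ground_truth(seed=seed)
    syn = synthetic.synthesize_spectra(truth)
    cs = decompose.nmf(spectral.smooth_matrix(syn.matrix, 5), n, seed=seed)
    filters = decompose.contribution_filters(cs)
    return syn, decompose.extract_contributions(syn.matrix, filters)


class TestEnergyTimecourse:
    def test_even_split_halves_the_total(self):
        freqs = np.array([8.0, 9.0, 10.0])
        raw = SpectraMatrix(
            np.arange(1.0, 7.0).reshape(2, 3), [(0, "ch05"), (1, "ch05")], freqs
        )
        ff = np.full((2, 2, 3), 0.5)
        filters = decompose.ContributionFilters(
            ff, ff, freqs, ["low", "high"], raw.row_index
        )
        contrib = decompose.extract_contributions(raw, filters)
        tc = temporal.energy_timecourse(contrib)["ch05"]
        assert np.allclose(tc.components[0], tc.components[1])
        assert np.allclose(tc.components[0], tc.total / 2)

    def test_zero_spectra_give_zero_curves(self):
        freqs = np.array([8.0, 9.0])
        raw = SpectraMatrix(np.zeros((2, 2)), [(0, "ch05"), (1, "ch05")], freqs)
        cs = decompose.ComponentSet(
            np.zeros((2, 2)), np.eye(2), 2, freqs, 0.0, ["low", "high"], raw.row_index
        )
        contrib = decompose.extract_contributions(
            raw, decompose.contribution_filters(cs)
        )
        tc = temporal.energy_timecourse(contrib)["ch05"]
        assert np.all(tc.total == 0.0) and np.all(tc.components == 0.0)

    def test_energy_conservation_total_equals_component_sum(self):
        syn, contrib = default_contributions()
        for tc in temporal.energy_timecourse(contrib).values():
            assert np.allclose(tc.total, tc.components.sum(axis=0), rtol=1e-8)

    def test_component_trends_follow_generator_envelopes(self):
        syn, contrib = default_contributions()
        agg = temporal.aggregate(
            list(temporal.energy_timecourse(contrib).values()), "trial"
        )
        low = agg.component("low")
        # low-frequency energy rises: late-trial mean well above early mean
        assert low[-10:].mean() > 2.0 * low[:10].mean()
        high = agg.component("high")
        # high-frequency energy decays after its early peak
        assert high[-6:].mean() < high[:20].max()


class TestAggregate:
    def _tc(self, total, components, times=None):
        times = np.arange(len(total)) * 0.5 if times is None else times
        return temporal.EnergyTimecourse(
            times, np.asarray(total, float), np.asarray(components, float), ["low", "high"]
        )

    def test_identical_curves_aggregate_to_themselves(self):
        tc = self._tc([1.0, 2.0, 3.0], [[0.5, 1.0, 1.5], [0.5, 1.0, 1.5]])
        agg = temporal.aggregate([tc, tc, tc])
        assert np.allclose(agg.total, tc.total)
        assert np.allclose(agg.total_sd, 0.0)

    def test_mean_and_sample_sd(self):
        a = self._tc([0.0, 0.0], [[0.0, 0.0], [0.0, 0.0]])
        b = self._tc([2.0, 2.0], [[1.0, 1.0], [1.0, 1.0]])
        agg = temporal.aggregate([a, b])
        assert np.allclose(agg.total, 1.0)
        assert np.allclose(agg.total_sd, np.sqrt(2.0))

    def test_grand_mean_equals_mean_of_equal_sized_groups(self, rng):
        tcs = [
            self._tc(rng.random(4), rng.random((2, 4))) for _ in range(12)
        ]
        direct = temporal.aggregate(tcs, "grand")
        halves = [temporal.aggregate(tcs[:6]), temporal.aggregate(tcs[6:])]
        nested = temporal.aggregate(halves, "grand")
        assert np.allclose(direct.total, nested.total)

    def test_misaligned_grids_rejected(self):
        a = self._tc([1.0, 2.0], [[1.0, 2.0], [0.0, 0.0]])
        b = self._tc([1.0, 2.0], [[1.0, 2.0], [0.0, 0.0]], times=np.array([0.0, 1.0]))
        with pytest.raises(InvalidInputError):
            temporal.aggregate([a, b])


class TestFitTrend:
    def test_exact_parabola_recovered(self):
        t = np.arange(60) * 0.5
        fit = temporal.polynomial_trend(t, 2.0 * t**2 - t + 3.0)
        assert np.allclose(fit.coefficients, [2.0, -1.0, 3.0], atol=1e-8)
        assert fit.rss == pytest.approx(0.0, abs=1e-8)

    def test_constant_series(self):
        t = np.arange(10) * 0.5
        fit = temporal.polynomial_trend(t, np.full(10, 5.0))
        assert np.allclose(fit.coefficients, [0.0, 0.0, 5.0], atol=1e-8)

    def test_noisy_ramp_has_no_spurious_curvature(self, rng):
        t = np.arange(120) * 0.5
        y = 0.7 * t + rng.standard_normal(120) * 0.3
        fit = temporal.polynomial_trend(t, y)
        # standard error of the quadratic coefficient from the normal equations
        X = np.vander(t, 3)
        resid_var = fit.rss / (len(t) - 3)
        cov = resid_var * np.linalg.inv(X.T @ X)
        assert abs(fit.coefficients[0]) < 2.0 * np.sqrt(cov[0, 0])

    def test_matches_normal_equations_oracle(self, rng):
        t = np.arange(40) * 0.5
        y = rng.random(40)
        fit = temporal.polynomial_trend(t, y)
        X = np.vander(t, 3)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coefficients, oracle, atol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            temporal.polynomial_trend(np.array([0.0, 1.0]), np.array([1.0, 2.0]))


class TestCrossoverTime:
    def test_no_crossing_returns_none(self):
        t = np.arange(10) * 0.5
        assert temporal.crossover_time(t, np.zeros(10), np.ones(10)) is None

    def test_identical_curves_cross_at_start(self):
        t = np.arange(10) * 0.5
        assert temporal.crossover_time(t, np.ones(10), np.ones(10)) == 0.0

    def test_flicker_does_not_count_as_crossing(self):
        t = np.arange(8) * 0.5
        low = np.array([0.0, 2.0, 0.0, 0.0, 2.0, 2.0, 2.0, 2.0])
        high = np.ones(8)
        assert temporal.crossover_time(t, low, high) == 2.0

    def test_generator_crossover_recovered_from_true_energy_curves(self):
        # jitter-free truth: energy curves are exactly weight x template area
        truth = synthetic.make_ground_truth(
            seed=3, weight_jitter_cv=0.0, modulation_sd=0.0, noise_sd=0.0
        )
        areas = [spectral.energy(t.as_spectrum()) for t in truth.templates]
        w = truth.envelopes.weights
        xo = temporal.crossover_time(
            truth.envelopes.time_grid, w[:, 0] * areas[0], w[:, 1] * areas[1]
        )
        assert xo == pytest.approx(22.0, abs=0.5)


class TestMedfreqTimecourse:
    def test_stationary_mixture_medians_are_stable(self, noisefree_spectra):
        # noise-free mixture: each component contribution keeps a constant
        # spectral shape, so its median frequency stays within +-2 Hz
        syn = noisefree_spectra
        cs = decompose.nmf(spectral.smooth_matrix(syn.matrix, 5), 2, seed=1)
        contrib = decompose.extract_contributions(
            syn.matrix, decompose.contribution_filters(cs)
        )
        mf = temporal.medfreq_timecourse(contrib, syn.matrix)
        for channel_mf in mf.values():
            for comp in channel_mf.components:
                assert np.nanmax(comp) - np.nanmin(comp) <= 4.0

    def test_total_median_between_component_medians(self):
        syn, contrib = default_contributions()
        mf = temporal.medfreq_timecourse(contrib, syn.matrix)
        for channel_mf in mf.values():
            low, high = channel_mf.components
            ok = (channel_mf.total >= low - 1e-9) & (channel_mf.total <= high + 1e-9)
            assert np.all(ok[~np.isnan(channel_mf.total)])

    def test_single_component_signal_total_equals_component_median(self):
        truth = synthetic.make_ground_truth(seed=5, weight_jitter_cv=0.0, noise_sd=0.0)
        env = truth.envelopes
        env.weights[:, 1] = 0.0  # silence the high component
        syn = synthetic.synthesize_spectra(truth)
        cs = decompose.ComponentSet(
            syn.w_true, syn.h_true, 2, syn.matrix.frequencies, 100.0,
            ["low", "high"], syn.matrix.row_index,
        )
        contrib = decompose.extract_contributions(
            syn.matrix, decompose.contribution_filters(cs)
        )
        mf = temporal.medfreq_timecourse(contrib, syn.matrix)
        for channel_mf in mf.values():
            assert np.all(np.abs(channel_mf.total - channel_mf.components[0]) <= 1.0)


def test_low_component_trend_rises_across_seeds():
    """The fitted linear coefficient of the low-frequency energy trend is
    positive on nearly all seeded trials (the low component keeps rising)."""
    hits = 0
    n_runs = 20
    for seed in range(n_runs):
        syn, contrib = default_contributions(seed=300 + seed)
        agg = temporal.aggregate(
            list(temporal.energy_timecourse(contrib).values()), "trial"
        )
        fit = temporal.fit_trend(agg, "low")
        if fit.coefficients[1] > 0:
            hits += 1
    assert hits / n_runs >= 0.9
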