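"""Factorization, VAF rank selection, contribution filters and extraction."""

import numpy as np
import pytest

from semgspec import decompose, spectral, synthetic
from semgspec.containers import SpectraMatrix
from semgspec.exceptions import (
    InvalidInputError,
    InvalidParameterError,
    NoRankFoundError,
    UndefinedVafError,
)

GRID = spectral.band_grid()


def matrix_from(values):
    values = np.asarray(values, dtype=float)
    rows = [(i, "ch05") for i in range(values.shape[0])]
    freqs = np.arange(8.0, 8.0 + values.shape[1])
    return SpectraMatrix(values, rows, freqs)


class TestVaf:
    def test_perfect_reconstruction(self, rng):
        m = rng.random((5, 7))
        assert decompose.vaf(m, m) == pytest.approx(100.0)

    def test_zero_reconstruction(self, rng):
        m = rng.random((5, 7))
        assert decompose.vaf(m, np.zeros_like(m)) == pytest.approx(0.0)

    def test_worked_example(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0]])
        m_hat = np.array([[1.0, 2.0], [3.0, 0.0]])
        assert decompose.vaf(m, m_hat) == pytest.approx((1 - 16 / 30) * 100, abs=0.01)

    def test_zero_reference_rejected(self):
        with pytest.raises(UndefinedVafError):
            decompose.vaf(np.zeros((2, 2)), np.ones((2, 2)))


class TestNmf:
    def test_exact_rank_one_factorization(self, rng):
        w = rng.random(30) + 0.5
        h = rng.random(40) + 0.5
        cs = decompose.nmf(matrix_from(np.outer(w, h)), 1, seed=0)
        assert cs.vaf_percent >= 99.9

    def test_noise_free_two_template_recovery(self, noisefree_spectra):
        cs = decompose.nmf(noisefree_spectra.matrix, 2, seed=0)
        for i in range(2):
            a, b = cs.H[i], noisefree_spectra.h_true[i]
            cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos >= 0.99

    def test_fixed_seed_is_bit_deterministic(self, default_spectra):
        a = decompose.nmf(default_spectra.matrix, 2, seed=5)
        b = decompose.nmf(default_spectra.matrix, 2, seed=5)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.H, b.H)

    def test_h_rows_unit_maximum_and_ordered(self, default_spectra):
        cs = decompose.nmf(default_spectra.matrix, 2, seed=0)
        assert np.allclose(cs.H.max(axis=1), 1.0)
        med = [
            spectral.median_frequency(cs.component_spectrum(i)) for i in range(2)
        ]
        assert med[0] < med[1]
        assert cs.labels == ["low", "high"]

    def test_negative_matrix_rejected(self):
        m = matrix_from(np.ones((3, 4)))
        m.values[0, 0] = -1.0  # bypasses construction-time validation
        with pytest.raises(InvalidInputError):
            decompose.nmf(m, 1)

    def test_rank_out_of_range_rejected(self, default_spectra):
        with pytest.raises(InvalidParameterError):
            decompose.nmf(default_spectra.matrix, 0)

    def test_vaf_monotone_in_rank(self, default_spectra):
        sm = spectral.smooth_matrix(default_spectra.matrix, 5)
        vafs = [decompose.nmf(sm, n, seed=0).vaf_percent for n in range(1, 5)]
        assert all(b >= a - 1e-9 for a, b in zip(vafs, vafs[1:]))


class TestSelectNComponents:
    def test_exact_rank_one_selects_one(self, rng):
        w = rng.random(20) + 0.5
        h = rng.random(30) + 0.5
        sel = decompose.select_n_components(matrix_from(np.outer(w, h)), seed=0)
        assert sel.n == 1

    def test_impossible_threshold_raises_with_curve(self, rng):
        m = matrix_from(rng.random((6, 8)))
        with pytest.raises(NoRankFoundError) as err:
            decompose.select_n_components(m, vaf_threshold=101.0, n_max=3, seed=0)
        assert set(err.value.vaf_curve) == {1, 2, 3}

    def test_reports_vaf_curve_up_to_selection(self, noisefree_spectra):
        sel = decompose.select_n_components(noisefree_spectra.matrix, seed=0)
        assert min(sel.vaf_curve) == 1
        assert sel.vaf_curve[sel.n] > 80.0


class TestContributionFilters:
    def test_single_component_filter_is_unity(self, rng):
        w = rng.random(10) + 0.5
        h = rng.random(12) + 0.5
        cs = decompose.nmf(matrix_from(np.outer(w, h)), 1, seed=0)
        filters = decompose.contribution_filters(cs)
        assert np.allclose(filters.FF, 1.0)

    def test_worked_two_component_example(self):
        cs = decompose.ComponentSet(
            W=np.array([[2.0, 1.0]]),
            H=np.array([[1.0, 0.5], [0.5, 1.0]]),
            n=2,
            frequencies=np.array([8.0, 9.0]),
            vaf_percent=100.0,
            labels=["low", "high"],
            row_index=[(0, "ch05")],
        )
        filters = decompose.contribution_filters(cs)
        assert np.allclose(filters.FF[0, 0], [0.8, 0.5])
        assert np.allclose(filters.FF[0, 1], [0.2, 0.5])

    def test_zero_denominator_falls_back_to_even_split(self):
        cs = decompose.ComponentSet(
            W=np.array([[0.0, 0.0]]),
            H=np.array([[1.0, 0.0], [0.0, 1.0]]),
            n=2,
            frequencies=np.array([8.0, 9.0]),
            vaf_percent=0.0,
            labels=["low", "high"],
            row_index=[(0, "ch05")],
        )
        filters = decompose.contribution_filters(cs)
        assert np.allclose(filters.FF, 0.5)

    def test_filters_sum_to_one_everywhere(self, default_spectra):
        cs = decompose.nmf(default_spectra.matrix, 2, seed=1)
        filters = decompose.contribution_filters(cs)
        assert np.allclose(filters.FF.sum(axis=1), 1.0, atol=1e-12)

    def test_scale_ambiguity_invariance(self, default_spectra):
        cs = decompose.nmf(default_spectra.matrix, 2, seed=1)
        scaled = decompose.ComponentSet(
            W=cs.W * np.array([3.0, 0.25]),
            H=cs.H / np.array([[3.0], [0.25]]),
            n=2,
            frequencies=cs.frequencies,
            vaf_percent=cs.vaf_percent,
            labels=cs.labels,
            row_index=cs.row_index,
        )
        a = decompose.contribution_filters(cs).FF
        b = decompose.contribution_filters(scaled).FF
        assert np.allclose(a, b, atol=1e-12)


class TestExtractContributions:
    def _filters(self, ff_rows, freqs):
        ff = np.asarray(ff_rows, float)
        return decompose.ContributionFilters(
            FF=ff,
            FC=ff,
            frequencies=freqs,
            labels=["low", "high"],
            row_index=[(i, "ch05") for i in range(ff.shape[0])],
        )

    def test_degenerate_filter_passes_everything_to_one_component(self):
        freqs = np.array([8.0, 9.0])
        raw = SpectraMatrix([[4.0, 2.0]], [(0, "ch05")], freqs)
        filters = self._filters([[[1.0, 1.0], [0.0, 0.0]]], freqs)
        out = decompose.extract_contributions(raw, filters)
        assert np.allclose(out.values[0, 0], [4.0, 2.0])
        assert np.allclose(out.values[0, 1], 0.0)

    def test_even_split(self):
        freqs = np.array([8.0, 9.0])
        raw = SpectraMatrix([[4.0, 2.0]], [(0, "ch05")], freqs)
        filters = self._filters([[[0.5, 0.5], [0.5, 0.5]]], freqs)
        out = decompose.extract_contributions(raw, filters)
        assert np.allclose(out.values[0], [[2.0, 1.0], [2.0, 1.0]])

    def test_worked_filter_applied_to_raw(self):
        freqs = np.array([8.0, 9.0])
        raw = SpectraMatrix([[4.0, 2.0]], [(0, "ch05")], freqs)
        filters = self._filters([[[0.8, 0.5], [0.2, 0.5]]], freqs)
        out = decompose.extract_contributions(raw, filters)
        assert np.allclose(out.values[0, 0], [3.2, 1.0])
        assert np.allclose(out.values[0, 1], [0.8, 1.0])

    def test_grid_mismatch_rejected(self):
        raw = SpectraMatrix([[4.0, 2.0]], [(0, "ch05")], np.array([8.0, 9.0]))
        filters = self._filters([[[1.0, 1.0], [0.0, 0.0]]], np.array([10.0, 11.0]))
        with pytest.raises(InvalidInputError):
            decompose.extract_contributions(raw, filters)

    def test_conservation_on_synthetic_decomposition(self, default_spectra):
        cs = decompose.nmf(default_spectra.matrix, 2, seed=2)
        filters = decompose.contribution_filters(cs)
        out = decompose.extract_contributions(default_spectra.matrix, filters)
        total = out.values.sum(axis=1)
        scale = np.abs(default_spectra.matrix.values).max()
        assert np.allclose(total, default_spectra.matrix.values, rtol=1e-10, atol=1e-10 * scale)


class TestNormalizePair:
    def test_division_by_pair_maximum(self):
        out = decompose.normalize_pair(np.array([[2.0, 4.0], [1.0, 3.0]]))
        assert np.allclose(out, [[0.5, 1.0], [0.25, 0.75]])

    def test_idempotent_when_already_normalized(self):
        h = np.array([[0.5, 1.0], [0.25, 0.75]])
        assert np.allclose(decompose.normalize_pair(h), h)

    def test_scale_invariance(self, rng):
        h = rng.random((2, 6))
        assert np.allclose(
            decompose.normalize_pair(7.0 * h), decompose.normalize_pair(h)
        )

    def test_zero_pair_rejected(self):
        with pytest.raises(InvalidInputError):
            decompose.normalize_pair(np.zeros((2, 4)))


def test_parameter_recovery_over_seeds():
    """Mean best-permutation cosine between recovered and true component
    spectra over 20 default-noise synthetic trials stays high."""
    cosines = []
    for seed in range(20):
        truth = synthetic.make_ground_truth(seed=100 + seed)
        syn = synthetic.synthesize_spectra(truth)
        sm = spectral.smooth_matrix(syn.matrix, 5)
        cs = decompose.nmf(sm, 2, seed=seed)
        best = -np.inf
        for perm in ([0, 1], [1, 0]):
            cos = np.mean(
                [
                    cs.H[i] @ syn.h_true[p] / np.linalg.norm(cs.H[i]) / np.linalg.norm(syn.h_true[p])
                    for i, p in enumerate(perm)
                ]
            )
            best = max(best, cos)
        cosines.append(best)
    assert np.mean(cosines) >= 0.95
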