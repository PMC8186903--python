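"""Travelling-wave Fourier statistics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somatomap import (TimeSeriesMatrix, assign_digits_from_phase,
                       average_mirror_runs, cluster_filter,
                       cross_subject_f_ratio, dispersion_index,
                       fourier_analyze, make_cortex_patch, winner_take_all)
from somatomap.fourier import f_ratio_pvalues


def _ts(data, tr=2.0, **meta):
    return TimeSeriesMatrix(data=np.atleast_2d(data).T
                            if np.ndim(data) == 1 else data, tr_s=tr, meta=meta)


class TestMirrorAveraging:
    def test_constant_runs_average_to_constant(self):
        c = np.full((16, 3), 7.0)
        out = average_mirror_runs(_ts(c), _ts(c))
        assert np.allclose(out.data, 7.0)

    def test_constructed_mirror_recovers_forward_run(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((64, 4))
        # a reverse run that is the exact time-mirror of the forward run
        # delayed by 2 TRs averages back to the forward run itself
        r = np.roll(f, -2, axis=0)[::-1]
        out = average_mirror_runs(_ts(f), _ts(r), shift_trs=2)
        assert np.allclose(out.data, f)

    def test_palindromic_series_fixed_point_at_zero_shift(self):
        n = 32
        x = np.cos(2 * np.pi * (np.arange(n) + 0.5) / n)  # x[k] == x[n-1-k]
        out = average_mirror_runs(_ts(x), _ts(x), shift_trs=0)
        assert np.allclose(out.data[:, 0], x)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_mirror_runs(_ts(np.zeros((8, 2))), _ts(np.zeros((8, 3))))


class TestFourierAnalyze:
    def test_matches_brute_force_dft_on_short_series(self):
        rng = np.random.default_rng(1)
        n, n_cycles = 64, 5
        y = rng.standard_normal(n)
        fm = fourier_analyze(_ts(y), n_cycles)
        # brute-force DFT coefficient
        t = np.arange(n)
        coef = np.sum((y - y.mean()) * np.exp(-2j * np.pi * n_cycles * t / n))
        assert fm.coefficient[0] == pytest.approx(coef)
        # brute-force noise power: bins at/above 0.005 Hz minus signal+harmonics
        freqs = np.arange(n // 2 + 1) / (n * 2.0)
        bins = [k for k in range(1, n // 2 + 1)
                if freqs[k] >= 0.005 and k not in (5, 10, 15)]
        powers = [abs(np.sum((y - y.mean())
                             * np.exp(-2j * np.pi * k * t / n))) ** 2
                  for k in bins]
        assert fm.f_ratio[0] == pytest.approx(abs(coef) ** 2 / np.mean(powers))
        assert fm.n_noise_bins == len(bins)

    def test_pure_cosine_flagged_infinite_with_correct_phase(self):
        n = 40
        phi = 1.1
        y = np.cos(2 * np.pi * 4 * np.arange(n) / n - phi)
        fm = fourier_analyze(_ts(y), 4)
        assert np.isinf(fm.f_ratio[0])  # zero noise power -> flagged infinite
        assert fm.phase[0] == pytest.approx(phi)

    def test_amplitude_percent_closed_form(self):
        # peak amplitude 0.01 about baseline 1.0 -> 2.0% peak-to-peak
        n = 256
        y = 1.0 + 0.01 * np.cos(2 * np.pi * 20 * np.arange(n) / n)
        fm = fourier_analyze(_ts(y), 20)
        assert fm.amplitude_percent[0] == pytest.approx(2.0)

    def test_white_noise_f_ratio_near_one(self):
        rng = np.random.default_rng(2)
        ts = _ts(rng.standard_normal((256, 2000)))
        fm = fourier_analyze(ts, 20)
        assert 0.8 < np.nanmean(fm.f_ratio) < 1.25

    def test_supra_threshold_rate_under_pure_noise(self):
        rng = np.random.default_rng(3)
        fm = fourier_analyze(_ts(rng.standard_normal((256, 6000))), 20)
        rate = np.mean(f_ratio_pvalues(fm) < 0.01)
        assert rate == pytest.approx(0.01, abs=0.005)


class TestPhaseAssignment:
    def _map_with_phase(self, phases, **meta):
        phases = np.atleast_1d(np.asarray(phases, float))
        from somatomap.datatypes import FourierMap
        n = len(phases)
        return FourierMap(coefficient=np.exp(-1j * phases),
                          amplitude_percent=np.ones(n), phase=phases,
                          f_ratio=np.ones(n), n_cycles=20, n_noise_bins=100,
                          tr_s=2.0, meta={"cycle_s": 25.6, **meta})

    def test_first_fifth_maps_to_d1_forward_d5_reverse(self):
        # delay phase at the center of the first fifth of the cycle
        phi = 2 * np.pi * 0.1
        fm = self._map_with_phase(phi)
        assert assign_digits_from_phase(fm, "forward",
                                        hemo_lag_s=0.0).assigned_digit[0] == 1
        fm = self._map_with_phase(phi)
        assert assign_digits_from_phase(fm, "reverse",
                                        hemo_lag_s=0.0).assigned_digit[0] == 5

    def test_all_bins_forward(self):
        phases = 2 * np.pi * (np.arange(5) + 0.5) / 5
        fm = self._map_with_phase(phases)
        assign_digits_from_phase(fm, "forward", hemo_lag_s=0.0)
        assert list(fm.assigned_digit) == [1, 2, 3, 4, 5]

    def test_metadata_phase_origin_used_as_default(self):
        phi = 2 * np.pi * 0.1
        shifted = phi + 2 * np.pi * (2.56 / 25.6)
        fm = self._map_with_phase(shifted, phase_origin_s=2.56)
        assert assign_digits_from_phase(fm, "forward").assigned_digit[0] == 1


class TestCrossSubjectF:
    def test_opposite_vectors_give_zero(self):
        assert cross_subject_f_ratio([1 + 0j, -1 + 0j]) == 0.0

    def test_identical_vectors_flagged_infinite(self):
        assert np.isinf(cross_subject_f_ratio([2 + 1j, 2 + 1j, 2 + 1j]))

    def test_matches_hand_evaluation(self):
        c = np.array([1 + 2j, 2 + 1j, 0.5 + 0.5j])
        x, y = c.real, c.imag
        n = 3
        num = x.mean() ** 2 + y.mean() ** 2
        den = (np.sum((x - x.mean()) ** 2) / n
               + np.sum((y - y.mean()) ** 2) / n) / (2 * n - 2)
        assert cross_subject_f_ratio(c) == pytest.approx(num / den)

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            cross_subject_f_ratio([1 + 1j])


class TestDispersionIndex:
    def test_aligned_vectors_give_one_independent_of_amplitude(self):
        assert dispersion_index([3 + 4j, 3 + 4j]) == pytest.approx(1.0)
        assert dispersion_index([0.1 + 0j, 10 + 0j]) == pytest.approx(1.0)

    def test_opposite_vectors_give_zero(self):
        assert dispersion_index([1 + 0j, -1 + 0j]) == pytest.approx(0.0)

    def test_orthogonal_pair_hand_value(self):
        assert dispersion_index([1 + 0j, 1j]) == pytest.approx(np.sqrt(2) / 2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.complex_numbers(max_magnitude=1e6, min_magnitude=1e-3,
                                       allow_nan=False, allow_infinity=False),
                    min_size=1, max_size=12),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariant_and_bounded(self, vecs, c):
        d = dispersion_index(vecs)
        assert -1e-9 <= d <= 1 + 1e-9
        assert dispersion_index([c * v for v in vecs]) == pytest.approx(
            d, rel=1e-6)


class TestClusterFilterAndWTA:
    def test_no_supra_threshold_vertex_empty_mask(self, patch):
        from somatomap.datatypes import FourierMap
        n = patch.n_vertices
        fm = FourierMap(coefficient=np.zeros(n, complex),
                        amplitude_percent=np.zeros(n),
                        phase=np.zeros(n), f_ratio=np.ones(n),
                        n_cycles=20, n_noise_bins=100, tr_s=2.0)
        assert not cluster_filter(fm, patch).any()

    def test_small_isolated_cluster_removed_large_kept(self, patch):
        from somatomap.datatypes import FourierMap
        n = patch.n_vertices
        f = np.ones(n)
        # one isolated supra-threshold vertex (~1 mm^2) and a 5x6 block
        f[0] = 1e3
        block = [10 * r + c for r in range(4, 9) for c in range(4, 9)]
        f[block] = 1e3
        fm = FourierMap(coefficient=np.zeros(n, complex),
                        amplitude_percent=np.zeros(n), phase=np.zeros(n),
                        f_ratio=f, n_cycles=20, n_noise_bins=100, tr_s=2.0)
        mask = cluster_filter(fm, patch, p_threshold=0.01, min_area_mm2=14.0)
        assert not mask[0]
        assert mask[block].all()

    def test_winner_take_all_dominant_and_tie_rule(self):
        stats = np.array([[0.1, 0.9, 0.2, 0.2, 0.1],
                          [0.5, 0.2, 0.5, 0.2, 0.1],   # tie D1/D3 -> D1
                          [0.0, 0.3, 0.0, 0.3, 0.0]])  # tie D2/D4 -> D2
        labels = winner_take_all(stats)
        assert list(labels) == [2, 1, 2]

    def test_winner_take_all_respects_mask(self):
        stats = np.tile([0, 0, 1, 0, 0.], (4, 1))
        labels = winner_take_all(stats, mask=[True, False, True, False])
        assert list(labels) == [3, 0, 3, 0]
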