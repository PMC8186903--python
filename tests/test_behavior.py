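"""Confusion analysis, chance model, G-test, SDT, 2PD thresholds."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, power_divergence

from somatomap import (BehavioralTrialTable, ConfusionMatrix, chance_expected,
                       confusion_from_trials, g_test, holm_bonferroni,
                       mislocalization_percentages, neighbor_counts,
                       sdt_measures, simulate_2pd, simulate_mislocalization,
                       two_pd_threshold, two_pd_threshold_runs)
from somatomap.behavior import NEIGHBOR_WEIGHTS


def _trials(pairs):
    rows = [(s, r, i) for i, (s, r) in enumerate(pairs)]
    df = pd.DataFrame(rows, columns=["stimulated_digit", "reported_digit",
                                     "trial"])
    return BehavioralTrialTable(trials=df, n_trials_per_digit=1)


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        t = _trials([(d, d) for d in range(1, 6) for _ in range(20)])
        conf = confusion_from_trials(t)
        assert np.allclose(conf.counts, np.eye(5) * 20)
        assert conf.n_mislocalizations == 0
        assert np.allclose(conf.hit_rate, 1.0)

    def test_one_error_per_digit_hit_rate(self):
        pairs = [(d, d) for d in range(1, 6) for _ in range(19)]
        pairs += [(d, d % 5 + 1) for d in range(1, 6)]
        conf = confusion_from_trials(_trials(pairs))
        assert np.allclose(conf.hit_rate, 0.95)

    def test_row_sums_conserve_trials(self):
        t = simulate_mislocalization(np.full((5, 5), 0.2), 20, seed=0)
        conf = confusion_from_trials(t)
        assert np.allclose(conf.trials_per_digit, 20)


class TestNeighborCounts:
    def test_d2_to_d4_is_second_neighbor(self):
        conf = ConfusionMatrix(np.zeros((5, 5)))
        conf.counts[1, 3] = 1  # D2 stimulated, D4 reported
        nc = neighbor_counts(conf)
        assert nc["N2"] == 1 and nc.drop("N2").sum() == 0

    def test_all_correct_gives_zero_everywhere(self):
        conf = ConfusionMatrix(np.eye(5) * 20)
        assert neighbor_counts(conf).sum() == 0

    def test_uniform_offdiagonal_enumerates_8_6_4_2(self):
        conf = ConfusionMatrix(np.ones((5, 5)) - np.eye(5))
        assert list(neighbor_counts(conf)) == [8.0, 6.0, 4.0, 2.0]

    def test_generating_neighbor_profile_recovered_in_expectation(self):
        # confusion model with decaying neighbor errors; large trial count
        P = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                P[i, j] = 1.0 if i == j else 0.5 ** abs(i - j)
            P[i] /= P[i].sum()
        t = simulate_mislocalization(P, 5000, seed=1)
        nc = neighbor_counts(confusion_from_trials(t))
        expected = np.array([sum(P[i, j] for i in range(5) for j in range(5)
                                 if abs(i - j) == k) * 5000 for k in (1, 2, 3, 4)])
        assert np.allclose(nc.to_numpy(), expected, atol=5 * np.sqrt(expected.max()))


class TestChanceModel:
    def test_worked_example_942_rounds_to_377(self):
        exp = chance_expected(942)
        assert exp.loc["N1", "expected"] == pytest.approx(376.8)
        assert exp.loc["N1", "expected_rounded"] == 377

    def test_total_20_gives_weights(self):
        assert list(chance_expected(20)["expected"]) == [8.0, 6.0, 4.0, 2.0]

    def test_zero_total_and_conservation(self):
        assert chance_expected(0)["expected"].sum() == 0
        assert chance_expected(333)["expected"].sum() == pytest.approx(333)


class TestGTest:
    def test_observed_equals_expected_gives_zero(self):
        g, df, p = g_test([8, 6, 4, 2], [8, 6, 4, 2])
        assert g == 0.0 and df == 3 and p == pytest.approx(1.0)

    def test_hand_example(self):
        g, df, p = g_test([10, 6, 3, 1], [8, 6, 4, 2])
        hand = 2 * (10 * np.log(10 / 8) + 3 * np.log(3 / 4) + np.log(1 / 2))
        assert g == pytest.approx(hand)
        assert g == pytest.approx(1.35, abs=0.02)
        assert df == 3

    def test_matches_scipy_log_likelihood_oracle_exhaustively(self):
        # all positive 4-cell tables with total 12, chance-model expectations
        for obs in itertools.product(range(1, 10), repeat=4):
            if sum(obs) != 12:
                continue
            exp = np.array(NEIGHBOR_WEIGHTS, float) * 12 / 20
            g, df, p = g_test(obs, exp)
            g2, p2 = power_divergence(obs, exp, lambda_="log-likelihood")
            assert g == pytest.approx(float(g2))
            assert p == pytest.approx(float(p2))

    def test_zero_observed_cells_use_limit_convention(self):
        g, df, p = g_test([12, 0, 0, 0], np.array([8, 6, 4, 2]) * 12 / 20.0)
        hand = 2 * 12 * np.log(12 / (8 * 12 / 20))
        assert g == pytest.approx(hand)

    def test_total_mismatch_rejected(self):
        with pytest.raises(ValueError):
            g_test([1, 2, 3, 4], [8, 6, 4, 2])

    def test_holm_bonferroni_ordering(self):
        reject, p_adj = holm_bonferroni([0.001, 0.04, 0.03], alpha=0.05)
        assert reject[0]
        assert np.all(p_adj >= [0.001, 0.04, 0.03])


class TestSDT:
    def test_equal_rates_give_zero_dprime_unit_beta(self):
        # symmetric confusion: hit rate == false alarm rate per digit
        conf = ConfusionMatrix(np.full((5, 5), 4.0))
        m = sdt_measures(conf)
        # raw hit and false-alarm rates are both 0.2; the log-linear
        # correction shifts them slightly apart (different denominators)
        assert np.allclose(m.d_prime, 0.0, atol=0.05)
        assert np.allclose(m.beta, 1.0, atol=0.05)

    def test_textbook_rates_give_dprime_two(self):
        # hit rate ~ .8413 (z=1), fa rate ~ .1587 (z=-1) after correction:
        # construct counts whose corrected rates hit those values exactly
        n_sig, n_noise = 100, 100
        hits = 0.8413 * (n_sig + 1) - 0.5
        fas = 0.1587 * (n_noise + 1) - 0.5
        zh = norm.ppf((hits + 0.5) / (n_sig + 1))
        zf = norm.ppf((fas + 0.5) / (n_noise + 1))
        assert zh == pytest.approx(1.0, abs=1e-3)
        assert zf == pytest.approx(-1.0, abs=1e-3)
        assert zh - zf == pytest.approx(2.0, abs=2e-3)
        assert np.exp((zf ** 2 - zh ** 2) / 2) == pytest.approx(1.0, abs=1e-2)

    def test_dprime_increases_with_hit_rate_at_fixed_fa(self):
        d_primes = []
        for extra in (0, 4, 8):
            counts = np.full((5, 5), 2.0)
            counts[0, 0] += extra  # more D1 hits, same D1 false alarms
            d_primes.append(sdt_measures(ConfusionMatrix(counts)).d_prime[0])
        assert d_primes[0] < d_primes[1] < d_primes[2]

    def test_rates_strictly_inside_unit_interval(self):
        conf = ConfusionMatrix(np.eye(5) * 20)  # perfect performance
        m = sdt_measures(conf)
        assert np.all((m.hit_rate > 0) & (m.hit_rate < 1))
        assert np.all((m.fa_rate > 0) & (m.fa_rate < 1))

    def test_percentages_normalizations(self):
        conf = ConfusionMatrix(np.ones((5, 5)))
        pct = mislocalization_percentages(conf)
        assert np.allclose(pct["per_digit"].sum(axis=1), 100.0)
        assert pct["per_total"].to_numpy().sum() == pytest.approx(100.0)


class TestTwoPointThreshold:
    def test_perfect_step_bracketed(self):
        d = np.repeat(np.arange(0.7, 2.9, 0.3), 10)
        y = (d >= 1.9).astype(float)
        res = two_pd_threshold(d, y)
        assert res.method == "bracket"
        assert 1.6 < res.threshold_mm < 1.9

    def test_symmetric_responses_give_midpoint(self):
        d = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        res = two_pd_threshold(d, y)
        assert res.threshold_mm == pytest.approx(2.0, abs=1e-4)

    def test_recovers_simulated_threshold(self):
        df = simulate_2pd(2.5, slope=3.0, n_per_distance=600, seed=0)
        res = two_pd_threshold(df.distance_mm.to_numpy(),
                               df.two_felt.to_numpy())
        assert res.method == "logistic"
        assert res.threshold_mm == pytest.approx(2.5, abs=0.1)

    def test_all_same_responses_non_estimable(self):
        res = two_pd_threshold([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert not res.estimable

    def test_run_averaging(self):
        tables = [simulate_2pd(2.5, 3.0, n_per_distance=300, seed=s)
                  for s in (1, 2)]
        assert two_pd_threshold_runs(tables) == pytest.approx(2.5, abs=0.15)
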