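"""Binomial mixture fitting, presence calling and cell assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from pacseq.guide_assignment import (
    MixtureFit,
    assign_cells,
    assignment_summary,
    call_presence,
    detection_rate,
    fit_all_guides,
    fit_binomial_mixture,
    noise_probability,
)
from pacseq.synthetic_data import SimConfig, make_guide_counts, make_mixture_counts


class TestFitBinomialMixture:
    def test_parameter_recovery(self):
        k, n, z = make_mixture_counts(2000, seed=1)
        fit = fit_binomial_mixture(k, n, seed=0)
        assert fit.converged
        assert fit.p_noise == pytest.approx(0.005, rel=0.10)
        assert fit.p_signal == pytest.approx(0.95, rel=0.10)
        assert fit.pi_signal == pytest.approx(0.3, abs=0.05)

    def test_all_zero_counts_degenerate(self):
        n = np.full(50, 100.0)
        fit = fit_binomial_mixture(np.zeros(50), n)
        assert fit.degenerate
        assert not call_presence(fit, np.zeros(50), n).any()

    def test_point_masses_recover_closed_form(self):
        # saturated responsibilities: p estimates are the component means
        n = np.full(400, 1000.0)
        k = np.concatenate([np.full(300, 1.0), np.full(100, 900.0)])
        fit = fit_binomial_mixture(k, n, seed=0)
        assert fit.p_noise == pytest.approx(0.001, rel=0.05)
        assert fit.p_signal == pytest.approx(0.9, rel=0.05)
        assert fit.pi_signal == pytest.approx(0.25, abs=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_loglik_trace_monotone(self, seed):
        k, n, _ = make_mixture_counts(500, pi_signal=0.2, seed=seed)
        fit = fit_binomial_mixture(k, n, seed=seed)
        gains = np.diff(fit.loglik_trace)
        assert np.all(gains >= -1e-8 * (1 + np.abs(fit.loglik_trace[:-1])))

    def test_relabeling_invariance(self):
        # different initialization seeds land on the same ordered solution
        k, n, _ = make_mixture_counts(800, seed=5)
        fits = [fit_binomial_mixture(k, n, seed=s) for s in range(4)]
        for f in fits[1:]:
            assert f.p_noise == pytest.approx(fits[0].p_noise, rel=1e-3)
            assert f.p_signal == pytest.approx(fits[0].p_signal, rel=1e-3)
            assert f.pi_signal == pytest.approx(fits[0].pi_signal, abs=1e-3)
        assert all(f.p_noise < f.p_signal for f in fits)

    def test_low_support_flagged(self):
        n = np.full(50, 100.0)
        k = np.zeros(50)
        k[0] = 60
        fit = fit_binomial_mixture(k, n, min_cells=3)
        assert fit.low_support

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_binomial_mixture(np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            fit_binomial_mixture(np.array([5.0]), np.array([2.0]))


class TestNoiseProbability:
    fit = MixtureFit(None, 0.005, 0.95, 0.3, np.array([]), True, 100)

    def test_zero_count_favors_noise(self):
        assert noise_probability(self.fit, 0, 500)[0] > 1 - 1e-6

    def test_identical_components_give_prior(self):
        flat = MixtureFit(None, 0.2, 0.2, 0.3, np.array([]), True, 10)
        p = noise_probability(flat, np.array([0, 5, 10]), np.array([20, 20, 20]))
        assert np.allclose(p, 0.7, atol=1e-9)

    def test_matches_direct_posterior_formula(self):
        expected = (0.7 * binom.pmf(90, 100, 0.005)) / (
            0.7 * binom.pmf(90, 100, 0.005) + 0.3 * binom.pmf(90, 100, 0.95)
        )
        assert noise_probability(self.fit, 90, 100)[0] == pytest.approx(expected, rel=1e-9)

    def test_n_zero_is_pure_noise(self):
        assert noise_probability(self.fit, 0, 0)[0] == 1.0

    def test_monotone_nonincreasing_in_k(self):
        n = 200
        p = noise_probability(self.fit, np.arange(n + 1), np.full(n + 1, n))
        assert np.all(np.diff(p) <= 1e-12)

    def test_presence_threshold_is_strict(self):
        p = noise_probability(self.fit, 3, 150)[0]
        assert not call_presence(self.fit, 3, 150, threshold=p)[0]
        assert call_presence(self.fit, 3, 150, threshold=p + 1e-12)[0]


class TestAssignment:
    def test_assignment_statuses(self):
        presence = pd.DataFrame(
            [[False, True, False], [True, True, False], [False, False, False]],
            index=["c1", "c2", "c3"],
            columns=["g1", "g2", "g3"],
        )
        table = assign_cells(presence)
        assert table.loc["c1", "status"] == "assigned"
        assert table.loc["c1", "assigned_guide"] == "g2"
        assert table.loc["c2", "status"] == "multiple_present"
        assert table.loc["c2", "assigned_guide"] is None
        assert table.loc["c3", "status"] == "none_present"

    def test_detection_rate_matches_enumeration(self, rng):
        presence = pd.DataFrame(
            rng.random((300, 4)) < 0.3,
            index=[f"c{i}" for i in range(300)],
            columns=list("abcd"),
        )
        table = assign_cells(presence)
        hq = [f"c{i}" for i in range(0, 300, 2)]
        # brute-force oracle: count cells with exactly one present guide
        expected = sum(presence.loc[c].sum() == 1 for c in hq) / len(hq)
        assert detection_rate(table, hq) == pytest.approx(expected)

    def test_detection_rate_printed_pool_arithmetic(self):
        # 13016 high-quality cells of which 3208 not singly assigned -> 75.3%
        barcodes = [f"c{i}" for i in range(13016)]
        presence = pd.DataFrame(
            {"g1": [i >= 3208 for i in range(13016)]}, index=barcodes
        )
        rate = detection_rate(assign_cells(presence), barcodes)
        assert rate * 100 == pytest.approx(75.3, abs=0.1)

    def test_all_assigned_rate_one(self):
        presence = pd.DataFrame({"g1": [True] * 5}, index=list("abcde"))
        assert detection_rate(assign_cells(presence), list("abcde")) == 1.0

    def test_empty_hq_set_rejected(self):
        presence = pd.DataFrame({"g1": [True]}, index=["c"])
        with pytest.raises(ValueError):
            detection_rate(assign_cells(presence), [])

    def test_summary_covers_all_cells(self):
        presence = pd.DataFrame(
            [[True, False], [True, True], [False, False], [False, True]],
            index=list("abcd"),
            columns=["g1", "g2"],
        )
        summary = assignment_summary(assign_cells(presence))
        assert summary["n_cells"].sum() == 4


class TestEndToEndCalls:
    def test_presence_calls_match_truth_on_separated_data(self):
        # separation p_signal/p_noise >= 50 and >= 500 cells -> >= 99% agreement
        k, n, z = make_mixture_counts(
            800, p_noise=0.01, p_signal=0.5, pi_signal=0.25, seed=9
        )
        fit = fit_binomial_mixture(k, n, seed=0)
        agree = (call_presence(fit, k, n) == z).mean()
        assert agree >= 0.99

    def test_screen_labels_recovered(self):
        cfg = SimConfig(seed=4, n_cells=600)
        gc, truth = make_guide_counts(cfg)
        fits, presence = fit_all_guides(gc, seed=0)
        table = assign_cells(presence)
        acc = (table["assigned_guide"] == truth.true_guide.reindex(table.index)).mean()
        assert acc >= 0.99
        for f in fits.values():
            assert f.p_noise < f.p_signal
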