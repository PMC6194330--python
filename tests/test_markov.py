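"""Transition-model estimation, sampling, closed forms, test processes."""

import logging

import numpy as np
import pytest

import autoinfo as ai
from autoinfo.markov import lifted_stationary_distribution


class TestEstimation:
    def test_deterministic_alternation(self):
        seq = ai.SymbolSequence(np.array([0, 1, 0, 1, 0, 1, 0, 1]), 2)
        model = ai.estimate_transition_model(seq, 1)
        assert np.allclose(model.table, [[0, 1], [1, 0]])

    def test_golden_mean_matrix(self, gm2_seq):
        model = ai.estimate_transition_model(gm2_seq, 1)
        assert np.allclose(model.table, [[0.5, 0.5], [1.0, 0.0]], atol=5e-3)

    def test_order2_parameter_recovery(self):
        """Recovered table within 0.01 of the generator at N = 10^6, 5 seeds."""
        truth = ai.random_transition_model(2, 2, seed=50)
        for seed in range(5):
            seq = ai.sample_markov(truth, 1_000_000, seed=60 + seed)
            est = ai.estimate_transition_model(seq, 2)
            assert np.abs(est.table - truth.table).max() <= 0.01

    def test_round_trip_accuracy_improves_with_n(self):
        truth = ai.random_transition_model(3, 1, seed=51)
        errs = []
        for n in (10_000, 1_000_000):
            seq = ai.sample_markov(truth, n, seed=70)
            est = ai.estimate_transition_model(seq, 1)
            errs.append(np.abs(est.table - truth.table).max())
        assert errs[1] < errs[0]

    def test_order_zero_is_symbol_distribution(self):
        seq = ai.SymbolSequence(np.array([0, 0, 1, 0]), 2)
        model = ai.estimate_transition_model(seq, 0)
        assert model.table.shape == (1, 2)
        assert np.allclose(model.table[0], [0.75, 0.25])

    def test_unobserved_histories_flagged(self, caplog):
        # symbol 2 never occurs: all histories containing it are unobserved
        seq = ai.SymbolSequence(np.array([0, 1, 0, 1, 0, 1] * 10), 3)
        with caplog.at_level(logging.INFO, logger="autoinfo"):
            model = ai.estimate_transition_model(seq, 1)
        assert not model.observed[2]
        assert np.isnan(model.table[2]).all()


class TestSampling:
    def test_deterministic_rows_give_deterministic_path(self):
        model = ai.TransitionModel(
            2, 1, np.array([[0.0, 1.0], [1.0, 0.0]]), np.array([1.0, 0.0])
        )
        seq = ai.sample_markov(model, 20, seed=0)
        assert np.array_equal(seq.symbols, np.arange(20) % 2)

    def test_seed_reproducibility(self):
        model = ai.random_transition_model(3, 2, seed=1)
        a = ai.sample_markov(model, 1000, seed=5)
        b = ai.sample_markov(model, 1000, seed=5)
        c = ai.sample_markov(model, 1000, seed=6)
        assert np.array_equal(a.symbols, b.symbols)
        assert not np.array_equal(a.symbols, c.symbols)

    def test_fair_coin_statistics(self):
        seq = ai.sample_markov(ai.two_state_model(0.5, 0.5), 200_000, seed=2)
        assert seq.symbols.mean() == pytest.approx(0.5, abs=5e-3)
        assert ai.active_information_storage(seq, 1) == pytest.approx(0.0, abs=1e-3)

    def test_estimate_then_resample_entropy_rate(self, gm2_seq):
        """Surrogate fidelity: resampled h_1 reproduces the estimated model's
        entropy rate (and hence sits within ~0.002 of the exact 2/3 bit)."""
        model = ai.estimate_transition_model(gm2_seq, 1)
        target = ai.two_state_analytics(model.table[0, 1], model.table[1, 0]).entropy_rate
        rates = [
            ai.entropy_rate(ai.sample_markov(model, 1_000_000, seed=s), 1)
            for s in range(5)
        ]
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - target) <= 3 * max(se, 1e-4)
        assert abs(np.mean(rates) - 2 / 3) <= 2e-3

    def test_unobserved_history_fallback(self, caplog):
        # the data end in a dead end: (1,1) always leads to 2, but the
        # history (1,2) has no observed successor, so its row is invalid and
        # the sampler must restart from the history distribution
        seq = ai.SymbolSequence(np.array([0, 1, 0, 0, 1, 0, 1, 1, 2]), 3)
        model = ai.estimate_transition_model(seq, 2)
        assert not model.observed[1 * 3 + 2]  # history (1, 2)
        with caplog.at_level(logging.INFO, logger="autoinfo"):
            out = ai.sample_markov(model, 5000, seed=3)
        assert out.length == 5000
        assert any("restarted" in r.message for r in caplog.records)

    def test_stationary_eigenvector_matches_frequencies(self):
        model = ai.random_transition_model(2, 1, seed=8)
        seq = ai.sample_markov(model, 500_000, seed=9)
        est = ai.estimate_transition_model(seq, 1)
        w, v = np.linalg.eig(est.table.T)
        vec = np.abs(np.real(v[:, np.argmin(np.abs(w - 1.0))]))
        vec /= vec.sum()
        freq = np.bincount(seq.symbols, minlength=2) / seq.length
        # generous SE allowance for the autocorrelated sample
        se = np.sqrt(freq * (1 - freq) / seq.length) * 5
        assert np.all(np.abs(freq - vec) <= 3 * np.maximum(se, 1e-4))


class TestTwoStateAnalytics:
    def test_fair_coin(self):
        ana = ai.two_state_analytics(0.5, 0.5)
        assert ana.stationary == (0.5, 0.5)
        assert ana.entropy == pytest.approx(1.0)
        assert ana.entropy_rate == pytest.approx(1.0)
        assert ana.active_information_storage == pytest.approx(0.0)

    def test_golden_mean_rates(self):
        ana = ai.two_state_analytics(0.5, 1.0)
        assert ana.stationary == pytest.approx((2 / 3, 1 / 3))
        assert ana.entropy == pytest.approx(0.9182958340544896)
        assert ana.entropy_rate == pytest.approx(2 / 3)
        assert ana.active_information_storage == pytest.approx(0.2516291673878229)
        assert ana.eigenvalues[1] == pytest.approx(-0.5)

    def test_conservation_exact_on_grid(self):
        for p in np.linspace(0.05, 1.0, 7):
            for q in np.linspace(0.05, 1.0, 7):
                ana = ai.two_state_analytics(p, q)
                assert ana.eigenvalues[0] == 1.0
                assert ana.entropy == pytest.approx(
                    ana.active_information_storage + ana.entropy_rate, abs=1e-14
                )
                assert min(ana.entropy, ana.entropy_rate,
                           ana.active_information_storage) >= 0.0

    def test_degenerate_rates_rejected(self):
        with pytest.raises(ValueError):
            ai.two_state_analytics(0.0, 0.0)
        with pytest.raises(ValueError):
            ai.two_state_analytics(1.2, 0.5)


class TestRandomModel:
    def test_rows_normalized_and_reproducible(self):
        a = ai.random_transition_model(4, 2, seed=3)
        b = ai.random_transition_model(4, 2, seed=3)
        c = ai.random_transition_model(4, 2, seed=4)
        assert np.allclose(a.table.sum(axis=1), 1.0, atol=1e-12)
        assert np.array_equal(a.table, b.table)
        assert not np.array_equal(a.table, c.table)

    def test_dirichlet_option(self):
        m = ai.random_transition_model(3, 1, seed=5, method="dirichlet")
        assert np.allclose(m.table.sum(axis=1), 1.0, atol=1e-12)

    def test_lifted_stationary_is_invariant(self):
        model = ai.random_transition_model(2, 2, seed=6)
        pi = model.history_probs
        # push forward one step: must be unchanged
        L, M = 2, 2
        out = np.zeros_like(pi)
        for h in range(L**M):
            for s in range(L):
                out[(h * L + s) % L**M] += pi[h] * model.table[h, s]
        assert np.allclose(out, pi, atol=1e-10)


class TestLagSkippingModel:
    def test_rows_depend_only_on_oldest_symbol(self):
        model = ai.lag_skipping_model(3, seed=7)
        table = model.table.reshape(3, 3, 3, 3)  # (x_{n-2}, x_{n-1}, x_n, next)
        for old in range(3):
            block = table[old]
            assert np.allclose(block, block[0, 0])

    def test_conditionals_well_separated(self):
        model = ai.lag_skipping_model(3, seed=7)
        conds = model.table.reshape(3, 9, 3)[:, 0, :]
        for i in range(3):
            for j in range(i + 1, 3):
                assert 0.5 * np.abs(conds[i] - conds[j]).sum() >= 0.2

    def test_aif_period_three(self, lag_skipping_seq):
        prof = ai.profile_with_band(lag_skipping_seq, 9, kind="aif",
                                    n_surrogates=100, seed=10)
        sig = prof.significant
        assert sig[3] and sig[6] and sig[9]
        assert not sig[[1, 2, 4, 5, 7, 8]].any()

    def test_paif_single_peak_at_three(self, lag_skipping_seq):
        prof = ai.profile_with_band(lag_skipping_seq, 6, kind="paif",
                                    n_surrogates=100, seed=11)
        assert prof.significant[3]
        assert not prof.significant[[1, 2, 4, 5, 6]].any()


class TestSerialization:
    def test_text_round_trip(self, tmp_path):
        model = ai.random_transition_model(3, 2, seed=12)
        path = tmp_path / "model.txt"
        model.to_text(path)
        back = ai.TransitionModel.from_text(path)
        assert back.n_symbols == 3 and back.order == 2
        assert np.allclose(back.table, model.table, atol=1e-15)
        assert np.allclose(back.history_probs, model.history_probs, atol=1e-15)

    def test_validation_rejects_bad_rows(self):
        with pytest.raises(ValueError):
            ai.TransitionModel(2, 1, np.array([[0.5, 0.6], [1.0, 0.0]]))
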