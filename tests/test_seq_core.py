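"""Sequence container, k-history counting and plug-in entropy estimators."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import autoinfo as ai
from autoinfo.seq_core import SequenceFormatError, _window_codes

from conftest import entropy_oracle, khistory_oracle


class TestSymbolSequence:
    def test_validation(self):
        with pytest.raises(ValueError):
            ai.SymbolSequence(np.array([]), 2)
        with pytest.raises(ValueError):
            ai.SymbolSequence(np.array([0, 2]), 2)
        with pytest.raises(ValueError):
            ai.SymbolSequence(np.array([-1, 0]), 2)
        with pytest.raises(ValueError):
            ai.SymbolSequence(np.array([0.5, 1.0]), 2)

    def test_explicit_alphabet_keeps_absent_symbols(self):
        seq = ai.SymbolSequence(np.zeros(10, dtype=int), 4)
        assert seq.n_symbols == 4
        dist = ai.khistory_distribution(seq, 1)
        assert dist.probabilities == {(0,): 1.0}

    def test_inferred_alphabet(self):
        seq = ai.SymbolSequence.from_iterable([0, 2, 1])
        assert seq.n_symbols == 3 and seq.length == 3


class TestKHistoryDistribution:
    @pytest.mark.parametrize(
        "symbols, L, k, expected",
        [
            ([0, 1, 0, 1, 0, 1], 2, 2, {(1, 0): 2, (0, 1): 3}),
            ([0, 0, 0, 0, 0], 2, 3, {(0, 0, 0): 3}),
        ],
    )
    def test_direct_counts(self, symbols, L, k, expected):
        dist = ai.khistory_distribution(ai.SymbolSequence(np.array(symbols), L), k)
        assert dist.counts == expected
        assert dist.total == len(symbols) - k + 1

    def test_k1_gives_symbol_frequencies(self):
        rng = np.random.default_rng(0)
        seq = ai.SymbolSequence(rng.integers(0, 3, 200), 3)
        dist = ai.khistory_distribution(seq, 1)
        for s in range(3):
            assert dist.probabilities.get((s,), 0.0) == pytest.approx(
                np.mean(seq.symbols == s)
            )

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        seq = ai.SymbolSequence(rng.integers(0, 2, 500), 2)
        dist = ai.khistory_distribution(seq, 4)
        assert sum(dist.probabilities.values()) == pytest.approx(1.0, abs=1e-12)
        assert dist.support_size <= min(2**4, seq.length - 3)

    def test_invalid_arguments(self):
        seq = ai.SymbolSequence(np.array([0, 1]), 2)
        with pytest.raises(ValueError):
            ai.khistory_distribution(seq, 3)
        with pytest.raises(ValueError):
            ai.khistory_distribution(seq, 0)

    def test_tuple_fallback_when_codes_overflow(self):
        # 3**45 does not fit 64 bits: the tuple-keyed path must take over
        rng = np.random.default_rng(2)
        seq = ai.SymbolSequence(rng.integers(0, 3, 50), 3)
        dist = ai.khistory_distribution(seq, 45)
        assert dist.total == 6
        assert dist.counts == khistory_oracle(seq.symbols, 45)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            ([0.5, 0.5], 1.0),
            ([2 / 3, 1 / 3], 0.9182958340544896),
            ([1.0, 0.0], 0.0),
        ],
    )
    def test_known_values(self, probs, expected):
        assert ai.shannon_entropy(probs) == pytest.approx(expected, abs=1e-12)

    def test_accepts_distribution_and_mapping(self):
        seq = ai.SymbolSequence(np.array([0, 1, 1]), 2)
        dist = ai.khistory_distribution(seq, 1)
        assert ai.shannon_entropy(dist) == pytest.approx(
            ai.shannon_entropy({"a": 1, "b": 2})
        )


class TestJointEntropyOracle:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        data=st.lists(st.integers(0, 2), min_size=5, max_size=200),
        k=st.integers(1, 4),
    )
    def test_matches_explicit_enumeration(self, data, k):
        """Pooled H_k equals a scan-and-count oracle on small instances."""
        seq = ai.SymbolSequence(np.array(data), 3)
        assert ai.joint_entropy(seq, k) == pytest.approx(
            entropy_oracle(khistory_oracle(data, k)), abs=1e-12
        )

    def test_iid_coin_h2_near_two_bits(self):
        rng = np.random.default_rng(3)
        seq = ai.SymbolSequence(rng.integers(0, 2, 500_000), 2)
        assert ai.joint_entropy(seq, 2) == pytest.approx(2.0, abs=1e-3)

    def test_constant_sequence_zero(self):
        seq = ai.SymbolSequence(np.zeros(100, dtype=int), 2)
        for k in (1, 3, 5):
            assert ai.joint_entropy(seq, k) == 0.0


class TestEntropyRateAndAIS:
    def test_iid_coin_rates(self):
        rng = np.random.default_rng(4)
        seq = ai.SymbolSequence(rng.integers(0, 2, 500_000), 2)
        for k in (1, 3):
            assert ai.entropy_rate(seq, k) == pytest.approx(1.0, abs=2e-3)
            assert ai.active_information_storage(seq, k) == pytest.approx(0.0, abs=2e-3)

    def test_periodic_sequence(self):
        seq = ai.SymbolSequence(np.tile([0, 1], 500), 2)
        # pooled window sets differ at the boundary, so "zero" carries a
        # tiny O(1/N) discrepancy (and may be marginally negative)
        assert ai.entropy_rate(seq, 1) == pytest.approx(0.0, abs=1e-5)
        assert ai.active_information_storage(seq, 1) == pytest.approx(1.0, abs=1e-2)

    def test_rate_monotone_and_bounded(self, gm2_seq):
        H = ai.history_entropies(gm2_seq, 11)
        h = np.diff(H)
        assert np.all(h <= 1.0 + 1e-9)
        assert np.all(np.diff(h) <= 1e-6)  # conditioning reduces entropy
        assert np.all(h >= -1e-9)

    def test_golden_mean_reference_values(self, gm2_seq):
        """H_1 ~ 0.919, h ~ 2/3, a ~ 0.2516 bits for the golden-mean chain."""
        assert ai.joint_entropy(gm2_seq, 1) == pytest.approx(0.9183, abs=2e-3)
        assert ai.entropy_rate(gm2_seq, 2) == pytest.approx(2 / 3, abs=2e-3)
        assert ai.active_information_storage(gm2_seq, 2) == pytest.approx(
            0.2516, abs=2e-3
        )


class TestConservation:
    def test_pooled_mode_small_boundary_error(self, gm2_seq):
        prof = ai.information_profile(gm2_seq, 10, mode="pooled")
        rel = np.abs(prof["conservation_error"]) / prof.attrs["H1"]
        assert rel.max() <= 1e-3

    def test_consistent_mode_exact(self, gm2_seq):
        prof = ai.information_profile(gm2_seq, 10, mode="consistent")
        assert np.abs(prof["conservation_error"]).max() <= 1e-12


class TestTwoStateConvergence:
    def test_sampled_chain_matches_closed_forms(self):
        """Mean plug-in H_1, h_1, a_1 over 20 seeds within 3 SE of theory."""
        p, q, n = 0.3, 0.6, 100_000
        model = ai.two_state_model(p, q)
        ana = ai.two_state_analytics(p, q)
        ests = np.array(
            [
                [
                    ai.joint_entropy(s, 1),
                    ai.entropy_rate(s, 1),
                    ai.active_information_storage(s, 1),
                ]
                for seed in range(20)
                for s in [ai.sample_markov(model, n, seed=seed)]
            ]
        )
        target = np.array([ana.entropy, ana.entropy_rate, ana.active_information_storage])
        mean = ests.mean(axis=0)
        se = ests.std(axis=0, ddof=1) / np.sqrt(20)
        assert np.all(np.abs(mean - target) <= 3 * np.maximum(se, 1e-6))


class TestUndersamplingWarning:
    def test_warning_logged(self, caplog):
        seq = ai.SymbolSequence(np.random.default_rng(5).integers(0, 4, 200), 4)
        with caplog.at_level(logging.WARNING, logger="autoinfo"):
            ai.joint_entropy(seq, 5)  # 4**5 = 1024 >> 196/10
        assert any("undersampled" in r.message for r in caplog.records)


class TestSequenceIO:
    def test_roundtrip_one_per_line(self, tmp_path):
        seq = ai.SymbolSequence(np.array([0, 3, 1, 2, 2]), 5)
        path = tmp_path / "seq.txt"
        ai.write_sequence(seq, path)
        back = ai.read_sequence(path)
        assert np.array_equal(back.symbols, seq.symbols)
        assert back.n_symbols == 5  # header preserves the declared alphabet

    def test_single_row_delimited(self, tmp_path):
        path = tmp_path / "row.txt"
        path.write_text("0, 1, 1, 0 2\n")
        seq = ai.read_sequence(path)
        assert np.array_equal(seq.symbols, [0, 1, 1, 0, 2])
        assert seq.n_symbols == 3

    def test_header_alphabet_override(self, tmp_path):
        path = tmp_path / "h.txt"
        path.write_text("# L=4\n0\n1\n")
        assert ai.read_sequence(path).n_symbols == 4

    def test_malformed_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0\n1\nfoo\n")
        with pytest.raises(SequenceFormatError, match=":3:"):
            ai.read_sequence(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        with pytest.raises(SequenceFormatError):
            ai.read_sequence(path)

    def test_metric_roundtrip(self, tmp_path):
        x = np.array([0.25, -1.5, 3.0])
        path = tmp_path / "x.txt"
        ai.write_values(x, path)
        assert np.allclose(ai.read_values(path), x)


def test_window_codes_bijective():
    rng = np.random.default_rng(6)
    s = rng.integers(0, 3, 40)
    codes = _window_codes(s, 3, 4)
    # decode back: most recent symbol in the lowest digit
    for i, c in enumerate(codes):
        w = [(c // 3**j) % 3 for j in (3, 2, 1, 0)]
        assert w == list(s[i : i + 4])
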