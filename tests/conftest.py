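"""Shared fixtures: long reference samples are generated once per session."""

import numpy as np
import pytest

import autoinfo as ai


@pytest.fixture(scope="session")
def gm2_seq() -> ai.SymbolSequence:
    """10^6 observable symbols of the 2-state golden-mean machine."""
    return ai.sample_hmm(ai.golden_mean_2state(), 1_000_000, seed=42)


@pytest.fixture(scope="session")
def gm7_seq() -> ai.SymbolSequence:
    """10^6 observable symbols of the 7-state golden-mean machine."""
    return ai.sample_hmm(ai.golden_mean_7state(), 1_000_000, seed=42)


@pytest.fixture(scope="session")
def even_seq() -> ai.SymbolSequence:
    """10^6 observable symbols of the even process."""
    return ai.sample_hmm(ai.even_process(), 1_000_000, seed=42)


@pytest.fixture(scope="session")
def mc3_seq() -> ai.SymbolSequence:
    """10^6 symbols of a random binary third-order Markov chain."""
    model = ai.random_transition_model(2, 3, seed=11)
    return ai.sample_markov(model, 1_000_000, seed=12)


@pytest.fixture(scope="session")
def lag_skipping_seq() -> ai.SymbolSequence:
    """10^6 symbols of the order-3 chain driven only by the symbol 3 back."""
    model = ai.lag_skipping_model(3, seed=21)
    return ai.sample_markov(model, 1_000_000, seed=22)


@pytest.fixture(scope="session")
def double_well_binary() -> ai.SymbolSequence:
    """Thresholded 10^6-step double-well trajectory at default parameters."""
    x = ai.simulate_double_well(ai.DoubleWellConfig(n_samples=1_000_000, seed=5))
    return ai.threshold_binarize(x)


def entropy_oracle(counts_dict) -> float:
    """Brute-force Shannon entropy (bits) from a mapping of counts."""
    total = sum(counts_dict.values())
    h = 0.0
    for c in counts_dict.values():
        if c > 0:
            p = c / total
            h -= p * np.log2(p)
    return h


def khistory_oracle(symbols, k) -> dict:
    """Count every contiguous k-window by explicit scanning."""
    out: dict = {}
    for i in range(len(symbols) - k + 1):
        key = tuple(int(v) for v in symbols[i : i + k])
        out[key] = out.get(key, 0) + 1
    return out
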