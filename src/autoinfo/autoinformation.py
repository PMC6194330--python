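"""Autoinformation (AIF) and partial autoinformation (PAIF) lag profiles.

The autoinformation function is the time-lagged mutual information

    alpha_k = I(X_{n+k}; X_n),

the symbolic analogue of the autocorrelation function: it measures all
statistical dependence between two time points, whether direct or conveyed
through the intermediate symbols.  The partial autoinformation function is
the conditional mutual information

    pi_k = I(X_{n+k}; X_n | X_{n+k-1}, ..., X_{n+1}),

which removes the influence of the intermediate values, exactly as the
partial autocorrelation removes intermediate linear correlations.  For a
stationary Markov process of order M the PAIF vanishes for all lags k > M,
so a stem plot of pi_k against k reads like a PACF plot: the last
significant lag estimates the Markov order.

Stationary identities used here (and asserted by the test-suite):

    pi_k = h_{k-1} - h_k = a_k - a_{k-1} = -(H_{k+1} - 2 H_k + H_{k-1}),

with ``pi_0 = alpha_0 = H_1`` and ``pi_1 = alpha_1`` by convention (there are
no intermediate symbols to condition on at lags 0 and 1).

Significance is judged against an iid null: the symbols are randomly
permuted (preserving the marginal distribution, destroying all temporal
order) and the empirical alpha/2 .. 1-alpha/2 percentile band of the
statistic across surrogates is reported per lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seq_core import (
    MAX_DENSE_STATES,
    SymbolSequence,
    _as_sequence,
    _check_mode,
    _codes_fit,
    _entropy_of_counts,
    _history_entropies_raw,
    _warn_undersampled,
    _window_codes,
)

logger = logging.getLogger("autoinfo")

#: default lag ranges: AIF is cheap at any lag (2-D distributions only),
#: PAIF cost grows like L**(k+1)
DEFAULT_MAX_LAG_AIF = 50
DEFAULT_MAX_LAG_PAIF = 8

PROFILE_KINDS = ("aif", "paif", "acf", "pacf")


@dataclass
class LagProfile:
    """Per-lag coefficients with optional surrogate confidence bounds.

    ``values`` are in bits for AIF/PAIF (unitless if ``normalized``) and
    unitless correlations for ACF/PACF.
    """

    lags: np.ndarray
    values: np.ndarray
    kind: str
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    alpha: float | None = None
    normalized: bool = False
    n_surrogates: int | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"kind must be one of {PROFILE_KINDS}")
        if self.lags.size != self.values.size:
            raise ValueError("lags and values must have equal length")
        if self.lags.size and (self.lags[0] != 0 or np.any(np.diff(self.lags) <= 0)):
            raise ValueError("lags must be strictly increasing and start at 0")
        if self.normalized and self.lags.size and not np.isclose(self.values[0], 1.0):
            raise ValueError("a normalized profile must have value 1 at lag 0")
        for name in ("ci_low", "ci_high"):
            ci = getattr(self, name)
            if ci is not None:
                setattr(self, name, np.asarray(ci, dtype=float))
        if self.ci_low is not None and self.ci_high is not None:
            if np.any(self.ci_low > self.ci_high + 1e-12):
                raise ValueError("ci_low must not exceed ci_high")

    @property
    def has_band(self) -> bool:
        return self.ci_low is not None and self.ci_high is not None

    @property
    def significant(self) -> np.ndarray:
        """Boolean mask of lags showing more structure than the null band.

        AIF/PAIF are non-negative dependence measures, so only exceedance of
        the upper band edge counts as evidence of temporal structure (a value
        below the lower edge merely reflects the smaller plug-in bias of a
        constrained support).  Correlation profiles (ACF/PACF) are signed and
        use the two-sided rule.
        """
        if not self.has_band:
            raise ValueError("profile has no confidence band")
        if self.kind in ("aif", "paif"):
            return self.values > self.ci_high
        return (self.values < self.ci_low) | (self.values > self.ci_high)

    def last_significant_lag(self) -> int:
        """Largest lag >= 1 outside the band; 0 if none (iid-compatible)."""
        sig = self.significant
        hits = self.lags[(self.lags >= 1) & sig]
        return int(hits.max()) if hits.size else 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"lag": self.lags, "value": self.values})
        df["ci_low"] = self.ci_low if self.has_band else np.nan
        df["ci_high"] = self.ci_high if self.has_band else np.nan
        df["kind"] = self.kind
        df["normalized"] = self.normalized
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# AIF
# ---------------------------------------------------------------------------


def _aif_values(s: np.ndarray, L: int, max_lag: int) -> np.ndarray:
    """Raw (unnormalized) AIF in bits for lags 0..max_lag."""
    n = s.size
    out = np.empty(max_lag + 1)
    out[0] = _entropy_of_counts(np.bincount(s, minlength=L))
    for k in range(1, max_lag + 1):
        pair = s[: n - k] * L + s[k:]
        joint = np.bincount(pair, minlength=L * L).reshape(L, L)
        h_joint = _entropy_of_counts(joint.ravel())
        h_left = _entropy_of_counts(joint.sum(axis=1))
        h_right = _entropy_of_counts(joint.sum(axis=0))
        out[k] = h_left + h_right - h_joint
    return out


def aif(seq, max_lag: int = DEFAULT_MAX_LAG_AIF, normalize: bool = False) -> LagProfile:
    """Autoinformation profile ``alpha_k = I(X_{n+k}; X_n)`` for ``k <= max_lag``.

    Each lag uses all ``N - k`` aligned pairs; the marginal entropies are
    those of the aligned pair distribution, so ``alpha_k >= 0``.  The cost is
    independent of the lag (only 1- and 2-symbol distributions are needed).
    ``alpha_0 = H_1``; with ``normalize=True`` all values are divided by it.
    """
    seq = _as_sequence(seq)
    if not (0 <= max_lag < seq.length):
        raise ValueError(f"max_lag={max_lag} must satisfy 0 <= max_lag < N={seq.length}")
    values = _aif_values(seq.symbols, seq.n_symbols, max_lag)
    if normalize:
        if values[0] == 0:
            raise ValueError("cannot normalize: H_1 = 0 (constant sequence)")
        values = values / values[0]
    return LagProfile(np.arange(max_lag + 1), values, kind="aif", normalized=normalize)


# ---------------------------------------------------------------------------
# PAIF
# ---------------------------------------------------------------------------


def _paif_values_pooled(s: np.ndarray, L: int, max_lag: int) -> np.ndarray:
    """PAIF via the entropy-rate difference ``pi_k = h_{k-1} - h_k``.

    All joint entropies come from their own pooled window pass; tiny negative
    values can occur at the sequence boundaries and are reported as-is.
    """
    out = np.empty(max_lag + 1)
    H = _history_entropies_raw(s, L, max_lag + 1)
    out[0] = H[1]
    if max_lag >= 1:
        out[1] = _aif_values(s, L, 1)[1]
    for k in range(2, max_lag + 1):
        out[k] = 2.0 * H[k] - H[k - 1] - H[k + 1]
    return out


def _paif_values_consistent(s: np.ndarray, L: int, max_lag: int) -> np.ndarray:
    """PAIF as conditional mutual information of the (k+1)-window distribution.

    For each lag the four entropies are marginals of the same empirical
    (k+1)-window distribution, hence ``pi_k >= 0`` by construction.
    """
    out = np.empty(max_lag + 1)
    out[0] = _entropy_of_counts(np.bincount(s, minlength=L))
    if max_lag >= 1:
        out[1] = _aif_values(s, L, 1)[1]
    for k in range(2, max_lag + 1):
        c = _window_codes(s, L, k + 1)
        h_full = _entropy_of_counts(np.bincount(c, minlength=L ** (k + 1)))
        h_first = _entropy_of_counts(np.bincount(c // L, minlength=L**k))
        h_last = _entropy_of_counts(np.bincount(c % L**k, minlength=L**k))
        h_mid = _entropy_of_counts(np.bincount((c // L) % L ** (k - 1), minlength=L ** (k - 1)))
        out[k] = h_last + h_first - h_mid - h_full
    return out


def paif(
    seq,
    max_lag: int = DEFAULT_MAX_LAG_PAIF,
    mode: str = "pooled",
    max_states: int = MAX_DENSE_STATES,
) -> LagProfile:
    """Partial autoinformation profile for lags ``0..max_lag``.

    ``pi_0 = alpha_0`` and ``pi_1 = alpha_1`` by convention; for ``k >= 2``
    the coefficient is the conditional mutual information between the two
    end points of a (k+1)-window given the intermediates.  The required
    (k+1)-history distributions grow like ``L**(k+1)``: a warning is logged
    when the lag range is undersampled, and lags whose state space exceeds
    ``max_states`` raise a ``ValueError``.
    """
    seq = _as_sequence(seq)
    _check_mode(mode)
    if not (0 <= max_lag) or max_lag + 1 > seq.length:
        raise ValueError(f"max_lag={max_lag} must satisfy max_lag + 1 <= N={seq.length}")
    L = seq.n_symbols
    if not _codes_fit(L, max_lag + 1) or float(L) ** (max_lag + 1) > max_states:
        raise ValueError(
            f"PAIF at lag {max_lag} needs L^(k+1) = {L}^{max_lag + 1} history "
            f"states, above the cap {max_states}; reduce max_lag"
        )
    _warn_undersampled(L, max_lag + 1, seq.length - max_lag)
    fn = _paif_values_pooled if mode == "pooled" else _paif_values_consistent
    values = fn(seq.symbols, L, max_lag)
    return LagProfile(np.arange(max_lag + 1), values, kind="paif")


# ---------------------------------------------------------------------------
# iid surrogate confidence band
# ---------------------------------------------------------------------------


def iid_confidence_band(
    seq,
    max_lag: int,
    kind: str = "paif",
    n_surrogates: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
    mode: str = "pooled",
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag percentile bounds of AIF or PAIF under the iid null.

    Each surrogate is a seeded random permutation of the observed symbols:
    the marginal distribution is preserved exactly while all temporal
    structure is destroyed.  Returns ``(low, high)`` — the empirical
    ``alpha/2`` and ``1 - alpha/2`` percentiles across surrogates, per lag.
    """
    seq = _as_sequence(seq)
    if kind not in ("aif", "paif"):
        raise ValueError("kind must be 'aif' or 'paif'")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates")
    if n_surrogates < 20:
        logger.warning("n_surrogates=%d is small; >= 20 recommended", n_surrogates)
    rng = np.random.default_rng(seed)
    L = seq.n_symbols
    stats = np.empty((n_surrogates, max_lag + 1))
    for i in range(n_surrogates):
        perm = rng.permutation(seq.symbols)
        if kind == "aif":
            vals = _aif_values(perm, L, max_lag)
            if normalize:
                vals = vals / vals[0] if vals[0] > 0 else vals
        else:
            fn = _paif_values_pooled if mode == "pooled" else _paif_values_consistent
            vals = fn(perm, L, max_lag)
        stats[i] = vals
    low = np.quantile(stats, alpha / 2.0, axis=0)
    high = np.quantile(stats, 1.0 - alpha / 2.0, axis=0)
    return low, high


def profile_with_band(
    seq,
    max_lag: int,
    kind: str = "paif",
    n_surrogates: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
    mode: str = "pooled",
    normalize: bool = False,
) -> LagProfile:
    """Convenience wrapper: compute a profile and attach its iid null band."""
    if kind == "aif":
        prof = aif(seq, max_lag, normalize=normalize)
    elif kind == "paif":
        prof = paif(seq, max_lag, mode=mode)
    else:
        raise ValueError("kind must be 'aif' or 'paif'")
    low, high = iid_confidence_band(
        seq, max_lag, kind=kind, n_surrogates=n_surrogates, alpha=alpha,
        seed=seed, mode=mode, normalize=normalize,
    )
    prof.ci_low, prof.ci_high = low, high
    prof.alpha = alpha
    prof.n_surrogates = n_surrogates
    return prof
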