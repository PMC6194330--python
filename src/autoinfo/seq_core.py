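"""Symbolic sequences and plug-in information estimators.

A symbolic time series is a sequence of integer labels drawn from a finite
alphabet ``{0, ..., L-1}`` — e.g. the open/closed states of an ion channel,
single Ising spins, or EEG microstate labels.  All information-theoretic
quantities in this package are built from the empirical distribution of
*k-histories*: contiguous blocks of ``k`` consecutive symbols.  From the
k-history distributions we obtain, by the plug-in (maximum-likelihood)
principle,

* the joint entropy ``H_k`` of a k-history,
* the entropy rate ``h_k = H(X_{n+1} | X_n^{(k)})`` — surprise per symbol
  given a history of length ``k``, and
* the active information storage ``a_k = I(X_{n+1}; X_n^{(k)})`` — the part
  of the next symbol's entropy that is predictable from the history.

These satisfy the conservation identity ``H_1 = a_k + h_k``.

Two estimation modes are available everywhere a choice arises:

``"pooled"`` (default)
    Every joint entropy is computed from its own pass over all available
    windows (``N - k + 1`` windows of length ``k``), and derived quantities
    combine entropies whose window sets differ slightly at the sequence
    boundaries.  Conservation then holds only up to a tiny boundary
    discrepancy of order ``k / N``.

``"consistent"``
    All quantities at history length ``k`` are marginals of the single
    (k+1)-window distribution, which makes the conservation and difference
    identities exact and conditional informations non-negative by
    construction.

All entropies are in bits (base-2 logarithms).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import entropy as _entropy

logger = logging.getLogger("autoinfo")

#: estimation modes understood throughout the package
MODES = ("pooled", "consistent")

#: largest dense contingency table allocated by the code-based counters
MAX_DENSE_STATES = 1 << 26


class SequenceFormatError(ValueError):
    """Raised when a sequence file cannot be parsed."""


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


# ---------------------------------------------------------------------------
# SymbolSequence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymbolSequence:
    """An integer-labelled time series over a finite alphabet.

    Parameters
    ----------
    symbols
        The label sequence; every element must lie in ``[0, n_symbols)``.
    n_symbols
        The alphabet size ``L``.  Declared explicitly so that symbols absent
        from a finite sample still count as zero-probability bins.
    """

    symbols: np.ndarray
    n_symbols: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.symbols)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("symbols must be a non-empty 1-D sequence")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("symbols must be integers")
        arr = np.ascontiguousarray(arr, dtype=np.int64)
        if int(self.n_symbols) < 1:
            raise ValueError("n_symbols must be a positive integer")
        if arr.min() < 0 or arr.max() >= self.n_symbols:
            raise ValueError(
                f"symbols must lie in [0, {self.n_symbols - 1}]; "
                f"observed range [{arr.min()}, {arr.max()}]"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "symbols", arr)
        object.__setattr__(self, "n_symbols", int(self.n_symbols))

    @classmethod
    def from_iterable(
        cls, symbols: Iterable[int], n_symbols: int | None = None
    ) -> "SymbolSequence":
        arr = np.asarray(list(symbols) if not isinstance(symbols, np.ndarray) else symbols)
        if n_symbols is None:
            n_symbols = int(arr.max()) + 1 if arr.size else 1
        return cls(arr, n_symbols)

    @property
    def length(self) -> int:
        return int(self.symbols.size)

    def __len__(self) -> int:
        return self.length

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.symbols, dtype=dtype)

    def reversed(self) -> "SymbolSequence":
        return SymbolSequence(self.symbols[::-1].copy(), self.n_symbols)

    def relabel(self, permutation: Iterable[int]) -> "SymbolSequence":
        """Apply a permutation of the alphabet to every symbol."""
        perm = np.asarray(list(permutation), dtype=np.int64)
        if sorted(perm.tolist()) != list(range(self.n_symbols)):
            raise ValueError("permutation must rearrange 0..L-1")
        return SymbolSequence(perm[self.symbols], self.n_symbols)


def _as_sequence(seq, n_symbols: int | None = None) -> SymbolSequence:
    if isinstance(seq, SymbolSequence):
        return seq
    return SymbolSequence.from_iterable(seq, n_symbols)


# ---------------------------------------------------------------------------
# k-history counting
# ---------------------------------------------------------------------------


def _window_codes(s: np.ndarray, L: int, k: int) -> np.ndarray:
    """Base-L integer codes of all contiguous k-windows.

    The most recent symbol of each window occupies the lowest digit, i.e. the
    window ``(x_i, ..., x_{i+k-1})`` maps to ``sum_j x_{i+j} L^{k-1-j}``.
    Requires ``L**k`` to fit a 64-bit signed integer.
    """
    n = s.size
    c = s[: n - k + 1].astype(np.int64)
    for j in range(1, k):
        c = c * L + s[j : n - k + 1 + j]
    return c


def _codes_fit(L: int, k: int) -> bool:
    return k * math.log2(L) <= 62


def _warn_undersampled(L: int, k: int, n_windows: int) -> None:
    if L**k > n_windows / 10:
        logger.warning(
            "k-history space undersampled: L^k = %d^%d = %g exceeds one tenth "
            "of the %d available windows; plug-in entropies will be biased",
            L, k, float(L) ** k, n_windows,
        )


@dataclass(frozen=True)
class KHistoryDistribution:
    """Empirical (maximum-likelihood) distribution of k-histories.

    ``codes``/``counts`` hold the observed histories only; ``counts.sum()``
    equals ``total = N - k + 1``, the number of contiguous windows.
    """

    k: int
    n_symbols: int
    codes: np.ndarray
    counts_array: np.ndarray
    total: int

    @property
    def counts(self) -> Mapping[tuple, int]:
        """Mapping from each observed k-tuple to its occurrence count."""
        return {self._decode(c): int(n) for c, n in zip(self.codes, self.counts_array)}

    @property
    def probabilities(self) -> Mapping[tuple, float]:
        return {self._decode(c): n / self.total for c, n in zip(self.codes, self.counts_array)}

    def _decode(self, code: int) -> tuple:
        digits = []
        for _ in range(self.k):
            digits.append(int(code % self.n_symbols))
            code //= self.n_symbols
        return tuple(reversed(digits))

    @property
    def support_size(self) -> int:
        return int(self.codes.size)


def khistory_distribution(seq, k: int, n_symbols: int | None = None) -> KHistoryDistribution:
    """Count every contiguous window of length ``k`` exactly once."""
    seq = _as_sequence(seq, n_symbols)
    n, L = seq.length, seq.n_symbols
    if not (1 <= k <= n):
        raise ValueError(f"history length k={k} must satisfy 1 <= k <= N={n}")
    _warn_undersampled(L, k, n - k + 1)
    if _codes_fit(L, k):
        codes = _window_codes(seq.symbols, L, k)
        uniq, counts = np.unique(codes, return_counts=True)
    else:
        windows = np.lib.stride_tricks.sliding_window_view(seq.symbols, k)
        uw, counts = np.unique(windows, axis=0, return_counts=True)
        powers = L ** np.arange(k - 1, -1, -1, dtype=object)
        uniq = np.array([int(np.dot(row.astype(object), powers)) for row in uw])
    return KHistoryDistribution(k, L, uniq, counts, int(counts.sum()))


def shannon_entropy(dist) -> float:
    """Shannon entropy in bits with the convention ``0 log 0 = 0``.

    Accepts a :class:`KHistoryDistribution`, a probability vector, or a
    mapping of outcomes to probabilities/counts.
    """
    if isinstance(dist, KHistoryDistribution):
        weights = dist.counts_array
    elif isinstance(dist, Mapping):
        weights = np.asarray(list(dist.values()), dtype=float)
    else:
        weights = np.asarray(dist, dtype=float)
    if weights.size == 0 or np.any(weights < 0):
        raise ValueError("distribution weights must be non-negative and non-empty")
    return float(_entropy(weights, base=2))


# ---------------------------------------------------------------------------
# joint entropies and derived quantities
# ---------------------------------------------------------------------------


def _entropy_of_counts(counts: np.ndarray) -> float:
    return float(_entropy(counts, base=2))


def _history_entropies_raw(s: np.ndarray, L: int, k_max: int) -> np.ndarray:
    """Pooled joint entropies ``H_1 .. H_{k_max}`` in one incremental pass.

    Fast path used by surrogate loops; assumes ``L**k_max`` fits 64 bits.
    """
    n = s.size
    H = np.zeros(k_max + 1)
    c = s.astype(np.int64)
    for k in range(1, k_max + 1):
        if k > 1:
            c = c[:-1] * L + s[k - 1 :]
        H[k] = _entropy_of_counts(np.bincount(c, minlength=L**k))
    return H


def history_entropies(seq, k_max: int) -> np.ndarray:
    """Array ``H`` with ``H[k]`` the pooled joint entropy for ``k = 1..k_max``.

    ``H[0] = 0`` by convention.
    """
    seq = _as_sequence(seq)
    if not (1 <= k_max <= seq.length):
        raise ValueError(f"k_max={k_max} must satisfy 1 <= k_max <= N={seq.length}")
    L = seq.n_symbols
    _warn_undersampled(L, k_max, seq.length - k_max + 1)
    if _codes_fit(L, k_max) and L**k_max <= MAX_DENSE_STATES:
        return _history_entropies_raw(seq.symbols, L, k_max)
    H = np.zeros(k_max + 1)
    for k in range(1, k_max + 1):
        H[k] = shannon_entropy(khistory_distribution(seq, k))
    return H


def joint_entropy(seq, k: int) -> float:
    """Pooled plug-in joint entropy ``H_k`` in bits."""
    seq = _as_sequence(seq)
    return float(history_entropies(seq, k)[k])


def _block_marginal_entropies(seq: SymbolSequence, k: int):
    """Entropies of the aligned (k+1)-window distribution and its marginals.

    Returns ``(H_full, H_first, H_last1, H_mid)`` where the (k+1)-window is
    ``(x_n, ..., x_{n+k})``: ``first`` drops the newest symbol, ``last1`` is
    the newest symbol alone, ``mid`` drops both ends.  All four come from the
    same ``N - k`` windows, hence are mutually consistent.
    """
    L = seq.n_symbols
    if not _codes_fit(L, k + 1) or L ** (k + 1) > MAX_DENSE_STATES:
        raise ValueError(
            f"alphabet size {L} with history length {k} exceeds the dense "
            f"state cap ({MAX_DENSE_STATES}); reduce k"
        )
    c = _window_codes(seq.symbols, L, k + 1)
    h_full = _entropy_of_counts(np.bincount(c, minlength=L ** (k + 1)))
    first = np.bincount(c // L, minlength=L**k)
    h_first = _entropy_of_counts(first)
    h_last1 = _entropy_of_counts(np.bincount(c % L, minlength=L))
    h_mid = _entropy_of_counts(np.bincount((c // L) % L ** (k - 1), minlength=L ** (k - 1))) if k >= 1 else 0.0
    return h_full, h_first, h_last1, h_mid


def entropy_rate(seq, k: int, mode: str = "pooled") -> float:
    """Finite-history entropy rate ``h_k = H(X_{n+1} | X_n^{(k)})`` in bits.

    In ``"pooled"`` mode this is the difference ``H_{k+1} - H_k`` of two
    independently pooled joint entropies; in ``"consistent"`` mode both terms
    are marginals of the same (k+1)-window distribution (guaranteeing
    ``h_k >= 0``).
    """
    seq = _as_sequence(seq)
    _check_mode(mode)
    if k + 1 > seq.length:
        raise ValueError(f"entropy rate requires k + 1 <= N (k={k}, N={seq.length})")
    if mode == "pooled":
        H = history_entropies(seq, k + 1)
        return float(H[k + 1] - H[k])
    h_full, h_first, _, _ = _block_marginal_entropies(seq, k)
    return float(h_full - h_first)


def active_information_storage(seq, k: int, mode: str = "pooled") -> float:
    """Active information storage ``a_k = I(X_{n+1}; X_n^{(k)})`` in bits.

    Computed as the plug-in mutual information of the aligned (k+1)-window
    distribution; the marginal entropies come from the same window set, so
    ``a_k >= 0``.  (The two modes coincide for this quantity; the mode
    argument is kept for interface symmetry.)
    """
    seq = _as_sequence(seq)
    _check_mode(mode)
    if k + 1 > seq.length:
        raise ValueError(f"AIS requires k + 1 <= N (k={k}, N={seq.length})")
    h_full, h_first, h_last1, _ = _block_marginal_entropies(seq, k)
    return float(h_last1 + h_first - h_full)


def information_profile(seq, k_max: int, mode: str = "pooled") -> pd.DataFrame:
    """Joint entropy, entropy rate and AIS for ``k = 1..k_max``.

    Returns a DataFrame with columns ``k, H, h, a, conservation_error`` where
    ``conservation_error = H_1 - a_k - h_k`` uses the single-symbol entropy
    consistent with the chosen mode (the pooled ``H_1`` in pooled mode, the
    newest-symbol marginal of the (k+1)-window distribution in consistent
    mode).  ``df.attrs["H1"]`` holds the pooled ``H_1``.
    """
    seq = _as_sequence(seq)
    _check_mode(mode)
    if k_max + 1 > seq.length:
        raise ValueError("information profile requires k_max + 1 <= N")
    Hpool = history_entropies(seq, k_max + 1)
    rows = []
    for k in range(1, k_max + 1):
        h_full, h_first, h_last1, _ = _block_marginal_entropies(seq, k)
        a = h_last1 + h_first - h_full
        if mode == "pooled":
            h = Hpool[k + 1] - Hpool[k]
            err = Hpool[1] - a - h
        else:
            h = h_full - h_first
            err = h_last1 - a - h
        rows.append((k, Hpool[k], h, a, err))
    df = pd.DataFrame(rows, columns=["k", "H", "h", "a", "conservation_error"])
    df.attrs["H1"] = float(Hpool[1])
    df.attrs["mode"] = mode
    return df


# ---------------------------------------------------------------------------
# sequence file I/O
# ---------------------------------------------------------------------------


def read_sequence(path) -> SymbolSequence:
    """Read a symbol sequence from plain text.

    Accepts one integer per line or a single delimited row (comma or
    whitespace).  A comment line ``# L=4`` declares the alphabet size;
    otherwise it is inferred as ``max + 1``.
    """
    path = Path(path)
    declared_L: int | None = None
    values: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").replace(" ", "")
                if body.upper().startswith("L="):
                    try:
                        declared_L = int(body[2:])
                    except ValueError as exc:
                        raise SequenceFormatError(
                            f"{path}:{lineno}: malformed alphabet header {stripped!r}"
                        ) from exc
                continue
            tokens = stripped.replace(",", " ").split()
            for tok in tokens:
                try:
                    values.append(int(tok))
                except ValueError as exc:
                    raise SequenceFormatError(
                        f"{path}:{lineno}: expected an integer symbol, got {tok!r}"
                    ) from exc
    if not values:
        raise SequenceFormatError(f"{path}: no symbols found")
    arr = np.asarray(values, dtype=np.int64)
    L = declared_L if declared_L is not None else int(arr.max()) + 1
    try:
        return SymbolSequence(arr, L)
    except ValueError as exc:
        raise SequenceFormatError(f"{path}: {exc}") from exc


def write_sequence(seq: SymbolSequence, path, header: bool = True) -> None:
    """Write one symbol per line, with an alphabet-size header comment."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write(f"# L={seq.n_symbols}\n")
        np.savetxt(fh, seq.symbols, fmt="%d")


def read_values(path) -> np.ndarray:
    """Read a real-valued series (one float per line, or one delimited row)."""
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            for tok in stripped.replace(",", " ").split():
                try:
                    values.append(float(tok))
                except ValueError as exc:
                    raise SequenceFormatError(
                        f"{path}:{lineno}: expected a number, got {tok!r}"
                    ) from exc
    if not values:
        raise SequenceFormatError(f"{path}: no values found")
    return np.asarray(values, dtype=float)


def write_values(x: np.ndarray, path) -> None:
    np.savetxt(Path(path), np.asarray(x, dtype=float), fmt="%.10g")
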