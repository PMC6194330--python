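"""Order-M Markov transition models: estimation, sampling, closed forms.

A stationary Markov process of order M over L symbols is specified by a
transition table of shape ``(L**M, L)``: one next-symbol distribution per
M-history.  Histories are indexed by their base-L code with the most recent
symbol in the lowest digit (the serialization convention; see
:meth:`TransitionModel.to_text`).

The module provides

* maximum-likelihood estimation of the table from data (the basis of the
  Markov surrogates used by the conditional-entropy order test),
* reproducible inverse-CDF sampling, with the first M symbols drawn from the
  empirical M-history distribution,
* exact closed forms for the two-state first-order chain (entropy,
  entropy rate, active information storage), and
* the two higher-order test processes: a fully random order-3 chain and a
  "lag-skipping" order-3 chain whose transition depends only on the symbol
  three steps back, which imprints a period-3 autoinformation signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .seq_core import SymbolSequence, _as_sequence, _window_codes

logger = logging.getLogger("autoinfo")


# ---------------------------------------------------------------------------
# sampling kernel
# ---------------------------------------------------------------------------


@njit(cache=False)
def _sample_markov_kernel(cdf, valid, hist_cdf, L, M, n, seed):
    """Sequential inverse-CDF sampler for an order-M chain.

    ``cdf`` has shape (L**M, L) with each valid row a cumulative next-symbol
    distribution ending at 1; ``hist_cdf`` is the cumulative M-history
    distribution used for initialization and for restarting when an
    unobserved history is reached.  Returns the symbols and the number of
    restarts.
    """
    np.random.seed(seed)
    out = np.empty(n, dtype=np.int64)
    n_states = cdf.shape[0]
    # initial M-history
    code = 0
    if M > 0:
        r = np.random.random()
        code = np.searchsorted(hist_cdf, r, side="right")
        if code >= n_states:
            code = n_states - 1
        c = code
        for j in range(M - 1, -1, -1):
            out[j] = c % L
            c //= L
    n_restarts = 0
    for t in range(M, n):
        if not valid[code]:
            r = np.random.random()
            code = np.searchsorted(hist_cdf, r, side="right")
            if code >= n_states:
                code = n_states - 1
            n_restarts += 1
        r = np.random.random()
        row = cdf[code]
        s = 0
        while s < L - 1 and row[s] <= r:
            s += 1
        out[t] = s
        code = (code * L + s) % n_states
    return out, n_restarts


# ---------------------------------------------------------------------------
# TransitionModel
# ---------------------------------------------------------------------------


@dataclass
class TransitionModel:
    """Transition probability table of an order-M chain over L symbols.

    ``table[h, j]`` is ``P(X_{n+1} = j | history code h)``; rows belonging to
    histories never observed during estimation are NaN and flagged in
    ``observed``.  ``history_probs`` is the M-history distribution used to
    initialize sample paths.  ``M = 0`` reduces to an iid symbol model with a
    single table row.
    """

    n_symbols: int
    order: int
    table: np.ndarray
    history_probs: np.ndarray | None = None
    observed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        L, M = int(self.n_symbols), int(self.order)
        if L < 2 or M < 0:
            raise ValueError("need n_symbols >= 2 and order >= 0")
        table = np.asarray(self.table, dtype=float)
        if table.shape != (L**M, L):
            raise ValueError(f"table must have shape ({L**M}, {L}), got {table.shape}")
        if self.observed is None:
            self.observed = ~np.isnan(table).any(axis=1)
        rows = table[self.observed]
        if rows.size:
            if np.nanmin(rows) < -1e-12 or np.nanmax(rows) > 1 + 1e-12:
                raise ValueError("transition probabilities must lie in [0, 1]")
            if np.max(np.abs(rows.sum(axis=1) - 1.0)) > 1e-12:
                raise ValueError("each observed table row must sum to 1")
        if self.history_probs is None:
            self.history_probs = lifted_stationary_distribution(table, L, M)
        hp = np.asarray(self.history_probs, dtype=float)
        if hp.shape != (L**M,) or abs(hp.sum() - 1.0) > 1e-9 or hp.min() < -1e-12:
            raise ValueError("history_probs must be a distribution over L**M histories")
        self.table = table
        self.history_probs = hp
        self.n_symbols, self.order = L, M

    def sample(self, n: int, seed: int | None = None) -> SymbolSequence:
        return sample_markov(self, n, seed)

    # -- serialization ------------------------------------------------------

    def to_text(self, path) -> None:
        L, M = self.n_symbols, self.order
        with Path(path).open("w") as fh:
            fh.write("# order-M Markov transition table\n")
            fh.write(f"# L={L} M={M}\n")
            fh.write("# rows: histories in base-L lexicographic order, most recent "
                     "symbol in the lowest digit\n")
            fh.write("# history_probs: " + " ".join(f"{p:.17g}" for p in self.history_probs) + "\n")
            for row in self.table:
                fh.write(" ".join(f"{p:.17g}" for p in row) + "\n")

    @classmethod
    def from_text(cls, path) -> "TransitionModel":
        L = M = None
        history_probs = None
        rows = []
        with Path(path).open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if body.startswith("L="):
                        parts = dict(tok.split("=") for tok in body.split())
                        L, M = int(parts["L"]), int(parts["M"])
                    elif body.startswith("history_probs:"):
                        history_probs = np.array(
                            [float(t) for t in body.split(":", 1)[1].split()]
                        )
                    continue
                rows.append([float(t) for t in line.split()])
        if L is None:
            raise ValueError(f"{path}: missing '# L=... M=...' header")
        return cls(L, M, np.asarray(rows), history_probs)


def lifted_stationary_distribution(table: np.ndarray, L: int, M: int) -> np.ndarray:
    """Stationary distribution of M-histories under the lifted chain.

    The order-M chain induces a first-order chain on history codes
    (``h -> (h*L + s) mod L**M`` with probability ``table[h, s]``); the
    leading left eigenvector gives the stationary history distribution.
    Unobserved (NaN) rows are treated as unreachable and get weight zero.
    """
    n_states = L**M
    if M == 0:
        return np.ones(1)
    T = np.zeros((n_states, n_states))
    for h in range(n_states):
        row = table[h]
        if np.isnan(row).any():
            continue
        for s in range(L):
            T[h, (h * L + s) % n_states] += row[s]
    # power iteration on the stochastic (sub-stochastic for invalid rows) matrix
    v = np.full(n_states, 1.0 / n_states)
    for _ in range(10_000):
        nxt = v @ T
        total = nxt.sum()
        if total <= 0:
            raise ValueError("transition table has no recurrent histories")
        nxt /= total
        if np.abs(nxt - v).max() < 1e-14:
            v = nxt
            break
        v = nxt
    v[v < 0] = 0.0
    return v / v.sum()


# ---------------------------------------------------------------------------
# estimation and sampling
# ---------------------------------------------------------------------------


def estimate_transition_model(seq, M: int) -> TransitionModel:
    """Maximum-likelihood order-M transition table from a symbol sequence.

    Counts all contiguous (M+1)-tuples; ``table[h, j] = #(h, j) / #(h)``.
    The M-history distribution is recorded from the same pass.  Histories
    never observed are left NaN and flagged: sampling restarts from the
    history distribution if such a row is ever reached.
    """
    seq = _as_sequence(seq)
    L, n = seq.n_symbols, seq.length
    if M < 0:
        raise ValueError("order M must be >= 0")
    if M + 1 > n:
        raise ValueError(f"estimating order {M} requires at least M + 1 = {M + 1} symbols")
    if (M + 1) * np.log2(L) > 62:
        raise ValueError(f"L**(M+1) = {L}**{M + 1} exceeds the integer coding range")
    codes = _window_codes(seq.symbols, L, M + 1)
    counts = np.bincount(codes, minlength=L ** (M + 1)).reshape(L**M, L).astype(float)
    row_sums = counts.sum(axis=1)
    observed = row_sums > 0
    table = np.full_like(counts, np.nan)
    table[observed] = counts[observed] / row_sums[observed, None]
    history_probs = row_sums / row_sums.sum()
    if not observed.all():
        logger.info(
            "%d of %d order-%d histories unobserved; their rows are flagged invalid",
            int((~observed).sum()), observed.size, M,
        )
    return TransitionModel(L, M, table, history_probs, observed)


def sample_markov(model: TransitionModel, n: int, seed: int | None = None) -> SymbolSequence:
    """Draw ``n`` symbols from an order-M transition model.

    The first M symbols are a draw from the model's history distribution;
    each subsequent symbol is drawn from the row of the current M-history by
    cumulative-sum inversion.  If an unobserved history is reached (possible
    when the estimation sample ended in a unique context) the current history
    is redrawn from the history distribution and the event is logged.
    """
    if n <= model.order:
        raise ValueError(f"sample length n={n} must exceed the model order {model.order}")
    cdf = np.cumsum(np.nan_to_num(model.table, nan=0.0), axis=1)
    cdf[model.observed, -1] = 1.0
    hist_cdf = np.cumsum(model.history_probs)
    hist_cdf[-1] = 1.0
    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    symbols, n_restarts = _sample_markov_kernel(
        cdf, model.observed, hist_cdf, model.n_symbols, model.order, int(n), kernel_seed
    )
    if n_restarts:
        logger.info("markov sampler restarted %d time(s) at unobserved histories", n_restarts)
    return SymbolSequence(symbols, model.n_symbols)


# ---------------------------------------------------------------------------
# two-state closed forms
# ---------------------------------------------------------------------------


def _phi(x: float) -> float:
    """phi(x) = -x log2 x, with phi(0) = 0."""
    return 0.0 if x <= 0.0 else -x * np.log2(x)


def _psi(x: float) -> float:
    """Binary entropy psi(x) = phi(x) + phi(1 - x) in bits."""
    return _phi(x) + _phi(1.0 - x)


@dataclass(frozen=True)
class TwoStateAnalytics:
    """Closed-form information quantities of the two-state first-order chain.

    With switching rates ``p`` (A to B) and ``q`` (B to A) the stationary
    distribution is ``(p_A, p_B) = (q, p) / (p + q)`` and

        H = psi(p_A),   h = p_A psi(p) + p_B psi(q),   a = H - h,

    so the conservation ``H = a + h`` holds exactly.
    """

    p: float
    q: float
    transition_matrix: np.ndarray
    eigenvalues: tuple[float, float]
    stationary: tuple[float, float]
    entropy: float
    entropy_rate: float
    active_information_storage: float


def two_state_analytics(p: float, q: float) -> TwoStateAnalytics:
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ValueError("rates p, q must lie in [0, 1]")
    if p + q == 0.0:
        raise ValueError("p = q = 0 admits no unique stationary distribution")
    p_a = q / (p + q)
    p_b = p / (p + q)
    H = _psi(p_a)
    h = p_a * _psi(p) + p_b * _psi(q)
    a = H - h
    T = np.array([[1.0 - p, p], [q, 1.0 - q]])
    return TwoStateAnalytics(
        p=p, q=q, transition_matrix=T,
        eigenvalues=(1.0, 1.0 - (p + q)),
        stationary=(p_a, p_b),
        entropy=H, entropy_rate=h, active_information_storage=a,
    )


def two_state_model(p: float, q: float) -> TransitionModel:
    """The two-state chain as an order-1 :class:`TransitionModel`."""
    ana = two_state_analytics(p, q)
    return TransitionModel(2, 1, ana.transition_matrix, np.array(ana.stationary))


# ---------------------------------------------------------------------------
# synthetic higher-order processes
# ---------------------------------------------------------------------------


def random_transition_model(
    L: int, M: int, seed: int | None = None, method: str = "uniform"
) -> TransitionModel:
    """Order-M model with independently random next-symbol distributions.

    ``method="uniform"`` draws each row as normalized iid uniform variates;
    ``method="dirichlet"`` draws flat-Dirichlet rows.  The history
    distribution is the stationary distribution of the lifted chain, so
    sample paths start in equilibrium.
    """
    if L < 2 or M < 1:
        raise ValueError("need L >= 2 and M >= 1")
    rng = np.random.default_rng(seed)
    if method == "uniform":
        rows = rng.random((L**M, L))
    elif method == "dirichlet":
        rows = rng.dirichlet(np.ones(L), size=L**M)
    else:
        raise ValueError("method must be 'uniform' or 'dirichlet'")
    rows = rows / rows.sum(axis=1, keepdims=True)
    return TransitionModel(L, M, rows)


def lag_skipping_model(
    L: int = 3, seed: int | None = None, min_separation: float = 0.2
) -> TransitionModel:
    """Order-3 model whose transition depends only on the symbol 3 steps back.

    All rows sharing the oldest history symbol ``x_{n-2}`` are identical, so
    the chain splits into three interleaved first-order chains and the
    autoinformation function acquires period 3, while the PAIF shows a single
    peak at lag 3.  The ``L`` next-symbol distributions are rejection-sampled
    until every pair is at least ``min_separation`` apart in total variation,
    making the dependence statistically detectable.
    """
    if L < 2:
        raise ValueError("need L >= 2")
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        conds = rng.random((L, L))
        conds /= conds.sum(axis=1, keepdims=True)
        tv = min(
            0.5 * np.abs(conds[i] - conds[j]).sum()
            for i in range(L) for j in range(i + 1, L)
        )
        if tv >= min_separation:
            break
    else:
        raise RuntimeError("could not draw sufficiently separated conditionals")
    # history code digits (M=3): d2 = x_{n-2} (oldest), d1 = x_{n-1}, d0 = x_n
    table = np.empty((L**3, L))
    for h in range(L**3):
        table[h] = conds[h // L**2]
    return TransitionModel(L, 3, table)
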