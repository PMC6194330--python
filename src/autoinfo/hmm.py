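"""Edge-emitting hidden Markov machines.

A probabilistic finite-state machine whose transitions each carry a
probability and an emitted observable symbol.  The hidden states follow a
first-order Markov chain, but the emitted symbol sequence need not be Markov
of any finite order — which is exactly what makes these machines useful test
beds for Markov-order diagnostics:

* :func:`even_process` — binary machine that emits 1s only in blocks of even
  length; the emitted process has no finite Markov order.
* :func:`golden_mean_2state` — the golden-mean process (no two consecutive
  1s) in its 2-hidden-state presentation; the emitted process is first-order
  Markov with transition matrix [[1/2, 1/2], [1, 0]].
* :func:`golden_mean_7state` — a 7-hidden-state machine whose emitted
  process also has golden-mean support but is exactly fourth-order Markov:
  the probability of emitting a 1 depends on the number of trailing zeros,
  capped at four.  (A constructed presentation; see the data file and
  docs/methods.md.)

Sampling starts from the stationary distribution of the hidden chain by
default, so emitted sequences carry no transient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np
from numba import njit

from .seq_core import SymbolSequence

logger = logging.getLogger("autoinfo")


class Edge(NamedTuple):
    source: str
    target: str
    probability: float
    symbol: int


@njit(cache=False)
def _sample_hmm_kernel(edge_cdf, edge_target, edge_symbol, out_degree, start_cdf, n, seed):
    np.random.seed(seed)
    out = np.empty(n, dtype=np.int64)
    r = np.random.random()
    state = np.searchsorted(start_cdf, r, side="right")
    if state >= start_cdf.size:
        state = start_cdf.size - 1
    for t in range(n):
        r = np.random.random()
        e = 0
        last = out_degree[state] - 1
        while e < last and edge_cdf[state, e] <= r:
            e += 1
        out[t] = edge_symbol[state, e]
        state = edge_target[state, e]
    return out


@dataclass
class HiddenMarkovMachine:
    """Finite-state machine with probabilistic, symbol-emitting edges."""

    states: tuple[str, ...]
    edges: tuple[Edge, ...]
    n_observables: int
    start_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.edges = tuple(Edge(*e) for e in self.edges)
        index = {s: i for i, s in enumerate(self.states)}
        if len(index) != len(self.states):
            raise ValueError("duplicate state names")
        out_p = np.zeros(len(self.states))
        for e in self.edges:
            if e.source not in index or e.target not in index:
                raise ValueError(f"edge {e} references an unknown state")
            if not (0.0 <= e.probability <= 1.0):
                raise ValueError(f"edge probability out of range: {e}")
            if not (0 <= int(e.symbol) < self.n_observables):
                raise ValueError(f"emitted symbol out of range: {e}")
            out_p[index[e.source]] += e.probability
        if np.max(np.abs(out_p - 1.0)) > 1e-12:
            raise ValueError("outgoing edge probabilities must sum to 1 for every state")
        if self.start_distribution is None:
            self.start_distribution = self.stationary_distribution()
        sd = np.asarray(self.start_distribution, dtype=float)
        if sd.shape != (len(self.states),) or abs(sd.sum() - 1.0) > 1e-9:
            raise ValueError("start_distribution must be a distribution over the states")
        self.start_distribution = sd

    @property
    def n_states(self) -> int:
        return len(self.states)

    def _state_index(self) -> dict:
        return {s: i for i, s in enumerate(self.states)}

    def hidden_transition_matrix(self) -> np.ndarray:
        idx = self._state_index()
        T = np.zeros((self.n_states, self.n_states))
        for e in self.edges:
            T[idx[e.source], idx[e.target]] += e.probability
        return T

    def stationary_distribution(self) -> np.ndarray:
        """Leading left eigenvector of the hidden transition matrix."""
        T = self.hidden_transition_matrix()
        w, v = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        vec = np.real(v[:, i])
        vec = np.abs(vec)
        return vec / vec.sum()

    def is_strongly_connected(self) -> bool:
        idx = self._state_index()
        fwd = {i: set() for i in range(self.n_states)}
        bwd = {i: set() for i in range(self.n_states)}
        for e in self.edges:
            if e.probability > 0:
                fwd[idx[e.source]].add(idx[e.target]); bwd[idx[e.target]].add(idx[e.source])

        def reach(adj):
            seen, stack = {0}, [0]
            while stack:
                for j in adj[stack.pop()]:
                    if j not in seen:
                        seen.add(j); stack.append(j)
            return seen

        return len(reach(fwd)) == self.n_states and len(reach(bwd)) == self.n_states

    def emission_matrices(self) -> np.ndarray:
        """Array ``A[sym, i, j]``: probability of edge i -> j emitting sym."""
        idx = self._state_index()
        A = np.zeros((self.n_observables, self.n_states, self.n_states))
        for e in self.edges:
            A[int(e.symbol), idx[e.source], idx[e.target]] += e.probability
        return A

    # -- serialization ------------------------------------------------------

    def to_text(self, path) -> None:
        with Path(path).open("w") as fh:
            fh.write("# edge-emitting hidden Markov machine\n")
            fh.write("# states: " + " ".join(self.states) + "\n")
            fh.write(f"# n_observables: {self.n_observables}\n")
            fh.write("# edges: source target probability symbol\n")
            for e in self.edges:
                fh.write(f"{e.source} {e.target} {e.probability:.17g} {e.symbol}\n")

    @classmethod
    def from_text(cls, path_or_lines) -> "HiddenMarkovMachine":
        if isinstance(path_or_lines, (str, Path)):
            lines = Path(path_or_lines).read_text().splitlines()
        else:
            lines = list(path_or_lines)
        states: tuple[str, ...] | None = None
        n_obs: int | None = None
        edges = []
        for line in lines:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("states:"):
                    states = tuple(body.split(":", 1)[1].split())
                elif body.startswith("n_observables:"):
                    n_obs = int(body.split(":", 1)[1])
                continue
            src, dst, prob, sym = line.split()
            edges.append(Edge(src, dst, float(prob), int(sym)))
        if states is None or n_obs is None:
            raise ValueError("machine text must declare '# states:' and '# n_observables:'")
        return cls(states, tuple(edges), n_obs)


# ---------------------------------------------------------------------------
# sampling and exact word probabilities
# ---------------------------------------------------------------------------


def _kernel_arrays(machine: HiddenMarkovMachine):
    idx = machine._state_index()
    S = machine.n_states
    per_state: list[list[Edge]] = [[] for _ in range(S)]
    for e in machine.edges:
        if e.probability > 0:
            per_state[idx[e.source]].append(e)
    max_deg = max(len(es) for es in per_state)
    cdf = np.ones((S, max_deg))
    target = np.zeros((S, max_deg), dtype=np.int64)
    symbol = np.zeros((S, max_deg), dtype=np.int64)
    degree = np.zeros(S, dtype=np.int64)
    for i, es in enumerate(per_state):
        acc = 0.0
        degree[i] = len(es)
        for j, e in enumerate(es):
            acc += e.probability
            cdf[i, j] = acc
            target[i, j] = idx[e.target]
            symbol[i, j] = int(e.symbol)
        cdf[i, len(es) - 1] = 1.0
    return cdf, target, symbol, degree


def sample_hmm(machine: HiddenMarkovMachine, n: int, seed: int | None = None) -> SymbolSequence:
    """Emit ``n`` observable symbols from the machine.

    The hidden start state is drawn from ``start_distribution``; at each step
    an outgoing edge is drawn by cumulative inversion, its symbol appended
    and its target state entered.  Reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    cdf, target, symbol, degree = _kernel_arrays(machine)
    start_cdf = np.cumsum(machine.start_distribution)
    start_cdf[-1] = 1.0
    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    out = _sample_hmm_kernel(cdf, target, symbol, degree, start_cdf, int(n), kernel_seed)
    return SymbolSequence(out, machine.n_observables)


def sample_words(
    machine: HiddenMarkovMachine, word_length: int, n_words: int, seed: int | None = None
) -> np.ndarray:
    """Independent emitted words, each restarted from the start distribution.

    Returns an ``(n_words, word_length)`` integer array; used to compare
    sampled word frequencies against :func:`word_probability`.
    """
    rng = np.random.default_rng(seed)
    cdf, target, symbol, degree = _kernel_arrays(machine)
    start_cdf = np.cumsum(machine.start_distribution)
    start_cdf[-1] = 1.0
    out = np.empty((n_words, word_length), dtype=np.int64)
    for i in range(n_words):
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        out[i] = _sample_hmm_kernel(cdf, target, symbol, degree, start_cdf, word_length, kernel_seed)
    return out


def word_probability(machine: HiddenMarkovMachine, word) -> float:
    """Exact probability of an emitted word via the forward recursion.

    Sums path probabilities over all hidden trajectories:
    ``P(word) = start @ A[w_0] @ ... @ A[w_{m-1}] @ 1``.
    """
    A = machine.emission_matrices()
    v = np.asarray(machine.start_distribution, dtype=float).copy()
    for sym in word:
        v = v @ A[int(sym)]
    return float(v.sum())


# ---------------------------------------------------------------------------
# the shipped machines
# ---------------------------------------------------------------------------


def even_process() -> HiddenMarkovMachine:
    """Binary machine emitting 1s only in pairs (even-length blocks).

    From state A: emit 0 and stay (p = 1/2) or emit 1 and move to B
    (p = 1/2); B always emits a second 1 and returns to A.  The emitted
    process has dependencies reaching arbitrarily far back (no finite Markov
    order): any run of 1s must be completed to even length.

    Sampling starts deterministically in A (a block boundary): a stationary
    hidden start could begin mid-pair and emit a lone leading 1, breaking
    the parity invariant.  Only the final run of a finite sample can be
    truncated to odd length.
    """
    edges = (
        Edge("A", "A", 0.5, 0),
        Edge("A", "B", 0.5, 1),
        Edge("B", "A", 1.0, 1),
    )
    return HiddenMarkovMachine(("A", "B"), edges, 2,
                               start_distribution=np.array([1.0, 0.0]))


def golden_mean_2state() -> HiddenMarkovMachine:
    """Golden-mean process, 2-state presentation: no two consecutive 1s.

    From A: emit 0 and stay (p = 1/2) or emit 1 and move to B (p = 1/2);
    B always emits 0 and returns to A.  The emitted process is first-order
    Markov with transition matrix [[1/2, 1/2], [1, 0]] and stationary symbol
    distribution (2/3, 1/3).
    """
    edges = (
        Edge("A", "A", 0.5, 0),
        Edge("A", "B", 0.5, 1),
        Edge("B", "A", 1.0, 0),
    )
    return HiddenMarkovMachine(("A", "B"), edges, 2)


def golden_mean_7state() -> HiddenMarkovMachine:
    """Golden-mean-support process of exact Markov order 4, 7 hidden states.

    Loaded from the packaged edge list (a synthetic presentation constructed
    for this package: the probability of emitting a 1 depends on the number
    of trailing zeros, capped at four, so histories differing only four
    steps back have different transition laws).  Swap the data file to use
    an alternative presentation.
    """
    ref = resources.files("autoinfo.data").joinpath("golden_mean_7state_synthetic.txt")
    return HiddenMarkovMachine.from_text(ref.read_text().splitlines())
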