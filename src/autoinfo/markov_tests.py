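"""Hypothesis tests for the Markov order of a symbolic sequence.

Two families of tests are provided.

**Likelihood-ratio (G) tests of low order.**  The order-m test compares the
hypothesis "the process is Markov of order m" against order m + 1 dependence
using the G statistic on (m+2)-tuple counts,

    G = 2 sum n_w ln( n_w * n_mid / (n_left * n_right) ),

where for each (m+2)-tuple ``w`` the marginals drop the newest symbol
(``left``), the oldest symbol (``right``) or both (``mid``).  Under the null
G is asymptotically chi-square with ``L**m (L-1)**2`` degrees of freedom.
For m = 0 this reduces to the classical independence test on the lag-one
contingency table.  Zero cells contribute zero (the ``n ln n -> 0``
continuity convention).

**Conditional-entropy surrogate test.**  For each candidate order
M = 0..M_max, the order-M transition table is ML-estimated from the data and
used to generate Markov surrogates of the same length; the finite-history
entropy rates ``h_k`` (k = 1..k_max) of the data are compared with the
empirical alpha/2..1-alpha/2 percentile band of the surrogate ``h_k``.  The
identified order is the smallest M whose band contains every data ``h_k``;
if no M <= M_max qualifies the report carries the sentinel ``None``
(printed as ``none <= M_max``) — the signature of a process with no low
finite Markov order, such as the even process.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .markov import estimate_transition_model, sample_markov
from .seq_core import _as_sequence, _history_entropies_raw, _window_codes, _warn_undersampled

logger = logging.getLogger("autoinfo")


@dataclass
class TestReport:
    """Outcome of a Markovianity test.

    For likelihood-ratio tests ``statistic``, ``dof`` and ``p_value`` are
    set; for the conditional-entropy test ``identified_order`` (None when no
    order <= M_max is accepted) and the per-(M, k) ``surrogate_summary``
    table are set.
    """

    test_name: str
    statistic: float | None = None
    dof: int | None = None
    p_value: float | None = None
    identified_order: int | None = None
    m_max: int | None = None
    surrogate_summary: pd.DataFrame | None = None
    alpha: float | None = None
    n_surrogates: int | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def order_label(self) -> str:
        if self.m_max is None:
            return ""
        return str(self.identified_order) if self.identified_order is not None else f"none <= {self.m_max}"

    def to_dict(self) -> dict:
        out = {"test_name": self.test_name}
        for key in ("statistic", "dof", "p_value", "identified_order", "m_max",
                    "alpha", "n_surrogates", "seed"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        if self.m_max is not None:
            out["order_label"] = self.order_label
        if self.surrogate_summary is not None:
            out["surrogate_summary"] = self.surrogate_summary.to_dict(orient="records")
        out.update(self.extras)
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [f"test: {self.test_name}"]
        if self.statistic is not None:
            lines.append(f"statistic: {self.statistic:.6g}")
            lines.append(f"dof: {self.dof}")
            lines.append(f"p_value: {self.p_value:.6g}")
        if self.m_max is not None:
            lines.append(f"identified_order: {self.order_label}")
            lines.append(f"alpha: {self.alpha}")
            lines.append(f"n_surrogates: {self.n_surrogates}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Kullback-style likelihood-ratio tests
# ---------------------------------------------------------------------------


def kullback_markov_test(seq, order: int) -> TestReport:
    """G test of Markov order ``order`` (0, 1 or 2) against one order higher.

    A small p-value rejects the hypothesis that dependencies of range
    ``order`` fully explain the (order+2)-tuple counts.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    seq = _as_sequence(seq)
    L, n = seq.n_symbols, seq.length
    m = order
    w = m + 2
    if n < w:
        raise ValueError(f"need at least {w} symbols for the order-{m} test")
    n_cells = L**w
    n_windows = n - w + 1
    if n_cells > 5 * n_windows:
        logger.warning(
            "order-%d test: expected cell counts below 1 (%d cells, %d windows)",
            m, n_cells, n_windows,
        )
    elif n_cells > n_windows:
        logger.warning(
            "order-%d test: expected cell counts below 5 (%d cells, %d windows)",
            m, n_cells, n_windows,
        )
    counts = np.bincount(_window_codes(seq.symbols, L, w), minlength=n_cells)
    counts = counts.reshape((L,) * w).astype(float)
    left = counts.sum(axis=-1)                       # drop newest symbol
    right = counts.sum(axis=0)                       # drop oldest symbol
    mid = counts.sum(axis=(0, -1)) if m > 0 else counts.sum()
    nz = counts > 0
    # log-ratio over non-zero cells; marginals are strictly positive there
    lw = np.zeros_like(counts)
    idx = np.nonzero(nz)
    left_b = np.broadcast_to(left[..., None], counts.shape)
    right_b = np.broadcast_to(right[None, ...], counts.shape)
    if m > 0:
        mid_b = np.broadcast_to(mid[None, ..., None], counts.shape)
    else:
        mid_b = np.broadcast_to(np.asarray(mid), counts.shape)
    lw[idx] = counts[idx] * np.log(
        counts[idx] * mid_b[idx] / (left_b[idx] * right_b[idx])
    )
    G = 2.0 * float(lw.sum())
    dof = int(L**m * (L - 1) ** 2)
    p = float(chi2.sf(G, dof))
    return TestReport(
        test_name=f"kullback-order-{m}", statistic=G, dof=dof, p_value=p,
        extras={"n_symbols": L, "window_length": w},
    )


# ---------------------------------------------------------------------------
# conditional-entropy surrogate test
# ---------------------------------------------------------------------------


def conditional_entropy_test(
    seq,
    M_max: int = 5,
    k_max: int | None = None,
    n_surrogates: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
) -> TestReport:
    """Markov-order identification by comparison with order-M surrogates.

    For each M in 0..M_max an order-M transition model is fitted and
    ``n_surrogates`` surrogate sequences of the data's length are sampled
    from it; the data's entropy rates ``h_k`` for k = 1..k_max are compared
    with the per-(M, k) empirical percentile band of the surrogates.  The
    identified order is the smallest M accepted at every k.  ``k_max``
    defaults to ``M_max + 1``, the smallest range that can discriminate all
    candidate orders.
    """
    seq = _as_sequence(seq)
    if M_max < 0:
        raise ValueError("M_max must be >= 0")
    if k_max is None:
        k_max = M_max + 1
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    L, n = seq.n_symbols, seq.length
    if (k_max + 1) * np.log2(L) > 62:
        raise ValueError("L**(k_max+1) exceeds the integer coding range; reduce k_max")
    _warn_undersampled(L, k_max + 1, n - k_max)
    data_H = _history_entropies_raw(seq.symbols, L, k_max + 1)
    data_h = np.diff(data_H[1:])  # h_k = H_{k+1} - H_k, k = 1..k_max
    ks = np.arange(1, k_max + 1)
    root = np.random.SeedSequence(seed)
    rows = []
    accepted = []
    for M, child in zip(range(M_max + 1), root.spawn(M_max + 1)):
        model = estimate_transition_model(seq, M)
        h_surr = np.empty((n_surrogates, k_max))
        for i, sseq in enumerate(child.spawn(n_surrogates)):
            surr_seed = int(sseq.generate_state(1)[0] % (2**31 - 1))
            surr = sample_markov(model, n, surr_seed)
            H = _history_entropies_raw(surr.symbols, L, k_max + 1)
            h_surr[i] = np.diff(H[1:])
        lo = np.quantile(h_surr, alpha / 2.0, axis=0)
        hi = np.quantile(h_surr, 1.0 - alpha / 2.0, axis=0)
        inside = (data_h >= lo) & (data_h <= hi)
        accepted.append(bool(inside.all()))
        for k, l, h, d, ok in zip(ks, lo, hi, data_h, inside):
            rows.append((M, int(k), l, h, d, bool(ok)))
    summary = pd.DataFrame(
        rows, columns=["M", "k", "ci_low", "ci_high", "data_h", "inside"]
    )
    identified = next((M for M, ok in enumerate(accepted) if ok), None)
    return TestReport(
        test_name="conditional-entropy",
        identified_order=identified,
        m_max=M_max,
        surrogate_summary=summary,
        alpha=alpha,
        n_surrogates=n_surrogates,
        seed=seed,
        extras={"k_max": int(k_max), "n": int(n)},
    )
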