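"""Physics-flavoured symbol sources: 2D Ising spins and a double-well channel.

Two simulators produce binary sequences with qualitatively different memory
structure:

* A single lattice site of a 2D Ising model under Gibbs (heat-bath)
  dynamics.  Far above the critical temperature the site series decorrelates
  within a few sweeps; at the critical temperature
  ``T_c = 2 / ln(1 + sqrt(2)) ~ 2.269`` the autoinformation decays as a
  power law (critical slowing down) and the partial autoinformation stays
  significant over many lags — long-range, non-Markovian memory.

* An overdamped particle in the double-well potential
  ``V(x) = -(a/2) x^2 + (b/4) x^4`` driven by per-step Gaussian noise — a
  minimal model of a two-state ion channel.  Thresholding the trajectory at
  zero maps it to open/closed symbols whose dynamics are diagnosed as
  first-order Markov by the PAIF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .seq_core import SymbolSequence

logger = logging.getLogger("autoinfo")

#: Onsager critical temperature of the square-lattice Ising model (J = k_B = 1)
T_CRITICAL = 2.0 / math.log(1.0 + math.sqrt(2.0))


# ---------------------------------------------------------------------------
# Ising model
# ---------------------------------------------------------------------------


@dataclass
class IsingConfig:
    """Gibbs-sampled 2D Ising lattice, recorded one value per raster sweep.

    ``n_sweeps`` full-lattice sweeps are recorded after ``burn_in`` discarded
    sweeps; temperature is in units of the coupling (J = k_B = 1).
    """

    temperature: float
    lattice_side: int = 50
    n_sweeps: int = 1_000_000
    burn_in: int = 10_000
    record_site: tuple[int, int] = (0, 0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lattice_side < 2:
            raise ValueError("lattice_side must be >= 2")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.burn_in < 0 or self.n_sweeps < 1:
            raise ValueError("need burn_in >= 0 and n_sweeps >= 1")
        ri, rj = self.record_site
        if not (0 <= ri < self.lattice_side and 0 <= rj < self.lattice_side):
            raise ValueError("record_site must lie on the lattice")


@njit(cache=False)
def _ising_gibbs_kernel(side, beta, n_sweeps, burn_in, ri, rj, seed, record_config):
    """Raster-scan heat-bath sweeps with periodic boundaries.

    Each site is set to +1 with probability ``1 / (1 + exp(-2 beta h))``
    where ``h`` is the sum of its four neighbours.  Records, per sweep after
    burn-in, either the spin at (ri, rj) mapped to {0, 1} or (for tiny
    lattices) the full configuration encoded as a bit pattern.
    """
    np.random.seed(seed)
    spins = np.empty((side, side), dtype=np.int8)
    for i in range(side):
        for j in range(side):
            spins[i, j] = 1 if np.random.random() < 0.5 else -1
    out = np.empty(n_sweeps, dtype=np.int64)
    for sweep in range(burn_in + n_sweeps):
        for i in range(side):
            for j in range(side):
                h = (
                    spins[(i + 1) % side, j]
                    + spins[(i - 1) % side, j]
                    + spins[i, (j + 1) % side]
                    + spins[i, (j - 1) % side]
                )
                p_up = 1.0 / (1.0 + np.exp(-2.0 * beta * h))
                spins[i, j] = 1 if np.random.random() < p_up else -1
        t = sweep - burn_in
        if t >= 0:
            if record_config:
                code = 0
                for i in range(side):
                    for j in range(side):
                        code = code * 2 + (1 if spins[i, j] == 1 else 0)
                out[t] = code
            else:
                out[t] = 1 if spins[ri, rj] == 1 else 0
    return out


def simulate_ising_site(config: IsingConfig) -> SymbolSequence:
    """Binary time series of one lattice site (spin -1 -> 0, +1 -> 1)."""
    rng = np.random.default_rng(config.seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    ri, rj = config.record_site
    out = _ising_gibbs_kernel(
        config.lattice_side, 1.0 / config.temperature, config.n_sweeps,
        config.burn_in, ri, rj, kernel_seed, False,
    )
    return SymbolSequence(out, 2)


def simulate_ising_configurations(config: IsingConfig) -> np.ndarray:
    """Per-sweep full-lattice configuration codes (tiny lattices only).

    Encodes each configuration as a ``side**2``-bit integer; intended for
    validating the sampler against the exact Boltzmann distribution by
    enumeration, hence restricted to ``side**2 <= 20`` sites.
    """
    if config.lattice_side**2 > 20:
        raise ValueError("configuration recording is limited to side**2 <= 20 sites")
    rng = np.random.default_rng(config.seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    ri, rj = config.record_site
    return _ising_gibbs_kernel(
        config.lattice_side, 1.0 / config.temperature, config.n_sweeps,
        config.burn_in, ri, rj, kernel_seed, True,
    )


# ---------------------------------------------------------------------------
# double-well "ion channel"
# ---------------------------------------------------------------------------


@dataclass
class DoubleWellConfig:
    """Euler-integrated overdamped motion in a symmetric double well.

    ``X_{n+1} = X_n + (a X_n - b X_n^3) dt + xi_n`` with iid Gaussian
    ``xi_n`` of standard deviation ``noise_sigma`` per step.  The stable
    minima sit at ``+-sqrt(a/b)``.  The default noise scale 0.025 puts the
    effective temperature ``noise_sigma**2 / (2 dt)`` at ~0.31 — comparable
    to the barrier height ``a**2/(4b) = 0.25`` — so the trajectory switches
    wells every ~1e4 steps and the stationary density is clearly bimodal.
    """

    a: float = 1.0
    b: float = 1.0
    noise_sigma: float = 0.025
    dt: float = 1e-3
    n_samples: int = 1_000_000
    x0: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("potential coefficients a, b must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def minima(self) -> tuple[float, float]:
        m = math.sqrt(self.a / self.b)
        return (-m, m)


@njit(cache=False)
def _double_well_kernel(a, b, sigma, dt, n, x0, bound, seed):
    np.random.seed(seed)
    x = np.empty(n)
    cur = x0
    for t in range(n):
        cur = cur + (a * cur - b * cur**3) * dt + sigma * np.random.randn()
        if abs(cur) > bound:
            return x, t
        x[t] = cur
    return x, -1


def simulate_double_well(config: DoubleWellConfig) -> np.ndarray:
    """Euler sample path of the double-well Langevin dynamics.

    Raises ``RuntimeError`` on numerical blow-up (``|X| > 10 sqrt(a/b)``),
    which indicates too large a time step or noise scale.
    """
    rng = np.random.default_rng(config.seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    x0 = config.x0 if config.x0 is not None else math.sqrt(config.a / config.b)
    bound = 10.0 * math.sqrt(config.a / config.b)
    x, blew_up_at = _double_well_kernel(
        config.a, config.b, config.noise_sigma, config.dt,
        int(config.n_samples), float(x0), bound, kernel_seed,
    )
    if blew_up_at >= 0:
        raise RuntimeError(
            f"double-well integration diverged at step {blew_up_at} "
            f"(|X| > {bound:.3g}); reduce dt or noise_sigma"
        )
    return x


def threshold_binarize(x, threshold: float = 0.0) -> SymbolSequence:
    """Map a real series to binary symbols: 1 where ``x > threshold`` else 0.

    Exact threshold values map to 0 (a measure-zero event for continuous
    dynamics; fixed for determinism).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("x must be a non-empty 1-D series")
    return SymbolSequence((arr > threshold).astype(np.int64), 2)
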