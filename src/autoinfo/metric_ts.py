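"""AR(p) simulation and ACF/PACF estimation for metric (real-valued) series.

The classical Box-Jenkins companion to the symbolic machinery: for a pure
autoregressive process ``X_n = phi_1 X_{n-1} + ... + phi_p X_{n-p} + eps_n``
the partial autocorrelation function (PACF) vanishes beyond lag p, so its
stem plot diagnoses the AR order exactly as the partial autoinformation
diagnoses the Markov order of a symbolic sequence.

Estimation is delegated to statsmodels: ACF as lagged Pearson correlations
with the biased (1/N) normalization, PACF via the Durbin-Levinson recursion
on the biased sample autocovariance.  Confidence bands are the standard
``+- z_{1-alpha/2} / sqrt(N)`` for an iid null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from scipy.stats import norm
from statsmodels.tsa.stattools import acf as _sm_acf
from statsmodels.tsa.stattools import pacf as _sm_pacf

from .autoinformation import LagProfile

logger = logging.getLogger("autoinfo")


@dataclass(frozen=True)
class ARModel:
    """Autoregressive model with coefficients ``phi_1..phi_p``."""

    coefficients: tuple[float, ...]
    noise_sigma: float = 1.0

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in np.atleast_1d(np.asarray(self.coefficients, dtype=float)))
        if len(coeffs) < 1:
            raise ValueError("need at least one AR coefficient")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        object.__setattr__(self, "coefficients", coeffs)
        if not self.is_stationary():
            logger.warning(
                "AR model %s is not stationary (a characteristic root lies on "
                "or inside the unit circle); sample paths may diverge",
                coeffs,
            )

    @property
    def p(self) -> int:
        return len(self.coefficients)

    def is_stationary(self) -> bool:
        """True if all roots of ``z^p - phi_1 z^{p-1} - ... - phi_p`` lie inside the unit circle."""
        roots = np.roots(np.concatenate(([1.0], -np.asarray(self.coefficients))))
        return bool(np.all(np.abs(roots) < 1.0)) if roots.size else True


def simulate_ar(model: ARModel, n: int, seed: int | None = None) -> np.ndarray:
    """Simulate ``n`` samples of the AR recursion with Gaussian innovations.

    The recursion starts from zeros and the first ``10 p`` samples are
    discarded as transient.
    """
    if n <= model.p:
        raise ValueError(f"n={n} must exceed the model order p={model.p}")
    transient = 10 * model.p
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, model.noise_sigma, size=n + transient)
    denom = np.concatenate(([1.0], -np.asarray(model.coefficients)))
    x = lfilter([1.0], denom, eps)
    return x[transient:]


def _check_metric_input(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be a 1-D series with at least 2 samples")
    if np.var(x) == 0:
        raise ValueError("input has zero variance; correlations are undefined")
    if not (0 <= max_lag < x.size):
        raise ValueError(f"max_lag={max_lag} must satisfy 0 <= max_lag < N={x.size}")
    return x


def _iid_band(n: int, max_lag: int, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    z = norm.ppf(1.0 - alpha / 2.0)
    half = np.full(max_lag + 1, z / np.sqrt(n))
    return -half, half


def acf(x, max_lag: int, alpha: float = 0.05) -> LagProfile:
    """Sample autocorrelation for lags ``0..max_lag`` (1 at lag 0).

    Uses the biased (1/N) autocovariance normalization; the attached band is
    the iid null ``+- z_{1-alpha/2}/sqrt(N)``.
    """
    x = _check_metric_input(x, max_lag)
    values = _sm_acf(x, nlags=max_lag, adjusted=False, fft=True)
    low, high = _iid_band(x.size, max_lag, alpha)
    return LagProfile(
        np.arange(max_lag + 1), values, kind="acf",
        ci_low=low, ci_high=high, alpha=alpha, normalized=True,
    )


def pacf(x, max_lag: int, alpha: float = 0.05) -> LagProfile:
    """Sample partial autocorrelation for lags ``0..max_lag`` (1 at lag 0).

    Computed by the Durbin-Levinson recursion on the biased sample
    autocovariance; for an AR(p) process the lag-p value estimates ``phi_p``
    and lags beyond p fall inside the iid band.
    """
    x = _check_metric_input(x, max_lag)
    if max_lag >= x.size / 2:
        raise ValueError(f"max_lag={max_lag} must be below N/2={x.size / 2:g} for the PACF")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = _sm_pacf(x, nlags=max_lag, method="ldb")
    low, high = _iid_band(x.size, max_lag, alpha)
    return LagProfile(
        np.arange(max_lag + 1), values, kind="pacf",
        ci_low=low, ci_high=high, alpha=alpha, normalized=True,
    )
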