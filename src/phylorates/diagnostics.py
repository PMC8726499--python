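"""MCMC trace diagnostics.

Effective sample size (ESS) follows Geyer's initial-monotone-sequence
estimator: autocovariances are computed by FFT, summed in adjacent pairs
Gamma_m = rho_{2m} + rho_{2m+1}, truncated at the first non-positive pair
and forced non-increasing, giving the integrated autocorrelation time
tau = -1 + 2 * sum(Gamma_m) and ESS = n / tau. For an AR(1) chain with
coefficient phi this converges to n (1 - phi) / (1 + phi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ess", "ChainDiagnostics"]


def _autocovariance(x: np.ndarray) -> np.ndarray:
    n = x.size
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real
    return acov / n


def ess(x) -> float:
    """Effective sample size of a (possibly autocorrelated) trace.

    Returns ``nan`` for degenerate traces (constant, or fewer than 4
    samples); callers should treat that as a flag, not a crash.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 4:
        return float("nan")
    acov = _autocovariance(x)
    if acov[0] <= 0 or not np.isfinite(acov[0]):
        return float("nan")
    rho = acov / acov[0]
    # adjacent pair sums Gamma_m = rho_{2m} + rho_{2m+1}, positive for a
    # reversible chain; truncate at the first non-positive pair and force
    # the sequence non-increasing
    n_pairs = n // 2
    gamma = rho[0 : 2 * n_pairs : 2] + rho[1 : 2 * n_pairs : 2]
    nonpos = np.flatnonzero(gamma <= 0)
    if nonpos.size:
        gamma = gamma[: nonpos[0]]
    if gamma.size == 0:
        return float("nan")
    gamma = np.minimum.accumulate(gamma)
    tau = -1.0 + 2.0 * float(gamma.sum())
    tau = max(tau, 1.0 / n)
    return float(min(n / tau, n))


@dataclass
class ChainDiagnostics:
    """Per-parameter ESS, per-move acceptance rates, and QC warnings."""

    ess: dict[str, float] = field(default_factory=dict)
    acceptance: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def min_ess(self) -> float:
        finite = [v for v in self.ess.values() if np.isfinite(v)]
        return min(finite) if finite else float("nan")
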