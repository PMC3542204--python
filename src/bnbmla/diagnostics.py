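"""Convergence diagnostics for feature-indicator traces.

The sampler's output is a set of binary feature traces per independent
cold-chain replicate.  Convergence is judged per feature: Gelman-Rubin
potential scale reduction across replicates (flagged at R >= 1.05) and
Geweke Z-scores within each replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

R_FLAG_THRESHOLD = 1.05


def gelman_rubin(traces: np.ndarray) -> float:
    """Potential scale reduction factor over >= 2 equal-length chains.

    ``traces`` is ``(m_chains, n_samples)``.  Computes
    ``sqrt(((n-1)/n * W + B/n) / W)`` with ``W`` the mean within-chain
    variance and ``B`` the between-chain variance.  Conventions: all chains
    constant and equal -> 1.0; constant but unequal -> +inf.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need >= 2 chains")
    m, n = traces.shape
    if n < 2:
        raise ValueError("chains must have length >= 2")
    chain_means = traces.mean(axis=1)
    W = float(traces.var(axis=1, ddof=1).mean())
    B = float(n * chain_means.var(ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def autocovariance(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocovariances gamma_0..gamma_max_lag (FFT-free)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        out[k] = np.dot(xc[: n - k], xc[k:]) / n
    return out


def spectral_variance(x: np.ndarray) -> float:
    """Spectral density at frequency zero via a Bartlett-windowed
    autocovariance sum (window length ~ sqrt(n))."""
    x = np.asarray(x, dtype=float)
    n = x.size
    L = max(1, int(np.sqrt(n)))
    gamma = autocovariance(x, min(L, n - 1))
    weights = 1.0 - np.arange(1, len(gamma)) / (L + 1.0)
    return float(gamma[0] + 2.0 * np.sum(weights * gamma[1:]))


def geweke_z(trace: np.ndarray, first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke convergence Z: difference of early/late segment means scaled
    by their spectral standard errors.  A constant trace returns 0."""
    x = np.asarray(trace, dtype=float)
    if x.size < 20:
        raise ValueError("trace too short for a Geweke diagnostic")
    n1 = int(np.floor(first_frac * x.size))
    n2 = int(np.floor(last_frac * x.size))
    a, b = x[:n1], x[x.size - n2 :]
    if np.ptp(x) == 0.0:
        return 0.0
    s1 = max(spectral_variance(a), 0.0)
    s2 = max(spectral_variance(b), 0.0)
    denom = np.sqrt(s1 / n1 + s2 / n2)
    if denom == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def effective_sample_size(x: np.ndarray) -> float:
    """Autocorrelation-adjusted ESS via Geyer's initial positive sequence."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.ptp(x) == 0.0:
        return float(n)
    gamma = autocovariance(x, min(n - 2, 1000))
    rho = gamma / gamma[0]
    # sum consecutive-pair autocorrelations while they stay positive
    s = 0.0
    k = 1
    while k + 1 < len(rho):
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        s += pair
        k += 2
    ess = n / (1.0 + 2.0 * s)
    return float(min(max(ess, 1.0), n))


@dataclass
class ConvergenceReport:
    """Per-feature Gelman-Rubin R and Geweke Z values with R-flagging."""

    r_scores: dict[str, float] = field(default_factory=dict)
    geweke_scores: dict[str, list[float]] = field(default_factory=dict)
    r_threshold: float = R_FLAG_THRESHOLD

    @property
    def flagged(self) -> list[str]:
        return sorted(
            f for f, r in self.r_scores.items() if not np.isfinite(r) or r >= self.r_threshold
        )

    @property
    def max_r(self) -> float:
        return max(self.r_scores.values()) if self.r_scores else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for feature, r in sorted(self.r_scores.items()):
            z = self.geweke_scores.get(feature, [])
            rows.append(
                {
                    "feature": feature,
                    "gelman_rubin_R": r,
                    "max_abs_geweke_Z": max((abs(v) for v in z), default=np.nan),
                    "flagged": (not np.isfinite(r)) or r >= self.r_threshold,
                }
            )
        return pd.DataFrame(rows, columns=["feature", "gelman_rubin_R", "max_abs_geweke_Z", "flagged"])
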