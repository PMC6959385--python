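"""Ergodic-average estimators, replicate statistics and integrated autocorrelation.

Conventions.  The CLT for the time average π_T(f) is
√T(π_T(f) − π(f)) → N(0, 2σ²_f), so Var[π_T(f)] ≈ 2σ²_f/T for large T; the
asymptotic variance σ²_f itself equals the one-sided integrated stationary
autocovariance ∫₀^∞ Cov(f(q₀), f(q_t)) dt.  Replicate-based estimation of
σ²_f therefore scales the across-replicate variance by (T − T₀)/2, and the
autocorrelation route integrates a biased (1/n) autocovariance estimate by the
trapezoid rule over a fixed lag window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import acovf

from ._validate import ValidationError

__all__ = [
    "ReplicateSummary",
    "AcfResult",
    "time_average",
    "replicate_summary",
    "replicate_asymptotic_variance",
    "integrated_autocorrelation",
]


@dataclass(frozen=True)
class ReplicateSummary:
    """Across-replicate statistics of the ergodic-average estimator."""

    estimates: np.ndarray
    mean: float
    std: float
    standard_error: float

    @property
    def n(self) -> int:
        return self.estimates.size


@dataclass(frozen=True)
class AcfResult:
    """Autocovariance estimates on a lag grid with their trapezoid integral."""

    lags: np.ndarray
    acf: np.ndarray
    integrated: float


def time_average(series, dt: float, burn_in_time: float = 0.0) -> float:
    """Left-Riemann time average of the samples remaining after burn-in.

    Burn-in is measured in time units and rounded down to whole steps.
    """
    series = np.asarray(series, dtype=float).reshape(-1)
    if dt <= 0:
        raise ValidationError("dt must be positive")
    n_burn = int(np.floor(burn_in_time / dt))
    if n_burn >= series.size:
        raise ValidationError("burn-in leaves no samples to average")
    return float(series[n_burn:].mean())


def replicate_summary(estimates) -> ReplicateSummary:
    """Sample mean, std (n−1 denominator) and standard error across replicates."""
    estimates = np.asarray(estimates, dtype=float).reshape(-1)
    if estimates.size < 2:
        raise ValidationError("at least two replicate estimates are required")
    mean = float(estimates.mean())
    std = float(estimates.std(ddof=1))
    return ReplicateSummary(estimates=estimates, mean=mean, std=std,
                            standard_error=std / np.sqrt(estimates.size))


def replicate_asymptotic_variance(estimates, effective_time: float
                                  ) -> tuple[float, float]:
    """Estimate σ²_f (and its standard error) from replicate time averages.

    Var[π_T(f)] ≈ 2σ²/(T − T₀), so σ̂² = (T − T₀)·s²/2 with s² the across-
    replicate sample variance; the SE uses the Gaussian-χ² approximation
    SE(σ̂²) ≈ σ̂²·√(2/(n − 1)).
    """
    summary = replicate_summary(estimates)
    if effective_time <= 0:
        raise ValidationError("effective averaging time must be positive")
    sigma2 = 0.5 * effective_time * summary.std**2
    se = sigma2 * np.sqrt(2.0 / (summary.n - 1))
    return float(sigma2), float(se)


def integrated_autocorrelation(series, dt: float, window: int) -> AcfResult:
    """Integrated autocovariance estimate of σ²_f over lags 0..window.

    Uses biased (1/n) autocovariance estimates (FFT-based) and integrates them
    over time lag with the trapezoid rule, i.e. with half weight at lag 0 and at
    the window edge.  The window is fixed, not adaptive.
    """
    series = np.asarray(series, dtype=float).reshape(-1)
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if not (0 < window < series.size / 2):
        raise ValidationError("window must satisfy 0 < window < len(series)/2")
    acf = acovf(series, adjusted=False, fft=True, nlag=window)
    lags = np.arange(window + 1) * dt
    integrated = float(np.trapezoid(acf, dx=dt))
    return AcfResult(lags=lags, acf=acf, integrated=integrated)
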