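"""Ensemble comparison statistics: moments, relative variance, KL, failures.

The headline statistic is the empirical relative stationary variance
``psi_hat = s^2 / Var[X*]`` — the sample variance of the replicate end
states over the exact chemical-master-equation variance — which the linear
theory predicts to equal ``psi(z)`` at ``z = -tau (k1 + k2)``.

Histogram comparisons use the Kullback-Leibler divergence in bits,

    D(P_E, P_M) = sum_x P_E(x) log2(P_E(x) / P_M(x)),

summed over the support of the reference ``P_E``.  Empty method bins are
undefined under D; :meth:`HistogramComparison.from_samples` therefore
applies add-half (Jeffreys) pseudo-count smoothing to the *method* pmf
only, identically across methods, and flags it in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import TrajectoryEnsemble

__all__ = [
    "Moments",
    "HistogramComparison",
    "empirical_moments",
    "relative_variance_estimate",
    "kl_divergence",
    "empirical_pmf",
    "failure_rate",
    "FAILURE_RATE_FLAG",
]

#: Failure rates above this are flagged in reports.
FAILURE_RATE_FLAG = 1e-3


@dataclass(frozen=True)
class Moments:
    mean: np.ndarray
    var: np.ndarray
    se_mean: np.ndarray
    se_var: np.ndarray
    n: int


def _states(ensemble) -> np.ndarray:
    if isinstance(ensemble, TrajectoryEnsemble):
        states = ensemble.successful_states
    else:
        states = np.asarray(ensemble, dtype=float)
    if states.ndim == 1:
        states = states[:, None]
    return states


def empirical_moments(ensemble) -> Moments:
    """Per-species sample mean and unbiased variance with standard errors.

    ``se_var`` uses the exact finite-sample variance of the sample variance,
    ``Var(s^2) = (m4 - (n-3)/(n-1) s^4) / n`` with ``m4`` the fourth central
    sample moment.
    """
    states = _states(ensemble)
    n = states.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 successful replicates, got {n}")
    mean = states.mean(axis=0)
    var = states.var(axis=0, ddof=1)
    centered = states - mean
    m4 = np.mean(centered**4, axis=0)
    var_of_var = np.maximum(m4 - (n - 3) / (n - 1) * var**2, 0.0) / n
    return Moments(
        mean=mean,
        var=var,
        se_mean=np.sqrt(var / n),
        se_var=np.sqrt(var_of_var),
        n=n,
    )


def relative_variance_estimate(
    ensemble,
    analytic_variance: float,
    *,
    species: int = 0,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """``psi_hat`` for one species, with a bootstrap standard error."""
    if analytic_variance <= 0:
        raise ValueError("analytic variance must be > 0")
    x = _states(ensemble)[:, species]
    n = x.shape[0]
    if n < 2:
        raise ValueError("need >= 2 successful replicates")
    psi_hat = float(np.var(x, ddof=1) / analytic_variance)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = np.var(x[rng.integers(0, n, size=n)], ddof=1)
    return psi_hat, float(boots.std(ddof=1) / analytic_variance)


def kl_divergence(p_ref: np.ndarray, p_method: np.ndarray) -> float:
    """KL divergence in bits over the support of ``p_ref``; inf on empty bins."""
    p_ref = np.asarray(p_ref, dtype=float)
    p_method = np.asarray(p_method, dtype=float)
    if p_ref.shape != p_method.shape:
        raise ValueError("pmfs must share one integer support")
    if abs(p_ref.sum() - 1.0) > 1e-8:
        raise ValueError("reference pmf must sum to 1")
    mask = p_ref > 0.0
    if np.any(p_method[mask] == 0.0):
        return np.inf
    return float(np.sum(p_ref[mask] * np.log2(p_ref[mask] / p_method[mask])))


def empirical_pmf(samples: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Normalized histogram of (rounded) samples on an integer support."""
    rounded = np.rint(np.asarray(samples, dtype=float)).astype(np.int64)
    lo = int(support[0])
    counts = np.bincount(
        np.clip(rounded - lo, 0, len(support) - 1), minlength=len(support)
    ).astype(float)
    return counts / counts.sum()


@dataclass(frozen=True)
class HistogramComparison:
    """Reference vs method pmfs on a shared integer support, with KL in bits."""

    support: np.ndarray
    p_ref: np.ndarray
    p_method: np.ndarray
    kl_bits: float
    n_ref: int | None
    n_method: int
    smoothed: bool

    @classmethod
    def from_samples(
        cls,
        method_samples: np.ndarray,
        *,
        ref_samples: np.ndarray | None = None,
        ref_pmf: np.ndarray | None = None,
        ref_support: np.ndarray | None = None,
        smooth: bool = True,
    ) -> "HistogramComparison":
        """Build the comparison from raw end states.

        The support is the union of the observed integer supports (after
        rounding real-valued RK states) and, when an analytic reference pmf
        is supplied, its support.  Add-half smoothing is applied to the
        method pmf only.
        """
        method_samples = np.rint(np.asarray(method_samples, dtype=float)).astype(int)
        if (ref_samples is None) == (ref_pmf is None):
            raise ValueError("supply exactly one of ref_samples / ref_pmf")
        if ref_pmf is not None and ref_support is None:
            raise ValueError("ref_pmf requires ref_support")
        pieces = [method_samples]
        if ref_samples is not None:
            ref_samples = np.rint(np.asarray(ref_samples, dtype=float)).astype(int)
            pieces.append(ref_samples)
        lo = min(int(p.min()) for p in pieces)
        hi = max(int(p.max()) for p in pieces)
        if ref_support is not None:
            lo = min(lo, int(ref_support[0]))
            hi = max(hi, int(ref_support[-1]))
        support = np.arange(lo, hi + 1)
        counts_m = np.bincount(method_samples - lo, minlength=len(support)).astype(float)
        if smooth:
            counts_m += 0.5
        p_method = counts_m / counts_m.sum()
        if ref_samples is not None:
            p_ref = empirical_pmf(ref_samples, support)
            n_ref = len(ref_samples)
        else:
            p_ref = np.zeros(len(support))
            offset = int(ref_support[0]) - lo
            p_ref[offset : offset + len(ref_pmf)] = ref_pmf
            p_ref = p_ref / p_ref.sum()
            n_ref = None
        return cls(
            support=support,
            p_ref=p_ref,
            p_method=p_method,
            kl_bits=kl_divergence(p_ref, p_method),
            n_ref=n_ref,
            n_method=len(method_samples),
            smoothed=smooth,
        )


def failure_rate(ensemble: TrajectoryEnsemble) -> float:
    """Fraction of replicates aborted (negative means or divergence)."""
    if ensemble.n_replicates == 0:
        return 0.0
    return ensemble.n_failed / ensemble.n_replicates
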