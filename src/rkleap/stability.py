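"""Runge-Kutta tableau algebra and linear stability/variance theory.

For an s-stage Runge-Kutta method with tableau ``(A, b, w)``, ``w = A e``,
the amplification on the scalar linear test problem ``y' = lambda*y`` is the
stability function

    R(z) = 1 + z b^T (I - A z)^{-1} e,

which for explicit methods (strictly lower-triangular ``A``) reduces to the
polynomial ``R(z) = 1 + sum_j r_j z^j`` with ``r_j = b^T A^{j-1} e``.

On the reversible isomerisation test system the stationary variance of an
RK tau-leap method built on this tableau is ``psi(z)`` times the exact
chemical-master-equation variance, where ``z = -tau (k1 + k2)`` and

    psi(z) = (2/z) (R(z) - 1) / (R(z) + 1),

with the removable singularity ``psi(0) = 1``.  The two interval searches
below measure, on the negative real axis, how far a method can be pushed
before it loses stability (``|R| > 1``) or before its stationary variance
error exceeds a tolerance (``|psi - 1| >= eps``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ButcherTableau",
    "StabilityPolynomial",
    "UNBOUNDED",
    "stability_function",
    "stability_polynomial_from_tableau",
    "relative_variance",
    "stability_interval",
    "variance_bounded_interval",
    "mean_propagator",
]

#: Distinguished sentinel for "no violation up to the search horizon".
UNBOUNDED = math.inf


@dataclass(frozen=True)
class ButcherTableau:
    """Runge-Kutta coefficients ``(A, b, w)`` with ``w = A e``."""

    A: np.ndarray
    b: np.ndarray
    w: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        s = len(b)
        if A.shape != (s, s):
            raise ValueError(f"A must be ({s}, {s}) to match b, got {A.shape}")
        w = A @ np.ones(s) if self.w is None else np.atleast_1d(np.asarray(self.w, dtype=float))
        if w.shape != (s,):
            raise ValueError(f"w must have length {s}")
        if not np.allclose(w, A @ np.ones(s), atol=1e-12):
            raise ValueError("abscissae w must equal A e")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "w", w)

    @property
    def s(self) -> int:
        return len(self.b)

    @property
    def is_explicit(self) -> bool:
        return bool(np.all(np.abs(np.triu(self.A)) == 0.0))

    @property
    def is_subdiagonal(self) -> bool:
        """True if ``b = (0,...,0,1)`` and ``A`` is zero off the first subdiagonal."""
        s = self.s
        if self.b[-1] != 1.0 or np.any(self.b[:-1] != 0.0):
            return False
        mask = np.zeros((s, s), dtype=bool)
        for i in range(1, s):
            mask[i, i - 1] = True
        return bool(np.all(self.A[~mask] == 0.0))

    def to_dict(self) -> dict:
        return {
            "s": self.s,
            "A": [[float(v) for v in row] for row in self.A],
            "b": [float(v) for v in self.b],
            "w": [float(v) for v in self.w],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ButcherTableau":
        return cls(A=np.asarray(doc["A"], dtype=float), b=np.asarray(doc["b"], dtype=float))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ButcherTableau":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class StabilityPolynomial:
    """Coefficients ``(r_1, ..., r_s)`` of ``R(z) = 1 + sum_j r_j z^j``."""

    r: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.r) < 1:
            raise ValueError("need at least r_1")
        object.__setattr__(self, "r", tuple(float(v) for v in self.r))

    @property
    def degree(self) -> int:
        return len(self.r)

    def __call__(self, z):
        # Horner on 1 + z(r1 + z(r2 + ...))
        acc = np.zeros_like(np.asarray(z, dtype=complex if np.iscomplexobj(z) else float))
        for rj in reversed(self.r):
            acc = acc * z + rj
        return acc * z + 1.0

    def psi(self, z):
        """Relative stationary variance of this stability polynomial."""
        return relative_variance(self, z)


def stability_function(tab: ButcherTableau, z):
    """Evaluate ``R(z) = 1 + z b^T (I - Az)^{-1} e`` (scalar or complex z)."""
    e = np.ones(tab.s)
    try:
        u = np.linalg.solve(np.eye(tab.s) - tab.A * z, e)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"stability function has a pole at z={z}") from exc
    return 1.0 + z * (tab.b @ u)


def stability_polynomial_from_tableau(tab: ButcherTableau) -> StabilityPolynomial:
    """Extract ``r_j = b^T A^{j-1} e`` for an explicit tableau.

    Trailing (numerically) zero coefficients are trimmed, but ``r_1`` is
    always kept so the polynomial has at least degree one.
    """
    if not tab.is_explicit:
        raise ValueError("stability function is rational, not polynomial")
    e = np.ones(tab.s)
    r = []
    v = e
    for _ in range(tab.s):
        r.append(float(tab.b @ v))
        v = tab.A @ v
    scale = max(1.0, max(abs(x) for x in r))
    while len(r) > 1 and abs(r[-1]) <= 1e-14 * scale:
        r.pop()
    return StabilityPolynomial(tuple(r))


def relative_variance(R_eval, z):
    """``psi(z) = (2/z) (R(z)-1)/(R(z)+1)``, with ``psi(0) = 1`` by its limit.

    ``R_eval`` is any callable ``z -> R(z)`` (a :class:`StabilityPolynomial`,
    a closure over :func:`stability_function`, ...).  Raises when ``R(z) = -1``
    (the ``R^2(z) != 1`` condition fails and the stationary variance has a
    pole there).
    """
    z_arr = np.asarray(z, dtype=float)
    scalar = z_arr.ndim == 0
    z_arr = np.atleast_1d(z_arr)
    out = np.empty_like(z_arr)
    nonzero = z_arr != 0.0
    out[~nonzero] = 1.0
    if np.any(nonzero):
        R = np.asarray([R_eval(zi) for zi in z_arr[nonzero]], dtype=float)
        if np.any(np.abs(R + 1.0) < 1e-14):
            bad = z_arr[nonzero][np.abs(R + 1.0) < 1e-14][0]
            raise ValueError(f"relative variance has a pole (R(z) = -1) at z={bad}")
        out[nonzero] = (2.0 / z_arr[nonzero]) * (R - 1.0) / (R + 1.0)
    return float(out[0]) if scalar else out


def _eval_R(R_eval, z: np.ndarray) -> np.ndarray:
    """Evaluate an R callable on an array, whether or not it vectorizes."""
    with np.errstate(over="ignore", invalid="ignore"):
        try:
            R = np.asarray(R_eval(z), dtype=float)
            if R.shape == z.shape:
                return R
        except (ValueError, TypeError, np.linalg.LinAlgError):
            pass
        return np.asarray([R_eval(zi) for zi in z], dtype=float)


def _psi_safe(R_eval, z: np.ndarray) -> np.ndarray:
    """Vectorized psi for interval scans; poles map to +inf, never raise."""
    out = np.ones_like(z)
    nonzero = z != 0.0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        R = _eval_R(R_eval, z[nonzero])
        val = (2.0 / z[nonzero]) * (R - 1.0) / (R + 1.0)
    val[~np.isfinite(val)] = np.inf
    out[nonzero] = val
    return out


def _largest_interval(violates, horizon: float, n_grid: int, tol: float) -> float:
    """Largest ``l`` such that ``violates`` is False on ``(-l, 0]``.

    ``violates`` maps an array of z values to a boolean array.  Dense grid
    pre-scan on ``(-horizon, 0]`` followed by bisection refinement of the
    first violation; returns :data:`UNBOUNDED` if the scan finds none.
    """
    z = np.linspace(0.0, -horizon, n_grid + 1)[1:]
    bad = violates(z)
    if not np.any(bad):
        return UNBOUNDED
    i = int(np.argmax(bad))
    hi = float(z[i])  # violating point (most negative end of bracket)
    lo = float(z[i - 1]) if i > 0 else 0.0  # non-violating
    while lo - hi > tol:
        mid = 0.5 * (lo + hi)
        if violates(np.asarray([mid]))[0]:
            hi = mid
        else:
            lo = mid
    return -0.5 * (lo + hi)


def stability_interval(
    R_eval, *, horizon: float = 200.0, n_grid: int = 10_000, tol: float = 1e-6
) -> float:
    """Largest ``l`` with ``|R(z)| <= 1`` on ``(-l, 0]`` (negative real axis)."""

    def violates(z: np.ndarray) -> np.ndarray:
        R = _eval_R(R_eval, z)
        return ~(np.abs(R) <= 1.0 + 1e-12)

    return _largest_interval(violates, horizon, n_grid, tol)


def variance_bounded_interval(
    R_eval, eps: float, *, horizon: float = 200.0, n_grid: int = 10_000, tol: float = 1e-6
) -> float:
    """Largest ``l`` with ``|psi(z) - 1| < eps`` on ``(-l, 0]``."""
    if not 0.0 < eps < 1.0:
        raise ValueError(f"eps must be in (0, 1), got {eps}")

    def violates(z: np.ndarray) -> np.ndarray:
        return ~(np.abs(_psi_safe(R_eval, z) - 1.0) < eps)

    return _largest_interval(violates, horizon, n_grid, tol)


def mean_propagator(tab: ButcherTableau, tau: float, W: np.ndarray) -> np.ndarray:
    """Matrix stability function ``R(tau W)`` propagating the ensemble mean.

    For linear kinetics with matrix ``W`` the mean of an RK tau-leap ensemble
    obeys ``E[X_{n+1}] = R(tau W) E[X_n]``.  Computed from the Kronecker form
    ``R(hL) = I_N + (h b^T (x) L)(I_sN - h A (x) L)^{-1}(e (x) I_N)``, which
    also covers implicit tableaus away from poles.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    W = np.asarray(W, dtype=float)
    N = W.shape[0]
    if W.shape != (N, N):
        raise ValueError("W must be square")
    s = tab.s
    e = np.ones(s)
    M = np.eye(s * N) - np.kron(tau * tab.A, W)
    try:
        X = np.linalg.solve(M, np.kron(e[:, None], np.eye(N)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Kronecker system in mean propagator") from exc
    return np.eye(N) + np.kron(tau * tab.b[None, :], W) @ X
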