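"""Built-in test systems with analytic ground truth, plus a fixture generator.

The reversible isomerisation ``S1 <-> S2`` (rates ``k1`` forward, ``k2``
backward) is the linear scalar test problem of the stability theory: total
count ``T`` is conserved, the kinetics matrix ``W`` has eigenvalues ``0``
and ``-(k1 + k2)``, and the stationary law of ``X1`` is exactly
``Binomial(T, k2/(k1 + k2))``, giving mean ``T/(k1+k2) (k2, k1)`` and
per-species variance ``T k1 k2 / (k1 + k2)^2``.

The Schlogl autocatalytic system is the canonical stiff nonlinear benchmark
with a bimodal stationary law; the two non-autocatalytic species are
buffered (held constant at counts ``A`` and ``B``), reducing it to a scalar
jump process with four channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .networks import Linear, MassAction, ReactionNetwork

__all__ = [
    "IsomerisationSpec",
    "SchloglSpec",
    "SCHLOGL_BISTABLE",
    "isomerisation_network",
    "isomerisation_stationary_moments",
    "isomerisation_stationary_pmf",
    "schlogl_network",
    "schlogl_drift_roots",
    "random_linear_network",
]


@dataclass(frozen=True)
class IsomerisationSpec:
    """Reversible isomerisation parameters; ``X0`` defaults to an even split."""

    k1: float = 10.0
    k2: float = 10.0
    T: int = 200
    X0: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0 or self.k1 + self.k2 <= 0:
            raise ValueError("rates must be nonnegative with k1 + k2 > 0")
        if self.T < 1:
            raise ValueError("total molecule count T must be >= 1")
        x0 = (self.T // 2, self.T - self.T // 2) if self.X0 is None else tuple(self.X0)
        if sum(x0) != self.T or any(v < 0 for v in x0):
            raise ValueError(f"X0 must be nonnegative and sum to T={self.T}, got {x0}")
        object.__setattr__(self, "X0", x0)

    @property
    def p(self) -> float:
        """Stationary success probability of X1, ``k2 / (k1 + k2)``."""
        return self.k2 / (self.k1 + self.k2)


def isomerisation_network(spec: IsomerisationSpec | None = None, **kwargs) -> ReactionNetwork:
    """Two linear channels: ``S1 -> S2`` at ``k1 x1`` and ``S2 -> S1`` at ``k2 x2``."""
    spec = spec if spec is not None else IsomerisationSpec(**kwargs)
    if spec.k1 <= 0 or spec.k2 <= 0:
        raise ValueError("network construction requires strictly positive rates")
    return ReactionNetwork(
        species_names=["S1", "S2"],
        nu=np.array([[-1, 1], [1, -1]]),
        propensities=[Linear(c=(spec.k1, 0.0)), Linear(c=(0.0, spec.k2))],
        initial_state=list(spec.X0),
    )


def isomerisation_stationary_moments(spec: IsomerisationSpec) -> tuple[np.ndarray, float]:
    """Exact stationary mean vector and (common) per-species variance."""
    mean = spec.T / (spec.k1 + spec.k2) * np.array([spec.k2, spec.k1])
    var = spec.T * spec.k1 * spec.k2 / (spec.k1 + spec.k2) ** 2
    return mean, float(var)


def isomerisation_stationary_pmf(spec: IsomerisationSpec) -> np.ndarray:
    """Binomial(T, p) stationary probability mass of ``X1`` on ``{0, ..., T}``."""
    return stats.binom.pmf(np.arange(spec.T + 1), spec.T, spec.p)


@dataclass(frozen=True)
class SchloglSpec:
    """Schlogl system rates and buffered counts.

    ``A`` and ``B`` are the held-constant counts of the two buffered species
    and must be supplied explicitly; :data:`SCHLOGL_BISTABLE` is a shipped
    bistable scenario.
    """

    A: float
    B: float
    k1: float = 3e-7
    k2: float = 1e-4
    k3: float = 3.5
    k4: float = 1e-3
    x0: int = 250

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise ValueError("buffered counts A and B must be provided and positive")


#: Bistable scenario reconstructed from the Cao/Gillespie/Petzold
#: parameterization of the Schlogl system (buffered counts are not part of
#: the shipped rate table); produces a clearly bimodal stationary histogram.
SCHLOGL_BISTABLE = SchloglSpec(A=1e5, B=2e5, x0=250)


def schlogl_network(spec: SchloglSpec) -> ReactionNetwork:
    """Scalar Schlogl network with buffered species folded into the rates.

    Channels and propensities (x = autocatalytic species count):

    ====================  =======================
    ``A + 2X -> 3X``      ``k1 x (x-1) A / 2``
    ``3X -> A + 2X``      ``k2 x (x-1) (x-2) / 6``
    ``X -> B``            ``k3 x``
    ``B -> X``            ``k4 B``
    ====================  =======================
    """
    return ReactionNetwork(
        species_names=["X"],
        nu=np.array([[1], [-1], [-1], [1]]),
        propensities=[
            MassAction(rate=spec.k1 * spec.A, reactants=((0, 2),)),
            MassAction(rate=spec.k2, reactants=((0, 3),)),
            MassAction(rate=spec.k3, reactants=((0, 1),)),
            MassAction(rate=spec.k4 * spec.B, reactants=()),
        ],
        initial_state=[spec.x0],
    )


def schlogl_drift_roots(spec: SchloglSpec) -> np.ndarray:
    """Real nonnegative roots of the deterministic drift cubic (sorted).

    Three such roots (two stable flanking one unstable) are the bistability
    precondition for the bimodal stationary histogram.
    """
    a = spec.k1 * spec.A / 2.0
    b = spec.k2 / 6.0
    # f(x) = a x(x-1) - b x(x-1)(x-2) - k3 x + k4 B
    coeffs = [
        -b,
        a + 3.0 * b,
        -a - 2.0 * b - spec.k3,
        spec.k4 * spec.B,
    ]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-8 * np.abs(roots.real).max()].real
    return np.sort(real[real >= 0.0])


def random_linear_network(
    seed: int, N: int, m: int, rate_scale: float = 1.0
) -> ReactionNetwork:
    """Seeded conservative unimolecular fixture network.

    Each channel transfers one molecule between two distinct species
    (``nu_j`` sums to zero) at a rate proportional to the donor count, so
    the kinetics matrix ``W`` has zero column sums and the total count is
    conserved.
    """
    if N < 2 or m < 1:
        raise ValueError("need N >= 2 species and m >= 1 channels")
    rng = np.random.default_rng(seed)
    nu_rows, props = [], []
    for _ in range(m):
        i, k = rng.choice(N, size=2, replace=False)
        rate = float(rate_scale * rng.uniform(0.5, 1.5))
        nu_j = np.zeros(N, dtype=np.int64)
        nu_j[i], nu_j[k] = -1, 1
        c = np.zeros(N)
        c[i] = rate
        nu_rows.append(nu_j)
        props.append(Linear(c=tuple(c)))
    x0 = rng.integers(20, 120, size=N)
    return ReactionNetwork(
        species_names=[f"S{i + 1}" for i in range(N)],
        nu=np.asarray(nu_rows),
        propensities=props,
        initial_state=x0,
    )
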