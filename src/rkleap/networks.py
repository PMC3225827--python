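"""Well-stirred reaction networks: species, stoichiometry, propensities.

A network couples ``m`` reaction channels to ``N`` species.  Each channel
``j`` carries an integer update (stoichiometric) vector ``nu_j`` of length
``N`` and a propensity function ``a_j(x) >= 0`` giving the firing intensity
at state ``x``.  Propensity definitions are declarative (kind + parameters)
so that networks round-trip through YAML config files; an opaque-callable
escape hatch exists but is excluded from serialization.

Propensity evaluation is vectorized: any leading batch shape ``(..., N)``
on the state is broadcast to ``(..., m)`` propensities.  States are handled
as real vectors (Runge-Kutta stage values are non-integer); no clamping is
applied, so propensities of slightly negative stage excursions are returned
as the raw formulas dictate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

__all__ = [
    "MassAction",
    "Linear",
    "GeneralPropensity",
    "LinearKinetics",
    "ReactionNetwork",
    "propensities",
    "drift",
    "linear_kinetics_matrix",
]


@dataclass(frozen=True)
class MassAction:
    """Mass-action propensity ``rate * prod_i C(x_i, c_i-combinations)``.

    The combinatorial convention is molecular: ``x(x-1)/2`` for two
    identical reactant molecules, ``x(x-1)(x-2)/6`` for three, i.e. falling
    factorials divided by ``c!`` — not concentration-style powers.
    ``reactants`` maps species index -> stoichiometric count (1..3 typical).
    An empty reactant tuple is a zeroth-order (source) channel with constant
    propensity ``rate``.
    """

    rate: float
    reactants: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"mass-action rate must be >= 0, got {self.rate}")
        for i, c in self.reactants:
            if c < 1:
                raise ValueError(f"reactant count must be >= 1, got {c} for species {i}")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        a = np.full(np.shape(x)[:-1], self.rate, dtype=float)
        for i, c in self.reactants:
            xi = np.asarray(x, dtype=float)[..., i]
            comb = xi.copy()
            for k in range(1, c):
                comb = comb * (xi - k)
            a = a * comb / math.factorial(c)
        return a


@dataclass(frozen=True)
class Linear:
    """Unimolecular/linear propensity ``a(x) = c . x`` with ``c >= 0``."""

    c: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(ci < 0 for ci in self.c):
            raise ValueError("linear propensity coefficients must be >= 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ np.asarray(self.c, dtype=float)


@dataclass(frozen=True)
class GeneralPropensity:
    """Arbitrary nonnegative-state propensity function (not serializable)."""

    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.fn(np.asarray(x, dtype=float)), dtype=float)


@dataclass(frozen=True)
class LinearKinetics:
    """Linear-kinetics structure: coefficient rows ``c_j`` and ``W = sum_j nu_j c_j^T``."""

    c_vectors: np.ndarray  # (m, N)
    W: np.ndarray  # (N, N)


class ReactionNetwork:
    """Reaction system: species names, update vectors and propensity definitions.

    Parameters
    ----------
    species_names
        Length-``N`` identifiers.
    nu
        ``(m, N)`` integer array; row ``j`` is the state change when channel
        ``j`` fires once.
    propensities
        Length-``m`` sequence of :class:`MassAction`, :class:`Linear` or
        :class:`GeneralPropensity` definitions.
    initial_state
        Length-``N`` nonnegative integer vector ``X(0)``.
    """

    def __init__(
        self,
        species_names: Sequence[str],
        nu: np.ndarray,
        propensities: Sequence[MassAction | Linear | GeneralPropensity],
        initial_state: Sequence[int],
    ) -> None:
        self.species_names = list(species_names)
        self.nu = np.asarray(nu, dtype=np.int64)
        self.propensity_defs = list(propensities)
        x0 = np.asarray(initial_state)
        if self.nu.ndim != 2:
            raise ValueError("nu must be a (m, N) array of update vectors")
        m, N = self.nu.shape
        if N != len(self.species_names) or N < 1:
            raise ValueError(
                f"update vectors have length {N}, expected {len(self.species_names)} species"
            )
        if m != len(self.propensity_defs) or m < 1:
            raise ValueError(
                f"{len(self.propensity_defs)} propensities for {m} update vectors"
            )
        if x0.shape != (N,):
            raise ValueError(f"initial state must have length {N}, got {x0.shape}")
        if np.any(x0 < 0) or not np.issubdtype(x0.dtype, np.integer):
            raise ValueError("initial state must be a nonnegative integer vector")
        self.initial_state = x0.astype(np.int64)
        self._nu_f = self.nu.astype(float)
        for p in self.propensity_defs:
            if isinstance(p, Linear) and len(p.c) != N:
                raise ValueError(f"linear coefficient vector must have length {N}")
            if isinstance(p, MassAction):
                for i, _ in p.reactants:
                    if not 0 <= i < N:
                        raise ValueError(f"reactant species index {i} out of range")

    # -- basic structure -------------------------------------------------

    @property
    def n_species(self) -> int:
        return self.nu.shape[1]

    @property
    def n_reactions(self) -> int:
        return self.nu.shape[0]

    def propensities(self, x: np.ndarray) -> np.ndarray:
        """Evaluate ``(a_1(x), ..., a_m(x))``; batched over leading axes."""
        x = np.asarray(x, dtype=float)
        if x.shape[-1:] != (self.n_species,):
            raise ValueError(
                f"state must have length {self.n_species}, got shape {x.shape}"
            )
        return np.stack([p(x) for p in self.propensity_defs], axis=-1)

    def drift(self, x: np.ndarray) -> np.ndarray:
        """Expected step-change per unit time, ``f(x) = sum_j nu_j a_j(x)``."""
        return self.propensities(x) @ self._nu_f

    def is_linear(self) -> bool:
        return all(isinstance(p, Linear) for p in self.propensity_defs)

    def linear_kinetics(self) -> LinearKinetics:
        """Return ``W = sum_j nu_j c_j^T`` for purely linear kinetics."""
        if not self.is_linear():
            raise ValueError("not a linear kinetics system")
        C = np.asarray([p.c for p in self.propensity_defs], dtype=float)
        W = self._nu_f.T @ C
        return LinearKinetics(c_vectors=C, W=W)

    # -- config round-trip -----------------------------------------------

    def to_dict(self) -> dict:
        reactions = []
        for nu_j, p in zip(self.nu, self.propensity_defs):
            if isinstance(p, MassAction):
                reactants = {self.species_names[i]: int(c) for i, c in p.reactants}
                # products = reactants + net change
                change = {name: int(v) for name, v in zip(self.species_names, nu_j)}
                products = {
                    name: reactants.get(name, 0) + change.get(name, 0)
                    for name in self.species_names
                }
                products = {k: v for k, v in products.items() if v != 0}
                reactions.append(
                    {
                        "kind": "mass_action",
                        "rate": float(p.rate),
                        "reactants": reactants,
                        "products": products,
                    }
                )
            elif isinstance(p, Linear):
                reactions.append(
                    {
                        "kind": "linear",
                        "c": [float(v) for v in p.c],
                        "nu": [int(v) for v in nu_j],
                    }
                )
            else:
                raise ValueError("general propensity functions are not serializable")
        return {
            "species": list(self.species_names),
            "reactions": reactions,
            "initial_state": [int(v) for v in self.initial_state],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ReactionNetwork":
        species = list(doc["species"])
        index = {name: i for i, name in enumerate(species)}
        nu_rows, props = [], []
        for rxn in doc["reactions"]:
            if rxn["kind"] == "mass_action":
                reactants = {index[k]: int(v) for k, v in rxn.get("reactants", {}).items()}
                products = {index[k]: int(v) for k, v in rxn.get("products", {}).items()}
                nu_j = np.zeros(len(species), dtype=np.int64)
                for i, c in reactants.items():
                    nu_j[i] -= c
                for i, c in products.items():
                    nu_j[i] += c
                props.append(
                    MassAction(rate=float(rxn["rate"]), reactants=tuple(sorted(reactants.items())))
                )
                nu_rows.append(nu_j)
            elif rxn["kind"] == "linear":
                props.append(Linear(c=tuple(float(v) for v in rxn["c"])))
                nu_rows.append(np.asarray(rxn["nu"], dtype=np.int64))
            else:
                raise ValueError(f"unknown reaction kind {rxn['kind']!r}")
        return cls(species, np.asarray(nu_rows), props, doc["initial_state"])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ReactionNetwork":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def __repr__(self) -> str:
        return (
            f"ReactionNetwork({self.n_species} species, {self.n_reactions} channels, "
            f"X0={self.initial_state.tolist()})"
        )


def propensities(net: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """Functional form of :meth:`ReactionNetwork.propensities`."""
    return net.propensities(x)


def drift(net: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """Functional form of :meth:`ReactionNetwork.drift`."""
    return net.drift(x)


def linear_kinetics_matrix(net: ReactionNetwork) -> LinearKinetics:
    """Functional form of :meth:`ReactionNetwork.linear_kinetics`."""
    return net.linear_kinetics()
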