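"""Named tableau presets.

Built-ins:

* ``"poisson"`` — the single-stage Poisson tau-leap (``A = 0``, ``beta = 1``).
* ``"gillespie-midpoint"`` — the explicit midpoint leap (``s = 2``,
  ``b = (0, 1)``, ``alpha_21 = 1/2``).
* ``"implicit-midpoint"`` — analysis-only implicit tableau with
  ``R(z) = (1 + z/2)/(1 - z/2)`` and ``psi == 1`` (simulators reject it).
* ``"rk-tauleap-s{S}-eps{E}"`` for ``S in {3, 5}``, ``E in {0.1, 0.25, 0.5}``
  — variance-bounded stability-maximal subdiagonal methods whose
  coefficients ship with the package and are regenerated by
  ``scripts/build_presets.py`` from :func:`rkleap.optimize.optimize_polynomial`.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .optimize import tableau_from_polynomial
from .stability import ButcherTableau, StabilityPolynomial

__all__ = ["get_tableau", "get_polynomial", "preset_names", "optimal_preset_info"]


def _load_optimal() -> dict:
    with resources.files("rkleap.data").joinpath("optimal_tableaus.json").open() as fh:
        return json.load(fh)


_BUILTINS = {
    "poisson": lambda: ButcherTableau(A=np.zeros((1, 1)), b=np.ones(1)),
    "gillespie-midpoint": lambda: ButcherTableau(
        A=np.array([[0.0, 0.0], [0.5, 0.0]]), b=np.array([0.0, 1.0])
    ),
    "implicit-midpoint": lambda: ButcherTableau(
        A=np.array([[0.5]]), b=np.array([1.0])
    ),
}


def preset_names() -> list[str]:
    return sorted(_BUILTINS) + sorted(_load_optimal())


def get_tableau(name: str) -> ButcherTableau:
    """Look up a preset tableau by name."""
    if name in _BUILTINS:
        return _BUILTINS[name]()
    table = _load_optimal()
    if name in table:
        return tableau_from_polynomial(StabilityPolynomial(tuple(table[name]["r"])))
    raise KeyError(f"unknown tableau preset {name!r}; known: {preset_names()}")


def get_polynomial(name: str) -> StabilityPolynomial:
    """Stability polynomial of an explicit preset."""
    if name == "poisson":
        return StabilityPolynomial((1.0,))
    if name == "gillespie-midpoint":
        return StabilityPolynomial((1.0, 0.5))
    table = _load_optimal()
    if name in table:
        return StabilityPolynomial(tuple(table[name]["r"]))
    raise KeyError(f"no polynomial for preset {name!r}")


def optimal_preset_info(name: str) -> dict:
    """Shipped metadata (s, eps, r, certified interval l) of an optimal preset."""
    table = _load_optimal()
    if name not in table:
        raise KeyError(f"unknown optimal preset {name!r}")
    return dict(table[name])
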