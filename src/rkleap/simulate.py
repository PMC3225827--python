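"""Stochastic simulation engines: exact SSA, Poisson tau-leap, RK tau-leap.

Step kernels
------------
All tau-leap kernels share one structural contract: exactly **one** set of
``m`` Poisson draws per step, regardless of the number of stages.  Writing
``K_j ~ Poisson(tau a_j(X_n))`` and the compensated fluctuation

    d_n = sum_j nu_j K_j - tau f(X_n),        f(x) = sum_j nu_j a_j(x),

the general explicit s-stage step is

    Y_i     = X_n + sum_{j<i} alpha_ij (tau f(Y_j) + d_n)
    X_{n+1} = X_n + tau sum_j beta_j f(Y_j) + d_n,

which uses ``omega_i d_n = (sum_j alpha_ij) d_n``.  All kernels evaluate the
update as ``X_n + sum_j nu_j K_j + tau (sum_j beta_j f(Y_j) - f(X_n))`` —
the same expression with ``d_n`` substituted — so that the single-stage
preset reproduces the plain Poisson tau-leap step exactly (same draws imply
equal states, bit for bit) and the efficient subdiagonal kernel reproduces
the general kernel exactly.

Failure semantics: a tau-leap replicate is marked *failed* when any Poisson
mean is negative or non-finite at a step start (a negative-population
excursion), when a mean overflows the Poisson sampler, or when any state
coordinate exceeds a divergence bound (default 1e12).  Failures are counted
and reported as a rate, never raised, by the ensemble drivers.

Reproducibility: :func:`simulate_ensemble` derives one independent
``SeedSequence`` substream per replicate by spawning the master seed, so
ensembles are order-independent and parallelizable.  The vectorized
helpers (:func:`ssa_end_states`, :func:`leap_end_states`) instead advance
all replicates in lockstep from a single seeded stream; they are the fast
path for histogram and variance studies at 1e4-1e5 replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import ReactionNetwork
from .stability import ButcherTableau

__all__ = [
    "StepKernelState",
    "TrajectoryEnsemble",
    "FailedStep",
    "ssa_step",
    "poisson_tau_leap_step",
    "rk_tau_leap_step",
    "rk_tau_leap_step_efficient",
    "simulate_ensemble",
    "ssa_end_states",
    "leap_end_states",
    "POISSON_TABLEAU",
]

#: Poisson means beyond this overflow the integer-valued sampler; treated as
#: divergence.
_LAM_MAX = 1e15

#: Single-stage tableau (A = 0, beta_1 = 1): the plain Poisson tau-leap.
POISSON_TABLEAU = ButcherTableau(A=np.zeros((1, 1)), b=np.ones(1))


class FailedStep(RuntimeError):
    """A tau-leap step produced an invalid Poisson mean (replicate failed)."""


@dataclass
class StepKernelState:
    """Current state of one trajectory: ``x``, time ``t`` and its RNG stream."""

    x: np.ndarray
    t: float
    rng: np.random.Generator


def _check_tableau(tab: ButcherTableau) -> None:
    if not tab.is_explicit:
        raise ValueError("tau-leap simulation supports explicit tableaus only")
    if abs(float(np.sum(tab.b)) - 1.0) > 1e-12:
        raise ValueError("simulation tableaus must satisfy sum(beta) = 1")


def _draw_poisson_set(net: ReactionNetwork, x: np.ndarray, tau: float, rng):
    """The one shared Poisson set of a step: returns ``(a, K)`` at ``X_n``."""
    a = net.propensities(x)
    mu = tau * a
    if not np.all(np.isfinite(mu)) or np.any(mu < 0.0) or np.any(mu > _LAM_MAX):
        raise FailedStep(f"invalid Poisson mean at state {x}")
    return a, rng.poisson(mu)


def ssa_step(net: ReactionNetwork, state: StepKernelState) -> StepKernelState | None:
    """One exact SSA event; returns ``None`` at absorption (all rates zero).

    The waiting time is exponential with rate ``a_0 = sum_j a_j`` and the
    firing channel is chosen by cumulative-sum inversion of ``a_j / a_0``.
    """
    a = net.propensities(state.x)
    a0 = float(a.sum())
    if a0 <= 0.0:
        return None
    dt = state.rng.exponential(1.0 / a0)
    k = int(np.searchsorted(np.cumsum(a), state.rng.random() * a0, side="right"))
    k = min(k, net.n_reactions - 1)
    return StepKernelState(x=state.x + net.nu[k], t=state.t + dt, rng=state.rng)


def poisson_tau_leap_step(
    net: ReactionNetwork, state: StepKernelState, tau: float
) -> StepKernelState:
    """One Poisson tau-leap step, ``X_{n+1} = X_n + sum_j nu_j K_j`` (integer)."""
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    _, K = _draw_poisson_set(net, state.x, tau, state.rng)
    x_new = state.x + K @ net.nu
    return StepKernelState(x=x_new, t=state.t + tau, rng=state.rng)


def _rk_update(net, x, tau, a0, K, stage_fn):
    """Shared RK update skeleton; ``stage_fn`` fills the stage drifts."""
    nu_f = net._nu_f
    k_change = K.astype(float) @ nu_f
    f0 = a0 @ nu_f
    d = k_change - tau * f0
    fsum = stage_fn(x, f0, d)
    return x + k_change + tau * (fsum - f0)


def rk_tau_leap_step(
    net: ReactionNetwork, tableau: ButcherTableau, state: StepKernelState, tau: float
) -> StepKernelState:
    """One general explicit s-stage RK tau-leap step (one Poisson set)."""
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    _check_tableau(tableau)
    x = np.asarray(state.x, dtype=float)
    a0, K = _draw_poisson_set(net, x, tau, state.rng)
    s = tableau.s
    A, b = tableau.A, tableau.b

    def stages(x, f0, d):
        F = np.empty((s, x.shape[-1]))
        G = np.empty_like(F)
        F[0] = f0
        G[0] = tau * f0 + d
        for i in range(1, s):
            Y = x + A[i, :i] @ G[:i]
            F[i] = net.drift(Y)
            G[i] = tau * F[i] + d
        return b @ F

    x_new = _rk_update(net, x, tau, a0, K, stages)
    return StepKernelState(x=x_new, t=state.t + tau, rng=state.rng)


def rk_tau_leap_step_efficient(
    net: ReactionNetwork, tableau: ButcherTableau, state: StepKernelState, tau: float
) -> StepKernelState:
    """Efficient subdiagonal form: ``Y_i = X_n + alpha_{i,i-1}(tau f(Y_{i-1}) + d_n)``.

    Requires ``beta_s = 1`` with all other weights zero and ``A`` zero off
    the first subdiagonal; uses ``s - 1`` stage drift evaluations and is
    exactly equivalent (same draws, same arithmetic) to the general kernel
    on the same tableau.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    _check_tableau(tableau)
    if not tableau.is_subdiagonal:
        raise ValueError(
            "tableau is not in efficient subdiagonal form; use rk_tau_leap_step"
        )
    x = np.asarray(state.x, dtype=float)
    a0, K = _draw_poisson_set(net, x, tau, state.rng)
    alphas = np.diag(tableau.A, k=-1)

    def stages(x, f0, d):
        F = f0
        G = tau * f0 + d
        for alpha in alphas:
            Y = x + alpha * G
            F = net.drift(Y)
            G = tau * F + d
        return F

    x_new = _rk_update(net, x, tau, a0, K, stages)
    return StepKernelState(x=x_new, t=state.t + tau, rng=state.rng)


@dataclass
class TrajectoryEnsemble:
    """Replicate end states plus failure bookkeeping and seed provenance."""

    method: str
    tau: float | None
    t_final: float
    n_replicates: int
    end_states: np.ndarray  # (n_replicates, N); NaN rows for failed replicates
    failed: np.ndarray  # (n_replicates,) bool
    seed: int
    species_names: list[str] = field(default_factory=list)
    paths: pd.DataFrame | None = None

    @property
    def n_failed(self) -> int:
        return int(self.failed.sum())

    @property
    def successful_states(self) -> np.ndarray:
        return self.end_states[~self.failed]

    def to_dataframe(self) -> pd.DataFrame:
        cols = self.species_names or [f"x{i}" for i in range(self.end_states.shape[1])]
        df = pd.DataFrame(self.end_states, columns=cols)
        df.insert(0, "replicate", np.arange(self.n_replicates))
        df["failed"] = self.failed
        return df

    def metadata(self) -> dict:
        return {
            "method": self.method,
            "tau": self.tau,
            "t_final": self.t_final,
            "n_replicates": self.n_replicates,
            "n_failed": self.n_failed,
            "seed": self.seed,
        }


def _run_ssa_replicate(net, x0, t_final, rng, record_every):
    state = StepKernelState(x=x0.copy(), t=0.0, rng=rng)
    records = []
    next_rec = 0.0
    while True:
        nxt = ssa_step(net, state)
        t_next = t_final if nxt is None else min(nxt.t, t_final)
        if record_every is not None:
            # state.x holds on [state.t, t_next); record the grid times inside
            while next_rec < t_next - 1e-12:
                records.append((next_rec, state.x.copy()))
                next_rec += record_every
        if nxt is None or nxt.t > t_final:
            break
        state = nxt
    if record_every is not None:
        while next_rec <= t_final + 1e-12:
            records.append((next_rec, state.x.copy()))
            next_rec += record_every
    return state.x, False, records


def _run_leap_replicate(net, x0, tau, n_steps, rng, kernel, record_every, bound):
    state = StepKernelState(x=x0, t=0.0, rng=rng)
    records = [(0.0, np.array(state.x, dtype=float))] if record_every else None
    for n in range(n_steps):
        try:
            state = kernel(state)
        except FailedStep:
            return state.x, True, records or []
        x_arr = np.asarray(state.x, dtype=float)
        if not np.all(np.isfinite(x_arr)) or np.any(np.abs(x_arr) > bound):
            return state.x, True, records or []
        if record_every and (n + 1) % record_every == 0:
            records.append((state.t, x_arr.copy()))
    return state.x, False, records or []


def simulate_ensemble(
    net: ReactionNetwork,
    method: str,
    *,
    t_final: float,
    n_replicates: int,
    seed: int,
    tau: float | None = None,
    tableau: ButcherTableau | None = None,
    x0: np.ndarray | None = None,
    record_every=None,
    divergence_bound: float = 1e12,
) -> TrajectoryEnsemble:
    """Run independent replicates of one method with per-replicate substreams.

    Parameters
    ----------
    method
        ``"ssa"``, ``"poisson"`` or ``"rk"`` (the latter requires a tableau;
        the efficient kernel is used when the tableau is in subdiagonal form).
    record_every
        For SSA, a time interval at which to record thinned path points; for
        leap methods, a step stride.  ``None`` disables path recording.
    """
    if method not in ("ssa", "poisson", "rk"):
        raise ValueError(f"unknown method {method!r}")
    if method in ("poisson", "rk") and (tau is None or tau <= 0):
        raise ValueError("leap methods require tau > 0")
    if method == "rk":
        if tableau is None:
            raise ValueError("method 'rk' requires a tableau")
        _check_tableau(tableau)
    x0 = net.initial_state if x0 is None else np.asarray(x0)
    N = net.n_species
    end = np.full((n_replicates, N), np.nan)
    failed = np.zeros(n_replicates, dtype=bool)
    all_records = []
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    n_steps = int(round(t_final / tau)) if tau else 0
    for i in range(n_replicates):
        rng = np.random.default_rng(children[i])
        if method == "ssa":
            xi, fail, recs = _run_ssa_replicate(
                net, x0.astype(np.int64), t_final, rng, record_every
            )
        else:
            if method == "poisson":
                kernel = lambda st: poisson_tau_leap_step(net, st, tau)
                xi0 = x0.astype(np.int64)
            else:
                step = (
                    rk_tau_leap_step_efficient
                    if tableau.is_subdiagonal
                    else rk_tau_leap_step
                )
                kernel = lambda st: step(net, tableau, st, tau)
                xi0 = x0.astype(float)
            xi, fail, recs = _run_leap_replicate(
                net, xi0, tau, n_steps, rng, kernel, record_every, divergence_bound
            )
        failed[i] = fail
        if not fail:
            end[i] = xi
        if record_every is not None:
            for t_rec, x_rec in recs:
                all_records.append((i, t_rec, *x_rec))
    paths = None
    if record_every is not None:
        paths = pd.DataFrame(
            all_records, columns=["replicate", "time", *net.species_names]
        )
    label = method if method != "rk" else f"rk(s={tableau.s})"
    return TrajectoryEnsemble(
        method=label,
        tau=tau,
        t_final=t_final,
        n_replicates=n_replicates,
        end_states=end,
        failed=failed,
        seed=seed,
        species_names=list(net.species_names),
        paths=paths,
    )


# ---------------------------------------------------------------------------
# Vectorized single-stream fast paths
# ---------------------------------------------------------------------------

def ssa_end_states(
    net: ReactionNetwork,
    *,
    t_final: float,
    n_replicates: int,
    seed: int,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Exact SSA end states for many replicates, advanced in lockstep.

    All replicates share one seeded stream (deterministic given ``seed``);
    each replicate freezes at the last state before its waiting time would
    cross ``t_final``.  Returns an ``(n_replicates, N)`` integer array.
    """
    rng = np.random.default_rng(seed)
    x0 = net.initial_state if x0 is None else np.asarray(x0, dtype=np.int64)
    x = np.tile(x0, (n_replicates, 1))
    t = np.zeros(n_replicates)
    active = np.ones(n_replicates, dtype=bool)
    nu = net.nu
    while np.any(active):
        idx = np.flatnonzero(active)
        a = net.propensities(x[idx])
        a0 = a.sum(axis=1)
        alive = a0 > 0.0
        if not np.all(alive):  # absorbed replicates stop advancing
            active[idx[~alive]] = False
            idx, a, a0 = idx[alive], a[alive], a0[alive]
            if idx.size == 0:
                continue
        t_new = t[idx] + rng.exponential(1.0, size=idx.size) / a0
        fire = t_new <= t_final
        done = idx[~fire]
        active[done] = False
        idx, a, a0, t_new = idx[fire], a[fire], a0[fire], t_new[fire]
        if idx.size == 0:
            continue
        u = rng.random(idx.size) * a0
        ch = (np.cumsum(a, axis=1) <= u[:, None]).sum(axis=1)
        np.clip(ch, 0, net.n_reactions - 1, out=ch)
        x[idx] += nu[ch]
        t[idx] = t_new
    return x


def leap_end_states(
    net: ReactionNetwork,
    tableau: ButcherTableau,
    *,
    tau: float,
    n_steps: int,
    n_replicates: int,
    seed: int,
    x0: np.ndarray | None = None,
    divergence_bound: float = 1e12,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched RK tau-leap over a fixed number of steps (single stream).

    Runs the general explicit kernel on all replicates at once (one Poisson
    set of shape ``(n_replicates, m)`` per step).  Returns ``(end_states,
    failed)``; failed replicates hold NaN and stop being advanced.
    """
    _check_tableau(tableau)
    rng = np.random.default_rng(seed)
    x0 = net.initial_state if x0 is None else np.asarray(x0)
    x = np.tile(x0.astype(float), (n_replicates, 1))
    failed = np.zeros(n_replicates, dtype=bool)
    nu_f = net._nu_f
    s, A, b = tableau.s, tableau.A, tableau.b
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(n_steps):
            a = net.propensities(x)
            mu = tau * a
            bad = ~np.all(np.isfinite(mu) & (mu >= 0.0) & (mu <= _LAM_MAX), axis=1)
            newly = bad & ~failed
            if np.any(newly):
                failed |= newly
            mu = np.where(failed[:, None], 0.0, mu)
            K = rng.poisson(mu).astype(float)
            k_change = K @ nu_f
            f0 = a @ nu_f
            d = k_change - tau * f0
            F = np.empty((s,) + x.shape)
            G = np.empty_like(F)
            F[0] = f0
            G[0] = tau * f0 + d
            for i in range(1, s):
                Y = x + np.tensordot(A[i, :i], G[:i], axes=1)
                F[i] = net.propensities(Y) @ nu_f
                G[i] = tau * F[i] + d
            fsum = np.tensordot(b, F, axes=1)
            x_new = x + k_change + tau * (fsum - f0)
            diverged = ~np.all(
                np.isfinite(x_new) & (np.abs(x_new) <= divergence_bound), axis=1
            )
            failed |= diverged
            x = np.where(failed[:, None], x, x_new)
    x[failed] = np.nan
    return x, failed
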