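"""Simulation kernels and ensemble drivers."""

import numpy as np
import pytest

import rkleap as rk
from rkleap.networks import Linear
from rkleap.simulate import FailedStep, StepKernelState


def make_state(x, seed=0, dtype=None):
    arr = np.asarray(x, dtype=dtype) if dtype else np.asarray(x)
    return StepKernelState(x=arr, t=0.0, rng=np.random.default_rng(seed))


def decay_network(k=1.0, n0=5):
    return rk.ReactionNetwork(["S"], np.array([[-1]]), [Linear(c=(k,))], [n0])


class TestSSA:
    def test_forced_channel(self):
        """From (T, 0) only the forward channel can fire."""
        net = rk.isomerisation_network(rk.IsomerisationSpec(k1=5, k2=5, T=10, X0=(10, 0)))
        nxt = rk.ssa_step(net, make_state([10, 0]))
        assert np.array_equal(nxt.x, [9, 1])

    def test_absorption_signalled(self):
        net = decay_network()
        assert rk.ssa_step(net, make_state([0])) is None

    def test_extinction_time_matches_harmonic_sum(self):
        """Pure decay from n: E[T_ext] = sum_{i<=n} 1/(k i) (sum of exponentials)."""
        k, n0, reps = 1.0, 5, 2000
        net = decay_network(k, n0)
        rng = np.random.default_rng(123)
        times = np.empty(reps)
        for r in range(reps):
            st = StepKernelState(x=np.array([n0]), t=0.0, rng=rng)
            while (nxt := rk.ssa_step(net, st)) is not None:
                st = nxt
            times[r] = st.t
        expect = sum(1.0 / (k * i) for i in range(1, n0 + 1))
        sd = np.sqrt(sum(1.0 / (k * i) ** 2 for i in range(1, n0 + 1)))
        assert abs(times.mean() - expect) < 3 * sd / np.sqrt(reps)

    def test_lockstep_ssa_matches_binomial_stationary_law(self, iso_sym, iso_spec_sym):
        """Chi-square GOF of SSA end states against the exact Binomial(T, 1/2)."""
        from scipy import stats

        end = rk.ssa_end_states(iso_sym, t_final=0.5, n_replicates=10_000, seed=99)
        pmf = rk.isomerisation_stationary_pmf(iso_spec_sym)
        counts = np.bincount(end[:, 0], minlength=201).astype(float)
        # pool tail bins so every expected count is >= 5
        expected = pmf * 10_000
        order = np.argsort(-expected)
        pooled_obs, pooled_exp, acc_o, acc_e = [], [], 0.0, 0.0
        for idx in order:
            if expected[idx] >= 5:
                pooled_obs.append(counts[idx])
                pooled_exp.append(expected[idx])
            else:
                acc_o += counts[idx]
                acc_e += expected[idx]
        pooled_obs.append(acc_o)
        pooled_exp.append(acc_e)
        stat, p = stats.chisquare(pooled_obs, np.array(pooled_exp) * sum(pooled_obs) / sum(pooled_exp))
        assert p > 0.01


class TestPoissonLeap:
    def test_zero_propensities_leave_state(self):
        net = decay_network()
        st = make_state([0])
        nxt = rk.poisson_tau_leap_step(net, st, 0.5)
        assert np.array_equal(nxt.x, [0])

    def test_one_step_mean_is_euler_drift(self, iso_sym):
        x0 = np.array([150, 50])
        tau = 0.02
        states = np.empty((4000, 2))
        rng = np.random.default_rng(5)
        for i in range(4000):
            st = StepKernelState(x=x0.copy(), t=0.0, rng=rng)
            states[i] = rk.poisson_tau_leap_step(iso_sym, st, tau).x
        expect = x0 + tau * iso_sym.drift(x0)
        se = states.std(axis=0, ddof=1) / np.sqrt(4000)
        assert np.all(np.abs(states.mean(axis=0) - expect) < 3 * se)

    def test_negative_mean_fails_replicate(self, iso_sym):
        st = StepKernelState(
            x=np.array([-5.0, 205.0]), t=0.0, rng=np.random.default_rng(0)
        )
        with pytest.raises(FailedStep):
            rk.rk_tau_leap_step(iso_sym, rk.POISSON_TABLEAU, st, 0.1)

    def test_instability_beyond_z_minus_two(self, iso_sym):
        """Poisson tau-leap diverges when z = -20 tau drops below -2."""
        _, failed = rk.leap_end_states(
            iso_sym, rk.POISSON_TABLEAU, tau=0.15, n_steps=60, n_replicates=500, seed=8
        )
        assert failed.mean() > 0.9


class TestRKKernels:
    def test_single_stage_preset_equals_poisson_kernel(self, iso_sym):
        rng_a, rng_b = np.random.default_rng(42), np.random.default_rng(42)
        st_a = StepKernelState(x=iso_sym.initial_state.copy(), t=0.0, rng=rng_a)
        st_b = StepKernelState(x=iso_sym.initial_state.astype(float), t=0.0, rng=rng_b)
        for _ in range(50):
            st_a = rk.poisson_tau_leap_step(iso_sym, st_a, 0.05)
            st_b = rk.rk_tau_leap_step(iso_sym, rk.POISSON_TABLEAU, st_b, 0.05)
            assert np.array_equal(st_a.x.astype(float), st_b.x)

    @pytest.mark.parametrize("preset", ["rk-tauleap-s3-eps0.5", "rk-tauleap-s5-eps0.1"])
    def test_efficient_kernel_equals_general(self, schlogl, preset):
        tab = rk.get_tableau(preset)
        rng_a, rng_b = np.random.default_rng(7), np.random.default_rng(7)
        st_a = StepKernelState(x=schlogl.initial_state.astype(float), t=0.0, rng=rng_a)
        st_b = StepKernelState(x=schlogl.initial_state.astype(float), t=0.0, rng=rng_b)
        for _ in range(100):
            st_a = rk.rk_tau_leap_step(schlogl, tab, st_a, 0.4)
            st_b = rk.rk_tau_leap_step_efficient(schlogl, tab, st_b, 0.4)
            assert np.array_equal(st_a.x, st_b.x)

    def test_efficient_kernel_rejects_dense_tableau(self, schlogl):
        dense = rk.ButcherTableau(
            A=np.array([[0, 0, 0], [0.3, 0, 0], [0.1, 0.2, 0]], dtype=float),
            b=np.array([0.2, 0.3, 0.5]),
        )
        with pytest.raises(ValueError, match="subdiagonal"):
            rk.rk_tau_leap_step_efficient(
                schlogl, dense, make_state([250], dtype=float), 0.1
            )

    def test_implicit_tableau_rejected(self, schlogl):
        im = rk.get_tableau("implicit-midpoint")
        with pytest.raises(ValueError, match="explicit"):
            rk.rk_tau_leap_step(schlogl, im, make_state([250], dtype=float), 0.1)

    def test_one_poisson_set_per_step(self, schlogl, counting_rng):
        """m draws from a single poisson() call per step, for any stage count."""
        for preset in ("poisson", "rk-tauleap-s5-eps0.1"):
            tab = rk.get_tableau(preset)
            rng = counting_rng(3)
            st = StepKernelState(x=schlogl.initial_state.astype(float), t=0.0, rng=rng)
            for _ in range(10):
                st = rk.rk_tau_leap_step(schlogl, tab, st, 0.2)
            assert rng.poisson_calls == 10
            assert rng.poisson_draws == 10 * schlogl.n_reactions

    def test_stage_drift_evaluations(self, schlogl, counting_network):
        """The efficient kernel uses s - 1 stage drift evaluations per step."""
        tab = rk.get_tableau("rk-tauleap-s5-eps0.1")
        net = counting_network(schlogl)
        st = make_state(schlogl.initial_state.astype(float), seed=1)
        rk.rk_tau_leap_step_efficient(net, tab, st, 0.2)
        assert net.drift_calls == tab.s - 1

    def test_deterministic_limit_is_classical_rk(self, iso_sym, midpoint_tab):
        """With Poisson draws replaced by their means, the step is the ODE RK step."""

        class MeanRNG:
            def poisson(self, lam):
                return np.asarray(lam, dtype=float)

        x0 = np.array([150.0, 50.0])
        tau = 0.03
        st = StepKernelState(x=x0.copy(), t=0.0, rng=MeanRNG())
        got = rk.rk_tau_leap_step(iso_sym, midpoint_tab, st, tau).x
        # classical explicit midpoint on x' = f(x)
        k1 = iso_sym.drift(x0)
        k2 = iso_sym.drift(x0 + 0.5 * tau * k1)
        assert np.allclose(got, x0 + tau * k2, rtol=1e-12)


class TestEnsembles:
    def test_empty_ensemble(self, iso_sym):
        ens = rk.simulate_ensemble(
            iso_sym, "poisson", tau=0.05, t_final=0.5, n_replicates=0, seed=1
        )
        assert ens.n_failed == 0
        assert ens.end_states.shape == (0, 2)
        assert rk.failure_rate(ens) == 0.0

    def test_identical_seed_identical_ensemble(self, iso_sym):
        kw = dict(tau=0.05, t_final=1.0, n_replicates=40, seed=77)
        a = rk.simulate_ensemble(iso_sym, "poisson", **kw)
        b = rk.simulate_ensemble(iso_sym, "poisson", **kw)
        assert np.array_equal(a.end_states, b.end_states, equal_nan=True)
        assert np.array_equal(a.failed, b.failed)

    def test_failures_counted_not_raised(self, iso_sym):
        ens = rk.simulate_ensemble(
            iso_sym, "poisson", tau=0.2, t_final=12.0, n_replicates=50, seed=3
        )
        assert ens.n_failed > 25  # z = -4 is far outside (-2, 0]
        assert ens.n_failed + (~ens.failed).sum() == 50

    def test_rk_ensemble_runs_and_is_stable(self, iso_sym):
        tab = rk.get_tableau("rk-tauleap-s3-eps0.5")
        ens = rk.simulate_ensemble(
            iso_sym, "rk", tableau=tab, tau=0.4, t_final=8.0, n_replicates=60, seed=4
        )
        assert ens.n_failed == 0
        assert ens.successful_states[:, 0].std() > 0

    def test_ssa_path_recording(self, iso_sym):
        ens = rk.simulate_ensemble(
            iso_sym, "ssa", t_final=0.2, n_replicates=3, seed=5, record_every=0.05
        )
        assert ens.paths is not None
        per_rep = ens.paths.groupby("replicate").size()
        assert (per_rep == 5).all()  # t = 0, 0.05, ..., 0.2
        # path totals conserved
        assert (ens.paths["S1"] + ens.paths["S2"] == 200).all()

    def test_dataframe_round_trip(self, iso_sym, tmp_path):
        ens = rk.simulate_ensemble(
            iso_sym, "poisson", tau=0.05, t_final=0.5, n_replicates=10, seed=6
        )
        df = ens.to_dataframe()
        assert list(df.columns) == ["replicate", "S1", "S2", "failed"]
        assert len(df) == 10

    def test_vectorized_leap_matches_theory_mean(self, iso_sym, midpoint_tab):
        W = iso_sym.linear_kinetics().W
        tau, n = 0.05, 6
        x0 = np.array([150, 50])
        end, failed = rk.leap_end_states(
            iso_sym, midpoint_tab, tau=tau, n_steps=n, n_replicates=8000, seed=21, x0=x0
        )
        assert not failed.any()
        M = np.linalg.matrix_power(rk.mean_propagator(midpoint_tab, tau, W), n)
        se = end.std(axis=0, ddof=1) / np.sqrt(len(end))
        assert np.all(np.abs(end.mean(axis=0) - M @ x0) < 3 * se)
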