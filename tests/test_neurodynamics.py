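"""Wilson–Cowan network: thresholds, derivatives, integration."""

import numpy as np
import pytest
from scipy import optimize

from pathodyn.neurodynamics import (PathologyProfile, SimulationDivergence,
                                    ThetaTriplet, WCParams,
                                    effective_threshold, multisine_input,
                                    simulate_network, wc_derivatives)


class TestEffectiveThreshold:
    def test_zero_pathology_gives_baseline(self):
        params = WCParams()
        profile = PathologyProfile(abeta=np.zeros(5), tau=np.zeros(5))
        thetas = ThetaTriplet(0.7, -0.3, 1.2)
        assert np.allclose(effective_threshold(params, thetas, profile),
                           params.theta0)

    def test_direct_substitution(self):
        # theta0=4, weights (0.5, -0.3, 1.0), fields (0.2, 0.5)
        params = WCParams(theta0=4.0)
        profile = PathologyProfile(abeta=np.array([0.2]), tau=np.array([0.5]))
        thetas = ThetaTriplet(0.5, -0.3, 1.0)
        out = effective_threshold(params, thetas, profile)
        assert out == pytest.approx([4.0 + 0.10 - 0.15 + 0.10])

    def test_zero_weights_any_pathology(self):
        params = WCParams()
        rng = np.random.default_rng(0)
        profile = PathologyProfile(abeta=rng.random(8), tau=rng.random(8))
        out = effective_threshold(params, ThetaTriplet(), profile)
        assert np.allclose(out, params.theta0)

    def test_pathology_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            PathologyProfile(abeta=np.array([1.5]), tau=np.array([0.2]))


class TestDerivatives:
    def test_rest_is_fixed_point_without_input(self):
        params = WCParams(P=0.0)
        C = np.zeros((3, 3))
        dE, dI, _ = wc_derivatives(np.zeros(3), np.zeros(3), params, C,
                                   np.full(3, params.theta0))
        assert np.allclose(dE, 0.0) and np.allclose(dI, 0.0)

    def test_zero_coupling_decouples_regions(self):
        params = WCParams(g=0.0)
        rng = np.random.default_rng(1)
        C = rng.random((4, 4))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 0)
        E, I = rng.random(4), rng.random(4)
        thr = np.full(4, params.theta0)
        dE, dI, _ = wc_derivatives(E, I, params, C, thr)
        for k in range(4):
            dEk, dIk, _ = wc_derivatives(E[k:k + 1], I[k:k + 1], params,
                                         np.zeros((1, 1)), thr[k:k + 1])
            assert dE[k] == pytest.approx(dEk[0], abs=1e-14)
            assert dI[k] == pytest.approx(dIk[0], abs=1e-14)

    def test_single_region_fixed_point_matches_root_search(self):
        """Fixed point from the derivative function agrees with an
        independent 2-D root search on the same equations to 1e-8."""
        params = WCParams(theta0=5.0)
        C = np.zeros((1, 1))
        thr = np.array([5.0])

        def fun(x):
            dE, dI, _ = wc_derivatives(x[:1], x[1:], params, C, thr)
            return [dE[0], dI[0]]

        sol = optimize.root(fun, [0.05, 0.05], tol=1e-12)
        assert sol.success
        dE, dI, _ = wc_derivatives(sol.x[:1], sol.x[1:], params, C, thr)
        assert abs(dE[0]) < 1e-8 and abs(dI[0]) < 1e-8

    def test_dimension_mismatch_rejected(self):
        params = WCParams()
        with pytest.raises(ValueError):
            wc_derivatives(np.zeros(2), np.zeros(3), params, np.zeros((3, 3)),
                           np.zeros(3))


def _stable_fixed_point(params, theta):
    C = np.zeros((1, 1))
    thr = np.array([float(theta)])

    def fun(x):
        dE, dI, _ = wc_derivatives(x[:1], x[1:], params, C, thr)
        return [dE[0], dI[0]]

    sol = optimize.root(fun, [0.05, 0.05], tol=1e-13)
    assert sol.success
    return sol.x


class TestSimulation:
    def test_fixed_point_initial_state_stays_constant(self):
        params = WCParams(theta0=5.0)
        fp = _stable_fixed_point(params, 5.0)
        out = simulate_network(params, np.zeros((1, 1)), np.array([5.0]),
                               duration=2.0, dt=0.001, burn_in=0.0,
                               initial_state=(fp[0], fp[1]))
        assert np.max(np.abs(out.E - fp[0])) < 1e-6
        assert np.max(np.abs(out.I - fp[1])) < 1e-6

    def test_dt_halving_self_convergence(self, small_connectome):
        params = WCParams()
        thr = np.full(small_connectome.n_regions, params.theta0 + 0.5)
        finals = []
        for dt in (0.002, 0.001):
            out = simulate_network(params, small_connectome, thr,
                                   duration=2.0, dt=dt, burn_in=0.0)
            finals.append((out.E[:, -1].copy(), out.I[:, -1].copy()))
        assert np.max(np.abs(finals[0][0] - finals[1][0])) < 1e-5
        assert np.max(np.abs(finals[0][1] - finals[1][1])) < 1e-5

    def test_decoupling_equivalence(self, small_connectome):
        """g=0 network simulation equals independent per-region runs."""
        params = WCParams(g=0.0)
        n = small_connectome.n_regions
        thr = np.linspace(3.5, 5.5, n)
        full = simulate_network(params, small_connectome, thr, duration=1.0,
                                dt=0.001, burn_in=0.0)
        for k in range(0, n, 5):
            solo = simulate_network(params, np.zeros((1, 1)), thr[k:k + 1],
                                    duration=1.0, dt=0.001, burn_in=0.0)
            assert np.max(np.abs(full.E[k] - solo.E[0])) < 1e-10
            assert np.max(np.abs(full.I[k] - solo.I[0])) < 1e-10

    def test_seeded_stochastic_run_reproducible(self, small_connectome):
        params = WCParams(noise_sd=0.1)
        thr = np.full(small_connectome.n_regions, 4.0)
        a = simulate_network(params, small_connectome, thr, duration=1.0,
                             dt=0.001, burn_in=0.0, seed=7)
        b = simulate_network(params, small_connectome, thr, duration=1.0,
                             dt=0.001, burn_in=0.0, seed=7)
        assert np.array_equal(a.E, b.E) and np.array_equal(a.I, b.I)

    @pytest.mark.parametrize("seed", range(5))
    def test_trajectories_bounded(self, small_connectome, seed):
        """States started in the unit box stay within [-0.1, 1.1]."""
        rng = np.random.default_rng(seed)
        params = WCParams(noise_sd=0.05)
        thr = np.full(small_connectome.n_regions,
                      4.0 + rng.uniform(-1, 1))
        out = simulate_network(params, small_connectome, thr, duration=2.0,
                               dt=0.001, burn_in=0.0, seed=seed,
                               initial_state=float(rng.uniform(0, 1)))
        assert out.E.min() > -0.1 and out.E.max() < 1.1
        assert out.I.min() > -0.1 and out.I.max() < 1.1

    def test_threshold_monotonicity_at_fixed_point(self):
        """Raising the excitatory threshold lowers the equilibrium E."""
        params = WCParams(theta0=4.0)
        es = [_stable_fixed_point(params, th)[0]
              for th in np.arange(4.5, 6.01, 0.5)]
        assert np.all(np.diff(es) < 0)

    def test_divergence_reports_step(self, small_connectome):
        params = WCParams(tau_e=1e-9)  # absurd stiffness forces blow-up
        thr = np.full(small_connectome.n_regions, 4.0)
        with pytest.raises(SimulationDivergence, match="step"):
            simulate_network(params, small_connectome, thr, duration=0.5,
                             dt=0.001, burn_in=0.0)

    def test_invalid_durations_rejected(self, small_connectome):
        params = WCParams()
        thr = np.full(small_connectome.n_regions, 4.0)
        with pytest.raises(ValueError):
            simulate_network(params, small_connectome, thr, duration=1.0,
                             burn_in=2.0)
        with pytest.raises(ValueError):
            simulate_network(params, small_connectome, thr, duration=1.0,
                             dt=-0.1)


def test_multisine_rms_and_determinism():
    x = multisine_input(100.0, 0.01, amplitude=0.4, seed=3)
    y = multisine_input(100.0, 0.01, amplitude=0.4, seed=3)
    assert np.array_equal(x, y)
    assert np.sqrt(np.mean(x ** 2)) == pytest.approx(0.4, rel=0.1)
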