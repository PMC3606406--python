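import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad, solve_ivp

import splaynet as sn
from splaynet.dynamics import FieldState, advance_potentials, field_between

from conftest import A, ALPHA, G


class TestPulseShape:
    def test_zero_at_origin_and_peak(self):
        assert sn.pulse_shape(0.0, ALPHA, 10) == 0.0
        # maximise alpha^2 t e^{-alpha t}: peak at t = 1/alpha, value alpha/e
        t_star = 1 / ALPHA
        assert sn.pulse_shape(t_star, ALPHA, 10) == pytest.approx(ALPHA * np.exp(-1) / 10)
        t = np.linspace(0, 2, 2001)
        assert np.max(sn.pulse_shape(t, ALPHA, 10)) <= sn.pulse_shape(t_star, ALPHA, 10)

    def test_unit_area_per_neuron(self):
        val, _ = quad(lambda t: sn.pulse_shape(t, 3.7, 25), 0, np.inf)
        assert val == pytest.approx(1 / 25, rel=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            sn.pulse_shape(-0.1, ALPHA, 10)


class TestFieldMap:
    def test_zero_interval_only_kicks(self):
        fs = sn.field_map(FieldState(0.3, 1.1), 0.0, ALPHA, 20)
        assert fs.E == pytest.approx(0.3)
        assert fs.P == pytest.approx(1.1 + ALPHA**2 / 20)

    def test_from_rest(self):
        fs = sn.field_map(FieldState(0.0, 0.0), 0.37, ALPHA, 20)
        assert fs == (0.0, ALPHA**2 / 20)

    @given(E0=st.floats(0.0, 3.0), P0=st.floats(0.0, 30.0),
           tau=st.floats(1e-4, 1.0), alpha=st.floats(0.5, 12.0))
    def test_matches_ode_oracle(self, E0, P0, tau, alpha):
        # E obeys E'' + 2 alpha E' + alpha^2 E = 0 between spikes
        sol = solve_ivp(lambda t, y: [y[1], -2 * alpha * y[1] - alpha**2 * y[0]],
                        (0, tau), [E0, P0 - alpha * E0],
                        method="DOP853", rtol=1e-12, atol=1e-14)
        E_ref = sol.y[0, -1]
        P_ref = alpha * sol.y[0, -1] + sol.y[1, -1] + alpha**2 / 20
        fs = sn.field_map(FieldState(E0, P0), tau, alpha, 20)
        assert fs.E == pytest.approx(E_ref, abs=1e-11)
        assert fs.P == pytest.approx(P_ref, abs=1e-11)

    def test_n_fold_composition_matches_geometric_closed_form(self):
        # P is an affine recursion, E follows by a geometric sum
        E0, P0, tau, alpha, N, n = 0.8, 2.0, 0.05, ALPHA, 30, 40
        fs = FieldState(E0, P0)
        for _ in range(n):
            fs = sn.field_map(fs, tau, alpha, N)
        q = np.exp(-alpha * tau)
        c = alpha**2 / N
        p_star = c / (1 - q)
        P_n = p_star + (P0 - p_star) * q**n
        E_n = q**n * E0 + tau * p_star * q * (1 - q**n) / (1 - q) \
            + tau * (P0 - p_star) * n * q**n
        assert fs.P == pytest.approx(P_n, abs=1e-12)
        assert fs.E == pytest.approx(E_n, abs=1e-12)


class TestLifChi:
    def test_zero_interval(self):
        assert sn.dynamics.lif_chi(0.0, FieldState(0.5, 2.0), A, G, ALPHA) == 0.0

    def test_uncoupled_reduces_to_free_charge(self):
        tau = 0.3
        got = sn.dynamics.lif_chi(tau, FieldState(0.5, 2.0), A, 0.0, ALPHA)
        assert got == pytest.approx(A * (1 - np.exp(-tau)), rel=1e-14)

    @given(E0=st.floats(0.0, 2.0), P0=st.floats(0.0, 20.0), tau=st.floats(1e-3, 0.5))
    def test_matches_variation_of_constants_quadrature(self, E0, P0, tau):
        fs = FieldState(E0, P0)
        forced, _ = quad(lambda s: np.exp(s - tau) * field_between(fs, s, ALPHA), 0, tau,
                         epsabs=1e-14, epsrel=1e-13)
        ref = A * (1 - np.exp(-tau)) + G * forced
        assert sn.dynamics.lif_chi(tau, fs, A, G, ALPHA) == pytest.approx(ref, abs=1e-12)

    def test_alpha_one_rejected(self):
        with pytest.raises(ValueError, match="alpha = 1"):
            sn.dynamics.lif_chi(0.1, FieldState(0.0, 0.0), A, G, 1.0)


class TestInterspikeTime:
    def test_inverts_free_lif_closed_form(self, lif):
        tau0 = 0.01
        u1 = 1 - (A - 1) * (np.exp(tau0) - 1)  # exact free-flight inversion
        state = sn.NetworkState(np.array([u1, 0.5, 0.0]), FieldState(0.0, 0.0))
        tau = sn.interspike_time(state, lif, 0.0, ALPHA)
        assert tau == pytest.approx(tau0, abs=1e-12)

    def test_vanishes_at_threshold(self, lif):
        u1 = 1 - 1e-12
        state = sn.NetworkState(np.array([u1, 0.0]), FieldState(0.1, 1.0))
        assert sn.interspike_time(state, lif, G, ALPHA) < 1e-11

    def test_generic_path_agrees_with_closed_form(self, lif, lif_generic):
        state = sn.NetworkState(np.array([0.9, 0.5, 0.2, 0.0]), FieldState(0.8, 3.0))
        t_exact = sn.interspike_time(state, lif, G, ALPHA)
        t_num = sn.interspike_time(state, lif_generic, G, ALPHA)
        assert t_num == pytest.approx(t_exact, abs=1e-10)

    def test_not_firing_error(self, lif):
        # an essentially constant, strongly inhibitory field never lets u reach 1
        state = sn.NetworkState(np.array([0.9, 0.0]), FieldState(1.0, 0.0))
        with pytest.raises(sn.NotFiringError):
            sn.interspike_time(state, lif, -1e6, 0.01)


class TestStep:
    def test_splay_fixed_point_invariance(self, lif, splay50):
        state = splay50.to_network_state()
        new = sn.step(state, lif, G, ALPHA)
        assert np.max(np.abs(new.u - state.u)) < 1e-10
        assert new.t == pytest.approx(splay50.tau, abs=1e-10)
        assert new.spike_count == 1

    def test_two_neuron_symmetric_state_halves_free_period(self, lif):
        T_free = np.log(A / (A - 1))
        u_half = A * (1 - np.exp(-T_free / 2))
        state = sn.NetworkState(np.array([u_half, 0.0]), FieldState(0.0, 0.0))
        new = sn.step(state, lif, 0.0, ALPHA)
        assert new.t == pytest.approx(T_free / 2, abs=1e-10)

    def test_lif_and_generic_paths_agree(self, lif, lif_generic, splay50):
        rng = np.random.default_rng(11)
        for _ in range(5):
            u = np.sort(rng.uniform(0.0, 0.98, 7))[::-1]
            u = np.concatenate([u, [0.0]])
            state = sn.NetworkState(u, FieldState(0.6, 2.0))
            a = sn.step(state.copy(), lif, G, ALPHA)
            b = sn.step(state.copy(), lif_generic, G, ALPHA)
            assert np.max(np.abs(a.u - b.u)) < 1e-9
            assert a.t == pytest.approx(b.t, abs=1e-9)

    def test_state_invariants_preserved(self, lif):
        state = sn.NetworkState(np.array([0.8, 0.6, 0.3, 0.0]), FieldState(0.2, 1.0))
        new = sn.step(state, lif, G, ALPHA)
        assert new.u.size == 4
        assert new.u[-1] == 0.0
        assert np.all(np.diff(new.u) < 0) and new.u[0] < 1.0

    def test_ordering_validation(self):
        state = sn.NetworkState(np.array([0.5, 0.5, 0.0]), FieldState(0.0, 0.0))
        with pytest.raises(sn.OrderingError):
            state.validate()


class TestSeriesUpdate:
    def test_zero_interval_identity(self, lif):
        u = np.array([0.7, 0.2])
        got = sn.dynamics.potential_update_series(u, FieldState(0.5, 2.0), 0.0,
                                                  lif, G, ALPHA)
        assert np.allclose(got, u)

    def test_defect_is_fifth_order_in_tau(self, lif):
        # Richardson: halving tau shrinks the defect vs the exact map ~32x
        fs = FieldState(0.8, 3.0)
        u = np.array([0.55])

        def defect(tau):
            exact = advance_potentials(u, fs, tau, lif, G, ALPHA)
            ser = sn.dynamics.potential_update_series(u, fs, tau, lif, G, ALPHA)
            return abs(float(exact[0] - ser[0]))

        r = defect(0.02) / defect(0.01)
        assert 25 < r < 40

    def test_uncoupled_matches_ode_oracle_to_fifth_order(self, lif):
        u0, tau = 0.4, 0.02
        sol = solve_ivp(lambda t, y: A - y, (0, tau), [u0], method="DOP853",
                        rtol=1e-13, atol=1e-15)
        ser = sn.dynamics.potential_update_series(np.array([u0]), FieldState(0.0, 0.0),
                                                  tau, lif, 0.0, ALPHA)
        assert abs(sol.y[0, -1] - ser[0]) < 10 * tau**5


class TestSimulate:
    def test_splay_state_fires_at_constant_intervals(self, lif, splay50):
        res = sn.simulate(splay50.to_network_state(), lif, G, ALPHA, n_spikes=150)
        assert np.max(np.abs(res.taus - splay50.tau)) < 1e-8
        # every neuron fires exactly once per period
        counts = np.bincount(res.neuron_ids, minlength=51)[1:]
        assert np.all(counts == 3)

    def test_time_bookkeeping(self, lif):
        state = sn.NetworkState(np.array([0.9, 0.4, 0.0]), FieldState(0.0, 0.0))
        res = sn.simulate(state, lif, G, ALPHA, n_spikes=7)
        assert res.final_state.t == pytest.approx(np.sum(res.taus))
        assert res.final_state.spike_count == 7

    def test_jittered_splay_relaxes_when_stable(self, lif):
        # alpha = 3: all Floquet exponents negative, so interval jitter decays
        alpha = 3.0
        st8 = sn.lif_splay_exact(A, G, alpha, 8)
        rng = np.random.default_rng(3)
        u = st8.u.copy()
        u[:-1] += 1e-3 * rng.uniform(-1, 1, 7)
        u[:-1] = np.sort(u[:-1])[::-1]
        state = sn.NetworkState(u, st8.fields)
        res = sn.simulate(state, lif, G, alpha, n_spikes=8 * 120)
        isi_std_early = np.std(res.taus[:80])
        isi_std_late = np.std(res.taus[-80:])
        assert isi_std_late < 0.5 * isi_std_early
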