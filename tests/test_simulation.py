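"""Integration engine: synaptic currents, RK4 accuracy, delays, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import aeifnet as an
from aeifnet.simulate import _heterogeneity, initial_state


def _graph_from_edges(n, is_exc, edges, weights, autaptic=None):
    """Hand-built NetworkGraph: edges as (pre, post, class) triples."""
    from aeifnet.network import EDGE_CLASSES

    code = {c: i for i, c in enumerate(EDGE_CLASSES)}
    pre = np.array([e[0] for e in edges], dtype=np.int64)
    post = np.array([e[1] for e in edges], dtype=np.int64)
    cls = np.array([code[e[2]] for e in edges], dtype=np.int8)
    if autaptic is None:
        autaptic = np.zeros(n, dtype=bool)
    return an.NetworkGraph(
        n=n, is_exc=np.asarray(is_exc, bool), pre=pre, post=post, cls=cls,
        weights=weights, autaptic=np.asarray(autaptic, bool),
    )


class TestSynapticCurrents:
    def test_single_excitatory_edge(self):
        # driving force (0 - (-70)) mV times 0.5 nS times trace 1 = 35 pA
        g = _graph_from_edges(2, [True, True], [(0, 1, "ee")], {"ee": 0.5})
        V = np.array([-70.0, -70.0])
        trace = np.array([1.0, 0.0])
        I_exc, I_inh = an.synaptic_currents(V, trace, trace, g)
        assert I_exc[1] == pytest.approx(35.0)
        assert I_exc[0] == 0.0
        assert np.all(I_inh == 0.0)

    def test_single_inhibitory_edge(self):
        # driving force (-80 - (-70)) mV times 2 nS times trace 1 = -20 pA
        g = _graph_from_edges(2, [False, False], [(0, 1, "ii")], {"ii": 2.0})
        V = np.array([-70.0, -70.0])
        trace = np.array([1.0, 0.0])
        I_exc, I_inh = an.synaptic_currents(V, trace, trace, g)
        assert I_inh[1] == pytest.approx(-20.0)
        assert np.all(I_exc == 0.0)

    def test_no_incoming_edges_gives_zero(self):
        g = _graph_from_edges(3, [True] * 3, [], {})
        V = np.full(3, -60.0)
        I_exc, I_inh = an.synaptic_currents(V, np.ones(3), np.ones(3), g)
        assert np.all(I_exc == 0.0) and np.all(I_inh == 0.0)

    @given(
        V=st.floats(-79.9, -0.1),
        trace=st.floats(0.0, 10.0),
        weight=st.floats(0.0, 50.0),
    )
    def test_driving_force_signs(self, V, trace, weight):
        # for V in (-80, 0): excitatory current >= 0, inhibitory <= 0
        g = _graph_from_edges(
            2, [True, False],
            [(0, 1, "ei"), (1, 0, "ie")],
            {"ei": weight, "ie": weight},
        )
        tr = np.full(2, trace)
        I_exc, I_inh = an.synaptic_currents(np.full(2, V), tr, tr, g)
        assert I_exc[1] >= 0.0
        assert I_inh[0] <= 0.0

    def test_matches_kernel_formulation(self, tiny_coupled_run):
        # the python edge-sum and the kernel CSR must agree on a random state
        res = tiny_coupled_run
        g = res.graph
        rng = np.random.default_rng(0)
        V = rng.uniform(-75, -45, g.n)
        tr_e = rng.uniform(0, 2, g.n)
        tr_i = rng.uniform(0, 2, g.n)
        I_exc, I_inh = an.synaptic_currents(V, tr_e, tr_i, g)
        eptr, eidx, ewt, iptr, iidx, iwt = g.presyn_csr()
        for j in range(g.n):
            acc_e = sum(ewt[p] * tr_e[eidx[p]] for p in range(eptr[j], eptr[j + 1]))
            acc_i = sum(iwt[p] * tr_i[iidx[p]] for p in range(iptr[j], iptr[j + 1]))
            assert I_exc[j] == pytest.approx((0.0 - V[j]) * acc_e, rel=1e-12, abs=1e-12)
            assert I_inh[j] == pytest.approx((-80.0 - V[j]) * acc_i, rel=1e-12, abs=1e-12)


def _reference_rk4_single(V0, w0, a, params, dt, n_steps):
    """Independent plain-python RK4 of the uncoupled neuron ODE."""
    V, w = V0, w0
    out = [V]
    for _ in range(n_steps):
        def f(v, wv):
            dv = (-params.g_L * (v - params.E_L)
                  + params.g_L * params.Delta_T * math.exp((v - params.V_T) / params.Delta_T)
                  - wv + params.I_const) / params.C_m
            dw = (a * (v - params.E_L) - wv) / params.tau_w
            return dv, dw

        k1v, k1w = f(V, w)
        k2v, k2w = f(V + 0.5 * dt * k1v, w + 0.5 * dt * k1w)
        k3v, k3w = f(V + 0.5 * dt * k2v, w + 0.5 * dt * k2w)
        k4v, k4w = f(V + dt * k3v, w + dt * k3w)
        V += dt * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0
        w += dt * (k1w + 2 * k2w + 2 * k3w + k4w) / 6.0
        out.append(V)
    return np.array(out)


class TestIntegrationAccuracy:
    def test_single_neuron_matches_refined_reference(self):
        # uncoupled neuron vs an independent RK4 at dt/10, before any spike
        cfg = an.NetworkConfig(
            N=1, P_exc=1.0, p_e=0, p_i=0, p_ei=0, p_ie=0, p_e_aut=0, p_i_aut=0,
            T_total=100.0, t_ini=10.0, t_fin=100.0, dt=0.01, seed=0,
        )
        g = an.assemble_network(cfg)
        a, b = _heterogeneity(cfg, g, 0)
        state = initial_state(cfg, g, 0)
        V0, w0 = float(state.V[0]), float(state.w[0])

        n_coarse = 2000  # 20 ms, well before the first spike (~500 ms)
        ref = _reference_rk4_single(V0, w0, float(a[0]), cfg.neuron, 0.001, n_coarse * 10)
        st = state
        errs = []
        for k in range(n_coarse):
            st, spiked = an.integrate_step(st, g, cfg, a=a, b=b)
            assert spiked.size == 0
            errs.append(abs(st.V[0] - ref[(k + 1) * 10]))
        # error budget: 1e-6 mV per simulated ms
        assert max(errs) < 1e-6 * n_coarse * 0.01

    def test_trace_decays_as_closed_form(self):
        cfg = an.NetworkConfig(
            N=1, P_exc=1.0, p_e=0, p_i=0, p_ei=0, p_ie=0, p_e_aut=0, p_i_aut=0,
            T_total=10.0, t_ini=1.0, t_fin=10.0, dt=0.01, seed=0,
        )
        g = an.assemble_network(cfg)
        a, b = _heterogeneity(cfg, g, 0)
        st = initial_state(cfg, g, 0)
        st.V[0] = -70.0
        st.w[0] = 0.0
        st.s[0] = 1.0
        tau_s = cfg.neuron.tau_s
        for k in range(1, 501):
            st, _ = an.integrate_step(st, g, cfg, a=a, b=b)
            exact = math.exp(-k * cfg.dt / tau_s)
            # RK4 on linear decay: relative error well below 1e-8 per step
            assert abs(st.s[0] - exact) / exact < 1e-8 * k

    def test_no_spikes_no_current(self, tiny_coupled_run):
        # before any spike the delayed traces, hence I_chem, are zero
        res = tiny_coupled_run
        first_spike = min(t[0] for t in res.spikes.trains if t.size)
        early = res.current_t < first_spike
        assert np.all(res.current_I[early] == 0.0)


class TestDelaysAndBookkeeping:
    def test_delay_must_divide_dt(self):
        cfg = an.NetworkConfig(N=2, d_exc=0.015, dt=0.01, T_total=10, t_ini=1, t_fin=10)
        with pytest.raises(ValueError, match="integer multiple"):
            an.run_simulation(cfg)

    def test_history_shift_by_one_slot_shifts_currents_by_dt(self):
        # two states identical up to a one-slot rotation of the history
        # ring see identical delayed traces one step apart
        cfg = an.NetworkConfig(
            N=4, P_exc=1.0, p_e=0.9, p_i=0, p_ei=0, p_ie=0, p_e_aut=0.5,
            g_e=0.4, g_e_aut=2.0, T_total=10.0, t_ini=1.0, t_fin=10.0, seed=3,
        )
        g = an.assemble_network(cfg)
        a, b = _heterogeneity(cfg, g, 3)
        st = initial_state(cfg, g, 3)
        # fabricate a non-trivial history
        rng = np.random.default_rng(1)
        depth = st.hist.shape[0]
        st.hist[:] = rng.uniform(0, 1, st.hist.shape)
        st.step = depth * 3  # past the zero-padding regime
        st.hist[st.step % depth] = st.s

        st_shift = st.copy()
        st_shift.step = st.step + 1
        st_shift.hist = np.roll(st.hist, 1, axis=0)

        out1, _ = an.integrate_step(st.copy(), g, cfg, a=a, b=b)
        out2, _ = an.integrate_step(st_shift, g, cfg, a=a, b=b)
        np.testing.assert_allclose(out1.V, out2.V, rtol=0, atol=0)
        np.testing.assert_allclose(out1.w, out2.w, rtol=0, atol=0)

    def test_every_spike_increments_trace_by_one(self):
        # step-by-step: on a spike, s jumps by exactly 1 beyond the RK4
        # decay factor; otherwise it just decays
        cfg = an.NetworkConfig(
            N=3, P_exc=1.0, p_e=1.0, p_i=0, p_ei=0, p_ie=0, p_e_aut=1.0,
            g_e=0.1, g_e_aut=1.0, T_total=1500.0, t_ini=100.0, t_fin=1500.0, seed=11,
        )
        g = an.assemble_network(cfg)
        a, b = _heterogeneity(cfg, g, 11)
        st = initial_state(cfg, g, 11)
        h = cfg.dt / cfg.neuron.tau_s
        decay = 1 - h + h**2 / 2 - h**3 / 6 + h**4 / 24  # RK4 polynomial
        n_spikes = 0
        for _ in range(80_000):  # 800 ms: enough for several spikes
            s_before = st.s.copy()
            st, spiked = an.integrate_step(st, g, cfg, a=a, b=b)
            expected = s_before * decay
            expected[spiked] += 1.0
            np.testing.assert_allclose(st.s, expected, rtol=1e-12, atol=1e-12)
            n_spikes += spiked.size
        assert n_spikes >= 3

    def test_stepwise_equals_block_run(self):
        # looping integrate_step reproduces run_simulation exactly
        cfg = an.NetworkConfig(
            N=4, P_exc=1.0, p_e=0.8, p_i=0, p_ei=0, p_ie=0, p_e_aut=0.5,
            g_e=0.2, g_e_aut=3.0, T_total=700.0, t_ini=100.0, t_fin=700.0, seed=5,
        )
        g = an.assemble_network(cfg)
        a, b = _heterogeneity(cfg, g, 5)
        res = an.run_simulation(cfg, graph=g)
        st = initial_state(cfg, g, 5)
        spikes = {j: [] for j in range(4)}
        n_steps = int(round(cfg.T_total / cfg.dt))
        for k in range(n_steps):
            st, spiked = an.integrate_step(st, g, cfg, a=a, b=b)
            for j in spiked:
                spikes[j].append((k + 1) * cfg.dt)
        for j in range(4):
            np.testing.assert_allclose(res.spikes.trains[j], spikes[j], atol=1e-12)


class TestRunSimulation:
    def test_determinism(self):
        cfg = an.NetworkConfig(
            N=10, P_exc=1.0, p_e=0.5, p_i=0, p_ei=0, p_ie=0, p_e_aut=0.3,
            g_e=0.2, g_e_aut=4.0, T_total=800.0, t_ini=100.0, t_fin=800.0, seed=21,
        )
        r1 = an.run_simulation(cfg)
        r2 = an.run_simulation(cfg)
        assert all(
            np.array_equal(x, y) for x, y in zip(r1.spikes.trains, r2.spikes.trains)
        )
        np.testing.assert_array_equal(r1.current_I, r2.current_I)

    def test_zero_coupling_decouples_into_single_neurons(self):
        cfg = an.NetworkConfig(
            N=3, P_exc=1.0, p_e=0.9, p_i=0, p_ei=0, p_ie=0, p_e_aut=0.5,
            g_e=0.0, g_e_aut=0.0, T_total=1500.0, t_ini=100.0, t_fin=1500.0, seed=8,
        )
        g = an.assemble_network(cfg)
        a, b = _heterogeneity(cfg, g, 8)
        st0 = initial_state(cfg, g, 8)
        res = an.run_simulation(cfg, graph=g)
        # re-run each neuron alone with the same a_j and initial conditions
        for j in range(3):
            cfg1 = an.NetworkConfig(
                N=1, P_exc=1.0, p_e=0, p_i=0, p_ei=0, p_ie=0, p_e_aut=0, p_i_aut=0,
                T_total=1500.0, t_ini=100.0, t_fin=1500.0, seed=8,
            )
            g1 = an.assemble_network(cfg1)
            st1 = initial_state(cfg1, g1, 8)
            st1.V[0] = st0.V[j]
            st1.w[0] = st0.w[j]
            r1 = an.run_simulation(
                cfg1, graph=g1, initial=st1,
                a=np.array([a[j]]), b=np.array([b[j]]),
            )
            np.testing.assert_allclose(r1.spikes.trains[0], res.spikes.trains[j])

    def test_spike_times_strictly_increasing_and_in_range(self, tiny_coupled_run):
        res = tiny_coupled_run
        for t in res.spikes.trains:
            if t.size > 1:
                assert np.all(np.diff(t) > 0)
            if t.size:
                assert t[0] > 0 and t[-1] <= res.config.T_total

    def test_sustained_firing_under_reference_drive(self):
        # uncoupled excitatory neurons with I = 270 pA fire tonically
        cfg = an.NetworkConfig(
            N=20, P_exc=1.0, p_e=0, p_i=0, p_ei=0, p_ie=0, p_e_aut=0, p_i_aut=0,
            T_total=4000.0, t_ini=1000.0, t_fin=4000.0, seed=13,
        )
        res = an.run_simulation(cfg)
        for t in res.spikes.trains:
            in_window = t[(t >= 1000.0) & (t <= 4000.0)]
            assert in_window.size >= 2

    def test_nonfinite_abort_names_neuron_and_time(self):
        cfg = an.NetworkConfig(
            N=3, P_exc=1.0, p_e=0, p_i=0, p_ei=0, p_ie=0,
            T_total=50.0, t_ini=10.0, t_fin=50.0, seed=0,
        )
        g = an.assemble_network(cfg)
        st = initial_state(cfg, g, 0)
        st.w[1] = np.inf
        with pytest.raises(RuntimeError, match="neuron 2"):
            an.run_simulation(cfg, graph=g, initial=st)

    def test_result_save_roundtrip(self, tiny_coupled_run, tmp_path):
        from aeifnet import io as _io

        tiny_coupled_run.save(tmp_path / "run")
        spikes, meta = _io.read_spikes(tmp_path / "run" / "spikes.tsv")
        assert spikes.n == tiny_coupled_run.spikes.n
        assert spikes.n_spikes == tiny_coupled_run.spikes.n_spikes
        assert meta["seed"] == str(tiny_coupled_run.seed)
        t, I, _ = _io.read_current(tmp_path / "run" / "current.tsv")
        assert t.size == tiny_coupled_run.current_t.size
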