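import numpy as np
import pytest

from dendroclust.params import nominal_params, stdp_control_params
from dendroclust.plasticity import (GeneralizedState, NeurotrophinState,
                                    Simulator, cooperativity_gate,
                                    dendritic_nonlinearity, step_generalized,
                                    step_inhibitory_weights, step_neurotrophin)


class TestDendriticNonlinearity:
    def test_identity_when_off(self):
        I = np.linspace(-1, 2, 7)
        assert np.allclose(dendritic_nonlinearity(I, 0.0), I)

    def test_sigmoid_midpoint_and_saturation(self):
        assert dendritic_nonlinearity(0.125, 1.0) == pytest.approx(0.25)
        assert dendritic_nonlinearity(50.0, 1.0) == pytest.approx(0.5, abs=1e-9)

    def test_monotone(self):
        I = np.linspace(-0.5, 1.0, 200)
        for g in (0.0, 0.3, 1.0):
            out = dendritic_nonlinearity(I, g)
            assert np.all(np.diff(out) >= -1e-12)

    def test_gamma_range(self):
        with pytest.raises(ValueError):
            dendritic_nonlinearity(0.1, 1.5)


class TestCooperativityGate:
    def test_single_active_never_gates(self):
        d = np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0)))
        flags = np.array([False, False, True, False, False])
        assert not cooperativity_gate(flags, d, spacing_thr=10.0).any()

    def test_five_coactive_close_synapses(self):
        pos = np.arange(5.0)           # 1 um apart
        d = np.abs(np.subtract.outer(pos, pos))
        flags = np.ones(5, dtype=bool)
        assert cooperativity_gate(flags, d, spacing_thr=10.0).all()

    def test_threshold_boundary(self):
        # reference synapse at 0; neighbors at 2 um spacing, all active
        for n_nbr, expected in ((4, True), (3, False)):
            pos = np.concatenate([[0.0], 2.0 * (1 + np.arange(n_nbr))])
            d = np.abs(np.subtract.outer(pos, pos))
            flags = np.ones(len(pos), dtype=bool)
            gate = cooperativity_gate(flags, d, spacing_thr=10.0, min_count=3)
            assert bool(gate[0]) is expected


class TestNeurotrophinStep:
    def test_decay_without_input(self, params, small_branch):
        _, _, s = small_branch
        st = NeurotrophinState.initial(s)
        st.P += 0.2
        st.B += 0.2
        st.M += 0.0
        w0 = st.W.copy()
        for _ in range(200):
            step_neurotrophin(st, np.zeros(5), 5.0, params)
        assert np.all(st.P < 1e-6) and np.all(st.B < 1e-6)
        # with M = 0, Y = 0 and B = P, potentiation and depression cancel
        assert np.allclose(st.W, w0, atol=1e-9)
        # calcium without MMP9 releases more proBDNF than BDNF (eta < 1/2)
        st1 = NeurotrophinState.initial(s)
        st1.Y += 1.0
        for _ in range(50):
            step_neurotrophin(st1, np.zeros(5), 5.0, params)
        assert np.all(st1.W < 0.5)
        # an M transient converts P to B and transiently potentiates
        st2 = NeurotrophinState.initial(s)
        st2.M += 1.0
        st2.P += 0.2
        st2.B += 0.2
        step_neurotrophin(st2, np.zeros(5), 5.0, params)
        step_neurotrophin(st2, np.zeros(5), 5.0, params)
        assert np.all(st2.W > 0.5)

    def test_conversion_conserves_neurotrophin(self, params, small_branch):
        """The M*P term moves mass from P to B; P+B evolves independently of M."""
        _, _, s = small_branch
        a = NeurotrophinState.initial(s)
        b = NeurotrophinState.initial(s)
        for st in (a, b):
            st.Y += 1.0
            st.P += 0.3
            st.B += 0.1
        b.M += 5.0
        x = np.zeros(5)
        step_neurotrophin(a, x, 1.0, params)
        step_neurotrophin(b, x, 1.0, params)
        assert np.allclose(a.P + a.B, b.P + b.B)
        assert not np.allclose(a.P, b.P)

    def test_constitutive_ratio_without_mmp9(self, params, small_branch):
        """With M = 0 and sustained drive, B/(B+P) relaxes to eta = 0.45."""
        _, _, s = small_branch
        st = NeurotrophinState.initial(s)
        p = params.replace(tau_M=1e12)     # freeze M at zero
        x = np.ones(5)
        for _ in range(2000):
            step_neurotrophin(st, x, 1.0, p)
        ratio = st.B / (st.B + st.P)
        assert np.allclose(ratio, params.eta, atol=1e-3)

    def test_dt_guard(self, params, small_branch):
        _, _, s = small_branch
        st = NeurotrophinState.initial(s)
        with pytest.raises(ValueError):
            step_neurotrophin(st, np.zeros(5), 10.0, params)  # > tau_P = 5 ms


class TestGeneralizedStep:
    def test_stimulated_synapse_potentiates(self, params):
        st = GeneralizedState.initial(np.eye(1))
        x = np.zeros(6000)
        x[::10] = 1            # sustained 50-ms events at high rate
        x = np.repeat(x[None, :], 1, axis=0)
        for t in range(x.shape[1]):
            step_generalized(st, x[:, t], 5.0, params)
        assert st.w[0] > 0.5

    def test_silent_neighbor_depresses(self, params):
        s = np.array([[1.0, 0.9], [0.9, 1.0]])
        st = GeneralizedState.initial(s)
        rng = np.random.default_rng(0)
        for t in range(12000):
            x = np.array([float(rng.random() < 0.01), 0.0])
            step_generalized(st, x, 5.0, params)
        assert st.w[1] < 0.5 < st.w[0] + 0.3
        assert st.w[1] < st.w[0]

    def test_nonlinearity_off_is_identity_path(self, params, small_branch):
        _, _, s = small_branch
        a = GeneralizedState.initial(s)
        b = GeneralizedState.initial(s)
        rng = np.random.default_rng(3)
        for t in range(500):
            x = (rng.random(5) < 0.02).astype(float)
            step_generalized(a, x, 5.0, params)
            step_generalized(b, x, 5.0, params.replace(gamma=0.0),
                             nonlinearity_on=True)
        assert np.array_equal(a.w, b.w)


class TestKernelEquivalence:
    """The numba kernels must reproduce the reference steppers exactly."""

    def _events(self, rng, n, T):
        return (rng.random((n, T)) < 0.01).astype(np.uint8)

    def test_generalized(self, params, small_branch, rng):
        _, _, s = small_branch
        x = self._events(rng, 5, 3000)
        sim = Simulator(model="generalized", params=params, s=s, dt=5.0)
        sim.run_chunk(x)
        ref = GeneralizedState.initial(s)
        for t in range(x.shape[1]):
            step_generalized(ref, x[:, t], 5.0, params)
        assert np.array_equal(sim.state.w, ref.w)
        assert np.array_equal(sim.state.u, ref.u)

    def test_neurotrophin_with_gaba(self, params, small_branch, rng):
        _, _, s = small_branch
        x = self._events(rng, 5, 2000)
        xg = self._events(rng, 2, 2000)
        s_eg = np.full((5, 2), 0.5)
        sim = Simulator(model="neurotrophin", params=params, s=s, dt=5.0,
                        n_gaba=2, s_eg=s_eg, gaba_sign=-1)
        sim.run_chunk(x, x_gaba=xg)
        ref = NeurotrophinState.initial(s, n_gaba=2, s_eg=s_eg)
        for t in range(x.shape[1]):
            step_neurotrophin(ref, x[:, t], 5.0, params, x_gaba=xg[:, t],
                              gaba_sign=-1)
        assert np.allclose(sim.state.W, ref.W, atol=1e-12)
        assert np.allclose(sim.state.W_gaba, ref.W_gaba, atol=1e-12)

    def test_frozen_weights_accumulate_drift(self, params, small_branch, rng):
        _, _, s = small_branch
        x = self._events(rng, 5, 2000)
        sim = Simulator(model="generalized", params=params, s=s, dt=5.0,
                        freeze_w=True)
        sim.run_chunk(x)
        assert np.all(sim.state.w == 0.5)
        assert np.any(sim.dw_sum != 0.0)


class TestInvariants:
    def test_bounds_under_strong_input(self, params, small_branch, rng):
        _, _, s = small_branch
        x = (rng.random((5, 20000)) < 0.2).astype(np.uint8)
        sim = Simulator(model="generalized", params=params, s=s, dt=5.0)
        sim.run_chunk(x)
        assert np.all((sim.state.w >= 0.0) & (sim.state.w <= 1.0))
        sim2 = Simulator(model="neurotrophin", params=params, s=s, dt=5.0)
        sim2.run_chunk(x)
        assert np.all((sim2.state.W >= 0.0) & (sim2.state.W <= 1.0))

    def test_euler_convergence(self, params, small_branch):
        """Halving dt changes a 1-min generalized trajectory by < 1%."""
        _, _, s = small_branch
        rng = np.random.default_rng(5)
        bins = (rng.random((5, 1200)) < 0.0125).astype(np.uint8)
        results = {}
        for dt in (5.0, 2.5):
            x = np.repeat(bins, int(round(50.0 / dt)), axis=1)
            sim = Simulator(model="generalized", params=params, s=s, dt=dt)
            sim.run_chunk(x)
            results[dt] = sim.state.w.copy()
        diff = np.max(np.abs(results[5.0] - results[2.5]))
        assert diff < 0.01 * max(np.max(np.abs(results[2.5])), 1e-12)

    def test_inhibitory_weight_sign_follows_bp(self, params):
        s = np.eye(2)
        st = NeurotrophinState.initial(s, n_gaba=1, s_eg=np.array([[1.0], [1.0]]))
        st.B += 0.3                      # B > P everywhere -> GABA strengthens
        w0 = st.W_gaba.copy()
        step_inhibitory_weights(st, params, 5.0)
        assert st.W_gaba[0] > w0[0]
        st.P += 1.0                      # now P > B -> weakens
        w1 = st.W_gaba.copy()
        step_inhibitory_weights(st, params, 5.0)
        assert st.W_gaba[0] < w1[0]

    def test_inhibitory_requires_gaba_state(self, params):
        st = NeurotrophinState.initial(np.eye(2))
        with pytest.raises(ValueError):
            step_inhibitory_weights(st, params, 5.0)


class TestReduction:
    def test_generalized_tracks_neurotrophin(self, params):
        """Quasi-steady-state reduction: trajectories correlate > 0.99.

        Two synapses, ten minutes of Poisson events; the full model with
        fast neurotrophin decay against the generalized model on the same
        event train.
        """
        rng = np.random.default_rng(11)
        s = np.array([[1.0, 0.7], [0.7, 1.0]])
        bins = (rng.random((2, 1200)) < 0.05).astype(np.uint8)
        x = np.repeat(bins, 50, axis=1)    # dt = 1 ms
        rec = {}
        for model in ("neurotrophin", "generalized"):
            sim = Simulator(model=model, params=params, s=s, dt=1.0)
            out = sim.run_chunk(x, record_stride=50)
            rec[model] = out[0]
        for k in range(2):
            r = np.corrcoef(rec["neurotrophin"][:, k], rec["generalized"][:, k])[0, 1]
            assert r > 0.99

    def test_stdp_preset_requires_fine_dt(self, small_branch):
        _, _, s = small_branch
        p = stdp_control_params()
        with pytest.raises(ValueError):
            Simulator(model="generalized", params=p, s=s, dt=5.0)
        Simulator(model="generalized", params=p, s=s, dt=1.0)  # ok
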