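import numpy as np
import pytest

from dendroclust.morphology import (Dendrite, apply_turnover, cross_distance,
                                    density_ramp_schedule, load_swc,
                                    pairwise_distance, place_synapses,
                                    proximity_matrix, resample, synthetic_tree,
                                    write_swc)
from dendroclust.stimulus import rf_sampler


class TestPlacement:
    @pytest.mark.parametrize("L,nu,expected", [(150.0, 0.2, 30), (64.0, 0.5, 32)])
    def test_floor_count(self, L, nu, expected):
        dend = Dendrite(mode="linear", length=L, periodic=True)
        syn = place_synapses(dend, nu, seed=0)
        assert syn.n == expected
        assert np.all(syn.efficacy == 0.5)
        assert np.all((syn.positions >= 0) & (syn.positions <= L))

    def test_zero_count_rejected(self):
        dend = Dendrite(mode="linear", length=3.0, periodic=False)
        with pytest.raises(ValueError):
            place_synapses(dend, 0.1, seed=0)

    def test_tree_placement_uniform_over_cable(self):
        tree = synthetic_tree(total_length=500.0, seed=3)
        syn = place_synapses(tree, 0.5, seed=1)
        assert syn.n == int(np.floor(tree.total_length * 0.5))
        seg = syn.positions[:, 0].astype(int)
        assert np.all(seg >= 0) and np.all(seg < tree.n_segments)


class TestDistances:
    def test_periodic_wraparound(self):
        dend = Dendrite(mode="linear", length=150.0, periodic=True)
        d = pairwise_distance(dend, np.array([10.0, 145.0]))
        assert d[0, 1] == pytest.approx(15.0)
        assert np.all(np.diag(d) == 0.0)

    def test_non_periodic(self):
        dend = Dendrite(mode="linear", length=150.0, periodic=False)
        d = pairwise_distance(dend, np.array([10.0, 145.0]))
        assert d[0, 1] == pytest.approx(135.0)

    def test_off_branch_rejected(self):
        dend = Dendrite(mode="linear", length=150.0, periodic=False)
        with pytest.raises(ValueError):
            pairwise_distance(dend, np.array([-1.0, 10.0]))

    def test_tree_siblings_through_branch_point(self):
        # two 20-um children on a 20-um trunk; synapses 5 and 7 um into each child
        tree = Dendrite(mode="tree", seg_parent=np.array([-1, 0, 0]),
                        seg_length=np.array([20.0, 20.0, 20.0]))
        pos = np.array([[1, 5.0], [2, 7.0]])
        d = pairwise_distance(tree, pos)
        assert d[0, 1] == pytest.approx(12.0)

    def test_tree_metric_properties(self):
        tree = synthetic_tree(total_length=400.0, seed=5)
        syn = place_synapses(tree, 0.05, seed=2)
        d = syn.distances()
        assert np.allclose(d, d.T)
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_cross_distance_matches_joint(self):
        dend = Dendrite(mode="linear", length=100.0, periodic=True)
        a = np.array([10.0, 20.0])
        b = np.array([90.0])
        d = cross_distance(dend, a, b)
        assert d[0, 0] == pytest.approx(20.0)
        assert d[1, 0] == pytest.approx(30.0)


class TestProximity:
    def test_values(self):
        d = np.array([[0.0, 6.0, 36.0], [6.0, 0.0, 1.0], [36.0, 1.0, 0.0]])
        s = proximity_matrix(d, 6.0)
        assert s[0, 0] == 1.0
        assert s[0, 1] == pytest.approx(np.exp(-0.5))
        assert s[0, 2] == 0.0          # beyond the 5-sigma cutoff
        assert np.allclose(s, s.T)

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            proximity_matrix(np.zeros((2, 2)), 0.0)


class TestSWC:
    def test_straight_cable(self):
        lines = ["1 1 0 0 0 1 -1"] + [
            f"{i + 2} 3 0 {10 * (i + 1)} 0 0.5 {i + 1}" for i in range(10)]
        dend = load_swc("\n".join(lines) + "\n")
        assert dend.n_segments == 10
        tip = np.array([[dend.n_segments - 1, dend.seg_length[-1]]])
        assert dend.soma_distance(tip)[0] == pytest.approx(100.0, abs=1.0)

    def test_y_tree_geometry(self, y_tree_swc):
        dend = load_swc(y_tree_swc)
        # tips: ends of the two child branches
        graph_tips = [i for i in range(dend.n_segments)
                      if i not in set(dend.seg_parent.tolist())]
        pos = np.array([[t, dend.seg_length[t]] for t in graph_tips])
        d = pairwise_distance(dend, pos)
        assert d[0, 1] == pytest.approx(100.0, abs=1.5)
        assert dend.soma_distance(pos[0:1])[0] == pytest.approx(100.0, abs=1.5)

    def test_resample_idempotent(self):
        tree = synthetic_tree(total_length=300.0, seed=1)
        once = resample(tree, 10.0)
        twice = resample(once, 10.0)
        assert once.n_segments == twice.n_segments
        assert once.total_length == pytest.approx(twice.total_length, rel=1e-6)

    def test_roundtrip_byte_stable(self):
        tree = synthetic_tree(total_length=300.0, seed=2)
        text1 = write_swc(tree)
        text2 = write_swc(load_swc(text1, step=10.0))
        text3 = write_swc(load_swc(text2, step=10.0))
        assert text2 == text3

    def test_multi_root_rejected(self):
        bad = "1 1 0 0 0 1 -1\n2 1 5 0 0 1 -1\n"
        with pytest.raises(ValueError):
            load_swc(bad)


class TestSyntheticTree:
    def test_deterministic(self):
        a = synthetic_tree(seed=9)
        b = synthetic_tree(seed=9)
        assert np.array_equal(a.seg_parent, b.seg_parent)
        assert np.allclose(a.seg_length, b.seg_length)

    def test_total_length_and_depth(self):
        tree = synthetic_tree(total_length=1500.0, seed=4)
        assert tree.total_length == pytest.approx(1500.0, rel=1e-6)
        # distal regimes exist for the largest attenuation factor (125 um)
        tips = [i for i in range(tree.n_segments)
                if i not in set(tree.seg_parent.tolist())]
        pos = np.array([[t, tree.seg_length[t]] for t in tips])
        assert tree.soma_distance(pos).max() >= 250.0


class TestTurnover:
    def _syn(self, seed=0):
        dend = Dendrite(mode="linear", length=150.0, periodic=True)
        syn = place_synapses(dend, 0.2, seed=seed)
        syn.rfs = [None] * syn.n
        return syn

    def test_no_change_above_threshold(self, rng):
        syn = self._syn()
        replaced = apply_turnover(syn, rf_sampler(5.3, 13.4), rng, W_thr=0.02)
        assert replaced == [] and syn.log == []

    def test_single_replacement(self, rng):
        syn = self._syn()
        sampler = rf_sampler(5.3, 13.4)
        syn.rfs = [sampler(rng) for _ in range(syn.n)]
        syn.efficacy[3] = 0.01
        n_before = syn.n
        replaced = apply_turnover(syn, sampler, rng, W_thr=0.02, time_ms=1000.0)
        assert replaced == [3]
        assert syn.n == n_before          # count preserved
        assert syn.efficacy[3] == 0.5
        assert syn.ids[3] == n_before     # fresh identity
        assert len(syn.log) == 1 and syn.log[0].old_id == 3


class TestDensityRamp:
    def test_insertion_schedule(self):
        four_days = 4 * 86400e3
        times, scale = density_ramp_schedule(150.0, 0.2, 0.8, four_days)
        assert len(times) == 90
        assert np.allclose(np.diff(times), 64 * 60e3)
        # conservation: sigma_c * increment * nu constant
        for t in np.linspace(0, four_days, 7):
            nu_t = 0.2 + 0.6 * t / four_days
            assert scale(t) ** 2 * nu_t == pytest.approx(0.2, rel=1e-9)

    def test_requires_increase(self):
        with pytest.raises(ValueError):
            density_ramp_schedule(150.0, 0.8, 0.2, 1e6)
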