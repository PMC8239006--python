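import os

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from dendroclust import cli as dcli
from dendroclust.experiments import (run_branch_clustering, run_btdp,
                                     run_distance_rate_sweep, run_inhibitory,
                                     run_phase_diagram)


class TestDistanceRateSweep:
    def test_zero_rate_gives_zero_change(self):
        df = run_distance_rate_sweep(rates_per_min=(0,), distances_um=(5.0,),
                                     duration_min=1.0, seed=0)
        assert df.dw_stim.abs().max() == 0.0
        assert df.dw_unstim.abs().max() == 0.0

    def test_short_sweep_sign_structure(self):
        df = run_distance_rate_sweep(rates_per_min=(15,), distances_um=(0.0, 12.0),
                                     duration_min=10.0, seed=1)
        assert (df.dw_stim > 0).all()
        assert (df.dw_unstim <= 0).all()
        near = df[df.distance_um == 0.0].dw_unstim.iloc[0]
        far = df[df.distance_um == 12.0].dw_unstim.iloc[0]
        assert abs(far) < abs(near)


class TestBTDP:
    def test_deterministic(self):
        a = run_btdp(offsets_s=(0.05, 1.5), n_pairings=3)
        b = run_btdp(offsets_s=(0.05, 1.5), n_pairings=3)
        pd.testing.assert_frame_equal(a, b)

    def test_single_pairing_signs(self):
        """Near-coincident bursts potentiate; well-separated bursts depress.

        The depression wing is asymmetric: the presynaptic protease
        accumulator (tau 600 ms) outlives the burst, so post-after-pre
        offsets cross into depression later (~ +2 s) than pre-after-post
        ones (~ -1.3 s).
        """
        df = run_btdp(offsets_s=(-1.5, 0.05, 3.0), n_pairings=1)
        assert df[df.dT_s == 0.05]["pct_efficacy_change"].iloc[0] > 0
        assert df[df.dT_s == -1.5]["pct_efficacy_change"].iloc[0] < 0
        assert df[df.dT_s == 3.0]["pct_efficacy_change"].iloc[0] < 0


class TestPhaseDiagram:
    def test_small_grid_structure(self):
        df = run_phase_diagram(nus=(0.125, 0.5), cs=(0.0, 0.4), reps=2,
                               duration_min=3.0, seed=0)
        assert len(df) == 4
        assert set(df.columns) >= {"nu", "c", "mean_dwdt", "analytic_sign", "c_star"}
        # high correlation cell drifts up relative to the uncorrelated one
        hi = df[(df.nu == 0.5) & (df.c == 0.4)].mean_dwdt.iloc[0]
        lo = df[(df.nu == 0.5) & (df.c == 0.0)].mean_dwdt.iloc[0]
        assert hi > lo


class TestDevelopmentRuns:
    def test_seed_determinism(self):
        a = run_branch_clustering(days=0.02, seed=3, record_final_minutes=5.0)
        b = run_branch_clustering(days=0.02, seed=3, record_final_minutes=5.0)
        assert np.array_equal(a.synapses.efficacy, b.synapses.efficacy)
        assert np.array_equal(a.final_train.data, b.final_train.data)

    def test_different_seeds_differ(self):
        a = run_branch_clustering(days=0.02, seed=3, record_final_minutes=5.0)
        b = run_branch_clustering(days=0.02, seed=4, record_final_minutes=5.0)
        assert not np.array_equal(a.final_train.data, b.final_train.data)

    def test_checkpoint_restart_equivalence(self, tmp_path):
        """A run split at a checkpoint equals the unsplit run."""
        kw = dict(days=1.0 / 24.0, seed=5, chunk_minutes=10.0,
                  record_final_minutes=0.0, turnover=True)
        full = run_branch_clustering(checkpoint_dir=None, **kw)
        # run the first half and checkpoint, then resume into the full span
        run_branch_clustering(days=0.5 / 24.0, seed=5, chunk_minutes=10.0,
                              record_final_minutes=0.0, turnover=True,
                              _checkpoint_to=str(tmp_path / "half.npz"))
        resumed = run_branch_clustering(days=1.0 / 24.0, seed=5, chunk_minutes=10.0,
                                        record_final_minutes=0.0, turnover=True,
                                        resume_from=str(tmp_path / "half.npz"))
        assert np.allclose(full.synapses.efficacy, resumed.synapses.efficacy)
        assert len(full.synapses.log) == len(resumed.synapses.log)

    def test_white_noise_control_runs(self):
        res = run_branch_clustering(stimulus="white-noise", days=0.02, seed=6,
                                    record_final_minutes=5.0)
        assert res.final_train is not None
        assert res.final_train.event_rate_per_min().mean() > 5.0


class TestInhibitory:
    def test_scenario_a_mechanics(self):
        res = run_inhibitory(scenario="A", days=0.02, seed=7, turnover=True)
        gab = res["gaba"]
        assert gab.n == int(np.floor(150.0 * 0.05))
        assert set(res["ei_table"].columns) == {"gaba_id", "theta_gaba", "ei_dtheta"}
        # GABA count preserved under turnover
        assert len(gab.efficacy) == gab.n

    def test_bad_scenario(self):
        with pytest.raises(ValueError):
            run_inhibitory(scenario="C", days=0.01)


class TestCLI:
    def test_make_fixtures_roundtrip(self, tmp_path):
        runner = CliRunner()
        out = str(tmp_path / "fx")
        res = runner.invoke(dcli.main, ["make-fixtures", "--out", out, "--seed", "1"])
        assert res.exit_code == 0, res.output
        assert os.path.exists(os.path.join(out, "tree.swc"))
        assert os.path.exists(os.path.join(out, "train.csv"))
        res2 = runner.invoke(dcli.main, ["analyze", out])
        assert res2.exit_code == 0

    def test_unknown_protocol_fails(self):
        runner = CliRunner()
        res = runner.invoke(dcli.main, ["simulate", "nonsense"])
        assert res.exit_code != 0

    def test_missing_config_fails(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(dcli.main, ["simulate", "btdp", "--config",
                                        str(tmp_path / "nope.yaml")])
        assert res.exit_code != 0

    def test_sensitivity_command(self, tmp_path):
        runner = CliRunner()
        out = str(tmp_path / "sens")
        res = runner.invoke(dcli.main, ["sensitivity", "--n", "50", "--seed", "2",
                                        "--out", out])
        assert res.exit_code == 0, res.output
        df = pd.read_csv(os.path.join(out, "parameter_draws.csv"))
        assert len(df) == 50 and (df.sigma_c >= 4.0).all()
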