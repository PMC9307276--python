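"""Scenario orchestration: determinism, replicates, sweeps, serialization,
and whole-engine invariants on small systems."""

import numpy as np
import pytest

from pcm_selforg import runner as R
from pcm_selforg.config import (ComplexSpec, Population, ScenarioConfig,
                                ImmobileSeedSpec, preset_scenario)
from pcm_selforg.engine import Engine


def tiny_config(n=6, adhesion="weak", kind="PCM", seconds=5.0, kT=4.2e-3,
                seeds=0):
    cfg = ScenarioConfig(name="tiny")
    cfg.world.cell_radius = 5.0
    cfg.world.total_time = seconds
    cfg.world.kT = kT
    spec = (ComplexSpec.pcm(adhesion) if kind == "PCM"
            else ComplexSpec.camsap_kin14(adhesion))
    cfg.populations = [Population(spec, n)]
    if seeds:
        cfg.immobile_seeds = ImmobileSeedSpec(count=seeds)
    return cfg


class TestRunScenario:
    def test_empty_config_runs_without_error(self):
        cfg = ScenarioConfig(name="empty")
        cfg.world.total_time = 1.0
        traj = R.run_scenario(cfg, seed=0)
        assert traj.final.complex_positions.shape == (0, 2)
        assert not traj.aborted

    def test_noise_free_bead_without_motors_is_stationary(self):
        cfg = tiny_config(n=1, adhesion="none", seconds=2.0, kT=0.0)
        cfg.populations[0].spec.nucleating = False
        traj = R.run_scenario(cfg, seed=3)
        assert np.allclose(traj.frames[0].complex_positions,
                           traj.final.complex_positions, atol=1e-12)

    def test_frame_times_increase_and_end_at_total_time(self):
        cfg = tiny_config(seconds=5.0)
        traj = R.run_scenario(cfg, seed=1)
        times = [f.time for f in traj.frames]
        assert all(b > a for a, b in zip(times, times[1:]))
        assert abs(times[-1] - 5.0) <= cfg.world.dt + 1e-9

    def test_same_seed_reproduces_trajectory_exactly(self):
        cfg = tiny_config(seconds=3.0)
        t1 = R.run_scenario(cfg, seed=9)
        t2 = R.run_scenario(cfg, seed=9)
        assert np.array_equal(t1.final.complex_positions,
                              t2.final.complex_positions)

    def test_invalid_config_rejected(self):
        cfg = tiny_config()
        cfg.world.dt = -1.0
        with pytest.raises(ValueError):
            R.run_scenario(cfg)


class TestEngineInvariants:
    def test_confinement_contract(self):
        # no bead center beyond R + 3 thermal lengths sqrt(kT/k_conf)
        cfg = tiny_config(n=20, seconds=20.0)
        eng = Engine(cfg, seed=2)
        w = cfg.world
        limit = w.cell_radius + 3 * np.sqrt(w.kT / w.confinement_stiffness)
        for _ in range(2000):
            eng.step()
            assert np.hypot(*eng.bead_pos.T).max() <= limit

    def test_segment_strain_contract(self):
        cfg = tiny_config(n=15, seconds=30.0, seeds=5)
        eng = Engine(cfg, seed=4)
        worst = 0.0
        for i in range(3000):
            eng.step()
            if i % 100 == 99:
                s = eng.segment_strains()
                if s.size:
                    worst = max(worst, s.max())
        assert worst < 0.05

    def test_immobile_seed_minus_ends_never_move(self):
        cfg = tiny_config(n=4, seconds=10.0, seeds=6)
        eng = Engine(cfg, seed=5)
        seed_slots = np.nonzero(eng.site_host < 0)[0]
        ref = eng.site_pos[seed_slots].copy()
        for _ in range(1000):
            eng.step()
        alive = seed_slots[eng.fil_alive[seed_slots]]
        assert np.allclose(eng.fil_xy[alive, 0],
                           eng.site_pos[alive], atol=1e-12)
        assert np.array_equal(eng.site_pos[seed_slots], ref)

    def test_abscissae_never_negative(self):
        cfg = tiny_config(n=15, seconds=20.0)
        eng = Engine(cfg, seed=6)
        for _ in range(2000):
            eng.step()
            assert eng.m_absc.min() >= 0.0

    def test_agent_ordering_does_not_bias_outcome(self):
        # permuting the build order of identical populations changes only
        # the stochastic realization, not the statistics of the final state
        base = tiny_config(n=20, seconds=60.0)
        med = []
        for flip in (False, True):
            cfg = tiny_config(n=20, seconds=60.0)
            if flip:
                cfg.populations = [Population(cfg.populations[0].spec, 10),
                                   Population(cfg.populations[0].spec, 10)]
            vals = [R.run_scenario(cfg, seed=s, record_frames=False)
                    .summary().mean_dist for s in (0, 1, 2)]
            med.append(np.median(vals))
        assert med[1] == pytest.approx(med[0], rel=0.75)


class TestReplicatesAndSweeps:
    def test_replicates_have_distinct_seeds(self):
        out = R.run_replicates(tiny_config(seconds=2.0), n=3, base_seed=10)
        assert [s.seed for s in out] == [10, 11, 12]

    def test_single_replicate_equals_run_scenario(self):
        cfg = tiny_config(seconds=2.0)
        (rep,) = R.run_replicates(cfg, n=1, base_seed=5)
        direct = R.run_scenario(cfg, seed=5).summary()
        assert rep.mean_dist == direct.mean_dist

    def test_same_base_seed_identical_summaries(self):
        cfg = tiny_config(seconds=2.0)
        a = R.run_replicates(cfg, n=2, base_seed=1)
        b = R.run_replicates(cfg, n=2, base_seed=1)
        assert [x.mean_dist for x in a] == [x.mean_dist for x in b]

    def test_sweep_cardinality_and_resume(self, tmp_path):
        out = tmp_path / "sweep.csv"

        def shrink(cfg):
            cfg.world.cell_radius = 5.0
            cfg.world.total_time = 1.0
            for p in cfg.populations:
                p.count = min(p.count, 5)
            cfg.immobile_seeds.count = 0
            return cfg

        grid = [("n_pcm", 3), ("n_pcm", 5)]
        df = R.run_sweep("sweep_n_pcm", grid, n_rep=2, base_seed=0,
                         out_csv=out, config_transform=shrink)
        assert len(df) == 4
        # resumable: a second call re-reads the csv and runs nothing new
        df2 = R.run_sweep("sweep_n_pcm", grid, n_rep=2, base_seed=0,
                          out_csv=out, config_transform=shrink)
        assert df2[["param", "value", "seed"]].equals(df[["param", "value", "seed"]])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            R.run_sweep("sweep_n_pcm", [], n_rep=1)

    def test_mixed_fraction_sweep_configures_counts(self):
        cfg = R.sweep_config("sweep_mixed_fraction", "adhesive_fraction", 0.5)
        counts = {p.spec.kind: p.count for p in cfg.populations}
        assert counts["PCM"] == 150 and counts["CAMSAP_KIN14"] == 150

    def test_scaled_config_tags_name_and_scales_counts(self):
        cfg = R.scaled_config(preset_scenario("fig8A"), dt=0.02)
        assert cfg.name.endswith("@scaled")
        assert cfg.world.cell_radius == 5.0
        assert cfg.populations[0].count == 75
        assert cfg.world.total_time == pytest.approx(600.0)
        assert cfg.fiber.L_max == 7.5  # fiber parameters untouched by default

    def test_scaled_config_optional_fiber_scaling_keeps_consistency(self):
        cfg = R.scaled_config(preset_scenario("fig8A"), scale_fibers=True)
        assert cfg.fiber.L_max == pytest.approx(3.75)
        assert cfg.fiber.k_cat == pytest.approx(cfg.fiber.v_grow / cfg.fiber.L_mean)


class TestSerialization:
    def test_csv_round_trip(self, tmp_path):
        traj = R.run_scenario(tiny_config(seconds=2.0, seeds=2), seed=7)
        path = tmp_path / "traj.csv"
        R.trajectory_to_csv(traj, path)
        back = R.trajectory_from_csv(path)
        assert back.scenario == traj.scenario and back.seed == 7
        assert len(back.frames) == len(traj.frames)
        assert np.allclose(back.final.complex_positions,
                           traj.final.complex_positions)
        assert len(back.final.filaments) == len(traj.final.filaments)
        for a, b in zip(back.final.filaments, traj.final.filaments):
            assert np.allclose(a, b)

    def test_hdf5_round_trip(self, tmp_path):
        traj = R.run_scenario(tiny_config(seconds=1.0), seed=8)
        path = tmp_path / "traj.h5"
        R.trajectory_to_hdf5(traj, path)
        back = R.trajectory_from_hdf5(path)
        assert np.allclose(back.final.complex_positions,
                           traj.final.complex_positions)
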