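"""Microtubule geometry, elasticity and dynamic instability."""

import numpy as np
import pytest
from scipy import stats

from pcm_selforg import filaments as F
from pcm_selforg.config import FiberParams
from tests.conftest import straight_filament


class TestNucleation:
    def test_seed_nucleation_geometry(self, fiber, rng):
        site = F.NucleationSite(host_bead=None, position=(3.0, 0.0),
                                orientation=np.pi / 2)
        fil = F.nucleate(site, rng, fiber)
        assert np.allclose(fil.vertices[0], [3.0, 0.0])
        assert np.allclose(fil.vertices[1], [3.0, fiber.segment_length])
        assert fil.dynamic_state == F.GROWING

    def test_initial_length_is_one_segment(self, fiber, rng):
        site = F.NucleationSite(host_bead=1, position=(0.0, 0.0))
        fil = F.nucleate(site, rng, fiber)
        assert fil.length == pytest.approx(fiber.segment_length)

    def test_occupied_site_rejects_second_filament(self, fiber, rng):
        site = F.NucleationSite(host_bead=None, position=(0, 0), orientation=0.0)
        F.nucleate(site, rng, fiber)
        with pytest.raises(F.OccupancyError):
            F.nucleate(site, rng, fiber)


class TestDynamicInstability:
    def test_unloaded_growth_rate(self, fiber):
        rng = np.random.default_rng(0)
        fil = straight_filament(n=3)
        fiber = FiberParams(k_cat=1e-15, L_mean=0.13 / 1e-15)  # no catastrophe
        L0 = fil.rest_length
        F.update_dynamic_instability(fil, 0.0, fiber, 1.0, rng)
        assert fil.rest_length - L0 == pytest.approx(0.13, rel=1e-9)

    def test_growth_at_characteristic_force_slows_e_fold(self):
        rng = np.random.default_rng(0)
        fil = straight_filament(n=3)
        fiber = FiberParams(k_cat=1e-15, L_mean=0.13 / 1e-15)
        L0 = fil.rest_length
        F.update_dynamic_instability(fil, 1.7, fiber, 1.0, rng)
        assert fil.rest_length - L0 == pytest.approx(0.13 / np.e, rel=1e-6)

    def test_length_cap_pauses_growth(self, fiber):
        rng = np.random.default_rng(0)
        fil = straight_filament(n=16)  # rest length 7.5 at the cap
        fiber = FiberParams(k_cat=1e-15, L_mean=0.13 / 1e-15)
        F.update_dynamic_instability(fil, 0.0, fiber, 0.01, rng)
        assert fil.dynamic_state == F.PAUSED_AT_CAP
        assert fil.rest_length <= fiber.L_max + fiber.v_grow * 0.01

    def test_shrinkage_rate_and_removal(self, fiber):
        rng = np.random.default_rng(0)
        fil = straight_filament(n=3)
        fil.dynamic_state = F.SHRINKING
        L0 = fil.rest_length
        F.update_dynamic_instability(fil, 0.0, fiber, 1.0, rng)
        assert L0 - fil.rest_length == pytest.approx(0.272, rel=1e-9)
        for _ in range(10):
            F.update_dynamic_instability(fil, 0.0, fiber, 1.0, rng)
        assert not fil.alive

    def test_non_positive_dt_rejected(self, fiber, rng):
        with pytest.raises(ValueError):
            F.update_dynamic_instability(straight_filament(), 0.0, fiber, 0.0, rng)

    def test_mean_length_at_catastrophe_is_5um(self, fiber):
        # without the cap, length at catastrophe ~ Exp(mean v_g/k_cat = 5 um)
        rng = np.random.default_rng(11)
        lengths, _ = F.simulate_growth_episodes(fiber, 0.1, 10_000, rng,
                                                cap=False)
        se = lengths.std() / np.sqrt(lengths.size)
        assert abs(lengths.mean() - 5.0) < 2 * se + 0.013  # + dt bias bound

    def test_catastrophe_times_are_exponential(self, fiber):
        rng = np.random.default_rng(13)
        _, times = F.simulate_growth_episodes(fiber, 0.05, 10_000, rng)
        # KS against Exp(k_cat); mean waiting time 1/0.026 = 38.46 s
        stat, p = stats.kstest(times, "expon", args=(0, 1.0 / fiber.k_cat))
        assert p > 0.05
        assert times.mean() == pytest.approx(1.0 / 0.026, rel=0.05)

    def test_capped_filament_never_exceeds_limit(self, fiber):
        rng = np.random.default_rng(3)
        lengths, _ = F.simulate_growth_episodes(fiber, 0.05, 2000, rng,
                                                cap=True)
        assert lengths.max() <= fiber.L_max + fiber.v_grow * 0.05


class TestBending:
    def test_straight_filament_has_zero_forces(self):
        assert np.allclose(F.bending_forces(straight_filament(n=8)), 0.0)

    def test_two_vertex_filament_has_no_curvature(self):
        assert np.allclose(F.bending_forces(straight_filament(n=2)), 0.0)

    def test_right_angle_conserves_momentum_and_torque(self):
        fil = F.Filament(
            vertices=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]),
            rest_segment_length=1.0, last_rest=1.0)
        forces = F.bending_forces(fil)
        assert np.allclose(forces.sum(axis=0), 0.0, atol=1e-12)
        torque = (fil.vertices[:, 0] * forces[:, 1]
                  - fil.vertices[:, 1] * forces[:, 0]).sum()
        assert abs(torque) < 1e-12
        assert not np.allclose(forces, 0.0)  # restoring forces exist

    def test_arc_energy_matches_continuum_rod(self):
        # elastic energy per unit length of an arc of radius R = kappa/(2 R^2)
        R, seg = 4.0, 0.1
        theta = np.arange(30) * seg / R
        fil = F.Filament(
            vertices=R * np.column_stack([np.cos(theta), np.sin(theta)]),
            rest_segment_length=seg, last_rest=seg, rigidity=20.0)
        # each of the n-2 interior vertices carries one curvature sample,
        # so the discrete energy covers (n-2) segment lengths of arc
        L = 28 * seg
        expected = 20.0 / (2.0 * R ** 2) * L
        assert F.bending_energy(fil) == pytest.approx(expected, rel=0.01)


class TestGeometry:
    def test_perpendicular_foot(self):
        fil = straight_filament(n=11, seg=0.5)  # (0,0) -> (5,0)
        s, d = F.closest_point(fil, [2.0, 0.05])
        assert s == pytest.approx(2.0, abs=1e-9)
        assert d == pytest.approx(0.05, abs=1e-9)

    def test_endpoint_clamp_beyond_plus_end(self):
        fil = straight_filament(n=11, seg=0.5)
        s, d = F.closest_point(fil, [6.0, 0.0])
        assert (s, d) == (pytest.approx(5.0), pytest.approx(1.0))

    def test_closest_point_matches_brute_force(self, rng):
        for _ in range(20):
            pts = np.cumsum(rng.normal(0, 0.4, (8, 2)), axis=0)
            fil = F.Filament(vertices=pts, rest_segment_length=0.5,
                             last_rest=0.5)
            x = rng.uniform(-2, 2, 2)
            s, d = F.closest_point(fil, x)
            # dense sampling oracle
            samples = []
            seg_len = np.hypot(*np.diff(pts, axis=0).T)
            cum = np.concatenate([[0], np.cumsum(seg_len)])
            for i in range(7):
                for t in np.linspace(0, 1, 400):
                    p = pts[i] + t * (pts[i + 1] - pts[i])
                    samples.append((cum[i] + t * seg_len[i], np.hypot(*(p - x))))
            s_best, d_best = min(samples, key=lambda q: q[1])
            assert d == pytest.approx(d_best, abs=1e-3)
            assert abs(s - s_best) < 5e-3 or abs(d - d_best) < 1e-6

    def test_point_at_abscissa_endpoints_and_interior(self):
        fil = straight_filament(n=4, seg=1.0)
        assert np.allclose(F.point_at_abscissa(fil, 0.0), fil.vertices[0])
        assert np.allclose(F.point_at_abscissa(fil, fil.length), fil.vertices[-1])
        assert np.allclose(F.point_at_abscissa(fil, 1.5), [1.5, 0.0])

    def test_point_at_abscissa_out_of_range(self):
        with pytest.raises(ValueError):
            F.point_at_abscissa(straight_filament(n=3), 5.0)
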