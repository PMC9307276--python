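"""Radiality decomposition, intensity profiles, normalizations and tracks."""

import numpy as np
import pandas as pd
import pytest

from pcm_selforg import imaging as I
from pcm_selforg import fixtures as FX


# --------------------------------------------------------------------------
# orientation and radiality


class TestOrientationMap:
    @staticmethod
    def stripes(axis, n=64, period=8):
        idx = np.arange(n)
        wave = 0.5 * (1 + np.sin(2 * np.pi * idx / period))
        img = np.tile(wave, (n, 1))
        if axis == "horizontal":  # intensity varies along rows
            img = img.T
        return I.Image2D(img)

    def test_horizontal_stripes_angle_zero(self):
        field = I.orientation_map(self.stripes("horizontal"))
        core = field.angle[20:-20, 20:-20]
        assert np.abs(np.sin(core)).max() < 0.05  # angle ~ 0 mod pi

    def test_vertical_stripes_angle_half_pi(self):
        field = I.orientation_map(self.stripes("vertical"))
        core = field.angle[20:-20, 20:-20]
        assert np.abs(np.cos(core)).max() < 0.05

    @pytest.mark.parametrize("theta_deg", [20, 45, 70, 110])
    def test_rotated_line_recovered_within_2_degrees(self, theta_deg):
        n = 129
        rr, cc = np.mgrid[0:n, 0:n]
        th = np.radians(theta_deg)
        # signed distance from each pixel to a line through the center with
        # direction (cos th, sin th) in (x=col, y=row) coordinates
        perp = (rr - n // 2) * np.cos(th) - (cc - n // 2) * np.sin(th)
        img = I.Image2D(np.exp(-0.5 * (perp / 2.0) ** 2))
        field = I.orientation_map(img)
        mask = np.abs(perp) < 1.5
        mask[:10] = mask[-10:] = False
        ang = field.angle[mask]
        err = np.angle(np.exp(2j * (ang - th))) / 2  # compare mod pi
        assert np.degrees(np.abs(np.median(err))) < 2.0

    def test_constant_image_flagged_unreliable(self):
        field = I.orientation_map(I.Image2D(np.ones((32, 32))))
        assert not field.reliable
        assert np.allclose(field.coherence, 0.0)


class TestRadiality:
    def test_decomposition_reconstructs_image(self, rng):
        img = I.Image2D(rng.random((64, 64)))
        field = I.orientation_map(img)
        rad, nonrad = I.radiality_decompose(img, field, (32, 32))
        assert np.allclose(rad + nonrad, img.data, rtol=1e-6)
        assert rad.sum() + nonrad.sum() == pytest.approx(img.data.sum(),
                                                         rel=1e-6)

    def test_aster_is_mostly_radial(self):
        img, truth = FX.make_filament_image("aster", n_filaments=60, seed=1)
        assert I.nonradial_fraction(img, truth["origin"]) < 0.1

    def test_tangential_is_mostly_nonradial(self):
        img, truth = FX.make_filament_image("tangential", n_filaments=60,
                                            seed=2)
        assert I.nonradial_fraction(img, truth["origin"]) > 0.9

    def test_random_filaments_near_analytic_mean(self):
        # isotropic orientations: expected non-radial fraction 1 - 2/pi
        img, truth = FX.make_filament_image("random", n_filaments=120, seed=3)
        frac = I.nonradial_fraction(img, truth["origin"])
        assert frac == pytest.approx(1.0 - 2.0 / np.pi, abs=0.05)

    def test_rotation_equivariance(self):
        img, truth = FX.make_filament_image("aster", n_filaments=40, seed=4,
                                            image_size_px=257)
        f0 = I.nonradial_fraction(img, truth["origin"])
        rot = I.Image2D(np.rot90(img.data).copy(), img.pixel_size)
        f90 = I.nonradial_fraction(rot, truth["origin"])
        assert f90 == pytest.approx(f0, abs=0.01)

    def test_zero_image_rejected(self):
        with pytest.raises(ValueError):
            I.nonradial_fraction(I.Image2D(np.zeros((16, 16))), (8, 8))

    def test_find_origin_locates_brightest_spot(self):
        img = np.zeros((64, 64))
        img[40, 22] = 50.0
        assert I.find_origin(I.Image2D(img)) == (40, 22)


# --------------------------------------------------------------------------
# profiles and normalizations


class TestRingProfile:
    def test_point_source_at_center(self):
        img = np.zeros((64, 64))
        img[32, 32] = 7.0
        prof = I.ring_profile(I.Image2D(img, pixel_size=0.1), (32, 32))
        assert prof[0] == pytest.approx(1.0)
        assert np.allclose(prof[1:], 0.0)

    def test_uniform_image_fractions_scale_with_annulus_area(self):
        n = 801  # rings fully inside: 10 rings x 2 um at 0.025 um/px = 800 px
        img = I.Image2D(np.ones((n, n)), pixel_size=0.025)
        prof = I.ring_profile(img, (n // 2, n // 2), n_rings=4,
                              ring_width_um=2.0)
        ratios = prof[1:] / prof[0]
        assert np.allclose(ratios, [3.0, 5.0, 7.0], rtol=0.02)

    def test_profile_sums_to_at_most_one(self, rng):
        img = I.Image2D(rng.random((100, 100)), pixel_size=0.5)
        prof = I.ring_profile(img, (50, 50), n_rings=5)
        assert prof.sum() <= 1.0 + 1e-12

    def test_twenty_circle_variant_reachable(self, rng):
        img = I.Image2D(rng.random((64, 64)), pixel_size=0.5)
        prof = I.ring_profile(img, (32, 32), n_rings=20, ring_width_um=1.0)
        assert prof.shape == (20,)


class TestFrapNormalize:
    def test_pre_bleach_mean_is_exactly_100(self, rng):
        trace = 500 + 20 * rng.random(60)
        bg = np.full(60, 50.0)
        out = I.frap_normalize(trace, bg, bleach_frame=15)
        assert out[:15].mean() == pytest.approx(100.0, abs=1e-9)

    def test_known_recovery_plateau(self):
        trace, bg, truth = FX.make_frap_trace(bleach_depth=1.0,
                                              recovery_amplitude=0.6,
                                              tau=5.0, n_frames=200)
        out = I.frap_normalize(trace, bg, truth["bleach_frame"])
        assert out[-5:].mean() == pytest.approx(truth["plateau_pct"], abs=1.0)

    def test_background_only_trace_rejected(self):
        with pytest.raises(ValueError):
            I.frap_normalize(np.full(20, 30.0), np.full(20, 30.0), 5)


class TestLocalDensity:
    def test_baseline_is_100_percent(self, rng):
        frames = np.tile(rng.random((32, 32)), (30, 1, 1))
        out, flags = I.local_density(frames, (16, 16), pixel_size=0.5,
                                     baseline_frames=20)
        assert np.allclose(out, 100.0)
        assert not flags.any()

    def test_halved_intensity_reads_50_percent(self):
        frames = np.ones((30, 32, 32))
        frames[25:] = 0.5
        out, _ = I.local_density(frames, (16, 16), pixel_size=0.5,
                                 baseline_frames=20)
        assert np.allclose(out[25:], 50.0)

    def test_clipped_disc_is_flagged(self):
        frames = np.ones((25, 32, 32))
        out, flags = I.local_density(frames, (1, 1), pixel_size=0.5,
                                     baseline_frames=20)
        assert flags.all()


# --------------------------------------------------------------------------
# track linking and filtering


def brute_force_link(locs, max_dist=5.0):
    """Oracle: repeatedly accept the globally closest remaining pair."""
    locs = locs.reset_index(drop=True)
    parent = {}
    frames = sorted(locs["frame"].unique())
    for f in frames:
        a_idx = locs.index[locs["frame"] == f].tolist()
        b_idx = locs.index[locs["frame"] == f + 1].tolist()
        pairs = []
        for ia in a_idx:
            for ib in b_idx:
                d = np.hypot(locs.x_px[ia] - locs.x_px[ib],
                             locs.y_px[ia] - locs.y_px[ib])
                if d <= max_dist:
                    pairs.append((d, ia, ib))
        used_a, used_b = set(), set()
        for d, ia, ib in sorted(pairs):
            if ia in used_a or ib in used_b:
                continue
            used_a.add(ia)
            used_b.add(ib)
            parent[ib] = ia
    # build track labels
    labels = {}
    nxt = 0
    for i in locs.sort_values("frame").index:
        if i in parent:
            labels[i] = labels[parent[i]]
        else:
            labels[i] = nxt
            nxt += 1
    return labels


class TestLinking:
    def test_two_points_within_range_form_one_track(self):
        locs = pd.DataFrame({"frame": [0, 1], "x_px": [0.0, 3.0],
                             "y_px": [0.0, 0.0]})
        tt = I.link_localizations(locs)
        assert tt.n_tracks == 1

    def test_out_of_range_points_stay_separate(self):
        locs = pd.DataFrame({"frame": [0, 1], "x_px": [0.0, 6.0],
                             "y_px": [0.0, 0.0]})
        assert I.link_localizations(locs).n_tracks == 2

    def test_no_gap_closing(self):
        locs = pd.DataFrame({"frame": [0, 2], "x_px": [0.0, 1.0],
                             "y_px": [0.0, 0.0]})
        assert I.link_localizations(locs).n_tracks == 2

    def test_matches_brute_force_on_ambiguous_frames(self):
        for seed in range(20):
            locs = FX.make_localizations(n_particles=5, n_frames=6,
                                         step_px=3.0, seed=seed)
            tt = I.link_localizations(locs)
            oracle = brute_force_link(locs)
            mine = tt.table.sort_values(["frame", "x_px", "y_px"])
            # same partition: compare co-membership matrices
            locs2 = locs.reset_index(drop=True)
            lab_mine = (tt.table.set_index(["frame", "x_px", "y_px"])
                        ["track_id"].to_dict())
            def labels_of(src):
                return [src[i] for i in locs2.index]
            lm = [lab_mine[(locs2.frame[i], locs2.x_px[i], locs2.y_px[i])]
                  for i in locs2.index]
            lo = labels_of(oracle)
            same_mine = np.equal.outer(lm, lm)
            same_oracle = np.equal.outer(lo, lo)
            assert np.array_equal(same_mine, same_oracle), f"seed {seed}"


def independent_rule_check(g, frame_interval, pixel_size):
    """Rule-by-rule reference for the track filter, coded independently."""
    g = g.sort_values("frame")
    n = len(g)
    if not (4 <= n <= 200):
        return False
    xy = g[["x_px", "y_px"]].to_numpy()
    disp = np.diff(xy, axis=0)
    disp = disp[np.hypot(*disp.T) > 0]
    for a, b in zip(disp[:-1], disp[1:]):
        cosv = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        if np.degrees(np.arccos(np.clip(cosv, -1, 1))) > 90.0:
            return False
    path_nm = np.hypot(*np.diff(xy, axis=0).T).sum() * pixel_size * 1000
    speed = path_nm / ((n - 1) * frame_interval)
    return 100.0 <= speed <= 1500.0


class TestTrackFilter:
    def test_boundary_cases_from_fixture(self):
        tt, keep = FX.make_track_table(n_tracks=30, seed=1)
        kept = set(I.filter_tracks(tt).table["track_id"].unique())
        for tid, expected in keep.items():
            assert (tid in kept) == expected, f"track {tid}"

    def test_agreement_with_independent_checker_on_1000_tracks(self):
        tt, _ = FX.make_track_table(n_tracks=1000, seed=2)
        kept = set(I.filter_tracks(tt).table["track_id"].unique())
        for tid, g in tt.groups():
            expected = independent_rule_check(g, tt.frame_interval,
                                              tt.pixel_size)
            assert (tid in kept) == expected, f"track {tid}"

    def test_filter_is_idempotent(self):
        tt, _ = FX.make_track_table(n_tracks=100, seed=3)
        once = I.filter_tracks(tt)
        twice = I.filter_tracks(once)
        assert once.table.equals(twice.table)

    def test_three_frame_track_removed(self):
        tt, keep = FX.make_track_table(n_tracks=12, seed=4)
        # fixture track 0 is the 3-frame boundary case
        assert keep[0] is False
        assert 0 not in set(I.filter_tracks(tt).table["track_id"])


class TestQuadrants:
    def test_sign_patterns(self):
        rows = [(0, 0, 0.0, 0.0), (0, 1, 3.0, 2.0),
                (1, 0, 5.0, 5.0), (1, 1, 4.0, 9.0)]
        tt = I.TrackTable(pd.DataFrame(rows, columns=["track_id", "frame",
                                                      "x_px", "y_px"]))
        q = I.quadrant_split(tt)
        assert set(q["++"].table["track_id"]) == {0}
        assert set(q["-+"].table["track_id"]) == {1}

    def test_outputs_partition_input(self):
        tt, _ = FX.make_track_table(n_tracks=40, seed=5)
        q = I.quadrant_split(tt)
        total = sum(len(sub.table) for sub in q.values())
        assert total == len(tt.table)
        ids = [set(sub.table["track_id"]) for sub in q.values()]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not ids[i] & ids[j]


class TestMinusEndFraction:
    def test_equal_lengths_give_half(self):
        segs = [(np.array([[0, 0], [1, 0]]), "minus_out"),
                (np.array([[0, 0], [0, 1]]), "plus_out")]
        assert I.minus_end_out_fraction(segs) == pytest.approx(0.5)

    def test_all_minus_out(self):
        segs = [(np.array([[0, 0], [2, 0], [2, 1]]), "minus_out")]
        assert I.minus_end_out_fraction(segs) == 1.0

    def test_polyline_lengths_summed_exactly(self, rng):
        segs = []
        total = minus = 0.0
        for i in range(10):
            poly = rng.normal(0, 5, (rng.integers(2, 8), 2))
            L = float(np.hypot(*np.diff(poly, axis=0).T).sum())
            label = "minus_out" if i % 2 else "plus_out"
            segs.append((poly, label))
            total += L
            minus += L if label == "minus_out" else 0.0
        assert I.minus_end_out_fraction(segs) == pytest.approx(minus / total,
                                                               rel=1e-12)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            I.minus_end_out_fraction([(np.zeros((2, 2)), "minus_out")])
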