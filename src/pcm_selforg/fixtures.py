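"""Synthetic test inputs with known ground truth.

Every analysis stage in this package can be exercised without any external
data: this module draws filament-pattern images (radial aster, tangential
arcs, isotropic random lines), point patterns with closed-form distance
statistics (Gaussian cluster, jittered ring, uniform disc), photobleaching
recovery traces, localization tables and boundary-straddling motor tracks —
all deterministic given a seed, and each paired with the values the
corresponding analysis should recover.

The image generator emulates the geometry of stained-filament micrographs
(default 512×512 px at 66.7 nm/px), not their optics: there is no PSF model,
and noise is additive Gaussian clipped at zero (Poisson optional).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imaging import Image2D, TrackTable

__all__ = [
    "make_filament_image",
    "make_point_pattern",
    "make_track_table",
    "make_frap_trace",
    "make_localizations",
]

DEFAULT_SIZE = 512
DEFAULT_PIXEL = 0.0667  # µm/px


def _draw_line(canvas: np.ndarray, p0, p1, width: float, amplitude: float = 1.0):
    """Accumulate a soft-edged line segment onto the canvas (row, col coords)."""
    n = canvas.shape[0]
    # distance from every pixel to the segment
    rr, cc = np.mgrid[0:n, 0:canvas.shape[1]]
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    L2 = max(float(d @ d), 1e-12)
    t = np.clip(((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / L2, 0.0, 1.0)
    dist = np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))
    canvas += amplitude * np.exp(-0.5 * (dist / (width / 2.0)) ** 2)


def make_filament_image(kind: str, n_filaments: int = 40,
                        image_size_px: int = DEFAULT_SIZE,
                        pixel_size: float = DEFAULT_PIXEL,
                        line_width_px: float = 3.0, noise_sd: float = 0.0,
                        seed: int = 0, noise: str = "gaussian"):
    """Synthesize a filament image; returns ``(Image2D, ground_truth dict)``.

    kinds: ``"aster"`` (line segments through the center — a radial pattern),
    ``"tangential"`` (arcs of concentric circles — everywhere perpendicular
    to the radius), ``"random"`` (uniform positions and orientations, for
    which the expected non-radial fraction is ``1 - E|cos| = 1 - 2/π``).
    Noise is additive Gaussian of SD ``noise_sd`` clipped at zero
    (``noise="poisson"`` scales to counts instead).
    """
    if n_filaments < 1:
        raise ValueError("n_filaments must be >= 1")
    rng = np.random.default_rng(seed)
    n = image_size_px
    img = np.zeros((n, n))
    center = np.array([(n - 1) / 2.0, (n - 1) / 2.0])
    rmax = 0.48 * n
    if kind == "aster":
        for theta in rng.uniform(0.0, 2.0 * np.pi, n_filaments):
            u = np.array([np.sin(theta), np.cos(theta)])
            _draw_line(img, center + 6.0 * u, center + rmax * u, line_width_px)
        truth = {"class": "radial", "expected_nonradial": 0.0}
    elif kind == "tangential":
        radii = rng.uniform(0.15 * n, rmax, n_filaments)
        for r, th0 in zip(radii, rng.uniform(0.0, 2.0 * np.pi, n_filaments)):
            arc = np.linspace(th0, th0 + 1.2, 60)
            pts = center + r * np.column_stack([np.sin(arc), np.cos(arc)])
            for a, b in zip(pts[:-1], pts[1:]):
                _draw_line(img, a, b, line_width_px)
        truth = {"class": "tangential", "expected_nonradial": 1.0}
    elif kind == "random":
        for _ in range(n_filaments):
            p0 = rng.uniform(0.1 * n, 0.9 * n, 2)
            theta = rng.uniform(0.0, np.pi)
            u = np.array([np.sin(theta), np.cos(theta)])
            length = rng.uniform(0.2 * n, 0.5 * n)
            _draw_line(img, p0 - length / 2 * u, p0 + length / 2 * u,
                       line_width_px)
        truth = {"class": "random", "expected_nonradial": 1.0 - 2.0 / np.pi}
    else:
        raise ValueError(f"unknown image kind {kind!r}")
    if noise_sd > 0:
        if noise == "poisson":
            scale = max(img.max(), 1e-12) / noise_sd ** 2
            img = rng.poisson(np.maximum(img, 0.0) * scale) / scale
        else:
            img = img + noise_sd * rng.standard_normal(img.shape)
        img = np.clip(img, 0.0, None)
    truth["origin"] = (float(center[0]), float(center[1]))
    return Image2D(img, pixel_size=pixel_size), truth


def make_point_pattern(kind: str, n: int, seed: int = 0, sigma: float = 0.5,
                       ring_radius: float = 5.0, ring_jitter: float = 0.0,
                       disc_radius: float = 10.0):
    """Point patterns with closed-form COM-distance statistics.

    Returns ``(positions (n,2), expected (mean_dist, sd_dist))``:
    ``gaussian_cluster`` — isotropic Gaussian, Rayleigh distances with mean
    ``σ√(π/2)`` and SD ``σ√(2-π/2)``; ``ring`` — radius r with radial jitter,
    mean ≈ r; ``uniform_disc`` — radius R, mean 2R/3 and SD R/√18.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    if kind == "gaussian_cluster":
        pts = sigma * rng.standard_normal((n, 2))
        expected = (sigma * np.sqrt(np.pi / 2.0),
                    sigma * np.sqrt(2.0 - np.pi / 2.0))
    elif kind == "ring":
        r = ring_radius + ring_jitter * rng.standard_normal(n)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        expected = (ring_radius, ring_jitter)
    elif kind == "uniform_disc":
        r = disc_radius * np.sqrt(rng.random(n))
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        expected = (2.0 * disc_radius / 3.0, disc_radius / np.sqrt(18.0))
    else:
        raise ValueError(f"unknown point pattern {kind!r}")
    return pts, expected


def make_frap_trace(I_pre: float = 1000.0, bleach_depth: float = 1.0,
                    recovery_amplitude: float = 0.6, tau: float = 10.0,
                    n_frames: int = 100, bleach_frame: int = 10,
                    background: float = 50.0, noise_sd: float = 0.0,
                    seed: int = 0):
    """Mono-exponential recovery trace; returns ``(trace, bg, truth)``.

    Intensity drops by ``bleach_depth`` of the pre-bleach level at
    ``bleach_frame`` and the bleached portion recovers a fraction
    ``recovery_amplitude`` with time constant ``tau`` frames, so the plateau
    is ``(1-depth) + amplitude*depth`` of pre-bleach; truth carries the
    normalized plateau in percent.  ``bleach_depth = 0`` gives a flat trace.
    """
    if not 0.0 <= bleach_depth <= 1.0:
        raise ValueError("bleach_depth must lie in [0, 1]")
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)
    trace = np.full(n_frames, float(I_pre))
    post = t >= bleach_frame
    floor = 1.0 - bleach_depth
    rec = recovery_amplitude * bleach_depth * \
        -np.expm1(-(t[post] - bleach_frame) / tau)
    trace[post] = I_pre * (floor + rec)
    trace = trace + background
    if noise_sd > 0:
        trace = trace + noise_sd * rng.standard_normal(n_frames)
    bg = np.full(n_frames, background)
    truth = {"plateau_pct": 100.0 * (floor + recovery_amplitude * bleach_depth),
             "bleach_frame": bleach_frame}
    return trace, bg, truth


def _straight_track(tid, n_frames, speed_nm_s, frame_interval, pixel_size,
                    start, theta, rng, turn_deg=0.0, turn_at=None):
    step_px = speed_nm_s * frame_interval / (pixel_size * 1000.0)
    rows = []
    pos = np.asarray(start, float)
    ang = theta
    for f in range(n_frames):
        rows.append((tid, f, pos[0], pos[1]))
        if turn_at is not None and f == turn_at:
            ang += np.radians(turn_deg)
        pos = pos + step_px * np.array([np.cos(ang), np.sin(ang)])
    return rows


def make_track_table(n_tracks: int = 50, frame_interval: float = 0.06,
                     pixel_size: float = 0.064, seed: int = 0):
    """Synthetic motor tracks straddling every filter boundary.

    Returns ``(TrackTable, keep)`` where ``keep`` maps track_id -> whether
    the track satisfies all standard filter rules (4–200 frames, turns
    <= 90°, speed 100–1500 nm/s).  A quarter of the tracks are boundary
    cases (3 vs 4 and 200 vs 201 frames, 89° vs 91° turns, speeds just
    inside/outside both limits); the rest are random.
    """
    rng = np.random.default_rng(seed)
    boundary = [
        dict(n_frames=3, speed=500.0, turn=0.0),
        dict(n_frames=4, speed=500.0, turn=0.0),
        dict(n_frames=200, speed=500.0, turn=0.0),
        dict(n_frames=201, speed=500.0, turn=0.0),
        dict(n_frames=10, speed=500.0, turn=89.0),
        dict(n_frames=10, speed=500.0, turn=91.0),
        dict(n_frames=10, speed=99.0, turn=0.0),
        dict(n_frames=10, speed=101.0, turn=0.0),
        dict(n_frames=10, speed=1499.0, turn=0.0),
        dict(n_frames=10, speed=1501.0, turn=0.0),
    ]
    rows = []
    keep = {}
    tid = 0
    for spec in boundary:
        rows += _straight_track(
            tid, spec["n_frames"], spec["speed"], frame_interval, pixel_size,
            rng.uniform(0, 400, 2), rng.uniform(0, 2 * np.pi), rng,
            turn_deg=spec["turn"],
            turn_at=spec["n_frames"] // 2 if spec["turn"] else None)
        keep[tid] = (4 <= spec["n_frames"] <= 200 and spec["turn"] <= 90.0
                     and 100.0 <= spec["speed"] <= 1500.0)
        tid += 1
    while tid < n_tracks:
        n_frames = int(rng.integers(2, 40))
        speed = float(rng.uniform(20.0, 2000.0))
        turn = float(rng.uniform(0.0, 150.0)) if rng.random() < 0.5 else 0.0
        rows += _straight_track(
            tid, n_frames, speed, frame_interval, pixel_size,
            rng.uniform(0, 400, 2), rng.uniform(0, 2 * np.pi), rng,
            turn_deg=turn, turn_at=n_frames // 2 if turn else None)
        keep[tid] = (4 <= n_frames <= 200 and turn <= 90.0
                     and 100.0 <= speed <= 1500.0)
        tid += 1
    table = pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px"])
    return (TrackTable(table, frame_interval=frame_interval,
                       pixel_size=pixel_size), keep)


def make_localizations(n_particles: int = 5, n_frames: int = 8,
                       step_px: float = 2.0, field_px: float = 100.0,
                       seed: int = 0) -> pd.DataFrame:
    """Random walker localizations (columns frame, x_px, y_px) for linking."""
    rng = np.random.default_rng(seed)
    rows = []
    pos = rng.uniform(10.0, field_px - 10.0, (n_particles, 2))
    for f in range(n_frames):
        for p in range(n_particles):
            rows.append((f, pos[p, 0], pos[p, 1]))
        pos = pos + rng.uniform(-step_px, step_px, pos.shape)
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])
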