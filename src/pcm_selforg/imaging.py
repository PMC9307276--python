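"""Image and track quantifications.

Four independent analyses used on micrographs and single-particle data:

* **radiality decomposition** — a structure-tensor orientation map splits a
  microtubule image into a radial component (intensity weighted by
  ``|cos Δθ|``, where Δθ is the local orientation relative to the ray from a
  chosen origin) and its complement; the two maps sum exactly to the input.
* **concentric ring profiles** — fraction of total intensity in annuli of
  fixed width around a center (default ten 2-µm rings).
* **normalizations** — photobleaching-recovery traces normalized to the mean
  pre-bleach level (= 100%), and local filament density in a 2-µm disc
  normalized to a pre-event baseline (= 100%).
* **motor tracks** — greedy mutual-nearest-neighbor frame linking (no gaps),
  rule-based track filtering (length, turning angle, speed), quadrant
  splitting by net displacement, and the minus-end-out length fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import structure_tensor

__all__ = [
    "Image2D",
    "OrientationField",
    "TrackTable",
    "orientation_map",
    "radiality_decompose",
    "nonradial_fraction",
    "find_origin",
    "ring_profile",
    "frap_normalize",
    "local_density",
    "link_localizations",
    "filter_tracks",
    "quadrant_split",
    "minus_end_out_fraction",
]


@dataclass
class Image2D:
    """A non-negative intensity grid with physical pixel size."""

    data: np.ndarray  # (rows, cols)
    pixel_size: float = 0.0667  # µm/px

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Image2D expects a 2D array")
        if not np.all(np.isfinite(self.data)) or (self.data < 0).any():
            raise ValueError("intensities must be finite and non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class OrientationField:
    """Per-pixel local orientation (radians in (-π/2, π/2]) and coherence."""

    angle: np.ndarray
    coherence: np.ndarray
    reliable: bool = True


@dataclass
class TrackTable:
    """Linked localizations: one row per (track, frame), consecutive frames."""

    table: pd.DataFrame  # columns: track_id, frame, x_px, y_px
    frame_interval: float = 0.06  # s
    pixel_size: float = 0.064  # µm/px

    def __post_init__(self):
        need = {"track_id", "frame", "x_px", "y_px"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"track table needs columns {sorted(need)}")

    @property
    def n_tracks(self) -> int:
        return self.table["track_id"].nunique()

    def groups(self):
        return self.table.groupby("track_id", sort=True)


# ---------------------------------------------------------------------------
# radiality


def orientation_map(img: Image2D, sigma_px: float = 6.0) -> OrientationField:
    """Local orientation from the smoothed 2D structure tensor.

    Gaussian-derivative gradients; tensor elements smoothed with
    ``sigma_px`` (default 6 px ≈ 0.4 µm at 67 nm/px).  The angle is that of
    the dominant *structure* direction (eigenvector of the smallest
    eigenvalue of the gradient tensor), mod π, mapped to (-π/2, π/2].
    Coherence is (λ1-λ2)/(λ1+λ2) in [0, 1]; a constant image yields zero
    coherence everywhere and is flagged unreliable.
    """
    if img.data.shape[0] < 3 or img.data.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    Arr, Arc, Acc = structure_tensor(img.data, sigma=sigma_px, order="rc",
                                     mode="nearest")
    # orientation of least gradient change (along the ridge): angle from the
    # tensor of gradients; for axes order (row, col) the structure direction
    # in x/y convention (x = col, y = row) is 0.5*atan2(2*Jxy, Jxx - Jyy) + π/2
    Jxx, Jxy, Jyy = Acc, Arc, Arr
    angle = 0.5 * np.arctan2(2.0 * Jxy, Jxx - Jyy) + np.pi / 2.0
    angle = (angle + np.pi / 2.0) % np.pi - np.pi / 2.0  # -> (-π/2, π/2]
    angle[angle <= -np.pi / 2.0] = np.pi / 2.0
    tr = Jxx + Jyy
    det_disc = np.sqrt(np.maximum((Jxx - Jyy) ** 2 + 4.0 * Jxy ** 2, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(tr > 0, det_disc / np.maximum(tr, 1e-300), 0.0)
    coherence = np.clip(coherence, 0.0, 1.0)
    return OrientationField(angle=angle, coherence=coherence,
                            reliable=bool(np.any(coherence > 0)))


def radiality_decompose(img: Image2D, orientation: OrientationField,
                        origin: tuple[float, float]):
    """Split an image into radial and non-radial components.

    For each pixel the radial angle is the difference between the local
    orientation and the direction of the ray from ``origin`` (row, col) to
    the pixel; radial map = ``|cos Δθ| · I``, non-radial = ``(1-|cos Δθ|) ·
    I``, so the two maps reconstruct the image exactly.  The pixel at the
    origin itself has no defined ray and takes radial weight 1 by convention.
    """
    r0, c0 = origin
    rows, cols = img.data.shape
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError("origin must lie inside the image")
    rr, cc = np.mgrid[0:rows, 0:cols]
    dy = rr - r0  # row axis = y (x/y convention: x = col, y = row)
    dx = cc - c0
    ray = np.arctan2(dy, dx)
    dtheta = orientation.angle - ray
    w = np.abs(np.cos(dtheta))
    at_origin = (dx == 0) & (dy == 0)
    w[at_origin] = 1.0
    radial = w * img.data
    return radial, img.data - radial


def nonradial_fraction(img: Image2D, origin: tuple[float, float],
                       sigma_px: float = 6.0) -> float:
    """Fraction of total intensity in the non-radial component."""
    total = float(img.data.sum())
    if total <= 0:
        raise ValueError("image has zero total intensity")
    _, nonrad = radiality_decompose(img, orientation_map(img, sigma_px), origin)
    return float(nonrad.sum() / total)


def find_origin(reference: Image2D, sigma_px: float = 2.0) -> tuple[int, int]:
    """Brightest spot of the Gaussian-smoothed reference channel (row, col)."""
    sm = ndimage.gaussian_filter(reference.data, sigma_px)
    return tuple(int(v) for v in np.unravel_index(np.argmax(sm), sm.shape))


# ---------------------------------------------------------------------------
# intensity profiles and normalizations


def ring_profile(img: Image2D, center: tuple[float, float], n_rings: int = 10,
                 ring_width_um: float = 2.0) -> np.ndarray:
    """Fraction of total image intensity in concentric annuli around center.

    Ring k collects intensity at radii ``[k*w, (k+1)*w)`` µm; each entry is
    divided by the *total* image intensity, so the profile sums to 1 exactly
    when all intensity falls within ``n_rings * w`` and to less otherwise.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    total = float(img.data.sum())
    if total <= 0:
        raise ValueError("image has zero total intensity")
    r0, c0 = center
    rows, cols = img.data.shape
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError("center must lie inside the image")
    rr, cc = np.mgrid[0:rows, 0:cols]
    radius = np.hypot(rr - r0, cc - c0) * img.pixel_size
    k = np.floor(radius / ring_width_um).astype(int)
    out = np.zeros(n_rings)
    inside = k < n_rings
    np.add.at(out, k[inside], img.data[inside])
    return out / total


def frap_normalize(trace, background_trace, bleach_frame: int) -> np.ndarray:
    """Normalize a photobleaching-recovery trace to its pre-bleach mean.

    Background is subtracted frame-wise, then the trace is scaled so the mean
    over the frames before ``bleach_frame`` is exactly 100 (%).
    """
    trace = np.asarray(trace, dtype=float)
    bg = np.asarray(background_trace, dtype=float)
    if trace.shape != bg.shape:
        raise ValueError("trace and background must have equal length")
    if bleach_frame < 1 or bleach_frame > len(trace):
        raise ValueError("bleach_frame must be >= 1 and within the trace")
    corrected = trace - bg
    pre = corrected[:bleach_frame].mean()
    if pre <= 0:
        raise ValueError("pre-bleach mean is non-positive after background "
                         "subtraction")
    return 100.0 * corrected / pre


def local_density(frames, point: tuple[float, float], pixel_size: float,
                  radius_um: float = 2.0, baseline_frames: int = 20):
    """Mean intensity in a disc around ``point``, per frame, as % of baseline.

    ``frames`` is (t, rows, cols); the baseline is the mean over the first
    ``baseline_frames`` frames (set as 100%).  If the disc extends past the
    image edge only the intersected region is used and those frames are
    flagged in the returned mask.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3:
        raise ValueError("frames must be (t, rows, cols)")
    if stack.shape[0] < baseline_frames:
        raise ValueError("need at least baseline_frames frames")
    r0, c0 = point
    rows, cols = stack.shape[1:]
    rr, cc = np.mgrid[0:rows, 0:cols]
    rad_px = radius_um / pixel_size
    disc = np.hypot(rr - r0, cc - c0) <= rad_px
    if not disc.any():
        raise ValueError("disc does not intersect the image")
    clipped = (r0 - rad_px < -0.5 or c0 - rad_px < -0.5
               or r0 + rad_px > rows - 0.5 or c0 + rad_px > cols - 0.5)
    means = stack[:, disc].mean(axis=1)
    baseline = means[:baseline_frames].mean()
    if baseline <= 0:
        raise ValueError("baseline mean intensity is non-positive")
    flags = np.full(stack.shape[0], clipped)
    return 100.0 * means / baseline, flags


# ---------------------------------------------------------------------------
# track linking and filtering


def link_localizations(localizations: pd.DataFrame, max_dist_px: float = 5.0,
                       frame_interval: float = 0.06,
                       pixel_size: float = 0.064) -> TrackTable:
    """Greedy mutual-nearest-neighbor linking of localizations into tracks.

    Candidate links between consecutive frames within ``max_dist_px`` are
    accepted greedily in order of increasing distance (ties broken by the
    smaller localization ids), which makes every accepted link a mutual
    nearest choice among the remaining candidates.  No frame gaps; unlinked
    localizations start or end tracks.
    """
    need = {"frame", "x_px", "y_px"}
    if not need.issubset(localizations.columns):
        raise ValueError(f"localizations need columns {sorted(need)}")
    loc = localizations.reset_index(drop=True)
    track_of = np.full(len(loc), -1, dtype=int)
    next_track = 0
    by_frame = {f: g.index.to_numpy() for f, g in loc.groupby("frame")}
    frames_sorted = sorted(by_frame)
    for f in frames_sorted:
        idx = by_frame[f]
        for i in idx:
            if track_of[i] < 0:
                track_of[i] = next_track
                next_track += 1
        nxt = by_frame.get(f + 1)
        if nxt is None:
            continue
        a = loc.loc[idx, ["x_px", "y_px"]].to_numpy()
        b = loc.loc[nxt, ["x_px", "y_px"]].to_numpy()
        d = np.hypot(*(a[:, None, :] - b[None, :, :]).T).T
        cands = [(d[i, j], int(idx[i]), int(nxt[j]))
                 for i in range(len(idx)) for j in range(len(nxt))
                 if d[i, j] <= max_dist_px]
        used_a, used_b = set(), set()
        for dist, ia, ib in sorted(cands):
            if ia in used_a or ib in used_b:
                continue
            used_a.add(ia)
            used_b.add(ib)
            track_of[ib] = track_of[ia]
    out = loc.assign(track_id=track_of).sort_values(
        ["track_id", "frame"]).reset_index(drop=True)
    return TrackTable(out[["track_id", "frame", "x_px", "y_px"]],
                      frame_interval=frame_interval, pixel_size=pixel_size)


def _track_keep(g: pd.DataFrame, frame_interval: float, pixel_size: float,
                min_len: int, max_len: int, max_turn_deg: float,
                v_min_nm_s: float, v_max_nm_s: float,
                speed: str = "path") -> bool:
    n = len(g)
    if n < min_len or n > max_len:
        return False
    xy = g.sort_values("frame")[["x_px", "y_px"]].to_numpy()
    steps = np.diff(xy, axis=0)
    lengths = np.hypot(steps[:, 0], steps[:, 1])
    nz = lengths > 0
    v = steps[nz]
    if len(v) >= 2:
        cosang = (v[:-1] * v[1:]).sum(axis=1) / (
            np.hypot(*v[:-1].T) * np.hypot(*v[1:].T))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if (ang > max_turn_deg).any():
            return False
    duration = (n - 1) * frame_interval
    if duration <= 0:
        return False
    if speed == "path":
        dist_um = lengths.sum() * pixel_size
    else:  # net displacement
        dist_um = float(np.hypot(*(xy[-1] - xy[0]))) * pixel_size
    v_nm_s = dist_um * 1000.0 / duration
    return v_min_nm_s <= v_nm_s <= v_max_nm_s


def filter_tracks(tracks: TrackTable, min_len: int = 4, max_len: int = 200,
                  max_turn_deg: float = 90.0, v_min_nm_s: float = 100.0,
                  v_max_nm_s: float = 1500.0, speed: str = "path") -> TrackTable:
    """Keep tracks passing the standard motor-track quality rules.

    Rules: 4–200 frames; every turning angle between consecutive non-zero
    displacement vectors <= 90°; mean speed (total path length / duration,
    or net displacement / duration with ``speed="net"``) within
    100–1500 nm/s.  Applying the filter twice changes nothing.
    """
    keep = [tid for tid, g in tracks.groups()
            if _track_keep(g, tracks.frame_interval, tracks.pixel_size,
                           min_len, max_len, max_turn_deg,
                           v_min_nm_s, v_max_nm_s, speed)]
    out = tracks.table[tracks.table["track_id"].isin(keep)].reset_index(drop=True)
    return TrackTable(out, frame_interval=tracks.frame_interval,
                      pixel_size=tracks.pixel_size)


def quadrant_split(tracks: TrackTable) -> dict[str, TrackTable]:
    """Partition tracks by the sign pattern of their net displacement.

    Quadrant keys are ``"++", "+-", "-+", "--"`` for (sign Δx, sign Δy) of
    the start→end displacement; zero components count as positive.  The four
    outputs partition the input.
    """
    assign: dict[str, list] = {"++": [], "+-": [], "-+": [], "--": []}
    for tid, g in tracks.groups():
        if len(g) < 2:
            raise ValueError(f"track {tid} has fewer than 2 frames")
        g = g.sort_values("frame")
        dx = g["x_px"].iloc[-1] - g["x_px"].iloc[0]
        dy = g["y_px"].iloc[-1] - g["y_px"].iloc[0]
        key = ("+" if dx >= 0 else "-") + ("+" if dy >= 0 else "-")
        assign[key].append(tid)
    return {
        k: TrackTable(
            tracks.table[tracks.table["track_id"].isin(v)].reset_index(drop=True),
            frame_interval=tracks.frame_interval, pixel_size=tracks.pixel_size)
        for k, v in assign.items()
    }


def minus_end_out_fraction(segments) -> float:
    """Total minus-end-out polyline length over total length.

    ``segments`` is an iterable of ``(polyline (n,2), label)`` with label in
    {"minus_out", "plus_out"}; lengths are summed Euclidean distances between
    consecutive points.
    """
    total = 0.0
    minus_out = 0.0
    for poly, label in segments:
        poly = np.asarray(poly, dtype=float)
        L = float(np.hypot(*np.diff(poly, axis=0).T).sum())
        total += L
        if label == "minus_out":
            minus_out += L
        elif label != "plus_out":
            raise ValueError(f"unknown label {label!r}")
    if total <= 0:
        raise ValueError("zero total length")
    return minus_out / total
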