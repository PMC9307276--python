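"""Quantification of final-frame organization.

The summary statistic is deliberately simple: distances of all complexes to
their center of mass (the arithmetic mean position), reported as the mean and
the population standard deviation, plus the empirical cumulative distribution
of those distances.  Small mean and SD indicate a compact cluster; a larger
mean with small relative SD describes the radius of a ring; large mean and SD
together indicate dispersed complexes.  Also provided: the smallest enclosing
circle (the cluster-extent measure used on micrographs) and the sweep
post-processing that locates clustering thresholds and bistable regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "StructureSummary",
    "com_distance_stats",
    "ecdf",
    "ECDF",
    "classify_structure",
    "summarize_positions",
    "find_clustering_threshold",
    "min_enclosing_circle",
    "COMPACT",
    "RING",
    "DISPERSED",
]

COMPACT = "compact"
RING = "ring"
DISPERSED = "dispersed"


@dataclass
class StructureSummary:
    """Per-run COM-distance statistics and the derived class label."""

    scenario: str
    seed: int
    n_points: int
    mean_dist: float  # µm
    sd_dist: float  # µm
    label: str


@dataclass
class ECDF:
    """Right-continuous empirical CDF of the COM distances."""

    x: np.ndarray  # sorted distances, µm
    y: np.ndarray  # cumulative fractions, 1/n ... 1

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.searchsorted(self.x, t, side="right") / len(self.x)


def com_distance_stats(positions) -> tuple[float, float]:
    """Mean and population SD of distances to the center of mass.

    The center of mass is the arithmetic mean of the positions; distances are
    Euclidean; the SD uses divisor n.
    """
    p = np.asarray(positions, dtype=float)
    if p.size == 0:
        raise ValueError("com_distance_stats requires at least one position")
    p = p.reshape(-1, 2)
    com = p.mean(axis=0)
    d = np.hypot(*(p - com).T)
    return float(d.mean()), float(d.std(ddof=0))


def ecdf(distances) -> ECDF:
    d = np.sort(np.asarray(distances, dtype=float).ravel())
    if d.size == 0:
        raise ValueError("ecdf requires at least one distance")
    return ECDF(x=d, y=np.arange(1, d.size + 1) / d.size)


def classify_structure(mean_dist: float, sd_dist: float, cell_radius: float,
                       compact_frac: float = 0.2,
                       ring_rel_sd: float = 0.3) -> str:
    """Label (mean, SD) as compact, ring or dispersed.

    compact iff ``mean <= compact_frac * cell_radius`` (default 0.2·R);
    otherwise ring iff ``sd <= ring_rel_sd * mean`` (default 0.3); otherwise
    dispersed.  The thresholds are configuration: they separate the three
    canonical patterns (tight blob / jittered ring / uniform disc) cleanly
    but are not themselves measured quantities.
    """
    if mean_dist < 0 or sd_dist < 0 or cell_radius <= 0:
        raise ValueError("inputs must be non-negative, cell_radius positive")
    if mean_dist <= compact_frac * cell_radius:
        return COMPACT
    if sd_dist <= ring_rel_sd * mean_dist:
        return RING
    return DISPERSED


def summarize_positions(positions, cell_radius: float, scenario: str = "",
                        seed: int = 0, **thresholds) -> StructureSummary:
    mean_d, sd_d = com_distance_stats(positions)
    return StructureSummary(
        scenario=scenario, seed=seed,
        n_points=int(np.asarray(positions).reshape(-1, 2).shape[0]),
        mean_dist=mean_d, sd_dist=sd_d,
        label=classify_structure(mean_d, sd_d, cell_radius, **thresholds))


def find_clustering_threshold(sweep: pd.DataFrame, criterion: float = 0.8,
                              direction: str = "ascending",
                              bistable_band: tuple[float, float] = (0.2, 0.8)):
    """Locate the parameter value where clustering becomes robust.

    ``sweep`` is a long-format table with columns ``value`` (the swept
    parameter) and ``label`` (per-replicate class).  Returns
    ``(threshold, table)`` where ``threshold`` is the smallest (ascending) or
    largest (descending) grid value whose compact fraction meets
    ``criterion`` (None if never met), and ``table`` has one row per grid
    point with its compact fraction and a ``bistable`` flag for fractions
    strictly inside ``bistable_band``.
    """
    required = {"value", "label"}
    if not required.issubset(sweep.columns):
        raise KeyError(f"sweep table needs columns {sorted(required)}, "
                       f"got {list(sweep.columns)}")
    per_point = (sweep.assign(compact=lambda t: t["label"] == COMPACT)
                 .groupby("value", sort=True)["compact"].mean()
                 .rename("compact_fraction").reset_index())
    lo, hi = bistable_band
    per_point["bistable"] = per_point["compact_fraction"].between(
        lo, hi, inclusive="neither")
    met = per_point[per_point["compact_fraction"] >= criterion]["value"]
    if met.empty:
        return None, per_point
    thr = met.min() if direction == "ascending" else met.max()
    return thr, per_point


# ---------------------------------------------------------------------------
# smallest enclosing circle (Welzl's algorithm, exact)


def _circle_two(a, b):
    c = (a + b) / 2.0
    return c, float(np.hypot(*(a - c)))


def _circle_three(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.hypot(*(a - center)))


def _in_circle(circle, p, eps=1e-9) -> bool:
    c, r = circle
    return np.hypot(*(p - c)) <= r + eps


def min_enclosing_circle(points) -> tuple[np.ndarray, float]:
    """Exact smallest enclosing circle: returns ``(center, diameter)``.

    Welzl's move-to-front algorithm, iterative form, O(n) expected after an
    initial deterministic shuffle (seeded, so results are reproducible).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("min_enclosing_circle requires at least one point")
    pts = pts[np.random.default_rng(0).permutation(pts.shape[0])]
    c = (pts[0].copy(), 0.0)
    for i in range(1, len(pts)):
        if _in_circle(c, pts[i]):
            continue
        c = (pts[i].copy(), 0.0)
        for j in range(i):
            if _in_circle(c, pts[j]):
                continue
            c = _circle_two(pts[i], pts[j])
            for m in range(j):
                if _in_circle(c, pts[m]):
                    continue
                cc = _circle_three(pts[i], pts[j], pts[m])
                if cc is not None:
                    c = cc
    return c[0], 2.0 * c[1]
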