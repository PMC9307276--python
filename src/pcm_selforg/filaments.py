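"""Microtubules as discretized elastic rods with dynamic instability.

A filament is an ordered polyline (index 0 = minus end) with near-uniform
segment lengths; the last segment carries the fractional remainder so the tip
can grow and shrink continuously.  Dynamic instability follows the classical
two-state model without rescue: a growing tip elongates at
``v_grow * exp(-load/F_grow)`` (antagonistic load only), undergoes catastrophe
at rate ``k_cat`` and then shrinks at ``v_shrink`` until the filament is
removed; growth stops (but catastrophe continues) at the hard cap ``L_max``.

Bending elasticity uses the linearized discrete rod: for near-uniform
segments the bending force is ``-kappa/seg**3`` times the squared
second-difference operator applied to the vertex positions, which conserves
linear and angular momentum exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import FiberParams

__all__ = [
    "Filament",
    "NucleationSite",
    "OccupancyError",
    "nucleate",
    "update_dynamic_instability",
    "bending_forces",
    "bending_energy",
    "bending_matrix",
    "closest_point",
    "point_at_abscissa",
    "simulate_growth_episodes",
]

GROWING = "growing"
SHRINKING = "shrinking"
PAUSED_AT_CAP = "paused_at_cap"


class OccupancyError(RuntimeError):
    """An active nucleation site can host at most one filament at a time."""


@dataclass
class NucleationSite:
    """A microtubule nucleation site on a bead or at a fixed world position.

    Bead-hosted sites launch filaments in a uniformly random direction;
    immobile seeds have a fixed position and a fixed launch orientation.
    """

    host_bead: Optional[int] = None  # bead id, or None for an immobile seed
    local_offset: tuple = (0.0, 0.0)  # attachment point relative to bead center
    position: tuple = (0.0, 0.0)  # world position (seeds) / last known (beads)
    orientation: Optional[float] = None  # radians; fixed for immobile seeds
    active: bool = True
    current_filament: Optional[int] = None


@dataclass
class Filament:
    """Discretized microtubule; vertex 0 is the minus end."""

    vertices: np.ndarray  # (n, 2) positions, µm
    rest_segment_length: float  # µm, interior segments
    last_rest: float  # µm, rest length of the final (tip) segment
    dynamic_state: str = GROWING
    rigidity: float = 20.0  # pN·µm²
    minus_anchor: Optional[NucleationSite] = None
    owner: Optional[int] = None  # complex id, or None
    alive: bool = True

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def rest_length(self) -> float:
        """Total rest length: interior segments plus the fractional tip."""
        return (self.n_vertices - 2) * self.rest_segment_length + self.last_rest

    @property
    def length(self) -> float:
        """Actual polyline length (equals rest length up to enforcement error)."""
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    def tip_direction(self) -> np.ndarray:
        d = self.vertices[-1] - self.vertices[-2]
        n = np.hypot(*d)
        return d / n if n > 0 else np.array([1.0, 0.0])


def nucleate(site: NucleationSite, rng: np.random.Generator,
             fiber: FiberParams, owner: Optional[int] = None) -> Filament:
    """Create a fresh filament of one segment length at the site.

    The minus end coincides with the site; the initial direction is the
    site's fixed orientation for immobile seeds, or uniform-random for
    bead-hosted sites.  Raises :class:`OccupancyError` if the site already
    hosts a filament.
    """
    if not site.active:
        raise OccupancyError("cannot nucleate on an inactive site")
    if site.current_filament is not None:
        raise OccupancyError("site already hosts a filament")
    if site.orientation is not None and site.host_bead is None:
        theta = site.orientation
    else:
        theta = rng.uniform(0.0, 2.0 * np.pi)
    p0 = np.asarray(site.position, dtype=float)
    direction = np.array([np.cos(theta), np.sin(theta)])
    seg = fiber.segment_length
    f = Filament(
        vertices=np.vstack([p0, p0 + seg * direction]),
        rest_segment_length=seg,
        last_rest=seg,
        dynamic_state=GROWING,
        rigidity=fiber.rigidity,
        minus_anchor=site,
        owner=owner,
    )
    site.current_filament = id(f)
    return f


def update_dynamic_instability(f: Filament, tip_load: float,
                               fiber: FiberParams, dt: float,
                               rng: np.random.Generator) -> Filament:
    """Advance the plus-end state of one filament by one time step.

    ``tip_load`` is the antagonistic (growth-opposing) force component in pN,
    >= 0.  Growth: the tip advances by ``v_grow*exp(-tip_load/F_grow)*dt``;
    a catastrophe switches to shrinking with probability ``1-exp(-k_cat*dt)``
    (also while paused at the cap).  Shrinking removes ``v_shrink*dt`` of
    length; once the rest length falls to ``L_min`` the filament dies
    (``alive = False``) and its site is vacated for immediate renucleation on
    the next step.  Rescues never occur.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if tip_load < 0:
        raise ValueError("tip_load is the antagonistic component, >= 0")
    if not f.alive:
        return f

    if f.dynamic_state in (GROWING, PAUSED_AT_CAP):
        if rng.random() < -np.expm1(-fiber.k_cat * dt):
            f.dynamic_state = SHRINKING
        elif f.dynamic_state == GROWING:
            delta = fiber.v_grow * np.exp(-tip_load / fiber.F_grow) * dt
            room = fiber.L_max - f.rest_length
            if delta >= room:
                delta = max(room, 0.0)
                f.dynamic_state = PAUSED_AT_CAP
            _extend_tip(f, delta)

    if f.dynamic_state == SHRINKING:
        _retract_tip(f, fiber.v_shrink * dt)
        if f.rest_length <= fiber.L_min:
            f.alive = False
            if f.minus_anchor is not None:
                f.minus_anchor.current_filament = None
    return f


def _extend_tip(f: Filament, delta: float) -> None:
    if delta <= 0:
        return
    seg = f.rest_segment_length
    t = f.tip_direction()
    f.vertices = f.vertices.copy()
    f.vertices[-1] = f.vertices[-1] + delta * t
    f.last_rest += delta
    while f.last_rest > seg:
        # the tip segment outgrew one discretization unit: split it
        new_interior = f.vertices[-2] + seg * t
        f.vertices = np.vstack([f.vertices[:-1], new_interior, f.vertices[-1]])
        f.last_rest -= seg


def _retract_tip(f: Filament, delta: float) -> None:
    seg = f.rest_segment_length
    while delta > 0 and f.n_vertices >= 2:
        if delta < f.last_rest or f.n_vertices == 2:
            t = f.tip_direction()
            f.vertices = f.vertices.copy()
            f.vertices[-1] = f.vertices[-1] - min(delta, f.last_rest) * t
            f.last_rest -= delta
            return
        delta -= f.last_rest
        f.vertices = f.vertices[:-1]
        f.last_rest = seg


# ---------------------------------------------------------------------------
# Elasticity


def bending_matrix(n: int) -> np.ndarray:
    """The (n, n) squared second-difference operator D = AᵀA.

    ``bending force = -(rigidity / seg³) · D @ vertices`` applied separately
    to each coordinate.  Zero for n < 3.
    """
    if n < 3:
        return np.zeros((n, n))
    A = np.zeros((n - 2, n))
    for i in range(n - 2):
        A[i, i:i + 3] = (1.0, -2.0, 1.0)
    return A.T @ A


def bending_forces(f: Filament) -> np.ndarray:
    """Linearized elastic-rod bending forces on the vertices (n, 2) in pN.

    Net force and net torque are exactly zero (the discrete energy is
    invariant under rigid motions).  A 2-vertex filament has no curvature
    and returns zeros.
    """
    n = f.n_vertices
    if n < 3:
        return np.zeros((n, 2))
    k = f.rigidity / f.rest_segment_length ** 3
    return -k * bending_matrix(n) @ f.vertices


def bending_energy(f: Filament) -> float:
    """Discrete bending energy kappa/(2·seg³) · Σ|Δ²x|² in pN·µm."""
    if f.n_vertices < 3:
        return 0.0
    d2 = np.diff(f.vertices, n=2, axis=0)
    return f.rigidity / (2.0 * f.rest_segment_length ** 3) * float(np.sum(d2 ** 2))


# ---------------------------------------------------------------------------
# Geometry


def closest_point(f: Filament, x) -> tuple[float, float]:
    """Closest point of the polyline to ``x``: returns (abscissa, distance).

    The abscissa is measured along the actual polyline from the minus end;
    ties break toward the smaller abscissa.
    """
    x = np.asarray(x, dtype=float)
    p = f.vertices
    a, b = p[:-1], p[1:]
    ab = b - a
    seg_len = np.hypot(ab[:, 0], ab[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(seg_len > 0,
                     ((x - a) * ab).sum(axis=1) / np.maximum(seg_len, 1e-300) ** 2,
                     0.0)
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    dist = np.hypot(*(proj - x).T)
    i = int(np.argmin(dist))  # first minimum -> smaller abscissa on ties
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    return float(cum[i] + t[i] * seg_len[i]), float(dist[i])


def point_at_abscissa(f: Filament, s: float) -> np.ndarray:
    """Linear interpolation along the polyline, s in [0, length] from minus end."""
    seg_len = np.hypot(*np.diff(f.vertices, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if s < -1e-9 or s > total + 1e-9:
        raise ValueError(f"abscissa {s} outside [0, {total}]")
    s = min(max(s, 0.0), total)
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg_len) - 1)
    t = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
    return f.vertices[i] + t * (f.vertices[i + 1] - f.vertices[i])


# ---------------------------------------------------------------------------
# Ensemble helper (shares the tip kinetics with update_dynamic_instability)


def simulate_growth_episodes(fiber: FiberParams, dt: float, n: int,
                             rng: np.random.Generator, cap: bool = True,
                             max_steps: int = 2_000_000):
    """Simulate ``n`` independent growth episodes from zero length until
    catastrophe; returns ``(lengths_at_catastrophe, waiting_times)``.

    Uses the same per-step law as :func:`update_dynamic_instability`
    (geometric catastrophe sampling, load-free growth), vectorized across
    episodes; with ``cap=False`` the length cap is disabled so the
    length-at-catastrophe distribution is exponential with mean
    ``v_grow / k_cat``.
    """
    length = np.zeros(n)
    t_cat = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)
    p_cat = -np.expm1(-fiber.k_cat * dt)
    step = 0
    while active.any() and step < max_steps:
        step += 1
        hit = active & (rng.random(n) < p_cat)
        t_cat[hit] = step * dt
        active &= ~hit
        grow = length[active] + fiber.v_grow * dt
        if cap:
            grow = np.minimum(grow, fiber.L_max)
        length[active] = grow
    return length[~np.isnan(t_cat)], t_cat[~np.isnan(t_cat)]
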