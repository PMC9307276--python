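"""Overdamped Langevin mechanics: drag, confinement, sterics, Euler–Maruyama.

The cell is a 2D projection of a 3D system, so translational drag keeps its
3D Stokes form 6πηr.  All interactions with the cell boundary are harmonic
(inward radial spring once an object's surface crosses the boundary), and the
only steric interactions are bead–bead and object–boundary.

Functions here are pure and operate on scalars or numpy arrays; the vectorized
time-stepping over whole populations lives in :mod:`pcm_selforg.engine`, which
composes these laws.
"""

from __future__ import annotations

import numpy as np

from .config import WorldParams

__all__ = [
    "drag_coefficient",
    "confinement_force",
    "steric_force_pair",
    "langevin_displacement",
    "NumericInstabilityError",
]


class NumericInstabilityError(RuntimeError):
    """A force or position became non-finite (time step too large or
    stiffness too high for the explicit part of the integrator)."""


def drag_coefficient(radius: float, viscosity: float) -> float:
    """Stokes translational drag 6πηr in pN·s/µm.

    Raises ``ValueError`` for non-positive radius or viscosity.
    """
    if not radius > 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if not viscosity > 0:
        raise ValueError(f"viscosity must be positive, got {viscosity}")
    return 6.0 * np.pi * viscosity * radius


def confinement_force(position, object_radius: float, world: WorldParams):
    """Inward radial harmonic force confining an object to the cell.

    Zero while ``|x| + object_radius <= cell_radius``; otherwise magnitude
    ``confinement_stiffness * (|x| + object_radius - cell_radius)`` pointing
    toward the cell center.  ``position`` may be one point ``(2,)`` or an
    array ``(n, 2)``.
    """
    x = np.asarray(position, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    r = np.hypot(x[:, 0], x[:, 1])
    overlap = np.maximum(0.0, r + object_radius - world.cell_radius)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[:, None] > 0, x / np.maximum(r, 1e-300)[:, None], 0.0)
    f = -world.confinement_stiffness * overlap[:, None] * unit
    return f[0] if single else f


def steric_force_pair(pos_i, pos_j, radius_i: float, radius_j: float,
                      stiffness: float, rng: np.random.Generator | None = None):
    """Harmonic contact repulsion between two beads.

    Returns ``(f_i, f_j)`` with ``f_i + f_j = 0``.  Zero unless the beads
    overlap (center distance < sum of radii).  Coincident centers are pushed
    apart along a direction drawn from ``rng`` (a deterministic draw given
    the generator state) with full-overlap magnitude.
    """
    pi = np.asarray(pos_i, dtype=float)
    pj = np.asarray(pos_j, dtype=float)
    d_vec = pi - pj
    d = float(np.hypot(*d_vec))
    contact = radius_i + radius_j
    if d >= contact:
        z = np.zeros(2)
        return z, z.copy()
    if d == 0.0:
        if rng is None:
            rng = np.random.default_rng(0)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        unit = np.array([np.cos(theta), np.sin(theta)])
        f = stiffness * contact * unit
    else:
        f = stiffness * (contact - d) * (d_vec / d)
    return f, -f


def langevin_displacement(force, drag, kT: float, dt: float,
                          rng: np.random.Generator):
    """Euler–Maruyama displacement for overdamped degrees of freedom.

    ``Δx = (F/γ)·dt + sqrt(2·kT·dt/γ)·N(0,1)`` per component.  ``force`` has
    shape ``(..., 2)``, ``drag`` broadcasts against ``(...)``.
    """
    force = np.asarray(force, dtype=float)
    drag = np.asarray(drag, dtype=float)[..., None]
    drift = force / drag * dt
    if kT > 0:
        noise = np.sqrt(2.0 * kT * dt / drag) * rng.standard_normal(force.shape)
    else:
        noise = 0.0
    out = drift + noise
    if not np.all(np.isfinite(out)):
        bad = np.argwhere(~np.isfinite(out))
        raise NumericInstabilityError(
            f"non-finite displacement for degree(s) of freedom {bad[:5].tolist()}; "
            "dt too large or stiffness too high")
    return out
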