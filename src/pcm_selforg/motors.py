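"""Binding elements: walking motor hands and passive adhesive couples.

A *hand* is a point-like binding element carried by a bead at a fixed
attachment point.  Motor hands (dynein, kinesin-14) bind microtubules within
their binding range, walk toward the minus end with a linear force–velocity
relation, unbind as a slip bond ``k_off = k_off0 * exp(F/F_d)`` and detach
when they reach the minus end.  Adhesive hands bind the 10-nm adhesive stubs
carried by other complexes and never step.  A bound hand is connected to its
target by a zero-rest-length Hookean spring (the universal 100 pN/µm link).

A complex's own filaments and stubs are excluded as binding targets: dynein
transports a complex along microtubules grown from *other* complexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .config import AdhesionParams, MotorSpecies, WorldParams
from .filaments import Filament, closest_point, point_at_abscissa

__all__ = [
    "Hand",
    "AdhesiveStub",
    "try_bind",
    "link_force",
    "motor_velocity",
    "unbinding_rate",
    "update_bound_motor",
]

FREE = "free"
BOUND = "bound"


@dataclass
class AdhesiveStub:
    """A 10-nm passive target element rigidly carried by its host bead."""

    host_bead: int
    local_offset: tuple = (0.0, 0.0)
    base: tuple = (0.0, 0.0)  # world position of the attachment point
    direction: tuple = (1.0, 0.0)  # unit orientation, follows the host
    length: float = 0.01  # µm, fixed

    def point_at(self, s: float) -> np.ndarray:
        s = min(max(s, 0.0), self.length)
        return np.asarray(self.base, float) + s * np.asarray(self.direction, float)

    def closest_point(self, x) -> tuple[float, float]:
        x = np.asarray(x, float)
        b = np.asarray(self.base, float)
        d = np.asarray(self.direction, float)
        s = float(np.clip(np.dot(x - b, d), 0.0, self.length))
        return s, float(np.hypot(*(b + s * d - x)))


@dataclass
class Hand:
    """A motor or adhesive binding element with its kinetic state."""

    species: Union[MotorSpecies, AdhesionParams]
    host_bead: int = 0
    host_complex: int = 0
    anchor: tuple = (0.0, 0.0)  # world position of the attachment point
    state: str = FREE
    target: Optional[object] = None  # Filament or AdhesiveStub
    abscissa: float = 0.0  # µm along the target from its minus end / base

    @property
    def is_motor(self) -> bool:
        return isinstance(self.species, MotorSpecies)

    @property
    def k_on(self) -> float:
        return self.species.k_on if self.is_motor else self.species.hand_k_on

    @property
    def binding_range(self) -> float:
        return (self.species.binding_range if self.is_motor
                else self.species.hand_range)


def _target_owner(target) -> Optional[int]:
    if isinstance(target, Filament):
        return target.owner
    return getattr(target, "host_complex", getattr(target, "host_bead", None))


def try_bind(h: Hand, candidates: Sequence[object], dt: float,
             rng: np.random.Generator,
             own_complex_targets: Optional[set] = None) -> Hand:
    """One binding attempt: bind the nearest in-range candidate with
    probability ``1 - exp(-k_on*dt)``.

    Motor hands consider filaments, adhesive hands consider stubs; targets
    belonging to the hand's own complex are excluded.  ``own_complex_targets``
    optionally lists target ids owned by the hand's complex (otherwise
    ownership is read off the target).  No candidate in range leaves the hand
    unchanged, and the random draw is still consumed only on an attempt with
    a candidate available.
    """
    if h.state != FREE:
        return h
    best = None
    best_s = 0.0
    best_d = np.inf
    for c in candidates:
        if own_complex_targets is not None and id(c) in own_complex_targets:
            continue
        owner = _target_owner(c)
        if owner is not None and owner == h.host_complex:
            continue
        if isinstance(c, Filament):
            if not h.is_motor or not c.alive:
                continue
            s, d = closest_point(c, h.anchor)
        elif isinstance(c, AdhesiveStub):
            if h.is_motor:
                continue
            s, d = c.closest_point(h.anchor)
        else:
            continue
        if d < best_d:
            best, best_s, best_d = c, s, d
    if best is None or best_d > h.binding_range:
        return h
    if rng.random() < -np.expm1(-h.k_on * dt):
        h.state = BOUND
        h.target = best
        h.abscissa = best_s
    return h


def _target_point(h: Hand) -> np.ndarray:
    if isinstance(h.target, Filament):
        return point_at_abscissa(h.target, h.abscissa)
    return h.target.point_at(h.abscissa)


def link_force(h: Hand, world: WorldParams):
    """Spring force of the bound link: ``(force_on_host, force_on_target)``.

    Zero-rest-length Hookean spring of ``world.link_stiffness`` between the
    hand's anchor and the attachment point on the target; the two returned
    forces are equal and opposite.  A free hand is a no-op returning zeros.
    """
    if h.state != BOUND:
        z = np.zeros(2)
        return z, z.copy()
    delta = _target_point(h) - np.asarray(h.anchor, float)
    f_on_host = world.link_stiffness * delta
    return f_on_host, -f_on_host


def motor_velocity(species: MotorSpecies, F_par: float) -> float:
    """Linear force–velocity toward the minus end, clamped to [0, v_0].

    ``F_par`` is the spring-force component along the local filament tangent,
    positive when it opposes minus-end-directed motion (negative = assisting,
    which does not speed the motor beyond ``v_0``).
    """
    v = species.v_0 * (1.0 - F_par / species.F_s)
    return float(min(max(v, 0.0), species.v_0))


def unbinding_rate(species, F: float) -> float:
    """Slip-bond unbinding rate ``k_off0 * exp(F/F_d)``, F = force magnitude."""
    if isinstance(species, MotorSpecies):
        k0, Fd = species.k_off0, species.F_d
    else:
        k0, Fd = species.hand_k_off0, species.hand_F_d
    return float(k0 * np.exp(F / Fd))


def update_bound_motor(h: Hand, dt: float, rng: np.random.Generator,
                       world: Optional[WorldParams] = None) -> Hand:
    """Advance a bound hand by one step: walk (motors only), then unbind.

    The motor moves its abscissa toward the minus end by
    ``motor_velocity(species, F_par)*dt`` and detaches on reaching abscissa
    <= 0 (minus-end release).  Both motor and adhesive hands unbind with
    probability ``1 - exp(-k_off(F)*dt)`` where ``F`` is the current link
    tension.  Adhesive hands do not step.
    """
    if h.state != BOUND:
        return h
    if world is None:
        world = WorldParams()
    f_on_host, _ = link_force(h, world)
    F_mag = float(np.hypot(*f_on_host))

    if h.is_motor and isinstance(h.target, Filament):
        # tangent at the motor position, pointing plus-ward
        fil = h.target
        seg_len = np.hypot(*np.diff(fil.vertices, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        i = min(int(np.searchsorted(cum, h.abscissa, side="right") - 1),
                len(seg_len) - 1)
        i = max(i, 0)
        tangent = fil.vertices[i + 1] - fil.vertices[i]
        norm = np.hypot(*tangent)
        tangent = tangent / norm if norm > 0 else np.array([1.0, 0.0])
        # force on the hand from the spring is -f_on_host; motion is minus-ward
        # (-tangent), so the antagonistic (opposing) component is the
        # projection of the spring force on +tangent.
        F_par = float(np.dot(-f_on_host, tangent))
        h.abscissa -= motor_velocity(h.species, F_par) * dt
        if h.abscissa <= 0.0:
            h.state = FREE
            h.target = None
            h.abscissa = 0.0
            return h

    if rng.random() < -np.expm1(-unbinding_rate(h.species, F_mag) * dt):
        h.state = FREE
        h.target = None
        h.abscissa = 0.0
    return h
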