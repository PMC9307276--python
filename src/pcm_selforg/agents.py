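"""Bead complexes and their placement in the cell.

A PCM complex is a 50-nm bead carrying one microtubule nucleation site and
one dynein; a CAMSAP-kin14 complex carries one nucleation site and five
kinesin-14 motors.  Adhesion adds stub/hand couples: one of each for weak
adhesion, or five random attachment points with five molecules each (25
stubs + 25 hands) for strong adhesion.  Attachment points are i.i.d. uniform
on the bead circle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .config import (AdhesionParams, ComplexSpec, DYNEIN, KIN14, MotorSpecies)
from .filaments import NucleationSite
from .motors import AdhesiveStub, Hand

__all__ = [
    "BeadComplex",
    "ImmobileSeed",
    "build_complex",
    "place_population",
]


@dataclass
class BeadComplex:
    """An assembled mobile complex: bead + sites + hands + adhesive units."""

    spec: ComplexSpec
    complex_id: int = 0
    position: np.ndarray = field(default_factory=lambda: np.zeros(2))
    nucleation_sites: list = field(default_factory=list)
    motor_hands: list = field(default_factory=list)
    adhesive_hands: list = field(default_factory=list)
    stubs: list = field(default_factory=list)


@dataclass
class ImmobileSeed:
    """A stationary nucleation site with fixed position and orientation."""

    position: np.ndarray
    orientation: float
    site: NucleationSite = None

    def __post_init__(self):
        if self.site is None:
            self.site = NucleationSite(
                host_bead=None, position=tuple(self.position),
                orientation=float(self.orientation), active=True)


def _surface_points(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return radius * np.column_stack([np.cos(theta), np.sin(theta)])


def build_complex(spec: ComplexSpec, rng: np.random.Generator,
                  adhesion: AdhesionParams | None = None,
                  dynein: MotorSpecies = DYNEIN,
                  kin14: MotorSpecies = KIN14,
                  complex_id: int = 0,
                  nucleating: bool | None = None) -> BeadComplex:
    """Assemble one complex from its spec with random attachment points.

    Weak adhesion gives 1 stub + 1 hand; strong adhesion places 5 molecules
    of each kind at each of 5 shared random attachment points (25 + 25).
    A non-nucleating complex carries its site(s) inactive.
    """
    if spec.kind not in ("PCM", "CAMSAP_KIN14"):
        raise ValueError(f"unknown complex kind {spec.kind!r}")
    if adhesion is None:
        adhesion = AdhesionParams()
    if nucleating is None:
        nucleating = spec.nucleating
    c = BeadComplex(spec=spec, complex_id=complex_id)

    for p in _surface_points(spec.n_nucleation_sites, spec.bead_radius, rng):
        c.nucleation_sites.append(NucleationSite(
            host_bead=complex_id, local_offset=tuple(p), active=bool(nucleating)))

    n_dyn = spec.n_dynein
    n_kin = spec.n_kin14
    for p in _surface_points(n_dyn, spec.bead_radius, rng):
        c.motor_hands.append(Hand(species=dynein, host_bead=complex_id,
                                  host_complex=complex_id, anchor=tuple(p)))
    for p in _surface_points(n_kin, spec.bead_radius, rng):
        c.motor_hands.append(Hand(species=kin14, host_bead=complex_id,
                                  host_complex=complex_id, anchor=tuple(p)))

    if spec.adhesion_level == "weak":
        points_stub = _surface_points(1, spec.bead_radius, rng)
        points_hand = _surface_points(1, spec.bead_radius, rng)
        per_point = 1
    elif spec.adhesion_level == "strong":
        shared = _surface_points(5, spec.bead_radius, rng)
        points_stub = points_hand = shared
        per_point = 5
    else:
        points_stub = points_hand = np.zeros((0, 2))
        per_point = 0
    for p in points_stub:
        unit = p / np.hypot(*p) if np.hypot(*p) > 0 else np.array([1.0, 0.0])
        for _ in range(per_point):
            c.stubs.append(AdhesiveStub(host_bead=complex_id,
                                        local_offset=tuple(p),
                                        direction=tuple(unit),
                                        length=adhesion.stub_length))
    for p in points_hand:
        for _ in range(per_point):
            c.adhesive_hands.append(Hand(species=adhesion, host_bead=complex_id,
                                         host_complex=complex_id,
                                         anchor=tuple(p)))
    return c


def place_population(count: int, mode: str, cell_radius: float,
                     rng: np.random.Generator,
                     annulus_width: float = 1.0) -> np.ndarray:
    """Random positions in the cell: returns (count, 2) array in µm.

    ``uniform_disc`` is area-uniform over the disc; ``peripheral_annulus`` is
    area-uniform over the 1 µm-broad (by default) annulus adjacent to the
    cell boundary.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if annulus_width > cell_radius:
        raise ValueError("annulus width exceeds the cell radius")
    if mode == "uniform_disc":
        r = cell_radius * np.sqrt(rng.random(count))
    elif mode == "peripheral_annulus":
        r_in = cell_radius - annulus_width
        # area-uniform over the annulus: r² uniform on [r_in², R²]
        r = np.sqrt(rng.uniform(r_in ** 2, cell_radius ** 2, size=count))
    else:
        raise ValueError(f"unknown placement mode {mode!r}")
    theta = rng.uniform(0.0, 2.0 * np.pi, size=count)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def place_without_overlap(count: int, mode: str, cell_radius: float,
                          bead_radius: float, rng: np.random.Generator,
                          annulus_width: float = 1.0,
                          max_attempts: int = 200) -> np.ndarray:
    """Placement with bead–bead overlap rejection by resampling.

    At a few hundred 50-nm beads in a 10-µm disc collisions are rare, so
    resampling terminates quickly; after ``max_attempts`` rounds remaining
    overlaps are accepted (they relax sterically within a few steps).
    """
    pos = place_population(count, mode, cell_radius, rng, annulus_width)
    for _ in range(max_attempts):
        if count < 2:
            break
        d = np.hypot(*(pos[:, None, :] - pos[None, :, :]).T).T
        np.fill_diagonal(d, np.inf)
        bad = np.where((d < 2 * bead_radius).any(axis=1))[0]
        if bad.size == 0:
            break
        pos[bad] = place_population(bad.size, mode, cell_radius, rng,
                                    annulus_width)
    return pos
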