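"""Scenario configuration: every model parameter, validation, presets, YAML/JSON I/O.

The model world is a two-dimensional circular cell (radius 10 µm by default)
containing mobile bead complexes that nucleate dynamic microtubules and carry
minus-end-directed motors, plus optional immobile nucleation seeds.  A scenario
is fully described by a :class:`ScenarioConfig`; named presets reproduce each
simulated system of the self-organization study (compact cluster, ring,
dispersed, mixed populations) and the systematic parameter sweeps around them.

Units throughout: µm, s, pN (so kT is in pN·µm, viscosity in pN·s/µm²).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Iterator

import yaml

__all__ = [
    "WorldParams",
    "MotorSpecies",
    "FiberParams",
    "AdhesionParams",
    "ComplexSpec",
    "ImmobileSeedSpec",
    "Population",
    "ScenarioConfig",
    "DYNEIN",
    "KIN14",
    "preset_scenario",
    "PRESET_NAMES",
    "validate",
    "to_yaml",
    "from_yaml",
    "to_dict",
    "from_dict",
    "UnknownPresetError",
]


class UnknownPresetError(ValueError):
    """Raised when a preset name is not recognised."""


@dataclass
class WorldParams:
    """Global physical parameters of the circular cell and the integrator.

    ``kT`` is 4.2 pN·nm = 0.0042 pN·µm (room temperature).  ``total_time``
    defaults to 1800 s (30 min of simulated time, after which the systems
    reach steady state); the 18,000 s variant used for some long runs is
    available by overriding this field.
    """

    cell_radius: float = 10.0  # µm
    viscosity: float = 1.0  # pN·s/µm²
    kT: float = 4.2e-3  # pN·µm
    dt: float = 0.01  # s
    total_time: float = 1800.0  # s
    link_stiffness: float = 100.0  # pN/µm, all linking elements
    confinement_stiffness: float = 100.0  # pN/µm (model choice, not measured)
    steric_stiffness: float = 100.0  # pN/µm (model choice, not measured)


@dataclass
class MotorSpecies:
    """Kinetic and mechanical parameters of one motor species.

    Both built-in species (dynein, kinesin-14) walk toward microtubule minus
    ends; the force–velocity relation is linear with stall force ``F_s`` and
    unbinding is slip-bond like, ``k_off = k_off0 * exp(F / F_d)``.
    """

    name: str
    direction: str = "minus_end"  # {"minus_end", "plus_end"}
    k_on: float = 5.0  # s⁻¹
    k_off0: float = 0.1  # s⁻¹, force-free unbinding
    F_d: float = 2.0  # pN, characteristic detachment force
    binding_range: float = 0.075  # µm
    v_0: float = 0.5  # µm/s, force-free speed
    F_s: float = 4.0  # pN, stall force


#: Cytoplasmic dynein: consensus single-molecule parameters.
DYNEIN = MotorSpecies(
    name="dynein", k_on=5.0, k_off0=0.1, F_d=2.0,
    binding_range=0.075, v_0=0.5, F_s=4.0,
)

#: Kinesin-14 parameterized with typical kinesin-1 values, minus-end directed.
KIN14 = MotorSpecies(
    name="kin14", k_on=1.0, k_off0=1.0, F_d=3.0,
    binding_range=0.075, v_0=0.8, F_s=7.0,
)


@dataclass
class FiberParams:
    """Microtubule parameters: dynamic instability without rescue, length cap.

    The catastrophe rate is tied to the target mean length by
    ``k_cat = v_grow / L_mean`` (0.13/5 = 0.026 s⁻¹); ``L_mean`` is
    documentation of that constraint, not an independent dial.
    """

    rigidity: float = 20.0  # pN·µm², flexural
    k_cat: float = 0.026  # s⁻¹
    v_grow: float = 0.13  # µm/s, force-free growth speed
    v_shrink: float = 0.272  # µm/s
    F_grow: float = 1.7  # pN, characteristic growing force
    L_max: float = 7.5  # µm, hard length cap
    rescue_rate: float = 0.0  # s⁻¹, rescues ignored
    L_mean: float = 5.0  # µm, mean length at catastrophe (defines k_cat)
    segment_length: float = 0.5  # µm, discretization
    L_min: float = 0.25  # µm, below this the filament is removed


@dataclass
class AdhesionParams:
    """Reversible stub/hand couple that makes complexes adhere to one another.

    A stub is a 10-nm passive target element rigidly carried by its bead; an
    adhesive hand on another bead binds it within ``hand_range`` and the bond
    is a slip bond with the parameters below.  These are effective values:
    the couple mimics an unspecific adhesive interaction, so the numbers are
    chosen in the range typical for motor–filament binding rather than
    measured for a specific molecule.
    """

    stub_length: float = 0.01  # µm
    hand_k_on: float = 10.0  # s⁻¹
    hand_range: float = 0.1  # µm
    hand_k_off0: float = 0.01  # s⁻¹
    hand_F_d: float = 3.0  # pN


@dataclass
class ComplexSpec:
    """Composition of one mobile bead complex.

    kind "PCM": 50-nm bead, one nucleation site, one dynein.
    kind "CAMSAP_KIN14": 50-nm bead, one nucleation site, five kinesin-14.
    ``adhesion_level``: "none", "weak" (1 stub + 1 hand) or "strong"
    (5 attachment points × 5 molecules = 25 stubs + 25 hands).
    """

    kind: str = "PCM"  # {"PCM", "CAMSAP_KIN14"}
    bead_radius: float = 0.05  # µm
    n_dynein: int = 1
    n_kin14: int = 0
    n_nucleation_sites: int = 1
    adhesion_level: str = "weak"  # {"none", "weak", "strong"}
    nucleating: bool = True

    @staticmethod
    def pcm(adhesion_level: str = "weak", nucleating: bool = True,
            n_nucleation_sites: int = 1) -> "ComplexSpec":
        return ComplexSpec(kind="PCM", n_dynein=1, n_kin14=0,
                           n_nucleation_sites=n_nucleation_sites,
                           adhesion_level=adhesion_level, nucleating=nucleating)

    @staticmethod
    def camsap_kin14(adhesion_level: str = "none",
                     nucleating: bool = True) -> "ComplexSpec":
        return ComplexSpec(kind="CAMSAP_KIN14", n_dynein=0, n_kin14=5,
                           adhesion_level=adhesion_level, nucleating=nucleating)


@dataclass
class Population:
    """A homogeneous population of complexes placed uniformly in the cell."""

    spec: ComplexSpec
    count: int
    fraction_nucleating: float = 1.0


@dataclass
class ImmobileSeedSpec:
    """Stationary nucleation sites (e.g. stabilized minus ends pinned in place).

    ``placement`` is "uniform" (area-uniform over the disc) or "peripheral"
    (area-uniform over a 1 µm-broad annulus adjacent to the cell boundary);
    ``peripheral_fraction`` mixes the two placements.
    """

    count: int = 0
    placement: str = "uniform"  # {"uniform", "peripheral"}
    peripheral_fraction: float = 0.0
    annulus_width: float = 1.0  # µm


@dataclass
class ScenarioConfig:
    """One fully parameterized simulated system."""

    world: WorldParams = field(default_factory=WorldParams)
    fiber: FiberParams = field(default_factory=FiberParams)
    species: list = field(default_factory=lambda: [
        dataclasses.replace(DYNEIN), dataclasses.replace(KIN14)])
    adhesion: AdhesionParams = field(default_factory=AdhesionParams)
    populations: list = field(default_factory=list)
    immobile_seeds: ImmobileSeedSpec = field(default_factory=ImmobileSeedSpec)
    seed: int = 0
    snapshot_interval: float = 10.0  # s of simulated time
    name: str = "custom"

    def motor(self, name: str) -> MotorSpecies:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Validation


def _positive(violations, obj, names, prefix):
    for n in names:
        v = getattr(obj, n)
        if not (isinstance(v, (int, float)) and v > 0):
            violations.append(f"{prefix}.{n}: must be strictly positive, got {v!r}")


def validate(config: ScenarioConfig) -> list[str]:
    """Check every type invariant; returns a list of human-readable violations.

    An empty list means the configuration is valid.  Violations are data,
    not exceptions, so a caller can collect and report all of them at once.
    """
    v: list[str] = []
    w = config.world
    _positive(v, w, ["cell_radius", "viscosity", "dt", "total_time",
                     "link_stiffness", "confinement_stiffness",
                     "steric_stiffness"], "world")
    # kT = 0 is allowed: noise-free runs are used to test the deterministic
    # part of the integrator
    if not (isinstance(w.kT, (int, float)) and w.kT >= 0):
        v.append(f"world.kT: must be non-negative, got {w.kT!r}")
    if isinstance(w.dt, (int, float)) and isinstance(w.total_time, (int, float)) \
            and w.dt > 0 and w.dt > w.total_time:
        v.append(f"world.dt: dt ({w.dt}) must not exceed total_time ({w.total_time})")

    f = config.fiber
    _positive(v, f, ["rigidity", "k_cat", "v_grow", "v_shrink", "F_grow",
                     "L_max", "L_mean", "segment_length", "L_min"], "fiber")
    if f.rescue_rate != 0:
        v.append(f"fiber.rescue_rate: rescues are not modelled, must be 0, got {f.rescue_rate}")
    if f.L_mean > 0 and abs(f.k_cat - f.v_grow / f.L_mean) > 1e-9 * abs(f.k_cat):
        v.append(
            f"fiber.k_cat: must equal v_grow/L_mean = {f.v_grow / f.L_mean!r}, "
            f"got {f.k_cat!r}")
    if not (0 < f.L_min < f.segment_length < f.L_max):
        v.append("fiber.L_min: requires 0 < L_min < segment_length < L_max, "
                 f"got L_min={f.L_min}, segment_length={f.segment_length}, "
                 f"L_max={f.L_max}")

    for sp in config.species:
        if sp.direction not in ("minus_end", "plus_end"):
            v.append(f"species[{sp.name}].direction: unknown {sp.direction!r}")
        _positive(v, sp, ["k_on", "k_off0", "F_d", "binding_range", "v_0", "F_s"],
                  f"species[{sp.name}]")

    a = config.adhesion
    _positive(v, a, ["stub_length", "hand_k_on", "hand_range", "hand_k_off0",
                     "hand_F_d"], "adhesion")

    for i, pop in enumerate(config.populations):
        s = pop.spec
        if s.kind not in ("PCM", "CAMSAP_KIN14"):
            v.append(f"populations[{i}].spec.kind: unknown {s.kind!r}")
        if not s.bead_radius > 0:
            v.append(f"populations[{i}].spec.bead_radius: must be positive")
        if s.adhesion_level not in ("none", "weak", "strong"):
            v.append(f"populations[{i}].spec.adhesion_level: unknown {s.adhesion_level!r}")
        if s.kind == "PCM" and (s.n_dynein != 1 or s.n_kin14 != 0):
            v.append(f"populations[{i}].spec: PCM carries exactly one dynein "
                     f"and no kin14, got n_dynein={s.n_dynein}, n_kin14={s.n_kin14}")
        if s.kind == "CAMSAP_KIN14" and (s.n_kin14 != 5 or s.n_dynein != 0):
            v.append(f"populations[{i}].spec: CAMSAP_KIN14 carries exactly five "
                     f"kin14 and no dynein, got n_kin14={s.n_kin14}, "
                     f"n_dynein={s.n_dynein}")
        if s.n_nucleation_sites < 1:
            v.append(f"populations[{i}].spec.n_nucleation_sites: must be >= 1")
        if pop.count < 0:
            v.append(f"populations[{i}].count: must be >= 0")
        if not 0.0 <= pop.fraction_nucleating <= 1.0:
            v.append(f"populations[{i}].fraction_nucleating: must lie in [0, 1]")

    seeds = config.immobile_seeds
    if seeds.count < 0:
        v.append("immobile_seeds.count: must be >= 0")
    if seeds.placement not in ("uniform", "peripheral"):
        v.append(f"immobile_seeds.placement: unknown {seeds.placement!r}")
    if not 0.0 <= seeds.peripheral_fraction <= 1.0:
        v.append("immobile_seeds.peripheral_fraction: must lie in [0, 1]")
    if seeds.placement == "peripheral" and seeds.annulus_width != 1.0:
        v.append("immobile_seeds.annulus_width: peripheral placement uses a "
                 f"1 µm annulus, got {seeds.annulus_width}")
    if isinstance(w.cell_radius, (int, float)) and seeds.annulus_width > w.cell_radius:
        v.append("immobile_seeds.annulus_width: exceeds the cell radius")

    if config.snapshot_interval <= 0:
        v.append("snapshot_interval: must be strictly positive")
    return v


# ---------------------------------------------------------------------------
# Presets

PRESET_NAMES = (
    "fig8A", "fig8B", "fig8C", "fig8D", "fig8G", "fig8H", "fig8I", "fig8J",
    "sweep_n_pcm", "sweep_n_immobile", "sweep_n_nucleators",
    "sweep_mt_per_complex", "sweep_peripheral", "sweep_mixed_fraction",
)


def preset_scenario(name: str) -> ScenarioConfig:
    """Build the named simulated system.

    The eight ``fig8*`` presets are the systems of the self-organization
    study: 300 weakly adhesive PCM complexes (A, compact cluster), the same
    without adhesion (B, ring), A plus 300 immobile random dynamic
    microtubules with only 50/300 complexes nucleating (C, dispersed), C with
    strong adhesion (D, compact again), 300 CAMSAP-kin14 complexes without
    (G, ring) and with (H, compact) adhesion, and the 150+150 mixed systems
    with adhesive (I, compact) or non-adhesive (J, ring) PCM.  The ``sweep_*``
    presets are the base configurations the systematic parameter sweeps
    modify.
    """
    base = ScenarioConfig(name=name)
    if name == "fig8A":
        base.populations = [Population(ComplexSpec.pcm("weak"), 300)]
    elif name == "fig8B":
        base.populations = [Population(ComplexSpec.pcm("none"), 300)]
    elif name in ("fig8C", "fig8D"):
        level = "weak" if name == "fig8C" else "strong"
        base.populations = [
            Population(ComplexSpec.pcm(level), 300, fraction_nucleating=50 / 300)]
        base.immobile_seeds = ImmobileSeedSpec(count=300, placement="uniform")
    elif name == "fig8G":
        base.populations = [Population(ComplexSpec.camsap_kin14("none"), 300)]
    elif name == "fig8H":
        base.populations = [Population(ComplexSpec.camsap_kin14("weak"), 300)]
    elif name in ("fig8I", "fig8J"):
        level = "weak" if name == "fig8I" else "none"
        base.populations = [
            Population(ComplexSpec.camsap_kin14("none"), 150),
            Population(ComplexSpec.pcm(level), 150),
        ]
    elif name in ("sweep_n_pcm", "sweep_mt_per_complex"):
        base.populations = [Population(ComplexSpec.pcm("weak"), 300)]
    elif name in ("sweep_n_immobile", "sweep_n_nucleators"):
        base.populations = [
            Population(ComplexSpec.pcm("weak"), 300, fraction_nucleating=50 / 300)]
        base.immobile_seeds = ImmobileSeedSpec(count=300, placement="uniform")
    elif name == "sweep_peripheral":
        base.populations = [
            Population(ComplexSpec.pcm("weak"), 300, fraction_nucleating=50 / 300)]
        base.immobile_seeds = ImmobileSeedSpec(
            count=300, placement="peripheral", peripheral_fraction=1.0)
    elif name == "sweep_mixed_fraction":
        base.populations = [
            Population(ComplexSpec.camsap_kin14("none"), 150),
            Population(ComplexSpec.pcm("weak"), 150),
        ]
    else:
        raise UnknownPresetError(
            f"unrecognized preset {name!r}; known presets: {', '.join(PRESET_NAMES)}")
    return base


# ---------------------------------------------------------------------------
# Serialization (YAML canonical; JSON accepted)


def to_dict(config: ScenarioConfig) -> dict[str, Any]:
    return dataclasses.asdict(config)


def from_dict(d: dict[str, Any]) -> ScenarioConfig:
    d = dict(d)
    d["world"] = WorldParams(**d.get("world", {}))
    d["fiber"] = FiberParams(**d.get("fiber", {}))
    d["species"] = [MotorSpecies(**s) for s in d.get("species", [])]
    d["adhesion"] = AdhesionParams(**d.get("adhesion", {}))
    d["populations"] = [
        Population(spec=ComplexSpec(**p["spec"]), count=p["count"],
                   fraction_nucleating=p.get("fraction_nucleating", 1.0))
        for p in d.get("populations", [])]
    d["immobile_seeds"] = ImmobileSeedSpec(**d.get("immobile_seeds", {}))
    return ScenarioConfig(**d)


def to_yaml(config: ScenarioConfig) -> str:
    return yaml.safe_dump(to_dict(config), sort_keys=False)


def from_yaml(text: str) -> ScenarioConfig:
    """Parse a scenario from YAML (JSON, being a YAML subset, also parses)."""
    try:
        d = json.loads(text)
    except json.JSONDecodeError:
        d = yaml.safe_load(text)
    return from_dict(d)


def sweep_grid(name: str) -> Iterator[tuple[str, Any]]:
    """Default grid for each named sweep, as (parameter label, value) pairs."""
    grids = {
        "sweep_n_pcm": ("n_pcm", [50, 100, 150, 200, 250, 300]),
        "sweep_n_immobile": ("n_immobile", [50, 100, 150, 200, 250, 300]),
        "sweep_n_nucleators": ("n_nucleators", [50, 100, 150, 300]),
        "sweep_mt_per_complex": ("mt_per_complex", [1, 2, 3]),
        "sweep_peripheral": ("peripheral_fraction", [0.0, 0.25, 0.5, 0.75, 1.0]),
        "sweep_mixed_fraction": ("adhesive_fraction", [0.0, 0.25, 0.5, 0.75, 1.0]),
    }
    if name not in grids:
        raise UnknownPresetError(f"unrecognized sweep {name!r}")
    label, values = grids[name]
    return ((label, v) for v in values)
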