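"""Run scenarios, replicate batches, and parameter sweeps; persist results.

Each simulated system is run to its configured total time and summarized
from the *last* frame by the center-of-mass distance statistics.  Every
system is replicated (10 times by default) with consecutive seeds.  Sweeps
run a full factorial over a parameter grid and are resumable: existing rows
in the output table are skipped.

Trajectories are recorded as snapshot frames (complex positions and filament
polylines) at ``snapshot_interval`` and can be written to HDF5 or to a plain
chunked CSV (columns: frame, time_s, agent_id, kind, x_um, y_um).
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import (Population, ScenarioConfig, preset_scenario, to_yaml,
                     validate)
from .engine import Engine
from .mechanics import NumericInstabilityError
from .metrics import StructureSummary, summarize_positions

__all__ = [
    "Frame",
    "Trajectory",
    "run_scenario",
    "run_replicates",
    "run_sweep",
    "scaled_config",
    "sweep_config",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "trajectory_to_hdf5",
    "trajectory_from_hdf5",
    "summaries_to_frame",
]

log = logging.getLogger("pcm_selforg")


@dataclass
class Frame:
    time: float
    complex_positions: np.ndarray  # (B, 2)
    complex_kinds: np.ndarray  # (B,) 0 = PCM, 1 = CAMSAP_KIN14
    filaments: list  # list of (n_i, 2) polylines


@dataclass
class Trajectory:
    scenario: str
    seed: int
    cell_radius: float
    frames: list = field(default_factory=list)
    aborted: bool = False

    @property
    def final(self) -> Frame:
        return self.frames[-1]

    def summary(self, **thresholds) -> StructureSummary:
        f = self.final
        return summarize_positions(
            f.complex_positions, self.cell_radius,
            scenario=self.scenario, seed=self.seed, **thresholds)


def _snapshot(eng: Engine) -> Frame:
    return Frame(
        time=eng.time,
        complex_positions=eng.complex_positions(),
        complex_kinds=eng.bead_kind.copy(),
        filaments=eng.filament_polylines(),
    )


def run_scenario(config: ScenarioConfig, seed: Optional[int] = None,
                 record_frames: bool = True) -> Trajectory:
    """Run one scenario to ``total_time``; deterministic given (config, seed).

    On numeric instability the last valid frame is kept and the trajectory is
    flagged ``aborted`` instead of losing the run.
    """
    problems = validate(config)
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))
    use_seed = config.seed if seed is None else seed
    eng = Engine(config, seed=use_seed)
    traj = Trajectory(scenario=config.name, seed=use_seed,
                      cell_radius=config.world.cell_radius)
    cfg_hash = hashlib.sha1(to_yaml(config).encode()).hexdigest()[:10]
    log.info("run scenario=%s seed=%d config=%s n_complexes=%d "
             "total_time=%.0fs", config.name, use_seed, cfg_hash,
             eng.n_beads, config.world.total_time)

    def cb(e: Engine):
        traj.frames.append(_snapshot(e))

    try:
        eng.run(snapshot_callback=cb if record_frames else None)
        if not record_frames:
            traj.frames.append(_snapshot(eng))
    except NumericInstabilityError as err:
        log.error("aborting run %s seed %d: %s", config.name, use_seed, err)
        traj.aborted = True
        traj.frames.append(_snapshot(eng))
    return traj


def run_replicates(config: ScenarioConfig, n: int = 10, base_seed: int = 0,
                   record_frames: bool = False) -> list[StructureSummary]:
    """Replicate a scenario with seeds ``base_seed .. base_seed+n-1``.

    Returns one final-frame summary per replicate; an aborted replicate is
    flagged by scenario name suffix ``!aborted`` rather than dropped.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for i in range(n):
        traj = run_scenario(config, seed=base_seed + i,
                            record_frames=record_frames)
        s = traj.summary()
        if traj.aborted:
            s = dataclasses.replace(s, scenario=s.scenario + "!aborted")
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# scenario transforms


def scaled_config(config: ScenarioConfig, radius_scale: float = 0.5,
                  count_scale: float = 0.25, time_scale: float = 1.0 / 3.0,
                  dt: Optional[float] = None,
                  scale_fibers: bool = False) -> ScenarioConfig:
    """Desk-scale variant of a scenario for fast testing.

    Multiplies the cell radius, agent counts and duration by the given
    factors (the defaults map the full systems, 10 µm / 300 complexes /
    1800 s, to 5 µm / 75 complexes / 600 s) and optionally coarsens dt.
    Microtubule parameters are left untouched by default; with
    ``scale_fibers=True`` the mean length and cap scale with the cell radius
    (and ``k_cat`` is re-derived from ``k_cat = v_grow / L_mean``), which
    preserves the filament-to-cell length ratios but changes filament
    turnover.  The scenario name is tagged ``@scaled`` so scaled results
    cannot be confused with full-scale ones.
    """
    c = copy.deepcopy(config)
    c.world.cell_radius *= radius_scale
    c.world.total_time *= time_scale
    if dt is not None:
        c.world.dt = dt
    if scale_fibers:
        c.fiber.L_max *= radius_scale
        c.fiber.L_mean *= radius_scale
        c.fiber.k_cat = c.fiber.v_grow / c.fiber.L_mean
    for pop in c.populations:
        pop.count = int(np.floor(pop.count * count_scale + 0.5))
    c.immobile_seeds.count = int(
        np.floor(c.immobile_seeds.count * count_scale + 0.5))
    c.name = config.name + "@scaled"
    return c


def sweep_config(sweep_name: str, param: str, value) -> ScenarioConfig:
    """Instantiate one grid point of a named sweep."""
    c = preset_scenario(sweep_name)
    if param == "n_pcm":
        c.populations[0].count = int(value)
    elif param == "n_immobile":
        c.immobile_seeds.count = int(value)
    elif param == "n_nucleators":
        c.populations[0].fraction_nucleating = value / c.populations[0].count
    elif param == "mt_per_complex":
        c.populations[0].spec.n_nucleation_sites = int(value)
    elif param == "peripheral_fraction":
        c.immobile_seeds.peripheral_fraction = float(value)
    elif param == "adhesive_fraction":
        total = sum(p.count for p in c.populations)
        n_pcm = int(np.floor(total * float(value) + 0.5))
        c.populations = [
            Population(c.populations[0].spec, total - n_pcm),
            Population(c.populations[1].spec, n_pcm),
        ]
    else:
        raise ValueError(f"unknown sweep parameter {param!r}")
    c.name = f"{sweep_name}[{param}={value}]"
    return c


def run_sweep(sweep_name: str, grid, n_rep: int = 10, base_seed: int = 0,
              out_csv: Optional[str | Path] = None,
              config_transform=None) -> pd.DataFrame:
    """Full factorial over ``grid`` (sequence of (param, value)) × replicates.

    Returns a long-format table with one row per (grid point, replicate):
    ``scenario, seed, param, value, n_points, mean_dist_um, sd_dist_um,
    label``.  If ``out_csv`` exists its rows are reused (the sweep is
    resumable); new rows are appended and written back.
    ``config_transform`` lets callers rescale each grid-point configuration
    (e.g. :func:`scaled_config`) before running.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    done = pd.DataFrame()
    if out_csv is not None and Path(out_csv).exists():
        done = pd.read_csv(out_csv)
    rows = [] if done.empty else done.to_dict("records")
    have = {(r["param"], r["value"], r["seed"]) for r in rows}
    for param, value in grid:
        cfg = sweep_config(sweep_name, param, value)
        if config_transform is not None:
            cfg = config_transform(cfg)
        for i in range(n_rep):
            seed = base_seed + i
            if (param, value, seed) in have:
                continue
            s = run_scenario(cfg, seed=seed, record_frames=False).summary()
            rows.append(dict(scenario=cfg.name, seed=seed, param=param,
                             value=value, n_points=s.n_points,
                             mean_dist_um=s.mean_dist, sd_dist_um=s.sd_dist,
                             label=s.label))
            if out_csv is not None:
                pd.DataFrame(rows).to_csv(out_csv, index=False)
    return pd.DataFrame(rows)


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


# ---------------------------------------------------------------------------
# trajectory serialization


def _traj_rows(traj: Trajectory):
    for fi, fr in enumerate(traj.frames):
        for bi, (x, y) in enumerate(fr.complex_positions):
            yield fi, fr.time, f"bead{bi}", int(fr.complex_kinds[bi]), x, y
        for li, poly in enumerate(fr.filaments):
            for vi, (x, y) in enumerate(poly):
                yield fi, fr.time, f"fil{li}v{vi}", 2, x, y


def trajectory_to_csv(traj: Trajectory, path: str | Path) -> None:
    df = pd.DataFrame(_traj_rows(traj),
                      columns=["frame", "time_s", "agent_id", "kind",
                               "x_um", "y_um"])
    with open(path, "w") as fh:
        fh.write(f"# scenario={traj.scenario} seed={traj.seed} "
                 f"cell_radius_um={traj.cell_radius}\n")
        df.to_csv(fh, index=False)


def trajectory_from_csv(path: str | Path) -> Trajectory:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(fh)
    traj = Trajectory(scenario=meta["scenario"], seed=int(meta["seed"]),
                      cell_radius=float(meta["cell_radius_um"]))
    for fi, g in df.groupby("frame", sort=True):
        beads = g[g["agent_id"].str.startswith("bead")]
        beads = beads.assign(_i=beads["agent_id"].str[4:].astype(int)).sort_values("_i")
        fils = []
        gf = g[g["agent_id"].str.startswith("fil")]
        if not gf.empty:
            ids = gf["agent_id"].str.extract(r"fil(\d+)v(\d+)").astype(int)
            gf = gf.assign(_f=ids[0].values, _v=ids[1].values)
            for _, poly in gf.groupby("_f", sort=True):
                poly = poly.sort_values("_v")
                fils.append(poly[["x_um", "y_um"]].to_numpy())
        traj.frames.append(Frame(
            time=float(g["time_s"].iloc[0]),
            complex_positions=beads[["x_um", "y_um"]].to_numpy(),
            complex_kinds=beads["kind"].to_numpy(),
            filaments=fils))
    return traj


def trajectory_to_hdf5(traj: Trajectory, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["scenario"] = traj.scenario
        f.attrs["seed"] = traj.seed
        f.attrs["cell_radius_um"] = traj.cell_radius
        for i, fr in enumerate(traj.frames):
            g = f.create_group(f"frame{i:05d}")
            g.attrs["time_s"] = fr.time
            g.create_dataset("complex_positions", data=fr.complex_positions)
            g.create_dataset("complex_kinds", data=fr.complex_kinds)
            fg = g.create_group("filaments")
            for j, poly in enumerate(fr.filaments):
                fg.create_dataset(f"{j:05d}", data=poly)


def trajectory_from_hdf5(path: str | Path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as f:
        traj = Trajectory(scenario=str(f.attrs["scenario"]),
                          seed=int(f.attrs["seed"]),
                          cell_radius=float(f.attrs["cell_radius_um"]))
        for name in sorted(f.keys()):
            g = f[name]
            traj.frames.append(Frame(
                time=float(g.attrs["time_s"]),
                complex_positions=g["complex_positions"][...],
                complex_kinds=g["complex_kinds"][...],
                filaments=[g["filaments"][k][...]
                           for k in sorted(g["filaments"].keys())]))
    return traj
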