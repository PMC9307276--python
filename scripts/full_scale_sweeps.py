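#!/usr/bin/env python
"""Full-scale parameter sweeps of the self-organization model.

This is the long batch (hours on one core): every sweep runs at the full
parameters — 10 µm cell, dt = 0.01 s, 1800 s, 10 replicates per grid point —
and appends to a resumable CSV per sweep, so an interrupted batch continues
where it stopped.  Post-processing reports, per sweep, the compact fraction
per grid point, bistable points, and the clustering threshold (smallest grid
value with compact fraction >= 0.8).

Usage:
    python scripts/full_scale_sweeps.py --out runs/sweeps [--seed 0]
        [--sweeps sweep_n_pcm sweep_n_immobile ...]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from pcm_selforg.config import sweep_grid
from pcm_selforg.metrics import find_clustering_threshold
from pcm_selforg.runner import run_sweep

ALL_SWEEPS = ["sweep_n_pcm", "sweep_n_immobile", "sweep_n_nucleators",
              "sweep_mt_per_complex", "sweep_peripheral",
              "sweep_mixed_fraction"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replicates", type=int, default=10)
    ap.add_argument("--sweeps", nargs="*", default=ALL_SWEEPS)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for name in args.sweeps:
        csv = args.out / f"{name}.csv"
        print(f"== {name} -> {csv}", flush=True)
        df = run_sweep(name, sweep_grid(name), n_rep=args.replicates,
                       base_seed=args.seed, out_csv=csv)
        thr, table = find_clustering_threshold(df)
        print(table.to_string(index=False), flush=True)
        print(f"{name}: clustering threshold (compact fraction >= 0.8): "
              f"{thr}", flush=True)


if __name__ == "__main__":
    main()
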