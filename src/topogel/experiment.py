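"""End-to-end experiment orchestration: build -> compress -> equilibrate ->
reconnection run -> topology analysis, with everything written to an output
directory (config copy, scalar series, snapshots, analysis tables, JSONL
event log)."""

from __future__ import annotations

import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .config import SimulationConfig
from .dynamics import (CompressionSchedule, IntegratorParams,
                       run_with_reconnection, compress)
from .model import ForceField, build_initial_ring, derived_densities
from .topology import analyze_frame

log = logging.getLogger("topogel")


class _EventLog:
    def __init__(self, path):
        self.path = Path(path)

    def emit(self, stage: str, **fields) -> None:
        rec = {"stage": stage, "wall_time": _time.time(), **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")
        log.info("%s %s", stage, fields)


def run_experiment(config: SimulationConfig | str, output_dir,
                   reconnect: bool = True, store_every: int = 1,
                   analyze: bool = True) -> Path:
    """Run the full protocol for one configuration; returns the output dir.

    Any stage failure propagates after the current state is dumped next to
    the log, so runs can be inspected and restarted.
    """
    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.from_file(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.txt")
    events = _EventLog(out / "events.jsonl")

    ff = ForceField(bending_k=config.stiffness)
    ip = IntegratorParams(timestep=config.timestep, seed=config.seed)
    dens = derived_densities(config)
    events.emit("setup", n_beads=config.n_beads, stiffness=config.stiffness,
                radius=config.sphere_radius, rho=dens.monomer_density,
                phi=dens.volume_fraction, seed=config.seed)

    stage = "build"
    state = None
    try:
        state = build_initial_ring(config)
        events.emit("build", initial_radius=state.box.radius)

        stage = "compress"
        schedule = CompressionSchedule(
            initial_radius=state.box.radius,
            final_radius=config.sphere_radius,
            compression_time=config.compression_time,
            post_equilibration_time=config.equilibration_time,
        )
        state = compress(state, schedule, ff, ip)
        events.emit("compress", final_radius=config.sphere_radius,
                    time=state.time)

        stage = "production"
        record = run_with_reconnection(
            state, config, ff, ip, reconnect=reconnect, store_snapshots=True
        )
        tio.write_series(record, out / "series.csv")
        snap_dir = out / "snapshots"
        snap_dir.mkdir(exist_ok=True)
        for k, snap in enumerate(record.snapshots):
            if snap is not None and k % store_every == 0:
                tio.write_xyz_bonds(snap, snap_dir / f"frame_{k:05d}.xyz")
        events.emit("production", samples=len(record.times),
                    attempts=record.attempts[-1], accepts=record.accepts[-1],
                    kappa_r=record.kappa_r[-1])

        if analyze:
            stage = "analysis"
            rows = []
            for t, snap in zip(record.times, record.snapshots):
                if snap is None:
                    continue
                res = analyze_frame(snap)
                rows.append(
                    {
                        "time": t,
                        "n_rings": res["n_rings"],
                        "mean_length": res["mean_length"],
                        "n_linked_pairs": res["n_linked_pairs"],
                        "total_abs_lk": res["total_abs_lk"],
                        "largest_cluster_fraction":
                            res["largest_cluster_fraction"],
                        "single_cluster": res["single_cluster"],
                    }
                )
            pd.DataFrame(rows).to_csv(out / "topology.csv", index=False)
            events.emit("analysis", frames=len(rows))
    except Exception as exc:
        if state is not None:
            try:
                tio.write_xyz_bonds(state, out / "failed_state.xyz")
            except Exception:
                pass
        events.emit("failure", failed_stage=stage, error=repr(exc))
        raise
    events.emit("done")
    return out
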