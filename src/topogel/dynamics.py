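"""Langevin dynamics driver: stepping, slow compression, reconnection runs.

The heavy lifting happens in :mod:`topogel._kernels`; this module owns the
protocol logic (compression ramp, sampling schedule, seeding, bookkeeping)
and the :class:`TrajectoryRecord` container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .config import SimulationConfig
from .model import ForceField, SphericalWall, PeriodicBox, SystemState, _cycles

#: wall speeds above this (sigma per tau_B) are flagged as too fast to keep
#: the melt near equilibrium during compression
MAX_COMPRESSION_SPEED = 0.1


@dataclass(frozen=True)
class IntegratorParams:
    timestep: float = 0.001
    friction: float = 1.0     # gamma; 0 gives the NVE (velocity Verlet) limit
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")


@dataclass(frozen=True)
class CompressionSchedule:
    initial_radius: float
    final_radius: float
    compression_time: float
    post_equilibration_time: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_radius < self.final_radius:
            raise ValueError("initial_radius must be >= final_radius")


@dataclass
class TrajectoryRecord:
    """Scalar time series plus per-frame ring data of one run."""

    times: list = field(default_factory=list)
    n_rings: list = field(default_factory=list)
    ring_lengths: list = field(default_factory=list)   # int arrays, one/frame
    kinetic_temperature: list = field(default_factory=list)
    attempts: list = field(default_factory=list)       # cumulative
    accepts: list = field(default_factory=list)        # cumulative
    kappa_r: list = field(default_factory=list)        # trailing-window rate
    snapshots: list = field(default_factory=list)      # SystemState or None
    final_state: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_rings": self.n_rings,
                "mean_length": [np.mean(l) for l in self.ring_lengths],
                "kinetic_temperature": self.kinetic_temperature,
                "attempts": self.attempts,
                "accepts": self.accepts,
                "kappa_r": self.kappa_r,
            }
        )


def _chunk_seed(seed: int, label: int, index: int) -> int:
    """Deterministic 31-bit seed for one kernel block.

    Separate ``label`` values give independent substreams (compression,
    equilibration, production, escape) from one master seed.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, label, index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


#: noise sub-blocks are capped at this many gaussian deviates (memory bound)
_NOISE_BUDGET = 3_000_000


def advance_arrays(pos, vel, nb, n_real, n_steps, ip: IntegratorParams,
                   ff: ForceField, *, seed: int, use_wall: bool = False,
                   wall_r: float = 0.0, wall_rate: float = 0.0,
                   box: float = 0.0, reconnect: bool = False,
                   rc: float = 1.3, min_ring: int = 3,
                   bending_k: float | None = None,
                   stats: np.ndarray | None = None) -> None:
    """Advance raw arrays by n_steps; thermostat noise comes from numpy.

    Splits the run into sub-blocks so the pre-drawn gaussian noise stays
    within a fixed memory budget; each sub-block gets its own derived seeds
    for the noise stream and the sweep stream.
    """
    if stats is None:
        stats = np.zeros(2, dtype=np.int64)
    kbend = ff.bending_k if bending_k is None else bending_k
    max_sub = max(int(_NOISE_BUDGET / max(3 * n_real, 1)), 1)
    done = 0
    sub = 0
    empty = np.zeros((1, 1, 3))
    while done < n_steps:
        n = min(max_sub, n_steps - done)
        ss = np.random.SeedSequence([seed, sub])
        noise_seed, sweep_seed = (int(s) & 0x7FFFFFFF
                                  for s in ss.generate_state(2))
        if ip.friction > 0.0:
            noise = np.random.Generator(
                np.random.PCG64(noise_seed)
            ).standard_normal((n, n_real, 3))
        else:
            noise = empty
        st = _kernels.run_block(
            pos, vel, nb, n_real, n, ip.timestep, ip.friction,
            ip.temperature, kbend, ff.fene_k, ff.fene_r0, use_wall,
            wall_r + wall_rate * done * ip.timestep, wall_rate, box,
            reconnect, rc, min_ring, sweep_seed, noise, stats,
        )
        if st > 0:
            raise FloatingPointError(
                f"FENE bond at bead {st - 1} overextended"
            )
        if st == -1:
            raise RuntimeError(
                "pair list overflow; system unphysically dense"
            )
        done += n
        sub += 1


def _run_raw(state: SystemState, ff: ForceField, ip: IntegratorParams,
             n_steps: int, *, seed: int, reconnect: bool = False,
             rc: float = 1.3, min_ring: int = 3, wall_rate: float = 0.0,
             stats: np.ndarray | None = None) -> None:
    """Advance ``state`` in place by n_steps kernel steps."""
    use_wall = isinstance(state.box, SphericalWall)
    box = state.box.length if isinstance(state.box, PeriodicBox) else 0.0
    wall_r = state.box.radius if use_wall else 0.0
    nb = state.neighbor_array()
    n_real = state.n_beads
    advance_arrays(
        state.positions, state.velocities, nb, n_real, n_steps, ip, ff,
        seed=seed, use_wall=use_wall, wall_r=wall_r, wall_rate=wall_rate,
        box=box, reconnect=reconnect, rc=rc, min_ring=min_ring, stats=stats,
    )
    if not np.isfinite(state.positions).all():
        bad = int(np.where(~np.isfinite(state.positions).all(axis=1))[0][0])
        raise FloatingPointError(f"non-finite coordinate at bead {bad}")
    state.bonds = SystemState.from_neighbor_array(
        state.positions, state.velocities, nb
    ).bonds
    state.time += n_steps * ip.timestep
    if use_wall and wall_rate != 0.0:
        state.box = SphericalWall(wall_r + wall_rate * n_steps * ip.timestep)


def step(state: SystemState, ff: ForceField, ip: IntegratorParams,
         seed: int | None = None) -> SystemState:
    """One velocity-Verlet/Langevin step; returns a new state.

    The bond graph is untouched.  At friction 0 this is plain velocity
    Verlet (symplectic, energy-conserving to O(dt^2)).
    """
    new = state.copy()
    _run_raw(new, ff, ip, 1, seed=ip.seed if seed is None else seed)
    return new


def run(state: SystemState, ff: ForceField, ip: IntegratorParams,
        duration: float, *, seed_label: int = 1, chunk_time: float = 10.0
        ) -> SystemState:
    """Plain equilibration for ``duration`` tau_B (no reconnection)."""
    new = state.copy()
    n_chunk = max(int(round(chunk_time / ip.timestep)), 1)
    total = int(round(duration / ip.timestep))
    i = 0
    done = 0
    while done < total:
        n = min(n_chunk, total - done)
        _run_raw(new, ff, ip, n, seed=_chunk_seed(ip.seed, seed_label, i))
        done += n
        i += 1
    return new


def compress(state: SystemState, schedule: CompressionSchedule,
             ff: ForceField, ip: IntegratorParams) -> SystemState:
    """Linearly shrink the wall to the final radius, then equilibrate.

    The ring is born in a large sphere that is slowly compressed; a runtime check warns when the wall moves faster
    than MAX_COMPRESSION_SPEED.
    """
    if not isinstance(state.box, SphericalWall):
        raise ValueError("compress requires a spherical wall")
    r = np.linalg.norm(state.positions, axis=1).max()
    if r > schedule.initial_radius:
        raise ValueError("beads outside the initial radius")
    new = state.copy()
    new.box = SphericalWall(schedule.initial_radius)
    if schedule.compression_time > 0 and \
            schedule.initial_radius > schedule.final_radius:
        rate = (schedule.final_radius - schedule.initial_radius) \
            / schedule.compression_time
        if abs(rate) > MAX_COMPRESSION_SPEED:
            warnings.warn(
                f"compression speed {abs(rate):.3f} sigma/tau_B exceeds "
                f"{MAX_COMPRESSION_SPEED}; melt may fall out of equilibrium",
                stacklevel=2,
            )
        n_chunk = max(int(round(10.0 / ip.timestep)), 1)
        total = int(round(schedule.compression_time / ip.timestep))
        done = 0
        i = 0
        while done < total:
            n = min(n_chunk, total - done)
            _run_raw(new, ff, ip, n, seed=_chunk_seed(ip.seed, 2, i),
                     wall_rate=rate)
            done += n
            i += 1
        new.box = SphericalWall(schedule.final_radius)   # exact endpoint
    if schedule.post_equilibration_time > 0:
        new2 = run(new, ff, ip, schedule.post_equilibration_time,
                   seed_label=3)
        new = new2
    rmax = np.linalg.norm(new.positions, axis=1).max()
    if rmax > schedule.final_radius + 0.5:
        raise FloatingPointError(
            f"bead escaped the wall during compression (|r|={rmax:.2f})"
        )
    return new


def run_with_reconnection(state: SystemState, config: SimulationConfig,
                          ff: ForceField, ip: IntegratorParams,
                          reconnect: bool = True,
                          store_snapshots: bool = False,
                          kappa_window: float = 100.0) -> TrajectoryRecord:
    """Production run: one reconnection sweep after every integration step.

    Snapshots and scalar series are recorded every ``config.sample_interval``
    tau_B (the first sample is the initial state).  kappa_r is the accepted
    swap rate over a trailing window (default 100 tau_B).
    """
    n_chunk = config.sample_interval / ip.timestep
    if abs(n_chunk - round(n_chunk)) > 1e-9:
        raise ValueError("sample_interval must be a multiple of the timestep")
    n_chunk = int(round(n_chunk))
    n_samples = int(round(config.run_length / config.sample_interval))

    new = state.copy()
    t0 = new.time
    rec = TrajectoryRecord()
    stats = np.zeros(2, dtype=np.int64)

    def record(snap_time):
        nb = new.neighbor_array()
        lengths = np.array([len(c) for c in _cycles(nb)], dtype=np.int64)
        if lengths.sum() != new.n_beads:
            raise AssertionError("ring lengths do not sum to the bead count")
        rec.times.append(snap_time)
        rec.n_rings.append(len(lengths))
        rec.ring_lengths.append(lengths)
        v2 = float((new.velocities ** 2).sum() / (3 * new.n_beads))
        rec.kinetic_temperature.append(v2)
        rec.attempts.append(int(stats[0]))
        rec.accepts.append(int(stats[1]))
        # trailing-window rate (whole run when shorter than the window)
        base = None
        for told, aold in zip(rec.times, rec.accepts):
            if snap_time - told >= kappa_window - 1e-9:
                base = (told, aold)
        if base is None and rec.times:
            base = (rec.times[0], rec.accepts[0])
        if base is not None and snap_time > base[0]:
            k = (int(stats[1]) - base[1]) / (snap_time - base[0])
        else:
            k = 0.0
        rec.kappa_r.append(k)
        rec.snapshots.append(new.copy() if store_snapshots else None)

    record(t0)
    for i in range(n_samples):
        _run_raw(new, ff, ip, n_chunk, seed=_chunk_seed(ip.seed, 4, i),
                 reconnect=reconnect, rc=config.reconnection_cutoff,
                 min_ring=config.min_ring_length, stats=stats)
        new.time = t0 + (i + 1) * config.sample_interval   # exact grid
        record(new.time)
    rec.final_state = new
    return rec
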