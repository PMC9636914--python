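"""Simulation configuration and its flat key=value file format.

All quantities are in reduced Kremer–Grest units: bead diameter sigma = 1,
thermal energy kBT = 1, bead mass m = 1, friction gamma = 1, so the Brownian
time tau_B (time for a bead to diffuse its own size) equals one reduced time
unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields


@dataclass
class SimulationConfig:
    """Parameters of one reconnecting-ring simulation.

    Attributes
    ----------
    n_beads:
        Total number of beads N; conserved by every reconnection move.
    stiffness:
        Bending constant K of the Kratky-Porod potential, in kBT. K is
        proportional to the persistence length (default mapping lp = K sigma).
    sphere_radius:
        Radius R of the confining sphere after compression, in sigma.
    reconnection_cutoff:
        Maximum 3D distance rc between the two designated swap ends of a
        candidate bond pair, in sigma.
    timestep:
        Integrator timestep in tau_B.
    sample_interval:
        Time between trajectory snapshots, in tau_B.
    seed:
        Master seed; all thermostat noise, sweep ordering and analysis
        randomness derive from it through named substreams.
    run_length:
        Production run length (after equilibration), in tau_B.
    min_ring_length:
        Smallest cycle the bond graph may contain.  A cycle needs at least
        3 beads to have defined bending angles; reconnections that would
        produce shorter cycles are rejected outright.
    compression_time:
        Duration of the linear wall-radius ramp, in tau_B.
    equilibration_time:
        Time at fixed final radius before reconnection is switched on.
    bond_length:
        Target spacing of consecutive beads in the initial ring.
    """

    n_beads: int
    stiffness: float = 0.0
    sphere_radius: float = 7.0
    reconnection_cutoff: float = 1.3
    timestep: float = 0.001
    sample_interval: float = 100.0
    seed: int = 0
    run_length: float = 1000.0
    min_ring_length: int = 3
    compression_time: float = 1000.0
    equilibration_time: float = 100.0
    bond_length: float = 0.97

    def __post_init__(self) -> None:
        if self.n_beads < self.min_ring_length:
            raise ValueError(
                f"n_beads={self.n_beads} smaller than "
                f"min_ring_length={self.min_ring_length}"
            )
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if not 0 < self.timestep <= 0.01:
            raise ValueError("timestep must lie in (0, 0.01] tau_B")
        if self.reconnection_cutoff > 2.0:
            # rc beyond twice the bead diameter makes "proximal" swaps
            # nonlocal; legal but suspicious.
            warnings.warn(
                f"reconnection_cutoff={self.reconnection_cutoff} sigma is "
                "large compared with the bead diameter",
                stacklevel=2,
            )

    # -- flat key=value file format ------------------------------------
    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                kind = known[key]
                if kind in ("int", int):
                    kwargs[key] = int(val)
                else:
                    kwargs[key] = float(val)
        return cls(**kwargs)
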