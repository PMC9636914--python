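"""Readers and writers for snapshots and time-series tables.

Two snapshot dialects are supported, both plain text:

* an XYZ-with-bonds file: a standard XYZ block followed by a ``Bonds``
  section listing one bead pair per line;
* a LAMMPS-data-style file (atoms + bonds + velocities sections) for
  interoperability with common visualization and analysis tools.

Round trips are exact for topology and to full float precision for
coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import PeriodicBox, SphericalWall, SystemState


def _box_tag(box) -> str:
    if isinstance(box, SphericalWall):
        return f"sphere:{float(box.radius)!r}"
    if isinstance(box, PeriodicBox):
        return f"pbc:{float(box.length)!r}"
    return "none"


def _parse_box(tag: str):
    if tag == "none":
        return None
    kind, val = tag.split(":")
    if kind == "sphere":
        return SphericalWall(float(val))
    if kind == "pbc":
        return PeriodicBox(float(val))
    raise ValueError(f"unknown box tag {tag!r}")


# ---------------------------------------------------------------------------
# XYZ with bonds
# ---------------------------------------------------------------------------

def write_xyz_bonds(state: SystemState, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{state.n_beads}\n")
        fh.write(f"time={state.time!r} box={_box_tag(state.box)}\n")
        for p, v in zip(state.positions, state.velocities):
            fh.write(
                "C "
                + " ".join(repr(float(x)) for x in p)
                + " "
                + " ".join(repr(float(x)) for x in v)
                + "\n"
            )
        fh.write("Bonds\n")
        for i, j in sorted(state.bonds):
            fh.write(f"{i} {j}\n")


def read_xyz_bonds(path) -> SystemState:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    n = int(lines[0])
    meta = dict(item.split("=", 1) for item in lines[1].split())
    pos = np.empty((n, 3))
    vel = np.zeros((n, 3))
    for i in range(n):
        parts = lines[2 + i].split()
        pos[i] = [float(x) for x in parts[1:4]]
        if len(parts) >= 7:
            vel[i] = [float(x) for x in parts[4:7]]
    if lines[2 + n].strip() != "Bonds":
        raise ValueError("missing Bonds section")
    bonds = set()
    for line in lines[3 + n:]:
        if not line.strip():
            continue
        i, j = (int(x) for x in line.split())
        bonds.add((min(i, j), max(i, j)))
    return SystemState(
        pos, vel, bonds, float(meta.get("time", 0.0)),
        _parse_box(meta.get("box", "none")),
    )


# ---------------------------------------------------------------------------
# LAMMPS-data dialect
# ---------------------------------------------------------------------------

def write_lammps_data(state: SystemState, path) -> None:
    pos = state.positions
    if isinstance(state.box, PeriodicBox):
        lo, hi = 0.0, state.box.length
    else:
        pad = 2.0
        ext = np.abs(pos).max() + pad if len(pos) else pad
        if isinstance(state.box, SphericalWall):
            ext = state.box.radius + pad
        lo, hi = -ext, ext
    bonds = sorted(state.bonds)
    with open(path, "w") as fh:
        fh.write(f"ring melt snapshot (time={state.time!r}, "
                 f"box={_box_tag(state.box)})\n\n")
        fh.write(f"{state.n_beads} atoms\n{len(bonds)} bonds\n\n")
        fh.write("1 atom types\n1 bond types\n\n")
        for tag in ("x", "y", "z"):
            fh.write(f"{float(lo)!r} {float(hi)!r} {tag}lo {tag}hi\n")
        fh.write("\nMasses\n\n1 1.0\n\nAtoms # bond\n\n")
        for i, p in enumerate(pos):
            fh.write(f"{i + 1} 1 1 " + " ".join(repr(float(x)) for x in p) + "\n")
        fh.write("\nVelocities\n\n")
        for i, v in enumerate(state.velocities):
            fh.write(f"{i + 1} " + " ".join(repr(float(x)) for x in v) + "\n")
        fh.write("\nBonds\n\n")
        for k, (i, j) in enumerate(bonds):
            fh.write(f"{k + 1} 1 {i + 1} {j + 1}\n")


def read_lammps_data(path) -> SystemState:
    with open(path) as fh:
        lines = fh.read().splitlines()
    header = lines[0]
    time = 0.0
    box = None
    if "time=" in header:
        inner = header[header.index("(") + 1: header.rindex(")")]
        for item in inner.split(", "):
            key, val = item.split("=", 1)
            if key == "time":
                time = float(val)
            elif key == "box":
                box = _parse_box(val)
    n_atoms = n_bonds = 0
    for line in lines:
        s = line.strip()
        if s.endswith(" atoms"):
            n_atoms = int(s.split()[0])
        elif s.endswith(" bonds"):
            n_bonds = int(s.split()[0])
    pos = np.empty((n_atoms, 3))
    vel = np.zeros((n_atoms, 3))
    bonds = set()
    section = None
    for line in lines[1:]:
        s = line.strip()
        if not s:
            continue
        word = s.split("#")[0].strip()
        if word in ("Masses", "Atoms", "Velocities", "Bonds"):
            section = word
            continue
        if section == "Atoms":
            parts = s.split()
            idx = int(parts[0]) - 1
            pos[idx] = [float(x) for x in parts[3:6]]
        elif section == "Velocities":
            parts = s.split()
            idx = int(parts[0]) - 1
            vel[idx] = [float(x) for x in parts[1:4]]
        elif section == "Bonds":
            parts = s.split()
            i, j = int(parts[2]) - 1, int(parts[3]) - 1
            bonds.add((min(i, j), max(i, j)))
    if len(bonds) != n_bonds:
        raise ValueError("bond count mismatch in data file")
    return SystemState(pos, vel, bonds, time, box)


# ---------------------------------------------------------------------------
# dump-style trajectory frames (read-only interop format)
# ---------------------------------------------------------------------------

def write_dump(state: SystemState, path, timestep_index: int = 0) -> None:
    """LAMMPS-dump-style frame (id type x y z), appendable."""
    pos = state.positions
    if isinstance(state.box, PeriodicBox):
        lo, hi = 0.0, state.box.length
    elif isinstance(state.box, SphericalWall):
        lo, hi = -state.box.radius, state.box.radius
    else:
        lo, hi = float(pos.min()), float(pos.max())
    with open(path, "a") as fh:
        fh.write("ITEM: TIMESTEP\n")
        fh.write(f"{timestep_index}\n")
        fh.write("ITEM: NUMBER OF ATOMS\n")
        fh.write(f"{state.n_beads}\n")
        fh.write("ITEM: BOX BOUNDS pp pp pp\n")
        for _ in range(3):
            fh.write(f"{float(lo)!r} {float(hi)!r}\n")
        fh.write("ITEM: ATOMS id type x y z\n")
        for i, p in enumerate(pos):
            fh.write(f"{i + 1} 1 " + " ".join(repr(float(x)) for x in p) + "\n")


def write_series(record, path) -> None:
    record.to_frame().to_csv(path, index=False)


def read_series(path) -> pd.DataFrame:
    return pd.read_csv(path)
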