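"""Parametric curves of known topology and prebuilt multi-ring states.

These fixtures carry their ground truth with them (pairwise linking
numbers, knot determinants, link-network edges) so the topology kernels can
be validated at any discretization and under arbitrary rigid motions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SphericalWall, SystemState

FIXTURE_NAMES = (
    "circle",
    "unlinked_pair",
    "hopf",
    "solomon",
    "trefoil",
    "figure_eight",
    "chain3",
    "ring_melt_small",
)


@dataclass
class Fixture:
    name: str
    curves: list                 # list of (n, 3) arrays
    expected: dict               # ground truth facts


def _circle(n, radius=1.0, center=(0, 0, 0), normal="z"):
    t = 2 * np.pi * np.arange(n) / n
    if normal == "z":
        pts = np.column_stack(
            [radius * np.cos(t), radius * np.sin(t), np.zeros(n)]
        )
    elif normal == "y":
        pts = np.column_stack(
            [radius * np.cos(t), np.zeros(n), radius * np.sin(t)]
        )
    else:
        pts = np.column_stack(
            [np.zeros(n), radius * np.cos(t), radius * np.sin(t)]
        )
    return pts + np.asarray(center, dtype=float)


def _trefoil(n):
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack(
        [
            np.sin(t) + 2 * np.sin(2 * t),
            np.cos(t) - 2 * np.cos(2 * t),
            -np.sin(3 * t),
        ]
    )


def _figure_eight(n):
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack(
        [
            (2 + np.cos(2 * t)) * np.cos(3 * t),
            (2 + np.cos(2 * t)) * np.sin(3 * t),
            np.sin(4 * t),
        ]
    )


def _torus_link_component(n, phase, big_r=2.0, small_r=0.7):
    """One (1,2) component of the (2,4) torus link; the pair has |Lk| = 2."""
    t = 2 * np.pi * np.arange(n) / n
    w = 2 * t + phase
    return np.column_stack(
        [
            (big_r + small_r * np.cos(w)) * np.cos(t),
            (big_r + small_r * np.cos(w)) * np.sin(t),
            small_r * np.sin(w),
        ]
    )


def apply_rigid_motion(curve: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Random rotation + translation (topology-preserving)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    shift = rng.uniform(-5, 5, size=3)
    return curve @ rot.T + shift


def make_fixture(name: str, n_points: int = 64, seed: int = 0) -> Fixture:
    """Build a named fixture at the requested discretization."""
    if name == "circle":
        return Fixture(name, [_circle(n_points)], {"determinant": 1})
    if name == "unlinked_pair":
        curves = [_circle(n_points), _circle(n_points, center=(5, 0, 0))]
        return Fixture(name, curves, {"abs_lk": 0.0, "edges": set()})
    if name == "hopf":
        curves = [
            _circle(n_points),
            _circle(n_points, center=(1, 0, 0), normal="y"),
        ]
        return Fixture(name, curves, {"abs_lk": 1.0, "edges": {(0, 1)}})
    if name == "solomon":
        curves = [
            _torus_link_component(n_points, 0.0),
            _torus_link_component(n_points, np.pi),
        ]
        return Fixture(name, curves, {"abs_lk": 2.0, "edges": {(0, 1)}})
    if name == "trefoil":
        return Fixture(name, [_trefoil(n_points)], {"determinant": 3})
    if name == "figure_eight":
        return Fixture(name, [_figure_eight(n_points)], {"determinant": 5})
    if name == "chain3":
        curves = [
            _circle(n_points),
            _circle(n_points, center=(1.2, 0, 0), normal="y"),
            _circle(n_points, center=(2.4, 0, 0)),
        ]
        return Fixture(
            name, curves,
            {"edges": {(0, 1), (1, 2)}, "n_linked_pairs": 2, "n_clusters": 1},
        )
    if name == "ring_melt_small":
        state = ring_melt_state(n_rings=3, ring_length=12, seed=seed)
        rings = []
        off = 0
        for _ in range(3):
            rings.append(state.positions[off: off + 12])
            off += 12
        return Fixture(name, rings, {"n_rings": 3, "state": state})
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def ring_melt_state(n_rings: int = 3, ring_length: int = 12,
                    seed: int = 0, bond_length: float = 0.97) -> SystemState:
    """A small multi-ring melt: separated circular rings in a loose sphere."""
    rng = np.random.default_rng(seed)
    radius = ring_length * bond_length / (2 * np.pi)
    centers = []
    gap = 2 * radius + 1.5
    for k in range(n_rings):
        centers.append(np.array([(k - (n_rings - 1) / 2) * gap, 0.0, 0.0]))
    pts = []
    bonds = set()
    off = 0
    for c in centers:
        ring = _circle(ring_length, radius=radius, center=c)
        pts.append(ring)
        for i in range(ring_length):
            a = off + i
            b = off + (i + 1) % ring_length
            bonds.add((min(a, b), max(a, b)))
        off += ring_length
    pos = np.vstack(pts)
    vel = rng.normal(size=pos.shape)
    vel -= vel.mean(axis=0)
    wall = np.linalg.norm(pos, axis=1).max() + 2.0
    state = SystemState(pos, vel, bonds, 0.0, SphericalWall(wall))
    state.validate()
    return state
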