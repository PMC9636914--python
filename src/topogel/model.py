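"""Physical state and force field of the confined bead-spring ring melt.

The model is the standard Kremer-Grest bead-spring polymer: purely repulsive
(WCA) excluded volume between *all* bead pairs, FENE springs along the chain,
a Kratky-Porod bending penalty K(1 - cos theta) per bond angle, and a
purely repulsive WCA-form wall acting on the distance to the inner surface of
the confining sphere.  Because the WCA term applies to bonded pairs as well,
rewiring bonds changes only FENE and bending energies -- the property the
reconnection move relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .config import SimulationConfig

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class SphericalWall:
    radius: float


@dataclass(frozen=True)
class PeriodicBox:
    length: float


@dataclass(frozen=True)
class ForceField:
    """Force-field parameters in reduced units (sigma = epsilon = kBT = 1)."""

    wca_epsilon: float = 1.0
    wca_sigma: float = 1.0
    fene_k: float = 30.0
    fene_r0: float = 1.5
    bending_k: float = 0.0
    wall_epsilon: float = 1.0

    def __post_init__(self) -> None:
        for name in ("wca_epsilon", "wca_sigma", "fene_k", "fene_r0", "wall_epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bending_k < 0:
            raise ValueError("bending_k must be non-negative")


def persistence_length(stiffness: float) -> float:
    """Persistence length lp(K) in sigma.

    The bending constant is proportional to the persistence length; the
    default mapping is the large-K limit of the discrete worm-like chain,
    lp = K sigma.  Replace this function (or pass explicit lp values to the
    theory module) to explore other conventions.
    """
    return float(stiffness)


@dataclass
class SystemState:
    """Positions, velocities and bond graph of every bead at one instant.

    The bond graph of a legal melt state is a disjoint union of cycles
    (every bead has exactly two bonds).  Isolated beads (no bonds) are also
    accepted so that single-particle integrator checks can share the type.
    """

    positions: np.ndarray          # (N, 3) float64, sigma
    velocities: np.ndarray         # (N, 3) float64
    bonds: set = field(default_factory=set)   # {(i, j) with i < j}
    time: float = 0.0
    box: object = None             # SphericalWall | PeriodicBox | None

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def neighbor_array(self) -> np.ndarray:
        """(N, 2) int64 array of bonded neighbours; -1 marks a free slot."""
        nb = np.full((self.n_beads, 2), -1, dtype=np.int64)
        for i, j in self.bonds:
            for a, b in ((i, j), (j, i)):
                if nb[a, 0] == -1:
                    nb[a, 0] = b
                elif nb[a, 1] == -1:
                    nb[a, 1] = b
                else:
                    raise ValueError(f"bead {a} has more than 2 bonds")
        return nb

    @classmethod
    def from_neighbor_array(
        cls, positions, velocities, nb, time=0.0, box=None
    ) -> "SystemState":
        bonds = set()
        for i in range(len(nb)):
            for j in nb[i]:
                if j >= 0:
                    bonds.add((min(i, int(j)), max(i, int(j))))
        return cls(positions, velocities, bonds, time, box)

    def validate(self, min_ring_length: int = 3) -> None:
        """Assert the bond graph is a disjoint union of cycles (plus free beads)."""
        nb = self.neighbor_array()
        deg = (nb >= 0).sum(axis=1)
        bad = np.where(deg == 1)[0]
        if len(bad):
            raise ValueError(f"bead {bad[0]} has degree 1 (dangling bond)")
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"bead {i} bonded to itself")
        for ring in _cycles(nb):
            if len(ring) < min_ring_length:
                raise ValueError(
                    f"cycle of length {len(ring)} < min_ring_length={min_ring_length}"
                )
        if isinstance(self.box, SphericalWall):
            r = np.linalg.norm(self.positions, axis=1)
            if (r > self.box.radius + 0.5).any():
                raise ValueError("bead outside the confining sphere")

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.velocities.copy(),
            set(self.bonds),
            self.time,
            self.box,
        )


def _cycles(nb: np.ndarray) -> Iterable[list]:
    """Deterministic cycle decomposition of a degree-2 neighbour array.

    Traversal starts at the lowest unvisited bead and steps to the lower-id
    neighbour first.
    """
    n = len(nb)
    seen = np.zeros(n, dtype=bool)
    for start in range(n):
        if seen[start] or nb[start, 0] < 0:
            continue
        ring = [start]
        seen[start] = True
        prev = start
        cur = int(min(nb[start, 0], nb[start, 1]))
        while cur != start:
            ring.append(cur)
            seen[cur] = True
            a, b = int(nb[cur, 0]), int(nb[cur, 1])
            nxt = a if a != prev else b
            # prefer the lower-id neighbour when both are unvisited and
            # distinct from prev (only possible at a doubled bond, which
            # validate() forbids)
            prev, cur = cur, nxt
        yield ring


# ---------------------------------------------------------------------------
# initial configuration
# ---------------------------------------------------------------------------

def build_initial_ring(config: SimulationConfig) -> SystemState:
    """One closed ring of N beads inscribed in a (large) initial sphere.

    Short rings are laid out as a planar circle; long ones as a closed coil
    wound around a torus so that the contour fits inside a sphere without
    self-overlap.  The exact shape is irrelevant: compression and
    equilibration erase it.  Velocities are Maxwell-distributed at T=1.
    """
    n = config.n_beads
    b = config.bond_length
    contour = n * b
    rng = np.random.default_rng(config.seed)

    circle_radius = contour / (2 * np.pi)
    if circle_radius <= 0.75 * max(config.sphere_radius, 6.0):
        pts = _circle_points(n, b)
        r0 = max(circle_radius + 2.0, config.sphere_radius)
    else:
        pts, r_fit = _torus_coil_points(n, b)
        r0 = max(r_fit, config.sphere_radius)

    if r0 > 200 * config.sphere_radius:
        raise ValueError(
            f"cannot lay out a ring of {n} beads inside a reasonable "
            "initial sphere"
        )

    vel = rng.normal(0.0, 1.0, size=(n, 3))
    vel -= vel.mean(axis=0)
    bonds = {(i, (i + 1) % n) if i + 1 < n else (0, n - 1) for i in range(n)}
    bonds = {(min(i, j), max(i, j)) for i, j in bonds}
    state = SystemState(pts, vel, bonds, 0.0, SphericalWall(r0))
    state.validate(config.min_ring_length)
    return state


def _circle_points(n: int, b: float) -> np.ndarray:
    r = n * b / (2 * np.pi)
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(n)])


def _torus_coil_points(n: int, b: float) -> tuple:
    """Closed coil on a torus, beads equally spaced in arc length.

    Winds m times around a torus of centre radius A and tube radius A/2;
    the gap between consecutive winds is kept above ~1.2 sigma so the coil
    does not self-overlap.
    """
    contour = n * b
    min_gap = 1.25
    # contour ~ pi * m * A and gap = 2 pi A / m >= min_gap
    big_a = max(np.sqrt(contour * min_gap / (2 * np.pi**2)) / 0.9, 3.0)
    m = max(int(contour / (np.pi * big_a)), 2)
    while 2 * np.pi * big_a / m < min_gap:
        big_a *= 1.1
        m = max(int(contour / (np.pi * big_a)), 2)
    a = big_a / 2.0

    # dense parametric sampling, then arc-length resampling
    t = np.linspace(0.0, 2 * np.pi, 200 * m, endpoint=False)
    x = (big_a + a * np.cos(m * t)) * np.cos(t)
    y = (big_a + a * np.cos(m * t)) * np.sin(t)
    z = a * np.sin(m * t)
    dense = np.column_stack([x, y, z])
    seg = np.linalg.norm(np.diff(np.vstack([dense, dense[:1]]), axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    want = np.linspace(0.0, total, n, endpoint=False)
    closed = np.vstack([dense, dense[:1]])
    pts = np.column_stack(
        [np.interp(want, arc, closed[:, k]) for k in range(3)]
    )
    # rescale so consecutive spacing matches b on average
    mean_b = np.linalg.norm(
        np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1
    ).mean()
    pts *= b / mean_b
    r_fit = np.linalg.norm(pts, axis=1).max() + 2.0
    return pts, r_fit


# ---------------------------------------------------------------------------
# energies (reference implementations; the numba kernels mirror these)
# ---------------------------------------------------------------------------

def wca_energy(r: float, eps: float = 1.0, sigma: float = 1.0) -> float:
    """Purely repulsive LJ, shifted to zero at the 2^(1/6) sigma cutoff."""
    if r >= WCA_CUTOFF * sigma:
        return 0.0
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6) + eps


def fene_energy(r: float, k: float = 30.0, r0: float = 1.5) -> float:
    """Attractive FENE part; diverges at the maximum extension r0."""
    if r >= r0:
        raise FloatingPointError(f"FENE bond overextended: r={r} >= r0={r0}")
    return -0.5 * k * r0**2 * np.log(1.0 - (r / r0) ** 2)


def bond_energy(r: float, ff: ForceField) -> float:
    """Full energy of a bonded pair: FENE spring + WCA repulsion."""
    return fene_energy(r, ff.fene_k, ff.fene_r0) + wca_energy(
        r, ff.wca_epsilon, ff.wca_sigma
    )


def bending_energy_at(positions, nb, i, k_bend: float) -> float:
    """Kratky-Porod energy of the angle centred at bead i."""
    a, b = int(nb[i, 0]), int(nb[i, 1])
    if a < 0 or b < 0 or k_bend == 0.0:
        return 0.0
    u = positions[i] - positions[a]
    v = positions[b] - positions[i]
    c = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return k_bend * (1.0 - c)


def wall_energy_of(positions, radius: float, eps: float = 1.0) -> float:
    r = np.linalg.norm(positions, axis=1)
    d = radius - r
    if (d <= 0).any():
        raise FloatingPointError("bead at or beyond the wall surface")
    e = 0.0
    for di in d:
        if di < WCA_CUTOFF:
            e += wca_energy(float(di), eps)
    return e


def total_energy(state: SystemState, ff: ForceField) -> float:
    """WCA (all pairs) + FENE (bonds) + bending + wall energy."""
    pos = state.positions
    n = len(pos)
    e = 0.0
    # all-pairs WCA; O(N^2) reference path, fine for analysis-size systems
    if n > 1:
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        iu = np.triu_indices(n, 1)
        rr = d[iu]
        close = rr < WCA_CUTOFF * ff.wca_sigma
        for r in rr[close]:
            e += wca_energy(float(r), ff.wca_epsilon, ff.wca_sigma)
    nb = state.neighbor_array()
    for i, j in state.bonds:
        r = float(np.linalg.norm(pos[i] - pos[j]))
        e += fene_energy(r, ff.fene_k, ff.fene_r0)
    if ff.bending_k:
        for i in range(n):
            e += bending_energy_at(pos, nb, i, ff.bending_k)
    if isinstance(state.box, SphericalWall):
        e += wall_energy_of(pos, state.box.radius, ff.wall_epsilon)
    return e


def local_energy(state: SystemState, beads, ff: ForceField) -> float:
    """Bond (FENE) and bending terms incident on the given beads.

    This is the part of the energy a rewiring move can change: WCA and wall
    terms depend on positions only and are excluded.  Each FENE bond with at
    least one endpoint in ``beads`` is counted once; each bending angle whose
    centre bead is in ``beads`` is counted once.
    """
    beads = set(int(b) for b in beads)
    pos = state.positions
    nb = state.neighbor_array()
    e = 0.0
    for i, j in state.bonds:
        if i in beads or j in beads:
            e += fene_energy(
                float(np.linalg.norm(pos[i] - pos[j])), ff.fene_k, ff.fene_r0
            )
    if ff.bending_k:
        for i in beads:
            e += bending_energy_at(pos, nb, i, ff.bending_k)
    return e


def bonded_energy(state: SystemState, ff: ForceField) -> float:
    """FENE + bending part of the total energy (for partition checks)."""
    return local_energy(state, range(state.n_beads), ff)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DerivedDensities:
    monomer_density: float   # rho, sigma^-3
    volume_fraction: float   # phi = (pi/6) rho sigma^3


def derived_densities(config) -> DerivedDensities:
    """rho = 3N/(4 pi R^3) and phi = (pi/6) rho (sphere-of-diameter-sigma).

    Accepts a :class:`SimulationConfig` or a plain ``(n_beads, radius)``
    pair (so an empty system can be queried too).
    """
    if isinstance(config, SimulationConfig):
        n, r = config.n_beads, config.sphere_radius
    else:
        n, r = config
    if r <= 0:
        raise ValueError("sphere radius must be positive")
    rho = 3.0 * n / (4.0 * np.pi * r**3)
    return DerivedDensities(rho, np.pi / 6.0 * rho)


def radius_for_density(n_beads: int, rho: float = 0.7) -> float:
    """Sphere radius giving monomer density rho for n_beads beads."""
    return (3.0 * n_beads / (4.0 * np.pi * rho)) ** (1.0 / 3.0)
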