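"""Single-site reconnection (bond-swap) moves on a ring melt.

A reconnection takes two bonds (a,b) and (c,d) whose designated ends a and
c are closer than the cutoff rc, deletes them, and creates (a,c) and (b,d).
In an undirected cycle graph this preserves degree 2 everywhere; whether
the move merges two rings, splits one, or merely reverses a contour
segment is determined by traversal, not by the rule.  Moves are accepted
with the Metropolis probability min(1, exp(-dE/kBT)), where dE contains
only the FENE terms of the two swapped bonds and the bending terms of the
four incident angles -- excluded-volume and wall energies depend on
positions only, which the move never changes.

This module is the transparent reference implementation operating on
:class:`~topogel.model.SystemState`; production runs use the equivalent
fused kernel in :mod:`topogel._kernels` (cross-checked in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ForceField, SystemState, local_energy


@dataclass(frozen=True)
class SwapProposal:
    old_bonds: tuple      # ((a, b), (c, d))
    new_bonds: tuple      # ((a, c), (b, d))
    delta_energy: float

    @property
    def beads(self):
        (a, b), (c, d) = self.old_bonds
        return (a, b, c, d)


@dataclass
class ReconnectionStats:
    attempts: int = 0
    accepts: int = 0
    elapsed_time: float = 0.0

    @property
    def rate(self) -> float:
        """Accepted swaps per tau_B (kappa_r)."""
        if self.elapsed_time <= 0:
            return float("nan")
        return self.accepts / self.elapsed_time


def _norm_bond(i, j):
    return (min(i, j), max(i, j))


def _cycle_length_through(nb, start, cap=None):
    prev = start
    cur = int(nb[start, 0])
    steps = 1
    while cur != start:
        a, b = int(nb[cur, 0]), int(nb[cur, 1])
        nxt = a if a != prev else b
        prev, cur = cur, nxt
        steps += 1
        if cap is not None and steps >= cap:
            return steps
    return steps


def _delta_energy(state: SystemState, ff: ForceField, a, b, c, d):
    """dE of rewiring (a,b),(c,d) -> (a,c),(b,d): FENE + bending terms only."""
    beads = {a, b, c, d}
    e_old = local_energy(state, beads, ff)
    trial = state.copy()
    trial.bonds.discard(_norm_bond(a, b))
    trial.bonds.discard(_norm_bond(c, d))
    trial.bonds.add(_norm_bond(a, c))
    trial.bonds.add(_norm_bond(b, d))
    e_new = local_energy(trial, beads, ff)
    return e_new - e_old


def find_candidates(state: SystemState, rc: float, ff: ForceField,
                    min_ring_length: int = 3) -> list:
    """All legal swap proposals with designated ends closer than rc.

    For every unordered bead pair (a, c) with |r_a - r_c| <= rc that is not
    already bonded, each combination of a's bonds (a,b) and c's bonds (c,d)
    yields the proposal (a,b),(c,d) -> (a,c),(b,d), provided the four beads
    are distinct, b and d are not already bonded, and the rewired graph
    contains no cycle shorter than ``min_ring_length``.  Proposals whose new
    bonds would exceed the FENE maximum extension are kept (their
    delta_energy is +inf); the Metropolis test rejects them.
    """
    pos = state.positions
    nb = state.neighbor_array()
    n = state.n_beads
    proposals = []
    bondset = state.bonds
    for a in range(n):
        for c in range(a + 1, n):
            if np.linalg.norm(pos[a] - pos[c]) > rc:
                continue
            if nb[a, 0] < 0 or nb[c, 0] < 0:
                continue
            if _norm_bond(a, c) in bondset:
                continue
            for b in (int(nb[a, 0]), int(nb[a, 1])):
                for d in (int(nb[c, 0]), int(nb[c, 1])):
                    if b == c or d == a or b == d:
                        continue
                    if _norm_bond(b, d) in bondset:
                        continue
                    # min-ring check on the rewired graph
                    trial_nb = nb.copy()
                    _swap_nb(trial_nb, a, b, c, d)
                    if (_cycle_length_through(trial_nb, a, cap=min_ring_length)
                            < min_ring_length):
                        continue
                    if (_cycle_length_through(trial_nb, b, cap=min_ring_length)
                            < min_ring_length):
                        continue
                    r_ac = float(np.linalg.norm(pos[a] - pos[c]))
                    r_bd = float(np.linalg.norm(pos[b] - pos[d]))
                    if r_ac >= ff.fene_r0 or r_bd >= ff.fene_r0:
                        de = float("inf")
                    else:
                        de = _delta_energy(state, ff, a, b, c, d)
                    proposals.append(
                        SwapProposal(
                            old_bonds=(_norm_bond(a, b), _norm_bond(c, d)),
                            new_bonds=(_norm_bond(a, c), _norm_bond(b, d)),
                            delta_energy=de,
                        )
                    )
    return proposals


def _swap_nb(nb, a, b, c, d):
    for x, old, new in ((a, b, c), (c, d, a), (b, a, d), (d, c, b)):
        if nb[x, 0] == old:
            nb[x, 0] = new
        else:
            nb[x, 1] = new


def acceptance_probability(delta_energy: float,
                           temperature: float = 1.0) -> float:
    """min(1, exp(-dE/kBT)): identical to the piecewise form (1 for dE < 0,
    exp(-dE/kBT) for dE >= 0) and manifestly detailed-balanced."""
    if delta_energy <= 0.0:
        return 1.0
    if not np.isfinite(delta_energy):
        return 0.0
    return float(np.exp(-delta_energy / temperature))


def metropolis_accept(proposal: SwapProposal, rng: np.random.Generator,
                      temperature: float = 1.0) -> bool:
    """Accept with probability min(1, exp(-dE/kBT))."""
    p = acceptance_probability(proposal.delta_energy, temperature)
    if p >= 1.0:
        return True
    return bool(rng.random() < p)


def apply_swap(state: SystemState, proposal: SwapProposal) -> SystemState:
    """Rewire the bond graph; positions untouched.  Raises on stale proposals."""
    for bond in proposal.old_bonds:
        if bond not in state.bonds:
            raise ValueError(f"stale proposal: bond {bond} no longer present")
    for bond in proposal.new_bonds:
        if bond in state.bonds:
            raise ValueError(f"stale proposal: bond {bond} already present")
    new = state.copy()
    for bond in proposal.old_bonds:
        new.bonds.discard(bond)
    for bond in proposal.new_bonds:
        new.bonds.add(bond)
    return new


def sweep(state: SystemState, rc: float, rng: np.random.Generator,
          stats: ReconnectionStats, ff: ForceField | None = None,
          min_ring_length: int = 3, temperature: float = 1.0) -> SystemState:
    """One reference sweep: visit candidates in random order.

    A bead participates in at most one accepted swap per sweep; proposals
    touching an already-modified bead are skipped.  Energies are
    re-evaluated against the current (possibly already rewired) state.
    """
    if ff is None:
        ff = ForceField()
    proposals = find_candidates(state, rc, ff, min_ring_length)
    order = rng.permutation(len(proposals))
    touched = set()
    new = state
    for k in order:
        p = proposals[int(k)]
        if touched & set(p.beads):
            continue
        stats.attempts += 1
        if not all(b in new.bonds for b in p.old_bonds):
            continue
        (a, b), (c, d) = p.old_bonds
        if p.delta_energy == float("inf"):
            de = float("inf")
        else:
            de = _delta_energy(new, ff, a, b, c, d)
        live = SwapProposal(p.old_bonds, p.new_bonds, de)
        if metropolis_accept(live, rng, temperature):
            new = apply_swap(new, live)
            touched |= set(p.beads)
            stats.accepts += 1
    return new
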