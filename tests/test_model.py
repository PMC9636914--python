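import math

import numpy as np
import pytest

from topogel import (ForceField, SimulationConfig, SphericalWall, SystemState,
                     build_initial_ring, derived_densities, local_energy,
                     total_energy)
from topogel.model import (bonded_energy, fene_energy, radius_for_density,
                           wca_energy)
from topogel.topology import extract_rings


def ring_state(positions, k_bend=0.0):
    n = len(positions)
    bonds = {(min(i, (i + 1) % n), max(i, (i + 1) % n)) for i in range(n)}
    return SystemState(np.asarray(positions, float),
                       np.zeros((n, 3)), bonds, 0.0, None)


class TestBuildInitialRing:
    @pytest.mark.parametrize("n", [50, 1000])
    def test_single_cycle_with_correct_spacing(self, n):
        cfg = SimulationConfig(n_beads=n, sphere_radius=7.0, seed=4)
        state = build_initial_ring(cfg)
        assert state.n_beads == n
        assert len(state.bonds) == n
        rings = extract_rings(state)
        assert rings.count == 1
        pos = state.positions
        order = rings.rings[0]
        spacing = np.linalg.norm(
            pos[order] - pos[np.roll(order, -1)], axis=1
        )
        assert np.all(np.abs(spacing - cfg.bond_length) < 0.15)
        # fits inside its own (initial) sphere
        assert np.linalg.norm(pos, axis=1).max() < state.box.radius

    def test_minimal_triangle(self):
        cfg = SimulationConfig(n_beads=3, sphere_radius=3.0, seed=0)
        state = build_initial_ring(cfg)
        assert extract_rings(state).lengths.tolist() == [3]

    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(n_beads=50, sphere_radius=7.0, seed=9)
        a = build_initial_ring(cfg)
        b = build_initial_ring(cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)
        assert a.bonds == b.bonds

    def test_maxwell_velocities(self):
        cfg = SimulationConfig(n_beads=1000, sphere_radius=7.0, seed=1)
        state = build_initial_ring(cfg)
        v2 = (state.velocities ** 2).mean()
        assert abs(v2 - 1.0) < 5.0 / math.sqrt(3000)


class TestEnergies:
    def test_wca_zero_at_cutoff(self):
        assert wca_energy(2 ** (1 / 6)) == 0.0
        assert wca_energy(1.0) == pytest.approx(1.0)  # 4(1-1)+1

    def test_collinear_bending_is_zero(self):
        state = ring_state([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0],
                            [3, 1e-9, 1], [0, 1e-9, 1]])
        ff0 = ForceField(bending_k=0.0)
        ff5 = ForceField(bending_k=5.0)
        # interior straight angle at bead 1 contributes nothing
        e0 = local_energy(state, {1}, ff0)
        e5 = local_energy(state, {1}, ff5)
        assert e5 - e0 == pytest.approx(0.0, abs=1e-12)

    def test_regular_polygon_bending_closed_form(self):
        n = 10
        t = 2 * np.pi * np.arange(n) / n
        r = 0.97 / (2 * np.sin(np.pi / n))   # bond length 0.97
        state = ring_state(np.column_stack(
            [r * np.cos(t), r * np.sin(t), np.zeros(n)]
        ))
        ff = ForceField(bending_k=1.0)
        expected = n * 1.0 * (1 - np.cos(2 * np.pi / n))
        bend = bonded_energy(state, ff) - bonded_energy(
            state, ForceField(bending_k=0.0)
        )
        assert bend == pytest.approx(expected, rel=1e-12)

    def test_rotation_invariance(self):
        cfg = SimulationConfig(n_beads=40, sphere_radius=7.0, seed=2)
        state = build_initial_ring(cfg)
        ff = ForceField(bending_k=2.0)
        e0 = total_energy(state, ff)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        rotated = state.copy()
        rotated.positions = state.positions @ rot.T
        assert total_energy(rotated, ff) == pytest.approx(e0, rel=1e-9)

    def test_bending_identically_zero_at_k0(self):
        rng = np.random.default_rng(3)
        r = 1.0 / (2 * np.sin(np.pi / 8))
        pts = np.array([[r * np.cos(a), r * np.sin(a), 0]
                        for a in 2 * np.pi * np.arange(8) / 8])
        pts += rng.normal(scale=0.02, size=pts.shape)
        state = ring_state(pts)
        assert bonded_energy(state, ForceField(bending_k=0.0)) == \
            pytest.approx(
                sum(fene_energy(np.linalg.norm(
                    state.positions[i] - state.positions[j]))
                    for i, j in state.bonds)
            )

    def test_local_energy_partition_completeness(self, melt_k0):
        _, ff, _, record = melt_k0
        state = record.snapshots[-1]
        full = local_energy(state, range(state.n_beads), ff)
        assert full == pytest.approx(bonded_energy(state, ff), rel=1e-12)

    def test_local_energy_window_oracle(self):
        """A 4-bead window's local energy matches term-by-term bookkeeping."""
        cfg = SimulationConfig(n_beads=12, sphere_radius=4.0, seed=6)
        state = build_initial_ring(cfg)
        rng = np.random.default_rng(0)
        state.positions += rng.normal(scale=0.02, size=state.positions.shape)
        ff = ForceField(bending_k=3.0)
        window = {2, 3, 4, 5}
        # oracle: bonds with an endpoint in the window + angles centred there
        e = 0.0
        for i, j in state.bonds:
            if i in window or j in window:
                e += fene_energy(
                    float(np.linalg.norm(state.positions[i]
                                         - state.positions[j])))
        nb = state.neighbor_array()
        for i in window:
            a, b = nb[i]
            u = state.positions[i] - state.positions[a]
            v = state.positions[b] - state.positions[i]
            c = u @ v / np.linalg.norm(u) / np.linalg.norm(v)
            e += 3.0 * (1 - c)
        assert local_energy(state, window, ff) == pytest.approx(e, rel=1e-12)

    def test_fene_overextension_raises(self):
        state = ring_state([[0, 0, 0], [1.6, 0, 0], [0.8, 1.0, 0]])
        with pytest.raises(FloatingPointError):
            total_energy(state, ForceField())


class TestDensities:
    def test_reference_conditions(self):
        cfg = SimulationConfig(n_beads=1000, sphere_radius=7.0)
        d = derived_densities(cfg)
        assert d.monomer_density == pytest.approx(0.6960, abs=1e-3)
        assert d.volume_fraction == pytest.approx(0.3644, abs=1e-3)

    def test_empty_system(self):
        d = derived_densities((0, 7.0))
        assert d.monomer_density == 0.0
        assert d.volume_fraction == 0.0

    def test_radius_for_density_round_trip(self):
        r = radius_for_density(240, 0.7)
        d = derived_densities((240, r))
        assert d.monomer_density == pytest.approx(0.7, rel=1e-12)


class TestStateInvariants:
    def test_validate_rejects_dangling_bond(self):
        state = ring_state([[0, 0, 0], [1, 0, 0], [0.5, 1, 0]])
        state.bonds.discard((0, 1))
        with pytest.raises(ValueError):
            state.validate()

    def test_validate_rejects_short_cycle(self):
        state = ring_state([[0, 0, 0], [1, 0, 0], [0.5, 1, 0]])
        with pytest.raises(ValueError):
            state.validate(min_ring_length=4)

    def test_neighbor_array_round_trip(self, melt_k0):
        _, _, _, record = melt_k0
        state = record.snapshots[-1]
        nb = state.neighbor_array()
        back = SystemState.from_neighbor_array(
            state.positions, state.velocities, nb
        )
        assert back.bonds == state.bonds
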