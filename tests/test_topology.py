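import numpy as np
import pytest

from topogel import (SystemState, build_link_network, extract_rings,
                     knot_invariant, linked_pair_indicator, linking_number,
                     linking_probability, single_cluster_probability)
from topogel.fixtures import apply_rigid_motion, make_fixture
from topogel.topology import LinkNetwork, kmt_reduce, _alexander_determinant_once

from conftest import lk_crossing_oracle


def state_from_cycles(cycles_positions):
    pos = np.vstack(cycles_positions)
    bonds = set()
    off = 0
    for c in cycles_positions:
        m = len(c)
        for i in range(m):
            a, b = off + i, off + (i + 1) % m
            bonds.add((min(a, b), max(a, b)))
        off += m
    return SystemState(pos, np.zeros_like(pos), bonds, 0.0, None)


class TestExtractRings:
    def test_two_triangles(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0.5, 1, 0.0]])
        state = state_from_cycles([tri, tri + [5, 0, 0]])
        rings = extract_rings(state)
        assert rings.lengths.tolist() == [3, 3]
        # deterministic: traversal starts at the lowest unvisited bead
        assert rings.rings[0][0] == 0 and rings.rings[1][0] == 3

    def test_corrupted_state_raises(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0.5, 1, 0.0]])
        state = state_from_cycles([tri])
        state.bonds.discard((0, 1))
        with pytest.raises(ValueError, match="degree"):
            extract_rings(state)


class TestLinkingNumber:
    @pytest.mark.parametrize("name,expected", [
        ("unlinked_pair", 0), ("hopf", 1), ("solomon", 2),
    ])
    @pytest.mark.parametrize("n_points", [32, 64, 128, 256])
    def test_known_links_integer_valued(self, name, expected, n_points):
        fix = make_fixture(name, n_points)
        lk = linking_number(*fix.curves)
        assert abs(abs(lk) - expected) < 1e-6

    @pytest.mark.parametrize("name", ["hopf", "solomon"])
    def test_crossing_sign_oracle_agreement(self, name):
        fix = make_fixture(name, 64)
        rng = np.random.default_rng(3)
        gauss = linking_number(*fix.curves)
        oracle = lk_crossing_oracle(*fix.curves, rng)
        assert gauss == pytest.approx(oracle, abs=1e-6)

    def test_antisymmetric_under_orientation_reversal(self):
        fix = make_fixture("hopf", 64)
        a, b = fix.curves
        assert linking_number(a[::-1], b) == pytest.approx(
            -linking_number(a, b), abs=1e-9
        )
        assert abs(linking_number(a[::-1], b)) == pytest.approx(
            abs(linking_number(a, b)), abs=1e-9
        )

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(17)
        fix = make_fixture("solomon", 96)
        base = linking_number(*fix.curves)
        for _ in range(5):
            # the same motion applied to both curves leaves Lk unchanged
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z),
                 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
                 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x),
                 1 - 2 * (x * x + y * y)],
            ])
            shift = rng.uniform(-3, 3, 3)
            lk = linking_number(fix.curves[0] @ rot.T + shift,
                                fix.curves[1] @ rot.T + shift)
            assert lk == pytest.approx(base, abs=1e-6)

    def test_shared_vertex_raises(self):
        fix = make_fixture("hopf", 32)
        b = fix.curves[1].copy()
        b[0] = fix.curves[0][0]
        with pytest.raises(ValueError, match="singular"):
            linking_number(fix.curves[0], b)


class TestLinkedPairIndicator:
    @pytest.mark.parametrize("lk,expected", [
        (0.49, 0), (0.5, 0), (-1.0, 1), (0.51, 1), (-0.5, 0), (2.0, 1),
    ])
    def test_threshold_half_strict(self, lk, expected):
        assert linked_pair_indicator(lk) == expected


class TestLinkNetwork:
    def test_all_unlinked(self):
        fix = make_fixture("unlinked_pair", 48)
        state = state_from_cycles(fix.curves)
        net = build_link_network(extract_rings(state), state.positions)
        assert net.n_linked_pairs == 0
        assert net.total_abs_lk == pytest.approx(0.0, abs=1e-6)
        assert len(net.clusters) == 2

    def test_chain_catenane(self):
        fix = make_fixture("chain3", 64)
        state = state_from_cycles(fix.curves)
        net = build_link_network(extract_rings(state), state.positions)
        assert net.n_linked_pairs == 2
        assert {tuple(sorted(e)) for e in net.graph.edges} == {(0, 1), (1, 2)}
        assert len(net.clusters) == 1
        assert net.is_single_cluster

    def test_solomon_pair_contributes_two(self):
        fix = make_fixture("solomon", 96)
        state = state_from_cycles(fix.curves)
        net = build_link_network(extract_rings(state), state.positions)
        assert net.total_abs_lk == pytest.approx(2.0, abs=1e-6)
        assert net.n_linked_pairs == 1

    def test_edge_count_equals_indicator_sum(self):
        """N_Lk from the half-sum of chi equals the network's edge count."""
        fix = make_fixture("chain3", 48)
        state = state_from_cycles(fix.curves)
        net = build_link_network(extract_rings(state), state.positions)
        chi_sum = sum(
            linked_pair_indicator(lk) for lk in net.pair_linking.values()
        )
        assert net.n_linked_pairs == chi_sum

    def test_disjoint_bounding_spheres_imply_unlinked(self):
        """The prefilter's premise: separated curves have Lk = 0."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = make_fixture("trefoil", 48).curves[0]
            b = make_fixture("circle", 48).curves[0]
            a = apply_rigid_motion(a, rng)
            b = apply_rigid_motion(b, rng) + [30.0, 0, 0]
            ca, cb = a.mean(0), b.mean(0)
            ra = np.linalg.norm(a - ca, axis=1).max()
            rb = np.linalg.norm(b - cb, axis=1).max()
            assert np.linalg.norm(ca - cb) > ra + rb
            assert abs(linking_number(a, b)) < 1e-6


class TestClusterProbabilities:
    def _net(self, n_nodes, edges):
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(range(n_nodes))
        g.add_edges_from(edges)
        return LinkNetwork(g, {}, 0.0)

    def test_single_cluster_probability_counts(self):
        full = self._net(3, [(0, 1), (1, 2)])
        split = self._net(3, [(0, 1)])
        nets = [full] * 3 + [split] * 7
        assert single_cluster_probability(nets) == pytest.approx(0.3)
        assert single_cluster_probability([full]) == 1.0
        assert single_cluster_probability([split]) == 0.0

    def test_linking_probability(self):
        lonely = self._net(4, [])
        paired = self._net(4, [(0, 1), (2, 3)])
        assert linking_probability([lonely]) == 0.0
        assert linking_probability([paired]) == 1.0
        assert linking_probability([lonely, paired]) == 0.5

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            single_cluster_probability([])
        with pytest.raises(ValueError):
            linking_probability([])


class TestKnotInvariant:
    @pytest.mark.parametrize("name,det", [
        ("circle", 1), ("trefoil", 3), ("figure_eight", 5),
    ])
    @pytest.mark.parametrize("n_points", [48, 96, 200])
    def test_known_knots(self, name, det, n_points):
        fix = make_fixture(name, n_points)
        rng = np.random.default_rng(11)
        rep = knot_invariant(fix.curves[0], rng=rng)
        assert rep.determinant == det

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(23)
        fix = make_fixture("trefoil", 80)
        for _ in range(5):
            moved = apply_rigid_motion(fix.curves[0], rng)
            assert knot_invariant(moved, rng=rng).determinant == 3

    def test_reduction_preserves_determinant(self):
        """Triangle elisions never change the Alexander determinant."""
        fix = make_fixture("trefoil", 40)
        rng = np.random.default_rng(2)
        full = None
        for _ in range(20):
            full = _alexander_determinant_once(fix.curves[0], rng)
            if full is not None:
                break
        red = kmt_reduce(fix.curves[0])
        assert len(red) < 40
        reduced = None
        for _ in range(20):
            reduced = _alexander_determinant_once(red, rng)
            if reduced is not None:
                break
        assert full == reduced == 3

    def test_determinant_odd(self):
        rng = np.random.default_rng(4)
        for name in ("circle", "trefoil", "figure_eight"):
            rep = knot_invariant(make_fixture(name, 64).curves[0], rng=rng)
            assert rep.determinant % 2 == 1

    def test_self_intersecting_polygon_raises(self):
        poly = np.array([
            [0, 0, 0], [2, 2, 0], [2, 0, 0], [0, 2, 0],
        ], dtype=float)   # edges (1,2) and (3,0) cross edge (0,1) plane region
        with pytest.raises(ValueError, match="self-intersect"):
            knot_invariant(poly)

    def test_simulation_rings_give_integer_linking(self, melt_k0):
        """Every melt ring pair has an integer Gauss linking number."""
        _, _, _, record = melt_k0
        state = record.snapshots[-1]
        rings = extract_rings(state)
        net = build_link_network(rings, state.positions)
        for lk in net.pair_linking.values():
            assert abs(lk - round(lk)) < 1e-6
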