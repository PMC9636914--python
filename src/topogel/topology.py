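"""Topological observables of a ring melt.

* ring extraction from the bond graph,
* pairwise Gauss linking numbers Lk, evaluated exactly segment-pair by
  segment-pair through the closed-form solid angle of the tetrahedron the
  two segments span (no quadrature),
* the linked-pair indicator chi = [|Lk| > 1/2], the linked-pair count N_Lk
  and the total unsigned linking number |Lk| of a configuration,
* the link network (rings = nodes, linked pairs = edges) and its connected
  components,
* knot detection by chain (triangle-elision) reduction followed by the
  Alexander determinant |Delta(-1)| read off a generic projection.

The determinant classifies knots only up to its own degeneracies (e.g. it
cannot separate 4_1 from 5_1); reports list every compatible tabled knot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit

from .model import SystemState, _cycles

INTEGER_SNAP_TOL = 1e-6

#: knots (up to 7 crossings) sharing each Alexander determinant |Delta(-1)|
DETERMINANT_TABLE = {
    1: ("0_1",),
    3: ("3_1",),
    5: ("4_1", "5_1"),
    7: ("5_2", "7_1"),
    9: ("6_1",),
    11: ("6_2", "7_2"),
    13: ("6_3", "7_3"),
    15: ("7_4",),
    17: ("7_5",),
    19: ("7_6",),
    21: ("7_7",),
}


# ---------------------------------------------------------------------------
# rings
# ---------------------------------------------------------------------------

@dataclass
class RingSet:
    """Partition of all beads into closed cycles."""

    rings: list                  # list of int64 arrays (ordered bead ids)
    lengths: np.ndarray          # Lr per ring

    @property
    def count(self) -> int:
        return len(self.rings)

    def coordinates(self, positions) -> list:
        return [positions[r] for r in self.rings]


def extract_rings(state: SystemState) -> RingSet:
    """Deterministic cycle decomposition of the bond graph.

    Each traversal starts at the lowest unvisited bead id and steps to the
    lower-id neighbour first.  Raises if any bead does not have exactly two
    bonds.
    """
    nb = state.neighbor_array()
    deg = (nb >= 0).sum(axis=1)
    bad = np.where(deg != 2)[0]
    if len(bad):
        raise ValueError(
            f"corrupted state: bead {bad[0]} has degree {int(deg[bad[0]])}"
        )
    rings = [np.asarray(r, dtype=np.int64) for r in _cycles(nb)]
    lengths = np.array([len(r) for r in rings], dtype=np.int64)
    if lengths.sum() != state.n_beads:
        raise AssertionError("cycle decomposition does not cover all beads")
    return RingSet(rings, lengths)


# ---------------------------------------------------------------------------
# Gauss linking number
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lk_segments(pa, pb):
    """Sum of the Gauss integral over all segment pairs of two closed curves.

    Closed form per segment pair: the signed solid angle subtended by the
    Gauss map quadrilateral (Klenin & Langowski's method).
    """
    n = pa.shape[0]
    m = pb.shape[0]
    total = 0.0
    for i in range(n):
        i2 = (i + 1) % n
        p1x, p1y, p1z = pa[i, 0], pa[i, 1], pa[i, 2]
        p2x, p2y, p2z = pa[i2, 0], pa[i2, 1], pa[i2, 2]
        for j in range(m):
            j2 = (j + 1) % m
            q1x, q1y, q1z = pb[j, 0], pb[j, 1], pb[j, 2]
            q2x, q2y, q2z = pb[j2, 0], pb[j2, 1], pb[j2, 2]

            r13x = q1x - p1x
            r13y = q1y - p1y
            r13z = q1z - p1z
            r14x = q2x - p1x
            r14y = q2y - p1y
            r14z = q2z - p1z
            r23x = q1x - p2x
            r23y = q1y - p2y
            r23z = q1z - p2z
            r24x = q2x - p2x
            r24y = q2y - p2y
            r24z = q2z - p2z

            # normals of the Gauss-map quadrilateral faces
            n1x = r13y * r14z - r13z * r14y
            n1y = r13z * r14x - r13x * r14z
            n1z = r13x * r14y - r13y * r14x
            n2x = r14y * r24z - r14z * r24y
            n2y = r14z * r24x - r14x * r24z
            n2z = r14x * r24y - r14y * r24x
            n3x = r24y * r23z - r24z * r23y
            n3y = r24z * r23x - r24x * r23z
            n3z = r24x * r23y - r24y * r23x
            n4x = r23y * r13z - r23z * r13y
            n4y = r23z * r13x - r23x * r13z
            n4z = r23x * r13y - r23y * r13x

            l1 = math.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
            l2 = math.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
            l3 = math.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
            l4 = math.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
            if l1 < 1e-14 or l2 < 1e-14 or l3 < 1e-14 or l4 < 1e-14:
                continue  # coplanar pair: zero solid angle

            a1 = (n1x * n2x + n1y * n2y + n1z * n2z) / (l1 * l2)
            a2 = (n2x * n3x + n2y * n3y + n2z * n3z) / (l2 * l3)
            a3 = (n3x * n4x + n3y * n4y + n3z * n4z) / (l3 * l4)
            a4 = (n4x * n1x + n4y * n1y + n4z * n1z) / (l4 * l1)
            if a1 > 1.0:
                a1 = 1.0
            elif a1 < -1.0:
                a1 = -1.0
            if a2 > 1.0:
                a2 = 1.0
            elif a2 < -1.0:
                a2 = -1.0
            if a3 > 1.0:
                a3 = 1.0
            elif a3 < -1.0:
                a3 = -1.0
            if a4 > 1.0:
                a4 = 1.0
            elif a4 < -1.0:
                a4 = -1.0
            omega = (math.asin(a1) + math.asin(a2)
                     + math.asin(a3) + math.asin(a4))

            # sign from (t2 x t1) . r13
            t1x = p2x - p1x
            t1y = p2y - p1y
            t1z = p2z - p1z
            t2x = q2x - q1x
            t2y = q2y - q1y
            t2z = q2z - q1z
            cx = t2y * t1z - t2z * t1y
            cy = t2z * t1x - t2x * t1z
            cz = t2x * t1y - t2y * t1x
            s = cx * r13x + cy * r13y + cz * r13z
            if s > 0.0:
                total += omega
            elif s < 0.0:
                total -= omega
    return total / (4.0 * math.pi)


def linking_number(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Gauss linking number of two closed, disjoint polygonal curves.

    Both arguments are (n, 3) vertex arrays; closure is implicit.  The
    result is within 1e-6 of an integer for disjoint closed curves.  A
    shared vertex makes the Gauss integral singular and raises ValueError.
    """
    pa = np.ascontiguousarray(curve_a, dtype=np.float64)
    pb = np.ascontiguousarray(curve_b, dtype=np.float64)
    if pa.ndim != 2 or pa.shape[1] != 3 or pb.ndim != 2 or pb.shape[1] != 3:
        raise ValueError("curves must be (n, 3) arrays")
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)
    if d2.min() < 1e-20:
        raise ValueError("curves share a vertex; Gauss integral is singular")
    return float(_lk_segments(pa, pb))


def linked_pair_indicator(lk: float) -> int:
    """chi = 1 iff |Lk| > 1/2 (the strictly-greater convention)."""
    return int(abs(lk) > 0.5)


# ---------------------------------------------------------------------------
# link network
# ---------------------------------------------------------------------------

@dataclass
class LinkNetwork:
    """Rings as nodes; edges join pairs with |Lk| > 1/2."""

    graph: nx.Graph
    pair_linking: dict                 # (i, j) -> Lk, i < j
    total_abs_lk: float                # |Lk| = sum over unordered pairs

    @property
    def n_rings(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_linked_pairs(self) -> int:
        """N_Lk: the number of edges."""
        return self.graph.number_of_edges()

    @property
    def clusters(self) -> list:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def largest_cluster_fraction(self) -> float:
        if self.n_rings == 0:
            return float("nan")
        return max(len(c) for c in self.clusters) / self.n_rings

    @property
    def is_single_cluster(self) -> bool:
        return nx.number_connected_components(self.graph) == 1

    def linked_ring_fraction(self) -> float:
        """Fraction of rings with at least one link edge."""
        if self.n_rings == 0:
            return float("nan")
        return sum(1 for _, d in self.graph.degree() if d > 0) / self.n_rings


def build_link_network(rings: RingSet, positions: np.ndarray) -> LinkNetwork:
    """Evaluate Lk for every unordered ring pair and assemble the network.

    Pairs whose bounding spheres are disjoint are necessarily unlinked and
    skip the Gauss sum.
    """
    curves = rings.coordinates(positions)
    centers = [c.mean(axis=0) for c in curves]
    radii = [np.linalg.norm(c - ctr, axis=1).max()
             for c, ctr in zip(curves, centers)]
    g = nx.Graph()
    g.add_nodes_from(range(rings.count))
    pair_linking = {}
    total = 0.0
    for i in range(rings.count):
        for j in range(i + 1, rings.count):
            sep = np.linalg.norm(centers[i] - centers[j])
            if sep > radii[i] + radii[j]:
                lk = 0.0
            else:
                lk = linking_number(curves[i], curves[j])
            pair_linking[(i, j)] = lk
            total += abs(lk)
            if linked_pair_indicator(lk):
                g.add_edge(i, j, lk=lk)
    return LinkNetwork(g, pair_linking, total)


def single_cluster_probability(networks: list) -> float:
    """Fraction of sampled configurations forming one connected cluster."""
    if not networks:
        raise ValueError("no networks given")
    return sum(1 for n in networks if n.is_single_cluster) / len(networks)


def linking_probability(networks: list) -> float:
    """Fraction of ring samples carrying at least one link edge."""
    if not networks:
        raise ValueError("no networks given")
    linked = 0
    rings = 0
    for n in networks:
        rings += n.n_rings
        linked += sum(1 for _, d in n.graph.degree() if d > 0)
    if rings == 0:
        raise ValueError("networks contain no rings")
    return linked / rings


# ---------------------------------------------------------------------------
# knot detection: KMT reduction + Alexander determinant
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _seg2d_cross(ax, ay, bx, by, cx, cy, dx, dy, eps):
    """Proper 2D intersection of open segments AB and CD."""
    rx, ry = bx - ax, by - ay
    sx, sy = dx - cx, dy - cy
    den = rx * sy - ry * sx
    if abs(den) < 1e-14:
        return False
    t = ((cx - ax) * sy - (cy - ay) * sx) / den
    u = ((cx - ax) * ry - (cy - ay) * rx) / den
    return eps < t < 1.0 - eps and eps < u < 1.0 - eps


@njit(cache=True)
def _coplanar_overlap(pts, ip, i, inx, j, j2):
    """Does coplanar edge (j, j2) overlap triangle (ip, i, inx) in-plane?

    Works in the plane's two dominant coordinates.  Touching exactly at a
    vertex shared with the polygon (ip or inx) does not count.
    """
    # pick projection axes from the triangle normal
    e1x = pts[i, 0] - pts[ip, 0]
    e1y = pts[i, 1] - pts[ip, 1]
    e1z = pts[i, 2] - pts[ip, 2]
    e2x = pts[inx, 0] - pts[ip, 0]
    e2y = pts[inx, 1] - pts[ip, 1]
    e2z = pts[inx, 2] - pts[ip, 2]
    nx_ = abs(e1y * e2z - e1z * e2y)
    ny_ = abs(e1z * e2x - e1x * e2z)
    nz_ = abs(e1x * e2y - e1y * e2x)
    if nz_ >= nx_ and nz_ >= ny_:
        a0, a1 = 0, 1
    elif ny_ >= nx_:
        a0, a1 = 0, 2
    else:
        a0, a1 = 1, 2
    tx = (pts[ip, a0], pts[i, a0], pts[inx, a0])
    ty = (pts[ip, a1], pts[i, a1], pts[inx, a1])
    sx0, sy0 = pts[j, a0], pts[j, a1]
    sx1, sy1 = pts[j2, a0], pts[j2, a1]
    eps = 1e-9
    # proper crossing with any triangle edge
    for k in range(3):
        k2 = (k + 1) % 3
        if _seg2d_cross(sx0, sy0, sx1, sy1, tx[k], ty[k], tx[k2], ty[k2],
                        eps):
            return True
    # an endpoint strictly inside the triangle (barycentric sign test)
    for (qx, qy, shared) in ((sx0, sy0, j == inx), (sx1, sy1, j2 == ip)):
        if shared:
            continue
        s0 = ((tx[1] - tx[0]) * (qy - ty[0])
              - (ty[1] - ty[0]) * (qx - tx[0]))
        s1 = ((tx[2] - tx[1]) * (qy - ty[1])
              - (ty[2] - ty[1]) * (qx - tx[1]))
        s2 = ((tx[0] - tx[2]) * (qy - ty[2])
              - (ty[0] - ty[2]) * (qx - tx[2]))
        if (s0 > eps and s1 > eps and s2 > eps) or \
                (s0 < -eps and s1 < -eps and s2 < -eps):
            return True
    return False


@njit(cache=True)
def _triangle_clear(pts, ip, i, inx):
    """True if no other edge of the closed polygon crosses triangle (ip,i,inx)."""
    n = pts.shape[0]
    ax, ay, az = pts[ip, 0], pts[ip, 1], pts[ip, 2]
    bx, by, bz = pts[i, 0], pts[i, 1], pts[i, 2]
    cx, cy, cz = pts[inx, 0], pts[inx, 1], pts[inx, 2]
    e1x, e1y, e1z = bx - ax, by - ay, bz - az
    e2x, e2y, e2z = cx - ax, cy - ay, cz - az
    nx_ = e1y * e2z - e1z * e2y
    ny_ = e1z * e2x - e1x * e2z
    nz_ = e1x * e2y - e1y * e2x
    area2 = math.sqrt(nx_ * nx_ + ny_ * ny_ + nz_ * nz_)
    if area2 < 1e-12:
        return False   # degenerate triangle: be conservative, keep vertex
    eps = 1e-9
    for j in range(n):
        j2 = (j + 1) % n
        if j == ip or j == i:
            continue   # the two edges being replaced
        ox, oy, oz = pts[j, 0], pts[j, 1], pts[j, 2]
        dx = pts[j2, 0] - ox
        dy = pts[j2, 1] - oy
        dz = pts[j2, 2] - oz
        # Moller-Trumbore
        px = dy * e2z - dz * e2y
        py = dz * e2x - dx * e2z
        pz = dx * e2y - dy * e2x
        det = e1x * px + e1y * py + e1z * pz
        if abs(det) < 1e-14:
            # segment parallel to the triangle plane: crosses the triangle
            # only if it is coplanar and overlaps it in-plane
            d0 = ((ox - ax) * nx_ + (oy - ay) * ny_ + (oz - az) * nz_) / area2
            d1 = ((pts[j2, 0] - ax) * nx_ + (pts[j2, 1] - ay) * ny_
                  + (pts[j2, 2] - az) * nz_) / area2
            if abs(d0) < eps or abs(d1) < eps:
                if _coplanar_overlap(pts, ip, i, inx, j, j2):
                    return False
            continue
        inv = 1.0 / det
        tx, ty, tz = ox - ax, oy - ay, oz - az
        u = (tx * px + ty * py + tz * pz) * inv
        if u < -eps or u > 1.0 + eps:
            continue
        qx = ty * e1z - tz * e1y
        qy = tz * e1x - tx * e1z
        qz = tx * e1y - ty * e1x
        v = (dx * qx + dy * qy + dz * qz) * inv
        if v < -eps or u + v > 1.0 + eps:
            continue
        t = (e2x * qx + e2y * qy + e2z * qz) * inv
        if t < -eps or t > 1.0 + eps:
            continue   # plane pierced outside the segment
        # touching exactly at a vertex shared with the triangle is allowed
        if j2 == ip and t > 1.0 - 1e-6:
            continue
        if j == inx and t < 1e-6:
            continue
        return False
    return True


@njit(cache=True)
def _min_nonadjacent_gap(pts):
    """Minimum distance between non-adjacent edges (self-intersection check)."""
    n = pts.shape[0]
    best = 1e30
    for i in range(n):
        i2 = (i + 1) % n
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            j2 = (j + 1) % n
            d = _seg_seg_dist(pts[i], pts[i2], pts[j], pts[j2])
            if d < best:
                best = d
    return best


@njit(cache=True, inline="always")
def _seg_seg_dist(p1, p2, q1, q2):
    ux, uy, uz = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    vx, vy, vz = q2[0] - q1[0], q2[1] - q1[1], q2[2] - q1[2]
    wx, wy, wz = p1[0] - q1[0], p1[1] - q1[1], p1[2] - q1[2]
    a = ux * ux + uy * uy + uz * uz
    b = ux * vx + uy * vy + uz * vz
    c = vx * vx + vy * vy + vz * vz
    d = ux * wx + uy * wy + uz * wz
    e = vx * wx + vy * wy + vz * wz
    den = a * c - b * b
    if den > 1e-14:
        s = (b * e - c * d) / den
        t = (a * e - b * d) / den
    else:
        s = 0.0
        t = e / c if c > 1e-14 else 0.0
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    t = (b * s + e) / c if c > 1e-14 else 0.0
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    s = (b * t - d) / a if a > 1e-14 else 0.0
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    dx = wx + s * ux - t * vx
    dy = wy + s * uy - t * vy
    dz = wz + s * uz - t * vz
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def kmt_reduce(poly: np.ndarray, min_size: int = 3) -> np.ndarray:
    """Chain reduction by repeated topology-preserving triangle elisions.

    A vertex is removed when the triangle spanned with its two neighbours
    is crossed by no other segment of the polygon, an exact segment-triangle
    test.  Iterates to a fixed point.
    """
    pts = np.ascontiguousarray(poly, dtype=np.float64)
    changed = True
    while changed and len(pts) > min_size:
        changed = False
        i = 0
        while len(pts) > min_size and i < len(pts):
            n = len(pts)
            if _triangle_clear(pts, (i - 1) % n, i, (i + 1) % n):
                pts = np.delete(pts, i, axis=0)
                changed = True
            else:
                i += 1
    return pts


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _crossings_2d(pts: np.ndarray):
    """Crossings of the projected polygon; None when degenerate."""
    n = len(pts)
    eps = 1e-9
    crossings = []
    for i in range(n):
        i2 = (i + 1) % n
        for j in range(i + 1, n):
            if j == i or j == (i + 1) % n or (j + 1) % n == i:
                continue
            j2 = (j + 1) % n
            p = pts[i, :2]
            r = pts[i2, :2] - p
            q = pts[j, :2]
            s = pts[j2, :2] - q
            den = r[0] * s[1] - r[1] * s[0]
            if abs(den) < 1e-14:
                continue
            t = ((q[0] - p[0]) * s[1] - (q[1] - p[1]) * s[0]) / den
            u = ((q[0] - p[0]) * r[1] - (q[1] - p[1]) * r[0]) / den
            if -eps < t < eps or 1 - eps < t < 1 + eps \
                    or -eps < u < eps or 1 - eps < u < 1 + eps:
                if -eps < t < 1 + eps and -eps < u < 1 + eps:
                    return None     # crossing at a vertex: degenerate
                continue
            if 0 < t < 1 and 0 < u < 1:
                za = pts[i, 2] + t * (pts[i2, 2] - pts[i, 2])
                zb = pts[j, 2] + u * (pts[j2, 2] - pts[j, 2])
                if abs(za - zb) < 1e-9:
                    return None
                crossings.append((i, t, j, u, za > zb))
    return crossings


def _alexander_determinant_once(pts: np.ndarray, rng: np.random.Generator):
    rot = _random_rotation(rng)
    proj = pts @ rot.T
    crossings = _crossings_2d(proj)
    if crossings is None:
        return None
    nc = len(crossings)
    if nc < 3:
        return 1
    # underpass events ordered along the curve
    events = []    # (edge, t, crossing index)
    for k, (i, t, j, u, a_over) in enumerate(crossings):
        if a_over:
            events.append((j, u, k))
        else:
            events.append((i, t, k))
    events.sort(key=lambda e: (e[0], e[1]))
    if len({(e[0], round(e[1], 12)) for e in events}) != nc:
        return None
    arc_of_event = {e[2]: idx for idx, e in enumerate(events)}

    def arc_at(edge, t):
        """Arc id of a point on the curve = index of last underpass before it."""
        lo, hi = -1, len(events)
        for idx, (e_edge, e_t, _) in enumerate(events):
            if (e_edge, e_t) <= (edge, t):
                lo = idx
        return lo % nc if lo >= 0 else nc - 1

    m = [[0] * nc for _ in range(nc)]
    for k, (i, t, j, u, a_over) in enumerate(crossings):
        if a_over:
            over_arc = arc_at(i, t)
        else:
            over_arc = arc_at(j, u)
        under_out = arc_of_event[k]
        under_in = (under_out - 1) % nc
        m[k][over_arc] += 2
        m[k][under_in] -= 1
        m[k][under_out] -= 1
    minor = [row[:-1] for row in m[:-1]]
    det = abs(_bareiss(minor))
    if det % 2 == 1:
        return det
    return None     # determinant of a knot is odd; projection artefact


def _bareiss(m):
    """Exact integer determinant (fraction-free Gaussian elimination)."""
    n = len(m)
    if n == 0:
        return 1
    m = [row[:] for row in m]
    sign = 1
    prev = 1
    for k in range(n - 1):
        if m[k][k] == 0:
            for r in range(k + 1, n):
                if m[r][k] != 0:
                    m[k], m[r] = m[r], m[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                m[i][j] = (m[i][j] * m[k][k] - m[i][k] * m[k][j]) // prev
            m[i][k] = 0
        prev = m[k][k]
    return sign * m[n - 1][n - 1]


@dataclass
class KnotReport:
    ring_id: int
    reduced_polygon_size: int
    determinant: int | None
    classification: tuple

    @property
    def is_unknot_compatible(self) -> bool:
        return self.determinant == 1


def knot_invariant(ring: np.ndarray, ring_id: int = 0,
                   rng: np.random.Generator | None = None,
                   max_reduced_size: int = 100,
                   max_projections: int = 20) -> KnotReport:
    """Knot content of one closed polygon via |Delta(-1)|.

    The polygon is first reduced by triangle elisions; the Alexander
    determinant is then computed from a crossing diagram in a randomized
    generic projection (re-drawn on degeneracies).  Rings whose reduction
    stays above ``max_reduced_size`` vertices, or whose determinant cannot
    be resolved, are reported as unresolved (determinant None).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    pts = np.ascontiguousarray(ring, dtype=np.float64)
    if len(pts) < 3:
        raise ValueError("a closed polygon needs at least 3 vertices")
    if _min_nonadjacent_gap(pts) < 1e-9:
        raise ValueError("polygon is self-intersecting")
    red = kmt_reduce(pts)
    if len(red) <= 3:
        return KnotReport(ring_id, len(red), 1, DETERMINANT_TABLE[1])
    if len(red) > max_reduced_size:
        return KnotReport(ring_id, len(red), None, ("unresolved",))
    for _ in range(max_projections):
        det = _alexander_determinant_once(red, rng)
        if det is not None:
            labels = DETERMINANT_TABLE.get(det, (f"determinant {det}",))
            return KnotReport(ring_id, len(red), det, labels)
    return KnotReport(ring_id, len(red), None, ("unresolved",))


def analyze_frame(state: SystemState) -> dict:
    """Per-frame topology summary: Nr, N_Lk, |Lk|, cluster statistics."""
    rings = extract_rings(state)
    net = build_link_network(rings, state.positions)
    return {
        "n_rings": rings.count,
        "mean_length": float(rings.lengths.mean()),
        "n_linked_pairs": net.n_linked_pairs,
        "total_abs_lk": net.total_abs_lk,
        "largest_cluster_fraction": net.largest_cluster_fraction,
        "single_cluster": bool(net.is_single_cluster),
        "network": net,
        "rings": rings,
    }
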