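"""Numba kernels: pair lists, forces, Langevin integration, bond-swap sweeps.

Everything here operates on plain arrays:

* ``pos``/``vel`` -- (n_tot, 3) float64.  Rows ``n_real:`` are immobile
  repulsive mesh sites (used by the permeabilized-sphere experiment) that
  feel no forces and never move.
* ``nb`` -- (n_real, 2) int64 bonded-neighbour table; -1 marks a free slot.
  A legal melt state has both slots filled for every bead.

Units are reduced Kremer-Grest units (sigma = epsilon = kBT = m = 1).
The integrator is the Gronbech-Jensen/Farago discretization of Langevin
dynamics, which reduces to velocity Verlet at zero friction.

Error codes returned by ``run_block``: 0 = ok; k > 0 = FENE bond at bead
k-1 overextended; -1 = pair-list overflow (caller should enlarge capacity).
"""

import math

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)
WCA_CUT2 = WCA_CUT * WCA_CUT
SKIN = 0.3
# proposals costlier than this are auto-rejected without drawing a random
# number: acceptance < e^-40 ~ 4e-18
DELTA_E_REJECT = 40.0


@njit(cache=True, inline="always", fastmath=True)
def _fene_e(r, k, r0):
    x = r / r0
    return -0.5 * k * r0 * r0 * math.log(1.0 - x * x)


@njit(cache=True, inline="always")
def _mi(d, box):
    if box > 0.0:
        d -= box * math.floor(d / box + 0.5)
    return d


@njit(cache=True, inline="always")
def _dist2(pos, i, j, box):
    dx = _mi(pos[i, 0] - pos[j, 0], box)
    dy = _mi(pos[i, 1] - pos[j, 1], box)
    dz = _mi(pos[i, 2] - pos[j, 2], box)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, inline="always", fastmath=True)
def _angle_energy(pos, nb, i, kbend, box):
    """Kratky-Porod energy K(1 - cos theta) of the angle centred at bead i."""
    a = nb[i, 0]
    b = nb[i, 1]
    if a < 0 or b < 0:
        return 0.0
    ux = _mi(pos[i, 0] - pos[a, 0], box)
    uy = _mi(pos[i, 1] - pos[a, 1], box)
    uz = _mi(pos[i, 2] - pos[a, 2], box)
    vx = _mi(pos[b, 0] - pos[i, 0], box)
    vy = _mi(pos[b, 1] - pos[i, 1], box)
    vz = _mi(pos[b, 2] - pos[i, 2], box)
    lu = math.sqrt(ux * ux + uy * uy + uz * uz)
    lv = math.sqrt(vx * vx + vy * vy + vz * vz)
    c = (ux * vx + uy * vy + uz * vz) / (lu * lv)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return kbend * (1.0 - c)


# ---------------------------------------------------------------------------
# pair list
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def build_pairs(pos, listcut, box, pi, pj):
    """Half list of all pairs with separation < listcut.

    Uses a cell list for large systems and a naive double loop for small
    ones (or when a periodic box is too small for 3 cells per side).
    Returns the number of pairs, or -1 if the ``pi``/``pj`` buffers are too
    small.
    """
    n = pos.shape[0]
    cap = pi.shape[0]
    c2 = listcut * listcut

    use_cells = n >= 400
    if box > 0.0 and box < 3.0 * listcut:
        use_cells = False

    if not use_cells:
        np_ = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                if _dist2(pos, i, j, box) < c2:
                    if np_ >= cap:
                        return -1
                    pi[np_] = i
                    pj[np_] = j
                    np_ += 1
        return np_

    if box > 0.0:
        lo0 = 0.0
        lo1 = 0.0
        lo2 = 0.0
        e0 = box
        e1 = box
        e2 = box
    else:
        lo0 = pos[0, 0]
        lo1 = pos[0, 1]
        lo2 = pos[0, 2]
        h0 = lo0
        h1 = lo1
        h2 = lo2
        for i in range(n):
            if pos[i, 0] < lo0:
                lo0 = pos[i, 0]
            if pos[i, 0] > h0:
                h0 = pos[i, 0]
            if pos[i, 1] < lo1:
                lo1 = pos[i, 1]
            if pos[i, 1] > h1:
                h1 = pos[i, 1]
            if pos[i, 2] < lo2:
                lo2 = pos[i, 2]
            if pos[i, 2] > h2:
                h2 = pos[i, 2]
        e0 = h0 - lo0 + 1e-9
        e1 = h1 - lo1 + 1e-9
        e2 = h2 - lo2 + 1e-9

    n0 = max(int(e0 / listcut), 1)
    n1 = max(int(e1 / listcut), 1)
    n2 = max(int(e2 / listcut), 1)
    ncell = n0 * n1 * n2
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    for i in range(n):
        c0 = int((pos[i, 0] - lo0) / e0 * n0)
        c1 = int((pos[i, 1] - lo1) / e1 * n1)
        c2i = int((pos[i, 2] - lo2) / e2 * n2)
        if c0 >= n0:
            c0 = n0 - 1
        if c1 >= n1:
            c1 = n1 - 1
        if c2i >= n2:
            c2i = n2 - 1
        if c0 < 0:
            c0 = 0
        if c1 < 0:
            c1 = 0
        if c2i < 0:
            c2i = 0
        cell = (c0 * n1 + c1) * n2 + c2i
        nxt[i] = head[cell]
        head[cell] = i

    # forward half-stencil for unique pairs
    offs = np.array(
        [
            [0, 0, 1],
            [0, 1, -1],
            [0, 1, 0],
            [0, 1, 1],
            [1, -1, -1],
            [1, -1, 0],
            [1, -1, 1],
            [1, 0, -1],
            [1, 0, 0],
            [1, 0, 1],
            [1, 1, -1],
            [1, 1, 0],
            [1, 1, 1],
        ],
        dtype=np.int64,
    )
    np_ = 0
    for c0 in range(n0):
        for c1 in range(n1):
            for c2i in range(n2):
                cell = (c0 * n1 + c1) * n2 + c2i
                i = head[cell]
                while i >= 0:
                    j = nxt[i]
                    while j >= 0:
                        if _dist2(pos, i, j, box) < c2:
                            if np_ >= cap:
                                return -1
                            if i < j:
                                pi[np_] = i
                                pj[np_] = j
                            else:
                                pi[np_] = j
                                pj[np_] = i
                            np_ += 1
                        j = nxt[j]
                    i = nxt[i]
                for o in range(13):
                    d0 = c0 + offs[o, 0]
                    d1 = c1 + offs[o, 1]
                    d2_ = c2i + offs[o, 2]
                    if box > 0.0:
                        d0 = d0 % n0
                        d1 = d1 % n1
                        d2_ = d2_ % n2
                    else:
                        if d0 < 0 or d0 >= n0 or d1 < 0 or d1 >= n1 \
                                or d2_ < 0 or d2_ >= n2:
                            continue
                    other = (d0 * n1 + d1) * n2 + d2_
                    i = head[cell]
                    while i >= 0:
                        j = head[other]
                        while j >= 0:
                            if _dist2(pos, i, j, box) < c2:
                                if np_ >= cap:
                                    return -1
                                if i < j:
                                    pi[np_] = i
                                    pj[np_] = j
                                else:
                                    pi[np_] = j
                                    pj[np_] = i
                                np_ += 1
                            j = nxt[j]
                        i = nxt[i]
    return np_


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def compute_forces(pos, f, nb, pi, pj, npairs, n_real, kbend, fene_k, fene_r0,
                   use_wall, wall_r, box):
    """Fill ``f`` with the total force; returns 0 or (bead+1) on FENE failure.

    WCA acts between every listed pair (bonded pairs included; mesh
    site-site pairs excluded); FENE along bonds; bending per interior
    angle; a WCA-form wall on the distance to the sphere surface.
    """
    n_tot = pos.shape[0]
    for i in range(n_tot):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0

    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        if i >= n_real and j >= n_real:
            continue
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < WCA_CUT2 and r2 > 0.0:
            sr2 = 1.0 / r2
            sr6 = sr2 * sr2 * sr2
            fr = 24.0 * (2.0 * sr6 * sr6 - sr6) * sr2
            f[i, 0] += fr * dx
            f[i, 1] += fr * dy
            f[i, 2] += fr * dz
            f[j, 0] -= fr * dx
            f[j, 1] -= fr * dy
            f[j, 2] -= fr * dz

    for i in range(n_real):
        for s in range(2):
            j = nb[i, s]
            if j > i:
                dx = _mi(pos[i, 0] - pos[j, 0], box)
                dy = _mi(pos[i, 1] - pos[j, 1], box)
                dz = _mi(pos[i, 2] - pos[j, 2], box)
                r2 = dx * dx + dy * dy + dz * dz
                r = math.sqrt(r2)
                x2 = r2 / (fene_r0 * fene_r0)
                if x2 >= 1.0:
                    return i + 1
                fr = -fene_k / (1.0 - x2)
                f[i, 0] += fr * dx
                f[i, 1] += fr * dy
                f[i, 2] += fr * dz
                f[j, 0] -= fr * dx
                f[j, 1] -= fr * dy
                f[j, 2] -= fr * dz

    if kbend > 0.0:
        for i in range(n_real):
            a = nb[i, 0]
            b = nb[i, 1]
            if a < 0 or b < 0:
                continue
            ux = _mi(pos[i, 0] - pos[a, 0], box)
            uy = _mi(pos[i, 1] - pos[a, 1], box)
            uz = _mi(pos[i, 2] - pos[a, 2], box)
            vx = _mi(pos[b, 0] - pos[i, 0], box)
            vy = _mi(pos[b, 1] - pos[i, 1], box)
            vz = _mi(pos[b, 2] - pos[i, 2], box)
            lu2 = ux * ux + uy * uy + uz * uz
            lv2 = vx * vx + vy * vy + vz * vz
            lu = math.sqrt(lu2)
            lv = math.sqrt(lv2)
            iluv = 1.0 / (lu * lv)
            c = (ux * vx + uy * vy + uz * vz) * iluv
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            # dc/du and dc/dv
            dux = vx * iluv - c * ux / lu2
            duy = vy * iluv - c * uy / lu2
            duz = vz * iluv - c * uz / lu2
            dvx = ux * iluv - c * vx / lv2
            dvy = uy * iluv - c * vy / lv2
            dvz = uz * iluv - c * vz / lv2
            # F_a = -K dc/du ; F_b = +K dc/dv ; F_i balances
            f[a, 0] -= kbend * dux
            f[a, 1] -= kbend * duy
            f[a, 2] -= kbend * duz
            f[b, 0] += kbend * dvx
            f[b, 1] += kbend * dvy
            f[b, 2] += kbend * dvz
            f[i, 0] += kbend * (dux - dvx)
            f[i, 1] += kbend * (duy - dvy)
            f[i, 2] += kbend * (duz - dvz)

    if use_wall:
        for i in range(n_real):
            r = math.sqrt(
                pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2
            )
            d = wall_r - r
            if d < WCA_CUT:
                if d < 0.05:
                    d = 0.05
                sr2 = 1.0 / (d * d)
                sr6 = sr2 * sr2 * sr2
                fmag = 24.0 * (2.0 * sr6 * sr6 - sr6) / d
                if r > 1e-12:
                    s = fmag / r
                    f[i, 0] -= s * pos[i, 0]
                    f[i, 1] -= s * pos[i, 1]
                    f[i, 2] -= s * pos[i, 2]
    return 0


# ---------------------------------------------------------------------------
# reconnection sweep
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _replace(nb, x, old, new):
    if nb[x, 0] == old:
        nb[x, 0] = new
    else:
        nb[x, 1] = new


@njit(cache=True, inline="always")
def _short_cycle(nb, start, min_ring):
    """True if the cycle through ``start`` is shorter than min_ring."""
    prev = start
    cur = nb[start, 0]
    steps = 1
    while steps < min_ring:
        if cur == start:
            return True
        nxt = nb[cur, 0]
        if nxt == prev:
            nxt = nb[cur, 1]
        prev = cur
        cur = nxt
        steps += 1
    return False


@njit(cache=True, fastmath=True)
def sweep(pos, nb, pi, pj, npairs, n_real, rc, kbend, fene_k, fene_r0, kT,
          min_ring, box, touched, cand, ebond, stats):
    """One reconnection sweep (Metropolis bond swaps).

    Candidates are bead pairs (a, c) closer than rc whose bonds (a,b) and
    (c,d) are rewired to (a,c) and (b,d).  All four (b, d) end choices are
    generated; candidates are visited in uniformly random order and a bead
    takes part in at most one accepted swap per sweep.  ``stats`` is an
    int64[2] array accumulating (attempts, accepts).  ``ebond`` is an
    (n_real, 2) scratch array for per-slot FENE energies.
    """
    rc2 = rc * rc
    ncand = 0
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        if j >= n_real:
            continue
        if nb[i, 0] < 0 or nb[j, 0] < 0:
            continue
        if nb[i, 0] == j or nb[i, 1] == j:
            continue
        if _dist2(pos, i, j, box) <= rc2:
            cand[ncand] = p
            ncand += 1
    if ncand == 0:
        return 0

    # FENE energy of every existing bond, indexed by (bead, slot); slots of
    # beads rewired by an accepted swap are never read again in this sweep
    # (the beads are marked touched)
    for i in range(n_real):
        for s in range(2):
            j = nb[i, s]
            if j >= 0:
                r = math.sqrt(_dist2(pos, i, j, box))
                ebond[i, s] = _fene_e(r, fene_k, fene_r0)
            else:
                ebond[i, s] = 0.0

    # Fisher-Yates shuffle
    for k in range(ncand - 1, 0, -1):
        r = np.random.randint(0, k + 1)
        tmp = cand[k]
        cand[k] = cand[r]
        cand[r] = tmp

    for i in range(n_real):
        touched[i] = 0

    for idx in range(ncand):
        p = cand[idx]
        a = pi[p]
        c = pj[p]
        if touched[a] or touched[c]:
            continue
        d2ac = _dist2(pos, a, c, box)
        r02 = fene_r0 * fene_r0
        e_ac = 1e30
        if d2ac < r02:
            e_ac = _fene_e(math.sqrt(d2ac), fene_k, fene_r0)
        accepted = False
        for kb in range(2):
            if accepted:
                break
            b = nb[a, kb]
            e_ab = ebond[a, kb]
            for kd in range(2):
                d = nb[c, kd]
                if b == c or d == a or b == d:
                    continue
                if touched[b] or touched[d]:
                    continue
                if nb[b, 0] == d or nb[b, 1] == d:
                    continue
                stats[0] += 1
                if d2ac >= r02:
                    continue
                d2bd = _dist2(pos, b, d, box)
                if d2bd >= r02:
                    continue
                dE = (
                    e_ac
                    + _fene_e(math.sqrt(d2bd), fene_k, fene_r0)
                    - e_ab
                    - ebond[c, kd]
                )
                ebend = 0.0
                if kbend > 0.0:
                    ebend = (
                        _angle_energy(pos, nb, a, kbend, box)
                        + _angle_energy(pos, nb, b, kbend, box)
                        + _angle_energy(pos, nb, c, kbend, box)
                        + _angle_energy(pos, nb, d, kbend, box)
                    )
                # tentatively rewire: (a,b),(c,d) -> (a,c),(b,d)
                _replace(nb, a, b, c)
                _replace(nb, c, d, a)
                _replace(nb, b, a, d)
                _replace(nb, d, c, b)
                if kbend > 0.0:
                    dE += (
                        _angle_energy(pos, nb, a, kbend, box)
                        + _angle_energy(pos, nb, b, kbend, box)
                        + _angle_energy(pos, nb, c, kbend, box)
                        + _angle_energy(pos, nb, d, kbend, box)
                        - ebend
                    )
                ok = dE < DELTA_E_REJECT
                if ok and (_short_cycle(nb, a, min_ring)
                           or _short_cycle(nb, b, min_ring)):
                    ok = False
                if ok and (dE <= 0.0
                           or np.random.random() < math.exp(-dE / kT)):
                    accepted = True
                    touched[a] = 1
                    touched[b] = 1
                    touched[c] = 1
                    touched[d] = 1
                    stats[1] += 1
                    break
                # revert
                _replace(nb, a, c, b)
                _replace(nb, c, a, d)
                _replace(nb, b, d, a)
                _replace(nb, d, b, c)
    return ncand


# ---------------------------------------------------------------------------
# fused integration block
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def run_block(pos, vel, nb, n_real, n_steps, dt, gamma, kT, kbend, fene_k,
              fene_r0, use_wall, wall_r0, wall_rate, box, do_recon, rc,
              min_ring, seed, noise, stats):
    """Advance ``n_steps`` Langevin steps, one reconnection sweep per step.

    Modifies pos/vel/nb in place.  ``wall_r0``/``wall_rate`` implement the
    linear compression ramp (radius at local step s is wall_r0 +
    wall_rate*s*dt).  ``noise`` holds unit-variance thermostat deviates of
    shape (n_steps, n_real, 3) (ignored at gamma = 0); ``seed`` drives the
    sweep randomness.  Returns an error code (see module docstring).
    """
    np.random.seed(seed)
    n_tot = pos.shape[0]
    cutoff = WCA_CUT
    if do_recon and rc > cutoff:
        cutoff = rc
    listcut = cutoff + SKIN
    cap = 90 * n_tot + 1024
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    cand = np.empty(cap, dtype=np.int64)
    touched = np.zeros(n_real, dtype=np.uint8)
    ebond = np.zeros((n_real, 2))
    f = np.zeros((n_tot, 3))
    fnew = np.zeros((n_tot, 3))
    beta = np.zeros((n_real, 3))
    disp = np.zeros((n_real, 3))

    b_gjf = 1.0 / (1.0 + gamma * dt / 2.0)
    a_gjf = (1.0 - gamma * dt / 2.0) * b_gjf
    sig = math.sqrt(2.0 * gamma * kT * dt)
    half_skin2 = (SKIN / 2.0) ** 2

    npairs = build_pairs(pos, listcut, box, pi, pj)
    if npairs < 0:
        return -1
    wall_r = wall_r0
    st = compute_forces(pos, f, nb, pi, pj, npairs, n_real, kbend, fene_k,
                        fene_r0, use_wall, wall_r, box)
    if st != 0:
        return st

    for step in range(n_steps):
        maxd2 = 0.0
        for i in range(n_real):
            for k in range(3):
                bb = 0.0
                if sig > 0.0:
                    bb = sig * noise[step, i, k]
                beta[i, k] = bb
                dx = (b_gjf * dt * vel[i, k]
                      + 0.5 * b_gjf * dt * dt * f[i, k]
                      + 0.5 * b_gjf * dt * bb)
                pos[i, k] += dx
                if box > 0.0:
                    pos[i, k] -= box * math.floor(pos[i, k] / box)
                disp[i, k] += dx
            d2 = (disp[i, 0] ** 2 + disp[i, 1] ** 2 + disp[i, 2] ** 2)
            if d2 > maxd2:
                maxd2 = d2

        if maxd2 > half_skin2:
            npairs = build_pairs(pos, listcut, box, pi, pj)
            if npairs < 0:
                return -1
            for i in range(n_real):
                disp[i, 0] = 0.0
                disp[i, 1] = 0.0
                disp[i, 2] = 0.0

        wall_r = wall_r0 + wall_rate * (step + 1) * dt
        st = compute_forces(pos, fnew, nb, pi, pj, npairs, n_real, kbend,
                            fene_k, fene_r0, use_wall, wall_r, box)
        if st != 0:
            return st

        for i in range(n_real):
            for k in range(3):
                vel[i, k] = (a_gjf * vel[i, k]
                             + 0.5 * dt * (a_gjf * f[i, k] + fnew[i, k])
                             + b_gjf * beta[i, k])
                f[i, k] = fnew[i, k]

        if do_recon:
            sweep(pos, nb, pi, pj, npairs, n_real, rc, kbend, fene_k,
                  fene_r0, kT, min_ring, box, touched, cand, ebond, stats)
    return 0
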