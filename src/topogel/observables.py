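"""Geometric and statistical observables of reconnecting-ring trajectories.

Covers the steady-state ring-size distribution and its discrete power-law
fit (maximum likelihood, not histogram slopes), the mixing probability of a
ring with its neighbourhood, the normalized radial monomer density G(r),
and the simulated elution experiment: the confining sphere is replaced by a
spherical mesh of repulsive sites with pores of controlled size and the
number of monomers still inside, n(t), is monitored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar
from scipy.spatial import cKDTree

from .dynamics import IntegratorParams, _chunk_seed, advance_arrays
from .model import ForceField, PeriodicBox, SphericalWall, SystemState
from .topology import RingSet, extract_rings


# ---------------------------------------------------------------------------
# ring-size distribution and power-law fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerLawFit:
    exponent: float          # alpha in P(L) ~ L^-alpha
    lmin: int                # lower cutoff used for the fit
    lmax: int
    n_tail: int              # samples at or above lmin
    ks_distance: float


def _discrete_powerlaw_nll(alpha, logs, lmin, lmax):
    support = np.arange(lmin, lmax + 1, dtype=float)
    z = np.sum(support ** (-alpha))
    return alpha * logs.mean() + math.log(z)


def fit_power_law(lengths, lmin: int | None = None,
                  lmax: int | None = None) -> PowerLawFit:
    """Maximum-likelihood fit of a discrete bounded power law P(L) ~ L^-alpha.

    When ``lmin`` is not given it is chosen by Kolmogorov-Smirnov
    minimization over the observed support (Clauset-style), which avoids
    the bias of histogram-slope fitting.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if len(lengths) < 10:
        raise ValueError("need at least 10 ring lengths to fit")
    if lmax is None:
        lmax = int(lengths.max())

    def fit_at(lm):
        tail = lengths[lengths >= lm]
        logs = np.log(tail.astype(float))
        res = minimize_scalar(
            _discrete_powerlaw_nll, args=(logs, lm, lmax),
            bounds=(0.05, 4.0), method="bounded",
            options={"xatol": 1e-6},
        )
        alpha = float(res.x)
        support = np.arange(lm, lmax + 1, dtype=float)
        pmf = support ** (-alpha)
        pmf /= pmf.sum()
        cdf_model = np.cumsum(pmf)
        emp = np.searchsorted(support, np.sort(tail), side="right")
        cdf_emp = np.arange(1, len(tail) + 1) / len(tail)
        ks = float(np.abs(cdf_model[emp - 1] - cdf_emp).max())
        return alpha, ks, len(tail)

    if lmin is not None:
        alpha, ks, ntail = fit_at(int(lmin))
        return PowerLawFit(alpha, int(lmin), lmax, ntail, ks)

    candidates = np.unique(lengths)
    candidates = candidates[candidates <= np.quantile(lengths, 0.75)]
    candidates = candidates[candidates >= lengths.min()]
    best = None
    for lm in candidates[:50]:
        tail_n = int((lengths >= lm).sum())
        if tail_n < 10:
            continue
        alpha, ks, ntail = fit_at(int(lm))
        if best is None or ks < best[1]:
            best = (alpha, ks, ntail, int(lm))
    if best is None:
        raise ValueError("no usable lower cutoff found")
    alpha, ks, ntail, lm = best
    return PowerLawFit(alpha, lm, lmax, ntail, ks)


def sample_power_law(n: int, alpha: float, lmin: int, lmax: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw n ring lengths from the discrete bounded power law L^-alpha."""
    support = np.arange(lmin, lmax + 1)
    p = support.astype(float) ** (-alpha)
    p /= p.sum()
    return rng.choice(support, size=n, p=p)


@dataclass
class SizeDistribution:
    bin_edges: np.ndarray
    pdf: np.ndarray              # probability density per unit length
    power_law: PowerLawFit
    lengths: np.ndarray = field(repr=False)


def size_distribution(ring_lengths_per_frame, steady_window=None,
                      log_bins: bool = True, n_bins: int = 24,
                      fit_lmin: int | None = None) -> SizeDistribution:
    """Normalized steady-state histogram of ring lengths + its power-law fit.

    ``ring_lengths_per_frame`` is a sequence of per-frame length arrays
    (e.g. ``TrajectoryRecord.ring_lengths``); ``steady_window`` selects the
    frames to pool (default: all).
    """
    frames = list(ring_lengths_per_frame)
    if steady_window is not None:
        frames = frames[steady_window]
    if not frames:
        raise ValueError("empty steady-state window")
    lengths = np.concatenate([np.asarray(f) for f in frames])
    if len(lengths) == 0:
        raise ValueError("no rings in the selected frames")
    lo, hi = lengths.min(), lengths.max()
    if log_bins and hi > lo:
        edges = np.geomspace(lo, hi + 1, n_bins + 1)
    else:
        edges = np.linspace(lo, hi + 1, n_bins + 1)
    counts, edges = np.histogram(lengths, bins=edges)
    widths = np.diff(edges)
    pdf = counts / counts.sum() / widths
    fit = fit_power_law(lengths, lmin=fit_lmin)
    return SizeDistribution(edges, pdf, fit, lengths)


def stationarity_check(values, n_se: float = 2.0) -> bool:
    """Are the first- and second-half means within n_se standard errors?"""
    v = np.asarray(values, dtype=float)
    h = len(v) // 2
    if h < 2:
        return False
    a, b = v[:h], v[h:]
    se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    if se == 0:
        return bool(abs(a.mean() - b.mean()) == 0)
    return bool(abs(a.mean() - b.mean()) <= n_se * se)


# ---------------------------------------------------------------------------
# mixing probability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixingResult:
    probability: float
    empty_neighborhoods: int    # monomers with no neighbour inside the probe


def mixing_probability(state: SystemState, rings: RingSet, ring_index: int,
                       probe_radius: float = 2.0) -> MixingResult:
    """Probability that a bead near this ring's monomers belongs to another ring.

    For each monomer of the ring, count the beads (of any ring, the centre
    bead excluded) inside a probe sphere and take the fraction belonging to
    other rings; average over the ring's monomers.  Monomers with an empty
    probe sphere contribute 0 and are counted in ``empty_neighborhoods``.
    """
    pos = state.positions
    ring = rings.rings[ring_index]
    own = np.zeros(len(pos), dtype=bool)
    own[ring] = True
    tree = cKDTree(pos)
    fractions = []
    empty = 0
    for i in ring:
        idx = tree.query_ball_point(pos[i], probe_radius)
        idx = [j for j in idx if j != i]
        if not idx:
            empty += 1
            fractions.append(0.0)
            continue
        other = sum(1 for j in idx if not own[j])
        fractions.append(other / len(idx))
    return MixingResult(float(np.mean(fractions)), empty)


# ---------------------------------------------------------------------------
# radial density
# ---------------------------------------------------------------------------

@dataclass
class RadialDensity:
    r_edges: np.ndarray
    length_edges: np.ndarray
    g: np.ndarray                # (n_length_bins, n_r_bins), uniform == 1
    counts: np.ndarray

    def total_beads(self) -> float:
        """Integrate g over shells; recovers the bead count per frame."""
        shell = 4.0 / 3.0 * math.pi * np.diff(self.r_edges ** 3)
        v = 4.0 / 3.0 * math.pi * self.r_edges[-1] ** 3
        tot = 0.0
        for b in range(len(self.length_edges) - 1):
            n_b = self.counts[b].sum()
            if n_b == 0:
                continue
            tot += (self.g[b] * shell).sum() * n_b / v
        return tot


def radial_density(frames, radius: float, r_bin: float = 0.25,
                   length_edges=None) -> RadialDensity:
    """G(r) per ring-length bin, normalized so a uniform gas gives G = 1.

    ``frames`` is a sequence of (positions, RingSet) pairs or SystemStates
    under spherical confinement.
    """
    r_edges = np.arange(0.0, radius + r_bin, r_bin)
    norm_frames = []
    for f in frames:
        if isinstance(f, SystemState):
            norm_frames.append((f.positions, extract_rings(f)))
        else:
            norm_frames.append(f)
    if length_edges is None:
        lmax = max(int(rs.lengths.max()) for _, rs in norm_frames)
        length_edges = np.unique(
            np.geomspace(3, max(lmax + 1, 4), 7).astype(int)
        ).astype(float)
    length_edges = np.asarray(length_edges, dtype=float)
    nb_l = len(length_edges) - 1
    counts = np.zeros((nb_l, len(r_edges) - 1))
    for pos, rs in norm_frames:
        for ring, L in zip(rs.rings, rs.lengths):
            b = np.searchsorted(length_edges, L, side="right") - 1
            if b < 0 or b >= nb_l:
                continue
            r = np.linalg.norm(pos[ring], axis=1)
            h, _ = np.histogram(r, bins=r_edges)
            counts[b] += h
    shell = 4.0 / 3.0 * math.pi * np.diff(r_edges ** 3)
    v = 4.0 / 3.0 * math.pi * r_edges[-1] ** 3
    g = np.zeros_like(counts)
    for b in range(nb_l):
        tot = counts[b].sum()
        if tot > 0:
            g[b] = counts[b] / shell / (tot / v)
    return RadialDensity(r_edges, length_edges, g, counts)


# ---------------------------------------------------------------------------
# permeabilized-sphere escape experiment
# ---------------------------------------------------------------------------

def fibonacci_mesh(radius: float, pore_size: float) -> np.ndarray:
    """Immobile repulsive sites on a Fibonacci spherical lattice.

    Site spacing is set to pore_size + 1 sigma (site diameter 1), so the
    openings between sites pass objects up to roughly ``pore_size`` across.
    """
    spacing = pore_size + 1.0
    m = max(int(round((3.809 * radius / spacing) ** 2)), 12)
    k = np.arange(m) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * np.arange(m)
    cos_t = 1.0 - 2.0 * k / m
    sin_t = np.sqrt(1.0 - cos_t**2)
    return radius * np.column_stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t]
    )


@dataclass
class EscapeExperiment:
    pore_size: float
    mesh: np.ndarray
    times: np.ndarray
    n_inside: np.ndarray
    box_length: float
    final_state: SystemState


def permeabilize_and_release(state: SystemState, pore_size: float,
                             post_stiffness: float = 1.0,
                             reconnect: bool = False,
                             run_length: float = 100.0,
                             sample_interval: float = 5.0,
                             ip: IntegratorParams | None = None,
                             ff: ForceField | None = None,
                             box_factor: float = 4.0,
                             rc: float = 1.3,
                             min_ring_length: int = 3) -> EscapeExperiment:
    """Replace the smooth wall by a porous spherical mesh and watch escape.

    The melt is transplanted into a periodic box (edge ``box_factor * R``),
    the wall becomes fixed WCA sites on a Fibonacci lattice at radius R with
    openings of ``pore_size``, the bending constant is set to
    ``post_stiffness`` (the elution protocol resets all systems to the same
    stiffness), reconnection is off unless requested, and n(t) -- the
    number of beads still within radius R of the sphere centre -- is
    recorded every ``sample_interval``.
    """
    if not isinstance(state.box, SphericalWall):
        raise ValueError("escape experiment starts from a confined state")
    if pore_size < 1.0:
        warnings.warn(
            f"pore_size={pore_size} sigma is below the bead diameter; "
            "nothing can escape", stacklevel=2,
        )
    if ip is None:
        ip = IntegratorParams()
    if ff is None:
        ff = ForceField(bending_k=post_stiffness)
    else:
        from dataclasses import replace as _dc_replace
        ff = _dc_replace(ff, bending_k=post_stiffness)
    radius = state.box.radius
    box = box_factor * radius
    if box < 2 * radius + 2:
        raise ValueError("periodic box too small to embed the sphere")
    center = np.array([box / 2.0] * 3)
    mesh = fibonacci_mesh(radius, pore_size)

    n = state.n_beads
    pos = np.vstack([state.positions + center, mesh + center])
    pos -= box * np.floor(pos / box)
    vel = np.vstack([state.velocities, np.zeros_like(mesh)])
    nb = state.neighbor_array()

    n_chunk = int(round(sample_interval / ip.timestep))
    n_samples = int(round(run_length / sample_interval))
    times = [0.0]

    def inside():
        d = pos[:n] - center
        d -= box * np.round(d / box)
        return int((np.linalg.norm(d, axis=1) < radius).sum())

    n_inside = [inside()]
    stats = np.zeros(2, dtype=np.int64)
    for i in range(n_samples):
        advance_arrays(
            pos, vel, nb, n, n_chunk, ip, ff, seed=_chunk_seed(ip.seed, 5, i),
            box=box, reconnect=reconnect, rc=rc, min_ring=min_ring_length,
            bending_k=post_stiffness, stats=stats,
        )
        times.append((i + 1) * sample_interval)
        n_inside.append(inside())

    final = SystemState.from_neighbor_array(
        pos[:n] - center, vel[:n], nb, state.time + run_length,
        PeriodicBox(box),
    )
    return EscapeExperiment(
        pore_size, mesh, np.array(times), np.array(n_inside), box, final
    )


# ---------------------------------------------------------------------------
# escape-curve fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EscapeFit:
    model: str               # "stretched_exponential" or "plateau"
    n0: float
    tau: float
    beta: float
    plateau_fraction: float  # plateau level / n(0)
    sse_stretched: float
    sse_plateau: float
    reliable: bool


def fit_escape_curve(times, n_t) -> EscapeFit:
    """Fit n(t) by a stretched exponential n0 exp(-(t/tau)^beta) or a plateau.

    The model with the smaller squared residual wins.  Series that rise
    substantially over time are flagged unreliable.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(n_t, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 points to fit an escape curve")

    level = y[-max(len(y) // 4, 1):].mean()
    sse_plateau = float(((y - level) ** 2).sum())

    def model(tt, n0, tau, beta):
        return n0 * np.exp(-((tt / tau) ** beta))

    tau0 = max(t[-1] / 3.0, 1e-6)
    try:
        popt, _ = curve_fit(
            model, t, y, p0=[y[0], tau0, 1.0],
            bounds=([0.0, 1e-9, 0.05], [np.inf, np.inf, 4.0]),
            maxfev=20000,
        )
        n0, tau, beta = (float(v) for v in popt)
        sse_str = float(((y - model(t, *popt)) ** 2).sum())
    except RuntimeError:
        n0, tau, beta = float(y[0]), float("inf"), 1.0
        sse_str = float("inf")

    rising = y[-1] > y[0] + 3.0 * y.std()
    if sse_str < sse_plateau:
        return EscapeFit("stretched_exponential", n0, tau, beta,
                         level / max(y[0], 1e-12), sse_str, sse_plateau,
                         not rising)
    return EscapeFit("plateau", float(y[0]), float("inf"), 0.0,
                     level / max(y[0], 1e-12), sse_str, sse_plateau,
                     not rising)
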