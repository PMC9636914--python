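"""Mean-field theory of the short-ring/long-ring transition.

A melt of N beads freely reconnecting into m rings inside a sphere of
volume V carries, per kBT and up to an additive constant,

    F(m) = 2 lp lam pi^2 m^2 / L  +  m log m - m - m log(a V),

with L = N sigma the *total* contour length (each of the m rings then has
length L/m and curvature ~ m/L, the short-ring regime where L/m ~ lp), lam
a shape factor of a curved polymer, and a a numerical factor; lam = 5.3 and
a = 0.27 reproduce the simulated ring numbers.  The combinatorial entropy
comes from the Stirling-number asymptotics {N, m} ~ m^N / m!; its
m-independent part is dropped with the additive constant.  Minimizing F
over m gives the mean ring number <Nr> = m* and mean length <Lr> = N/m*.

Gelation: rings of mean length L_r overlap when their concentration exceeds
c* = 3 L_r / (4 pi sigma Rg^3) with the ideal-ring gyration radius
Rg^2 = L_r lp / 6 for K >= 1 (and Rg^2 = L_r sigma / 12 for K = 0).  The
concentration contributed by one mean-length ring, c = L_r / V, rises with
K while c* falls; their crossing locates the critical stiffness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .model import persistence_length


@dataclass(frozen=True)
class TheoryParams:
    """Parameters of the free energy; lengths in sigma, energies in kBT."""

    n_beads: int = 1000
    radius: float = 7.0
    lam: float = 5.3
    a: float = 0.27
    lp_of_k: object = persistence_length     # K -> lp mapping
    min_ring_length: int = 3
    concentration_mode: str = "mean_ring"    # or "monomer"

    def __post_init__(self) -> None:
        if self.n_beads <= 0 or self.radius <= 0 or self.lam <= 0 \
                or self.a <= 0:
            raise ValueError("all theory parameters must be positive")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3


@dataclass(frozen=True)
class PhasePoint:
    stiffness: float
    m_star: float          # optimal ring number <Nr>
    length_mean: float     # <Lr> = N / m*
    c: float               # ring concentration (sigma^-3)
    c_star: float          # overlap concentration (sigma^-3)

    @property
    def regime(self) -> str:
        return "gel" if self.c > self.c_star else "liquid"


def free_energy(m: float, stiffness: float, params: TheoryParams) -> float:
    """F(m)/kBT at ring number m (continuous)."""
    if m <= 0:
        raise ValueError("ring number m must be positive")
    lp = params.lp_of_k(stiffness)
    n = params.n_beads
    av = params.a * params.volume
    bending = 2.0 * lp * params.lam * math.pi**2 * m**2 / n
    entropy = m * math.log(m) - m - m * math.log(av)
    return bending + entropy


def minimize_ring_number(stiffness: float, params: TheoryParams) -> PhasePoint:
    """Continuous argmin of F(m) over m in [1, N/min_ring_length]."""
    hi = params.n_beads / params.min_ring_length
    res = minimize_scalar(
        lambda m: free_energy(m, stiffness, params),
        bounds=(1.0, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    m_star = float(res.x)
    if m_star <= 1.0 + 1e-6 or m_star >= hi - 1e-6:
        warnings.warn(
            f"free-energy minimum at the bracket boundary (m={m_star:.3g})",
            stacklevel=2,
        )
    length = params.n_beads / m_star
    c_star = overlap_concentration(length, stiffness, params)
    if params.concentration_mode == "monomer":
        c = params.n_beads / params.volume
    else:
        c = length / params.volume
    return PhasePoint(stiffness, m_star, length, c, c_star)


def predicted_ring_numbers(stiffnesses, params: TheoryParams) -> np.ndarray:
    return np.array(
        [minimize_ring_number(k, params).m_star for k in stiffnesses]
    )


def ring_number_exponent(params: TheoryParams, k_min: float = 1.0,
                         k_max: float = 5.0, n_grid: int = 17) -> float:
    """Log-log slope of the predicted <Nr> versus K over [k_min, k_max]."""
    ks = np.linspace(k_min, k_max, n_grid)
    ms = predicted_ring_numbers(ks, params)
    return float(np.polyfit(np.log(ks), np.log(ms), 1)[0])


# ---------------------------------------------------------------------------
# Stirling numbers of the second kind
# ---------------------------------------------------------------------------

def stirling_second_kind(n: int, m: int, method: str = "exact") -> float:
    """log S(n, m), partitions of n labelled beads into m nonempty rings.

    ``method='exact'`` uses the standard recurrence
    S(n, m) = m S(n-1, m) + S(n-1, m-1) with exact integer arithmetic;
    ``method='asymptotic'`` uses the large-n form S(n, m) ~ m^n / m!.
    """
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m <= n, got n={n}, m={m}")
    if method == "asymptotic":
        return n * math.log(m) - math.lgamma(m + 1)
    if method != "exact":
        raise ValueError("method must be 'exact' or 'asymptotic'")
    prev = [0] * (m + 1)
    prev[0] = 1                       # S(0, 0) = 1
    for row in range(1, n + 1):
        cur = [0] * (m + 1)
        for col in range(1, min(row, m) + 1):
            cur[col] = col * prev[col] + prev[col - 1]
        prev = cur
    return math.log(prev[m])


# ---------------------------------------------------------------------------
# overlap concentration and the gelation point
# ---------------------------------------------------------------------------

def gyration_radius_sq(length: float, stiffness: float,
                       params: TheoryParams) -> float:
    """Ideal-ring Rg^2: (L/2lp)(2lp)^2/12 for K >= 1, L sigma/12 at K = 0.

    Between K = 0 and 1 (where neither ideal branch applies) the two are
    linearly interpolated.
    """
    flexible = length / 12.0
    if stiffness <= 0:
        return flexible
    lp = params.lp_of_k(stiffness)
    stiff = (length / (2.0 * lp)) * (2.0 * lp) ** 2 / 12.0
    if stiffness >= 1:
        return stiff
    return (1.0 - stiffness) * flexible + stiffness * stiff


def overlap_concentration(length: float, stiffness: float,
                          params: TheoryParams | None = None) -> float:
    """c* = 3 L / (4 pi sigma Rg^3) in sigma^-3."""
    if params is None:
        params = TheoryParams()
    if length <= 0:
        raise ValueError("length must be positive")
    rg3 = gyration_radius_sq(length, stiffness, params) ** 1.5
    return 3.0 * length / (4.0 * math.pi * rg3)


def gelation_point(params: TheoryParams, k_min: float = 0.5,
                   k_max: float = 6.0, n_grid: int = 23,
                   xtol: float = 1e-6) -> float | None:
    """Critical stiffness where c(K) crosses c*(K).

    Scans a K grid for a sign change of c - c* and bisects it.  Returns
    None when no crossing lies in the sweep ("no transition in range").
    """
    def excess(k):
        p = minimize_ring_number(k, params)
        return p.c - p.c_star

    ks = np.linspace(k_min, k_max, n_grid)
    vals = [excess(k) for k in ks]
    for i in range(len(ks) - 1):
        if vals[i] == 0.0:
            return float(ks[i])
        if vals[i] * vals[i + 1] < 0:
            return float(brentq(excess, ks[i], ks[i + 1], xtol=xtol))
    warnings.warn("no gelation transition in the scanned stiffness range",
                  stacklevel=2)
    return None


def phase_table(params: TheoryParams, stiffnesses) -> "pandas.DataFrame":
    """Tabulate (K, m*, <Lr>, c, c*, regime) for a stiffness sweep."""
    import pandas as pd

    rows = []
    for k in stiffnesses:
        p = minimize_ring_number(k, params)
        rows.append(
            {
                "K": k,
                "m_star": p.m_star,
                "mean_length": p.length_mean,
                "c": p.c,
                "c_star": p.c_star,
                "regime": p.regime,
            }
        )
    return pd.DataFrame(rows)
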