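# Methods

## Model

Rings are Kremer–Grest bead-spring polymers in reduced units
(σ = ε = k_BT = m = 1, friction γ = 1, so the Brownian time τ_B is the
reduced time unit). The energy has four parts:

* **Excluded volume**: purely repulsive Lennard-Jones (WCA) between *all*
  bead pairs, cutoff 2^{1/6}σ, shifted to zero at the cutoff.
* **Bonds**: FENE springs, `U = −½ k R₀² ln(1 − r²/R₀²)` with k = 30 ε/σ²
  and R₀ = 1.5σ. Because the WCA term also acts between bonded beads, a
  bonded pair feels the standard FENE+WCA combination with its minimum
  near r ≈ 0.96σ. The division of labour matters for reconnection: since
  WCA applies to every pair regardless of bonding, rewiring bonds changes
  only FENE and bending terms, never pair or wall terms.
* **Bending**: discrete worm-like-chain (Kratky–Porod) penalty
  `K(1 − cos θ)` per interior angle. The stiffness K is proportional to
  the persistence length; the package's default mapping is the large-K
  limit l_p = Kσ (`model.persistence_length`, replaceable).
* **Wall**: a WCA-form repulsion acting on the distance d = R − |r| to the
  inner surface of the confining sphere, cutoff 2^{1/6}σ.

Bond extension beyond R₀ or a non-finite coordinate aborts the run naming
the offending bead.

## Dynamics

The integrator is the Grønbech-Jensen/Farago discretization of Langevin
dynamics with Δt = 10⁻³ τ_B:

```
b = 1/(1 + γΔt/2),  a = (1 − γΔt/2) b,  β ~ N(0, 2γk_BT Δt)
x' = x + b Δt v + ½ b Δt² f + ½ b Δt β
v' = a v + ½ Δt (a f + f') + b β
```

At γ = 0 this reduces to velocity Verlet (used for energy-conservation
checks). Thermostat deviates are drawn from a PCG64 stream and sweep
randomness from a separately seeded stream; both derive from the master
seed through named `SeedSequence` substreams, so identical configurations
and seeds reproduce trajectories bit for bit.

Pair interactions use a Verlet list built from a cell list
(cutoff = max(2^{1/6}, r_c) + 0.3σ skin, rebuilt when any bead moves more
than half the skin). The same list serves the WCA forces and the
reconnection candidate search.

**Protocol.** A run starts from a single ring of all N beads laid out as a
closed coil wound on a torus (a flat circle for short rings) inside a
large sphere; the wall radius is then ramped linearly down to the target R
and the melt equilibrated at fixed R before reconnection is switched on.
The initial shape is irrelevant — compression and equilibration erase it.
A runtime check warns when the wall moves faster than 0.1 σ/τ_B.

## Reconnection moves

Candidates are bead pairs (a, c) with |r_a − r_c| ≤ r_c (default 1.3σ)
that are not bonded to each other. For each combination of a's bonds
(a,b) and c's bonds (c,d) with four distinct beads and b,d not already
bonded, the move deletes (a,b), (c,d) and creates (a,c), (b,d). The
alternative end-pairing arises as its own candidate (from the proximal
pair (a,d) or (b,c)). Degree 2 is preserved by construction; whether the
move merges two rings, splits one into two, or reverses a contour segment
is determined by traversal. Rewirings that would create a cycle shorter
than `min_ring_length` (default 3, the shortest cycle with defined bending
angles) are excluded.

ΔE contains the FENE terms of the two deleted and two created bonds plus
the four bending angles centred on a, b, c, d — the only terms a rewiring
can change. Acceptance is Metropolis, `min(1, e^{−ΔE/k_BT})` (identical to
the piecewise form with probability 1 for ΔE < 0). One sweep visits all
candidates in uniformly random order after every integration step; a bead
participates in at most one accepted swap per sweep. Proposals with
ΔE > 40 k_BT are rejected without drawing a random number (acceptance
below e⁻⁴⁰ ≈ 4·10⁻¹⁸; the distortion of detailed balance is far below
floating-point resolution). The accepted-swap rate κ_r is reported both
cumulatively and over a trailing window (default 100 τ_B).

**Attempt-rate normalization.** With every proximal candidate attempted at
every step, a flexible melt at ρ ≈ 0.7σ⁻³ accepts on the order of 10³
swaps per τ_B — reconnection is then much faster than conformational
relaxation, and the steady-state *ensemble* (which is what the package's
observables measure) is set by detailed balance, not by the attempt rate.
Published rate constants for comparable systems depend on how many
attempts per step the protocol makes, a bookkeeping choice; the absolute
κ_r should therefore be compared across protocols only up to such a
normalization, while its dependence on stiffness (κ_r falls steeply with
K as bending-costly rewirings are rejected) is protocol-independent.

## Topology

Rings are extracted from the bond graph by deterministic cycle traversal
(lowest unvisited bead first, lower-id neighbour first). For every ring
pair the Gauss linking number is evaluated exactly as a sum over segment
pairs of the signed solid angle of the tetrahedron the two segments span
(the Klenin–Langowski closed form) — no quadrature, integer to 10⁻⁶ for
disjoint closed curves. Ring pairs whose bounding spheres are disjoint are
unlinked and skip the sum. A pair is *linked* when |Lk| > ½ (strictly);
the linked-pair count N_Lk is the edge count of the link network, total
|Lk| the half-sum of |Lk| over ordered pairs, and clusters are connected
components (networkx).

Knots are detected per ring: the polygon is first reduced by repeated
triangle elisions — a vertex is removed when no other segment crosses the
triangle spanned with its two neighbours, an exact segment–triangle test
with conservative handling of coplanar and endpoint-touching cases — and
the Alexander determinant |Δ(−1)| is then read off a crossing diagram in a
randomized generic projection (redrawn on degenerate projections; at
t = −1 the crossing relation is handedness-independent, each crossing row
being +2 on the over-arc and −1 on the two under-arcs, and the determinant
is the absolute value of any cofactor, computed exactly with Bareiss
integer elimination). The determinant is 1 for the unknot, 3 for the
trefoil, 5 for the figure-eight; distinct knots sharing a determinant are
reported with all compatible labels, and rings that do not reduce below
100 vertices (or whose determinant cannot be resolved) are reported
unresolved rather than guessed.

## Mean-field theory

Distributing N beads over m rings costs bending energy and gains entropy:

```
F(m)/k_BT = 2 l_p λ π² m²/L + m log m − m − m log(aV),   L = Nσ
```

Here L is the **total** contour length — each of the m rings then has
length L/m and curvature ~ m/L, the regime where rings are at most a few
persistence lengths long — λ = 5.3 is a shape factor of a curved polymer,
and a = 0.27 calibrates the translational-entropy volume; `m log m − m`
is Stirling's form of log m!, the m-dependent part of the combinatorial
entropy `{N, m} ~ m^N/m!` (the module also provides exact log-Stirling
numbers by recurrence). Minimizing over continuous m ∈ [1, N/3] (bounded
Brent, xatol 10⁻⁸; integer rounding is display-only) yields ⟨N_r⟩ = m*
and ⟨L_r⟩ = N/m*.

Overlap: `c* = 3L_r/(4πσR_g³)` with the ideal-ring gyration radius
`R_g² = L_r l_p/6` for K ≥ 1 and `R_g² = L_r σ/12` for K = 0 (linear
interpolation between the branches on 0 < K < 1, where neither ideal
limit applies — flagged, not asserted). The concentration the mean ring
contributes is taken as `c = L_r(K)/V`; with this (configurable) reading
the `c = c*` crossing falls at K ≈ 2.3 for N = 1000, R = 7σ, consistent
with the percolation onset of the link network. Taking c as the fixed
total monomer concentration instead moves the crossing to K ≈ 0.8; the
per-ring reading is the default because it reproduces the transition
located by the topology observables. The log-log slope of m*(K) over
K ∈ [1, 5] is −0.79 with the defaults; it approaches −1 from above as the
bending term dominates the entropy, so the ⟨N_r⟩ ~ 1/K scaling is an
asymptotic statement about this curve, not its finite-K regression slope.

## Observables

* **Ring-size distribution**: lengths pooled over the steady-state window
  (default: last half of the run, with a first-half/second-half
  stationarity check at 2 SE); fitted by maximum likelihood to a discrete
  bounded power law `P(L) ∝ L^{−α}` on [L_min, L_max], with L_min chosen
  by Kolmogorov–Smirnov minimization — histogram-slope fitting is biased,
  and the KS rule automatically discounts the small-L head where the
  bending penalty suppresses tight rings.
* **Mixing probability**: for each monomer of a ring, the fraction of
  beads inside a probe sphere (default radius 2σ; the centre bead
  excluded, all rings counted in the denominator) that belong to *other*
  rings, averaged over the ring. Monomers with empty probe spheres
  contribute 0 and are flagged.
* **Radial density** G(r): per ring-length bin (logarithmic), monomer
  count per radial shell (width 0.25σ) over shell volume, normalized so a
  uniform gas gives G ≡ 1.
* **Elution experiment**: the smooth wall is replaced by immobile WCA
  sites on a Fibonacci spherical lattice at radius R, spaced
  pore_size + 1σ apart so openings pass objects up to roughly pore_size
  across; the melt is transplanted into a periodic box (edge 4R), the
  stiffness reset to a common value (default K = 1) and reconnection
  disabled, isolating the effect of the accumulated topology; n(t) counts
  beads within R of the sphere centre. n(t) is fitted by a stretched
  exponential `n₀ e^{−(t/τ)^β}` against a constant-plateau alternative,
  selected by residual comparison; rising series are flagged unreliable.

## Scale of the shipped experiments

The full-size study conditions are N = 1000 beads in R = 7σ
(ρ ≈ 0.7σ⁻³, φ ≈ 0.37). The test suite and the acceptance script keep the
density fixed and scale bead numbers and run lengths to what a single CPU
core handles in minutes: melts of 120–240 beads over 10²–10² ⁵ τ_B for
phenomenology (ring-number plateaus, power-law sizes, stiffness trends in
linking, cluster condensation and elution), and the full N = 1000 system
for the flexible-melt reconnection-rate measurement (10³ τ_B window after
compression and burn-in). At 120–240 beads the steady state holds only a
handful of rings at a time, so linked-pair counts are small and stiffness
trends are assessed on time-averages; these runs demonstrate the
mechanisms, not publication-grade statistics. What the synthetic melts do
not emulate of real recombining DNA: sequence heterogeneity and
protein-mediated site specificity of recombination, hydrodynamic
interactions, and topoisomerase-like strand crossing — the model's only
topology-changing operation is the single-site bond swap.

## Numerical choices and degenerate inputs

* Integer snapping tolerance for linking numbers: 10⁻⁶; χ threshold at
  exactly ½, strict inequality on the linked side.
* Gauss solid-angle terms with (nearly) coplanar segment pairs contribute
  zero (their normals degenerate); shared vertices between curves raise
  an error rather than returning a singular integral.
* KMT elision is conservative: degenerate (near-zero-area) triangles and
  ambiguous coplanar contacts block elision — reduction may stall early
  but never changes topology.
* Compression endpoint is set exactly (no floating-point ramp residue);
  sample times are reconstructed from the sample index, not accumulated.
* The pair list capacity assumes at most ~90 neighbours per bead within
  1.6σ; overflow (unphysically dense input) raises instead of truncating.
* `free_energy` at the bracket boundary warns (the flexible limit at
  large aV has its optimum beyond N/min_ring_length).

## Known limitations

* The absolute reconnection rate depends on the attempt-rate normalization
  (see above); only its K-dependence and the steady-state ensemble are
  protocol-independent.
* The Alexander determinant does not separate all knots (4₁ vs 5₁, …);
  reports list all compatible tabled knots, and composite knots are not
  decomposed.
* Escape runs re-enter equilibrium slowly: beads that leave the sphere can
  re-enter through the pores, so n(t) at long times approaches the
  box-partition equilibrium rather than zero.
* No hydrodynamic interactions; friction acts per bead.
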