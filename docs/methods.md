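# Methods

## Model

A walk lives on an undirected graph with sites `n`, edge weights
`J_nm > 0`, edge phases `θ_nm = −θ_mn` and optional on-site energies `ε_n`.
The generator is the Hermitian matrix

    ⟨n|H|m⟩ = J_nm e^{iθ_nm},    ⟨n|H|n⟩ = ε_n ,

with ħ = 1 and couplings in a reference unit, so time is dimensionless
(inverse couplings).  All phases are stored on the canonical edge
orientation lower-index → higher-index and reduced into (−π, π] on every
mutation, giving each graph a unique representation.

**Sign convention.**  Either sign convention for θ is internally
consistent; this package fixes: edge (n, m) with n < m and phase θ
contributes `J e^{iθ}` to ⟨n|H|m⟩.  With this choice a control phase of
**−π/2** on the switch (and triangle-chain) control edges maximally
enhances transport from S toward E, and +π/2 maximally suppresses it;
θ → −θ mirrors the device (E and F trajectories swap exactly).  All
directional statements in code and docs are relative to this convention.

Open-system dynamics is the Lindblad equation

    dρ/dt = −i[H, ρ] + Σ_k c_k ( L_k ρ L_k† − ½{L_k†L_k, ρ} ),  c_k ≥ 0,

with jump operators `L = |target⟩⟨source|` covering site-to-site channels,
pure dephasing `|n⟩⟨n|`, and traps/sinks.  A sink is realized as an
explicit auxiliary absorbing basis state with no Hamiltonian coupling
(rather than as population leakage), so the trace stays 1 and transport
efficiency is directly the sink occupancy.  Several spec entries may feed
one shared sink label (used for the FMO loss channel); their inflows add.

## Gauge calculus

A diagonal unitary `U = diag(e^{iα_n})` maps `H → U H U†`, shifting each
canonical edge phase by `α_n − α_m` while leaving weights, energies and
every site-to-site transfer probability invariant — also under Lindblad
dynamics, because each jump operator picks up a pure phase that cancels
against its conjugate.  Consequences implemented and tested:

* **Loop sums are the invariants.**  `loop_phase_sum` returns the oriented
  flux through a cycle; it is conserved by every gauge to 1e−12.
* **Trees are trivial.**  `remove_tree_phases` sweeps a BFS tree level by
  level, fixing `α_child = α_parent + φ_parent→child`; all phases vanish
  and tree transport equals the achiral walk pointwise.
* **Canonical form.**  `normalize_spanning_tree` zeroes the phases on the
  BFS spanning tree from the lowest-indexed site (neighbours in index
  order — deterministic), concentrating all chirality on co-tree edges,
  whose residual phases are exactly the fundamental-cycle fluxes.

## Propagation routes

* **Unitary:** spectral decomposition of H (`numpy.linalg.eigh`); valid for
  positive and negative times.
* **General Lindblad:** adaptive ODE (`DOP853`, rtol 1e−8 / atol 1e−10) on
  the density matrix, with the drift written as `Kρ + ρK†+ Σ c LρL†`,
  `K = −iH − ½Σ c L†L`.
* **Oracle:** exponentiation of the dense vectorized Liouvillian
  (column-major convention, `vec(AρB) = (Bᵀ⊗A) vec(ρ)`); the test suite
  holds the ODE route to within 1e−7 of it on small systems.
* **Sink-only fast path:** when every channel feeds an absorbing sink and
  the initial state is a pure site state, the in-graph amplitude evolves
  exactly under `H_eff = H − (i/2)Σ c|a⟩⟨a|` (no-jump evolution — jumps
  leave the graph forever), and each sink occupancy is a closed-form sum of
  elementary exponentials.  One 32×32 eigendecomposition replaces a
  1089-dimensional ODE solve; this is what makes ensemble-scale phase
  optimization cheap.  Sink occupancies are monotone here, so half-arrival
  crossings are bracketed on `[0, horizon]` and refined by `brentq`.
* **Small-basis spectral path:** systems with in-graph dissipation (e.g.
  dephasing) and extended basis ≤ 12 states use one dense-Liouvillian
  eigendecomposition per system; larger ones fall back to event-located ODE
  integration (terminal event on the target's diagonal element).

Backward (negative-time) evolution is defined only for the unitary case;
`evolve_lindblad` refuses negative times explicitly.

## Transport metrics

* `half_arrival_time` — earliest `t` with occupancy ≥ ½ (inclusive
  threshold; bisection to 1e−6 time units), `inf` sentinel when the horizon
  (default 100, configurable) is never crossed.  Non-monotone site series
  are scanned on a dense grid (20 points per time unit) before refinement.
* `first_maximum` — first interior local maximum on a 10× refined cubic
  interpolant of a trajectory (grid-aliasing guard); the exact variant
  evaluates the closed-form occupancy instead.  Monotone series return the
  endpoint flagged as a boundary.
* `transport_efficiency` — asymptotic target-sink occupancy; errors out
  unless the total sink inflow rate has dropped below 1e−8 at the horizon.
* `enhancement` — percentage comparisons (speed, first-max ratio, τ
  reduction) between two summaries.

## Phase optimization

Phases of a chosen edge subset are optimized in the box [−π, π] per edge
with L-BFGS-B (finite-difference gradients, step 1e−6, ftol 1e−8) from
`n_restarts` uniformly random seeded start points **plus the baseline
phases as one deterministic start**; the reported best additionally never
falls below the baseline value because the baseline is in the feasible set.
The baseline keeps whatever phases the graph already carries — zero for the
achiral zoo systems, π where a negative coupling is encoded (FMO) — so
"achiral baseline" always means the unmodified system.  Unreachable
targets under some phase assignment are penalized at 10× horizon, letting
the optimizer create reachability.  Results are bit-reproducible given
(seed, n_restarts, tolerances), and the optimum value is gauge-invariant.

## Model zoo: geometry defaults and calibration

The switch and triangle-chain geometries are fixed by calibration and
recorded here as the package defaults:

* **Switch:** central triangle, source wire of 3 sites, E/F wires of 2
  sites (mirror-symmetric — required for the E↔F swap identity), unit
  couplings, control edge opposite the S junction, sink rate 1.  With these
  defaults the first maximum of P_S→E at θ = −π/2 is 2.354× the achiral
  value (a 135.4 % enhancement), the θ-sweep of the first maximum is
  symmetric about ±π/2 with extrema there, and the optimal-phase sink
  efficiency at the preferred pole is 81.55 %.  Behaviour is weakly
  dependent on wire lengths (enhancement stays within ~±5 % over lengths
  1–3); the suppressed-branch first maximum is the one geometry-sensitive
  number (5–11 % of achiral over the same range, 5.95 % at the defaults).
* **Triangle chain:** eight corner-sharing triangles, a pendant input site
  S attached to the first corner, trap (rate 1) on the last corner E, one
  control edge per triangle (the edge opposite the entry corner; the other
  slanted edge is gauge-equivalent).  The pendant source matters: started
  on a bare corner, half of the initial amplitude overlaps a dark subspace
  invisible to the trap and the sink saturates at exactly ½, making τ½
  undefined.  With the pendant, trap occupancy → 1 and the achiral /
  chiral (−π/2) half-arrival times are 38.22 / 5.29 inverse couplings at
  trap rate 1 (a 623 % speed-up).  The acceptance script additionally
  calibrates the trap rate against the achiral value 38.1 (root at
  κ ≈ 0.997) before reporting, treating the rate as the one free parameter.
* **Rings:** unit-weight cycles, optional π phase on one link.  Even rings
  with the π flux suppress the antipodal site exactly (the two path classes
  around the ring acquire opposite signs); odd rings can only be enhanced.
* **Random networks:** connected Watts-Strogatz (and Barabási-Albert)
  realizations, regenerated with incremented sub-seeds (cap 50) when
  disconnected; source/target are a maximally distant pair with ties broken
  toward the lowest indices.
* **FMO:** seven-site exciton Hamiltonian from the shipped YAML config
  (structure-based literature parameterization, cm⁻¹, converted to rad/ps
  via 2πc·1 cm⁻¹ = 0.18837 rad/ps so times are ps).  Negative couplings are
  encoded as phase-π edges, keeping the baseline Hamiltonian real.  Open
  system: per-site dephasing 1 ps⁻¹, trapping 3 → reaction centre 1 ps⁻¹,
  recombination 1 ns⁻¹ from every pigment into a shared loss sink.  The
  optimization edge sets are the seven strongest couplings (A1) and its
  three strongest (A2 ⊂ A1, allowing the A2 optimum to warm-start A1).

## Ensemble experiment

For each rewiring probability p: draw a connected 32-node, mean-degree-4
Watts-Strogatz graph; attach a unit-rate sink at the target of the farthest
pair; measure the achiral sink half-arrival time; optimize the phases of
the target-incident edges (3 restarts by default); record the optimized
time.  Two summary statistics are reported, since "X % less time on
average" admits both: the mean of per-graph percentage reductions and the
percentage reduction of the ensemble-mean arrival time.  At 50 realizations
per p ∈ {0.1, 0.2, 0.4, 0.8} these come out ≈ 44 % and ≈ 57 % respectively,
roughly flat in p; the mean-time reduction is the headline number.  The
horizon is 3000 time units — essentially free in the closed-form path, and
important because truncating slow achiral realizations would discard
exactly the strongest enhancement cases.  Realizations whose achiral walk
never crosses ½ (dark-state-protected targets; a fraction of a percent)
are excluded from both statistics.

Problem sizes used by the test suite and the acceptance script (50
realizations per p, 3 restarts, 8-triangle chains, horizons as above) were
chosen so every quantity is converged at the reported precision while a
full run stays in the minutes range on one core.

## What the synthetic systems do and do not show

The zoo systems are idealized: unit couplings, flat (Markovian) dephasing,
rate-1 traps, no disorder, no vibronic structure.  Passing tests therefore
demonstrate the interference mechanisms — directional biasing, even-ring
suppression, gauge/TRS identities — not quantitative predictions for any
experimental platform.  In particular the FMO config is a conventional
parameterization assembled for methodology work: absolute enhancement
percentages depend strongly on the assumed bath and trapping rates, which
is why the FMO checks are ordering statements (optimized ≥ baseline,
larger edge set ≥ subset) rather than numeric targets.

## Numerical choices and edge cases

* Phases wrapped with `math.remainder` (−π folds to +π); weights must be
  strictly positive; self-loops are rejected (diagonals live in
  `site_energy`).
* τ½ uses the inclusive threshold (≥ ½); bisection tolerance 1e−6 makes
  the open/closed distinction immaterial.
* First-maximum detection ignores flat starts at t = 0 (roundoff guard
  1e−12) and reports boundary maxima explicitly.
* Degenerate Liouvillians: the spectral path assumes diagonalizability
  (generic for these dissipators); the ODE route is the fallback and the
  oracle of record.
* Disconnected graphs are rejected where connectivity is semantically
  required (tree sweeps, spanning-tree normalization, ensemble draws).

## Known limitations

Single-excitation subspace only (no multi-exciton Fock spaces); Markovian
baths only (no structured spectral densities); local phase optimization
with multi-start, without global guarantees; backward evolution undefined
for open systems; the dense-Liouvillian oracle is exponential in system
size and restricted to small instances.
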