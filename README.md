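# chiralwalk

Continuous-time **chiral quantum walks**: quantum transport on graphs whose
hopping amplitudes carry complex phases.

A standard continuous-time quantum walk is generated by a real weighted
adjacency matrix `J` (plus optional on-site energies), which makes the
dynamics time-reversal symmetric: the site-to-site transfer probability
(STP) obeys `P_S→E(t) = P_S→E(−t) = P_E→S(t)`, so transport can never be
directionally biased.  Decorating an edge with a phase,

```
⟨n|H|m⟩ = J_nm · exp(i θ_nm),   θ_mn = −θ_nm,
```

keeps `H` Hermitian but breaks time-reversal symmetry whenever a loop
carries nonzero flux `Σ θ` — and that single extra degree of freedom is
enough to steer, speed up, or completely shut off transport.  This package
simulates those walks (closed and Markovian open-system dynamics), provides
the gauge calculus that classifies which phase patterns can matter, computes
the standard transport metrics, and optimizes phases over chosen edge
subsets.  It is aimed at researchers studying quantum transport on networks,
from exciton transfer in pigment-protein complexes to engineered waveguide
or ion-trap walks.

## What is inside

| module | contents |
| --- | --- |
| `chiralwalk.phased_graph` | `PhasedGraph` (weights, phases, site energies), Hamiltonian assembly, gauge transformations, loop-flux sums, tree-phase removal, spanning-tree canonical form, YAML/TSV graph I/O |
| `chiralwalk.dynamics` | unitary propagation, Lindblad master equation (jump channels, dephasing, absorbing sinks), effective non-Hermitian fast path, dense-Liouvillian oracle, time reversal and TRS diagnostics |
| `chiralwalk.transport_metrics` | half-arrival time τ½ and speed ν½ = 1/τ½, first-maximum detection, asymptotic sink efficiency, percentage enhancement reports |
| `chiralwalk.phase_optimizer` | common-phase sweeps, multi-start bounded phase optimization, random-graph ensemble runner |
| `chiralwalk.model_zoo` | the three-port quantum switch, triangle chains, flux-threaded rings, Watts-Strogatz / Barabási-Albert graphs, a seven-site FMO exciton model |
| `chiralwalk.cli` | `chiralwalk simulate / optimize / ensemble / gauge / zoo` |

Physics guaranteed by construction and verified by the test suite:

* a diagonal gauge transformation shifts edge phases by `α_n − α_m` and
  leaves every STP invariant (unitary *and* open-system);
* loop phase sums are the gauge invariants; phases on trees are removable;
* `P_S→E(−t) = P_E→S(t)` for every Hamiltonian, with equality to
  `P_S→E(t)` exactly in the time-reversal-symmetric (achiral, tree,
  bipartite) cases;
* a π flux on an even ring suppresses antipodal transport exactly, at all
  times, with or without a trap.

## Worked example: the quantum switch

The switch is a triangle junction with three wires ending at poles S, E and
F; one control edge across the junction carries a phase θ.  At θ = 0 the
device is mirror-symmetric, at θ = −π/2 it routes the walker toward E:

```python
import math
import numpy as np
from chiralwalk import evolve_unitary, first_maximum_exact, transport_efficiency
from chiralwalk.model_zoo import make_switch

sw0 = make_switch()                       # achiral reference
S, E = sw0.poles["S"], sw0.poles["E"]
_, p0, _ = first_maximum_exact(sw0.system, S, E, horizon=60)

swE = make_switch(theta=-math.pi / 2)     # bias toward E
_, p1, _ = first_maximum_exact(swE.system, S, E, horizon=60)
print(f"achiral first max {p0:.4f}, chiral {p1:.4f}, "
      f"enhancement {100 * (p1 / p0 - 1):.1f}%")

swk = make_switch(theta=-math.pi / 2, sink_rate=1.0)   # sinks at E and F
eff = transport_efficiency(swk.system, swk.poles["S"], "sink_E", horizon=3000)
print(f"absorbed at the preferred pole: {100 * eff:.1f}%")
```

Output:

```
achiral first max 0.3358, chiral 0.7906, enhancement 135.4%
absorbed at the preferred pole: 81.6%
```

The first maximum of `P_S→E` more than doubles (a ~135 % enhancement over
the achiral switch), and with equal-rate sinks at both output poles about
82 % of the walker is absorbed at the preferred one.  Flipping the sign of
θ routes everything to F instead — the two trajectories swap exactly.

The same mechanism composes: a chain of eight corner-sharing triangles with
a common control phase of −π/2 reaches half occupancy at its trapped end
site roughly seven times sooner than the achiral chain (τ½ ≈ 38 → ≈ 5.3 in
inverse-coupling units), and on random 32-node small-world networks,
optimizing only the handful of phases incident to the target shortens the
mean sink half-arrival time by about half.

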