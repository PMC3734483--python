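"""Ready-made walk systems: switch, triangle chain, cycles, random graphs, FMO.

Each constructor returns a :class:`~chiralwalk.dynamics.WalkSystem` (or a
thin wrapper) with unit hopping weights unless stated otherwise, so time is
measured in inverse-coupling units throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .dynamics import LindbladSpec, WalkSystem
from .phased_graph import PhasedGraph

__all__ = [
    "SwitchSystem",
    "FmoModel",
    "make_switch",
    "make_triangle_chain",
    "make_cycle",
    "make_watts_strogatz",
    "make_barabasi_albert",
    "load_fmo",
    "fmo_example_config",
    "DEFAULT_SINK_RATE",
]

#: Default absorption rate for traps/sinks, in coupling units.  The natural
#: single scale of the problem; configurable everywhere it is used.
DEFAULT_SINK_RATE = 1.0


# -- quantum switch --------------------------------------------------------


@dataclass
class SwitchSystem:
    """Central triangle with three wires to poles S, E and F.

    The wire from pole S attaches to triangle vertex ``in``; the control
    edge is the triangle edge opposite that junction (between the E-side and
    F-side vertices).  With the phase convention of this package, a control
    phase of -pi/2 biases transport toward E and +pi/2 toward F; theta -> -theta
    mirrors the device (swaps the roles of E and F exactly).
    """

    system: WalkSystem
    control_edge: tuple
    wire_length: int
    poles: dict = field(default_factory=dict)  # {"S": ..., "E": ..., "F": ...}

    @property
    def graph(self) -> PhasedGraph:
        return self.system.graph

    def set_control_phase(self, theta: float) -> "SwitchSystem":
        g = self.graph.copy()
        g.set_edge_phase(*self.control_edge, theta)
        return SwitchSystem(
            WalkSystem(g, self.system.lindblad),
            self.control_edge,
            self.wire_length,
            self.poles,
        )


def make_switch(
    wire_length: int = 2,
    theta: float = 0.0,
    sink_rate: float | None = None,
    source_wire_length: int | None = None,
) -> SwitchSystem:
    """Build the three-port quantum switch.

    ``wire_length`` sites per E/F wire (>= 1), the outermost being the pole;
    the source wire has ``source_wire_length`` sites (default: one more than
    the output wires — the calibrated default geometry recorded for this
    fixture).  Unit couplings throughout; ``theta`` goes on the control edge
    only, with theta = -pi/2 maximally biasing transport toward E and
    +pi/2 toward F.  With ``sink_rate`` set, absorbing sinks are attached at
    poles E and F.
    """
    if wire_length < 1:
        raise ValueError("wire_length must be >= 1")
    w = wire_length
    ws = wire_length + 1 if source_wire_length is None else source_wire_length
    if ws < 1:
        raise ValueError("source_wire_length must be >= 1")
    # triangle vertices 0 (S side), 1 (F side), 2 (E side); wires appended
    sites = list(range(3 + ws + 2 * w))
    edges = []
    cursor = 3

    def wire(junction: int, length: int) -> int:
        nonlocal cursor
        prev = junction
        for _ in range(length):
            edges.append((prev, cursor, 1.0, 0.0))
            prev = cursor
            cursor += 1
        return prev  # pole site

    pole_s = wire(0, ws)
    pole_f = wire(1, w)
    pole_e = wire(2, w)
    edges.append((0, 1, 1.0, 0.0))
    edges.append((0, 2, 1.0, 0.0))
    edges.append((1, 2, 1.0, theta))
    g = PhasedGraph(sites, edges)
    spec = LindbladSpec()
    if sink_rate is not None:
        spec = LindbladSpec(
            sinks=[(pole_e, "sink_E", sink_rate), (pole_f, "sink_F", sink_rate)]
        )
    return SwitchSystem(
        WalkSystem(g, spec),
        control_edge=(1, 2),
        wire_length=w,
        poles={"S": pole_s, "E": pole_e, "F": pole_f},
    )


# -- triangle chain --------------------------------------------------------


def make_triangle_chain(
    n_triangles: int = 8,
    theta: float = 0.0,
    trap_rate: float | None = None,
    control: str = "far",
) -> WalkSystem:
    """Chain of corner-sharing triangles with a common control phase.

    Triangle ``i`` occupies sites ``(2i, 2i+1, 2i+2)``; consecutive triangles
    share the even-indexed corner sites.  The source S is a pendant input
    site attached to corner 0 (the input lead of the first switch in the
    composition), and the end site E is the far corner ``2 n_triangles``.
    Every triangle carries one control edge holding the common phase
    ``theta``; theta = -pi/2 gives maximal transport enhancement toward E
    and +pi/2 maximal suppression.  The ``control`` pattern selects the edge
    under the chain's translational symmetry:

    * ``"far"``  — edge (2i+1, 2i+2), opposite the triangle's entry corner
      (the analogue of the switch's control edge; the default);
    * ``"near"`` — edge (2i, 2i+1) (gauge-equivalent to "far": same flux);
    * ``"base"`` — the direct edge (2i, 2i+2) (opposite flux orientation).

    With ``trap_rate`` set, a trap (absorbing sink ``"trap"``) is attached
    at E.  Note the pendant source is essential for trapped transport: with
    the walker started on a bare corner, half the initial amplitude lies in
    a dark subspace invisible to the trap and the sink saturates at 1/2.
    """
    if n_triangles < 1:
        raise ValueError("n_triangles must be >= 1")
    n_core = 2 * n_triangles + 1
    source = n_core  # pendant input site
    sites = list(range(n_core + 1))
    edges = []
    control_edges = []
    for i in range(n_triangles):
        a, b, c = 2 * i, 2 * i + 1, 2 * i + 2
        tri = {"near": (a, b), "far": (b, c), "base": (a, c)}
        ctrl = tri[control]
        for e in [(a, b), (b, c), (a, c)]:
            edges.append((*e, 1.0, theta if e == ctrl else 0.0))
        control_edges.append(ctrl)
    edges.append((0, source, 1.0, 0.0))
    g = PhasedGraph(sites, edges)
    spec = LindbladSpec()
    if trap_rate is not None:
        spec = LindbladSpec(sinks=[(n_core - 1, "trap", trap_rate)])
    system = WalkSystem(g, spec)
    system.control_edges = control_edges  # type: ignore[attr-defined]
    system.source = source  # type: ignore[attr-defined]
    system.target = n_core - 1  # type: ignore[attr-defined]
    return system


# -- cycles ----------------------------------------------------------------


def make_cycle(n_sites: int, pi_edge: bool = False) -> PhasedGraph:
    """Unit-weight ring, optionally with phase pi on exactly one link.

    On an even ring the pi flux makes the two path classes to the antipodal
    site interfere destructively at all times — complete suppression.  Odd
    rings admit enhancement but never complete suppression.
    """
    if n_sites < 3:
        raise ValueError("a cycle needs at least 3 sites")
    edges = [(i, (i + 1) % n_sites, 1.0, 0.0) for i in range(n_sites)]
    if pi_edge:
        edges[0] = (0, 1, 1.0, math.pi)
    return PhasedGraph(list(range(n_sites)), edges)


# -- random networks -------------------------------------------------------


def _from_networkx(gx: nx.Graph) -> PhasedGraph:
    nodes = sorted(gx.nodes())
    return PhasedGraph(nodes, [(u, v, 1.0, 0.0) for u, v in sorted(gx.edges())])


def _connected_realization(builder, seed: int, retries: int = 50) -> PhasedGraph:
    for k in range(retries):
        gx = builder(seed + k)
        if nx.is_connected(gx):
            return _from_networkx(gx)
    raise RuntimeError(f"no connected realization within {retries} attempts")


def make_watts_strogatz(n: int, k: int, p: float, seed: int) -> PhasedGraph:
    """Connected Watts-Strogatz small-world graph, unit weights, zero phases.

    Disconnected draws are regenerated with an incremented sub-seed (cap 50).
    """
    return _connected_realization(
        lambda s: nx.watts_strogatz_graph(n, k, p, seed=s), seed
    )


def make_barabasi_albert(n: int, m: int, seed: int) -> PhasedGraph:
    """Barabasi-Albert scale-free graph, unit weights, zero phases."""
    return _connected_realization(
        lambda s: nx.barabasi_albert_graph(n, m, seed=s), seed
    )


def farthest_pair(g: PhasedGraph) -> tuple:
    """Maximally distant (source, target) pair; ties -> lowest indices.

    The 'oppositely aligned' endpoints used for transport experiments on
    random networks.
    """
    gx = nx.Graph()
    gx.add_nodes_from(range(g.n_sites))
    for a, b, _w, _t in g.edges():
        gx.add_edge(g.site_index(a), g.site_index(b))
    best = (-1, 0, 0)
    lengths = dict(nx.all_pairs_shortest_path_length(gx))
    for i in range(g.n_sites):
        for j in range(i + 1, g.n_sites):
            d = lengths[i][j]
            if d > best[0]:
                best = (d, i, j)
    return g.sites[best[1]], g.sites[best[2]]


# -- FMO -------------------------------------------------------------------


@dataclass
class FmoModel:
    """Seven-site exciton model of the Fenna-Matthews-Olson complex.

    Site energies and couplings (cm^-1) come from the structure-based
    literature parameterizations shipped in the example config; the open
    system includes per-site dephasing (thermal bath), trapping from site 3
    into the reaction-centre sink, and recombination from every site into a
    loss sink.  ``edge_sets`` maps set names (e.g. "A1", "A2") to lists of
    site pairs whose phases are open for optimization.
    """

    system: WalkSystem
    initial_site: int
    target_sink: str
    edge_sets: dict
    energy_unit: str
    time_unit: str

    @property
    def graph(self) -> PhasedGraph:
        return self.system.graph


#: 1 cm^-1 expressed as an angular frequency in rad/ps (2*pi*c*1cm^-1).
CM1_TO_RAD_PER_PS = 0.1883651567


def load_fmo(config_path: str | Path) -> FmoModel:
    """Assemble an FMO model from a YAML parameter config.

    The config supplies ``site_energies`` (cm^-1, length 7), ``couplings``
    (symmetric 7x7, cm^-1), ``dephasing_rate``, ``trap_rate``,
    ``recombination_rate`` (ps^-1), ``trap_site`` (1-based), ``initial_site``
    (1-based) and ``edge_sets`` (lists of 1-based site pairs).  Energies are
    converted to rad/ps via the recorded constant so that time is in ps.
    """
    doc = yaml.safe_load(Path(config_path).read_text())
    for key in (
        "site_energies",
        "couplings",
        "dephasing_rate",
        "trap_rate",
        "recombination_rate",
        "trap_site",
        "initial_site",
    ):
        if key not in doc:
            raise KeyError(f"FMO config missing required field {key!r}")
    energies = np.asarray(doc["site_energies"], dtype=float)
    J = np.asarray(doc["couplings"], dtype=float)
    if J.shape != (len(energies), len(energies)):
        raise ValueError("coupling table shape does not match site energies")
    if not np.allclose(J, J.T, atol=1e-9):
        raise ValueError("coupling table must be symmetric (non-Hermitian input)")
    conv = float(doc.get("cm1_to_rad_per_ps", CM1_TO_RAD_PER_PS))
    n = len(energies)
    sites = list(range(1, n + 1))  # pigment numbering is 1-based
    edges = [
        (i + 1, j + 1, abs(J[i, j]) * conv, math.pi if J[i, j] < 0 else 0.0)
        for i in range(n)
        for j in range(i + 1, n)
        if J[i, j] != 0.0
    ]
    site_energy = {s: (energies[k] - energies.min()) * conv for k, s in enumerate(sites)}
    g = PhasedGraph(sites, edges, site_energy)
    deph = float(doc["dephasing_rate"])
    spec = LindbladSpec(
        dephasing={s: deph for s in sites} if deph > 0 else {},
        sinks=[
            (int(doc["trap_site"]), "reaction_centre", float(doc["trap_rate"])),
        ],
    )
    rec = float(doc["recombination_rate"])
    if rec > 0:
        # one shared loss sink fed from every pigment
        spec.sinks.extend((s, "loss", rec) for s in sites)
    edge_sets = {
        name: [tuple(p) for p in pairs]
        for name, pairs in doc.get("edge_sets", {}).items()
    }
    model = FmoModel(
        system=WalkSystem(g, spec),
        initial_site=int(doc["initial_site"]),
        target_sink="reaction_centre",
        edge_sets=edge_sets,
        energy_unit="cm^-1",
        time_unit="ps",
    )
    return model


def fmo_example_config() -> Path:
    """Path to the packaged example FMO parameter file."""
    return Path(__file__).parent / "data" / "fmo_seven_site.yaml"
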