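"""Graphs with complex-phase edges and the gauge-transformation calculus.

A chiral continuous-time quantum walk is generated by a Hermitian matrix

    <n|H|m> = J_nm * exp(i * theta_nm),   <n|H|n> = eps_n,

where ``J_nm > 0`` is the hopping magnitude of edge ``(n, m)``,
``theta_nm = -theta_mn`` is an antisymmetric edge phase, and ``eps_n`` is an
optional on-site energy.  A real (all phases zero) Hamiltonian gives the
standard, time-reversal symmetric walk; any nonzero phase on an edge that
belongs to a cycle breaks time-reversal symmetry.

Edge phases are gauge degrees of freedom up to loop sums: a diagonal unitary
``U = diag(exp(i alpha_n))`` maps ``H -> U H U†`` and shifts each oriented
edge phase by ``alpha_n - alpha_m`` while leaving every site-to-site transfer
probability unchanged.  The sum of oriented phases around any cycle is the
gauge invariant (a discrete magnetic flux).  Consequently all phases on a
tree can be removed, and on a general graph they can be concentrated on the
co-tree edges of a spanning tree.  This module implements those operations.

Conventions (fixed here, since either sign choice is self-consistent):

* canonical edge orientation is lower site index -> higher site index;
* edge ``(n, m)`` with ``n < m`` and stored phase ``theta`` contributes
  ``J * exp(i*theta)`` to ``<n|H|m>``;
* a gauge vector ``alpha`` acts as ``theta'_nm = theta_nm + alpha_n - alpha_m``
  (so setting ``alpha_n = -theta`` on the first endpoint of an isolated edge
  removes its phase);
* phases are reduced into ``(-pi, pi]`` on every mutation.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PhasedGraph",
    "GaugeVector",
    "Hamiltonian",
    "wrap_phase",
    "to_hamiltonian",
    "apply_gauge",
    "loop_phase_sum",
    "remove_tree_phases",
    "normalize_spanning_tree",
    "read_graph",
    "write_graph",
    "read_edge_list",
    "write_edge_list",
]

_TWO_PI = 2.0 * math.pi


def wrap_phase(theta: float) -> float:
    """Reduce an angle into the half-open interval ``(-pi, pi]``."""
    t = math.remainder(float(theta), _TWO_PI)
    # math.remainder returns values in [-pi, pi]; fold -pi onto +pi.
    if t <= -math.pi:
        t = math.pi
    return t


@dataclass(frozen=True)
class GaugeVector:
    """One phase angle per site, defining the diagonal unitary diag(e^{i alpha_n})."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        a = np.array([wrap_phase(x) for x in a])
        object.__setattr__(self, "alpha", a)

    def __len__(self) -> int:
        return len(self.alpha)


@dataclass(frozen=True)
class Hamiltonian:
    """Complex Hermitian walk generator over an ordered site basis."""

    matrix: np.ndarray
    sites: tuple = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("Hamiltonian matrix must be square")
        if not np.allclose(m, m.conj().T, atol=1e-12):
            raise ValueError("Hamiltonian must be Hermitian to 1e-12")
        object.__setattr__(self, "matrix", m)
        if not self.sites:
            object.__setattr__(self, "sites", tuple(range(m.shape[0])))

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    def site_index(self, site) -> int:
        return self.sites.index(site)


class PhasedGraph:
    """Weighted undirected graph with an antisymmetric phase on each edge.

    Parameters
    ----------
    sites
        Ordered site labels (any hashable; integers by default).
    edges
        Iterable of ``(a, b, weight)`` or ``(a, b, weight, phase)`` tuples.
        The phase is interpreted on the canonical orientation
        lower-index -> higher-index regardless of the order of ``a, b``
        (supplying ``(b, a, w, theta)`` is the same as ``(a, b, w, -theta)``).
    site_energy
        Optional mapping from site label to on-site (diagonal) energy.
    """

    def __init__(
        self,
        sites: Sequence,
        edges: Iterable[tuple] = (),
        site_energy: Mapping | None = None,
    ) -> None:
        self.sites: tuple = tuple(sites)
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate site labels")
        self._index = {s: i for i, s in enumerate(self.sites)}
        self._edges: dict[tuple[int, int], tuple[float, float]] = {}
        for e in edges:
            if len(e) == 3:
                a, b, w = e
                th = 0.0
            else:
                a, b, w, th = e
            self.add_edge(a, b, w, th)
        energy = np.zeros(len(self.sites))
        if site_energy:
            for s, val in site_energy.items():
                energy[self._index[s]] = float(val)
        self.site_energy = energy

    # -- basic structure ---------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self, site) -> int:
        try:
            return self._index[site]
        except KeyError:
            raise KeyError(f"unknown site {site!r}") from None

    def add_edge(self, a, b, weight: float, phase: float = 0.0) -> None:
        i, j = self.site_index(a), self.site_index(b)
        if i == j:
            raise ValueError(f"self-loop on site {a!r} not allowed")
        if weight <= 0:
            raise ValueError("edge weight must be strictly positive")
        if i > j:
            i, j = j, i
            phase = -phase
        self._edges[(i, j)] = (float(weight), wrap_phase(phase))

    def has_edge(self, a, b) -> bool:
        i, j = self.site_index(a), self.site_index(b)
        return (min(i, j), max(i, j)) in self._edges

    def edge_weight(self, a, b) -> float:
        i, j = self.site_index(a), self.site_index(b)
        return self._edges[(min(i, j), max(i, j))][0]

    def edge_phase(self, a, b) -> float:
        """Oriented phase of the edge traversed a -> b (negated vs b -> a)."""
        i, j = self.site_index(a), self.site_index(b)
        w_th = self._edges.get((min(i, j), max(i, j)))
        if w_th is None:
            raise KeyError(f"no edge between {a!r} and {b!r}")
        th = w_th[1]
        return th if i < j else wrap_phase(-th)

    def set_edge_phase(self, a, b, phase: float) -> None:
        """Set the phase of an existing edge, oriented a -> b."""
        i, j = self.site_index(a), self.site_index(b)
        key = (min(i, j), max(i, j))
        if key not in self._edges:
            raise KeyError(f"no edge between {a!r} and {b!r}")
        w = self._edges[key][0]
        self._edges[key] = (w, wrap_phase(phase if i < j else -phase))

    def edges(self) -> list[tuple]:
        """Edges as ``(site_a, site_b, weight, phase)`` in canonical orientation."""
        out = []
        for (i, j), (w, th) in sorted(self._edges.items()):
            out.append((self.sites[i], self.sites[j], w, th))
        return out

    def neighbors(self, site) -> list:
        i = self.site_index(site)
        nbrs = []
        for (a, b) in self._edges:
            if a == i:
                nbrs.append(self.sites[b])
            elif b == i:
                nbrs.append(self.sites[a])
        return sorted(nbrs, key=self._index.__getitem__)

    def copy(self) -> "PhasedGraph":
        g = PhasedGraph(self.sites)
        g._edges = dict(self._edges)
        g.site_energy = self.site_energy.copy()
        return g

    def is_connected(self) -> bool:
        if self.n_sites == 0:
            return True
        seen = {0}
        queue = deque([0])
        adj = self._adjacency_index()
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        return len(seen) == self.n_sites

    def _adjacency_index(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_sites)]
        for (i, j) in self._edges:
            adj[i].append(j)
            adj[j].append(i)
        for lst in adj:
            lst.sort()
        return adj

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhasedGraph):
            return NotImplemented
        return (
            self.sites == other.sites
            and self._edges.keys() == other._edges.keys()
            and all(
                math.isclose(self._edges[k][0], other._edges[k][0], abs_tol=1e-12)
                and math.isclose(
                    wrap_phase(self._edges[k][1] - other._edges[k][1]), 0.0, abs_tol=1e-12
                )
                for k in self._edges
            )
            and np.allclose(self.site_energy, other.site_energy, atol=1e-12)
        )

    def __repr__(self) -> str:
        return f"PhasedGraph(n_sites={self.n_sites}, n_edges={len(self._edges)})"


# -- Hamiltonian construction ---------------------------------------------


def to_hamiltonian(g: PhasedGraph) -> Hamiltonian:
    """Assemble the chiral walk generator H with <n|H|m> = J_nm e^{i theta_nm}."""
    n = g.n_sites
    h = np.zeros((n, n), dtype=complex)
    for (i, j), (w, th) in g._edges.items():
        amp = w * np.exp(1j * th)
        h[i, j] = amp
        h[j, i] = np.conj(amp)
    h[np.diag_indices(n)] = g.site_energy
    return Hamiltonian(h, g.sites)


# -- gauge calculus --------------------------------------------------------


def apply_gauge(g: PhasedGraph, a: GaugeVector) -> PhasedGraph:
    """Re-phase the site basis by diag(e^{i alpha_n}).

    Weights and on-site energies are untouched; each canonical edge phase
    becomes ``theta + alpha_n - alpha_m``.  Site-to-site transfer
    probabilities are invariant under this map, for unitary and for
    Markovian open dynamics alike (jump operators |m><n| pick up a pure
    phase that cancels against the conjugate).
    """
    if len(a) != g.n_sites:
        raise ValueError(
            f"gauge vector length {len(a)} != number of sites {g.n_sites}"
        )
    out = g.copy()
    alpha = a.alpha
    out._edges = {
        (i, j): (w, wrap_phase(th + alpha[i] - alpha[j]))
        for (i, j), (w, th) in g._edges.items()
    }
    return out


def loop_phase_sum(g: PhasedGraph, cycle: Sequence) -> float:
    """Oriented phase sum along a closed walk, reduced to ``(-pi, pi]``.

    This is the discrete flux through the loop — the quantity left invariant
    by every gauge transformation.
    """
    if len(cycle) < 2:
        raise ValueError("cycle must contain at least two sites")
    seq = list(cycle)
    if seq[0] != seq[-1]:
        seq = seq + [seq[0]]
    total = 0.0
    for u, v in zip(seq[:-1], seq[1:]):
        total += g.edge_phase(u, v)  # raises KeyError on a missing edge
    return wrap_phase(total)


def _bfs_tree_gauge(g: PhasedGraph, require_tree: bool) -> GaugeVector:
    """Gauge angles zeroing phases along a BFS spanning forest from site 0.

    The sweep fixes ``alpha`` level by level: crossing tree edge u -> v with
    oriented phase ``phi`` forces ``alpha_v = alpha_u + phi`` so the gauged
    phase ``phi + alpha_u - alpha_v`` vanishes.
    """
    n = g.n_sites
    adj = g._adjacency_index()
    alpha = np.zeros(n)
    visited = [False] * n
    n_tree_edges = 0
    for root in range(n):
        if visited[root]:
            continue
        visited[root] = True
        queue = deque([root])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if not visited[v]:
                    visited[v] = True
                    n_tree_edges += 1
                    alpha[v] = alpha[u] + g.edge_phase(g.sites[u], g.sites[v])
                    queue.append(v)
    if require_tree and n_tree_edges != len(g._edges):
        raise ValueError("graph contains a cycle; expected a tree")
    return GaugeVector(alpha)


def remove_tree_phases(g: PhasedGraph) -> tuple[PhasedGraph, GaugeVector]:
    """Gauge all phases off a tree.

    Returns the phase-free graph and the gauge vector that produced it
    (``apply_gauge(g, gauge)`` reproduces the returned graph).  Raises if the
    graph is disconnected or contains a cycle; use
    :func:`normalize_spanning_tree` for general connected graphs.
    """
    if not g.is_connected():
        raise ValueError("graph is disconnected")
    gauge = _bfs_tree_gauge(g, require_tree=True)
    return apply_gauge(g, gauge), gauge


def normalize_spanning_tree(g: PhasedGraph) -> tuple[PhasedGraph, GaugeVector]:
    """Canonical gauge: zero phases on a BFS spanning tree.

    All chirality is concentrated on the co-tree edges, whose gauged phases
    equal the fundamental-cycle fluxes.  Two gauge-equivalent graphs with the
    same topology map to the same canonical form.  The spanning tree is the
    breadth-first tree from the lowest-indexed site with neighbours visited
    in index order, so the form is deterministic.
    """
    if not g.is_connected():
        raise ValueError("graph is disconnected")
    gauge = _bfs_tree_gauge(g, require_tree=False)
    return apply_gauge(g, gauge), gauge


# -- file I/O --------------------------------------------------------------


def write_graph(g: PhasedGraph, path: str | Path) -> None:
    """Serialize to a YAML document (sites, edges, site_energy)."""
    doc = {
        "sites": list(g.sites),
        "edges": [
            {"a": a, "b": b, "weight": w, "phase": th} for a, b, w, th in g.edges()
        ],
    }
    if np.any(g.site_energy != 0):
        doc["site_energy"] = {
            s: float(e) for s, e in zip(g.sites, g.site_energy) if e != 0
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_graph(path: str | Path) -> PhasedGraph:
    doc = yaml.safe_load(Path(path).read_text())
    edges = [(e["a"], e["b"], e["weight"], e.get("phase", 0.0)) for e in doc["edges"]]
    return PhasedGraph(doc["sites"], edges, doc.get("site_energy"))


def write_edge_list(g: PhasedGraph, path: str | Path) -> None:
    """Write a 4-column tab-separated edge list with a header line."""
    lines = ["site_a\tsite_b\tweight\tphase"]
    for a, b, w, th in g.edges():
        lines.append(f"{a}\t{b}\t{w!r}\t{th!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path, sites: Sequence | None = None) -> PhasedGraph:
    """Read a 4-column tab-separated edge list (header required).

    Site labels are parsed as integers when possible.  If ``sites`` is not
    given, the site set is the sorted union of edge endpoints.
    """
    rows = []
    lines = Path(path).read_text().strip().splitlines()
    for line in lines[1:]:
        a, b, w, th = line.split("\t")
        try:
            a, b = int(a), int(b)
        except ValueError:
            pass
        rows.append((a, b, float(w), float(th)))
    if sites is None:
        sites = sorted({r[0] for r in rows} | {r[1] for r in rows})
    return PhasedGraph(sites, rows)
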