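"""Unitary and Markovian propagation of chiral walks, and time reversal.

Closed-system evolution is ``rho(t) = e^{-iHt} rho(0) e^{iHt}`` (hbar = 1,
couplings in a reference unit, time dimensionless).  Open-system evolution is
the Lindblad master equation

    drho/dt = -i[H, rho] + sum_k c_k ( L_k rho L_k† - 1/2 {L_k† L_k, rho} ),

with jump operators ``L = |target><source|``: site-to-site channels,
pure dephasing ``|n><n|``, and traps/sinks.  A sink is an auxiliary absorbing
basis state attached to a graph site by a one-way jump channel; it carries no
Hamiltonian coupling, so total probability stays 1 and transport efficiency
is directly readable as sink occupancy.

Solvers
-------
Three propagation routes are available, agreeing to tight tolerance (the
dense route is the oracle in the test-suite):

* ``evolve_unitary`` — spectral decomposition of H (exact up to eigensolver
  accuracy).
* ``evolve_lindblad(method="ode")`` — adaptive ODE on the density matrix,
  rtol 1e-8 / atol 1e-10.
* ``evolve_lindblad(method="expm")`` — exponentiation of the dense
  vectorized Liouvillian (small systems; the independent oracle).

When every jump channel feeds an absorbing sink and the initial state is a
pure site state, the dynamics additionally admits an exact pure-state
shortcut: the in-graph amplitude evolves under the effective non-Hermitian
generator ``H_eff = H - (i/2) sum_k c_k L_k† L_k`` (the no-jump evolution;
every jump leaves the graph for good), and each sink fills at rate
``c |<attach|psi(t)>|^2``.  This is used heavily by the metric and
optimization layers; ``method="auto"`` selects it when valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg as sla
from scipy.integrate import solve_ivp

from .phased_graph import Hamiltonian, PhasedGraph, to_hamiltonian

__all__ = [
    "LindbladSpec",
    "DensityState",
    "Trajectory",
    "WalkSystem",
    "evolve_unitary",
    "evolve_lindblad",
    "liouvillian_matrix",
    "time_reverse",
    "check_trs",
    "TrsReport",
    "EffectiveEvolution",
]


# -- specifications --------------------------------------------------------


@dataclass
class LindbladSpec:
    """Jump channels of the dissipator.

    channels   : (source site, target site, rate) with L = |target><source|
    dephasing  : {site: rate} with L = |n><n|
    sinks      : (attached site, sink label, rate); the sink label becomes an
                 auxiliary absorbing basis state with no Hamiltonian coupling.
    """

    channels: list[tuple] = field(default_factory=list)
    dephasing: dict = field(default_factory=dict)
    sinks: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        for *_, rate in self.channels:
            if rate < 0:
                raise ValueError("channel rate must be >= 0")
        for rate in self.dephasing.values():
            if rate < 0:
                raise ValueError("dephasing rate must be >= 0")
        for *_, rate in self.sinks:
            if rate < 0:
                raise ValueError("sink rate must be >= 0")

    @property
    def sink_labels(self) -> list:
        """Unique sink labels in first-appearance order.

        Several entries may feed one shared absorbing state (e.g. a common
        loss sink attached to every site).
        """
        seen: list = []
        for _, label, _ in self.sinks:
            if label not in seen:
                seen.append(label)
        return seen

    def is_empty(self) -> bool:
        return not self.channels and not self.dephasing and not self.sinks

    def absorbing_only(self) -> bool:
        """True when the only dissipation is one-way flow into sinks."""
        return not self.channels and not self.dephasing and bool(self.sinks)

    def jump_operators(self, sites: Sequence) -> list[tuple[np.ndarray, float]]:
        """Dense (L, rate) pairs on the extended basis (sites + sinks)."""
        basis = list(sites) + self.sink_labels
        idx = {s: i for i, s in enumerate(basis)}
        d = len(basis)
        ops = []
        for src, tgt, rate in self.channels:
            L = np.zeros((d, d))
            L[idx[tgt], idx[src]] = 1.0
            ops.append((L, float(rate)))
        for site, rate in self.dephasing.items():
            L = np.zeros((d, d))
            L[idx[site], idx[site]] = 1.0
            ops.append((L, float(rate)))
        for site, label, rate in self.sinks:
            L = np.zeros((d, d))
            L[idx[label], idx[site]] = 1.0
            ops.append((L, float(rate)))
        return ops


@dataclass
class DensityState:
    """Density matrix over the site basis (plus any sink states)."""

    matrix: np.ndarray
    basis: tuple = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=complex)
        object.__setattr__(self, "matrix", m)
        if not self.basis:
            self.basis = tuple(range(m.shape[0]))

    def validate(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.conj().T, atol=1e-10):
            raise ValueError("density matrix not Hermitian to 1e-10")
        if abs(np.trace(m).real - 1.0) > 1e-8:
            raise ValueError("density matrix trace differs from 1 by > 1e-8")
        if np.linalg.eigvalsh(m).min() < -1e-8:
            raise ValueError("density matrix has eigenvalue < -1e-8")

    @classmethod
    def site_basis(cls, site, basis: Sequence) -> "DensityState":
        d = len(basis)
        m = np.zeros((d, d), dtype=complex)
        i = list(basis).index(site)
        m[i, i] = 1.0
        return cls(m, tuple(basis))


@dataclass
class Trajectory:
    """Occupancy time series: diagonal of rho(t) per site (and sink)."""

    times: np.ndarray
    labels: tuple
    occupancy: np.ndarray  # shape (len(times), len(labels))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)

    def series(self, label) -> np.ndarray:
        return self.occupancy[:, list(self.labels).index(label)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.occupancy, columns=[str(s) for s in self.labels]
        ).assign(time=self.times).set_index("time")

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class WalkSystem:
    """A graph plus its dissipator — the unit the metric layer consumes."""

    graph: PhasedGraph
    lindblad: LindbladSpec = field(default_factory=LindbladSpec)

    @property
    def hamiltonian(self) -> Hamiltonian:
        return to_hamiltonian(self.graph)

    @property
    def labels(self) -> tuple:
        return tuple(self.graph.sites) + tuple(self.lindblad.sink_labels)


# -- unitary propagation ---------------------------------------------------


def evolve_unitary(h: Hamiltonian, initial_site, times) -> Trajectory:
    """Occupancies |<m| e^{-iHt} |initial>|^2 via spectral decomposition.

    Negative times are allowed (backward evolution); the walk Hamiltonian is
    time-independent so the propagator is e^{-iHt} for any real t.
    """
    times = np.asarray(times, dtype=float)
    evals, evecs = np.linalg.eigh(h.matrix)
    psi0 = np.zeros(h.n_sites, dtype=complex)
    psi0[h.site_index(initial_site)] = 1.0
    coeff = evecs.conj().T @ psi0
    # psi(t) = V @ (e^{-i evals t} * coeff), vectorized over the time grid
    phases = np.exp(-1j * np.outer(evals, times))  # (n, T)
    psi_t = evecs @ (phases * coeff[:, None])  # (n, T)
    occ = np.abs(psi_t.T) ** 2
    return Trajectory(times, h.sites, occ, {"initial_site": initial_site, "solver": "eigh"})


# -- Lindblad propagation --------------------------------------------------


def _extended_hamiltonian(h: Hamiltonian, spec: LindbladSpec) -> np.ndarray:
    """Embed H into the basis extended by sink states (zero coupling)."""
    n = h.n_sites
    d = n + len(spec.sink_labels)
    hext = np.zeros((d, d), dtype=complex)
    hext[:n, :n] = h.matrix
    return hext


def liouvillian_matrix(h: Hamiltonian, spec: LindbladSpec) -> np.ndarray:
    """Dense superoperator L acting on vec(rho), column-major convention.

    vec(A rho B) = (B.T kron A) vec(rho); used as the small-system oracle.
    """
    hext = _extended_hamiltonian(h, spec)
    d = hext.shape[0]
    eye = np.eye(d)
    sup = -1j * (np.kron(eye, hext) - np.kron(hext.T, eye))
    for L, rate in spec.jump_operators(h.sites):
        LdL = L.conj().T @ L
        sup += rate * (
            np.kron(L.conj(), L)
            - 0.5 * np.kron(eye, LdL)
            - 0.5 * np.kron(LdL.T, eye)
        )
    return sup


class EffectiveEvolution:
    """Exact pure-state propagation when all dissipation flows into sinks.

    Diagonalizes ``H_eff = H - (i/2) sum_s c_s |a_s><a_s|`` once; in-graph
    amplitudes and cumulative sink occupancies then follow in closed form at
    any time.  Writing ``<a|psi(t)> = sum_k w_k e^{-i lambda_k t}``, the sink
    integral ``c * int_0^t |<a|psi>|^2`` is a sum of elementary exponentials.
    """

    def __init__(self, h: Hamiltonian, spec: LindbladSpec, initial_site) -> None:
        if not spec.absorbing_only():
            raise ValueError("EffectiveEvolution requires sink-only dissipation")
        n = h.n_sites
        heff = h.matrix.astype(complex).copy()
        for site, _label, rate in spec.sinks:
            i = h.site_index(site)
            heff[i, i] -= 0.5j * rate
        self.sites = h.sites
        self.spec = spec
        evals, evecs = sla.eig(heff)
        coeff = np.linalg.solve(evecs, _unit_vector(n, h.site_index(initial_site)))
        self._evals = evals
        self._evecs = evecs
        self._coeff = coeff
        # Per sink s with attach index a: <a|psi(t)> = sum_k w_k e^{-i l_k t}
        self._sink_info = []
        for site, label, rate in spec.sinks:
            a = h.site_index(site)
            w = evecs[a, :] * coeff
            self._sink_info.append((label, float(rate), w))
        # pairwise exponents for the closed-form sink integral
        self._pair_exp = -1j * (evals[:, None] - evals.conj()[None, :])

    def amplitudes(self, times) -> np.ndarray:
        """In-graph amplitudes psi(t), shape (n_sites, len(times))."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        phases = np.exp(-1j * np.outer(self._evals, times))
        return self._evecs @ (phases * self._coeff[:, None])

    def sink_occupancy(self, label, times) -> np.ndarray:
        """Cumulative occupancy of one sink: sum of c * int_0^t |<a|psi>|^2 dt'.

        Entries of the spec sharing the label feed the same absorbing state;
        their inflows add.
        """
        times = np.atleast_1d(np.asarray(times, dtype=float))
        entries = [(r, w) for lab, r, w in self._sink_info if lab == label]
        if not entries:
            raise KeyError(f"unknown sink {label!r}")
        # |<a|psi(t)>|^2 = sum_jk w_j conj(w_k) e^{mu_jk t}, mu_jk = -i(l_j - conj(l_k))
        mu = self._pair_exp
        safe_mu = np.where(np.abs(mu) > 1e-12, mu, 1.0)
        out = np.zeros(len(times))
        with np.errstate(divide="ignore", invalid="ignore"):
            for i, t in enumerate(times):
                # int_0^t e^{mu t'} dt' = (e^{mu t} - 1)/mu, -> t as mu -> 0
                integ = np.where(
                    np.abs(mu) > 1e-12, (np.exp(mu * t) - 1.0) / safe_mu, t
                )
                for rate, w in entries:
                    W = np.outer(w, w.conj())
                    out[i] += rate * np.real(np.sum(W * integ))
        return out

    def sink_inflow(self, label, t: float) -> float:
        """Instantaneous filling rate, summed over entries feeding the sink."""
        total = 0.0
        found = False
        for lab, rate, w in self._sink_info:
            if lab == label:
                found = True
                amp = np.sum(w * np.exp(-1j * self._evals * t))
                total += rate * float(np.abs(amp) ** 2)
        if not found:
            raise KeyError(f"unknown sink {label!r}")
        return total

    def trajectory(self, times) -> Trajectory:
        times = np.asarray(times, dtype=float)
        psi = self.amplitudes(times)  # (n, T)
        occ_sites = np.abs(psi.T) ** 2
        cols = [occ_sites]
        for label in self.spec.sink_labels:
            cols.append(self.sink_occupancy(label, times)[:, None])
        occ = np.hstack(cols)
        labels = tuple(self.sites) + tuple(self.spec.sink_labels)
        return Trajectory(times, labels, occ, {"solver": "effective"})


class LiouvillianEvolution:
    """Closed-form Lindblad propagation via dense Liouvillian eigendecomposition.

    Practical for small extended bases (the superoperator is d^2 x d^2); the
    metric layer uses it when jump channels act inside the graph (dephasing,
    relaxation), where no pure-state shortcut exists.  Assumes the
    Liouvillian is diagonalizable — generically true for the dissipators
    built here; the ODE route remains the arbiter in case of doubt.
    """

    def __init__(self, h: Hamiltonian, spec: LindbladSpec, initial_site) -> None:
        self.labels = tuple(h.sites) + tuple(spec.sink_labels)
        d = len(self.labels)
        sup = liouvillian_matrix(h, spec)
        evals, evecs = sla.eig(sup)
        rho0 = DensityState.site_basis(initial_site, self.labels).matrix
        coeff = np.linalg.solve(evecs, rho0.reshape(-1, order="F"))
        self._d = d
        self._evals = evals
        self._evecs = evecs
        self._coeff = coeff

    def occupancy(self, label, times) -> np.ndarray:
        """Diagonal element <label|rho(t)|label> on a vector of times."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        j = self.labels.index(label)
        row = self._evecs[j * self._d + j, :] * self._coeff  # vec index (j,j)
        out = np.real(np.exp(np.outer(times, self._evals)) @ row)
        return out

    def trajectory(self, times) -> Trajectory:
        times = np.asarray(times, dtype=float)
        occ = np.column_stack([self.occupancy(lab, times) for lab in self.labels])
        return Trajectory(times, self.labels, occ, {"solver": "liouvillian-eig"})


def _unit_vector(n: int, i: int) -> np.ndarray:
    v = np.zeros(n, dtype=complex)
    v[i] = 1.0
    return v


def _lindblad_rhs_factory(hext: np.ndarray, ops: list[tuple[np.ndarray, float]]):
    d = hext.shape[0]
    # Precompute the deterministic drift K = -iH - 1/2 sum c L†L so the RHS is
    # K rho + rho K† + sum c L rho L†.
    K = -1j * hext
    jump = []
    for L, rate in ops:
        if rate == 0:
            continue
        K -= 0.5 * rate * (L.conj().T @ L)
        jump.append((np.sqrt(rate) * L,))
    Kd = K.conj().T

    def rhs(_t, y):
        rho = np.ascontiguousarray(y).view(complex).reshape(d, d)
        drho = K @ rho + rho @ Kd
        for (Ls,) in jump:
            drho += Ls @ rho @ Ls.conj().T
        return drho.ravel().view(float)

    return rhs


def evolve_lindblad(
    h: Hamiltonian,
    spec: LindbladSpec,
    initial: DensityState | object,
    times,
    method: str = "auto",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the Lindblad equation and report per-site/sink occupancies.

    ``initial`` may be a DensityState on the extended basis or a site label
    (interpreted as the pure state localized there).  ``method`` is one of
    ``auto`` (pure-state shortcut when valid, else ODE), ``ode``, ``expm``.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError(
            "backward Lindblad evolution is not defined here; negative times "
            "are supported only for unitary dynamics"
        )
    labels = tuple(h.sites) + tuple(spec.sink_labels)
    d = len(labels)

    initial_site = None
    if not isinstance(initial, DensityState):
        initial_site = initial
        rho0 = DensityState.site_basis(initial, labels)
    else:
        rho0 = initial
        if rho0.matrix.shape[0] != d:
            raise ValueError(
                f"initial state dimension {rho0.matrix.shape[0]} != basis size {d}"
            )

    if spec.is_empty():
        if initial_site is None:
            raise ValueError("closed-system limit requires a site-basis initial state")
        return evolve_unitary(h, initial_site, times)

    if method == "auto" and spec.absorbing_only() and initial_site is not None:
        eff = EffectiveEvolution(h, spec, initial_site)
        return eff.trajectory(times)

    hext = _extended_hamiltonian(h, spec)
    ops = spec.jump_operators(h.sites)

    if method == "expm":
        sup = liouvillian_matrix(h, spec)
        occ = np.empty((len(times), d))
        vec0 = rho0.matrix.reshape(-1, order="F")
        for k, t in enumerate(times):
            rho = (sla.expm(sup * t) @ vec0).reshape(d, d, order="F")
            occ[k] = np.diag(rho).real
        return Trajectory(times, labels, occ, {"solver": "expm"})

    rhs = _lindblad_rhs_factory(hext, ops)
    y0 = rho0.matrix.astype(complex).ravel().view(float)
    t_end = float(times[-1]) if len(times) else 0.0
    sol = solve_ivp(
        rhs,
        (0.0, max(t_end, 1e-12)),
        y0,
        t_eval=times,
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"Lindblad integration failed: {sol.message}")
    occ = np.empty((len(times), d))
    for k in range(len(times)):
        rho = np.ascontiguousarray(sol.y[:, k]).view(complex).reshape(d, d)
        occ[k] = np.diag(rho).real
    return Trajectory(
        times, labels, occ, {"solver": "ode", "rtol": rtol, "atol": atol}
    )


# -- time reversal ---------------------------------------------------------


def time_reverse(h: Hamiltonian) -> Hamiltonian:
    """Conjugate H in the site basis: T H T with T = complex conjugation.

    Equivalent to negating every edge phase; real (achiral) walks are fixed
    points.  The transfer probabilities obey
    P[h, S->E](t) = P[time_reverse(h), S->E](-t).
    """
    return Hamiltonian(h.matrix.conj(), h.sites)


@dataclass
class TrsReport:
    """STP series probing time-reversal symmetry between two sites."""

    times: np.ndarray
    forward: np.ndarray          # P_S->E(t)
    backward: np.ndarray         # P_S->E(-t)
    reversed_roles: np.ndarray   # P_E->S(t)
    tolerance: float
    symmetric: bool              # max|forward - backward| <= tolerance

    @property
    def max_asymmetry(self) -> float:
        return float(np.max(np.abs(self.forward - self.backward)))


def check_trs(g: PhasedGraph, source, target, times, tol: float = 1e-8) -> TrsReport:
    """Probe the unitary time-reversal identities between two sites.

    For every Hamiltonian, P_S->E(-t) = P_E->S(t) (an antiunitarity identity).
    Time-reversal symmetry additionally demands P_S->E(t) = P_S->E(-t); it
    holds for achiral walks, for trees, and for bipartite graphs with
    arbitrary phases, but is generically broken by chiral loops.
    """
    times = np.asarray(times, dtype=float)
    h = to_hamiltonian(g)
    fwd = evolve_unitary(h, source, times).series(target)
    bwd = evolve_unitary(h, source, -times).series(target)
    rev = evolve_unitary(h, target, times).series(source)
    sym = bool(np.max(np.abs(fwd - bwd)) <= tol)
    return TrsReport(times, fwd, bwd, rev, tol, sym)
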