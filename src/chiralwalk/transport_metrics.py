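"""Transport figures of merit: half-arrival time, first maximum, efficiency.

The half-arrival time ``tau_half`` is the earliest time the occupancy of the
target site (or sink) reaches one half; the transport speed ``nu_half`` is
its reciprocal.  ``first_maximum`` locates the first apex of the target
occupancy curve — the natural figure of merit for unitary dynamics where the
occupancy oscillates rather than saturates.  ``transport_efficiency`` is the
asymptotic share of probability absorbed by a designated sink when several
absorbing channels compete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .dynamics import (
    EffectiveEvolution,
    LindbladSpec,
    LiouvillianEvolution,
    Trajectory,
    WalkSystem,
    evolve_lindblad,
    evolve_unitary,
)

__all__ = [
    "NOT_REACHED",
    "TransportSummary",
    "half_arrival_time",
    "first_maximum",
    "transport_efficiency",
    "enhancement",
    "occupancy_function",
]

#: Sentinel returned when the target never reaches half occupancy.
NOT_REACHED = math.inf

_DEFAULT_HORIZON = 100.0
_GRID_POINTS_PER_UNIT = 20


@dataclass
class TransportSummary:
    """Bundle of transport metrics for one (source, target) pair."""

    tau_half: float = NOT_REACHED
    first_max_time: float | None = None
    first_max_value: float | None = None
    first_max_at_boundary: bool = False
    efficiency: float | None = None

    @property
    def speed(self) -> float:
        """nu_half = 1 / tau_half (0 when the target is never reached)."""
        return 0.0 if self.tau_half == NOT_REACHED else 1.0 / self.tau_half


def occupancy_function(
    system: WalkSystem, source, target
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized t -> occupancy of ``target`` starting from ``source``.

    Uses the closed-form spectral evaluation: plain eigendecomposition for
    unitary systems, the effective non-Hermitian evolution when dissipation
    is sink-only.  For general Lindblad dynamics there is no closed form;
    callers fall back to grid trajectories from ``evolve_lindblad``.
    """
    spec = system.lindblad
    h = system.hamiltonian
    if spec.is_empty():
        evals, evecs = np.linalg.eigh(h.matrix)
        i, j = h.site_index(source), h.site_index(target)
        w = evecs[j, :] * evecs.conj()[i, :]  # <j|k><k|i> amplitudes

        def occ_unitary(t):
            t = np.atleast_1d(np.asarray(t, dtype=float))
            amps = (w[None, :] * np.exp(-1j * np.outer(t, evals))).sum(axis=1)
            return np.abs(amps) ** 2

        return occ_unitary
    if spec.absorbing_only():
        eff = EffectiveEvolution(h, spec, source)
        if target in spec.sink_labels:
            return lambda t: eff.sink_occupancy(target, t)
        j = h.site_index(target)
        return lambda t: np.abs(eff.amplitudes(t)[j, :]) ** 2
    if h.n_sites + len(spec.sink_labels) <= 12:
        # dense-Liouvillian spectral evaluation stays cheap for small bases
        lv = LiouvillianEvolution(h, spec, source)
        return lambda t: lv.occupancy(target, t)
    raise ValueError("no closed form for general Lindblad dynamics")


def _grid(horizon: float) -> np.ndarray:
    n = max(200, int(horizon * _GRID_POINTS_PER_UNIT)) + 1
    return np.linspace(0.0, horizon, n)


def half_arrival_time(
    system: WalkSystem,
    source,
    target,
    horizon: float = _DEFAULT_HORIZON,
    time_tol: float = 1e-6,
) -> float:
    """Earliest t with occupancy(target, t) >= 1/2, or NOT_REACHED.

    The crossing is bracketed on a dense grid and refined by bisection to
    ``time_tol`` time units.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    spec = system.lindblad
    if spec.absorbing_only() and target in spec.sink_labels:
        # Sink occupancy is monotone non-decreasing, so the earliest crossing
        # is the unique root: bracket on [0, horizon] directly.
        eff = EffectiveEvolution(system.hamiltonian, spec, source)
        f = lambda t: float(eff.sink_occupancy(target, t)[0]) - 0.5
        if f(horizon) < 0:
            return NOT_REACHED
        return float(brentq(f, 0.0, horizon, xtol=time_tol))
    try:
        occ_fn = occupancy_function(system, source, target)
    except ValueError:
        return _tau_half_ode_event(system, source, target, horizon, time_tol)
    times = _grid(horizon)
    occ = occ_fn(times)
    return _first_crossing(occ_fn, times, occ, 0.5, time_tol)


def _tau_half_ode_event(
    system: WalkSystem, source, target, horizon: float, time_tol: float
) -> float:
    """Event-located half crossing for general Lindblad dynamics.

    Integrates the master equation with a terminal event on the target's
    diagonal element; the adaptive solver's root finder locates the earliest
    upward crossing.
    """
    from scipy.integrate import solve_ivp

    from .dynamics import DensityState, _extended_hamiltonian, _lindblad_rhs_factory

    spec = system.lindblad
    h = system.hamiltonian
    labels = tuple(h.sites) + tuple(spec.sink_labels)
    d = len(labels)
    j = list(labels).index(target)
    idx = 2 * (j * d + j)  # real part of rho_jj in the float view
    rhs = _lindblad_rhs_factory(_extended_hamiltonian(h, spec), spec.jump_operators(h.sites))
    y0 = DensityState.site_basis(source, labels).matrix.ravel().view(float)

    def crossing(_t, y):
        return y[idx] - 0.5

    crossing.terminal = True
    crossing.direction = 1
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        y0,
        method="DOP853",
        rtol=1e-8,
        atol=1e-10,
        events=crossing,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"Lindblad integration failed: {sol.message}")
    if sol.t_events[0].size == 0:
        return NOT_REACHED
    return float(sol.t_events[0][0])


def _first_crossing(occ_fn, times, occ, level, time_tol) -> float:
    above = occ >= level
    if not above.any():
        return NOT_REACHED
    k = int(np.argmax(above))
    if k == 0:
        return float(times[0])
    lo, hi = times[k - 1], times[k]
    f = lambda t: float(occ_fn(t)[0]) - level
    try:
        root = brentq(f, lo, hi, xtol=time_tol)
    except ValueError:  # grid point sits exactly on the level
        return float(times[k])
    return float(root)


def first_maximum(
    traj: Trajectory, target, refine: int = 10
) -> tuple[float, float, bool]:
    """First interior local maximum of the target occupancy series.

    The solver grid is refined ``refine``-fold by cubic interpolation before
    peak detection, then the apex is polished on the interpolant.  Returns
    ``(time, value, at_boundary)``; ``at_boundary`` is True when the series
    is monotone over the horizon and the endpoint is returned instead.
    """
    if len(traj.times) < 3:
        raise ValueError("trajectory too short for peak detection")
    from scipy.interpolate import CubicSpline

    y = traj.series(target)
    cs = CubicSpline(traj.times, y)
    tt = np.linspace(traj.times[0], traj.times[-1], refine * len(traj.times))
    yy = cs(tt)
    interior = np.flatnonzero((yy[1:-1] >= yy[:-2]) & (yy[1:-1] >= yy[2:])) + 1
    # skip a spurious peak at t=0 from roundoff-flat starts
    interior = interior[yy[interior] > yy[0] + 1e-12]
    if len(interior) == 0:
        return float(tt[-1]), float(yy[-1]), True
    k = int(interior[0])
    lo, hi = tt[max(k - 1, 0)], tt[min(k + 1, len(tt) - 1)]
    res = minimize_scalar(lambda t: -cs(t), bounds=(lo, hi), method="bounded")
    return float(res.x), float(-res.fun), False


def first_maximum_exact(
    system: WalkSystem, source, target, horizon: float = _DEFAULT_HORIZON
) -> tuple[float, float, bool]:
    """First local maximum evaluated on the closed-form occupancy.

    Like :func:`first_maximum` but free of solver-grid aliasing; valid for
    unitary or sink-only systems.
    """
    occ_fn = occupancy_function(system, source, target)
    tt = _grid(horizon)
    yy = occ_fn(tt)
    interior = np.flatnonzero((yy[1:-1] >= yy[:-2]) & (yy[1:-1] >= yy[2:])) + 1
    interior = interior[yy[interior] > yy[0] + 1e-12]
    if len(interior) == 0:
        return float(tt[-1]), float(yy[-1]), True
    k = int(interior[0])
    res = minimize_scalar(
        lambda t: -float(occ_fn(t)[0]),
        bounds=(tt[k - 1], tt[k + 1]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(-res.fun), False


def transport_efficiency(
    system: WalkSystem,
    source,
    target_sink,
    horizon: float = 400.0,
    inflow_tol: float = 1e-8,
) -> float:
    """Asymptotic occupancy of ``target_sink`` starting from ``source``.

    Integrates until the total sink inflow rate drops below ``inflow_tol``;
    raises if the horizon is too short for convergence (advice: extend it).
    """
    spec = system.lindblad
    if not spec.sinks:
        raise ValueError("transport_efficiency requires at least one sink")
    if spec.absorbing_only():
        eff = EffectiveEvolution(system.hamiltonian, spec, source)
        total_inflow = sum(
            eff.sink_inflow(lab, horizon) for lab in spec.sink_labels
        )
        if total_inflow >= inflow_tol:
            raise RuntimeError(
                f"sink inflow {total_inflow:.2e} at t={horizon} exceeds "
                f"{inflow_tol:.0e}; increase the horizon"
            )
        return float(eff.sink_occupancy(target_sink, np.array([horizon]))[0])
    times = np.linspace(0.0, horizon, max(400, int(horizon * 4)) + 1)
    traj = evolve_lindblad(system.hamiltonian, spec, source, times)
    sink_total = np.sum(
        [traj.series(lab) for lab in spec.sink_labels], axis=0
    )
    dt = times[-1] - times[-2]
    if (sink_total[-1] - sink_total[-2]) / dt >= inflow_tol:
        raise RuntimeError(
            f"sink inflow at t={horizon} exceeds {inflow_tol:.0e}; "
            "increase the horizon"
        )
    return float(traj.series(target_sink)[-1])


def append_metrics_row(path, record: dict) -> None:
    """Append one flat record to a comma-separated results table.

    Creates the file with a header on first use; subsequent rows must share
    the header's keys (extra keys raise).
    """
    import csv
    from pathlib import Path

    path = Path(path)
    exists = path.exists()
    if exists:
        header = path.read_text().splitlines()[0].split(",")
        if set(record) - set(header):
            raise ValueError("record keys do not match existing table header")
    else:
        header = list(record)
    with path.open("a", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=header)
        if not exists:
            writer.writeheader()
        writer.writerow(record)


def enhancement(baseline: TransportSummary, variant: TransportSummary) -> dict:
    """Percentage comparisons of a variant against a baseline.

    Returns ``speed_enhancement_pct`` = 100 (nu_v/nu_b - 1),
    ``first_max_ratio_pct`` = 100 P_max,v / P_max,b, and
    ``tau_reduction_pct`` = 100 (1 - tau_v/tau_b).
    """
    out: dict[str, float] = {}
    if baseline.tau_half == NOT_REACHED:
        raise ValueError("baseline never reaches half occupancy")
    if variant.tau_half == NOT_REACHED:
        out["speed_enhancement_pct"] = -100.0
        out["tau_reduction_pct"] = -math.inf
    else:
        out["speed_enhancement_pct"] = 100.0 * (
            variant.speed / baseline.speed - 1.0
        )
        out["tau_reduction_pct"] = 100.0 * (1.0 - variant.tau_half / baseline.tau_half)
    if baseline.first_max_value and variant.first_max_value is not None:
        out["first_max_ratio_pct"] = (
            100.0 * variant.first_max_value / baseline.first_max_value
        )
    return out
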