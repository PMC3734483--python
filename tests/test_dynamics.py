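import math

import numpy as np
import pytest

from chiralwalk import (
    DensityState,
    LindbladSpec,
    PhasedGraph,
    check_trs,
    evolve_lindblad,
    evolve_unitary,
    liouvillian_matrix,
    time_reverse,
    to_hamiltonian,
)
from chiralwalk.dynamics import EffectiveEvolution
from conftest import random_phased_graph


def two_site_chain():
    return to_hamiltonian(PhasedGraph([0, 1], [(0, 1, 1.0)]))


class TestEvolveUnitary:
    def test_initial_condition_is_localized(self):
        h = two_site_chain()
        traj = evolve_unitary(h, 1, np.array([0.0]))
        assert traj.occupancy[0] == pytest.approx([0.0, 1.0])

    def test_two_site_rabi_closed_form(self):
        """A single bond J=1 transfers with probability sin^2(t)."""
        h = two_site_chain()
        t = np.linspace(0.0, 12.0, 241)
        traj = evolve_unitary(h, 0, t)
        assert np.max(np.abs(traj.series(1) - np.sin(t) ** 2)) < 1e-10

    def test_probability_conserved(self, rng):
        g = random_phased_graph(rng, n_sites=7, extra_edges=3)
        traj = evolve_unitary(to_hamiltonian(g), 0, np.linspace(0, 30, 61))
        assert np.max(np.abs(traj.occupancy.sum(axis=1) - 1.0)) < 1e-8


class TestEvolveLindblad:
    def test_empty_spec_matches_unitary(self, rng):
        g = random_phased_graph(rng, n_sites=4, extra_edges=1)
        h = to_hamiltonian(g)
        t = np.linspace(0, 5, 11)
        a = evolve_lindblad(h, LindbladSpec(), 0, t).occupancy
        b = evolve_unitary(h, 0, t).occupancy
        assert np.max(np.abs(a - b)) < 1e-8

    def test_pure_decay_closed_form(self):
        """h = 0 with a single jump 1 -> 2 at rate 1 empties site 1 as e^-t."""
        g = PhasedGraph([1, 2])
        spec = LindbladSpec(channels=[(1, 2, 1.0)])
        t = np.linspace(0, 6, 61)
        traj = evolve_lindblad(to_hamiltonian(g), spec, 1, t, method="ode")
        assert np.max(np.abs(traj.series(1) - np.exp(-t))) < 1e-8

    def test_ode_matches_superoperator_exponential(self, rng):
        """Independent oracle: dense Liouvillian exponentiation."""
        g = random_phased_graph(rng, n_sites=4, extra_edges=2)
        h = to_hamiltonian(g)
        spec = LindbladSpec(
            channels=[(1, 2, 0.4), (3, 0, 0.15)],
            dephasing={0: 0.2},
            sinks=[(2, "s", 0.6)],
        )
        t = np.linspace(0, 4, 9)
        a = evolve_lindblad(h, spec, 0, t, method="ode").occupancy
        b = evolve_lindblad(h, spec, 0, t, method="expm").occupancy
        assert np.max(np.abs(a - b)) < 1e-7

    def test_effective_evolution_matches_superoperator(self, rng):
        """The pure-state shortcut for sink-only dissipation is exact."""
        g = random_phased_graph(rng, n_sites=5, extra_edges=2)
        h = to_hamiltonian(g)
        spec = LindbladSpec(sinks=[(3, "sA", 0.8), (1, "sB", 0.3)])
        t = np.linspace(0, 8, 17)
        a = evolve_lindblad(h, spec, 0, t, method="auto").occupancy
        b = evolve_lindblad(h, spec, 0, t, method="expm").occupancy
        assert np.max(np.abs(a - b)) < 1e-7

    def test_state_stays_physical_along_trajectory(self, rng):
        g = random_phased_graph(rng, n_sites=4, extra_edges=2)
        h = to_hamiltonian(g)
        spec = LindbladSpec(channels=[(0, 2, 0.5)], dephasing={1: 0.4})
        times = np.linspace(0, 10, 21)
        # re-propagate to each time and validate the full density matrix
        from chiralwalk.dynamics import _extended_hamiltonian, _lindblad_rhs_factory
        from scipy.integrate import solve_ivp

        labels = tuple(h.sites)
        rhs = _lindblad_rhs_factory(
            _extended_hamiltonian(h, spec), spec.jump_operators(h.sites)
        )
        y0 = DensityState.site_basis(0, labels).matrix.ravel().view(float)
        sol = solve_ivp(rhs, (0, 10), y0, t_eval=times, rtol=1e-8, atol=1e-10)
        for k in range(len(times)):
            rho = np.ascontiguousarray(sol.y[:, k]).view(complex).reshape(4, 4)
            DensityState(rho, labels).validate()

    def test_trajectory_time_slices_sum_to_one_with_sinks(self, rng):
        g = random_phased_graph(rng, n_sites=5, extra_edges=2)
        spec = LindbladSpec(sinks=[(4, "trap", 1.0)])
        traj = evolve_lindblad(to_hamiltonian(g), spec, 0, np.linspace(0, 20, 41))
        assert np.max(np.abs(traj.occupancy.sum(axis=1) - 1.0)) < 1e-6

    def test_sink_filling_is_monotone(self, rng):
        g = random_phased_graph(rng, n_sites=5, extra_edges=2)
        spec = LindbladSpec(sinks=[(4, "trap", 0.7)])
        traj = evolve_lindblad(to_hamiltonian(g), spec, 0, np.linspace(0, 30, 301))
        assert np.all(np.diff(traj.series("trap")) >= -1e-10)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            LindbladSpec(channels=[(0, 1, -0.1)])

    def test_backward_time_refused(self):
        h = two_site_chain()
        spec = LindbladSpec(sinks=[(1, "s", 1.0)])
        with pytest.raises(ValueError, match="backward"):
            evolve_lindblad(h, spec, 0, np.array([0.0, -1.0]))

    def test_dimension_mismatch_rejected(self):
        h = two_site_chain()
        spec = LindbladSpec(sinks=[(1, "s", 1.0)])
        bad = DensityState(np.eye(2) / 2, (0, 1))
        with pytest.raises(ValueError, match="dimension"):
            evolve_lindblad(h, spec, bad, np.array([0.0, 1.0]))


class TestDensityState:
    def test_validation_catches_unphysical_matrices(self):
        with pytest.raises(ValueError, match="Hermitian"):
            DensityState(np.array([[0.5, 1.0], [0.0, 0.5]])).validate()
        with pytest.raises(ValueError, match="trace"):
            DensityState(np.eye(2)).validate()
        with pytest.raises(ValueError, match="eigenvalue"):
            DensityState(np.diag([1.5, -0.5])).validate()


class TestTimeReverse:
    def test_achiral_hamiltonian_is_fixed_point(self):
        h = two_site_chain()
        assert np.array_equal(time_reverse(h).matrix, h.matrix)

    def test_phases_negated(self):
        theta = 0.8
        g = PhasedGraph([0, 1, 2], [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0, theta)])
        hr = time_reverse(to_hamiltonian(g))
        gr = PhasedGraph([0, 1, 2], [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0, -theta)])
        assert np.allclose(hr.matrix, to_hamiltonian(gr).matrix)

    def test_reversal_swaps_sign_of_time(self, rng):
        """P[T H T, S->E](t) = P[H, S->E](-t) for arbitrary chiral H."""
        g = random_phased_graph(rng, n_sites=6, extra_edges=3)
        h = to_hamiltonian(g)
        times = np.linspace(0.5, 10, 20)
        fwd = evolve_unitary(time_reverse(h), 0, times).occupancy
        bwd = evolve_unitary(h, 0, -times).occupancy
        assert np.max(np.abs(fwd - bwd)) < 1e-9


class TestCheckTrs:
    times = np.linspace(0.0, 15.0, 31)

    def test_achiral_graph_is_time_symmetric(self):
        g = PhasedGraph([0, 1, 2, 3], [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])
        rep = check_trs(g, 0, 3, self.times)
        assert rep.symmetric
        assert np.max(np.abs(rep.forward - rep.reversed_roles)) < 1e-8

    def test_bipartite_graph_time_symmetric_despite_phases(self, rng):
        # 4-cycle (bipartite) with arbitrary phases on every edge
        g = PhasedGraph(
            [0, 1, 2, 3],
            [
                (0, 1, 1.0, rng.uniform(-3, 3)),
                (1, 2, 1.0, rng.uniform(-3, 3)),
                (2, 3, 1.0, rng.uniform(-3, 3)),
                (3, 0, 1.0, rng.uniform(-3, 3)),
            ],
        )
        rep = check_trs(g, 0, 2, self.times)
        assert rep.symmetric

    def test_chiral_triangle_breaks_trs(self):
        g = PhasedGraph(
            [0, 1, 2], [(0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0, math.pi / 2)]
        )
        rep = check_trs(g, 0, 1, self.times)
        assert not rep.symmetric
        # the antiunitarity identity always holds: P_S->E(-t) = P_E->S(t)
        assert np.max(np.abs(rep.backward - rep.reversed_roles)) < 1e-9

    def test_reversal_identity_holds_for_random_chiral_graphs(self, rng):
        for _ in range(3):
            g = random_phased_graph(rng, n_sites=6, extra_edges=3)
            rep = check_trs(g, 0, 4, self.times)
            assert np.max(np.abs(rep.backward - rep.reversed_roles)) < 1e-9


class TestLiouvillianMatrix:
    def test_preserves_trace_infinitesimally(self, rng):
        """Columns of the superoperator annihilate the trace functional."""
        g = random_phased_graph(rng, n_sites=3, extra_edges=1)
        spec = LindbladSpec(channels=[(0, 1, 0.3)], dephasing={2: 0.5})
        sup = liouvillian_matrix(to_hamiltonian(g), spec)
        d = 3
        tr = np.eye(d).reshape(-1, order="F")
        assert np.max(np.abs(tr @ sup)) < 1e-12


class TestEffectiveEvolution:
    def test_requires_sink_only_dissipation(self):
        h = two_site_chain()
        spec = LindbladSpec(dephasing={0: 0.1})
        with pytest.raises(ValueError, match="sink-only"):
            EffectiveEvolution(h, spec, 0)

    def test_shared_sink_label_accumulates_all_inflow(self):
        # both sites feed one loss sink; eventually everything is lost
        g = PhasedGraph([0, 1], [(0, 1, 1.0)])
        spec = LindbladSpec(sinks=[(0, "loss", 0.5), (1, "loss", 0.5)])
        eff = EffectiveEvolution(to_hamiltonian(g), spec, 0)
        assert eff.sink_occupancy("loss", [200.0])[0] == pytest.approx(1.0, abs=1e-8)
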