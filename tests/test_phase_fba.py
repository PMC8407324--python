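import numpy as np
import pytest

from phasedfba.gem_io import MetabolicNetwork
from phasedfba.phase_fba import (PhaseLP, PhaseSchedule, assemble_problem,
                                 phase_at, phase_spec, scalarize_objective,
                                 solve_pfba)
from phasedfba.reference import vertex_lp_max
from phasedfba.simulator import CultureState
from phasedfba.studies import random_small_network


class TestPhaseAt:
    SCHED = PhaseSchedule(0, 2, 20, 60, 150, 300)

    @pytest.mark.parametrize("t,expected", [
        (0, "lag"),
        (2, "exponential"),     # half-open boundary
        (20, "n_limited"),
        (100, "stationary"),
        (150, "decay"),
        (300, "decay"),
    ])
    def test_interval_lookup(self, t, expected):
        assert phase_at(t, self.SCHED) == expected

    def test_outside_horizon_rejected(self):
        with pytest.raises(ValueError):
            phase_at(-1, self.SCHED)
        with pytest.raises(ValueError):
            phase_at(301, self.SCHED)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            PhaseSchedule(0, 10, 5, 60, 150, 300)


class TestObjectives:
    def test_phase_objectives(self):
        assert phase_spec("lag").objective == (("atp_maintenance", 1.0),)
        assert phase_spec("exponential").objective == (("biomass", 1.0),)
        assert phase_spec("stationary", 0.3).objective == (
            ("protein_production", 1.0), ("atp_maintenance", 0.3))

    def test_scalarization_vector(self, toy):
        net = toy.network
        c = scalarize_objective(phase_spec("stationary", 0.3), net)
        assert c[net.role_index("protein_production")] == 1.0
        assert c[net.role_index("atp_maintenance")] == 0.3
        assert np.count_nonzero(c) == 2
        c0 = scalarize_objective(phase_spec("stationary", 0.0), net)
        assert np.count_nonzero(c0) == 1  # pure protein objective
        ce = scalarize_objective(phase_spec("exponential"), net)
        assert np.count_nonzero(ce) == 1
        assert ce[net.role_index("biomass")] == 1.0

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            phase_spec("stationary", -0.1)

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            phase_spec("bust")


class TestAssemble:
    def test_lag_fixes_growth_and_maximizes_atp(self, toy):
        prob = assemble_problem(toy.network, "lag", toy.init, toy.params)
        j = toy.network.role_index("biomass")
        assert prob.lb[j] == prob.ub[j] == 0.0
        assert prob.c[toy.network.role_index("atp_maintenance")] == 1.0

    def test_stationary_without_protein_shuts_turnover(self, toy):
        state = CultureState.from_vector(toy.init.to_vector(), 3, 4)
        state.Prot = 0.0
        prob = assemble_problem(toy.network, "stationary", state, toy.params)
        for rid in toy.network.amino_acid_exchanges[1:]:
            assert prob.lb[toy.network.rxn_index(rid)] == 0.0

    def test_ngam_floor_only_when_quiescent(self, toy):
        j = toy.network.role_index("atp_maintenance")
        grow = assemble_problem(toy.network, "exponential", toy.init,
                                toy.params)
        quiet = assemble_problem(toy.network, "stationary", toy.init,
                                 toy.params)
        assert grow.lb[j] == 0.0
        assert quiet.lb[j] == toy.params.NGAM

    def test_nitrogen_free_medium_cannot_grow(self, toy):
        state = CultureState.from_vector(toy.init.to_vector(), 3, 4)
        state.NH4 = 0.0
        state.AA = np.zeros(3)
        prob = assemble_problem(toy.network, "n_limited", state, toy.params)
        sol = solve_pfba(prob)
        assert sol.status == "optimal"
        assert sol.mu == pytest.approx(0.0, abs=1e-9)

    def test_negative_state_rejected(self, toy):
        state = CultureState.from_vector(toy.init.to_vector(), 3, 4)
        state.Glx = -5.0
        with pytest.raises(ValueError):
            assemble_problem(toy.network, "exponential", state, toy.params)


class TestSolvePfba:
    def test_no_inputs_no_flux(self, toy):
        state = CultureState(X_A=1.0, X_V=1.0, Prot=0.0, Glx=0.0, F=0.0,
                             Suc=0.0, O2=0.0, NH4=0.0, AA=np.zeros(3),
                             P=np.zeros(4))
        prob = assemble_problem(toy.network, "exponential", state,
                                toy.params)
        sol = solve_pfba(prob)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        assert np.abs(sol.v).max() == pytest.approx(0.0, abs=1e-9)

    def test_steady_state_residual(self, toy):
        prob = assemble_problem(toy.network, "exponential", toy.init,
                                toy.params)
        sol = solve_pfba(prob)
        assert sol.status == "optimal"
        assert np.abs(toy.network.S @ sol.v).max() <= 1e-9

    def test_stage2_preserves_stage1_objective(self, toy):
        prob = assemble_problem(toy.network, "exponential", toy.init,
                                toy.params)
        sol = solve_pfba(prob)
        achieved = float(prob.c @ sol.v)
        floor = sol.objective_value - 1e-6 * max(1.0,
                                                 abs(sol.objective_value))
        assert achieved >= floor - 1e-9

    def test_more_glucose_never_slows_growth(self, toy):
        mus = []
        for glx in (1.0, 5.0, 50.0, 500.0):
            state = CultureState.from_vector(toy.init.to_vector(), 3, 4)
            state.Glx = glx
            sol = solve_pfba(assemble_problem(toy.network, "exponential",
                                              state, toy.params))
            mus.append(sol.mu)
        assert all(b >= a - 1e-9 for a, b in zip(mus, mus[1:]))

    def test_infeasible_status_reported(self, toy):
        prob = assemble_problem(toy.network, "stationary", toy.init,
                                toy.params)
        # demand maintenance ATP while all substrates are shut off
        for rid in toy.network.exchanges:
            j = toy.network.rxn_index(rid)
            prob.lb[j] = prob.ub[j] = 0.0
        prob.lb[toy.network.role_index("atp_maintenance")] = 5.0
        for row in prob.couplings:
            row.active = False
        sol = solve_pfba(prob)
        assert sol.status == "infeasible"

    def test_parsimony_avoids_free_cycles(self, toy):
        """The fructose isomerase is reversible; stage 2 must not carry a
        gratuitous back-and-forth flux through it."""
        state = CultureState.from_vector(toy.init.to_vector(), 3, 4)
        state.F = 0.0  # glucose-only growth
        sol = solve_pfba(assemble_problem(toy.network, "exponential", state,
                                          toy.params))
        assert abs(sol.flux("fru2glc")) <= 1e-9


class TestVertexOracle:
    def test_matches_brute_force_on_random_networks(self, rng):
        """Production two-stage solver against exhaustive vertex
        enumeration on >= 25 random bounded networks (<= 8 reactions)."""
        for _ in range(25):
            S, lb, ub, c = random_small_network(rng)
            S = S[~np.all(S == 0, axis=1)]
            if S.size == 0:
                S = np.zeros((1, len(lb)))
            net = MetabolicNetwork(
                [f"m{i}" for i in range(S.shape[0])],
                [f"r{j}" for j in range(len(lb))], S, lb, ub)
            sol = solve_pfba(PhaseLP(net, "exponential", c, lb.copy(),
                                     ub.copy(), []))
            oracle = vertex_lp_max(S, lb, ub, c)
            assert sol.objective_value == pytest.approx(
                oracle, rel=1e-6, abs=1e-6)
            # parsimonious solution still attains the optimum
            assert c @ sol.v >= oracle - 1e-6 * max(1.0, abs(oracle)) - 1e-9
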