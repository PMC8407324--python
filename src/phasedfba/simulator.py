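"""Batch-culture ODE system with an embedded phase-specific pFBA.

Static-optimization dFBA: every evaluation of the ODE right-hand side
refreshes the biomass composition, assembles the current phase LP from
the medium concentrations, solves it parsimoniously and maps the exchange
fluxes onto concentration derivatives (dC/dt = X_A * v_C).  Active and
viable biomass follow

    dX_A/dt = mu X_V - X_A k_decay + X_A v_Prot - lambda Prot
    dX_V/dt = dX_A/dt - X_V k_Edeath E^n / (E^n + k^n)

with k_decay active only in decay and the protein terms only in
stationary/decay.  Integration is piecewise over the five phase windows
(the integrator restarts at each boundary; the state is continuous,
only derivatives jump).

An auxiliary state accumulates the carbon imported by the cells, so a
whole simulation can be audited for carbon conservation against the
declared per-metabolite carbon counts of the toy network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import biomass as bm
from .gem_io import MetabolicNetwork
from .kinetics import KineticParams, sucrose_hydrolysis_rate
from .phase_fba import (FluxSolution, PhaseSchedule, assemble_problem,
                        binding_constraints, phase_at, reset_solver,
                        solve_pfba)

__all__ = ["CultureState", "Trajectory", "SimulationError", "rhs",
           "simulate", "observe", "default_initial_state"]

QUIESCENT = ("stationary", "decay")
GROWTH = ("lag", "exponential", "n_limited")


class SimulationError(RuntimeError):
    pass


@dataclass
class CultureState:
    """Extracellular concentrations (mmol/L) plus biomass pools (g/L).

    ``AA`` holds the amino acids with proline first; ``P`` the products
    with ethanol, glycerol, acetate first (ethanol doubles as the
    inhibitor/death driver E).  ``C_bio`` is the bookkeeping state for
    carbon imported into cells (mmol C/L).
    """

    X_A: float
    X_V: float
    Prot: float
    Glx: float
    F: float
    Suc: float
    O2: float
    NH4: float
    AA: np.ndarray
    P: np.ndarray
    CO2: float = 0.0
    C_bio: float = 0.0

    def __post_init__(self) -> None:
        self.AA = np.asarray(self.AA, dtype=float)
        self.P = np.asarray(self.P, dtype=float)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            [self.X_A, self.X_V, self.Prot, self.Glx, self.F, self.Suc,
             self.O2, self.NH4], self.AA, self.P, [self.CO2, self.C_bio],
        ])

    @classmethod
    def from_vector(cls, y: np.ndarray, n_aa: int, n_p: int) -> "CultureState":
        return cls(*y[:8], AA=y[8:8 + n_aa].copy(),
                   P=y[8 + n_aa:8 + n_aa + n_p].copy(), CO2=float(y[-2]),
                   C_bio=float(y[-1]))

    def clipped(self) -> "CultureState":
        y = np.maximum(self.to_vector(), 0.0)
        return CultureState.from_vector(y, len(self.AA), len(self.P))

    def names(self, network: MetabolicNetwork) -> list[str]:
        aa = [rid[3:] for rid in network.amino_acid_exchanges]
        prods = [rid[3:] for rid in network.product_exchanges]
        p_names = [prods[0], prods[1], "ace"] + prods[2:]
        return (["X_A", "X_V", "Prot", "Glx", "F", "Suc", "O2", "NH4"]
                + [f"AA_{a}" for a in aa] + [f"P_{p}" for p in p_names]
                + ["CO2", "C_bio"])


def default_initial_state(network: MetabolicNetwork) -> CultureState:
    """Wine-must-like inoculation conditions for the toy network:
    ~150 g/L hexoses, a little sucrose, moderate assimilable nitrogen,
    trace dissolved oxygen and a small starter population."""
    n_aa = len(network.amino_acid_exchanges)
    n_p = len(network.product_exchanges) + 1  # + acetate
    aa = np.full(n_aa, 1.5)
    aa[0] = 3.0  # proline
    return CultureState(
        X_A=0.05, X_V=0.05, Prot=0.018,
        Glx=500.0, F=500.0, Suc=10.0, O2=0.25, NH4=8.0,
        AA=aa, P=np.zeros(n_p),
    )


@dataclass
class Trajectory:
    """Simulation record at the integrator's accepted steps: states, the
    pFBA solution and the phase label at each stored time."""

    times: np.ndarray
    states: np.ndarray            # n_t x n_state
    phases: list[str]
    fluxes: np.ndarray | None     # n_t x n_reactions
    residuals: np.ndarray | None  # max |S v| per stored solve
    state_names: list[str]
    reaction_ids: list[str]
    network: MetabolicNetwork
    params: KineticParams
    schedule: PhaseSchedule

    def state_at(self, t: float) -> np.ndarray:
        return np.array([
            np.interp(t, self.times, self.states[:, k])
            for k in range(self.states.shape[1])
        ])

    def series(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]

    def flux_series(self, rxn_id: str) -> np.ndarray:
        if self.fluxes is None:
            raise ValueError("trajectory was recorded without fluxes")
        return self.fluxes[:, self.reaction_ids.index(rxn_id)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (time, variable, value, phase) table."""
        rows = []
        for k, name in enumerate(self.state_names):
            rows.append(pd.DataFrame({
                "time": self.times, "variable": name,
                "value": self.states[:, k], "phase": self.phases,
            }))
        return pd.concat(rows, ignore_index=True)

    def fluxes_frame(self) -> pd.DataFrame:
        """Long-format (time, reaction, flux) table."""
        if self.fluxes is None:
            raise ValueError("trajectory was recorded without fluxes")
        rows = []
        for j, rid in enumerate(self.reaction_ids):
            rows.append(pd.DataFrame({
                "time": self.times, "reaction": rid,
                "flux": self.fluxes[:, j],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class _Context:
    network: MetabolicNetwork
    params: KineticParams
    schedule: PhaseSchedule
    n_aa: int
    n_p: int
    biomass_update: str = "growth_phases"   # or "n_limited", "never"
    _exchange_cols: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        net = self.network
        cols = {
            "Glx": net.role_index("glucose_exchange"),
            "F": net.role_index("fructose_exchange"),
            "O2": net.role_index("oxygen_exchange"),
            "NH4": net.role_index("ammonium_exchange"),
        }
        for i, rid in enumerate(net.amino_acid_exchanges):
            cols[f"AA{i}"] = net.rxn_index(rid)
        prods = net.product_exchanges
        p_cols = [net.rxn_index(prods[0]), net.rxn_index(prods[1]),
                  net.role_index("acetate_exchange")]
        p_cols += [net.rxn_index(r) for r in prods[2:]]
        for j, cj in enumerate(p_cols):
            cols[f"P{j}"] = cj
        cols["CO2"] = net.rxn_index("EX_co2") if "EX_co2" in net._rxn_index \
            else None
        self._exchange_cols = cols
        self.col_glx = cols["Glx"]
        self.col_fru = cols["F"]
        self.col_o2 = cols["O2"]
        self.col_nh4 = cols["NH4"]
        self.col_co2 = cols["CO2"]
        self.aa_cols = np.array([cols[f"AA{i}"] for i in range(self.n_aa)])
        self.p_cols = np.array(p_cols)
        self.alpha = net.protein_alpha()
        c = net.element_vector("carbon")
        # per-reaction vector: carbon exported per unit exchange flux
        self.exchange_carbon_vec = np.zeros(net.n_reactions)
        for rid in net.exchanges:
            j = net.rxn_index(rid)
            self.exchange_carbon_vec[j] = -float(c @ net.S[:, j])
        self.aa_carbon = np.array([
            net.carbon.get(net._exchange_metabolite(r), 0.0)
            for r in net.amino_acid_exchanges
        ])
        self.turnover_release_carbon = float(
            (self.alpha[1:] * self.aa_carbon[1:]).sum())


def _update_composition(ctx: _Context, state: CultureState, phase: str) -> None:
    p = ctx.params
    do = (ctx.biomass_update == "growth_phases" and phase in GROWTH) or \
         (ctx.biomass_update == "n_limited" and phase == "n_limited")
    if not do:
        return
    comp = bm.compose_biomass(
        bm.protein_content(bm.yan(state), p.A, p.B), p.RNA_to_Prot,
        p.dna_content)
    gam = bm.gam_total(comp, p.GAM_fitted, p.unit_costs)
    bm.update_biomass_reaction(ctx.network, comp, gam)


def _solve_phase(ctx: _Context, t: float, state: CultureState,
                 phase: str) -> FluxSolution:
    _update_composition(ctx, state, phase)
    problem = assemble_problem(ctx.network, phase, state, ctx.params)
    sol = solve_pfba(problem)
    if sol.status != "optimal":
        tight = "; ".join(binding_constraints(problem)[:12])
        raise SimulationError(
            f"pFBA infeasible at t={t:.3f} h (phase {phase}); "
            f"binding constraints: {tight}"
        )
    return sol


def rhs(t: float, y: np.ndarray, ctx: _Context,
        phase: str | None = None) -> np.ndarray:
    """Derivative of the culture state vector at time t.

    Fixed layout: [X_A, X_V, Prot, Glx, F, Suc, O2, NH4, AA..., P...,
    CO2, C_bio].
    """
    p = ctx.params
    state = CultureState.from_vector(np.maximum(y, 0.0), ctx.n_aa, ctx.n_p)
    if phase is None:
        phase = phase_at(t, ctx.schedule)
    quiescent = phase in QUIESCENT

    dy = np.zeros_like(y)
    hyd = sucrose_hydrolysis_rate(state.Suc, p.k_hydro)
    dy[5] = -hyd        # sucrose -> glucose + fructose in the medium
    dy[3] += hyd
    dy[4] += hyd

    if state.X_A <= 1e-9:
        return dy

    sol = _solve_phase(ctx, t, state, phase)
    v = sol.v
    X_A, X_V, Prot = state.X_A, state.X_V, state.Prot

    dy[3] += X_A * v[ctx.col_glx]
    dy[4] += X_A * v[ctx.col_fru]
    dy[6] = X_A * v[ctx.col_o2]
    dy[7] = X_A * v[ctx.col_nh4]
    dy[8:8 + ctx.n_aa] = X_A * v[ctx.aa_cols]
    if quiescent:
        # turnover release into the medium; proline is excretion-only
        dy[9:8 + ctx.n_aa] += p.lam * Prot * ctx.alpha[1:]
    dy[8 + ctx.n_aa:8 + ctx.n_aa + ctx.n_p] = X_A * v[ctx.p_cols]
    if ctx.col_co2 is not None:
        dy[-2] = X_A * v[ctx.col_co2]

    mu, v_Prot = sol.mu, sol.v_Prot
    prot_content = bm.protein_content(bm.yan(state), p.A, p.B)
    dX_A = mu * X_V
    dProt = mu * X_V * prot_content
    if phase == "decay":
        dX_A -= X_A * p.k_decay
        dProt -= Prot * p.k_death
    if quiescent:
        dX_A += X_A * v_Prot - p.lam * Prot
        dProt += X_A * v_Prot - p.lam * Prot
    E = state.P[0]
    En = E ** p.n_hill
    hill = p.k_Edeath * En / (En + p.k_hill ** p.n_hill)
    dy[0] = dX_A
    dy[1] = dX_A - X_V * hill
    dy[2] = dProt

    # carbon imported into cells, minus turnover release back to the medium
    carbon_in = -X_A * float(v @ ctx.exchange_carbon_vec)
    if quiescent:
        carbon_in -= p.lam * Prot * ctx.turnover_release_carbon
    dy[-1] = carbon_in
    return dy


def simulate(params: KineticParams, network: MetabolicNetwork,
             schedule: PhaseSchedule, init: CultureState,
             t_grid: np.ndarray | None = None, *, rtol: float = 1e-6,
             atol: float = 1e-9, method: str = "LSODA",
             store_fluxes: bool = True,
             biomass_update: str = "growth_phases") -> Trajectory:
    """Integrate a full batch, restarting the integrator at every phase
    boundary; returns the trajectory at the accepted solver steps (plus
    any requested ``t_grid`` points).
    """
    y0 = init.to_vector()
    if np.any(y0[:-1] < 0):
        raise ValueError("initial state must be non-negative")
    n_aa, n_p = len(init.AA), len(init.P)
    ctx = _Context(network, params, schedule, n_aa, n_p, biomass_update)
    reset_solver(network)  # history-independent degenerate tie-breaking

    times, states, phases = [], [], []
    bounds = schedule.boundaries()
    y = y0.copy()
    for a, b, label in zip(bounds[:-1], bounds[1:],
                           ("lag", "exponential", "n_limited", "stationary",
                            "decay")):
        if b <= a:
            continue
        t_eval = None
        if t_grid is not None:
            inside = t_grid[(t_grid >= a) & (t_grid <= b)]
            t_eval = np.unique(np.concatenate([[a], inside, [b]]))
        sol = solve_ivp(
            rhs, (a, b), y, method=method, rtol=rtol, atol=atol,
            dense_output=False, t_eval=t_eval, args=(ctx, label),
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed in phase {label}: {sol.message}")
        if not np.all(np.isfinite(sol.y)):
            raise SimulationError(f"non-finite state in phase {label}")
        times.append(sol.t)
        states.append(sol.y.T)
        phases.extend([label] * len(sol.t))
        y = sol.y[:, -1].copy()

    times = np.concatenate(times)
    states = np.vstack(states)

    if states.min() < -1e-6:
        k = int(np.argmin(states.min(axis=0)))
        raise SimulationError(
            f"state {init.names(network)[k]} went significantly negative")
    states = np.maximum(states, 0.0)

    fluxes = residuals = None
    if store_fluxes:
        fluxes = np.zeros((len(times), network.n_reactions))
        residuals = np.zeros(len(times))
        for k, (t, label) in enumerate(zip(times, phases)):
            state = CultureState.from_vector(states[k], n_aa, n_p).clipped()
            if state.X_A > 1e-9:
                sol = _solve_phase(ctx, t, state, label)
                fluxes[k] = sol.v
                # audit against the S matrix in force for this solve (the
                # biomass column is rewritten dynamically)
                residuals[k] = float(np.abs(network.S @ sol.v).max())

    return Trajectory(times, states, phases, fluxes, residuals,
                      init.names(network), list(network.reaction_ids),
                      network, params, schedule)


def observe(traj: Trajectory, c_CFU: float | None = None,
            c_OD: float | None = None) -> pd.DataFrame:
    """Observation table: CFU = c_CFU * X_V, OD = c_OD * X_A, identity for
    concentrations and dry weight."""
    if c_CFU is None:
        c_CFU = traj.params.c_CFU
    if c_OD is None:
        c_OD = traj.params.c_OD
    if c_CFU <= 0 or c_OD <= 0:
        raise ValueError("observation scalings must be positive")
    df = pd.DataFrame({"time": traj.times})
    for name in traj.state_names:
        if name != "C_bio":
            df[name] = traj.series(name)
    df["CFU"] = c_CFU * traj.series("X_V")
    df["OD"] = c_OD * traj.series("X_A")
    return df
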