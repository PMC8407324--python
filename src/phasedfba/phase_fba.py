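"""Phase scheduling and the phase-specific parsimonious FBA problem.

Batch fermentation is split into five phases with distinct cellular
objectives and constraint sets:

==============  ======================  =================================
phase           objective               notable constraints
==============  ======================  =================================
lag             maximize ATP            growth fixed to 0; O2 available
exponential     maximize growth         kinetic uptake bounds
n_limited       maximize growth         kinetic bounds, falling YAN
stationary      max v_Prot + phi*v_ATP  turnover AA bounds, proline
                                        coupling, NGAM floor, growth 0
decay           max v_Prot + phi*v_ATP  as stationary
==============  ======================  =================================

Each solve is parsimonious: stage 1 maximizes the scalarized phase
objective, stage 2 fixes that optimum (to 1e-6 relative) and minimizes
the total flux load sum(|v|).  The LP backend keeps two persistent GLPK
problems per network structure and mutates bounds/objective in place, so
a re-solve inside the ODE right-hand side costs microseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import swiglpk as glp

from . import kinetics as kin
from .biomass import BiomassComposition
from .gem_io import MetabolicNetwork
from .kinetics import KineticParams

__all__ = [
    "PhaseSchedule",
    "PhaseSpec",
    "PhaseLP",
    "FluxSolution",
    "InfeasibleProblem",
    "phase_at",
    "phase_spec",
    "scalarize_objective",
    "assemble_problem",
    "solve_pfba",
    "fba",
]

PHASES = ("lag", "exponential", "n_limited", "stationary", "decay")
_INF = 1000.0
_DEPLETION = 1e-12  # below this concentration a substrate's uptake is shut


class InfeasibleProblem(RuntimeError):
    """Raised when a phase LP stays infeasible after the slack retry."""


@dataclass(frozen=True)
class PhaseSchedule:
    """Phase switch times (h): lag ends at tL, growth at tE, nitrogen-
    limited growth at tS, stationary at tD, the process at tF."""

    t0: float
    tL: float
    tE: float
    tS: float
    tD: float
    tF: float

    def __post_init__(self) -> None:
        ts = (self.t0, self.tL, self.tE, self.tS, self.tD, self.tF)
        if any(a > b for a, b in zip(ts, ts[1:])):
            raise ValueError(f"phase times must be non-decreasing: {ts}")

    @classmethod
    def from_params(cls, params: KineticParams, t0: float = 0.0,
                    tF: float = 250.0) -> "PhaseSchedule":
        return cls(t0, params.t_L, params.t_E, params.t_S, params.t_D, tF)

    def boundaries(self) -> list[float]:
        return [self.t0, self.tL, self.tE, self.tS, self.tD, self.tF]

    def window(self, label: str) -> tuple[float, float]:
        starts = dict(zip(PHASES, self.boundaries()[:-1]))
        ends = dict(zip(PHASES, self.boundaries()[1:]))
        return starts[label], ends[label]


def phase_at(t: float, schedule: PhaseSchedule) -> str:
    """Phase label at time t; intervals are half-open [start, end) except
    the final decay interval which includes tF."""
    if t < schedule.t0 or t > schedule.tF:
        raise ValueError(f"t={t} outside [{schedule.t0}, {schedule.tF}]")
    for label, end in zip(PHASES[:-1], schedule.boundaries()[1:-1]):
        if t < end:
            return label
    return "decay"


@dataclass(frozen=True)
class PhaseSpec:
    """Objective and constraint switches of one phase."""

    label: str
    objective: tuple[tuple[str, float], ...]
    NGAM_active: bool
    active_constraints: frozenset[str] = frozenset()


def phase_spec(label: str, phi: float = 0.0) -> PhaseSpec:
    """Build the PhaseSpec for a phase label; phi weights ATP against
    protein in the quiescent-phase objective."""
    if phi < 0:
        raise ValueError("phi must be non-negative")
    if label == "lag":
        return PhaseSpec(label, (("atp_maintenance", 1.0),), False,
                         frozenset({"no_growth", "product_coupling"}))
    if label in ("exponential", "n_limited"):
        return PhaseSpec(label, (("biomass", 1.0),), False,
                         frozenset({"product_coupling"}))
    if label in ("stationary", "decay"):
        return PhaseSpec(
            label,
            (("protein_production", 1.0), ("atp_maintenance", phi)),
            True,
            frozenset({"no_growth", "product_coupling", "turnover_bounds",
                       "proline_coupling", "ngam"}),
        )
    raise ValueError(f"unknown phase {label!r}")


def scalarize_objective(spec: PhaseSpec, network: MetabolicNetwork) -> np.ndarray:
    """Weighted-sum objective vector c over reactions."""
    c = np.zeros(network.n_reactions)
    for role, weight in spec.objective:
        c[network.role_index(role)] += weight
    return c


@dataclass
class CouplingRow:
    """Equality row  coef . v = 0  that ties fluxes together (product
    secretion to hexose transport, proline excretion likewise)."""

    name: str
    cols: np.ndarray      # reaction indices
    coefs: np.ndarray
    active: bool


@dataclass
class PhaseLP:
    """A fully assembled phase LP: bounds, objective and coupling rows."""

    network: MetabolicNetwork
    label: str
    c: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    couplings: list[CouplingRow] = field(default_factory=list)


@dataclass
class FluxSolution:
    """pFBA solution: flux vector plus the named fluxes the ODEs consume."""

    v: np.ndarray
    objective_value: float
    status: str
    reaction_ids: list[str]
    mu: float = 0.0
    v_Prot: float = 0.0
    v_ATP: float = 0.0

    def flux(self, rxn_id: str) -> float:
        return float(self.v[self.reaction_ids.index(rxn_id)])


def coupling_layout(network: MetabolicNetwork) -> list[tuple[str, np.ndarray]]:
    """Fixed ordering of potential coupling rows for a network: one per
    hexose-coupled product, one for acetate, one for proline.  Each entry
    is (name, [product_col, glx_col, fru_col])."""
    if "glucose_exchange" not in network.special:
        return []  # bare stoichiometric model without fermentation roles
    jg = network.role_index("glucose_exchange")
    jf = network.role_index("fructose_exchange")
    rows = []
    for k, rid in enumerate(network.product_exchanges):
        rows.append((f"product[{k}]",
                     np.array([network.rxn_index(rid), jg, jf])))
    if "acetate_exchange" in network.special:
        rows.append(("acetate",
                     np.array([network.role_index("acetate_exchange"), jg, jf])))
    if "proline_exchange" in network.special:
        rows.append(("proline",
                     np.array([network.role_index("proline_exchange"), jg, jf])))
    return rows


def assemble_problem(network: MetabolicNetwork, phase: PhaseSpec | str,
                     state, params: KineticParams,
                     comp: BiomassComposition | None = None) -> PhaseLP:
    """Install phase- and state-dependent bounds and couplings.

    ``state`` needs the culture-state attributes (Glx, F, O2, NH4, AA, P,
    Prot, X_A); ``comp`` is accepted for interface symmetry (the biomass
    column itself is rewritten by the biomass module).
    """
    if isinstance(phase, str):
        phase = phase_spec(phase, params.phi)
    label = phase.label
    if label not in PHASES:
        raise ValueError(f"unknown phase {label!r}")

    lowest = min(float(state.Glx), float(state.F), float(state.O2),
                 float(state.NH4), float(np.min(state.AA)),
                 float(np.min(state.P)))
    if lowest < -1e-9:
        raise ValueError(f"negative concentration in state ({lowest})")
    conc = lambda x: 0.0 if x < _DEPLETION else float(x)
    E = conc(state.P[0])  # ethanol is product 1 and the inhibitor
    lb = network.lb.copy()
    ub = network.ub.copy()

    def set_bounds(role, lo, hi):
        j = network.role_index(role)
        lb[j], ub[j] = lo, hi

    set_bounds("glucose_exchange",
               kin.hexose_uptake_bound(conc(state.Glx), E, params.vmaxG,
                                       params.kG, params.KEi), 0.0)
    set_bounds("fructose_exchange",
               kin.hexose_uptake_bound(conc(state.F), E, params.vmaxF,
                                       params.kF, params.KEiF), 0.0)
    set_bounds("oxygen_exchange",
               kin.oxygen_uptake_bound(conc(state.O2), params.kO2), 0.0)
    set_bounds("ammonium_exchange",
               kin.ammonium_uptake_bound(conc(state.NH4), params.vmaxNH4,
                                         params.kNH4), _INF)

    aa_ids = network.amino_acid_exchanges
    quiescent = "turnover_bounds" in phase.active_constraints
    if quiescent:
        alpha = network.protein_alpha()
        X_A = max(float(state.X_A), 0.0)
        release = params.lam * max(float(state.Prot), 0.0) * alpha
        for i, rid in enumerate(aa_ids):
            j = network.rxn_index(rid)
            if i == 0:  # proline: excretion only, tied by its coupling row
                lb[j], ub[j] = 0.0, _INF
            else:
                lb[j] = -release[i] / X_A if X_A > 1e-9 else 0.0
                ub[j] = _INF
    else:
        for i, rid in enumerate(aa_ids):
            j = network.rxn_index(rid)
            if i == 0:
                lb[j], ub[j] = 0.0, 0.0
            else:
                lb[j] = kin.amino_acid_uptake_bound(conc(state.AA[i]),
                                                    params.kAA[i])
                ub[j] = 0.0

    # acetate: produced while growing (coupling row), consumed when quiescent
    j_ace = network.role_index("acetate_exchange")
    ace_idx = 2  # acetate is product state 3 by construction
    if quiescent:
        # forced mass-action consumption (production is growth-associated)
        lb[j_ace] = ub[j_ace] = -params.k_ace * conc(state.P[ace_idx])
    else:
        lb[j_ace], ub[j_ace] = 0.0, _INF

    if "no_growth" in phase.active_constraints:
        set_bounds("biomass", 0.0, 0.0)
    else:
        set_bounds("biomass", 0.0, _INF)
    set_bounds("protein_production", 0.0, _INF if quiescent else 0.0)
    j_atp = network.role_index("atp_maintenance")
    lb[j_atp] = params.NGAM if phase.NGAM_active else network.lb[j_atp]

    couplings = []
    for name, cols in coupling_layout(network):
        if name.startswith("product["):
            k = int(name[8:-1])
            coefs = np.array([1.0, params.kP[k], params.kP[k]])
            active = True
        elif name == "acetate":
            coefs = np.array([1.0, params.kP_ace, params.kP_ace])
            active = not quiescent
        else:  # proline
            coefs = np.array([1.0, params.alpha_Pro, params.alpha_Pro])
            active = quiescent
        couplings.append(CouplingRow(name, cols, coefs, active))

    c = scalarize_objective(phase, network)
    return PhaseLP(network, label, c, lb, ub, couplings)


# -- GLPK backend ----------------------------------------------------------

class _GlpkPfba:
    """Two persistent GLPK problems (stage 1 and stage 2 with |v| split
    variables) for one network structure; bounds, objective, the biomass
    column and coupling coefficients are mutated per solve."""

    def __init__(self, network: MetabolicNetwork):
        glp.glp_term_out(glp.GLP_OFF)
        self.network = network
        self.structure_version = network.structure_version
        self.n = network.n_reactions
        self.m = network.n_metabolites
        self.layout = coupling_layout(network)
        self.n_couple = len(self.layout)
        self.biomass_col = (network.role_index("biomass")
                            if "biomass" in network.special else None)
        self.p1 = self._build(stage2=False)
        self.p2 = self._build(stage2=True)
        self.parm = glp.glp_smcp()
        glp.glp_init_smcp(self.parm)
        self.parm.msg_lev = glp.GLP_MSG_OFF
        # change-detection caches so consecutive solves only push deltas
        self._cache = {id(self.p1): {}, id(self.p2): {}}
        # start from the standard basis for reproducible tie-breaking
        glp.glp_std_basis(self.p1)
        glp.glp_std_basis(self.p2)
        self._disposed = False

    def dispose(self) -> None:
        if not self._disposed:
            glp.glp_delete_prob(self.p1)
            glp.glp_delete_prob(self.p2)
            self._disposed = True

    def __del__(self):  # pragma: no cover - interpreter-shutdown guard
        try:
            self.dispose()
        except Exception:
            pass

    def _build(self, stage2: bool):
        n, m = self.n, self.m
        ncols = 2 * n if stage2 else n
        nrows = m + self.n_couple + (1 + 2 * n if stage2 else 0)
        lp = glp.glp_create_prob()
        glp.glp_set_obj_dir(lp, glp.GLP_MIN if stage2 else glp.GLP_MAX)
        glp.glp_add_rows(lp, nrows)
        glp.glp_add_cols(lp, ncols)
        entries = []  # (row, col, coef) 1-based
        S = self.network.S
        for i in range(m):
            glp.glp_set_row_bnds(lp, i + 1, glp.GLP_FX, 0.0, 0.0)
        for i, j in zip(*np.nonzero(S)):
            entries.append((int(i) + 1, int(j) + 1, float(S[i, j])))
        row = m
        for name, cols in self.layout:
            row += 1
            glp.glp_set_row_bnds(lp, row, glp.GLP_FR, 0.0, 0.0)
            for col in cols:
                entries.append((row, int(col) + 1, 1.0))  # coefs set later
        if stage2:
            self.obj_row = row + 1
            glp.glp_set_row_bnds(lp, self.obj_row, glp.GLP_FR, 0.0, 0.0)
            row += 1
            for j in range(n):
                # t_j - v_j >= 0 and t_j + v_j >= 0
                entries.append((row + 1, n + j + 1, 1.0))
                entries.append((row + 1, j + 1, -1.0))
                glp.glp_set_row_bnds(lp, row + 1, glp.GLP_LO, 0.0, 0.0)
                entries.append((row + 2, n + j + 1, 1.0))
                entries.append((row + 2, j + 1, 1.0))
                glp.glp_set_row_bnds(lp, row + 2, glp.GLP_LO, 0.0, 0.0)
                row += 2
            for j in range(n):
                glp.glp_set_col_bnds(lp, n + j + 1, glp.GLP_LO, 0.0, 0.0)
                glp.glp_set_obj_coef(lp, n + j + 1, 1.0)
        ne = len(entries)
        ia, ja = glp.intArray(ne + 1), glp.intArray(ne + 1)
        ar = glp.doubleArray(ne + 1)
        for k, (i, j, a) in enumerate(entries, start=1):
            ia[k], ja[k], ar[k] = i, j, a
        glp.glp_load_matrix(lp, ne, ia, ja, ar)
        return lp

    def _push(self, lp, problem: PhaseLP, stage2: bool) -> None:
        n = self.n
        cache = self._cache[id(lp)]
        last_lb, last_ub = cache.get("lb"), cache.get("ub")
        if last_lb is None:
            changed = range(n)
        else:
            changed = np.nonzero((problem.lb != last_lb)
                                 | (problem.ub != last_ub))[0]
        for j in changed:
            lo, hi = problem.lb[j], problem.ub[j]
            if lo == hi:
                glp.glp_set_col_bnds(lp, int(j) + 1, glp.GLP_FX, lo, hi)
            else:
                glp.glp_set_col_bnds(lp, int(j) + 1, glp.GLP_DB, lo, hi)
        cache["lb"], cache["ub"] = problem.lb.copy(), problem.ub.copy()

        if not stage2:
            last_c = cache.get("c")
            if last_c is None or not np.array_equal(problem.c, last_c):
                for j in range(n):
                    glp.glp_set_obj_coef(lp, j + 1, float(problem.c[j]))
                cache["c"] = problem.c.copy()

        if self.biomass_col is not None:
            col = self.network.S[:, self.biomass_col]
            last_col = cache.get("biomass")
            if last_col is None or not np.array_equal(col, last_col):
                idx = np.nonzero(col)[0]
                entries = [(int(i) + 1, float(col[i])) for i in idx]
                if stage2:
                    # keep this column's |v|-split row entries intact
                    jb = self.biomass_col
                    base = self.obj_row
                    entries.append((base + 2 * jb + 1, -1.0))
                    entries.append((base + 2 * jb + 2, 1.0))
                ind = glp.intArray(len(entries) + 1)
                val = glp.doubleArray(len(entries) + 1)
                for k, (i, a) in enumerate(entries, start=1):
                    ind[k], val[k] = i, a
                glp.glp_set_mat_col(lp, self.biomass_col + 1, len(entries),
                                    ind, val)
                cache["biomass"] = col.copy()
                # the column rewrite clears this column's objective-row
                # entry; force the row to be re-pushed
                cache.pop("obj_c", None)

        signature = tuple((tuple(r.coefs), r.active)
                          for r in problem.couplings)
        if cache.get("couplings") != signature:
            for k, rowdef in enumerate(problem.couplings):
                row = self.m + k + 1
                ind = glp.intArray(len(rowdef.cols) + 1)
                val = glp.doubleArray(len(rowdef.cols) + 1)
                for kk, (cj, cv) in enumerate(zip(rowdef.cols, rowdef.coefs),
                                              start=1):
                    ind[kk], val[kk] = int(cj) + 1, float(cv)
                glp.glp_set_mat_row(lp, row, len(rowdef.cols), ind, val)
                if rowdef.active:
                    glp.glp_set_row_bnds(lp, row, glp.GLP_FX, 0.0, 0.0)
                else:
                    glp.glp_set_row_bnds(lp, row, glp.GLP_FR, 0.0, 0.0)
            cache["couplings"] = signature

    def _simplex(self, lp) -> int:
        ret = glp.glp_simplex(lp, self.parm)
        status = glp.glp_get_status(lp)
        if ret != 0 or status not in (glp.GLP_OPT, glp.GLP_NOFEAS,
                                      glp.GLP_UNBND):
            glp.glp_std_basis(lp)  # cold restart on numerical trouble
            glp.glp_simplex(lp, self.parm)
            status = glp.glp_get_status(lp)
        return status

    def solve(self, problem: PhaseLP) -> FluxSolution:
        # GLPK aborts the process on non-finite input; refuse it here
        if not (np.all(np.isfinite(problem.lb))
                and np.all(np.isfinite(problem.ub))
                and np.all(np.isfinite(problem.c))):
            raise ValueError("non-finite bounds or objective in phase LP")
        self._push(self.p1, problem, stage2=False)
        status = self._simplex(self.p1)
        if status == glp.GLP_UNBND:
            raise InfeasibleProblem(
                f"phase {problem.label!r} LP is unbounded (model defect)")
        if status != glp.GLP_OPT:
            # a stale warm basis can report spurious infeasibility after
            # many bound mutations; always retry cold before relaxing
            glp.glp_std_basis(self.p1)
            status = self._simplex(self.p1)
        if status != glp.GLP_OPT:
            relaxed = self._relax(problem)
            self._push(self.p1, relaxed, stage2=False)
            glp.glp_std_basis(self.p1)
            status = self._simplex(self.p1)
            if status != glp.GLP_OPT:
                return FluxSolution(np.zeros(self.n), np.nan, "infeasible",
                                    self.network.reaction_ids)
            problem = relaxed
        obj1 = glp.glp_get_obj_val(self.p1)

        self._push(self.p2, problem, stage2=True)
        n = self.n
        cache2 = self._cache[id(self.p2)]
        if cache2.get("obj_c") is None or not np.array_equal(
                problem.c, cache2["obj_c"]):
            ind = glp.intArray(n + 1)
            val = glp.doubleArray(n + 1)
            nz = 0
            for j in range(n):
                if problem.c[j] != 0.0:
                    nz += 1
                    ind[nz], val[nz] = j + 1, float(problem.c[j])
            glp.glp_set_mat_row(self.p2, self.obj_row, nz, ind, val)
            cache2["obj_c"] = problem.c.copy()
        floor = obj1 - 1e-6 * max(1.0, abs(obj1))
        glp.glp_set_row_bnds(self.p2, self.obj_row, glp.GLP_LO, floor, 0.0)
        status2 = self._simplex(self.p2)
        if status2 != glp.GLP_OPT:
            # fall back to the stage-1 solution rather than fail the step
            v = np.array([glp.glp_get_col_prim(self.p1, j + 1)
                          for j in range(n)])
        else:
            v = np.array([glp.glp_get_col_prim(self.p2, j + 1)
                          for j in range(n)])
        return self._solution(v, obj1)

    def _relax(self, problem: PhaseLP) -> PhaseLP:
        """Machine-epsilon-scale slack on all finite bounds (single retry)."""
        eps = 1e-9
        lb = problem.lb - eps * np.maximum(1.0, np.abs(problem.lb))
        ub = problem.ub + eps * np.maximum(1.0, np.abs(problem.ub))
        return PhaseLP(problem.network, problem.label, problem.c, lb, ub,
                       problem.couplings)

    def _solution(self, v: np.ndarray, obj: float) -> FluxSolution:
        net = self.network
        sol = FluxSolution(v, obj, "optimal", net.reaction_ids)
        if "biomass" in net.special:
            sol.mu = float(v[net.role_index("biomass")])
        if "protein_production" in net.special:
            sol.v_Prot = float(v[net.role_index("protein_production")])
        if "atp_maintenance" in net.special:
            sol.v_ATP = float(v[net.role_index("atp_maintenance")])
        return sol


def _solver_for(network: MetabolicNetwork) -> _GlpkPfba:
    cached = getattr(network, "_pfba_solver", None)
    if cached is None or cached.structure_version != network.structure_version:
        cached = _GlpkPfba(network)
        network._pfba_solver = cached
    return cached


def reset_solver(network: MetabolicNetwork) -> None:
    """Discard the network's cached LP backend so the next solve starts
    from a freshly constructed problem.

    Warm starts and in-place matrix edits make a solve's degenerate
    tie-breaking depend on the entire preceding solve history; rebuilding
    (about a millisecond) at the start of every simulation keeps repeated
    runs bitwise identical while preserving in-run warm starts.
    """
    cached = getattr(network, "_pfba_solver", None)
    if cached is not None:
        cached.dispose()
        network._pfba_solver = None


def solve_pfba(problem: PhaseLP) -> FluxSolution:
    """Two-stage parsimonious solve of an assembled phase LP.

    Stage 1 maximizes the scalarized phase objective; stage 2 pins the
    objective at its optimum (1e-6 relative) and minimizes sum(|v|).
    Returns status ``infeasible`` (caller decides) if stage 1 remains
    infeasible after one slack retry; raises on unbounded problems.
    """
    return _solver_for(problem.network).solve(problem)


def binding_constraints(problem: PhaseLP, tol: float = 1e-7) -> list[str]:
    """Human-readable list of tight bounds, for infeasibility diagnostics."""
    out = []
    for j, rid in enumerate(problem.network.reaction_ids):
        if problem.lb[j] == problem.ub[j]:
            out.append(f"{rid}: fixed at {problem.lb[j]:.6g}")
        elif problem.ub[j] - problem.lb[j] < tol:
            out.append(f"{rid}: [{problem.lb[j]:.6g}, {problem.ub[j]:.6g}]")
    return out


def fba(network: MetabolicNetwork, objective_rxn: str, maximize: bool = True,
        bounds_override: dict[str, tuple[float, float]] | None = None) -> float:
    """One-off single-objective FBA via scipy (no couplings); returns the
    optimal objective flux.  Used for feasibility probes, not simulation."""
    from scipy.optimize import linprog

    lb, ub = network.lb.copy(), network.ub.copy()
    for rid, (lo, hi) in (bounds_override or {}).items():
        j = network.rxn_index(rid)
        lb[j], ub[j] = lo, hi
    c = np.zeros(network.n_reactions)
    c[network.rxn_index(objective_rxn)] = -1.0 if maximize else 1.0
    res = linprog(c, A_eq=network.S, b_eq=np.zeros(network.n_metabolites),
                  bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        raise InfeasibleProblem(f"FBA infeasible: {res.message}")
    return float(res.x[network.rxn_index(objective_rxn)])
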