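"""Self-contained validation studies on the toy fermentation.

Each function runs one end-to-end check of the framework under the
reference study conditions and returns plain numbers: steady-state
closure of every pFBA solve across a batch, agreement of the production
LP path with a brute-force vertex-enumeration oracle, whole-batch carbon
conservation, the five-phase batch phenomenology, parameter recovery
from noisy synthetic data, the bootstrap leave-out fraction, and the
dynamic flux-ratio identities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import (FitContext, fit, generate_synthetic_dataset,
                         leave_out_fractions)
from .flux_analysis import dynamic_flux_ratio
from .gem_io import MetabolicNetwork
from .phase_fba import PhaseLP, solve_pfba
from .presets import ToyStudy, toy_study
from .reference import vertex_lp_max
from .simulator import Trajectory, simulate

__all__ = [
    "batch_steady_state_residual", "pfba_oracle_comparison",
    "carbon_conservation", "phase_phenomenology", "recovery_study",
    "bootstrap_leaveout", "flux_ratio_identities", "random_small_network",
    "piecewise_constant_trajectory",
]


def _default_batch(study: ToyStudy | None = None) -> tuple[ToyStudy, Trajectory]:
    st = study or toy_study()
    traj = simulate(st.params, st.network, st.schedule, st.init)
    return st, traj


def batch_steady_state_residual(study: ToyStudy | None = None) -> dict:
    """Max ||S v||_inf over every pFBA solve of a full simulated batch."""
    st, traj = _default_batch(study)
    n_solves = int((np.abs(traj.fluxes).sum(axis=1) > 0).sum())
    return {"max_residual": float(traj.residuals.max()),
            "n_solves": n_solves}


def random_small_network(rng: np.random.Generator, max_reactions: int = 8
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                    np.ndarray]:
    """Random bounded LP instance (S, lb, ub, c) with v=0 feasible and
    at most ``max_reactions`` reactions."""
    n = int(rng.integers(3, max_reactions + 1))
    m = int(rng.integers(1, max(2, n - 1)))
    S = rng.integers(-2, 3, size=(m, n)).astype(float)
    lb = np.where(rng.random(n) < 0.5, 0.0, -rng.uniform(1, 10, n))
    ub = rng.uniform(1, 10, n)
    c = rng.normal(size=n)
    return S, lb, ub, c


def pfba_oracle_comparison(n_networks: int = 20, seed: int = 0) -> dict:
    """Stage-1 objective of the production two-stage solver versus
    exhaustive vertex enumeration on random networks (<= 8 reactions)."""
    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(n_networks):
        S, lb, ub, c = random_small_network(rng)
        m, n = S.shape
        nonzero_rows = ~np.all(S == 0, axis=1)
        S = S[nonzero_rows] if nonzero_rows.any() else S[:1]
        net = MetabolicNetwork(
            [f"m{i}" for i in range(S.shape[0])],
            [f"r{j}" for j in range(n)], S, lb, ub)
        problem = PhaseLP(net, "exponential", c, lb.copy(), ub.copy(), [])
        sol = solve_pfba(problem)
        oracle = vertex_lp_max(S, lb, ub, c)
        diffs.append(abs(sol.objective_value - oracle)
                     / max(1.0, abs(oracle)))
    return {"n_networks": n_networks,
            "max_rel_diff": float(np.max(diffs))}


def carbon_conservation(study: ToyStudy | None = None) -> dict:
    """Whole-batch carbon audit on the toy network.

    Total carbon = extracellular carbon (sugars, products, amino acids,
    CO2) plus the integrated carbon imported by the cells; the drift is
    reported relative to the carbon throughput (carbon taken up by cells).
    """
    st, traj = _default_batch(study)
    net = st.network
    names = traj.state_names

    def total(y):
        d = dict(zip(names, y))
        ext = (6 * d["Glx"] + 6 * d["F"] + 12 * d["Suc"] + d["CO2"])
        for rid in net.amino_acid_exchanges:
            met = net._exchange_metabolite(rid)
            ext += net.carbon[met] * d[f"AA_{met}"]
        prods = [net._exchange_metabolite(r) for r in net.product_exchanges]
        p_names = [prods[0], prods[1], "ace"] + prods[2:]
        for pn in p_names:
            ext += net.carbon[pn] * d[f"P_{pn}"]
        return ext + d["C_bio"]

    drift = abs(total(traj.states[-1]) - total(traj.states[0]))
    throughput = float(traj.states[-1][names.index("C_bio")])
    return {"drift_mmolC": float(drift),
            "throughput_mmolC": throughput,
            "drift_pct_of_throughput": float(100 * drift / throughput)}


def phase_phenomenology(study: ToyStudy | None = None) -> dict:
    """Signed-derivative checks of the five-phase batch curve.

    Returns the quantities a qualitative reading of a batch fermentation
    requires: no growth in lag, exponential growth in the growth window,
    assimilable nitrogen exhausted by the stationary switch, ongoing sugar
    consumption with near-constant active biomass in stationary, and an
    active-biomass decline in decay.
    """
    st, traj = _default_batch(study)
    s = st.schedule
    X = traj.series("X_A")
    hexose = traj.series("Glx") + traj.series("F")
    yan = traj.series("NH4") + sum(
        traj.series(f"AA_{st.network._exchange_metabolite(r)}")
        for r in st.network.amino_acid_exchanges[1:])

    def at(t, arr):
        return float(np.interp(t, traj.times, arr))

    lag_rel_change = abs(at(s.tL, X) - at(s.t0, X)) / at(s.t0, X)
    growth_factor = at(s.tE, X) / at(s.tL, X)
    # log-linearity of exponential growth: correlation of log X with t
    mask = (traj.times >= s.tL + 1) & (traj.times <= s.tE)
    r = np.corrcoef(traj.times[mask], np.log(X[mask]))[0, 1]
    stat_sugar_drop = at(s.tS, hexose) - at(s.tD, hexose)
    stat_X_rel_change = (at(s.tD, X) - at(s.tS, X)) / at(s.tS, X)
    return {
        "lag_X_rel_change": lag_rel_change,
        "exponential_growth_factor": float(growth_factor),
        "exponential_log_linearity_r": float(r),
        "yan_at_tS_fraction_of_initial": at(s.tS, yan) / yan[0],
        "stationary_sugar_consumed_mmol": float(stat_sugar_drop),
        "stationary_X_rel_change": float(stat_X_rel_change),
        "decay_X_change": at(s.tF, X) - at(s.tD, X),
    }


def recovery_study(n_seeds: int = 10, noise_cv: float = 0.05,
                   n_replicates: int = 3, seed0: int = 100, *,
                   maxiter: int = 10, popsize: int = 4) -> pd.DataFrame:
    """Fit noisy synthetic data from known parameters, once per seed.

    Free parameters: maximum glucose uptake (vmaxG), ethanol yield
    (kP[0]), protein turnover rate (lam) and the biomass-equation
    amplitude (A).  Returns per-seed relative errors in percent.
    """
    st = toy_study()
    ctx = FitContext(st.network, st.params, ["vmaxG", "kP[0]", "lam", "A"],
                     st.init, st.schedule.t0, st.schedule.tF,
                     sim_options={"rtol": 1e-4, "atol": 1e-7},
                     log_params=("lam",))
    bounds = {"vmaxG": (0.5, 6.0), "kP[0]": (0.8, 1.9),
              "lam": (-3.0, -1.3), "A": (0.2, 0.7)}
    truth = ctx.natural_theta(ctx.theta_from_params(st.params))
    rows = []
    for k in range(n_seeds):
        seed = seed0 + k
        data = generate_synthetic_dataset(
            st.params, st.network, st.schedule, noise_cv=noise_cv,
            n_replicates=n_replicates, seed=seed, init=st.init,
            sim_options={"rtol": 1e-5, "atol": 1e-8})
        res = fit(data, bounds, seed, ctx, maxiter=maxiter, popsize=popsize)
        rel_err = 100 * np.abs(ctx.natural_theta(res.theta) - truth) / truth
        rows.append(dict(zip(ctx.free_names, rel_err), seed=seed,
                         objective=res.objective))
    return pd.DataFrame(rows)


def bootstrap_leaveout(n_records: int = 100, n_resamples: int = 1000,
                       seed: int = 0) -> dict:
    """Mean per-resample leave-out percentage of bootstrap resampling."""
    fracs = leave_out_fractions(n_records, n_resamples, seed)
    return {"mean_leaveout_pct": float(100 * fracs.mean()),
            "n_records": n_records, "n_resamples": n_resamples}


def piecewise_constant_trajectory() -> Trajectory:
    """Hand-integrable fixture: constant biomass, constant fluxes
    (v_i = 1, v_Glx = -4, v_F = -1) on a stub network."""
    rxns = ["v_i", "EX_glc", "EX_fru", "hexose_uptake_total", "v_zero"]
    net = MetabolicNetwork(["x"], rxns, np.zeros((1, len(rxns))),
                           -1e3 * np.ones(len(rxns)),
                           1e3 * np.ones(len(rxns)),
                           special={"glucose_exchange": "EX_glc",
                                    "fructose_exchange": "EX_fru"})
    times = np.linspace(0.0, 10.0, 21)
    n_t = len(times)
    states = np.zeros((n_t, 2))
    states[:, 0] = 2.0  # constant dry weight
    fluxes = np.tile([1.0, -4.0, -1.0, 5.0, 0.0], (n_t, 1))
    return Trajectory(times, states, ["stationary"] * n_t, fluxes, None,
                      ["X_A", "C_bio"], rxns, net, None, None)


def flux_ratio_identities() -> dict:
    """Self-normalization, null and hand-integral identities of the
    dynamic flux-ratio score on the piecewise-constant fixture."""
    traj = piecewise_constant_trajectory()
    window = (0.0, 10.0)
    return {
        "hexose_self_ratio": dynamic_flux_ratio(
            traj, "hexose_uptake_total", window),
        "zero_flux_ratio": dynamic_flux_ratio(traj, "v_zero", window),
        "hand_integral_ratio": dynamic_flux_ratio(traj, "v_i", window),
    }
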