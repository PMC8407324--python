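"""Maximum-likelihood parameter estimation and bootstrap-ensemble
uncertainty.

The fit objective is the weighted least-squares distance

    J(theta) = sum_k sum_j sum_i ((y_kji(theta) - y^m_kji) / sigma_kji)^2

over experiments, observables and sampling times, with sigma the
measurement standard deviation.  Optimization uses a seeded
population-based global search (differential evolution) followed by a
bounded local polish; a failed simulation is penalized with
1e10 plus the number of hours the integration fell short, which ranks
partial failures smoothly.

Uncertainty is quantified by bagging: N bootstrap realizations of the
dataset (resampling individual replicate measurements uniformly with
replacement, preserving dataset size) are each fitted, and the resulting
parameter matrix Theta drives an ensemble of simulations whose per-time
median and quantiles form the prediction band.  Each resample leaves out
roughly a 1/e ~ 37% fraction of the original records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize

from .gem_io import MetabolicNetwork
from .kinetics import KineticParams
from .phase_fba import PhaseSchedule
from .simulator import (CultureState, SimulationError, Trajectory, simulate)

__all__ = [
    "DataSet", "EnsembleMatrix", "FitContext", "FitResult",
    "nll", "fit", "bootstrap_ensemble", "ensemble_predict",
    "generate_synthetic_dataset", "resample_dataset", "leave_out_fractions",
]

_PENALTY = 1.0e10

REQUIRED_COLUMNS = ["experiment", "observable", "time_h", "replicate",
                    "value", "sigma"]


@dataclass
class DataSet:
    """Tidy measurement table: one row per (experiment, observable,
    time, replicate) with its value and standard deviation."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if (self.records["sigma"] <= 0).any():
            raise ValueError("sigma must be > 0 for every observation")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def observables(self) -> list[str]:
        return sorted(self.records["observable"].unique())

    @classmethod
    def from_csv(cls, path) -> "DataSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class FitContext:
    """Everything needed to map a parameter vector to simulated
    observables: the network, the template parameter set, which parameter
    names are free (``kP[0]``-style indexing reaches into arrays; phase
    times may be given as increments ``dt_L``, ``dt_EL``, ``dt_SE``,
    ``dt_DS`` to enforce ordering), the horizon and the initial state."""

    network: MetabolicNetwork
    params_template: KineticParams
    free_names: list[str]
    init: CultureState
    t0: float = 0.0
    tF: float = 250.0
    sim_options: dict = field(default_factory=dict)
    #: parameters searched on a log10 scale (bounds given in log10 units)
    log_params: tuple[str, ...] = ()

    def make_params(self, theta: np.ndarray) -> KineticParams:
        p = self.params_template.replace(
            kAA=self.params_template.kAA.copy(),
            kP=self.params_template.kP.copy())
        increments = {}
        for name, value in zip(self.free_names, theta):
            if name in self.log_params:
                value = 10.0 ** value
            if name.startswith("dt_"):
                increments[name] = float(value)
            elif "[" in name:
                base, idx = name[:-1].split("[")
                getattr(p, base)[int(idx)] = value
            else:
                p = p.replace(**{name: float(value)})
        if increments:
            tL = increments.get("dt_L", p.t_L)
            tE = tL + increments.get("dt_EL", p.t_E - p.t_L)
            tS = tE + increments.get("dt_SE", p.t_S - p.t_E)
            tD = tS + increments.get("dt_DS", p.t_D - p.t_S)
            p = p.replace(t_L=tL, t_E=tE, t_S=tS, t_D=tD)
        return p

    def theta_from_params(self, p: KineticParams) -> np.ndarray:
        out = []
        for name in self.free_names:
            if name.startswith("dt_"):
                cum = {"dt_L": p.t_L, "dt_EL": p.t_E - p.t_L,
                       "dt_SE": p.t_S - p.t_E, "dt_DS": p.t_D - p.t_S}
                value = cum[name]
            elif "[" in name:
                base, idx = name[:-1].split("[")
                value = float(getattr(p, base)[int(idx)])
            else:
                value = float(getattr(p, name))
            if name in self.log_params:
                value = np.log10(value)
            out.append(value)
        return np.array(out)

    def natural_theta(self, theta: np.ndarray) -> np.ndarray:
        """Parameter vector on the natural (linear) scale."""
        out = np.asarray(theta, dtype=float).copy()
        for k, name in enumerate(self.free_names):
            if name in self.log_params:
                out[k] = 10.0 ** out[k]
        return out

    def simulate(self, params: KineticParams, **kw) -> Trajectory:
        schedule = PhaseSchedule.from_params(params, self.t0, self.tF)
        opts = {"store_fluxes": False, **self.sim_options, **kw}
        return simulate(params, self.network, schedule, self.init, **opts)

    def predict(self, traj: Trajectory, observable: str,
                times: np.ndarray) -> np.ndarray:
        p = traj.params
        if observable == "CFU":
            series, scale = traj.series("X_V"), p.c_CFU
        elif observable == "OD":
            series, scale = traj.series("X_A"), p.c_OD
        else:
            series, scale = traj.series(observable), 1.0
        return scale * np.interp(times, traj.times, series)


def nll(theta: np.ndarray, data: DataSet, ctx: FitContext) -> float:
    """Weighted sum-of-squares objective; large flagged penalty when the
    simulation fails (1e10 + missing hours)."""
    try:
        params = ctx.make_params(np.asarray(theta, dtype=float))
        traj = ctx.simulate(params)
    except SimulationError as err:
        reached = getattr(err, "t_reached", ctx.t0)
        return _PENALTY + max(ctx.tF - reached, 0.0)
    except ValueError:
        return _PENALTY + (ctx.tF - ctx.t0)
    total = 0.0
    for (exp, obs), group in data.records.groupby(["experiment",
                                                   "observable"]):
        y = ctx.predict(traj, obs, group["time_h"].to_numpy())
        r = (y - group["value"].to_numpy()) / group["sigma"].to_numpy()
        total += float(r @ r)
    return total


@dataclass
class FitResult:
    theta: np.ndarray
    objective: float
    free_names: list[str]
    n_evaluations: int
    seed: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.free_names, self.theta))


def fit(data: DataSet, bounds: dict[str, tuple[float, float]], seed: int,
        ctx: FitContext, *, maxiter: int = 25, popsize: int = 12,
        polish: bool = True, tol: float = 1e-3) -> FitResult:
    """Seeded global fit: differential evolution over the boxed parameter
    space, then a bounded local polish.  Deterministic for a fixed seed."""
    if len(data) == 0:
        raise ValueError("dataset is empty")
    names = ctx.free_names
    missing = [n for n in names if n not in bounds]
    if missing:
        raise ValueError(f"no bounds for free parameters {missing}")
    box = [bounds[n] for n in names]
    if not all(np.isfinite(b).all() for b in map(np.asarray, box)):
        raise ValueError("bounds must be finite")

    result = differential_evolution(
        nll, box, args=(data, ctx), seed=seed, maxiter=maxiter,
        popsize=popsize, tol=tol, polish=False, init="sobol",
    )
    theta, obj, nfev = result.x, float(result.fun), int(result.nfev)
    if polish and obj < _PENALTY:
        # polish from the best distinct population members; the landscape
        # has LP-switching kinks, so several starts beat one long descent
        order = np.argsort(result.population_energies)
        starts = [result.x] + [result.population[k] for k in order[1:2]]
        lo = np.array([b[0] for b in box])
        hi = np.array([b[1] for b in box])
        for x0 in starts:
            local = minimize(
                nll, x0, args=(data, ctx), method="Nelder-Mead", bounds=box,
                options={"maxfev": 60 * len(names), "xatol": 1e-4,
                         "fatol": 1e-8})
            nfev += int(local.nfev)
            if local.fun < obj:
                theta, obj = np.clip(local.x, lo, hi), float(local.fun)
    if obj >= _PENALTY:
        raise RuntimeError(
            "every parameter evaluation failed to simulate; "
            "check bounds and initial state")
    return FitResult(theta, obj, list(names), nfev, seed)


# -- bootstrap -------------------------------------------------------------

def resample_dataset(data: DataSet, rng: np.random.Generator) -> tuple[
        DataSet, float]:
    """One bootstrap realization: sample individual replicate measurements
    uniformly with replacement, preserving the dataset size.  Returns the
    resampled dataset and the fraction of original records left out."""
    n = len(data)
    idx = rng.integers(0, n, size=n)
    left_out = 1.0 - len(np.unique(idx)) / n
    return DataSet(data.records.iloc[idx].reset_index(drop=True)), left_out


def leave_out_fractions(n_records: int, n_resamples: int,
                        seed: int) -> np.ndarray:
    """Empirical per-resample leave-out fractions of uniform resampling
    with replacement (converges to 1/e as the record count grows)."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.integers(0, n_records, size=n_records)
        out[b] = 1.0 - len(np.unique(idx)) / n_records
    return out


@dataclass
class EnsembleMatrix:
    """Bootstrap parameter ensemble Theta = [theta_1 ... theta_N]^T."""

    Theta: np.ndarray                 # N x d
    objectives: np.ndarray
    free_names: list[str]
    seeds: list[int]
    n_failed: int = 0

    def __len__(self) -> int:
        return self.Theta.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Theta, columns=self.free_names)
        df["objective"] = self.objectives
        df["seed"] = self.seeds
        return df


def bootstrap_ensemble(data: DataSet, N: int, seed: int, ctx: FitContext,
                       bounds: dict[str, tuple[float, float]],
                       resample: bool = True, **fit_options) -> EnsembleMatrix:
    """Fit N bootstrap realizations of the data (bagging).  With
    ``resample=False`` and N=1 this reduces to a single plain fit.
    Failed fits are excluded and counted."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    thetas, objectives, seeds = [], [], []
    n_failed = 0
    for b in range(N):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        realization = (resample_dataset(data, rng)[0] if resample else data)
        try:
            res = fit(realization, bounds, sub_seed, ctx, **fit_options)
        except RuntimeError as err:
            warnings.warn(f"bootstrap fit {b} failed: {err}")
            n_failed += 1
            continue
        thetas.append(res.theta)
        objectives.append(res.objective)
        seeds.append(sub_seed)
    if not thetas:
        raise RuntimeError("all bootstrap fits failed")
    return EnsembleMatrix(np.vstack(thetas), np.array(objectives),
                          list(ctx.free_names), seeds, n_failed)


def ensemble_predict(ensemble: EnsembleMatrix, ctx: FitContext,
                     observables: list[str], t_grid: np.ndarray,
                     quantiles: tuple[float, ...] = (0.05, 0.5, 0.95),
                     ) -> pd.DataFrame:
    """Simulate every ensemble member and summarize per-time quantiles.

    Returns a long table (observable, time, quantile, value); the 0.5
    quantile row is the model prediction.  Members whose simulation fails
    are excluded with a warning.
    """
    curves: dict[str, list[np.ndarray]] = {obs: [] for obs in observables}
    for k in range(len(ensemble)):
        try:
            params = ctx.make_params(ensemble.Theta[k])
            traj = ctx.simulate(params)
        except (SimulationError, ValueError) as err:
            warnings.warn(f"ensemble member {k} failed: {err}")
            continue
        for obs in observables:
            curves[obs].append(ctx.predict(traj, obs, t_grid))
    rows = []
    for obs in observables:
        if not curves[obs]:
            continue
        stack = np.vstack(curves[obs])
        for q in quantiles:
            rows.append(pd.DataFrame({
                "observable": obs, "time": t_grid, "quantile": q,
                "value": np.quantile(stack, q, axis=0),
            }))
    return pd.concat(rows, ignore_index=True)


# -- synthetic data --------------------------------------------------------

def generate_synthetic_dataset(theta_true: KineticParams,
                               network: MetabolicNetwork,
                               schedule: PhaseSchedule,
                               noise_cv: float, n_replicates: int, seed: int,
                               *, init: CultureState | None = None,
                               observables: tuple[str, ...] = (
                                   "Glx", "F", "NH4", "P_etoh", "X_A", "Prot"),
                               sample_times: np.ndarray | None = None,
                               sim_options: dict | None = None) -> DataSet:
    """Simulate known parameters and emit noisy replicate measurements.

    Per observation sigma = max(noise_cv * |y|, floor) with floor set to
    noise_cv times 5% of the observable's dynamic range (so sigma stays
    positive near zero signal); the recorded sigma is the truth used for
    sampling.  With noise_cv = 0 the replicates equal the simulation and
    sigma is recorded as 1 (unit weights).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    from .simulator import default_initial_state

    if init is None:
        init = default_initial_state(network)
    if sample_times is None:
        sample_times = np.linspace(schedule.t0 + 1.0, schedule.tF, 12)
    rng = np.random.default_rng(seed)
    traj = simulate(theta_true, network, schedule, init, store_fluxes=False,
                    **(sim_options or {}))
    ctx = FitContext(network, theta_true, [], init, schedule.t0, schedule.tF)
    rows = []
    for obs in observables:
        y = ctx.predict(traj, obs, sample_times)
        floor = noise_cv * 0.05 * (np.max(np.abs(y)) if len(y) else 1.0)
        sigma = np.maximum(noise_cv * np.abs(y), max(floor, 1e-12))
        for r in range(n_replicates):
            noisy = y + rng.normal(0.0, sigma) if noise_cv > 0 else y.copy()
            rows.append(pd.DataFrame({
                "experiment": "synthetic", "observable": obs,
                "time_h": sample_times, "replicate": r + 1,
                "value": noisy,
                "sigma": sigma if noise_cv > 0 else np.ones_like(y),
            }))
    return DataSet(pd.concat(rows, ignore_index=True))
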