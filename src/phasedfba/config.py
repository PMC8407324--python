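"""Run configuration: schema, validation, defaults and (de)serialization.

A single YAML file drives every pipeline command.  The schema is strict
(unknown keys are rejected) and mirrors the model structure: ``kinetics``
for uptake/production constants, ``biomass`` for the dynamic biomass
equation and maintenance costs, ``turnover`` for the protein-turnover
loop, ``phases`` for the switch times and the quiescent objective weight,
plus the initial state, the integration settings and output paths.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .gem_io import MetabolicNetwork, build_toy_network, read_model
from .kinetics import KineticParams
from .phase_fba import PhaseSchedule
from .simulator import CultureState, default_initial_state

__all__ = ["RunConfig", "load_config", "default_config_dict", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ToyModelSection(_Strict):
    n_amino_acids: int = 3
    n_products: int = 4


class ModelSection(_Strict):
    path: str | None = None
    role_map: dict[str, str] = Field(default_factory=dict)
    toy: ToyModelSection | None = ToyModelSection()

    @field_validator("toy")
    @classmethod
    def _at_least_one_source(cls, v, info):
        return v


class KineticsSection(_Strict):
    vmaxG: float = 2.0
    kG: float = 10.0
    KEi: float = 350.0
    vmaxF: float = 1.7
    kF: float = 12.0
    KEiF: float = 350.0
    k_hydro: float = 0.05
    kO2: float = 2.0
    vmaxNH4: float = 0.8
    kNH4: float = 0.5
    kAA: list[float] | None = None
    kP: list[float] | None = None
    kP_ace: float = 0.014
    k_ace: float = 0.005
    k_Edeath: float = 0.012
    n_hill: float = 2.0
    k_hill: float = 1200.0
    c_CFU: float = 5.0e7
    c_OD: float = 2.0


class BiomassSection(_Strict):
    A: float = 0.44
    B: float = -0.25
    RNA_to_Prot: float = 8.0
    dna_content: float = 0.01
    GAM_fitted: float = 25.0
    NGAM: float = 0.4
    # per-gram polymerization costs (mmol ATP/g); placeholder defaults
    unit_costs: dict[str, float] = Field(default_factory=lambda: {
        "protein": 30.0, "rna": 4.0, "carbohydrate": 6.2, "dna": 8.0})


class TurnoverSection(_Strict):
    lam: float = 0.008
    k_death: float = 0.004
    k_decay: float = 0.008
    alpha_Pro: float = 0.002


class PhasesSection(_Strict):
    t_L: float = 4.0
    t_E: float = 55.0
    t_S: float = 65.0
    t_D: float = 200.0
    t0: float = 0.0
    tF: float = 250.0
    phi: float = 0.01


class InitialStateSection(_Strict):
    X_A: float = 0.05
    X_V: float = 0.05
    Prot: float = 0.018
    Glx: float = 500.0
    F: float = 500.0
    Suc: float = 10.0
    O2: float = 0.25
    NH4: float = 8.0
    AA: list[float] | None = None
    P: list[float] | None = None


class SimulationSection(_Strict):
    rtol: float = 1.0e-6
    atol: float = 1.0e-9
    method: str = "LSODA"
    biomass_update: str = "growth_phases"
    t_grid_points: int | None = None
    volume_L: float = 1.0


class EstimationSection(_Strict):
    free: list[str] = Field(default_factory=lambda: [
        "vmaxG", "kP[0]", "lam", "A"])
    bounds: dict[str, tuple[float, float]] = Field(default_factory=lambda: {
        "vmaxG": (0.5, 6.0), "kP[0]": (0.8, 1.9),
        "lam": (0.001, 0.05), "A": (0.2, 0.7)})
    maxiter: int = 12
    popsize: int = 4
    n_boot: int = 20
    fit_rtol: float = 1.0e-4
    fit_atol: float = 1.0e-7


class OutputSection(_Strict):
    directory: str = "results"


class RunConfig(_Strict):
    model: ModelSection = ModelSection()
    kinetics: KineticsSection = KineticsSection()
    biomass: BiomassSection = BiomassSection()
    turnover: TurnoverSection = TurnoverSection()
    phases: PhasesSection = PhasesSection()
    initial_state: InitialStateSection = InitialStateSection()
    simulation: SimulationSection = SimulationSection()
    estimation: EstimationSection = EstimationSection()
    outputs: OutputSection = OutputSection()
    seed: int = 1

    # -- constructors -----------------------------------------------------
    def build_network(self) -> MetabolicNetwork:
        if self.model.path:
            return read_model(self.model.path, self.model.role_map)
        toy = self.model.toy or ToyModelSection()
        return build_toy_network(toy.n_amino_acids, toy.n_products)

    def build_params(self, network: MetabolicNetwork) -> KineticParams:
        n_aa = len(network.amino_acid_exchanges)
        n_p = len(network.product_exchanges)
        k = self.kinetics
        kAA = np.asarray(k.kAA if k.kAA is not None else np.full(n_aa, 0.05))
        if k.kP is not None:
            kP = np.asarray(k.kP)
        else:
            kP = np.full(n_p, 0.004)
            kP[0] = 1.55
            if n_p > 1:
                kP[1] = 0.14
        if len(kAA) != n_aa or len(kP) != n_p:
            raise ValueError(
                f"kAA/kP lengths ({len(kAA)}/{len(kP)}) do not match the "
                f"network ({n_aa} amino acids, {n_p} coupled products)")
        b, t, ph = self.biomass, self.turnover, self.phases
        return KineticParams(
            vmaxG=k.vmaxG, kG=k.kG, KEi=k.KEi, vmaxF=k.vmaxF, kF=k.kF,
            KEiF=k.KEiF, k_hydro=k.k_hydro, kO2=k.kO2, vmaxNH4=k.vmaxNH4,
            kNH4=k.kNH4, kAA=kAA, kP=kP, kP_ace=k.kP_ace, k_ace=k.k_ace,
            lam=t.lam, k_death=t.k_death, k_decay=t.k_decay,
            k_Edeath=k.k_Edeath, n_hill=k.n_hill, k_hill=k.k_hill,
            A=b.A, B=b.B, RNA_to_Prot=b.RNA_to_Prot,
            dna_content=b.dna_content, GAM_fitted=b.GAM_fitted, NGAM=b.NGAM,
            unit_costs=dict(b.unit_costs), phi=ph.phi,
            alpha_Pro=t.alpha_Pro, c_CFU=k.c_CFU, c_OD=k.c_OD,
            t_L=ph.t_L, t_E=ph.t_E, t_S=ph.t_S, t_D=ph.t_D,
        )

    def build_schedule(self, params: KineticParams) -> PhaseSchedule:
        return PhaseSchedule.from_params(params, self.phases.t0,
                                         self.phases.tF)

    def build_initial_state(self, network: MetabolicNetwork) -> CultureState:
        s = self.initial_state
        base = default_initial_state(network)
        AA = np.asarray(s.AA) if s.AA is not None else base.AA
        P = np.asarray(s.P) if s.P is not None else base.P
        return CultureState(s.X_A, s.X_V, s.Prot, s.Glx, s.F, s.Suc, s.O2,
                            s.NH4, AA=AA, P=P)

    def sim_options(self) -> dict:
        sim = self.simulation
        return {"rtol": sim.rtol, "atol": sim.atol, "method": sim.method,
                "biomass_update": sim.biomass_update}

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read and validate a YAML config; unknown keys are a hard error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def default_config_dict() -> dict:
    return RunConfig().model_dump()


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(),
                                         sort_keys=False))
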