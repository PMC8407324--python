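"""Concentration-dependent exchange-flux bounds and production couplings.

Uptake follows the FBA sign convention: uptake fluxes are negative,
secretion positive.  Hexoses obey Michaelis-Menten kinetics with
competitive ethanol inhibition,

    v_Glx >= -vmax_G * Glx/(Glx + k_G) * 1/(1 + E/K_Ei),

ammonium plain Michaelis-Menten, oxygen and amino acids mass action.
Fermentation products are coupled to the instantaneous hexose transport,
v_Pj = -k_Pj (v_Glx + v_F), imposed as equality constraints inside the LP.
Acetate is the exception: it is produced (hexose-coupled) during the
growth phases and consumed by mass action during stationary/decay.

All laws return exactly zero at zero concentration and are monotone in
their substrate, which the property tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KineticParams",
    "hexose_uptake_bound",
    "sucrose_hydrolysis_rate",
    "oxygen_uptake_bound",
    "ammonium_uptake_bound",
    "amino_acid_uptake_bound",
    "product_flux",
    "acetate_flux",
]

GROWTH_PHASES = ("lag", "exponential", "n_limited")
QUIESCENT_PHASES = ("stationary", "decay")
PHASES = GROWTH_PHASES + QUIESCENT_PHASES


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


def hexose_uptake_bound(C: float, E: float, vmax: float, km: float,
                        KEi: float) -> float:
    """Signed lower bound on hexose uptake (mmol/gDW/h), in [-vmax, 0].

    Michaelis-Menten saturation in the sugar C with competitive inhibition
    by ethanol E; KEi sets the ethanol concentration that halves uptake.
    """
    _check_nonneg("sugar concentration", C)
    _check_nonneg("ethanol concentration", E)
    if C == 0.0:
        return 0.0
    return -vmax * C / (C + km) / (1.0 + E / KEi)


def sucrose_hydrolysis_rate(Suc: float, k_hydro: float) -> float:
    """Extracellular sucrose hydrolysis rate (mmol/L/h), mass action.

    Each hydrolysed sucrose yields one glucose and one fructose in the
    culture ODEs; the reaction happens in the medium, not in the network.
    """
    _check_nonneg("sucrose concentration", Suc)
    return k_hydro * Suc


def oxygen_uptake_bound(O2: float, kO2: float) -> float:
    """Signed lower bound on oxygen exchange: -kO2 * O2 (mass action)."""
    _check_nonneg("oxygen concentration", O2)
    return -kO2 * O2


def ammonium_uptake_bound(NH4: float, vmaxNH4: float, kNH4: float) -> float:
    """Signed lower bound on ammonium uptake, Michaelis-Menten."""
    _check_nonneg("ammonium concentration", NH4)
    if NH4 == 0.0:
        return 0.0
    return -vmaxNH4 * NH4 / (NH4 + kNH4)


def amino_acid_uptake_bound(AAi: float, kAAi: float) -> float:
    """Signed lower bound on amino-acid uptake, mass action: -kAAi * AAi."""
    _check_nonneg("amino-acid concentration", AAi)
    return -kAAi * AAi


def product_flux(vGlx: float, vF: float, kPj: float) -> float:
    """Secretion flux of product j, proportional to hexose transport.

    v_Pj = -k_Pj (v_Glx + v_F) >= 0 for uptake-signed (negative) hexose
    fluxes.  Inside the LP the same relation is installed as an equality
    constraint row so v_Glx, v_F remain decision variables.
    """
    if vGlx > 0 or vF > 0:
        raise ValueError("hexose fluxes must be uptake-signed (<= 0)")
    return -kPj * (vGlx + vF)


def acetate_flux(phase: str, Ace: float, vGlx: float, vF: float,
                 kP_ace: float, k_ace: float) -> float:
    """Acetate exchange: hexose-coupled production while growing,
    mass-action consumption bound (-k_ace * Ace) when quiescent."""
    _check_nonneg("acetate concentration", Ace)
    if phase in GROWTH_PHASES:
        return product_flux(vGlx, vF, kP_ace)
    if phase in QUIESCENT_PHASES:
        return -k_ace * Ace
    raise ValueError(f"unknown phase {phase!r}")


@dataclass
class KineticParams:
    """Full parameter vector of the batch-fermentation model.

    Defaults describe an anaerobic wine-like fermentation on the toy
    network (two hexoses at ~150 g/L total, moderate assimilable nitrogen);
    they are the reference conditions of the synthetic-data studies.
    Units: rates mmol/gDW/h, affinities mmol/L, first-order constants 1/h,
    phase times h.
    """

    # hexose uptake (Michaelis-Menten + competitive ethanol inhibition)
    vmaxG: float = 2.0
    kG: float = 10.0
    KEi: float = 350.0
    vmaxF: float = 1.7
    kF: float = 12.0
    KEiF: float = 350.0
    # sucrose hydrolysis and oxygen transport
    k_hydro: float = 0.05
    kO2: float = 2.0
    # nitrogen sources
    vmaxNH4: float = 0.8
    kNH4: float = 0.5
    kAA: np.ndarray = field(default_factory=lambda: np.full(3, 0.05))
    # hexose-coupled product yields (ordered like product_exchange[j]:
    # ethanol, glycerol, then generic products)
    kP: np.ndarray = field(
        default_factory=lambda: np.array([1.55, 0.14, 0.004])
    )
    kP_ace: float = 0.014
    k_ace: float = 0.005
    # protein turnover / death / decay
    lam: float = 0.008
    k_death: float = 0.004
    k_decay: float = 0.008
    k_Edeath: float = 0.012
    n_hill: float = 2.0
    k_hill: float = 1200.0
    # dynamic biomass equation
    A: float = 0.44
    B: float = -0.25
    RNA_to_Prot: float = 8.0
    dna_content: float = 0.01
    GAM_fitted: float = 25.0
    NGAM: float = 0.4
    unit_costs: dict = field(
        default_factory=lambda: {
            "protein": 30.0, "rna": 4.0, "carbohydrate": 6.2, "dna": 8.0,
        }
    )
    # stationary/decay objective and proline excretion
    phi: float = 0.01
    alpha_Pro: float = 0.002
    # observation scalings
    c_CFU: float = 5.0e7
    c_OD: float = 2.0
    # phase switch times
    t_L: float = 4.0
    t_E: float = 55.0
    t_S: float = 65.0
    t_D: float = 200.0

    def __post_init__(self) -> None:
        self.kAA = np.asarray(self.kAA, dtype=float)
        self.kP = np.asarray(self.kP, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name in ("vmaxG", "vmaxF", "kG", "kF", "KEi", "KEiF", "k_hydro",
                     "kO2", "vmaxNH4", "kNH4", "kP_ace", "k_ace", "lam",
                     "k_death", "k_decay", "k_Edeath", "n_hill", "k_hill",
                     "A", "B", "RNA_to_Prot", "dna_content", "GAM_fitted",
                     "NGAM", "phi", "alpha_Pro", "t_L", "t_E", "t_S", "t_D"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("vmaxG", "vmaxF", "k_hydro", "kO2", "vmaxNH4", "kP_ace",
                     "k_ace", "lam", "k_death", "k_decay", "k_Edeath",
                     "NGAM", "phi", "alpha_Pro"):
            _check_nonneg(name, getattr(self, name))
        for name in ("kG", "kNH4", "k_hill", "KEi", "KEiF"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if np.any(self.kAA < 0) or np.any(self.kP < 0):
            raise ValueError("kAA and kP entries must be non-negative")
        if not 0 <= self.t_L <= self.t_E <= self.t_S <= self.t_D:
            raise ValueError("phase times must satisfy t_L <= t_E <= t_S <= t_D")

    @classmethod
    def for_network(cls, network, **overrides) -> "KineticParams":
        """Defaults sized to a network's amino-acid/product exchange lists."""
        n_aa = len(network.amino_acid_exchanges)
        n_p = len(network.product_exchanges)
        kP = np.full(n_p, 0.004)
        kP[0] = 1.55
        if n_p > 1:
            kP[1] = 0.14
        base = dict(kAA=np.full(n_aa, 0.05), kP=kP)
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes) -> "KineticParams":
        return replace(self, **changes)
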