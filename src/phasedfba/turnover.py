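"""Protein turnover and nitrogen recycling in the quiescent phases.

After nitrogen depletion the cell's existing protein pool (Prot, g/L) is
degraded at rate lambda into free amino acids that appear in the medium
and can be re-assimilated, so nitrogen keeps cycling through protein even
though the net nitrogen sources are exhausted.  During stationary/decay
the LP's amino-acid uptake bounds are set by this turnover supply rather
than by the medium kinetics:

    v_AAi >= -lambda * Prot * alpha_AAi / X_A      (per-gDW basis)

where alpha_AAi is the amino-acid composition of the protein
pseudoreaction.  The per-liter release flux is normalized by the active
biomass X_A at the call site because LP fluxes are specific (per gDW).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProteinPool",
    "turnover_aa_bound",
    "protein_rhs",
    "recycled_aa_rhs",
    "proline_rhs",
]

QUIESCENT = ("stationary", "decay")


@dataclass
class ProteinPool:
    """Protein concentration (g/L), turnover rate (1/h) and amino-acid
    composition alpha_AA (mmol per g protein)."""

    Prot: float
    lam: float
    alpha_AA: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.alpha_AA = np.asarray(self.alpha_AA, dtype=float)
        if self.Prot < 0 or self.lam < 0:
            raise ValueError("Prot and lambda must be non-negative")


def turnover_aa_bound(pool: ProteinPool, i: int) -> float:
    """Volumetric turnover release bound for amino acid i:
    -lambda * Prot * alpha_AA[i] (mmol/L/h; divide by X_A for per-gDW)."""
    return -pool.lam * pool.Prot * float(pool.alpha_AA[i])


def protein_rhs(pool: ProteinPool, mu: float, X_V: float, X_A: float,
                Prot_content: float, v_Prot: float, k_death: float,
                phase: str) -> float:
    """dProt/dt (g/L/h): growth deposition, decay-phase degradation, and
    quiescent-phase synthesis/turnover.

    k_death acts only in decay; the v_Prot and lambda terms only in
    stationary/decay (during growth, protein dynamics are carried by the
    biomass deposition term alone).
    """
    dprot = mu * X_V * Prot_content
    if phase == "decay":
        dprot -= pool.Prot * k_death
    if phase in QUIESCENT:
        dprot += X_A * v_Prot - pool.lam * pool.Prot
    return dprot


def recycled_aa_rhs(pool: ProteinPool, X: float, v_AAi: float, i: int) -> float:
    """dAAi/dt (mmol/L/h): biomass-scaled exchange plus turnover release,
    X * v_AAi + lambda * Prot * alpha_AA[i].

    When the uptake bound binds exactly (v_AAi = -lambda Prot alpha / X)
    the released amino acid is fully recycled and the medium concentration
    is stationary.
    """
    return X * v_AAi + pool.lam * pool.Prot * float(pool.alpha_AA[i])


def proline_rhs(X_A: float, v_Pro: float) -> float:
    """dPro/dt = X_A * v_Pro with v_Pro >= 0 (excretion only); proline
    accumulates in the medium throughout the fermentation."""
    if v_Pro < 0:
        raise ValueError("proline flux must be excretion-signed (>= 0)")
    return X_A * v_Pro
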