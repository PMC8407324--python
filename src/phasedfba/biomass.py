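"""Dynamic biomass composition and growth-associated maintenance.

Protein content of newly formed biomass tracks the yeast assimilable
nitrogen (YAN) of the medium,

    Prot_content = A (1 - exp(B * YAN)),   B < 0,

so cells growing on rich must make protein-rich biomass and cells growing
after nitrogen depletion make carbohydrate-rich biomass.  mRNA is held
proportional to protein (mRNA = Prot/RNA-to-Prot ratio), DNA is a fixed
fraction, and carbohydrate compensates so the mass fractions always sum
to one.  The ATP coefficient of the biomass pseudoreaction (GAM) is the
fitted base cost plus composition-weighted polymerization costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gem_io import MetabolicNetwork

__all__ = [
    "BiomassComposition",
    "yan",
    "protein_content",
    "compose_biomass",
    "gam_total",
    "update_biomass_reaction",
]

#: biomass-pseudoreaction pool metabolites, in composition order
POOLS = ("prot", "rna", "carb", "dna")


@dataclass(frozen=True)
class BiomassComposition:
    """Mass fractions (g/gDW) of the four macromolecule pools."""

    Prot_content: float
    mRNA_content: float
    carb_content: float
    dna_content: float

    def __post_init__(self) -> None:
        fractions = self.as_array()
        if np.any(fractions < -1e-12) or np.any(fractions > 1 + 1e-12):
            raise ValueError(f"mass fractions outside [0, 1]: {fractions}")
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError(f"mass fractions sum to {fractions.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.Prot_content, self.mRNA_content,
                         self.carb_content, self.dna_content])


def yan(state) -> float:
    """Yeast assimilable nitrogen (mmol N-equivalents/L): ammonium plus
    free amino acids, excluding proline (not catabolized anaerobically).

    ``state`` needs attributes ``NH4`` and ``AA`` with proline at index 0.
    """
    nh4 = max(float(state.NH4), 0.0)
    aa = np.maximum(np.asarray(state.AA, dtype=float), 0.0)
    return nh4 + float(aa[1:].sum())


def protein_content(YAN: float, A: float, B: float) -> float:
    """Protein fraction of new biomass, A(1 - e^{B YAN}), saturating at A."""
    if YAN < 0:
        raise ValueError("YAN must be non-negative")
    if B >= 0:
        raise ValueError("B must be negative (saturating form)")
    value = A * (1.0 - math.exp(B * YAN))
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"protein content {value} outside [0, 1]; check A")
    return value


def compose_biomass(Prot_content: float, RNA_to_Prot: float,
                    dna_content: float) -> BiomassComposition:
    """Fill in mRNA (proportional to protein) and the compensating
    carbohydrate fraction; fractions sum to one by construction."""
    mrna = Prot_content / RNA_to_Prot
    carb = 1.0 - Prot_content - mrna - dna_content
    if carb < -1e-12:
        raise ValueError(
            f"infeasible composition: carbohydrate remainder {carb:.4g} < 0"
        )
    return BiomassComposition(Prot_content, mrna, max(carb, 0.0), dna_content)


def gam_total(comp: BiomassComposition, GAM_fitted: float,
              unit_costs: dict[str, float]) -> float:
    """Growth-associated maintenance (mmol ATP/gDW): fitted base plus
    per-gram polymerization costs weighted by composition."""
    costs = np.array([
        unit_costs.get("protein", 0.0),
        unit_costs.get("rna", 0.0),
        unit_costs.get("carbohydrate", 0.0),
        unit_costs.get("dna", 0.0),
    ])
    if np.any(costs < 0):
        raise ValueError("polymerization costs must be non-negative")
    return GAM_fitted + float(comp.as_array() @ costs)


def update_biomass_reaction(network: MetabolicNetwork,
                            comp: BiomassComposition,
                            GAM: float) -> MetabolicNetwork:
    """Rewrite the biomass pseudoreaction column in place.

    Pool coefficients become the (negative) mass fractions and the ATP
    coefficient the (negative) GAM; every other column is untouched.  The
    mass-weighted column sum stays -1 g per unit biomass flux.  Idempotent
    for a fixed composition.  Returns the same network object.
    """
    j = network.role_index("biomass")
    for met in POOLS:
        if met not in network._met_index:
            raise ValueError(f"missing macromolecule pool metabolite {met!r}")
    col = np.zeros(network.n_metabolites)
    for met, frac in zip(POOLS, comp.as_array()):
        col[network.met_index(met)] = -frac
    if "atp" in network._met_index:
        col[network.met_index("atp")] = -GAM
    network.S[:, j] = col
    return network
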