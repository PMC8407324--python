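"""Canonical toy study: the reference batch-fermentation conditions used
by the tests, the synthetic-data studies and the worked examples."""

from __future__ import annotations

from dataclasses import dataclass

from .gem_io import MetabolicNetwork, build_toy_network
from .kinetics import KineticParams
from .phase_fba import PhaseSchedule
from .simulator import CultureState, default_initial_state

__all__ = ["ToyStudy", "toy_study"]


@dataclass
class ToyStudy:
    network: MetabolicNetwork
    params: KineticParams
    schedule: PhaseSchedule
    init: CultureState


def toy_study(n_amino_acids: int = 3, n_products: int = 4,
              t0: float = 0.0, tF: float = 250.0, **param_overrides) -> ToyStudy:
    """Toy network plus the default wine-like fermentation conditions."""
    network = build_toy_network(n_amino_acids, n_products)
    params = KineticParams.for_network(network, **param_overrides)
    schedule = PhaseSchedule.from_params(params, t0, tF)
    init = default_initial_state(network)
    return ToyStudy(network, params, schedule, init)
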