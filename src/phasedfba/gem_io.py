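"""Metabolic network container, SBML input/output and network extension.

The central object is :class:`MetabolicNetwork`, a plain stoichiometric
matrix with flux bounds and a map of *special roles* (biomass pseudoreaction,
ATP maintenance, protein production, the exchange reactions the batch
simulator drives).  Genome-scale models are read from SBML Level 3 + fbc
files via COBRApy; the special roles are always resolved from an explicit
role map supplied by the caller, never inferred from reaction names, so the
same machinery works for any reconstruction.

``build_toy_network`` constructs a small, elementally book-kept fermentation
network (hexose uptake, fermentative and respiratory ATP production, amino
acid synthesis/degradation, protein/carbohydrate/RNA/DNA pools, a dynamic
biomass pseudoreaction and secreted products) used throughout the test suite
and the synthetic-data studies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetabolicNetwork",
    "ExtensionTable",
    "NewMetabolite",
    "NewReaction",
    "read_model",
    "write_model",
    "extend_model",
    "build_toy_network",
]

#: canonical names for the first few amino acids of the toy network;
#: index 0 is always proline (the non-assimilable amino acid).
_AA_NAMES = [
    "pro", "arg", "ala", "val", "leu", "ile", "ser", "thr", "phe", "tyr",
    "trp", "asp", "glu", "asn", "gln", "gly", "his", "lys", "met", "cys",
]

_INF = 1000.0  # conventional "unbounded" flux magnitude, mmol/gDW/h


class RoleResolutionError(KeyError):
    """A special role in the role map does not resolve to a reaction."""


@dataclass
class MetabolicNetwork:
    """Stoichiometric model: ``S`` (metabolites x reactions), bounds, roles.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Ordered identifiers labelling the rows/columns of ``S``.
    S
        Stoichiometric coefficients, negative = consumed.
    lb, ub
        Flux bounds per reaction (mmol/gDW/h; the biomass reaction in 1/h,
        macromolecule-pool reactions in g/gDW/h).
    special
        Role -> reaction id.  Indexed roles use bracket notation, e.g.
        ``amino_acid_exchange[1]``.
    exchanges
        Reaction ids that cross the system boundary.
    carbon, nitrogen
        Declared element content per metabolite unit (mmol C or N per mmol,
        per gram for the macromolecule pools).  Used for conservation
        bookkeeping without formula parsing.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    special: dict[str, str] = field(default_factory=dict)
    exchanges: set[str] = field(default_factory=set)
    carbon: dict[str, float] = field(default_factory=dict)
    nitrogen: dict[str, float] = field(default_factory=dict)
    #: bumped whenever the sparsity structure changes (solver caches key on it)
    structure_version: int = 0

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self._met_index = {m: i for i, m in enumerate(self.metabolite_ids)}
        self._rxn_index = {r: j for j, r in enumerate(self.reaction_ids)}

    # -- indexing ---------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def met_index(self, met_id: str) -> int:
        return self._met_index[met_id]

    def rxn_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def role_index(self, role: str) -> int:
        return self.rxn_index(self.special[role])

    def indexed_roles(self, prefix: str) -> list[str]:
        """Reaction ids for roles ``prefix[1]``, ``prefix[2]``, ... in order."""
        out = []
        i = 1
        while f"{prefix}[{i}]" in self.special:
            out.append(self.special[f"{prefix}[{i}]"])
            i += 1
        return out

    @property
    def amino_acid_exchanges(self) -> list[str]:
        return self.indexed_roles("amino_acid_exchange")

    @property
    def product_exchanges(self) -> list[str]:
        return self.indexed_roles("product_exchange")

    def protein_alpha(self) -> np.ndarray:
        """Amino-acid coefficients alpha_AA (mmol/g protein) of the protein
        synthesis pseudoreaction, ordered like ``amino_acid_exchanges``."""
        js = self.rxn_index(self.special["protein_synthesis"])
        alphas = []
        for ex in self.amino_acid_exchanges:
            met = self._exchange_metabolite(ex)
            alphas.append(-self.S[self.met_index(met), js])
        return np.asarray(alphas)

    def _exchange_metabolite(self, rxn_id: str) -> str:
        col = self.S[:, self.rxn_index(rxn_id)]
        (rows,) = np.nonzero(col)
        if len(rows) != 1:
            raise ValueError(f"{rxn_id} is not a single-metabolite exchange")
        return self.metabolite_ids[rows[0]]

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            list(self.metabolite_ids),
            list(self.reaction_ids),
            self.S.copy(),
            self.lb.copy(),
            self.ub.copy(),
            dict(self.special),
            set(self.exchanges),
            dict(self.carbon),
            dict(self.nitrogen),
            self.structure_version,
        )

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        for role, rid in self.special.items():
            if rid not in self._rxn_index:
                raise RoleResolutionError(
                    f"special role {role!r} maps to unknown reaction {rid!r}"
                )
        if np.any(self.lb > self.ub):
            bad = [
                self.reaction_ids[j]
                for j in np.nonzero(self.lb > self.ub)[0]
            ]
            raise ValueError(f"lb > ub for reactions {bad}")
        empty = np.all(self.S == 0, axis=1)
        if np.any(empty):
            bad = [self.metabolite_ids[i] for i in np.nonzero(empty)[0]]
            raise ValueError(f"all-zero metabolite rows: {bad}")

    # -- element bookkeeping ---------------------------------------------
    def element_vector(self, element: str = "carbon") -> np.ndarray:
        table = self.carbon if element == "carbon" else self.nitrogen
        return np.array([table.get(m, 0.0) for m in self.metabolite_ids])

    def carbon_balance(self, v: np.ndarray) -> dict[str, float]:
        """Split the carbon flow of a flux vector into boundary terms.

        For any v with ``S v = 0`` on internal metabolites, carbon imported
        through the exchanges equals carbon leaving through the biomass and
        protein-accumulation sinks (the toy network's internal reactions are
        carbon-balanced by construction), so ``net`` is ~0 for feasible v.
        """
        c = self.element_vector("carbon")
        ex_cols = [self.rxn_index(r) for r in sorted(self.exchanges)]
        uptake = 0.0
        for j in ex_cols:
            met_c = float(c @ self.S[:, j])  # = -C of the metabolite
            uptake += met_c * v[j]           # uptake flux v<0 adds carbon
        sink = 0.0
        for role in ("biomass", "protein_production"):
            if role in self.special:
                j = self.role_index(role)
                if j not in ex_cols:
                    sink += -float(c @ self.S[:, j]) * v[j]
        return {"uptake": uptake, "into_biomass": sink, "net": uptake - sink}


# -- extension tables ------------------------------------------------------

@dataclass(frozen=True)
class NewMetabolite:
    id: str
    formula: str = ""
    compartment: str = "c"

    @property
    def carbon(self) -> float:
        return _element_count(self.formula, "C")

    @property
    def nitrogen(self) -> float:
        return _element_count(self.formula, "N")


@dataclass(frozen=True)
class NewReaction:
    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    gene_note: str = ""


@dataclass
class ExtensionTable:
    """Generic reaction/metabolite additions to an existing network."""

    new_metabolites: list[NewMetabolite] = field(default_factory=list)
    new_reactions: list[NewReaction] = field(default_factory=list)

    @classmethod
    def from_csv(cls, path) -> "ExtensionTable":
        """Read the delimited format (kind, id, stoichiometry, reversible).

        Metabolite rows put their chemical formula in the stoichiometry
        column; reaction rows encode stoichiometry as ``met:coef;met:coef``.
        """
        import pandas as pd

        df = pd.read_csv(path)
        table = cls()
        for _, row in df.iterrows():
            if row["kind"] == "metabolite":
                table.new_metabolites.append(
                    NewMetabolite(row["id"], str(row.get("stoichiometry", "") or ""))
                )
            elif row["kind"] == "reaction":
                stoich = {}
                for term in str(row["stoichiometry"]).split(";"):
                    met, coef = term.split(":")
                    stoich[met.strip()] = float(coef)
                table.new_reactions.append(
                    NewReaction(row["id"], stoich, bool(row.get("reversible", False)))
                )
            else:
                raise ValueError(f"unknown extension row kind {row['kind']!r}")
        return table


def _element_count(formula: str, element: str) -> float:
    if not formula:
        return 0.0
    m = re.search(rf"{element}(?![a-z])(\d*)", formula)
    if not m:
        return 0.0
    return float(m.group(1)) if m.group(1) else 1.0


def extend_model(network: MetabolicNetwork, table: ExtensionTable) -> MetabolicNetwork:
    """Append the table's metabolites/reactions; returns a new network.

    Raises on duplicate identifiers and on reactions that reference
    metabolites neither in the network nor declared in the table.
    """
    new_met_ids = [m.id for m in table.new_metabolites]
    new_rxn_ids = [r.id for r in table.new_reactions]
    for mid in new_met_ids:
        if mid in network._met_index:
            raise ValueError(f"duplicate metabolite id {mid!r}")
    for rid in new_rxn_ids:
        if rid in network._rxn_index:
            raise ValueError(f"duplicate reaction id {rid!r}")
    known = set(network.metabolite_ids) | set(new_met_ids)
    for rxn in table.new_reactions:
        for met in rxn.stoichiometry:
            if met not in known:
                raise ValueError(
                    f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                )

    met_ids = list(network.metabolite_ids) + new_met_ids
    rxn_ids = list(network.reaction_ids) + new_rxn_ids
    S = np.zeros((len(met_ids), len(rxn_ids)))
    S[: network.n_metabolites, : network.n_reactions] = network.S
    met_index = {m: i for i, m in enumerate(met_ids)}
    lb = np.concatenate([network.lb, np.zeros(len(new_rxn_ids))])
    ub = np.concatenate([network.ub, np.zeros(len(new_rxn_ids))])
    for k, rxn in enumerate(table.new_reactions):
        j = network.n_reactions + k
        for met, coef in rxn.stoichiometry.items():
            S[met_index[met], j] = coef
        lb[j] = -_INF if rxn.reversible else 0.0
        ub[j] = _INF

    carbon = dict(network.carbon)
    nitrogen = dict(network.nitrogen)
    for m in table.new_metabolites:
        carbon[m.id] = m.carbon
        nitrogen[m.id] = m.nitrogen

    exchanges = set(network.exchanges)
    for k, rxn in enumerate(table.new_reactions):
        if len(rxn.stoichiometry) == 1:
            exchanges.add(rxn.id)

    out = MetabolicNetwork(
        met_ids, rxn_ids, S, lb, ub, dict(network.special), exchanges,
        carbon, nitrogen, network.structure_version + 1,
    )
    return out


# -- SBML ------------------------------------------------------------------

def read_model(path, role_map: dict[str, str]) -> MetabolicNetwork:
    """Read an SBML Level 3 + fbc model and resolve special roles.

    Only fbc-style flux bounds are accepted; reactions carrying kinetic laws
    or lacking bound annotations are rejected with a hard error.  ``role_map``
    maps role names (``biomass``, ``glucose_exchange``, ...) to reaction ids
    of the reconstruction at hand.
    """
    import libsbml

    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(f"SBML parse error in {path}")
    model = doc.getModel()
    if model is None:
        raise ValueError(f"no model in {path}")
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        if rxn.isSetKineticLaw():
            raise ValueError(
                f"reaction {rxn.getId()!r} carries a kinetic law; "
                "only fbc flux bounds are supported"
            )
        fbc = rxn.getPlugin("fbc")
        if (
            fbc is None
            or not fbc.isSetLowerFluxBound()
            or not fbc.isSetUpperFluxBound()
        ):
            raise ValueError(f"missing bounds for reaction {rxn.getId()!r}")

    import cobra.io

    cmodel = cobra.io.read_sbml_model(str(path))
    return _from_cobra(cmodel, role_map)


def _from_cobra(cmodel, role_map: dict[str, str]) -> MetabolicNetwork:
    from cobra.util.array import create_stoichiometric_matrix

    met_ids = [m.id for m in cmodel.metabolites]
    rxn_ids = [r.id for r in cmodel.reactions]
    S = create_stoichiometric_matrix(cmodel)
    lb = np.array([r.lower_bound for r in cmodel.reactions])
    ub = np.array([r.upper_bound for r in cmodel.reactions])
    carbon, nitrogen = {}, {}
    for m in cmodel.metabolites:
        notes = m.notes or {}
        if "carbon" in notes:
            carbon[m.id] = float(notes["carbon"])
        if "nitrogen" in notes:
            nitrogen[m.id] = float(notes["nitrogen"])
    exchanges = {r.id for r in cmodel.reactions if r.boundary}
    net = MetabolicNetwork(met_ids, rxn_ids, S, lb, ub, dict(role_map),
                           exchanges, carbon, nitrogen)
    net.validate()
    return net


def write_model(network: MetabolicNetwork, path) -> None:
    """Write the network as SBML Level 3 + fbc (round-trips S, lb, ub)."""
    import cobra
    import cobra.io

    cmodel = cobra.Model("phasedfba_export")
    mets = {}
    for mid in network.metabolite_ids:
        m = cobra.Metabolite(mid, compartment="c")
        notes = {}
        if mid in network.carbon:
            notes["carbon"] = network.carbon[mid]
        if mid in network.nitrogen:
            notes["nitrogen"] = network.nitrogen[mid]
        m.notes = notes
        mets[mid] = m
    cmodel.add_metabolites(list(mets.values()))
    rxns = []
    for j, rid in enumerate(network.reaction_ids):
        r = cobra.Reaction(rid)
        r.lower_bound = float(network.lb[j])
        r.upper_bound = float(network.ub[j])
        rxns.append(r)
    cmodel.add_reactions(rxns)
    for j, rid in enumerate(network.reaction_ids):
        col = network.S[:, j]
        stoich = {
            mets[network.metabolite_ids[i]]: col[i]
            for i in np.nonzero(col)[0]
        }
        cmodel.reactions.get_by_id(rid).add_metabolites(stoich)
    cobra.io.write_sbml_model(cmodel, str(path))


# -- toy network -----------------------------------------------------------

def build_toy_network(n_amino_acids: int = 3, n_products: int = 4) -> MetabolicNetwork:
    """Desk-scale batch-fermentation network with full element bookkeeping.

    The network carries glucose/fructose/oxygen/ammonium/amino-acid
    exchanges, fermentative (2 ATP), acetogenic (4 ATP) and respiratory
    (18 ATP) hexose catabolism, glycerol overflow, per-amino-acid synthesis
    and degradation routes, gram-based protein/carbohydrate/RNA/DNA pools,
    a biomass pseudoreaction (coefficients rewritten dynamically by the
    biomass module) and product exchanges.  Products 1..3 are always
    ethanol, glycerol and acetate; extra products are generic C5
    fusel-alcohol-like compounds.

    Every internal reaction conserves the declared per-metabolite carbon
    and nitrogen counts exactly, which is what makes whole-simulation
    conservation checks possible without formula parsing.

    Parameters
    ----------
    n_amino_acids
        Number of amino acids (>= 1); the first is always proline.
    n_products
        Number of secreted products (>= 3).
    """
    if n_amino_acids < 1:
        raise ValueError("n_amino_acids must be >= 1")
    if n_products < 3:
        raise ValueError("n_products must be >= 3 (ethanol, glycerol, acetate)")

    aa_names = [
        _AA_NAMES[i] if i < len(_AA_NAMES) else f"aa{i + 1}"
        for i in range(n_amino_acids)
    ]
    extra_products = [f"p{j + 1}" for j in range(3, n_products)]

    mets = ["glc", "fru", "o2", "nh4", "co2", "atp", "etoh", "glyc", "ace"]
    mets += aa_names + extra_products + ["prot", "carb", "rna", "dna"]

    carbon = {"glc": 6, "fru": 6, "co2": 1, "etoh": 2, "glyc": 3, "ace": 2,
              "carb": 37.2, "rna": 30, "dna": 30}
    nitrogen = {"nh4": 1, "rna": 2, "dna": 2}
    for aa in aa_names:
        carbon[aa] = 5
        nitrogen[aa] = 1
    for p in extra_products:
        carbon[p] = 5
    alpha = 9.0 / n_amino_acids  # mmol residue per g protein, uniform
    carbon["prot"] = 5 * alpha * n_amino_acids  # = 45 mmol C / g
    nitrogen["prot"] = alpha * n_amino_acids    # = 9 mmol N / g

    cols: dict[str, dict[str, float]] = {}
    bounds: dict[str, tuple[float, float]] = {}

    def add(rid, stoich, lb=0.0, ub=_INF):
        cols[rid] = stoich
        bounds[rid] = (lb, ub)

    # exchanges (boundary): flux < 0 is uptake, > 0 secretion
    substrates = ["glc", "fru", "o2", "nh4"] + aa_names
    products = ["etoh", "glyc", "ace"] + extra_products + ["co2"]
    for m in substrates:
        add(f"EX_{m}", {m: -1.0}, -_INF, _INF)
    for m in products:
        add(f"EX_{m}", {m: -1.0}, 0.0, _INF)

    # catabolism
    add("ferm", {"glc": -1, "etoh": 2, "co2": 2, "atp": 2})
    add("fru2glc", {"fru": -1, "glc": 1}, -_INF, _INF)
    add("glyc_syn", {"glc": -1, "atp": -0.5, "glyc": 2})
    add("ace_syn", {"glc": -1, "ace": 2, "co2": 2, "atp": 2})
    add("ace_use", {"ace": -1, "co2": 2})
    add("resp", {"glc": -1, "o2": -6, "co2": 6, "atp": 18})

    # amino-acid metabolism
    for aa in aa_names:
        add(f"syn_{aa}", {"glc": -5.0 / 6.0, "nh4": -1, "atp": -1, aa: 1})
    for aa in aa_names[1:]:  # proline is not catabolized anaerobically
        add(f"deg_{aa}", {aa: -1, "nh4": 1, "co2": 5, "atp": 1})

    # macromolecule pools (gram-based fluxes)
    add("prot_syn", {aa: -alpha for aa in aa_names} | {"atp": -10.0, "prot": 1.0})
    add("carb_syn", {"glc": -6.2, "atp": -0.5, "carb": 1.0})
    add("rna_syn", {"glc": -5.0, "nh4": -2.0, "atp": -6.0, "rna": 1.0})
    add("dna_syn", {"glc": -5.0, "nh4": -2.0, "atp": -8.0, "dna": 1.0})

    # product synthesis for the generic extra products
    for p in extra_products:
        add(f"syn_{p}", {"glc": -5.0 / 6.0, "atp": -0.5, p: 1.0})

    # sinks: biomass pseudoreaction (placeholder composition; rewritten by
    # the biomass module), protein accumulation, ATP maintenance
    add("biomass", {"prot": -0.40, "rna": -0.05, "carb": -0.54, "dna": -0.01,
                    "atp": -40.0})
    add("prot_acc", {"prot": -1.0})
    add("atp_maint", {"atp": -1.0})

    rxn_ids = list(cols)
    met_index = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rxn_ids)))
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        for met, coef in cols[rid].items():
            S[met_index[met], j] = coef
        lb[j], ub[j] = bounds[rid]

    special = {
        "biomass": "biomass",
        "atp_maintenance": "atp_maint",
        "protein_production": "prot_acc",
        "protein_synthesis": "prot_syn",
        "glucose_exchange": "EX_glc",
        "fructose_exchange": "EX_fru",
        "oxygen_exchange": "EX_o2",
        "ammonium_exchange": "EX_nh4",
        "proline_exchange": "EX_pro",
        "acetate_exchange": "EX_ace",
    }
    for i, aa in enumerate(aa_names, start=1):
        special[f"amino_acid_exchange[{i}]"] = f"EX_{aa}"
    # products subject to hexose-proportional secretion (acetate handled
    # separately by its phase-switching rule)
    for j, p in enumerate(["etoh", "glyc"] + extra_products, start=1):
        special[f"product_exchange[{j}]"] = f"EX_{p}"

    exchanges = {f"EX_{m}" for m in substrates + products}
    net = MetabolicNetwork(mets, rxn_ids, S, lb, ub, special, exchanges,
                           carbon, nitrogen)
    net.validate()
    _assert_element_closure(net)
    return net


def _assert_element_closure(net: MetabolicNetwork) -> None:
    """Internal reactions must conserve declared carbon and nitrogen."""
    sinks = {net.special.get("biomass"), net.special.get("protein_production")}
    for element in ("carbon", "nitrogen"):
        e = net.element_vector(element)
        imbalance = e @ net.S
        for j, rid in enumerate(net.reaction_ids):
            if rid in net.exchanges or rid in sinks:
                continue
            if abs(imbalance[j]) > 1e-9:
                raise AssertionError(
                    f"{element} imbalance {imbalance[j]:.3g} in {rid}"
                )
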