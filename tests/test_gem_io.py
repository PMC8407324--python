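import numpy as np
import pytest

from phasedfba.gem_io import (ExtensionTable, MetabolicNetwork, NewMetabolite,
                              NewReaction, build_toy_network, extend_model,
                              read_model, write_model)
from phasedfba.phase_fba import fba

ROLE_MAP_KEYS = ["biomass", "atp_maintenance", "protein_production",
                 "glucose_exchange", "fructose_exchange", "oxygen_exchange",
                 "ammonium_exchange", "proline_exchange", "acetate_exchange"]


class TestToyNetwork:
    def test_roles_resolve_and_invariants_hold(self, toy):
        net = toy.network
        net.validate()
        for role in ROLE_MAP_KEYS:
            assert net.special[role] in net.reaction_ids
        assert len(net.amino_acid_exchanges) == 3
        assert len(net.product_exchanges) == 3  # ethanol, glycerol, extra
        assert np.all(net.lb <= net.ub)
        assert not np.any(np.all(net.S == 0, axis=1))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            build_toy_network(n_amino_acids=0)
        with pytest.raises(ValueError):
            build_toy_network(n_products=2)

    def test_growth_viable_on_glucose(self, toy):
        mu = fba(toy.network, toy.network.special["biomass"],
                 bounds_override={"EX_glc": (-5.0, 0.0),
                                  "EX_nh4": (-2.0, 0.0)})
        assert mu > 0

    def test_no_input_no_growth(self, toy):
        net = toy.network
        override = {rid: (0.0, 0.0) for rid in net.exchanges}
        mu = fba(net, net.special["biomass"], bounds_override=override)
        assert mu == pytest.approx(0.0, abs=1e-9)

    def test_internal_reactions_conserve_declared_elements(self, toy):
        net = toy.network
        sinks = {net.special["biomass"], net.special["protein_production"]}
        for element in ("carbon", "nitrogen"):
            imbalance = net.element_vector(element) @ net.S
            for j, rid in enumerate(net.reaction_ids):
                if rid in net.exchanges or rid in sinks:
                    continue
                assert abs(imbalance[j]) < 1e-9, (element, rid)

    def test_feasible_flux_closes_carbon(self, toy):
        """Carbon entering through exchanges equals carbon leaving into the
        biomass/protein sinks for an actual pFBA solution."""
        from phasedfba.phase_fba import assemble_problem, solve_pfba

        problem = assemble_problem(toy.network, "exponential", toy.init,
                                   toy.params)
        sol = solve_pfba(problem)
        balance = toy.network.carbon_balance(sol.v)
        assert sol.status == "optimal"
        assert balance["uptake"] > 0
        assert abs(balance["net"]) < 1e-9


class TestSbmlRoundTrip:
    def test_round_trip_preserves_structure(self, toy, tmp_path):
        path = tmp_path / "toy.xml"
        write_model(toy.network, path)
        back = read_model(path, dict(toy.network.special))
        assert back.reaction_ids == toy.network.reaction_ids
        assert back.metabolite_ids == toy.network.metabolite_ids
        np.testing.assert_allclose(back.S, toy.network.S, atol=1e-12)
        np.testing.assert_allclose(back.lb, toy.network.lb)
        np.testing.assert_allclose(back.ub, toy.network.ub)
        assert back.carbon == pytest.approx(toy.network.carbon)

    def test_reaction_count_preserved(self, toy, tmp_path):
        path = tmp_path / "toy.xml"
        write_model(toy.network, path)
        back = read_model(path, dict(toy.network.special))
        assert back.n_reactions == toy.network.n_reactions

    def test_unresolved_role_is_hard_error(self, toy, tmp_path):
        path = tmp_path / "toy.xml"
        write_model(toy.network, path)
        with pytest.raises(KeyError, match="nonexistent"):
            read_model(path, {"biomass": "nonexistent_rxn"})

    def test_missing_bounds_rejected(self, tmp_path):
        import libsbml

        doc = libsbml.SBMLDocument(3, 1)
        model = doc.createModel("bare")
        c = model.createCompartment()
        c.setId("c"), c.setConstant(True)
        s = model.createSpecies()
        s.setId("met"), s.setCompartment("c")
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False), s.setConstant(False)
        r = model.createReaction()
        r.setId("rxn"), r.setReversible(True), r.setFast(False)
        sr = r.createReactant()
        sr.setSpecies("met"), sr.setStoichiometry(1.0), sr.setConstant(True)
        path = tmp_path / "nobounds.xml"
        libsbml.writeSBML(doc, str(path))
        with pytest.raises(ValueError, match="missing bounds"):
            read_model(path, {})

    def test_kinetic_law_rejected(self, toy, tmp_path):
        import libsbml

        path = tmp_path / "toy.xml"
        write_model(toy.network, path)
        doc = libsbml.readSBML(str(path))
        rxn = doc.getModel().getReaction(0)
        kl = rxn.createKineticLaw()
        kl.setMath(libsbml.parseL3Formula("1"))
        bad = tmp_path / "kinetic.xml"
        libsbml.writeSBML(doc, str(bad))
        with pytest.raises(ValueError, match="kinetic law"):
            read_model(bad, dict(toy.network.special))


class TestExtendModel:
    def _table(self):
        return ExtensionTable(
            new_metabolites=[NewMetabolite("succ", "C4H6O4")],
            new_reactions=[
                NewReaction("succ_syn", {"glc": -2.0 / 3.0, "succ": 1.0,
                                         "atp": -0.5}),
                NewReaction("EX_succ", {"succ": -1.0}),
            ],
        )

    def test_empty_table_is_identity(self, toy):
        out = extend_model(toy.network, ExtensionTable())
        assert out.reaction_ids == toy.network.reaction_ids
        np.testing.assert_array_equal(out.S, toy.network.S)

    def test_counts_grow_by_table_size(self, toy):
        out = extend_model(toy.network, self._table())
        assert out.n_metabolites == toy.network.n_metabolites + 1
        assert out.n_reactions == toy.network.n_reactions + 2
        assert out.carbon["succ"] == 4

    def test_duplicate_id_rejected(self, toy):
        table = ExtensionTable(new_reactions=[
            NewReaction("ferm", {"glc": -1.0})])
        with pytest.raises(ValueError, match="duplicate"):
            extend_model(toy.network, table)

    def test_unknown_metabolite_rejected(self, toy):
        table = ExtensionTable(new_reactions=[
            NewReaction("bad", {"mystery": 1.0})])
        with pytest.raises(ValueError, match="unknown metabolite"):
            extend_model(toy.network, table)

    def test_extension_makes_product_feasible(self, toy):
        """A secreted product is infeasible until its synthesis route and
        exchange are added."""
        extended = extend_model(toy.network, self._table())
        vmax = fba(extended, "EX_succ",
                   bounds_override={"EX_glc": (-5.0, 0.0)})
        assert vmax > 0

    def test_disjoint_extensions_commute(self, toy):
        t1 = self._table()
        t2 = ExtensionTable(
            new_metabolites=[NewMetabolite("mal", "C4H6O5")],
            new_reactions=[NewReaction("EX_mal", {"mal": -1.0})],
        )

        def coef_map(net):
            out = {}
            for j, rid in enumerate(net.reaction_ids):
                for i in np.nonzero(net.S[:, j])[0]:
                    out[(net.metabolite_ids[i], rid)] = net.S[i, j]
            return out

        a = extend_model(extend_model(toy.network, t1), t2)
        b = extend_model(extend_model(toy.network, t2), t1)
        assert coef_map(a) == coef_map(b)

    def test_extension_table_csv_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame([
            {"kind": "metabolite", "id": "succ", "stoichiometry": "C4H6O4",
             "reversible": False},
            {"kind": "reaction", "id": "EX_succ",
             "stoichiometry": "succ:-1", "reversible": True},
        ])
        path = tmp_path / "ext.csv"
        df.to_csv(path, index=False)
        table = ExtensionTable.from_csv(path)
        assert table.new_metabolites[0].carbon == 4
        assert table.new_reactions[0].stoichiometry == {"succ": -1.0}
        assert table.new_reactions[0].reversible
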