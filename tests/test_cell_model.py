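"""Cell-scale model builders, variants, validation and serialisation."""

import math

import numpy as np
import pytest

from gridfba import (
    apply_variant,
    build_branched_model,
    build_linear_model,
    load_model,
    save_model,
    solve_cell_scale,
    validate_model,
)
from gridfba.cell_model import ReactionSpec

# Stoichiometric matrices of the two toy pathways (rows: declared metabolite
# order; columns: declared reaction order).
S_LINEAR = np.array(
    [
        [1, -1, 0, 0, 0],
        [0, 1, -1, 0, 0],
        [0, 0, 1, -1, 0],
        [0, 0, 0, 1, -1],
    ],
    dtype=float,
)

S_BRANCHED = np.array(
    [
        [1, -1, 0, 0, 0, 0, 0],
        [0, 1, -1, 0, 0, 0, 0],
        [0, 0, 1, -1, -1, 0, 0],
        [0, 0, 0, 4, 3, -1, 0],
        [0, 0, 0, 0, 1, 0, -1],
    ],
    dtype=float,
)


class TestBuilders:
    def test_linear_stoichiometric_matrix(self, linear_model):
        np.testing.assert_array_equal(linear_model.stoichiometric_matrix(), S_LINEAR)

    def test_branched_stoichiometric_matrix(self, branched_model):
        np.testing.assert_array_equal(
            branched_model.stoichiometric_matrix(), S_BRANCHED
        )

    def test_linear_objective_is_biomass_sink(self, linear_model):
        np.testing.assert_array_equal(
            linear_model.objective_vector(), [0, 0, 0, 0, 1]
        )

    def test_branched_objective_scalarisation(self, branched_model):
        np.testing.assert_array_equal(
            branched_model.objective_vector(), [0, 0, 0, 0, 0, 1, -2]
        )

    def test_linear_parameters(self, linear_model):
        assert linear_model.reaction("R1").upper_bound == 100.0
        assert linear_model.reaction("R5").upper_bound == math.inf
        for rxn_id, enz_id in [("R2", "E1"), ("R3", "E2"), ("R4", "E3")]:
            rxn = linear_model.reaction(rxn_id)
            assert rxn.catalyst == enz_id
            enz = linear_model.enzyme(enz_id)
            assert enz.total_amount == 100.0 and enz.kcat == 1.0

    def test_branched_fast_secondary_enzyme(self, branched_model):
        assert branched_model.enzyme("E7").kcat == 2.0
        for eid in ("E4", "E5", "E6"):
            assert branched_model.enzyme(eid).kcat == 1.0
        assert all(e.total_amount == 100.0 for e in branched_model.enzymes)

    def test_builders_validate_clean(self, linear_model, branched_model):
        assert validate_model(linear_model) == []
        assert validate_model(branched_model) == []


class TestConventionalFBA:
    """Cell-scale LP optima; the printed parameter sets pin these exactly."""

    @pytest.mark.parametrize(
        "builder,expected",
        [(build_linear_model, 100.0), (build_branched_model, 400.0)],
    )
    def test_optimum(self, builder, expected):
        sol = solve_cell_scale(builder())
        assert sol.optimal
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)

    def test_branched_optimum_uses_primary_path_only(self, branched_model):
        sol = solve_cell_scale(branched_model)
        assert sol.fluxes["R9"] == pytest.approx(100.0, abs=1e-6)
        assert sol.fluxes["R10"] == pytest.approx(0.0, abs=1e-6)

    def test_agrees_with_cobrapy(self, linear_model, branched_model):
        """Independent oracle: the same LPs solved through cobrapy/GLPK."""
        cobra = pytest.importorskip("cobra")
        for model, expected in [(linear_model, 100.0), (branched_model, 400.0)]:
            cm = cobra.Model(model.name)
            mets = {
                m.id: cobra.Metabolite(m.id.replace("[", "_").replace("]", ""),
                                       compartment=m.compartment)
                for m in model.metabolites
            }
            for rxn in model.reactions:
                lo, hi = model.capacity_bounds(rxn)
                cr = cobra.Reaction(rxn.id)
                cr.lower_bound = lo
                cr.upper_bound = min(hi, 1e6)
                cm.add_reactions([cr])
                cr.add_metabolites(
                    {mets[m]: c for m, c in rxn.stoichiometry.items()}
                )
            cm.objective = {
                cm.reactions.get_by_id(r.id): r.objective_weight
                for r in model.reactions
                if r.objective_weight != 0
            }
            assert cm.optimize().objective_value == pytest.approx(expected, abs=1e-6)


class TestVariants:
    def test_default_is_identity(self, linear_model):
        assert apply_variant(linear_model, "default") is linear_model

    def test_b_limiting_doubles_b_consumption(self, linear_model):
        out = apply_variant(linear_model, "B_limiting")
        assert out.reaction("R4").stoichiometry["B[c]"] == -2.0
        assert linear_model.reaction("R4").stoichiometry["B[c]"] == -1.0  # original intact
        assert [e.total_amount for e in out.enzymes] == [100.0] * 3

    def test_a_limiting_halves_the_optimum(self, linear_model):
        out = apply_variant(linear_model, "A_limiting")
        assert out.reaction("R3").stoichiometry["A[c]"] == -2.0
        # 100 A available but 2 consumed per B => at most 50 biomass
        assert solve_cell_scale(out).objective_value == pytest.approx(50.0, abs=1e-6)

    def test_b_limiting_keeps_optimum(self, linear_model):
        # B supply 100, 2 B per biomass, E3 capacity 100 -> optimum 50
        out = apply_variant(linear_model, "B_limiting")
        assert solve_cell_scale(out).objective_value == pytest.approx(50.0, abs=1e-6)

    def test_variant_requires_linear_reactions(self, branched_model):
        with pytest.raises(ValueError, match="R3/R4"):
            apply_variant(branched_model, "B_limiting")

    def test_unknown_variant_rejected(self, linear_model):
        with pytest.raises(ValueError, match="unknown variant"):
            apply_variant(linear_model, "C_limiting")


class TestValidation:
    def test_dangling_metabolite_reported(self, linear_model):
        linear_model.reactions[2].stoichiometry["ghost"] = 1.0
        problems = validate_model(linear_model)
        assert len(problems) == 1 and "ghost" in problems[0]

    def test_inverted_bounds_reported(self, linear_model):
        linear_model.reaction("R1").lower_bound = 5.0
        linear_model.reaction("R1").upper_bound = 1.0
        problems = validate_model(linear_model)
        assert len(problems) == 1 and "R1" in problems[0]

    def test_unknown_catalyst_reported(self, linear_model):
        linear_model.reaction("R3").catalyst = "E99"
        assert any("E99" in p for p in validate_model(linear_model))

    def test_missing_objective_reported(self, linear_model):
        linear_model.reaction("R5").objective_weight = 0.0
        assert any("objective" in p for p in validate_model(linear_model))


class TestSerialisation:
    @pytest.mark.parametrize("builder", [build_linear_model, build_branched_model])
    def test_yaml_round_trip(self, builder, tmp_path):
        model = builder()
        path = tmp_path / "model.yaml"
        save_model(model, path)
        back = load_model(path)
        assert back == model

    def test_infinite_bounds_survive_round_trip(self, linear_model, tmp_path):
        path = tmp_path / "model.yaml"
        save_model(linear_model, path)
        assert load_model(path).reaction("R5").upper_bound == math.inf


class TestSBMLImport:
    def test_reads_fbc_model(self, linear_model, tmp_path):
        """Round-trip through cobrapy's SBML-FBC writer recovers the network."""
        cobra = pytest.importorskip("cobra")
        pytest.importorskip("libsbml")
        from gridfba.cell_model import read_sbml

        cm = cobra.Model("linear_sbml")
        ids = {}
        for m in linear_model.metabolites:
            cid = m.id.replace("[", "_").replace("]", "")
            ids[m.id] = cid
            cm.add_metabolites(
                [cobra.Metabolite(cid, compartment=m.compartment)]
            )
        for rxn in linear_model.reactions:
            cr = cobra.Reaction(rxn.id)
            cr.lower_bound, cr.upper_bound = rxn.lower_bound, min(rxn.upper_bound, 1000)
            cm.add_reactions([cr])
            cr.add_metabolites(
                {cm.metabolites.get_by_id(ids[m]): c for m, c in rxn.stoichiometry.items()}
            )
        cm.objective = cm.reactions.R5
        path = tmp_path / "linear.xml"
        cobra.io.write_sbml_model(cm, str(path))

        imported = read_sbml(path)
        assert [r.id for r in imported.reactions] == linear_model.reaction_ids
        np.testing.assert_array_equal(
            imported.stoichiometric_matrix(), linear_model.stoichiometric_matrix()
        )
        assert imported.reaction("R5").objective_weight == 1.0
        assert imported.reaction("R2").kind == "transport"
        assert imported.reaction("R1").kind == "exchange"
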