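"""Model container, edits, GPR logic, and JSON/SBML I/O."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_eval_gpr, oracle_fba_optimum
from undermet import (
    LARGE_BOUND,
    Reaction,
    add_demand,
    add_isozyme,
    add_reaction,
    eval_gpr,
    fba,
    fva,
    knock_out_genes,
    load_model,
    save_model,
    set_exchange,
)
from undermet.model import GPRSyntaxError, ModelValidationError
from conftest import random_toy_models


class TestIO:
    def test_round_trip_preserves_all_fields(self, toy_model, tmp_path):
        path = tmp_path / "toy.json"
        save_model(toy_model, path)
        loaded = load_model(path)
        assert loaded.objective_id == toy_model.objective_id
        assert loaded.genes == toy_model.genes
        assert {m.id for m in loaded.metabolites} == {m.id for m in toy_model.metabolites}
        for orig in toy_model.reactions:
            back = loaded.reaction(orig.id)
            assert back.stoichiometry == orig.stoichiometry
            assert back.lower_bound == orig.lower_bound
            assert back.upper_bound == orig.upper_bound
            assert back.gpr == orig.gpr
            assert back.tags == orig.tags

    def test_toy_fixture_loads_with_objective(self, toy_model, tmp_path):
        path = tmp_path / "toy.json"
        save_model(toy_model, path)
        model = load_model(path)
        assert len(model.reactions) == len(toy_model.reactions)
        assert model.objective_id == "BIOMASS"

    def test_undeclared_metabolite_is_a_validation_error(self, toy_model, tmp_path):
        path = tmp_path / "bad.json"
        save_model(toy_model, path)
        raw = json.loads(path.read_text())
        raw["reactions"][1]["metabolites"]["ghost_c"] = 1.0
        path.write_text(json.dumps(raw))
        with pytest.raises(ModelValidationError, match="ghost_c"):
            load_model(path)

    def test_missing_objective_is_a_validation_error(self, toy_model, tmp_path):
        path = tmp_path / "noobj.json"
        save_model(toy_model, path)
        raw = json.loads(path.read_text())
        for rec in raw["reactions"]:
            rec["objective_coefficient"] = 0.0
            rec["notes"]["tags"] = []
        raw["reactions"] = [r for r in raw["reactions"] if r["id"] != "BIOMASS"]
        path.write_text(json.dumps(raw))
        with pytest.raises(ModelValidationError):
            load_model(path)

    def test_malformed_json_names_the_file(self, tmp_path):
        path = tmp_path / "garbage.json"
        path.write_text("{not json")
        with pytest.raises(Exception, match="garbage.json"):
            load_model(path)

    def test_sbml_import_agrees_with_json(self, toy_model, tmp_path):
        """Write the toy through cobra's SBML writer, read it back with ours."""
        cobra = pytest.importorskip("cobra")
        from cobra.io import load_json_model, write_sbml_model

        json_path = tmp_path / "toy.json"
        save_model(toy_model, json_path)
        sbml_path = tmp_path / "toy.xml"
        write_sbml_model(load_json_model(str(json_path)), str(sbml_path))
        model = load_model(sbml_path, format="sbml")
        assert {r.id for r in model.reactions} == {r.id for r in toy_model.reactions}
        for orig in toy_model.reactions:
            back = model.reaction(orig.id)
            assert back.stoichiometry == orig.stoichiometry
            assert back.lower_bound == pytest.approx(orig.lower_bound)
            assert back.upper_bound == pytest.approx(orig.upper_bound)
        assert abs(fba(model).objective_value - fba(toy_model).objective_value) < 1e-9


class TestSetExchange:
    def test_uptake_bound_minus_ten(self, toy_model):
        out = set_exchange(toy_model, "nat_e", -10.0, 0.0)
        ex = out.exchange_for("nat_e")
        assert (ex.lower_bound, ex.upper_bound) == (-10.0, 0.0)

    def test_idempotent(self, toy_model):
        once = set_exchange(toy_model, "nat_e", -10.0, 0.0)
        twice = set_exchange(once, "nat_e", -10.0, 0.0)
        ex1, ex2 = once.exchange_for("nat_e"), twice.exchange_for("nat_e")
        assert (ex1.lower_bound, ex1.upper_bound) == (ex2.lower_bound, ex2.upper_bound)
        assert len(once.reactions) == len(twice.reactions)

    def test_creates_exchange_when_absent(self, toy_model):
        model = toy_model.copy()
        from undermet import Metabolite

        model.metabolites.append(Metabolite("lyx_e", compartment="e"))
        out = set_exchange(model, "lyx_e", -10.0, 0.0)
        ex = out.exchange_for("lyx_e")
        assert ex is not None and ex.lower_bound == -10.0

    def test_inverted_bounds_rejected(self, toy_model):
        with pytest.raises(ModelValidationError):
            set_exchange(toy_model, "nat_e", 1.0, -1.0)

    def test_unknown_metabolite_rejected(self, toy_model):
        with pytest.raises(KeyError):
            set_exchange(toy_model, "nope_e", -10.0, 0.0)

    def test_other_reactions_untouched(self, toy_model):
        out = set_exchange(toy_model, "nat_e", -5.0, 0.0)
        for rxn in toy_model.reactions:
            if rxn.id == "EX_nat_e":
                continue
            back = out.reaction(rxn.id)
            assert (back.lower_bound, back.upper_bound) == (rxn.lower_bound, rxn.upper_bound)


class TestAddReaction:
    def test_optimum_never_decreases(self):
        """Adding any column can only enlarge the feasible set."""
        import numpy as np

        rng = np.random.default_rng(42)
        for model in random_toy_models(8, seed=7):
            before = fba(model).objective_value
            mets = sorted(model.metabolite_ids)
            a, b = rng.choice(len(mets), size=2, replace=False)
            rxn = Reaction(
                "RANDOM_NEW",
                {mets[a]: -float(rng.integers(1, 3)), mets[b]: float(rng.integers(1, 3))},
                lower_bound=0.0,
                upper_bound=float(rng.integers(1, 20)),
            )
            after = fba(add_reaction(model, rxn)).objective_value
            assert after >= before - 1e-9

    def test_enabling_reaction_turns_optimum_positive(self, planted_scenario):
        scen = planted_scenario
        sub = scen.novel_substrates[0][0]
        base = set_exchange(scen.model, sub, -10.0, 0.0)
        assert fba(base).objective_value <= 1e-9
        grown = add_reaction(base, scen.underground[0].reaction)
        assert fba(grown).objective_value > 1e-6
        # independent vertex-enumeration check on both LPs
        assert oracle_fba_optimum(base) == pytest.approx(0.0, abs=1e-8)
        assert oracle_fba_optimum(grown) == pytest.approx(
            fba(grown).objective_value, abs=1e-6
        )

    def test_blocked_column_leaves_optimum_unchanged(self, toy_model):
        rxn = Reaction("BLOCKED", {"nat_c": -1.0, "prec_c": 1.0},
                       lower_bound=0.0, upper_bound=0.0)
        assert fba(add_reaction(toy_model, rxn)).objective_value == pytest.approx(
            fba(toy_model).objective_value
        )

    def test_duplicate_id_rejected(self, toy_model):
        with pytest.raises(ModelValidationError, match="BIOMASS"):
            add_reaction(toy_model, Reaction("BIOMASS", {"nat_c": -1.0}))


class TestAddDemand:
    def test_demand_definition(self, toy_model):
        out = add_demand(toy_model, "prec_c")
        dm = out.reaction("DM_prec_c")
        assert dm.stoichiometry == {"prec_c": -1.0}
        assert (dm.lower_bound, dm.upper_bound) == (0.0, LARGE_BOUND)
        assert "demand" in dm.tags

    def test_demand_unblocks_dead_end_in_fva(self, toy_model):
        """A reaction producing a dead-end metabolite is blocked until a sink exists."""
        from undermet import Metabolite

        model = toy_model.copy()
        model.metabolites.append(Metabolite("dead_c", compartment="c"))
        model.validate()
        model = add_reaction(
            model,
            Reaction("MAKE_DEAD", {"nat_c": -1.0, "dead_c": 1.0},
                     lower_bound=0.0, upper_bound=LARGE_BOUND),
        )
        before = fva(model, ["MAKE_DEAD"], fraction=0.0)[0]
        assert (before.min_flux, before.max_flux) == (0.0, 0.0)
        after = fva(add_demand(model, "dead_c"), ["MAKE_DEAD"], fraction=0.0)[0]
        assert after.max_flux > 1.0

    def test_second_demand_conflicts(self, toy_model):
        once = add_demand(toy_model, "prec_c")
        with pytest.raises(ModelValidationError):
            add_demand(once, "prec_c")

    def test_unknown_metabolite(self, toy_model):
        with pytest.raises(KeyError):
            add_demand(toy_model, "nope_c")


class TestAddIsozyme:
    def test_gpr_becomes_or(self, toy_model):
        out = add_isozyme(toy_model, "TPT_nat", "g_iso")
        assert out.reaction("TPT_nat").gpr == "(g_tpt) or (g_iso)"
        assert "g_iso" in out.genes

    def test_isozyme_protects_against_single_knockout(self, toy_model):
        protected = add_isozyme(toy_model, "TPT_nat", "g_iso")
        assert fba(knock_out_genes(toy_model, {"g_tpt"})).objective_value == 0.0
        assert fba(knock_out_genes(protected, {"g_tpt"})).objective_value == pytest.approx(
            fba(toy_model).objective_value
        )

    def test_empty_gpr_gains_single_gene(self, chain_model):
        out = add_isozyme(chain_model, "BIOMASS", "g2")
        assert out.reaction("BIOMASS").gpr == "(g2)"


class TestEvalGpr:
    @pytest.mark.parametrize(
        "expr, inactive, expected",
        [
            ("(g1 and g2) or g3", {"g1"}, True),
            ("(g1 and g2) or g3", {"g1", "g3"}, False),
            ("", {"g1", "g2"}, True),
            ("g1 AND g2", {"g2"}, False),
            ("g1 Or g2", {"g1"}, True),
        ],
    )
    def test_examples(self, expr, inactive, expected):
        assert eval_gpr(expr, inactive) is expected

    def test_parse_error_reports_position(self):
        with pytest.raises(GPRSyntaxError):
            eval_gpr("g1 and (g2 or", set())
        with pytest.raises(GPRSyntaxError):
            eval_gpr("and g1", set())

    @given(st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_agrees_with_truth_table_oracle(self, data):
        """Random expressions over <= 6 genes, all 2^k knockout patterns."""
        genes = [f"g{i}" for i in range(data.draw(st.integers(1, 6)))]

        def expr(depth):
            if depth == 0 or data.draw(st.booleans()):
                return data.draw(st.sampled_from(genes))
            op = data.draw(st.sampled_from([" and ", " or "]))
            return "(" + expr(depth - 1) + op + expr(depth - 1) + ")"

        e = expr(3)
        import itertools

        for pattern in itertools.product([False, True], repeat=len(genes)):
            inactive = {g for g, dead in zip(genes, pattern) if dead}
            assert eval_gpr(e, inactive) == oracle_eval_gpr(e, inactive)


class TestKnockOut:
    def test_absent_gene_is_inert(self, toy_model):
        out = knock_out_genes(toy_model, {"not_a_gene"})
        assert fba(out).objective_value == pytest.approx(fba(toy_model).objective_value)

    def test_sole_pathway_gene_kills_growth(self, chain_model):
        assert fba(knock_out_genes(chain_model, {"g_t"})).objective_value == 0.0
        assert oracle_fba_optimum(knock_out_genes(chain_model, {"g_t"})) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_empty_set_is_identity(self, toy_model):
        out = knock_out_genes(toy_model, set())
        for rxn in toy_model.reactions:
            back = out.reaction(rxn.id)
            assert (back.lower_bound, back.upper_bound) == (rxn.lower_bound, rxn.upper_bound)

    def test_knockouts_are_monotone(self):
        """A superset knockout can never grow faster than a subset knockout."""
        import numpy as np

        rng = np.random.default_rng(11)
        for model in random_toy_models(6, seed=5):
            genes = sorted(model.genes)
            small = set(rng.choice(genes, size=1))
            big = small | set(rng.choice(genes, size=2))
            opt_small = fba(knock_out_genes(model, small)).objective_value
            opt_big = fba(knock_out_genes(model, big)).objective_value
            assert opt_big <= opt_small + 1e-9
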