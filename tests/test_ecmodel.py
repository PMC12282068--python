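"""Model types, formula handling, I/O round trips, and the GECKO-style converter."""

import json

import numpy as np
import pytest

import morp
from morp import (
    ECModel,
    EnzymeSpec,
    FormatError,
    Metabolite,
    Reaction,
    StoichiometricModel,
    ValidationError,
    build_ec_model,
    check_mass_balance,
    load_gem,
    parse_formula,
    read_enzyme_table,
    save_model,
    write_enzyme_table,
)
from morp.optimize import ObjectiveSpec, fba


def small_gem():
    return StoichiometricModel(
        metabolites=[
            Metabolite("glc", formula="C6H12O6", compartment="e"),
            Metabolite("pyr", formula="C3H4O3"),
        ],
        reactions=[
            Reaction("EX_glc", {"glc": -1}, -5.0, 0.0, kind="exchange"),
            Reaction("GLY", {"glc": -1, "pyr": 2}, -10.0, 10.0),
            Reaction("EX_pyr", {"pyr": -1}, 0.0, 10.0, kind="exchange"),
        ],
    )


@pytest.mark.parametrize(
    "formula,expected",
    [
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("CO2", {"C": 1, "O": 2}),
        ("C3H7O6P", {"C": 3, "H": 7, "O": 6, "P": 1}),
        ("H2", {"H": 2}),
    ],
)
def test_parse_formula(formula, expected):
    assert parse_formula(formula) == expected


@pytest.mark.parametrize("bad", ["c6h12", "C6-H12", "6C", "C6 H12"])
def test_parse_formula_rejects_garbage(bad):
    with pytest.raises(ValidationError):
        parse_formula(bad)


def test_reaction_invariants():
    with pytest.raises(ValidationError):
        Reaction("r", {}, lb=1.0, ub=0.0)
    with pytest.raises(ValidationError):
        Reaction("r", {}, kind="mystery")


def test_model_rejects_undeclared_metabolite():
    with pytest.raises(ValidationError, match="undeclared"):
        StoichiometricModel(
            metabolites=[Metabolite("a")],
            reactions=[Reaction("r", {"a": -1, "ghost": 1})],
        )


def test_json_round_trip(tmp_path):
    gem = small_gem()
    path = tmp_path / "model.json"
    save_model(gem, str(path), dialect="json")
    back = load_gem(str(path), dialect="json")
    assert back.reaction_ids == gem.reaction_ids
    assert back.metabolite_ids == gem.metabolite_ids
    for rid in gem.reaction_ids:
        a, b = gem.reaction(rid), back.reaction(rid)
        assert (a.lb, a.ub, a.kind, a.stoichiometry) == (b.lb, b.ub, b.kind, b.stoichiometry)


def test_sbml_round_trip(tmp_path, toy_scenario):
    gem = morp.make_toy_gem(toy_scenario.params)
    path = tmp_path / "model.xml"
    save_model(gem, str(path), dialect="sbml")
    back = load_gem(str(path), dialect="sbml")
    assert set(back.reaction_ids) == set(gem.reaction_ids)
    assert back.biomass_id == gem.biomass_id
    for rid in gem.reaction_ids:
        a, b = gem.reaction(rid), back.reaction(rid)
        assert a.stoichiometry == pytest.approx(b.stoichiometry)
        assert (a.lb, a.ub, a.kind) == (b.lb, b.ub, b.kind)


def test_ecmodel_json_round_trip_preserves_pool(tmp_path, toy_model):
    path = tmp_path / "ec.json"
    save_model(toy_model, str(path), dialect="json")
    back = load_gem(str(path), dialect="json")
    assert isinstance(back, ECModel)
    assert back.pool_capacity == toy_model.pool_capacity
    assert back.enzyme_usage_ids == toy_model.enzyme_usage_ids
    assert [e.enzyme_id for e in back.enzymes] == [e.enzyme_id for e in toy_model.enzymes]


def test_load_gem_malformed_json(tmp_path):
    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    with pytest.raises(FormatError):
        load_gem(str(bad), dialect="json")
    bad2 = tmp_path / "bad2.json"
    bad2.write_text(json.dumps({"metabolites": [], "reactions": [{"id": "r"}]}))
    with pytest.raises(FormatError):
        load_gem(str(bad2), dialect="json")


def test_dialect_mismatch_is_format_error(tmp_path):
    gem = small_gem()
    path = tmp_path / "model.json"
    save_model(gem, str(path), dialect="json")
    with pytest.raises(FormatError):
        load_gem(str(path), dialect="sbml")


def test_load_sbml_undeclared_species_is_format_error(tmp_path):
    # a structurally broken SBML document must not load silently
    path = tmp_path / "broken.xml"
    path.write_text(
        """<?xml version="1.0"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
 <model id="m"><listOfReactions>
  <reaction id="r" reversible="false">
   <listOfReactants><speciesReference species="ghost" stoichiometry="1"/></listOfReactants>
  </reaction>
 </listOfReactions></model></sbml>"""
    )
    with pytest.raises(FormatError):
        load_gem(str(path), dialect="sbml")


def test_json_fixture_reaction_count(tmp_path):
    """A 12-reaction JSON-dialect fixture loads with all reactions and bounds intact."""
    mets = [Metabolite(f"m{i}") for i in range(13)]
    rxns = [
        Reaction(f"r{i}", {f"m{i}": -1, f"m{i+1}": 1}, lb=-float(i), ub=10.0 + i)
        for i in range(12)
    ]
    gem = StoichiometricModel(metabolites=mets, reactions=rxns)
    path = tmp_path / "chain12.json"
    save_model(gem, str(path), dialect="json")
    back = load_gem(str(path), dialect="json")
    assert len(back.reactions) == 12
    assert [(r.lb, r.ub) for r in back.reactions] == [(-float(i), 10.0 + i) for i in range(12)]


# ---------------------------------------------------------------------------
# build_ec_model
# ---------------------------------------------------------------------------

def test_single_reaction_capacity_closed_form():
    """v_max = kcat * pool / mw for one enzyme drawing the whole pool."""
    gem = StoichiometricModel(
        metabolites=[Metabolite("s"), Metabolite("p")],
        reactions=[
            Reaction("EX_s", {"s": -1}, -1000.0, 0.0, kind="exchange"),
            Reaction("R", {"s": -1, "p": 1}, 0.0, 1000.0),
            Reaction("EX_p", {"p": -1}, 0.0, 1000.0, kind="exchange"),
        ],
    )
    ec = build_ec_model(gem, [EnzymeSpec("e", 0.05, {"R": 100.0})], pool_capacity=0.1)
    sol = fba(ec, ObjectiveSpec(kind="custom_linear", coefficients={"R": 1.0}))
    assert sol.optimal
    assert sol.fluxes["R"] == pytest.approx(100.0 * 0.1 / 0.05, abs=1e-6)  # = 200


def test_empty_enzyme_table_leaves_optima_unchanged():
    gem = small_gem()
    ec = build_ec_model(gem, [], pool_capacity=0.1)
    obj = ObjectiveSpec(kind="custom_linear", coefficients={"EX_pyr": 1.0})
    assert fba(ec, obj).objective_value == pytest.approx(fba(gem, obj).objective_value)


def test_reversible_split_and_coupling():
    gem = small_gem()
    ec = build_ec_model(gem, [EnzymeSpec("e", 0.04, {"GLY": 50.0})], pool_capacity=0.1)
    rids = ec.base.reaction_ids
    assert "GLY__fwd" in rids and "GLY__rev" in rids and "GLY" not in rids
    fwd = ec.base.reaction("GLY__fwd")
    rev = ec.base.reaction("GLY__rev")
    assert fwd.lb == 0.0 and fwd.ub == 10.0
    assert rev.lb == 0.0 and rev.ub == 10.0
    assert fwd.stoichiometry["enzyme__e"] == pytest.approx(-1.0 / 50.0)
    assert rev.stoichiometry["enzyme__e"] == pytest.approx(-1.0 / 50.0)
    assert rev.stoichiometry["glc"] == 1.0  # direction flipped


def test_isozyme_policies():
    gem = small_gem()
    enzymes = [
        EnzymeSpec("fast", 0.04, {"EX_pyr": 0.1}),  # dummy to keep ids distinct
    ]
    enzymes = [
        EnzymeSpec("iso1", 0.04, {"GLY": 50.0}),
        EnzymeSpec("iso2", 0.03, {"GLY": 80.0}),
    ]
    ec = build_ec_model(gem, enzymes, pool_capacity=0.1, isozyme_policy="parallel")
    arms = [r for r in ec.base.reaction_ids if "__iso__" in r]
    assert len(arms) == 4  # fwd/rev x two isozymes
    ec2 = build_ec_model(gem, enzymes, pool_capacity=0.1, isozyme_policy="fastest")
    assert all("__iso__" not in r for r in ec2.base.reaction_ids)
    assert ec2.base.reaction("GLY__fwd").stoichiometry["enzyme__iso2"] == pytest.approx(-1 / 80.0)


def test_build_ec_model_validation_errors():
    gem = small_gem()
    with pytest.raises(ValidationError):
        build_ec_model(gem, [EnzymeSpec("e", 0.04, {"NOPE": 10.0})], pool_capacity=0.1)
    with pytest.raises(ValidationError):
        build_ec_model(gem, [], pool_capacity=0.0)
    with pytest.raises(ValidationError):
        EnzymeSpec("e", -1.0, {})
    with pytest.raises(ValidationError):
        EnzymeSpec("e", 0.04, {"GLY": 0.0})
    dup = [EnzymeSpec("e", 0.04, {"GLY": 1.0}), EnzymeSpec("e", 0.04, {"EX_pyr": 1.0})]
    with pytest.raises(ValidationError, match="duplicate"):
        build_ec_model(gem, dup, pool_capacity=0.1)


def test_pool_draw_equals_mass_weighted_usage(toy_model):
    """The pool-exchange flux equals sum_i mw_i * v_usage,i at any optimum."""
    sol = fba(toy_model, ObjectiveSpec(kind="max_growth"),
              extra_bounds={"EX_glc": (-5.0, -5.0), "EX_tre": (0.0, 0.0)})
    assert sol.optimal
    mws = np.array([e.mw for e in toy_model.enzymes])
    assert sol.fluxes["pool_exchange"] == pytest.approx(float(mws @ sol.enzyme_usage), abs=1e-8)


# ---------------------------------------------------------------------------
# check_mass_balance
# ---------------------------------------------------------------------------

def test_toy_network_is_carbon_balanced(toy_scenario):
    gem = morp.make_toy_gem(toy_scenario.params)
    assert check_mass_balance(gem, elements=["C"]) == []


def test_forced_imbalance_is_reported():
    gem = StoichiometricModel(
        metabolites=[Metabolite("A", formula="C6H12O6"), Metabolite("B", formula="C3H6O3")],
        reactions=[Reaction("bad", {"A": -1, "B": 1})],
    )
    issues = check_mass_balance(gem, elements=["C"])
    assert issues == [("bad", "C", -3.0)]


def test_exchange_and_biomass_never_reported():
    gem = StoichiometricModel(
        metabolites=[Metabolite("A", formula="C6H12O6")],
        reactions=[
            Reaction("EX_A", {"A": -1}, kind="exchange"),
            Reaction("BIO", {"A": -1}, kind="biomass"),
        ],
        biomass_id="BIO",
    )
    assert check_mass_balance(gem) == []


def test_formulaless_metabolites_skipped_with_warning():
    gem = StoichiometricModel(
        metabolites=[Metabolite("A", formula="C6H12O6"), Metabolite("x")],
        reactions=[Reaction("r", {"A": -1, "x": 1})],
    )
    with pytest.warns(UserWarning, match="skipped"):
        assert check_mass_balance(gem) == []


def test_mass_balance_matches_bruteforce_per_element():
    """Residuals are the literal per-element linear sums of S coefficients."""
    rng = np.random.default_rng(0)
    mets = [
        Metabolite(f"m{i}", formula=f"C{rng.integers(1,7)}H{rng.integers(1,13)}")
        for i in range(5)
    ]
    rxns = [
        Reaction(
            f"r{j}",
            {m.id: float(rng.integers(-3, 4)) for m in mets if rng.random() < 0.8},
        )
        for j in range(6)
    ]
    gem = StoichiometricModel(metabolites=mets, reactions=rxns)
    issues = {(rid, el): res for rid, el, res in check_mass_balance(gem)}
    for r in rxns:
        for el in ("C", "H"):
            expected = sum(
                coeff * parse_formula(gem.metabolite(mid).formula).get(el, 0)
                for mid, coeff in r.stoichiometry.items()
            )
            got = issues.get((r.id, el), 0.0)
            assert got == pytest.approx(expected if abs(expected) > 1e-9 else 0.0)


# ---------------------------------------------------------------------------
# enzyme tables
# ---------------------------------------------------------------------------

def test_enzyme_table_round_trip(tmp_path, toy_scenario):
    enzymes = morp.toy_enzymes(toy_scenario.params)
    path = tmp_path / "enzymes.tsv"
    write_enzyme_table(enzymes, str(path))
    back = read_enzyme_table(str(path))
    assert {e.enzyme_id: (e.mw, e.kcats) for e in back} == {
        e.enzyme_id: (e.mw, e.kcats) for e in enzymes
    }


def test_enzyme_table_missing_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("enzyme_id\treaction_id\n" "e\tr\n")
    with pytest.raises(FormatError, match="missing"):
        read_enzyme_table(str(path))
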