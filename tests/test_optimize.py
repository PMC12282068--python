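"""Static objectives: FBA, MORP against enumeration oracles, proteome minimization, FVA."""

import copy

import numpy as np
import pytest

import morp
from morp import ObjectiveSpec, ValidationError, fba, fva, min_total_proteome
from morp.optimize import morp as morp_opt


GLC_ONLY = {"EX_glc": (-1.0, -1.0), "EX_tre": (0.0, 0.0), "NGAM": (0.0, 1000.0)}


def _sv_residual(model, sol):
    net = model.base
    v = np.array([sol.fluxes[r] for r in net.reaction_ids])
    return float(np.abs(net.stoich_matrix() @ v).max()), float(np.abs(v).max())


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def test_homolactic_max_lactate_is_two_per_glucose(toy_model):
    """EMP glycolysis converts 1 glucose to 2 lactate: the 1 g/g mass yield."""
    sol = fba(toy_model, ObjectiveSpec(kind="max_lactate", target="EX_lac"), extra_bounds=GLC_ONLY)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(2.0, abs=1e-9)
    mass_yield = 2.0 * morp.MW["lactate"] / morp.MW["glucose"]
    assert mass_yield == pytest.approx(1.0, abs=1e-3)


def test_fba_agrees_with_cobra(toy_model):
    """Independent LP route: the same model solved through cobrapy."""
    from morp.ecmodel import _to_cobra

    cm = _to_cobra(toy_model.base)
    cm.reactions.EX_glc.bounds = (-1.0, -1.0)
    cm.reactions.EX_tre.bounds = (0.0, 0.0)
    cm.reactions.NGAM.bounds = (0.0, 1000.0)
    cm.objective = "EX_lac"
    expected = cm.slim_optimize()
    sol = fba(toy_model, ObjectiveSpec(kind="max_lactate", target="EX_lac"), extra_bounds=GLC_ONLY)
    assert sol.objective_value == pytest.approx(expected, abs=1e-6)


def test_heterolactic_route_splits_carbon(toy_model):
    """With EMP blocked, each glucose gives 1 lactate plus 1 two-carbon product."""
    bounds = dict(GLC_ONLY)
    bounds["PFKA"] = (0.0, 0.0)
    sol = fba(toy_model, ObjectiveSpec(kind="max_lactate", target="EX_lac"), extra_bounds=bounds)
    assert sol.optimal
    assert sol.fluxes["EX_lac"] == pytest.approx(1.0, abs=1e-9)
    assert sol.fluxes["EX_etoh"] + sol.fluxes["EX_ac"] == pytest.approx(1.0, abs=1e-9)
    assert sol.fluxes["EX_co2"] == pytest.approx(1.0, abs=1e-9)


def test_all_uptakes_closed_gives_zero_optimum(toy_model):
    bounds = {"EX_glc": (0.0, 0.0), "EX_tre": (0.0, 0.0), "NGAM": (0.0, 1000.0)}
    sol = fba(toy_model, ObjectiveSpec(kind="max_lactate", target="EX_lac"), extra_bounds=bounds)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
    assert max(abs(v) for v in sol.fluxes.values()) <= 1e-9


def test_fba_statuses(toy_model):
    infeasible = fba(
        toy_model,
        ObjectiveSpec(kind="max_lactate", target="EX_lac"),
        extra_bounds={"EX_glc": (0.0, 0.0), "EX_tre": (0.0, 0.0)},  # NGAM floor unmet
    )
    assert infeasible.status == "infeasible"
    gem = morp.make_toy_gem()
    unbounded = fba(
        gem,
        ObjectiveSpec(kind="custom_linear", coefficients={"GAPD": 1.0}),
        extra_bounds={"GAPD": (0.0, float("inf")), "PFKA": (0.0, float("inf")),
                      "LDH": (0.0, float("inf")), "EX_lac": (0.0, float("inf")),
                      "EX_glc": (-float("inf"), 0.0), "GLCT": (0.0, float("inf")),
                      "NGAM": (0.0, float("inf"))},
    )
    assert unbounded.status == "unbounded"


def test_fba_steady_state_residual(toy_model):
    sol = fba(toy_model, ObjectiveSpec(kind="max_growth"),
              extra_bounds={"EX_glc": (-10.0, -10.0), "EX_tre": (0.0, 0.0)})
    resid, vmax = _sv_residual(toy_model, sol)
    assert resid <= 1e-9 * vmax + 1e-9


# ---------------------------------------------------------------------------
# MORP vs dense-enumeration oracle
# ---------------------------------------------------------------------------

EXPECTED_L1 = {
    "two_pathway_capacity_halved": 0.15,
    "forced_demand_zero_reference": 0.125,
    "branched_uptake_and_split": 0.08,
}


def test_morp_matches_bruteforce_enumeration(enumerable_case, request):
    model, extra_bounds, ref, grid = enumerable_case
    grid_min = float(np.abs(grid - ref).sum(axis=1).min())
    sol = morp_opt(model, ref, extra_bounds=extra_bounds)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(grid_min, abs=1e-6)
    case_id = request.node.callspec.id
    assert sol.objective_value == pytest.approx(EXPECTED_L1[case_id], abs=1e-9)


def test_morp_zero_reference_equals_min_total_usage(enumerable_case):
    model, extra_bounds, _ref, _grid = enumerable_case
    zero = np.zeros(model.n_enzymes)
    sol = morp_opt(model, zero, extra_bounds=extra_bounds)
    usage_obj = ObjectiveSpec(
        kind="custom_linear",
        coefficients={rid: -1.0 for rid in model.enzyme_usage_ids},
    )
    min_usage = fba(model, usage_obj, extra_bounds=extra_bounds, tie_break=False)
    assert sol.objective_value == pytest.approx(-min_usage.objective_value, abs=1e-8)


def test_morp_own_optimum_is_fixed_point(toy_model):
    ref_sol = fba(toy_model, ObjectiveSpec(kind="max_growth"),
                  extra_bounds={"EX_glc": (-5.0, -5.0), "EX_tre": (0.0, 0.0)})
    assert ref_sol.optimal
    sol = morp_opt(toy_model, ref_sol,
                   extra_bounds={"EX_glc": (-5.0, -5.0), "EX_tre": (0.0, 0.0)})
    assert sol.objective_value == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(sol.enzyme_usage, ref_sol.enzyme_usage, atol=1e-7)


def test_morp_no_sampled_point_beats_optimum(two_pathway_model):
    """1000 uniformly sampled feasible points never undercut the LP optimum."""
    model = two_pathway_model
    ref = np.array([0.1, 0.0])
    cap = {"usage__eA": (0.0, 0.05)}
    sol = morp_opt(model, ref, extra_bounds=cap)
    sample = morp.sample_flux_space(model, n=1000, seed=11, thinning=5, extra_bounds=cap)
    uidx = [sample.reaction_ids.index(r) for r in model.enzyme_usage_ids]
    l1 = np.abs(sample.matrix[:, uidx] - ref).sum(axis=1)
    assert l1.min() >= sol.objective_value - 1e-6


def test_morp_scaling_equivariance(two_pathway_model):
    model = two_pathway_model
    ref = np.array([0.1, 0.0])
    cap = {"usage__eA": (0.0, 0.05)}
    base = morp_opt(model, ref, extra_bounds=cap).objective_value
    c = 3.5
    scaled = model.copy()
    for r in scaled.base.reactions:
        r.lb, r.ub = r.lb * c, r.ub * c
    scaled_cap = {"usage__eA": (0.0, 0.05 * c)}
    got = morp_opt(scaled, ref * c, extra_bounds=scaled_cap).objective_value
    assert got == pytest.approx(c * base, rel=1e-9)


def test_morp_two_linearizations_agree(enumerable_case, toy_model):
    model, extra_bounds, ref, _grid = enumerable_case
    a = morp_opt(model, ref, extra_bounds=extra_bounds, formulation="aux")
    b = morp_opt(model, ref, extra_bounds=extra_bounds, formulation="split")
    assert a.objective_value == pytest.approx(b.objective_value, abs=1e-8)


def test_morp_validation(toy_model):
    with pytest.raises(ValidationError):
        morp_opt(toy_model, np.zeros(3))  # misaligned reference
    with pytest.raises(ValidationError):
        morp_opt(toy_model, "previous")
    with pytest.raises(ValidationError):
        ObjectiveSpec(kind="morp")  # reference is mandatory


def test_morp_infeasible_status(toy_model):
    sol = morp_opt(
        toy_model,
        np.zeros(toy_model.n_enzymes),
        extra_bounds={"EX_glc": (0.0, 0.0), "EX_tre": (0.0, 0.0)},
    )
    assert sol.status == "infeasible"


# ---------------------------------------------------------------------------
# min_total_proteome
# ---------------------------------------------------------------------------

def test_min_proteome_matches_fba_pool_draw(toy_model):
    ref = fba(toy_model, ObjectiveSpec(kind="max_lactate", target="EX_lac"), extra_bounds=GLC_ONLY)
    sol = min_total_proteome(
        toy_model,
        exchange_bounds={
            "EX_glc": (-1.0, -1.0),
            "EX_tre": (0.0, 0.0),
            "EX_lac": (ref.fluxes["EX_lac"], ref.fluxes["EX_lac"]),
        },
    )
    assert sol.optimal
    # fba's lexicographic stage already minimizes usage at the optimum
    assert sol.fluxes["pool_exchange"] == pytest.approx(ref.fluxes["pool_exchange"], abs=1e-8)


def test_min_proteome_zero_when_idle():
    sc = morp.make_toy_scenario(morp.ToyParams(ngam=0.0))
    bounds = {rid: (0.0, 0.0) for rid in sc.model.base.reaction_ids
              if sc.model.base.reaction(rid).kind == "exchange"}
    sol = min_total_proteome(sc.model, exchange_bounds=bounds)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(0.0, abs=1e-10)


def test_min_proteome_conflicting_bounds_infeasible(toy_model):
    sol = min_total_proteome(
        toy_model,
        exchange_bounds={"EX_glc": (-1.0, -1.0), "EX_tre": (0.0, 0.0), "EX_lac": (5.0, 5.0)},
    )
    assert sol.status == "infeasible"


def test_min_proteome_rejects_non_exchange(toy_model):
    with pytest.raises(ValidationError, match="not an exchange"):
        min_total_proteome(toy_model, exchange_bounds={"LDH": (0.0, 0.0)})


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def test_fva_fixed_blocked_and_containment(toy_model):
    bounds = dict(GLC_ONLY)
    bounds["ALSD"] = (0.0, 0.0)
    ranges = fva(toy_model, ["EX_glc", "ALSD", "LDH"], extra_bounds=bounds)
    assert ranges["EX_glc"] == pytest.approx((-1.0, -1.0))
    assert ranges["ALSD"] == pytest.approx((0.0, 0.0), abs=1e-10)
    sol = fba(toy_model, ObjectiveSpec(kind="max_lactate", target="EX_lac"), extra_bounds=bounds)
    lo, hi = ranges["LDH"]
    assert lo - 1e-8 <= sol.fluxes["LDH"] <= hi + 1e-8
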