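"""Shared fixtures: the synthetic toy scenario (session-scoped, since the
dynamic simulations are the expensive part) and hand-sized enzyme-constrained
models whose flux polytopes are low-dimensional enough to enumerate densely."""

from __future__ import annotations

import numpy as np
import pytest

import morp
from morp import (
    ECModel,
    EnzymeSpec,
    Metabolite,
    Reaction,
    StoichiometricModel,
    build_ec_model,
)


@pytest.fixture(scope="session")
def toy_scenario():
    return morp.make_toy_scenario()


@pytest.fixture(scope="session")
def toy_model(toy_scenario):
    return toy_scenario.model


@pytest.fixture(scope="session")
def toy_kinetics(toy_scenario):
    return toy_scenario.kinetics


@pytest.fixture(scope="session")
def toy_traj(toy_scenario):
    """The packaged diauxic run: growth maximization on glucose, then dMORP."""
    sc = toy_scenario
    return morp.simulate(sc.model, sc.schedule, sc.kinetics, sc.init, dt=sc.dt, t_end=sc.t_end)


# ---------------------------------------------------------------------------
# Hand-sized models with enumerable flux polytopes
# ---------------------------------------------------------------------------

def _two_pathway_model() -> ECModel:
    """Fixed uptake 1 split between pathways A (kcat 10) and B (kcat 5)."""
    gem = StoichiometricModel(
        metabolites=[Metabolite("s"), Metabolite("p")],
        reactions=[
            Reaction("EX_s", {"s": -1}, -1.0, -1.0, kind="exchange"),
            Reaction("A", {"s": -1, "p": 1}, 0.0, 10.0),
            Reaction("B", {"s": -1, "p": 1}, 0.0, 10.0),
            Reaction("EX_p", {"p": -1}, 0.0, 10.0, kind="exchange"),
        ],
    )
    enzymes = [
        EnzymeSpec("eA", 0.01, {"A": 10.0}),
        EnzymeSpec("eB", 0.02, {"B": 5.0}),
    ]
    return build_ec_model(gem, enzymes, pool_capacity=1.0)


def _forced_demand_model() -> ECModel:
    """Product demand fixed at 1, met by a slow (kcat 4) or fast (kcat 8) route."""
    gem = StoichiometricModel(
        metabolites=[Metabolite("s"), Metabolite("p")],
        reactions=[
            Reaction("EX_s", {"s": -1}, -2.0, 0.0, kind="exchange"),
            Reaction("C1", {"s": -1, "p": 1}, 0.0, 10.0),
            Reaction("C2", {"s": -1, "p": 1}, 0.0, 10.0),
            Reaction("EX_p", {"p": -1}, 1.0, 1.0, kind="exchange"),
        ],
    )
    enzymes = [
        EnzymeSpec("eC1", 0.01, {"C1": 4.0}),
        EnzymeSpec("eC2", 0.01, {"C2": 8.0}),
    ]
    return build_ec_model(gem, enzymes, pool_capacity=1.0)


def _branched_model() -> ECModel:
    """Variable uptake feeding a branch point with sinks p (fast) and q (slow)."""
    gem = StoichiometricModel(
        metabolites=[Metabolite("s"), Metabolite("a"), Metabolite("p"), Metabolite("q")],
        reactions=[
            Reaction("EX_s", {"s": -1}, -1.5, -0.5, kind="exchange"),
            Reaction("R1", {"s": -1, "a": 1}, 0.0, 10.0),
            Reaction("R2", {"a": -1, "p": 1}, 0.0, 10.0),
            Reaction("R3", {"a": -1, "q": 1}, 0.0, 10.0),
            Reaction("EX_p", {"p": -1}, 0.0, 10.0, kind="exchange"),
            Reaction("EX_q", {"q": -1}, 0.0, 10.0, kind="exchange"),
        ],
    )
    enzymes = [
        EnzymeSpec("eR1", 0.01, {"R1": 10.0}),
        EnzymeSpec("eR2", 0.01, {"R2": 10.0}),
        EnzymeSpec("eR3", 0.01, {"R3": 2.0}),
    ]
    return build_ec_model(gem, enzymes, pool_capacity=1.0)


def _grid_two_pathway(step=1e-3):
    """Enumerate (usage vectors) of the two-pathway model with A capacity halved."""
    model = _two_pathway_model()
    pts = []
    for x in np.arange(0.0, 0.5 + step / 2, step):  # v_A <= 0.5 under the cap
        pts.append(np.array([x / 10.0, (1.0 - x) / 5.0]))
    return model, {"usage__eA": (0.0, 0.05)}, np.array([0.1, 0.0]), np.array(pts)


def _grid_forced_demand(step=1e-3):
    model = _forced_demand_model()
    pts = []
    for v1 in np.arange(0.0, 1.0 + step / 2, step):
        pts.append(np.array([v1 / 4.0, (1.0 - v1) / 8.0]))
    return model, None, np.zeros(2), np.array(pts)


def _grid_branched(step=1e-3):
    """Two free dimensions: uptake u in [0.5, 1.5] and branch split."""
    model = _branched_model()
    pts = []
    for u in np.arange(0.5, 1.5 + step / 2, step):
        for v2 in np.arange(0.0, u + step / 2, step * 10):  # coarser inner grid
            v2 = min(v2, u)
            if v2 / 10.0 > 0.06 + 1e-12:  # eR2 usage cap
                continue
            v3 = u - v2
            pts.append(np.array([u / 10.0, v2 / 10.0, v3 / 2.0]))
    return model, {"usage__eR2": (0.0, 0.06)}, np.array([0.1, 0.1, 0.0]), np.array(pts)


#: (name, builder) pairs; each builder returns
#: (ECModel, extra_bounds, reference usage, dense grid of feasible usage vectors)
ENUMERABLE_CASES = [
    ("two_pathway_capacity_halved", _grid_two_pathway),
    ("forced_demand_zero_reference", _grid_forced_demand),
    ("branched_uptake_and_split", _grid_branched),
]


@pytest.fixture(params=ENUMERABLE_CASES, ids=[c[0] for c in ENUMERABLE_CASES])
def enumerable_case(request):
    return request.param[1]()


@pytest.fixture
def two_pathway_model():
    return _two_pathway_model()
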