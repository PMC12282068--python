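"""Static optimization on enzyme-constrained models.

All objectives reduce to linear programs over the flux polytope
{v : S v = 0, lb <= v <= ub} and are solved with HiGHS (via
``scipy.optimize.linprog``).  The minimal-proteome-reallocation objective
minimizes the L1 distance of the enzyme-usage subvector to a reference usage
vector:

    min sum_i |v_enzyme,i - v_enzyme,i,ref|   s.t.  S v = 0,  lb <= v <= ub.

Two exact linearizations are provided (auxiliary-variable and split-variable);
both return the same optimum and are cross-checked in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .ecmodel import ECModel, StoichiometricModel, ValidationError

__all__ = [
    "FluxSolution",
    "ObjectiveSpec",
    "fba",
    "morp",
    "min_total_proteome",
    "fva",
]

logger = logging.getLogger("morp")

#: feasibility / optimality tolerances passed to the solver and used in checks
FEASIBILITY_TOL = 1e-9

OBJECTIVE_KINDS = ("max_growth", "max_lactate", "max_ngam", "morp", "min_total_proteome", "custom_linear")


@dataclass
class FluxSolution:
    """Result of one LP solve on an (EC)model."""

    fluxes: Dict[str, float]
    enzyme_usage: np.ndarray
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, rid: str) -> float:
        return self.fluxes[rid]

    def usage_by_enzyme(self, model: ECModel) -> Dict[str, float]:
        return {
            e.enzyme_id: float(u)
            for e, u in zip(model.enzymes, self.enzyme_usage)
        }


@dataclass
class ObjectiveSpec:
    """What to optimize in one FBA-type solve.

    ``target`` names the reaction for ``max_growth``/``max_lactate``/``max_ngam``
    (for ``max_growth`` it defaults to the model's biomass reaction);
    ``reference`` carries the enzyme-usage reference for ``morp``;
    ``coefficients`` the linear objective for ``custom_linear`` (maximized).
    """

    kind: str
    target: Optional[str] = None
    reference: Optional[Union["FluxSolution", np.ndarray, Sequence[float]]] = None
    coefficients: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise ValidationError(f"unknown objective kind {self.kind!r}")
        if self.kind == "morp" and self.reference is None:
            raise ValidationError("morp objective requires a reference")


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def _network(model: Union[ECModel, StoichiometricModel]) -> StoichiometricModel:
    return model.base if isinstance(model, ECModel) else model


def _lp_parts(
    model: Union[ECModel, StoichiometricModel],
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
):
    net = _network(model)
    S = net.stoich_matrix()
    lb, ub = net.bounds()
    rids = net.reaction_ids
    if extra_bounds:
        pos = {rid: j for j, rid in enumerate(rids)}
        for rid, (blo, bhi) in extra_bounds.items():
            if rid not in pos:
                raise ValidationError(f"bound references unknown reaction {rid!r}")
            lb[pos[rid]] = blo
            ub[pos[rid]] = bhi
    return S, lb, ub, rids


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve(c, A_eq, b_eq, lb, ub, A_ub=None, b_ub=None):
    bounds = list(zip(lb, ub))
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"presolve": True},
    )
    status = _STATUS.get(res.status, "infeasible")
    return res, status


def _pack(model, rids, x, objective_value, status) -> FluxSolution:
    fluxes = {rid: float(v) for rid, v in zip(rids, x)} if x is not None else {}
    if isinstance(model, ECModel) and x is not None:
        idx = model.enzyme_usage_index()
        usage = np.asarray(x, dtype=float)[idx]
    else:
        usage = np.zeros(model.n_enzymes if isinstance(model, ECModel) else 0)
    return FluxSolution(fluxes=fluxes, enzyme_usage=usage, objective_value=objective_value, status=status)


def _empty(model, status) -> FluxSolution:
    m = model.n_enzymes if isinstance(model, ECModel) else 0
    return FluxSolution(fluxes={}, enzyme_usage=np.zeros(m), objective_value=np.nan, status=status)


def _resolve_target(model, objective: ObjectiveSpec) -> str:
    net = _network(model)
    target = objective.target
    if objective.kind == "max_growth" and target is None:
        target = net.biomass_id
    if not target:
        raise ValidationError(f"objective {objective.kind!r} needs a target reaction")
    if not net.has_reaction(target):
        raise ValidationError(f"objective target {target!r} not in model")
    return target


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def fba(
    model: Union[ECModel, StoichiometricModel],
    objective: ObjectiveSpec,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    tie_break: bool = True,
) -> FluxSolution:
    """Maximize a single reaction flux (or a custom linear objective).

    When ``tie_break`` is on and the model is enzyme-constrained, a second
    lexicographic stage fixes the optimal objective value and minimizes total
    enzyme usage, making the returned flux distribution deterministic among
    alternate optima — which the rolling-reference dynamic simulations need.
    """
    S, lb, ub, rids = _lp_parts(model, extra_bounds)
    n = len(rids)
    c = np.zeros(n)
    if objective.kind == "custom_linear":
        if not objective.coefficients:
            raise ValidationError("custom_linear objective needs coefficients")
        pos = {rid: j for j, rid in enumerate(rids)}
        for rid, w in objective.coefficients.items():
            if rid not in pos:
                raise ValidationError(f"objective coefficient on unknown reaction {rid!r}")
            c[pos[rid]] = -float(w)  # linprog minimizes
        target_j = None
    else:
        target = _resolve_target(model, objective)
        target_j = rids.index(target)
        c[target_j] = -1.0
    b = np.zeros(S.shape[0])
    res, status = _solve(c, S, b, lb, ub)
    if status != "optimal":
        logger.info("fba(%s): %s", objective.kind, status)
        return _empty(model, status)
    opt = -res.fun
    x = res.x
    if tie_break and isinstance(model, ECModel) and model.n_enzymes:
        # stage 2: fix the achieved objective, minimize total enzyme usage
        lb2, ub2 = lb.copy(), ub.copy()
        if target_j is not None:
            lb2[target_j] = ub2[target_j] = x[target_j]
            c2 = np.zeros(n)
            for j in model.enzyme_usage_index():
                c2[j] = 1.0
            res2, status2 = _solve(c2, S, b, lb2, ub2)
            if status2 == "optimal":
                x = res2.x
    sol = _pack(model, rids, x, opt, "optimal")
    logger.debug("fba(%s): objective %.6g", objective.kind, opt)
    return sol


# ---------------------------------------------------------------------------
# MORP
# ---------------------------------------------------------------------------

def _reference_vector(model: ECModel, reference) -> np.ndarray:
    if isinstance(reference, str):
        raise ValidationError(
            "morp needs a numeric reference usage (a FluxSolution or vector); "
            f"got the placeholder {reference!r}"
        )
    if isinstance(reference, FluxSolution):
        ref = np.asarray(reference.enzyme_usage, dtype=float)
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.ndim != 1 or ref.shape[0] != model.n_enzymes:
        raise ValidationError(
            f"reference usage has length {ref.shape}, expected ({model.n_enzymes},)"
        )
    return ref


def morp(
    model: ECModel,
    reference,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    formulation: str = "aux",
    mass_weighted: bool = False,
) -> FluxSolution:
    """Minimize the summed absolute change of enzyme-usage fluxes vs. a reference.

    ``reference`` is either a :class:`FluxSolution` or a vector aligned to
    ``model.enzyme_usage_ids``.  The L1 objective is linearized exactly:

    - ``formulation="aux"`` (default): one auxiliary d_i per enzyme with
      d_i >= +(u_i - ref_i) and d_i >= -(u_i - ref_i), minimizing sum d_i;
    - ``formulation="split"``: u_i - ref_i = p_i - q_i with p, q >= 0,
      minimizing sum (p_i + q_i).

    With ``mass_weighted`` the deviations are weighted by molecular weight
    (grams of reallocated protein instead of mmol of enzyme); the default is
    the unweighted sum of usage-flux differences.

    ``objective_value`` is the minimal L1 distance.
    """
    if not isinstance(model, ECModel):
        raise ValidationError("morp requires an enzyme-constrained model")
    ref = _reference_vector(model, reference)
    if np.any(ref < -FEASIBILITY_TOL):
        raise ValidationError("reference usage must be non-negative")
    S, lb, ub, rids = _lp_parts(model, extra_bounds)
    n = len(rids)
    m = model.n_enzymes
    uidx = np.array(model.enzyme_usage_index())
    w = np.array([e.mw for e in model.enzymes]) if mass_weighted else np.ones(m)

    n_mets = S.shape[0]
    if formulation == "aux":
        # variables [v (n), d (m)]
        c = np.concatenate([np.zeros(n), w])
        A_eq = sparse.hstack([S, sparse.csr_matrix((n_mets, m))], format="csr")
        b_eq = np.zeros(n_mets)
        # u_i - d_i <= ref_i  and  -u_i - d_i <= -ref_i
        rows = np.concatenate([np.arange(m), np.arange(m) + m])
        cols_u = np.concatenate([uidx, uidx])
        data_u = np.concatenate([np.ones(m), -np.ones(m)])
        U = sparse.csr_matrix((data_u, (rows, cols_u)), shape=(2 * m, n))
        D = sparse.vstack([-sparse.identity(m), -sparse.identity(m)], format="csr")
        A_ub = sparse.hstack([U, D], format="csr")
        b_ub = np.concatenate([ref, -ref])
        lo = np.concatenate([lb, np.zeros(m)])
        hi = np.concatenate([ub, np.full(m, np.inf)])
        res, status = _solve(c, A_eq, b_eq, lo, hi, A_ub=A_ub, b_ub=b_ub)
        if status != "optimal":
            return _empty(model, status)
        x = res.x[:n]
    elif formulation == "split":
        # variables [v (n), p (m), q (m)] with u_i - p_i + q_i = ref_i
        c = np.concatenate([np.zeros(n), w, w])
        sel = sparse.csr_matrix((np.ones(m), (np.arange(m), uidx)), shape=(m, n))
        A_eq = sparse.vstack(
            [
                sparse.hstack([S, sparse.csr_matrix((n_mets, 2 * m))]),
                sparse.hstack([sel, -sparse.identity(m), sparse.identity(m)]),
            ],
            format="csr",
        )
        b_eq = np.concatenate([np.zeros(n_mets), ref])
        lo = np.concatenate([lb, np.zeros(2 * m)])
        hi = np.concatenate([ub, np.full(2 * m, np.inf)])
        res, status = _solve(c, A_eq, b_eq, lo, hi)
        if status != "optimal":
            return _empty(model, status)
        x = res.x[:n]
    else:
        raise ValidationError(f"unknown morp formulation {formulation!r}")

    usage = np.asarray(x)[uidx]
    l1 = float(np.sum(w * np.abs(usage - ref)))
    sol = _pack(model, rids, x, l1, "optimal")
    logger.debug("morp: L1 distance %.6g (%s)", l1, formulation)
    return sol


# ---------------------------------------------------------------------------
# Minimal total proteome
# ---------------------------------------------------------------------------

def min_total_proteome(
    model: ECModel,
    exchange_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> FluxSolution:
    """Minimize the protein-pool draw under measurement-derived exchange bounds.

    ``exchange_bounds`` maps exchange-reaction ids to (lb, ub) in
    mmol/gDW/h, typically derived from measured extracellular rates; they
    may only reference reactions of kind ``exchange``.
    """
    if not isinstance(model, ECModel):
        raise ValidationError("min_total_proteome requires an enzyme-constrained model")
    net = model.base
    if exchange_bounds:
        for rid in exchange_bounds:
            if not net.has_reaction(rid):
                raise ValidationError(f"unknown exchange reaction {rid!r}")
            if net.reaction(rid).kind != "exchange":
                raise ValidationError(f"{rid!r} is not an exchange reaction")
    S, lb, ub, rids = _lp_parts(model, exchange_bounds)
    c = np.zeros(len(rids))
    c[rids.index(model.pool_exchange_id)] = 1.0
    res, status = _solve(c, S, np.zeros(S.shape[0]), lb, ub)
    if status != "optimal":
        return _empty(model, status)
    return _pack(model, rids, res.x, float(res.fun), "optimal")


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def fva(
    model: Union[ECModel, StoichiometricModel],
    reaction_ids: Optional[Sequence[str]] = None,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction flux minimum/maximum under the model's constraints."""
    S, lb, ub, rids = _lp_parts(model, extra_bounds)
    if reaction_ids is None:
        reaction_ids = rids
    pos = {rid: j for j, rid in enumerate(rids)}
    out: Dict[str, Tuple[float, float]] = {}
    b = np.zeros(S.shape[0])
    for rid in reaction_ids:
        if rid not in pos:
            raise ValidationError(f"unknown reaction {rid!r}")
        j = pos[rid]
        lohi = []
        for sign in (1.0, -1.0):
            c = np.zeros(len(rids))
            c[j] = sign
            res, status = _solve(c, S, b, lb, ub)
            if status != "optimal":
                raise ValidationError(f"fva: model {status} when optimizing {rid!r}")
            lohi.append(sign * res.fun)
        out[rid] = (lohi[0], lohi[1])
    return out
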