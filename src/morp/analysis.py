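"""Post-processing of simulations: yields, relative fluxes, usage fold changes, RMSE.

Conventions:

* yields are g product formed per g substrate consumed over a time window,
  with consumption counted positive;
* relative fluxes express each reaction as a percentage of the
  glucose-equivalent substrate uptake, where disaccharide (trehalose) uptake
  counts double;
* enzyme-usage fold changes are log2 ratios with a small pseudo-usage floor so
  that zero usages are well defined;
* RMSE pools squared deviations over all listed products and measurement
  times by default (a per-product-averaged mode is available).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .ecmodel import ECModel, ValidationError
from .optimize import FluxSolution
from .toydata import MeasurementSeries

__all__ = [
    "YieldReport",
    "compute_yield",
    "yield_report",
    "relative_fluxes",
    "log2fc_enzyme_usage",
    "rmse_products",
    "cumulative_reallocation",
    "carbon_recovery",
]

logger = logging.getLogger("morp")


@dataclass
class YieldReport:
    phase: str
    substrate: str
    product: str
    yield_g_per_g: float

    def __post_init__(self) -> None:
        if self.yield_g_per_g < 0:
            raise ValidationError(
                f"negative yield {self.yield_g_per_g} for {self.product} on {self.substrate}"
            )


def _conc_at(traj: Trajectory, species: str, t: float) -> float:
    times = traj.times
    if t < times[0] - 1e-9 or t > times[-1] + 1e-9:
        raise ValidationError(f"time {t} h outside the trajectory span")
    return float(np.interp(t, times, traj.concentration(species)))


def compute_yield(
    traj: Trajectory, product: str, substrate: str, t0: float, t1: float
) -> float:
    """Mass yield (g/g) of ``product`` on ``substrate`` over the window [t0, t1].

    (C_product(t1) - C_product(t0)) / (C_substrate(t0) - C_substrate(t1)),
    both in g/L.  Raises when no substrate is consumed over the window or the
    apparent consumption is negative (substrate accumulating).
    """
    if not t0 < t1:
        raise ValidationError(f"need t0 < t1, got {t0} >= {t1}")
    consumed = _conc_at(traj, substrate, t0) - _conc_at(traj, substrate, t1)
    if consumed <= 1e-12:
        raise ValidationError(
            f"no net {substrate} consumption over [{t0}, {t1}] h "
            f"(Delta = {consumed:.3g} g/L); pick a window where the substrate falls"
        )
    formed = _conc_at(traj, product, t1) - _conc_at(traj, product, t0)
    return max(formed, 0.0) / consumed


def yield_report(
    traj: Trajectory,
    phases: Dict[str, Dict[str, object]],
    products: Sequence[str],
) -> List[YieldReport]:
    """Yield table over named windows, each ``{"substrate": id, "t0":..., "t1":...}``."""
    out = []
    for label, spec in phases.items():
        for product in products:
            out.append(
                YieldReport(
                    phase=label,
                    substrate=str(spec["substrate"]),
                    product=product,
                    yield_g_per_g=compute_yield(
                        traj, product, str(spec["substrate"]), float(spec["t0"]), float(spec["t1"])
                    ),
                )
            )
    return out


def relative_fluxes(
    sol: FluxSolution,
    substrate_uptake_id: str,
    trehalose_ids: Optional[Set[str]] = None,
    reaction_ids: Optional[Sequence[str]] = None,
) -> Dict[str, float]:
    """Each reaction's |flux| as a percentage of glucose-equivalent uptake.

    Uptake through any reaction listed in ``trehalose_ids`` counts at twice its
    flux (one disaccharide = two hexose equivalents).
    """
    trehalose_ids = trehalose_ids or set()
    if substrate_uptake_id not in sol.fluxes:
        raise ValidationError(f"uptake reaction {substrate_uptake_id!r} not in solution")
    uptake = abs(sol.fluxes[substrate_uptake_id])
    if substrate_uptake_id in trehalose_ids:
        uptake *= 2.0
    if uptake <= 1e-12:
        raise ValidationError(f"zero flux through uptake reaction {substrate_uptake_id!r}")
    rids = reaction_ids if reaction_ids is not None else list(sol.fluxes)
    return {rid: abs(sol.fluxes[rid]) / uptake * 100.0 for rid in rids}


def log2fc_enzyme_usage(
    sol: FluxSolution,
    ref: FluxSolution,
    model: Optional[ECModel] = None,
    pseudo: float = 1e-9,
) -> Union[np.ndarray, Dict[str, float]]:
    """log2((u_i + pseudo) / (u_ref,i + pseudo)) per enzyme-usage reaction.

    The pseudo-usage floor keeps zero/zero comparisons at 0.  Returns a vector
    aligned to the usage ordering, or an enzyme-id map when ``model`` is given.
    """
    if pseudo <= 0:
        raise ValidationError(f"pseudo floor must be > 0, got {pseudo}")
    u = np.asarray(sol.enzyme_usage, dtype=float)
    r = np.asarray(ref.enzyme_usage, dtype=float)
    if u.shape != r.shape:
        raise ValidationError(f"usage vectors differ in shape: {u.shape} vs {r.shape}")
    if np.any(u < -1e-12) or np.any(r < -1e-12):
        raise ValidationError("enzyme usages must be non-negative")
    fc = np.log2((np.maximum(u, 0.0) + pseudo) / (np.maximum(r, 0.0) + pseudo))
    if model is None:
        return fc
    return {e.enzyme_id: float(v) for e, v in zip(model.enzymes, fc)}


def cumulative_reallocation(traj: Trajectory, phase: Optional[int] = None) -> float:
    """Total enzyme-usage movement sum_r sum_i |u_{i,r} - u_{i,r-1}| (mmol/gDW/h).

    Restricted to the intervals labelled ``phase`` when given; the interval
    preceding the phase supplies the starting reference, so the jump into the
    phase is counted.
    """
    if len(traj.solutions) < 2:
        return 0.0
    total = 0.0
    for r in range(1, len(traj.solutions)):
        if phase is not None and traj.phase_labels[r] != phase:
            continue
        du = np.asarray(traj.solutions[r].enzyme_usage) - np.asarray(
            traj.solutions[r - 1].enzyme_usage
        )
        total += float(np.abs(du).sum())
    return total


def carbon_recovery(
    traj: Trajectory,
    model: ECModel,
    kinetics,
    phase: int,
) -> float:
    """Fraction of consumed substrate carbon recovered in products plus biomass.

    Carbon is counted in mmol C/L from tracked concentration changes over the
    phase (using each species' elemental formula via its exchange reaction)
    and from biomass growth (carbon drain per unit biomass flux from the
    biomass reaction's stoichiometry).  1.0 means closed carbon balance.
    """
    from .ecmodel import parse_formula  # local to avoid cycle at import time

    net = model.base
    t0, t1 = traj.phase_span(phase)
    consumed = 0.0
    produced = 0.0
    for species, (rid, mw) in kinetics.tracked().items():
        rxn = net.reaction(rid)
        (mid,) = rxn.stoichiometry.keys()
        n_c = parse_formula(net.metabolite(mid).formula).get("C", 0)
        if n_c == 0:
            continue
        delta = _conc_at(traj, species, t1) - _conc_at(traj, species, t0)
        if delta < 0:
            consumed += -delta / mw * n_c
        else:
            produced += delta / mw * n_c
    if model.biomass_id:
        bio = net.reaction(model.biomass_id)
        c_per_unit = 0.0
        for mid, coeff in bio.stoichiometry.items():
            if coeff < 0:
                formula = net.metabolite(mid).formula
                if formula:
                    c_per_unit += -coeff * parse_formula(formula).get("C", 0)
        times = traj.times
        dx = float(np.interp(t1, times, traj.biomass) - np.interp(t0, times, traj.biomass))
        produced += max(dx, 0.0) * c_per_unit
        consumed += max(-dx, 0.0) * c_per_unit
    if consumed <= 0:
        raise ValidationError(f"no carbon consumed in phase {phase}")
    return produced / consumed


def _series_like(obj) -> Dict[str, tuple]:
    if isinstance(obj, MeasurementSeries):
        return obj.data
    if isinstance(obj, Trajectory):
        return {sp: (obj.times, obj.concentration(sp)) for sp in obj.species()}
    if isinstance(obj, dict):
        return {sp: (np.asarray(t, float), np.asarray(c, float)) for sp, (t, c) in obj.items()}
    raise ValidationError(f"cannot interpret {type(obj).__name__} as a concentration series")


def rmse_products(
    predicted,
    measured: MeasurementSeries,
    products: Sequence[str],
    mode: str = "pooled",
) -> float:
    """Root-mean-square error between predicted and measured product concentrations.

    The prediction (a trajectory, measurement series, or
    ``{species: (times, values)}`` mapping) is linearly interpolated onto each
    product's measurement grid.  ``mode="pooled"`` (default) pools squared
    errors over all products and time points; ``mode="per_product"`` averages
    the per-product RMSEs instead.
    """
    if not products:
        raise ValidationError("products list must be non-empty")
    if mode not in ("pooled", "per_product"):
        raise ValidationError(f"unknown RMSE mode {mode!r}")
    pred = _series_like(predicted)
    sq: List[float] = []
    per_product: List[float] = []
    for sp in products:
        if sp not in measured.data:
            raise ValidationError(f"species {sp!r} missing from measurements")
        if sp not in pred:
            raise ValidationError(f"species {sp!r} missing from prediction")
        mt, mc = measured.data[sp]
        pt, pc = pred[sp]
        if mt[-1] < pt[0] or mt[0] > pt[-1]:
            raise ValidationError(f"{sp}: measured and predicted time ranges are disjoint")
        interp = np.interp(mt, pt, pc)
        errs = (interp - mc) ** 2
        sq.extend(errs.tolist())
        per_product.append(math.sqrt(float(np.mean(errs))))
    if mode == "pooled":
        return math.sqrt(float(np.mean(sq)))
    return float(np.mean(per_product))
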