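"""Dynamic FBA by the static optimization approach, including dMORP.

Batch culture is advanced on a fixed time grid.  At interval k the uptake
bound of each active substrate is set from Monod kinetics evaluated at the
previous interval's concentration,

    v_s,k = v_s,max * [S]_{k-1} / (Km + [S]_{k-1}),

an FBA-type LP is solved with the phase's objective, and biomass and
extracellular concentrations are integrated forward with an explicit Euler
step: X <- X * (1 + mu * dt), C <- C + v_exchange * mw * X * dt.

dMORP runs the minimal-reallocation objective with a rolling reference: each
interval's reference is the previous interval's enzyme-usage vector, and the
first interval of a dMORP phase takes the last solution of the preceding
phase as its reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .ecmodel import ECModel, MorpError, ValidationError
from .optimize import FluxSolution, ObjectiveSpec, fba, min_total_proteome, morp

__all__ = [
    "SubstrateKinetics",
    "KineticsSpec",
    "CultureState",
    "PhaseSpec",
    "Trajectory",
    "StepError",
    "monod_uptake",
    "step",
    "simulate",
    "detect_depletion",
]

logger = logging.getLogger("morp")

#: concentrations above this negative magnitude are clamped to zero
CLAMP_TOL = 1e-9
#: Euler undershoot below this aborts with a step-size error
NEGATIVE_TOL = 1e-6
#: default depletion threshold for phase switching (g/L)
DEPLETION_THRESHOLD = 0.01


class StepError(MorpError):
    """An interval LP failed or a concentration went unphysically negative."""


def monod_uptake(v_s_max: float, km: float, s: float) -> float:
    """Monod uptake rate v_s_max * s / (km + s), mmol/gDW/h.

    Monotone non-decreasing in the substrate concentration ``s`` (g/L);
    zero at zero substrate and v_s_max/2 at s = km.
    """
    if v_s_max < 0 or km < 0 or s < 0:
        raise ValidationError(
            f"monod_uptake: negative input (v_s_max={v_s_max}, km={km}, s={s})"
        )
    if s == 0:
        return 0.0
    return v_s_max * s / (km + s)


@dataclass
class SubstrateKinetics:
    """Monod parameters for one substrate's uptake."""

    species: str  #: concentration key (e.g. "glucose")
    uptake_reaction: str  #: exchange reaction id (uptake = negative flux)
    v_s_max: float  #: mmol/gDW/h
    km: float  #: g/L
    mw: float  #: g/mmol, for g/L bookkeeping

    def __post_init__(self) -> None:
        if self.v_s_max <= 0:
            raise ValidationError(f"{self.species}: v_s_max must be > 0")
        if self.km <= 0:
            raise ValidationError(f"{self.species}: km must be > 0")


@dataclass
class KineticsSpec:
    """Per-substrate Monod kinetics plus tracked-product bookkeeping.

    ``substrates`` drive dynamic uptake bounds; ``products`` maps tracked
    species to ``(exchange_reaction_id, mw)`` so secretion accumulates in g/L.
    """

    substrates: List[SubstrateKinetics]
    products: Dict[str, Tuple[str, float]] = field(default_factory=dict)

    def substrate(self, species: str) -> SubstrateKinetics:
        for s in self.substrates:
            if s.species == species:
                return s
        raise KeyError(f"no substrate kinetics for {species!r}")

    def tracked(self) -> Dict[str, Tuple[str, float]]:
        out = {s.species: (s.uptake_reaction, s.mw) for s in self.substrates}
        out.update(self.products)
        return out


@dataclass
class CultureState:
    t: float  #: h
    biomass: float  #: gDW/L
    concentrations: Dict[str, float]  #: g/L

    def __post_init__(self) -> None:
        if self.biomass < 0:
            raise ValidationError(f"biomass must be >= 0, got {self.biomass}")
        for sp, c in self.concentrations.items():
            if c < 0:
                raise ValidationError(f"concentration of {sp!r} must be >= 0, got {c}")

    def copy(self) -> "CultureState":
        return CultureState(self.t, self.biomass, dict(self.concentrations))


@dataclass
class PhaseSpec:
    """One schedule phase: an objective plus its exit condition.

    ``until`` is either ``("depleted", species, threshold_g_per_L)`` or
    ``("time", t_h)``; the final phase may use ``("end",)`` to run to t_end.
    ``active_substrates`` restricts which substrates receive Monod uptake
    bounds in this phase (None = all); inactive substrates are closed,
    emulating hierarchical (catabolite-repressed) sugar utilization.
    """

    objective: ObjectiveSpec
    until: Tuple = ("end",)
    active_substrates: Optional[Set[str]] = None

    def __post_init__(self) -> None:
        if self.until[0] not in ("depleted", "time", "end"):
            raise ValidationError(f"unknown phase condition {self.until!r}")
        if self.until[0] == "depleted" and self.until[2] < 0:
            raise ValidationError("depletion threshold must be >= 0")

    def done(self, state: CultureState) -> bool:
        if self.until[0] == "depleted":
            _, species, threshold = self.until
            if species not in state.concentrations:
                raise ValidationError(f"phase condition on untracked species {species!r}")
            return state.concentrations[species] <= threshold
        if self.until[0] == "time":
            return state.t >= self.until[1] - 1e-12
        return False


@dataclass
class Trajectory:
    """Time-indexed culture states with the per-interval LP solutions."""

    states: List[CultureState]
    solutions: List[FluxSolution]
    phase_labels: List[int]
    dt: float

    def __post_init__(self) -> None:
        if len(self.solutions) != max(len(self.states) - 1, 0):
            raise ValidationError("need exactly one solution per interval")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    def concentration(self, species: str) -> np.ndarray:
        return np.array([s.concentrations[species] for s in self.states])

    @property
    def biomass(self) -> np.ndarray:
        return np.array([s.biomass for s in self.states])

    def species(self) -> List[str]:
        return sorted(self.states[0].concentrations) if self.states else []

    def phase_span(self, phase: int) -> Tuple[float, float]:
        """(start, end) times of the intervals labelled with ``phase``."""
        idx = [i for i, p in enumerate(self.phase_labels) if p == phase]
        if not idx:
            raise ValidationError(f"phase {phase} never ran")
        return self.states[idx[0]].t, self.states[idx[-1] + 1].t

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy (time, variable, value) frame of biomass and concentrations."""
        rows = []
        for s in self.states:
            rows.append({"time": s.t, "variable": "biomass", "value": s.biomass})
            for sp, c in s.concentrations.items():
                rows.append({"time": s.t, "variable": sp, "value": c})
        return pd.DataFrame(rows)

    def save_csv(self, path: str) -> str:
        self.to_dataframe().to_csv(path, index=False)
        return path


def _interval_bounds(
    kinetics: KineticsSpec,
    state: CultureState,
    active: Optional[Set[str]],
    uptake_sense: str,
) -> Dict[str, Tuple[float, float]]:
    """Exchange bounds for one interval from the previous state's concentrations."""
    bounds: Dict[str, Tuple[float, float]] = {}
    for sub in kinetics.substrates:
        if active is not None and sub.species not in active:
            bounds[sub.uptake_reaction] = (0.0, 0.0)
            continue
        s = state.concentrations.get(sub.species, 0.0)
        v = monod_uptake(sub.v_s_max, sub.km, s)
        if uptake_sense == "equality":
            bounds[sub.uptake_reaction] = (-v, -v)
        elif uptake_sense == "upper":
            bounds[sub.uptake_reaction] = (-v, 0.0)
        else:
            raise ValidationError(f"unknown uptake sense {uptake_sense!r}")
    return bounds


def _solve_interval(model, objective, bounds):
    if objective.kind == "morp":
        return morp(model, objective.reference, extra_bounds=bounds)
    if objective.kind == "min_total_proteome":
        return min_total_proteome(model, exchange_bounds=bounds)
    return fba(model, objective, extra_bounds=bounds)


def step(
    model: ECModel,
    state: CultureState,
    kinetics: KineticsSpec,
    objective: ObjectiveSpec,
    dt: float,
    active_substrates: Optional[Set[str]] = None,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    uptake_sense: str = "equality",
    decay_rate: float = 0.0,
) -> Tuple[FluxSolution, CultureState]:
    """Advance the culture by one Euler interval.

    Substrate uptake bounds come from Monod kinetics at the *previous* state's
    concentrations (equality by default; ``uptake_sense="upper"`` relaxes to an
    upper bound on the uptake magnitude).  ``decay_rate`` (1/h) applies an
    optional first-order biomass decay, default off.
    """
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    bounds = _interval_bounds(kinetics, state, active_substrates, uptake_sense)
    if extra_bounds:
        bounds.update(extra_bounds)
    sol = _solve_interval(model, objective, bounds)
    if not sol.optimal:
        raise StepError(
            f"interval LP {sol.status} at t={state.t:g} h "
            f"(objective {objective.kind}, active bounds {bounds})"
        )
    mu = sol.fluxes.get(model.biomass_id, 0.0) if model.biomass_id else 0.0
    X = state.biomass
    new_biomass = X * (1.0 + (mu - decay_rate) * dt)
    conc = dict(state.concentrations)
    for species, (rid, mw) in kinetics.tracked().items():
        v = sol.fluxes.get(rid, 0.0)
        c = conc.get(species, 0.0) + v * mw * X * dt
        if c < -NEGATIVE_TOL:
            raise StepError(
                f"{species} would reach {c:.3g} g/L at t={state.t + dt:g} h; "
                f"reduce dt"
            )
        conc[species] = max(c, 0.0)
    new_state = CultureState(t=state.t + dt, biomass=max(new_biomass, 0.0), concentrations=conc)
    return sol, new_state


def simulate(
    model: ECModel,
    schedule: Sequence[PhaseSpec],
    kinetics: KineticsSpec,
    init: CultureState,
    dt: float = 0.1,
    t_end: float = 10.0,
    uptake_sense: str = "equality",
    decay_rate: float = 0.0,
    measured_bounds: Optional[Mapping[str, Tuple[str, "MeasurementInterp"]]] = None,
) -> Trajectory:
    """Run a phase-switching dynamic simulation.

    Phases run in schedule order; a phase ends when its ``until`` condition
    holds at the start of an interval.  Within a ``morp`` phase each
    interval's reference is the previous interval's enzyme usage, and the
    phase's first interval uses the last solution of the preceding phase
    (a ``morp`` first phase must carry its own reference).  If the last
    phase's condition never fires, the run completes at ``t_end`` with a
    warning.
    """
    if not schedule:
        raise ValidationError("schedule must contain at least one phase")
    if t_end <= init.t:
        raise ValidationError("t_end must exceed the initial time")
    states = [init.copy()]
    solutions: List[FluxSolution] = []
    phase_labels: List[int] = []
    phase_idx = 0
    prev_sol: Optional[FluxSolution] = None
    n_steps = int(round((t_end - init.t) / dt))
    for _ in range(n_steps):
        state = states[-1]
        while phase_idx < len(schedule) - 1 and schedule[phase_idx].done(state):
            phase_idx += 1
            logger.info("t=%.2f h: switching to phase %d", state.t, phase_idx)
        phase = schedule[phase_idx]
        if phase_idx == len(schedule) - 1 and phase.until[0] != "end" and phase.done(state):
            # the final phase's exit condition ends the run; t_end is a cap
            logger.info("t=%.2f h: final phase condition fired; stopping", state.t)
            break
        objective = phase.objective
        if objective.kind == "morp":
            # rolling reference: previous interval's usage; "previous" marks a
            # phase whose first reference comes from the preceding phase
            ref = prev_sol if prev_sol is not None else objective.reference
            if ref is None or isinstance(ref, str):
                raise ValidationError(
                    "a morp phase with no preceding interval needs an explicit "
                    "reference usage vector"
                )
            objective = ObjectiveSpec(kind="morp", reference=ref)
        extra = None
        if measured_bounds:
            extra = {
                rid: interp.bounds_at(state.t)
                for rid, interp in measured_bounds.items()
            }
        try:
            sol, new_state = step(
                model,
                state,
                kinetics,
                objective,
                dt,
                active_substrates=phase.active_substrates,
                extra_bounds=extra,
                uptake_sense=uptake_sense,
                decay_rate=decay_rate,
            )
        except StepError as exc:
            raise StepError(f"phase {phase_idx}: {exc}") from exc
        states.append(new_state)
        solutions.append(sol)
        phase_labels.append(phase_idx)
        prev_sol = sol
    if phase_idx < len(schedule) - 1:
        warnings.warn(
            f"schedule condition for phase {phase_idx} never fired; "
            f"run completed at t_end={t_end:g} h"
        )
    return Trajectory(states=states, solutions=solutions, phase_labels=phase_labels, dt=dt)


class MeasurementInterp:
    """Linear-in-time exchange-rate bounds derived from measured concentrations.

    Given measured times (h) and concentrations (g/L) of one species together
    with the biomass trace, the apparent specific exchange rate on each
    measured interval is (C_{k+1} - C_k) / (mw * X * dt) and is interpolated
    to the simulation grid; ``rel_slack``/``abs_slack`` widen it into a
    (lb, ub) band.
    """

    def __init__(
        self,
        times: np.ndarray,
        concentrations: np.ndarray,
        biomass: np.ndarray,
        mw: float,
        rel_slack: float = 0.1,
        abs_slack: float = 1e-6,
    ) -> None:
        times = np.asarray(times, dtype=float)
        conc = np.asarray(concentrations, dtype=float)
        X = np.asarray(biomass, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValidationError("need at least two measurement times")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("measurement times must be strictly increasing")
        mid = 0.5 * (times[:-1] + times[1:])
        Xmid = 0.5 * (X[:-1] + X[1:])
        rate = np.diff(conc) / np.diff(times) / (mw * np.maximum(Xmid, 1e-12))
        self._mid = mid
        self._rate = rate
        self.rel_slack = rel_slack
        self.abs_slack = abs_slack

    def bounds_at(self, t: float) -> Tuple[float, float]:
        v = float(np.interp(t, self._mid, self._rate))
        half = abs(v) * self.rel_slack + self.abs_slack
        return (v - half, v + half)


def detect_depletion(traj: Trajectory, species: str, threshold: float) -> float:
    """First time (h) at which ``species`` is at or below ``threshold`` g/L.

    Returns the trajectory's end time as a sentinel when the species never
    depletes.
    """
    if species not in traj.states[0].concentrations:
        raise ValidationError(f"species {species!r} not tracked")
    for s in traj.states:
        if s.concentrations[species] <= threshold:
            return s.t
    return traj.states[-1].t
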