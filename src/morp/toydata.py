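"""Synthetic enzyme-constrained central-carbon model of a lactic acid bacterium.

The toy network carries the two competing fermentation routes whose interplay
the package is built to study:

* homolactic: lumped EMP glycolysis (PFKA upper half, GAPD lower half) feeding
  LDH, converting one glucose into two lactates at 2 net ATP — the 1 g/g
  theoretical lactate yield;
* heterolactic: a lumped oxidative/phosphoketolase shunt (XFP) splitting
  hexose-phosphate into glyceraldehyde-3-phosphate plus acetyl-phosphate and
  CO2, with acetyl-phosphate drained either to acetate (ACKA, ATP-yielding) or
  ethanol (ADHP, NADH-regenerating) — halving the lactate yield per hexose.

Glucose enters directly; trehalose (a glucose disaccharide) is cleaved into
two hexose-phosphates, so one unit of trehalose uptake equals two glucose
equivalents.  An acetoin branch (ALSD), a lumped biomass drain, and an NGAM
ATP-hydrolysis floor complete the network.  Currency metabolites (ATP as a
phosphoanhydride-bond equivalent, NADH as a reducing equivalent) carry
carbon-free formulas so that carbon balance is checkable on every reaction.

Calibration (the defaults below are the package's fixture conditions): the
phosphoketolase-branch enzymes have a much higher turnover than the lumped
upper-EMP step, so heterolactic flux is cheap in enzyme usage, while EMP
yields 2 ATP/glucose against the heterolactic route's 1 — growth maximization
on fast glucose therefore stays homolactic, and minimal-reallocation
simulation of the slow trehalose phase shifts flux onto the phosphoketolase
branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .dynamics import CultureState, KineticsSpec, PhaseSpec, SubstrateKinetics, Trajectory
from .ecmodel import (
    CalibrationError,
    ECModel,
    EnzymeSpec,
    Metabolite,
    Reaction,
    StoichiometricModel,
    ValidationError,
    build_ec_model,
    check_mass_balance,
)
from .optimize import ObjectiveSpec

__all__ = [
    "ToyParams",
    "MeasurementSeries",
    "make_toy_gem",
    "make_toy_ccm",
    "make_toy_scenario",
    "make_coutilization_scenario",
    "make_synthetic_measurements",
    "MW",
]

logger = logging.getLogger("morp")

#: molecular weights used for g/L bookkeeping (g/mmol)
MW = {
    "glucose": 0.18016,
    "trehalose": 0.34230,
    "lactate": 0.09008,
    "acetate": 0.06005,
    "ethanol": 0.04607,
    "acetoin": 0.08811,
    "co2": 0.04401,
}

_ENZYME_RXNS = ("GLCT", "TRET", "PFKA", "GAPD", "LDH", "XFP", "ACKA", "ADHP", "ALSD")


@dataclass
class ToyParams:
    """Tunable conditions of the synthetic model and its batch scenario."""

    #: turnover numbers per lumped enzyme, 1/h
    kcats: Dict[str, float] = field(
        default_factory=lambda: {
            "GLCT": 1.0e5,
            "TRET": 1.0e4,
            "PFKA": 5.0e3,  # slow distal EMP step: homolactic flux is usage-expensive
            "GAPD": 2.0e5,
            "LDH": 2.0e5,
            "XFP": 8.0e4,  # fast phosphoketolase branch
            "ACKA": 6.0e4,
            "ADHP": 6.0e4,
            "ALSD": 4.0e4,
        }
    )
    #: enzyme molecular weights, g/mmol
    mws: Dict[str, float] = field(
        default_factory=lambda: {
            "GLCT": 0.070,
            "TRET": 0.110,
            "PFKA": 0.085,
            "GAPD": 0.037,
            "LDH": 0.035,
            "XFP": 0.092,
            "ACKA": 0.043,
            "ADHP": 0.095,
            "ALSD": 0.062,
        }
    )
    pool_capacity: float = 0.05  #: g catalytic protein / gDW
    glc_vmax: float = 12.0  #: mmol/gDW/h
    glc_km: float = 2.0  #: g/L; gentle taper so uptake is already low at the phase switch
    tre_vmax: float = 1.5  #: mmol/gDW/h
    tre_km: float = 1.0  #: g/L
    biomass_g6p: float = 5.0  #: mmol hexose-P per gDW
    biomass_atp: float = 75.0  #: mmol ATP per gDW
    ngam: float = 0.3  #: maintenance ATP floor, mmol/gDW/h
    glc0: float = 20.0  #: initial glucose, g/L
    tre0: float = 20.0  #: initial trehalose, g/L
    biomass0: float = 0.4  #: initial biomass, gDW/L
    dt: float = 0.1  #: h
    t_end: float = 18.0  #: h
    depletion_threshold: float = 0.05  #: g/L, glucose -> trehalose switch
    noise_sd: float = 0.5  #: g/L, synthetic measurement noise
    seed: int = 42

    def validate(self) -> None:
        for name, d in (("kcats", self.kcats), ("mws", self.mws)):
            for rid in _ENZYME_RXNS:
                if d.get(rid, 0) <= 0:
                    raise ValidationError(f"ToyParams.{name}[{rid!r}] must be > 0")
        for attr in (
            "pool_capacity", "glc_vmax", "glc_km", "tre_vmax", "tre_km",
            "biomass_g6p", "biomass_atp", "glc0", "tre0", "biomass0", "dt", "t_end",
        ):
            if getattr(self, attr) <= 0:
                raise ValidationError(f"ToyParams.{attr} must be > 0")
        if self.ngam < 0 or self.noise_sd < 0 or self.depletion_threshold < 0:
            raise ValidationError("ngam, noise_sd and depletion_threshold must be >= 0")


def make_toy_gem(params: Optional[ToyParams] = None) -> StoichiometricModel:
    """The plain (pre-conversion) stoichiometric network."""
    p = params or ToyParams()
    p.validate()
    mets = [
        Metabolite("glc_e", "glucose", "C6H12O6", "e"),
        Metabolite("tre_e", "trehalose", "C12H22O11", "e"),
        Metabolite("lac_e", "lactate", "C3H6O3", "e"),
        Metabolite("ac_e", "acetate", "C2H4O2", "e"),
        Metabolite("etoh_e", "ethanol", "C2H6O", "e"),
        Metabolite("actn_e", "acetoin", "C4H8O2", "e"),
        Metabolite("co2_e", "CO2", "CO2", "e"),
        Metabolite("g6p", "hexose 6-phosphate", "C6H13O9P", "c"),
        Metabolite("gap", "glyceraldehyde 3-phosphate", "C3H7O6P", "c"),
        Metabolite("pyr", "pyruvate", "C3H4O3", "c"),
        Metabolite("acp", "acetyl phosphate", "C2H5O5P", "c"),
        # currency carriers: carbon-free pseudo-formulas keep the C balance checkable
        Metabolite("atp", "phosphoanhydride-bond equivalent", "P", "c"),
        Metabolite("nadh", "reducing equivalent", "H2", "c"),
    ]
    B = 1000.0
    rxns = [
        # transport
        Reaction("GLCT", {"glc_e": -1, "atp": -1, "g6p": 1}, 0, B, name="glucose uptake & phosphorylation"),
        Reaction("TRET", {"tre_e": -1, "atp": -1, "g6p": 2}, 0, B, name="trehalose uptake & cleavage"),
        # EMP glycolysis, lumped
        Reaction("PFKA", {"g6p": -1, "atp": -1, "gap": 2}, 0, B, name="upper EMP (PGI/PFK/FBA)"),
        Reaction("GAPD", {"gap": -1, "pyr": 1, "atp": 2, "nadh": 1}, 0, B, name="lower EMP (GAP..PYK)"),
        Reaction("LDH", {"pyr": -1, "nadh": -1, "lac_e": 1}, 0, B, name="lactate dehydrogenase"),
        # phosphoketolase shunt, lumped oxidative part included
        Reaction("XFP", {"g6p": -1, "gap": 1, "acp": 1, "co2_e": 1, "nadh": 2}, 0, B, name="phosphoketolase shunt"),
        Reaction("ACKA", {"acp": -1, "ac_e": 1, "atp": 1}, 0, B, name="acetate kinase"),
        Reaction("ADHP", {"acp": -1, "nadh": -2, "etoh_e": 1}, 0, B, name="acetylphosphate to ethanol"),
        Reaction("ALSD", {"pyr": -2, "actn_e": 1, "co2_e": 2}, 0, B, name="acetoin branch"),
        # sinks
        Reaction("BIOMASS", {"g6p": -p.biomass_g6p, "atp": -p.biomass_atp}, 0, B, kind="biomass", name="lumped biomass"),
        Reaction("NGAM", {"atp": -1}, p.ngam, B, kind="ngam", name="non-growth maintenance ATP"),
        # exchanges (uptake negative)
        Reaction("EX_glc", {"glc_e": -1}, -B, 0, kind="exchange"),
        Reaction("EX_tre", {"tre_e": -1}, -B, 0, kind="exchange"),
        Reaction("EX_lac", {"lac_e": -1}, 0, B, kind="exchange"),
        Reaction("EX_ac", {"ac_e": -1}, 0, B, kind="exchange"),
        Reaction("EX_etoh", {"etoh_e": -1}, 0, B, kind="exchange"),
        Reaction("EX_actn", {"actn_e": -1}, 0, B, kind="exchange"),
        Reaction("EX_co2", {"co2_e": -1}, 0, B, kind="exchange"),
    ]
    return StoichiometricModel(
        metabolites=mets, reactions=rxns, biomass_id="BIOMASS", objective_default="BIOMASS"
    )


def _route_usage_costs(p: ToyParams) -> Tuple[float, float]:
    """Enzyme usage (mmol/gDW per unit hexose-P flux) of the two routes."""
    k = p.kcats
    emp = 1 / k["PFKA"] + 2 / k["GAPD"] + 2 / k["LDH"]
    pk = 1 / k["XFP"] + 1 / k["GAPD"] + 1 / k["LDH"] + 1 / k["ADHP"]
    return emp, pk


def toy_enzymes(params: Optional[ToyParams] = None) -> List[EnzymeSpec]:
    p = params or ToyParams()
    return [
        EnzymeSpec(f"E_{rid}", p.mws[rid], {rid: p.kcats[rid]}) for rid in _ENZYME_RXNS
    ]


def make_toy_ccm(params: Optional[ToyParams] = None) -> Tuple[ECModel, KineticsSpec]:
    """Build the enzyme-constrained toy model and its Monod kinetics.

    Raises :class:`CalibrationError` when the parameter set does not make the
    phosphoketolase route materially cheaper in enzyme usage than the EMP
    route (the property the trehalose-phase transition rests on).
    """
    p = params or ToyParams()
    p.validate()
    gem = make_toy_gem(p)
    issues = check_mass_balance(gem, elements=["C"])
    if issues:
        raise CalibrationError(f"toy network is not carbon balanced: {issues}")
    emp_cost, pk_cost = _route_usage_costs(p)
    if not pk_cost <= 0.5 * emp_cost:
        raise CalibrationError(
            "phosphoketolase route must cost at most half the EMP route in enzyme "
            f"usage per hexose-P (got EMP {emp_cost:.3g}, PK {pk_cost:.3g} mmol/gDW "
            "per unit flux); raise XFP/ADHP kcats or lower PFKA"
        )
    ec = build_ec_model(gem, toy_enzymes(p), pool_capacity=p.pool_capacity)
    kinetics = KineticsSpec(
        substrates=[
            SubstrateKinetics("glucose", "EX_glc", p.glc_vmax, p.glc_km, MW["glucose"]),
            SubstrateKinetics("trehalose", "EX_tre", p.tre_vmax, p.tre_km, MW["trehalose"]),
        ],
        products={
            "lactate": ("EX_lac", MW["lactate"]),
            "acetate": ("EX_ac", MW["acetate"]),
            "ethanol": ("EX_etoh", MW["ethanol"]),
            "acetoin": ("EX_actn", MW["acetoin"]),
            "co2": ("EX_co2", MW["co2"]),
        },
    )
    return ec, kinetics


@dataclass
class ToyScenario:
    """Everything :func:`morp.dynamics.simulate` needs for one batch run."""

    model: ECModel
    kinetics: KineticsSpec
    schedule: List[PhaseSpec]
    init: CultureState
    dt: float
    t_end: float
    params: ToyParams


def make_toy_scenario(params: Optional[ToyParams] = None) -> ToyScenario:
    """Diauxic glucose+trehalose batch: growth maximization on glucose, then a
    rolling minimal-reallocation (dMORP) trehalose phase.

    Glucose is the sole active substrate in phase 1 and trehalose in phase 2,
    emulating hierarchical (catabolite-repressed) utilization.
    """
    p = params or ToyParams()
    model, kinetics = make_toy_ccm(p)
    schedule = [
        PhaseSpec(
            objective=ObjectiveSpec(kind="max_growth"),
            until=("depleted", "glucose", p.depletion_threshold),
            active_substrates={"glucose"},
        ),
        PhaseSpec(
            objective=ObjectiveSpec(kind="morp", reference="previous"),
            until=("end",),
            active_substrates={"trehalose"},
        ),
    ]
    init = CultureState(
        t=0.0,
        biomass=p.biomass0,
        concentrations={
            "glucose": p.glc0,
            "trehalose": p.tre0,
            "lactate": 0.0,
            "acetate": 0.0,
            "ethanol": 0.0,
            "acetoin": 0.0,
            "co2": 0.0,
        },
    )
    return ToyScenario(model, kinetics, schedule, init, p.dt, p.t_end, p)


def make_coutilization_scenario(params: Optional[ToyParams] = None) -> ToyScenario:
    """Evolved-strain variant: both sugars active under growth maximization
    until trehalose runs low, then minimal reallocation."""
    p = params or ToyParams()
    scenario = make_toy_scenario(p)
    scenario.schedule = [
        PhaseSpec(
            objective=ObjectiveSpec(kind="max_growth"),
            until=("depleted", "trehalose", 2.0),
            active_substrates={"glucose", "trehalose"},
        ),
        PhaseSpec(
            objective=ObjectiveSpec(kind="morp", reference="previous"),
            until=("depleted", "trehalose", 0.5),
            active_substrates={"trehalose"},
        ),
    ]
    scenario.t_end = 20.0
    return scenario


# ---------------------------------------------------------------------------
# Synthetic measurements
# ---------------------------------------------------------------------------

@dataclass
class MeasurementSeries:
    """Per-species measured time points: {species: (times_h, concentrations_g_per_L)}."""

    data: Dict[str, Tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for sp, (t, c) in self.data.items():
            t = np.asarray(t, dtype=float)
            c = np.asarray(c, dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValidationError(f"{sp}: measurement times must be increasing")
            if np.any(c < 0):
                raise ValidationError(f"{sp}: concentrations must be >= 0")
            self.data[sp] = (t, c)

    def species(self) -> List[str]:
        return sorted(self.data)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"time": float(t), "species": sp, "concentration": float(c)}
            for sp, (ts, cs) in sorted(self.data.items())
            for t, c in zip(ts, cs)
        ]
        return pd.DataFrame(rows, columns=["time", "species", "concentration"])

    def save_csv(self, path: str) -> str:
        self.to_dataframe().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str) -> "MeasurementSeries":
        df = pd.read_csv(path)
        data = {
            sp: (g["time"].to_numpy(), g["concentration"].to_numpy())
            for sp, g in df.groupby("species")
        }
        return cls(data)


def make_synthetic_measurements(
    traj: Trajectory,
    noise_sd: float,
    seed: int,
    species: Optional[List[str]] = None,
    sample_every: float = 1.0,
) -> MeasurementSeries:
    """Noisy 'measured' concentration series subsampled from a trajectory.

    Gaussian noise of standard deviation ``noise_sd`` g/L is added and
    truncated at zero; sampling times are every ``sample_every`` hours on the
    trajectory grid.  Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    if not traj.states:
        raise ValidationError("empty trajectory")
    rng = np.random.default_rng(seed)
    times = traj.times
    stride = max(int(round(sample_every / traj.dt)), 1)
    idx = np.arange(0, len(times), stride)
    data = {}
    for sp in species or traj.species():
        conc = traj.concentration(sp)[idx]
        noisy = np.maximum(conc + rng.normal(0.0, noise_sd, size=idx.size), 0.0) if noise_sd else conc
        data[sp] = (times[idx], noisy)
    return MeasurementSeries(data)
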