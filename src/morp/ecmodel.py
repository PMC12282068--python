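"""Stoichiometric and enzyme-constrained model types, I/O, and the GECKO-style converter.

An enzyme-constrained model augments a stoichiometric network with one
pseudo-metabolite per enzyme, one enzyme-usage pseudo-reaction per enzyme
drawing protein mass from a shared pool, and a pool-exchange reaction bounded
by the total catalytic protein budget.  Flux through a catalyzed reaction j is
coupled to the amount of its enzyme i via the coefficient 1/kcat_ij, so that
v_j <= kcat_ij * e_i and sum_i mw_i * e_i <= pool_capacity.

Units, fixed package-wide: fluxes mmol/gDW/h; kcat 1/h; molecular weight
g/mmol; protein pool g/gDW.
"""

from __future__ import annotations

import copy as _copy
import json
import re
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "EnzymeSpec",
    "StoichiometricModel",
    "ECModel",
    "MorpError",
    "ValidationError",
    "FormatError",
    "ConfigurationError",
    "CalibrationError",
    "parse_formula",
    "load_gem",
    "save_model",
    "build_ec_model",
    "check_mass_balance",
    "read_enzyme_table",
    "write_enzyme_table",
]

REACTION_KINDS = ("metabolic", "exchange", "biomass", "ngam", "enzyme_usage", "pool_exchange")

#: default magnitude used for unbounded fluxes (mmol/gDW/h)
DEFAULT_BOUND = 1000.0

#: pseudo-metabolite id of the shared protein pool
POOL_MET_ID = "protein_pool"
#: reaction id of the pool exchange added by :func:`build_ec_model`
POOL_EXCHANGE_ID = "pool_exchange"

ENZYME_MET_PREFIX = "enzyme__"
USAGE_PREFIX = "usage__"
FWD_SUFFIX = "__fwd"
REV_SUFFIX = "__rev"


class MorpError(Exception):
    """Base class for package errors."""


class ValidationError(MorpError):
    """A model, parameter set, or argument violates an invariant."""


class FormatError(MorpError):
    """A file does not parse in the named dialect."""


class ConfigurationError(MorpError):
    """A required configuration entry is missing or inconsistent."""


class CalibrationError(MorpError):
    """A synthetic parameter set fails its asserted qualitative property."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into element counts.

    Raises :class:`ValidationError` on anything that is not a plain
    concatenation of element symbols with optional integer counts.
    """
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValidationError(f"unparseable formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise ValidationError(f"unparseable formula {formula!r}")
    return counts


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""
    compartment: str = "c"
    is_boundary: bool = False

    def element_counts(self) -> Dict[str, int]:
        return parse_formula(self.formula) if self.formula else {}


@dataclass
class Reaction:
    """One column of S.  ``stoichiometry`` maps metabolite id -> signed coefficient."""

    id: str
    stoichiometry: Dict[str, float]
    lb: float = -DEFAULT_BOUND
    ub: float = DEFAULT_BOUND
    kind: str = "metabolic"
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ValidationError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        if self.lb > self.ub:
            raise ValidationError(f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}")

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub


@dataclass
class EnzymeSpec:
    """One enzyme (or lumped complex): molecular weight and per-reaction kcats."""

    enzyme_id: str
    mw: float
    kcats: Dict[str, float]

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValidationError(f"enzyme {self.enzyme_id!r}: mw must be > 0, got {self.mw}")
        for rid, kcat in self.kcats.items():
            if kcat <= 0:
                raise ValidationError(
                    f"enzyme {self.enzyme_id!r}: kcat for {rid!r} must be > 0, got {kcat}"
                )


@dataclass
class StoichiometricModel:
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    biomass_id: str = ""
    objective_default: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- indexing helpers -------------------------------------------------
    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        try:
            return self._met_index[mid]
        except KeyError:
            raise KeyError(f"no metabolite {mid!r}") from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"no reaction {rid!r}") from None

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def _reindex(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    def validate(self) -> None:
        self._reindex()
        if len(self._met_index) != len(self.metabolites):
            raise ValidationError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ValidationError("duplicate reaction ids")
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in self._met_index:
                    raise ValidationError(
                        f"reaction {r.id!r} references undeclared metabolite {mid!r}"
                    )
        if self.biomass_id:
            if self.biomass_id not in self._rxn_index:
                raise ConfigurationError(f"biomass reaction {self.biomass_id!r} not in model")
            if self._rxn_index[self.biomass_id].kind != "biomass":
                raise ConfigurationError(
                    f"biomass reaction {self.biomass_id!r} has kind "
                    f"{self._rxn_index[self.biomass_id].kind!r}, expected 'biomass'"
                )

    def stoich_matrix(self) -> sparse.csr_matrix:
        """S as a sparse metabolites x reactions matrix (boundary species excluded)."""
        mids = {m.id: i for i, m in enumerate(self.metabolites) if not m.is_boundary}
        rows, cols, data = [], [], []
        for j, r in enumerate(self.reactions):
            for mid, coeff in r.stoichiometry.items():
                if mid in mids:
                    rows.append(mids[mid])
                    cols.append(j)
                    data.append(float(coeff))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(mids), len(self.reactions))
        )

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions], dtype=float)
        ub = np.array([r.ub for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "StoichiometricModel":
        return _copy.deepcopy(self)


@dataclass
class ECModel:
    """Enzyme-constrained model.

    ``base`` holds the full augmented, irreversibly-split network including the
    enzyme pseudo-metabolites, usage reactions, and the pool exchange;
    ``enzyme_usage_ids`` orders the usage reactions consistently with
    ``enzymes``.
    """

    base: StoichiometricModel
    enzymes: List[EnzymeSpec]
    enzyme_usage_ids: List[str]
    pool_exchange_id: str
    pool_capacity: float

    def __post_init__(self) -> None:
        if len(self.enzyme_usage_ids) != len(self.enzymes):
            raise ValidationError("enzyme_usage_ids and enzymes differ in length")
        if self.pool_capacity <= 0:
            raise ValidationError(f"pool_capacity must be > 0, got {self.pool_capacity}")
        for rid in self.enzyme_usage_ids + [self.pool_exchange_id]:
            if not self.base.has_reaction(rid):
                raise ValidationError(f"pseudo-reaction {rid!r} missing from network")

    @property
    def n_enzymes(self) -> int:
        return len(self.enzymes)

    @property
    def reaction_ids(self) -> List[str]:
        return self.base.reaction_ids

    @property
    def biomass_id(self) -> str:
        return self.base.biomass_id

    def enzyme_usage_index(self) -> List[int]:
        pos = {rid: j for j, rid in enumerate(self.base.reaction_ids)}
        return [pos[rid] for rid in self.enzyme_usage_ids]

    def copy(self) -> "ECModel":
        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# GECKO-style conversion
# ---------------------------------------------------------------------------

def build_ec_model(
    gem: StoichiometricModel,
    enzymes: List[EnzymeSpec],
    pool_capacity: float,
    isozyme_policy: str = "parallel",
) -> ECModel:
    """Convert a stoichiometric model into an enzyme-constrained one.

    Every reaction carrying a kcat is made irreversible (reversible reactions
    are split into ``<id>__fwd``/``<id>__rev`` arms, each coupled separately).
    Reactions catalyzed by several enzymes follow ``isozyme_policy``:
    ``"parallel"`` creates one arm per isozyme (``<id>__iso__<enzyme>``),
    ``"fastest"`` couples the single original reaction to the isozyme with the
    highest kcat.

    Parameters
    ----------
    pool_capacity:
        Total condition-dependent catalytic protein budget in g/gDW.  There is
        no universal default; it must be supplied by the caller.
    """
    if pool_capacity <= 0:
        raise ValidationError(f"pool_capacity must be > 0, got {pool_capacity}")
    if isozyme_policy not in ("parallel", "fastest"):
        raise ValidationError(f"unknown isozyme_policy {isozyme_policy!r}")
    seen = set()
    for e in enzymes:
        if e.enzyme_id in seen:
            raise ValidationError(f"duplicate enzyme_id {e.enzyme_id!r}")
        seen.add(e.enzyme_id)
        for rid in e.kcats:
            if not gem.has_reaction(rid):
                raise ValidationError(
                    f"enzyme {e.enzyme_id!r} references unknown reaction {rid!r}"
                )

    # reaction -> [(enzyme, kcat)]
    catalysis: Dict[str, List[Tuple[EnzymeSpec, float]]] = {}
    for e in enzymes:
        for rid, kcat in e.kcats.items():
            catalysis.setdefault(rid, []).append((e, kcat))

    mets = [_copy.deepcopy(m) for m in gem.metabolites]
    reactions: List[Reaction] = []
    # enzyme met coupling accumulates here: new reaction id -> {enzyme_id: kcat}
    coupling: Dict[str, Dict[str, float]] = {}

    for r in gem.reactions:
        if r.id not in catalysis:
            reactions.append(_copy.deepcopy(r))
            continue
        arms = catalysis[r.id]
        if isozyme_policy == "fastest" and len(arms) > 1:
            arms = [max(arms, key=lambda ek: ek[1])]
        # irreversible split first, then isozyme expansion of each direction
        directions: List[Tuple[str, Dict[str, float], float, float]] = []
        if r.reversible:
            directions.append((r.id + FWD_SUFFIX, dict(r.stoichiometry), 0.0, r.ub))
            directions.append(
                (r.id + REV_SUFFIX, {m: -c for m, c in r.stoichiometry.items()}, 0.0, -r.lb)
            )
        else:
            lb, ub = max(r.lb, 0.0), max(r.ub, 0.0)
            directions.append((r.id, dict(r.stoichiometry), lb, ub))
        for rid, stoich, lb, ub in directions:
            if len(arms) == 1:
                enzyme, kcat = arms[0]
                reactions.append(Reaction(rid, stoich, lb=lb, ub=ub, kind=r.kind, name=r.name))
                coupling[rid] = {enzyme.enzyme_id: kcat}
            else:
                for enzyme, kcat in arms:
                    arm_id = f"{rid}__iso__{enzyme.enzyme_id}"
                    reactions.append(
                        Reaction(arm_id, dict(stoich), lb=lb, ub=ub, kind=r.kind, name=r.name)
                    )
                    coupling[arm_id] = {enzyme.enzyme_id: kcat}

    # enzyme pseudo-metabolites and the protein pool
    mets.append(Metabolite(POOL_MET_ID, name="protein pool", compartment="c"))
    usage_ids: List[str] = []
    for e in enzymes:
        mets.append(Metabolite(ENZYME_MET_PREFIX + e.enzyme_id, name=e.enzyme_id, compartment="c"))
        usage_id = USAGE_PREFIX + e.enzyme_id
        reactions.append(
            Reaction(
                usage_id,
                {POOL_MET_ID: -e.mw, ENZYME_MET_PREFIX + e.enzyme_id: 1.0},
                lb=0.0,
                ub=DEFAULT_BOUND,
                kind="enzyme_usage",
                name=f"usage of {e.enzyme_id}",
            )
        )
        usage_ids.append(usage_id)
    reactions.append(
        Reaction(
            POOL_EXCHANGE_ID,
            {POOL_MET_ID: 1.0},
            lb=0.0,
            ub=pool_capacity,
            kind="pool_exchange",
            name="protein pool exchange",
        )
    )

    # wire 1/kcat consumption of enzyme pseudo-metabolites
    for rid, enz_kcats in coupling.items():
        rxn = next(r for r in reactions if r.id == rid)
        for enzyme_id, kcat in enz_kcats.items():
            rxn.stoichiometry[ENZYME_MET_PREFIX + enzyme_id] = -1.0 / kcat

    base = StoichiometricModel(
        metabolites=mets,
        reactions=reactions,
        biomass_id=gem.biomass_id,
        objective_default=gem.objective_default,
    )
    return ECModel(
        base=base,
        enzymes=[_copy.deepcopy(e) for e in enzymes],
        enzyme_usage_ids=usage_ids,
        pool_exchange_id=POOL_EXCHANGE_ID,
        pool_capacity=pool_capacity,
    )


# ---------------------------------------------------------------------------
# Mass balance checking
# ---------------------------------------------------------------------------

def check_mass_balance(
    model: StoichiometricModel,
    elements: Optional[Iterable[str]] = None,
    tol: float = 1e-9,
) -> List[Tuple[str, str, float]]:
    """Report internal reactions whose element counts do not cancel.

    Exchange, biomass, NGAM, and pseudo-reactions are exempt by definition.
    Reactions touching a formula-less (non-pseudo) metabolite are skipped with
    a warning, since biomass precursors and currency metabolites commonly lack
    formulas.  Returns ``(reaction_id, element, residual)`` triples; an empty
    list means every checkable reaction is balanced.
    """
    issues: List[Tuple[str, str, float]] = []
    skipped: List[str] = []
    want = set(elements) if elements is not None else None
    for r in model.reactions:
        if r.kind != "metabolic":
            continue
        counts: Dict[str, float] = {}
        incomplete = False
        for mid, coeff in r.stoichiometry.items():
            met = model.metabolite(mid)
            if not met.formula:
                incomplete = True
                continue
            for elem, n in met.element_counts().items():
                counts[elem] = counts.get(elem, 0.0) + coeff * n
        if incomplete:
            skipped.append(r.id)
            continue
        for elem, residual in sorted(counts.items()):
            if want is not None and elem not in want:
                continue
            if abs(residual) > tol:
                issues.append((r.id, elem, residual))
    if skipped:
        warnings.warn(
            f"{len(skipped)} reaction(s) skipped in mass-balance check "
            f"(formula-less metabolites): {', '.join(skipped[:5])}"
            + ("..." if len(skipped) > 5 else "")
        )
    return issues


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: StoichiometricModel) -> dict:
    return {
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "compartment": m.compartment,
                "is_boundary": m.is_boundary,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lb": r.lb,
                "ub": r.ub,
                "kind": r.kind,
            }
            for r in model.reactions
        ],
        "biomass_id": model.biomass_id,
        "objective_default": model.objective_default,
    }


def _model_from_dict(d: dict) -> StoichiometricModel:
    try:
        mets = [Metabolite(**m) for m in d["metabolites"]]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lb=float(r["lb"]),
                ub=float(r["ub"]),
                kind=r.get("kind", "metabolic"),
                name=r.get("name", ""),
            )
            for r in d["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed model JSON: {exc}") from exc
    return StoichiometricModel(
        metabolites=mets,
        reactions=rxns,
        biomass_id=d.get("biomass_id", ""),
        objective_default=d.get("objective_default", ""),
    )


def _ecmodel_to_dict(model: ECModel) -> dict:
    return {
        "ec_version": 1,
        "network": _model_to_dict(model.base),
        "enzymes": [
            {"enzyme_id": e.enzyme_id, "mw": e.mw, "kcats": e.kcats} for e in model.enzymes
        ],
        "enzyme_usage_ids": model.enzyme_usage_ids,
        "pool_exchange_id": model.pool_exchange_id,
        "pool_capacity": model.pool_capacity,
    }


def _ecmodel_from_dict(d: dict) -> ECModel:
    try:
        return ECModel(
            base=_model_from_dict(d["network"]),
            enzymes=[
                EnzymeSpec(e["enzyme_id"], float(e["mw"]), {k: float(v) for k, v in e["kcats"].items()})
                for e in d["enzymes"]
            ],
            enzyme_usage_ids=list(d["enzyme_usage_ids"]),
            pool_exchange_id=d["pool_exchange_id"],
            pool_capacity=float(d["pool_capacity"]),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed EC-model JSON: {exc}") from exc


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

def _to_cobra(model: StoichiometricModel):
    import cobra

    cm = cobra.Model("model")
    cmets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id, formula=m.formula or None, name=m.name, compartment=m.compartment or "c"
        )
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name, lower_bound=r.lb, upper_bound=r.ub)
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[mid]: c for mid, c in r.stoichiometry.items()})
    if model.objective_default and model.objective_default in [r.id for r in model.reactions]:
        cm.objective = model.objective_default
    elif model.biomass_id:
        cm.objective = model.biomass_id
    return cm


def _infer_kind(rid: str, n_mets: int, biomass_id: str) -> str:
    if rid.startswith(USAGE_PREFIX):
        return "enzyme_usage"
    if rid == POOL_EXCHANGE_ID:
        return "pool_exchange"
    if rid == biomass_id:
        return "biomass"
    if rid.upper() in ("ATPM", "NGAM") or rid.upper().startswith("NGAM"):
        return "ngam"
    if n_mets == 1:
        return "exchange"
    return "metabolic"


def _from_cobra(cm) -> StoichiometricModel:
    mets = [
        Metabolite(
            m.id,
            name=m.name or "",
            formula=m.formula or "",
            compartment=m.compartment or "c",
        )
        for m in cm.metabolites
    ]
    biomass_id = ""
    try:
        obj_ids = [v.name for v in cm.objective.variables]
        for r in cm.reactions:
            if r.id in obj_ids and r.objective_coefficient:
                biomass_id = r.id
                break
    except Exception:
        pass
    rxns = []
    for r in cm.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        kind = _infer_kind(r.id, len(stoich), biomass_id)
        rxns.append(
            Reaction(r.id, stoich, lb=float(r.lower_bound), ub=float(r.upper_bound), kind=kind, name=r.name or "")
        )
    # biomass_id only kept when the inferred kind survived
    bid = biomass_id if any(r.id == biomass_id and r.kind == "biomass" for r in rxns) else ""
    return StoichiometricModel(metabolites=mets, reactions=rxns, biomass_id=bid, objective_default=bid)


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------

def load_gem(path: str, dialect: str = "json"):
    """Load a model from SBML or the package's JSON dialect.

    JSON files produced from an :class:`ECModel` load back as an ``ECModel``;
    plain networks load as :class:`StoichiometricModel`.  SBML always yields a
    :class:`StoichiometricModel` (reaction kinds re-inferred by convention).
    """
    if dialect == "json":
        try:
            with open(path) as fh:
                d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})") from exc
        if not isinstance(d, dict):
            raise FormatError(f"{path}: expected a JSON object at top level")
        if "ec_version" in d:
            return _ecmodel_from_dict(d)
        return _model_from_dict(d)
    if dialect == "sbml":
        import cobra.io

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cm = cobra.io.read_sbml_model(path)
        except Exception as exc:
            raise FormatError(f"{path}: SBML parse failure ({exc})") from exc
        return _from_cobra(cm)
    raise ValidationError(f"unknown dialect {dialect!r}")


def save_model(model, path: str, dialect: str = "json") -> str:
    """Write a model to disk; ``load_gem(save_model(m))`` round-trips.

    For SBML, an :class:`ECModel` is written as its augmented network only
    (enzyme table and pool capacity are JSON-dialect metadata).
    """
    if dialect == "json":
        d = _ecmodel_to_dict(model) if isinstance(model, ECModel) else _model_to_dict(model)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)
        return path
    if dialect == "sbml":
        import cobra.io

        net = model.base if isinstance(model, ECModel) else model
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cobra.io.write_sbml_model(_to_cobra(net), path)
        return path
    raise ValidationError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Enzyme tables
# ---------------------------------------------------------------------------

ENZYME_TABLE_COLUMNS = ["enzyme_id", "reaction_id", "kcat_per_h", "mw_g_per_mmol"]


def read_enzyme_table(path: str) -> List[EnzymeSpec]:
    """Read a TSV with columns enzyme_id, reaction_id, kcat_per_h, mw_g_per_mmol."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ENZYME_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing enzyme-table columns {missing}")
    enzymes: Dict[str, EnzymeSpec] = {}
    for _, row in df.iterrows():
        eid = str(row["enzyme_id"])
        if eid not in enzymes:
            enzymes[eid] = EnzymeSpec(eid, float(row["mw_g_per_mmol"]), {})
        elif abs(enzymes[eid].mw - float(row["mw_g_per_mmol"])) > 1e-12:
            raise ValidationError(f"{path}: enzyme {eid!r} listed with conflicting mw")
        enzymes[eid].kcats[str(row["reaction_id"])] = float(row["kcat_per_h"])
    return list(enzymes.values())


def write_enzyme_table(enzymes: List[EnzymeSpec], path: str) -> str:
    rows = [
        {
            "enzyme_id": e.enzyme_id,
            "reaction_id": rid,
            "kcat_per_h": kcat,
            "mw_g_per_mmol": e.mw,
        }
        for e in enzymes
        for rid, kcat in e.kcats.items()
    ]
    pd.DataFrame(rows, columns=ENZYME_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
    return path
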