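"""Constraint-based metabolic models: containers, JSON I/O, FBA and FVA.

A model is a set of metabolites distributed over compartments and a set of
stoichiometric reactions with flux bounds (mmol/gDW/day).  Flux balance
analysis (FBA) maximizes or minimizes one reaction's flux subject to
steady-state mass balance ``S v = 0``, the box bounds ``lb <= v <= ub`` and,
for community models, additional linear coupling inequalities.  Flux
variability analysis (FVA) brackets the attainable flux range of a reaction
while the designated objective is held at a fraction of its optimum.

Sign conventions follow constraint-based modeling practice: exchange
reactions are written as ``met ->`` so that negative flux is uptake and
positive flux is secretion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "StrainModel",
    "FluxResult",
    "LinearConstraint",
    "ModelValidationError",
    "ModelParseError",
    "SolverError",
    "read_model",
    "write_model",
    "validate_model",
    "fba",
    "fva",
    "LinearProblem",
]

# Feasibility tolerance handed to the LP solver; residuals are checked at a
# looser 1e-6 when reporting, standard double-precision LP practice.
FEASIBILITY_TOL = 1e-9
RESIDUAL_TOL = 1e-6


class ModelValidationError(ValueError):
    """A model violates a structural invariant (names the offending field)."""


class ModelParseError(ValueError):
    """A model file does not conform to the JSON schema."""


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasible/unbounded."""


@dataclass
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    extras: dict = field(default_factory=dict)


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float
    upper_bound: float
    reaction_class: Optional[str] = None
    name: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        return self.id.startswith("EX_")


@dataclass
class StrainModel:
    strain_id: str
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    biomass_reaction_id: str
    compartments: Set[str]
    extras: dict = field(default_factory=dict)

    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(f"unknown reaction id: {reaction_id!r}")

    def has_reaction(self, reaction_id: str) -> bool:
        return any(r.id == reaction_id for r in self.reactions)

    def copy(self) -> "StrainModel":
        return StrainModel(
            strain_id=self.strain_id,
            metabolites=[
                Metabolite(m.id, m.compartment, m.name, dict(m.extras))
                for m in self.metabolites
            ],
            reactions=[
                Reaction(
                    r.id,
                    dict(r.stoichiometry),
                    r.lower_bound,
                    r.upper_bound,
                    r.reaction_class,
                    r.name,
                    dict(r.extras),
                )
                for r in self.reactions
            ],
            biomass_reaction_id=self.biomass_reaction_id,
            compartments=set(self.compartments),
            extras=dict(self.extras),
        )


@dataclass
class LinearConstraint:
    """One linear inequality  sum_r coeffs[r] * v_r <= upper."""

    coeffs: Dict[str, float]
    upper: float


@dataclass
class FluxResult:
    objective_value: float
    fluxes: Dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def validate_model(model: StrainModel) -> None:
    """Raise :class:`ModelValidationError` on any structural defect."""
    met_ids = [m.id for m in model.metabolites]
    met_set = set(met_ids)
    if len(met_set) != len(met_ids):
        dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
        raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
    for m in model.metabolites:
        if m.compartment not in model.compartments:
            raise ModelValidationError(
                f"metabolite {m.id!r}: compartment {m.compartment!r} not in "
                f"declared compartment set"
            )
    rxn_ids = [r.id for r in model.reactions]
    if len(set(rxn_ids)) != len(rxn_ids):
        dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
        raise ModelValidationError(f"duplicate reaction ids: {dupes}")
    for r in model.reactions:
        if not r.stoichiometry:
            raise ModelValidationError(f"reaction {r.id!r}: empty stoichiometry")
        if not (r.lower_bound <= r.upper_bound):
            raise ModelValidationError(
                f"reaction {r.id!r}: lower_bound {r.lower_bound} > "
                f"upper_bound {r.upper_bound}"
            )
        for met_id, coef in r.stoichiometry.items():
            if met_id not in met_set:
                raise ModelValidationError(
                    f"reaction {r.id!r} references undeclared metabolite {met_id!r}"
                )
            if not math.isfinite(coef):
                raise ModelValidationError(
                    f"reaction {r.id!r}: non-finite coefficient for {met_id!r}"
                )
        if r.is_exchange and len(r.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {r.id!r} must have exactly one metabolite"
            )
    if not any(r.id == model.biomass_reaction_id for r in model.reactions):
        raise ModelValidationError(
            f"biomass_reaction_id {model.biomass_reaction_id!r} not found"
        )


# ---------------------------------------------------------------------------
# JSON schema I/O.  Schema: one object per model, UTF-8, two-space indent,
# sorted keys (so identical models serialize to byte-identical files).
# ---------------------------------------------------------------------------

_MODEL_KEYS = {"strain_id", "compartments", "metabolites", "reactions", "biomass_reaction_id"}
_MET_KEYS = {"id", "compartment", "name"}
_RXN_KEYS = {"id", "stoichiometry", "lower_bound", "upper_bound", "reaction_class", "name"}


def _model_to_dict(model: StrainModel) -> dict:
    d = {
        "strain_id": model.strain_id,
        "compartments": sorted(model.compartments),
        "metabolites": [
            {"id": m.id, "compartment": m.compartment, "name": m.name, **m.extras}
            for m in model.metabolites
        ],
        "reactions": [],
        "biomass_reaction_id": model.biomass_reaction_id,
        **model.extras,
    }
    for r in model.reactions:
        rd = {
            "id": r.id,
            "stoichiometry": dict(sorted(r.stoichiometry.items())),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            **r.extras,
        }
        if r.reaction_class is not None:
            rd["reaction_class"] = r.reaction_class
        if r.name:
            rd["name"] = r.name
        d["reactions"].append(rd)
    return d


def _model_from_dict(d: dict) -> StrainModel:
    if not isinstance(d, dict):
        raise ModelParseError("model file must contain a JSON object")
    for key in ("strain_id", "compartments", "metabolites", "reactions", "biomass_reaction_id"):
        if key not in d:
            raise ModelParseError(f"missing required field {key!r}")
    mets = []
    for md in d["metabolites"]:
        if "id" not in md or "compartment" not in md:
            raise ModelParseError(f"metabolite entry missing 'id'/'compartment': {md}")
        extras = {k: v for k, v in md.items() if k not in _MET_KEYS}
        mets.append(Metabolite(md["id"], md["compartment"], md.get("name", ""), extras))
    rxns = []
    for rd in d["reactions"]:
        for key in ("id", "stoichiometry", "lower_bound", "upper_bound"):
            if key not in rd:
                raise ModelParseError(
                    f"reaction entry {rd.get('id', '<no id>')!r} missing field {key!r}"
                )
        if not isinstance(rd["stoichiometry"], dict):
            raise ModelParseError(f"reaction {rd['id']!r}: stoichiometry must be an object")
        extras = {k: v for k, v in rd.items() if k not in _RXN_KEYS}
        rxns.append(
            Reaction(
                rd["id"],
                {k: float(v) for k, v in rd["stoichiometry"].items()},
                float(rd["lower_bound"]),
                float(rd["upper_bound"]),
                rd.get("reaction_class"),
                rd.get("name", ""),
                extras,
            )
        )
    extras = {k: v for k, v in d.items() if k not in _MODEL_KEYS}
    model = StrainModel(
        strain_id=d["strain_id"],
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=d["biomass_reaction_id"],
        compartments=set(d["compartments"]),
        extras=extras,
    )
    validate_model(model)
    return model


def read_model(path) -> StrainModel:
    """Read a strain model from the JSON schema; validates on load."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as e:
            raise ModelParseError(f"{path}: invalid JSON: {e}") from e
    return _model_from_dict(d)


def write_model(model: StrainModel, path) -> None:
    """Write a model to the JSON schema (deterministic byte-stable output)."""
    validate_model(model)
    text = json.dumps(_model_to_dict(model), indent=2, sort_keys=True, ensure_ascii=False)
    Path(path).write_text(text + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Linear programming
# ---------------------------------------------------------------------------


class LinearProblem:
    """LP data for a model, reusable across many objectives.

    Builds the sparse stoichiometric matrix, the bound arrays and any extra
    inequality rows (coupling constraints) once; :meth:`solve` then only pays
    for the HiGHS call.  Community FSP computations solve tens of LPs per
    sample on the same matrices, which is where this pays off.
    """

    def __init__(self, model):
        self.model = model
        self.rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
        self.met_index = {m.id: i for i, m in enumerate(model.metabolites)}
        n = len(model.reactions)
        m = len(model.metabolites)
        rows, cols, vals = [], [], []
        for j, r in enumerate(model.reactions):
            for met_id, coef in r.stoichiometry.items():
                rows.append(self.met_index[met_id])
                cols.append(j)
                vals.append(float(coef))
        self.A_eq = sparse.csr_matrix((vals, (rows, cols)), shape=(m, n))
        self.b_eq = np.zeros(m)
        self.lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        constraints = list(getattr(model, "coupling_constraints", []) or [])
        if constraints:
            crows, ccols, cvals = [], [], []
            cub = []
            for i, c in enumerate(constraints):
                for rid, coef in c.coeffs.items():
                    crows.append(i)
                    ccols.append(self.rxn_index[rid])
                    cvals.append(float(coef))
                cub.append(float(c.upper))
            self.A_ub = sparse.csr_matrix(
                (cvals, (crows, ccols)), shape=(len(constraints), n)
            )
            self.b_ub = np.array(cub)
        else:
            self.A_ub = None
            self.b_ub = None
        self._extra_rows: List[Tuple[np.ndarray, float]] = []

    def set_bounds(self, reaction_id: str, lower: float, upper: float) -> None:
        j = self.rxn_index[reaction_id]
        self.lb[j] = lower
        self.ub[j] = upper

    def solve(self, objective: Mapping[str, float], direction: str = "max") -> FluxResult:
        if direction not in ("max", "min"):
            raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
        n = len(self.lb)
        c = np.zeros(n)
        for rid, coef in objective.items():
            c[self.rxn_index[rid]] = coef
        sign = -1.0 if direction == "max" else 1.0
        res = linprog(
            sign * c,
            A_ub=self.A_ub,
            b_ub=self.b_ub,
            A_eq=self.A_eq,
            b_eq=self.b_eq,
            bounds=np.column_stack([self.lb, self.ub]),
            method="highs",
            options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
        )
        if res.status == 0:
            fluxes = {r.id: float(res.x[j]) for j, r in enumerate(self.model.reactions)}
            return FluxResult(float(c @ res.x), fluxes, "optimal")
        if res.status == 2:
            return FluxResult(math.nan, {}, "infeasible")
        if res.status == 3:
            return FluxResult(math.inf if direction == "max" else -math.inf, {}, "unbounded")
        raise SolverError(f"LP solver failure (status {res.status}): {res.message}")


def _get_lp(model) -> LinearProblem:
    """Cached LinearProblem for a model; invalidated by mutating helpers."""
    lp = getattr(model, "_lp_cache", None)
    if lp is None or lp.model is not model:
        lp = LinearProblem(model)
        try:
            model._lp_cache = lp
        except AttributeError:
            pass
    return lp


def clear_lp_cache(model) -> None:
    if hasattr(model, "_lp_cache"):
        model._lp_cache = None


def fba(model, objective_reaction: str, direction: str = "max") -> FluxResult:
    """Flux balance analysis: optimize one reaction's flux.

    Maximizes (or minimizes) ``v_obj`` subject to ``S v = 0``, the flux
    bounds, and any coupling constraints the model carries.  Infeasibility
    and unboundedness are reported in ``status``, never silently as zero.
    """
    lp = _get_lp(model)
    if objective_reaction not in lp.rxn_index:
        raise KeyError(f"unknown reaction id: {objective_reaction!r}")
    result = fba_on_lp(lp, objective_reaction, direction)
    if result.ok:
        _check_solution(lp, result)
    return result


def fba_on_lp(lp: LinearProblem, objective_reaction: str, direction: str = "max") -> FluxResult:
    return lp.solve({objective_reaction: 1.0}, direction)


def _check_solution(lp: LinearProblem, result: FluxResult) -> None:
    v = np.array([result.fluxes[r.id] for r in lp.model.reactions])
    residual = np.abs(lp.A_eq @ v)
    if residual.size and residual.max() > RESIDUAL_TOL:
        raise SolverError(
            f"optimal solution violates mass balance: max |S v| = {residual.max():.3g}"
        )


def fva(
    model,
    reaction_id: str,
    fraction_of_optimum: float = 0.0,
    objective_reaction: Optional[str] = None,
) -> Tuple[float, float]:
    """Flux variability: (min, max) flux of ``reaction_id``.

    When ``fraction_of_optimum > 0`` the model's objective reaction is first
    optimized by FBA and then constrained to at least that fraction of its
    optimum.  At fraction 0 only the model's own bounds apply, so the range
    brackets every feasible flux of the target reaction.
    """
    if not (0.0 <= fraction_of_optimum <= 1.0):
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    lp = _get_lp(model)
    if reaction_id not in lp.rxn_index:
        raise KeyError(f"unknown reaction id: {reaction_id!r}")
    if objective_reaction is None:
        objective_reaction = getattr(model, "biomass_reaction_id", None)
    restore = None
    if fraction_of_optimum > 0.0:
        if objective_reaction is None:
            raise ValueError("objective_reaction required when fraction_of_optimum > 0")
        opt = fba(model, objective_reaction)
        if not opt.ok:
            raise SolverError(f"objective FBA not optimal: status {opt.status}")
        j = lp.rxn_index[objective_reaction]
        restore = (j, lp.lb[j])
        lp.lb[j] = max(lp.lb[j], fraction_of_optimum * opt.objective_value)
    try:
        lo = lp.solve({reaction_id: 1.0}, "min")
        hi = lp.solve({reaction_id: 1.0}, "max")
    finally:
        if restore is not None:
            lp.lb[restore[0]] = restore[1]
    for r in (lo, hi):
        if r.status == "infeasible":
            raise SolverError("FVA: constrained model is infeasible")
    return lo.objective_value, hi.objective_value
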