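"""Per-sample community model assembly.

Strain models are merged into a single community model: every member's
reactions and metabolites are namespaced with a ``<strain>__`` prefix, the
members' extracellular compartments are fused into one shared gut lumen
``u``, and the lumen is connected to a passive body-fluid compartment ``b``
and a fecal compartment ``fe`` through bile-acid transport and exchange
reactions.  A community biomass reaction consumes each member's biomass
metabolite weighted by that sample's relative abundance, and flux coupling
inequalities ``|v_r| <= c * v_biomass(strain) + eps`` tie every strain
reaction to its owner's growth, so taxa that are absent from a sample cannot
carry flux.

Diet is applied as bounds on the lumen exchange reactions; unlisted lumen
exchanges are closed to uptake by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .gem_core import (
    LinearConstraint,
    Metabolite,
    ModelValidationError,
    Reaction,
    StrainModel,
    clear_lp_cache,
    fba,
    fva,
)

__all__ = [
    "AbundanceVector",
    "DietSpec",
    "CommunityOptions",
    "CommunityModel",
    "SanityReport",
    "build_community",
    "apply_diet",
    "apply_diet_to_strain",
    "sanity_check",
    "renormalize_abundance",
]

LUMEN = "u"
BODY_FLUID = "b"
FECAL = "fe"
EXTRACELLULAR = "e"

COMMUNITY_BIOMASS_ID = "community_biomass"

_COMP_RE = re.compile(r"\[([^\[\]]+)\]$")


def _met_compartment_suffix(met_id: str) -> Optional[str]:
    m = _COMP_RE.search(met_id)
    return m.group(1) if m else None


def _relabel(met_id: str, new_comp: str) -> str:
    return _COMP_RE.sub(f"[{new_comp}]", met_id)


@dataclass
class AbundanceVector:
    """Relative abundances of the modeled strains in one sample."""

    sample_id: str
    abundances: Dict[str, float]

    def renormalized(self, threshold: float = 1e-6) -> "AbundanceVector":
        return renormalize_abundance(self, threshold)


def renormalize_abundance(abundance: AbundanceVector, threshold: float = 1e-6) -> AbundanceVector:
    """Drop strains below ``threshold`` and rescale the rest to sum to 1."""
    for sid, a in abundance.abundances.items():
        if a < 0:
            raise ValueError(f"negative abundance for strain {sid!r}: {a}")
    kept = {sid: a for sid, a in abundance.abundances.items() if a >= threshold}
    total = sum(kept.values())
    if total <= 0:
        raise ValueError(
            f"empty community: no strain above threshold {threshold} "
            f"in sample {abundance.sample_id!r}"
        )
    return AbundanceVector(abundance.sample_id, {sid: a / total for sid, a in kept.items()})


@dataclass
class DietSpec:
    """Bounds on lumen exchange reactions (mmol/gDW/day).

    Keys are lumen exchange ids (``EX_glc[u]``); values are
    ``(lower_bound, upper_bound)`` with negative lower bound = allowed uptake.
    """

    exchange_bounds: Dict[str, Tuple[float, float]]

    def validate(self) -> None:
        for rid, (lb, ub) in self.exchange_bounds.items():
            if lb > ub:
                raise ValueError(f"diet bound {rid!r}: lower {lb} > upper {ub}")


@dataclass
class CommunityOptions:
    coupling_c: float = 400.0
    coupling_eps: float = 0.01
    biomass_bounds: Tuple[float, float] = (0.4, 1.0)
    abundance_threshold: float = 1e-6
    secretion_ub: float = 1000.0
    # BA metabolite base ids that get lumen->fecal and lumen->body-fluid routes
    ba_metabolites: Tuple[str, ...] = ()
    close_unlisted_uptake: bool = True


@dataclass
class CommunityModel:
    """Merged multi-strain model with shared lumen and coupling constraints."""

    community_id: str
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    biomass_reaction_id: str  # == community_biomass_reaction_id
    compartments: Set[str]
    member_strains: List[str]
    abundance: AbundanceVector
    coupling_constraints: List[LinearConstraint]
    options: CommunityOptions
    extras: dict = field(default_factory=dict)

    @property
    def community_biomass_reaction_id(self) -> str:
        return self.biomass_reaction_id

    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(f"unknown reaction id: {reaction_id!r}")

    def has_reaction(self, reaction_id: str) -> bool:
        return any(r.id == reaction_id for r in self.reactions)

    def lumen_exchange_ids(self) -> List[str]:
        return [r.id for r in self.reactions if r.id.startswith("EX_") and r.id.endswith("[u]")]


def _biomass_metabolite(model: StrainModel) -> str:
    """The metabolite produced by the strain's biomass reaction."""
    rxn = model.get_reaction(model.biomass_reaction_id)
    products = [m for m, c in rxn.stoichiometry.items() if c > 0]
    if len(products) != 1:
        raise ModelValidationError(
            f"strain {model.strain_id!r}: biomass reaction "
            f"{rxn.id!r} must produce exactly one biomass metabolite"
        )
    return products[0]


def build_community(
    models: Sequence[StrainModel],
    abundance: AbundanceVector,
    diet: Optional[DietSpec] = None,
    options: Optional[CommunityOptions] = None,
) -> CommunityModel:
    """Assemble a personalized community model for one sample.

    Strains below the abundance threshold are dropped and the remaining
    abundances renormalized to the simplex before they enter the community
    biomass stoichiometry.
    """
    opts = options or CommunityOptions()
    by_id = {m.strain_id: m for m in models}
    unknown = sorted(set(abundance.abundances) - set(by_id))
    if unknown:
        raise KeyError(f"abundance references strains without models: {unknown}")
    ab = renormalize_abundance(abundance, opts.abundance_threshold)
    members = sorted(ab.abundances)

    metabolites: List[Metabolite] = []
    met_seen: Set[str] = set()
    reactions: List[Reaction] = []
    compartments: Set[str] = {LUMEN, BODY_FLUID, FECAL}
    coupling: List[LinearConstraint] = []
    lumen_mets: Set[str] = set()

    def add_met(met: Metabolite) -> None:
        if met.id not in met_seen:
            met_seen.add(met.id)
            metabolites.append(met)

    for sid in members:
        model = by_id[sid]
        prefix = f"{sid}__"
        met_map: Dict[str, str] = {}
        for met in model.metabolites:
            if met.compartment == EXTRACELLULAR:
                new_id = _relabel(met.id, LUMEN)
                met_map[met.id] = new_id
                add_met(Metabolite(new_id, LUMEN, met.name))
                lumen_mets.add(new_id)
            else:
                new_comp = f"{sid}__{met.compartment}"
                compartments.add(new_comp)
                met_map[met.id] = prefix + met.id
                add_met(Metabolite(prefix + met.id, new_comp, met.name))
        biomass_rid = prefix + model.biomass_reaction_id
        for rxn in model.reactions:
            if rxn.is_exchange:
                continue  # strain-level exchanges are replaced by lumen exchanges
            if rxn.id.startswith("DM_"):
                continue  # standalone demand sinks; the community biomass is the sink
            new_rxn = Reaction(
                prefix + rxn.id,
                {met_map[m]: c for m, c in rxn.stoichiometry.items()},
                rxn.lower_bound,
                rxn.upper_bound,
                rxn.reaction_class,
                rxn.name,
            )
            reactions.append(new_rxn)
            if new_rxn.id != biomass_rid:
                c = opts.coupling_c
                eps = opts.coupling_eps
                coupling.append(LinearConstraint({new_rxn.id: 1.0, biomass_rid: -c}, eps))
                coupling.append(LinearConstraint({new_rxn.id: -1.0, biomass_rid: -c}, eps))

    # lumen exchanges (closed to uptake until the diet opens them)
    for met_id in sorted(lumen_mets):
        reactions.append(
            Reaction(f"EX_{met_id}", {met_id: -1.0}, 0.0, opts.secretion_ub)
        )

    # bile-acid routing: lumen -> fecal and lumen -> body fluid.  Panel BAs
    # absent from every member still get lumen metabolites and exchanges so
    # diets and secretion queries are well-defined for any community.
    for ba in opts.ba_metabolites:
        u_id = f"{ba}[{LUMEN}]"
        if u_id not in met_seen:
            add_met(Metabolite(u_id, LUMEN, ba))
            reactions.append(Reaction(f"EX_{u_id}", {u_id: -1.0}, 0.0, opts.secretion_ub))
        for comp, tag in ((FECAL, "FE"), (BODY_FLUID, "BF")):
            c_id = f"{ba}[{comp}]"
            add_met(Metabolite(c_id, comp, ba))
            reactions.append(
                Reaction(
                    f"{tag}t_{ba}",
                    {u_id: -1.0, c_id: 1.0},
                    0.0,
                    opts.secretion_ub,
                    reaction_class="ba_transport",
                )
            )
            reactions.append(Reaction(f"EX_{c_id}", {c_id: -1.0}, 0.0, opts.secretion_ub))

    # community biomass: consumes each member's biomass metabolite, weighted
    # by relative abundance; the growth corridor makes secretion potentials
    # comparable across samples.
    biomass_stoich = {
        f"{sid}__{_biomass_metabolite(by_id[sid])}": -ab.abundances[sid] for sid in members
    }
    reactions.append(
        Reaction(
            COMMUNITY_BIOMASS_ID,
            biomass_stoich,
            opts.biomass_bounds[0],
            opts.biomass_bounds[1],
        )
    )

    community = CommunityModel(
        community_id=f"community_{ab.sample_id}",
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=COMMUNITY_BIOMASS_ID,
        compartments=compartments,
        member_strains=members,
        abundance=ab,
        coupling_constraints=coupling,
        options=opts,
    )
    if diet is not None:
        apply_diet(community, diet)
    return community


def apply_diet(community: CommunityModel, diet: DietSpec) -> CommunityModel:
    """Overwrite lumen exchange bounds from the diet (in place).

    Unlisted lumen exchanges are closed to uptake (lower bound 0) unless the
    community options say otherwise.  Idempotent.
    """
    diet.validate()
    lumen_ex = set(community.lumen_exchange_ids())
    unknown = sorted(set(diet.exchange_bounds) - lumen_ex)
    if unknown:
        raise KeyError(f"diet references unknown lumen exchanges: {unknown}")
    for rxn in community.reactions:
        if rxn.id not in lumen_ex:
            continue
        if rxn.id in diet.exchange_bounds:
            rxn.lower_bound, rxn.upper_bound = diet.exchange_bounds[rxn.id]
        elif community.options.close_unlisted_uptake:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    clear_lp_cache(community)
    return community


def apply_diet_to_strain(model: StrainModel, diet: DietSpec) -> StrainModel:
    """Apply a lumen diet to a standalone strain (``[u]`` ids map to ``[e]``).

    Lets a strain be simulated "under the same diet" as a community; strain
    exchanges absent from the diet are closed to uptake.
    """
    diet.validate()
    bounds = {_relabel_exchange(rid): b for rid, b in diet.exchange_bounds.items()}
    for rxn in model.reactions:
        if not rxn.is_exchange:
            continue
        if rxn.id in bounds:
            rxn.lower_bound, rxn.upper_bound = bounds[rxn.id]
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    clear_lp_cache(model)
    return model


def _relabel_exchange(rid: str) -> str:
    return rid.replace(f"[{LUMEN}]", f"[{EXTRACELLULAR}]")


@dataclass
class SanityCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class SanityReport:
    checks: List[SanityCheck]

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed(self) -> List[SanityCheck]:
        return [c for c in self.checks if not c.passed]


def sanity_check(community: CommunityModel) -> SanityReport:
    """Feasibility, nonzero community growth, and BA secretion reachability.

    Never raises on a failing check; failures are report entries naming the
    offending reactions.
    """
    checks: List[SanityCheck] = []
    result = fba(community, community.biomass_reaction_id, "max")
    feasible = result.status == "optimal"
    checks.append(
        SanityCheck("feasible", feasible, "" if feasible else f"status: {result.status}")
    )
    nonzero = feasible and result.objective_value > 1e-9
    checks.append(
        SanityCheck(
            "nonzero biomass",
            nonzero,
            "" if nonzero else "community biomass optimum is zero or model infeasible",
        )
    )
    fecal_ex = [r.id for r in community.reactions if r.id.startswith("EX_") and r.id.endswith(f"[{FECAL}]")]
    checks.append(
        SanityCheck(
            "BA fecal exchange present",
            bool(fecal_ex),
            "" if fecal_ex else "no fecal BA exchange reactions",
        )
    )
    if fecal_ex and feasible:
        bad = []
        for rid in fecal_ex:
            try:
                lo, hi = fva(community, rid, 0.0)
            except Exception as e:  # infeasible sub-LP counts as failure
                bad.append(f"{rid} ({e})")
                continue
            import math

            if not (math.isfinite(lo) and math.isfinite(hi)):
                bad.append(rid)
        checks.append(
            SanityCheck(
                "BA secretion reachable",
                not bad,
                "" if not bad else f"non-finite FVA range: {bad}",
            )
        )
    else:
        checks.append(
            SanityCheck("BA secretion reachable", False, "no fecal exchanges or infeasible")
        )
    return SanityReport(checks)
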