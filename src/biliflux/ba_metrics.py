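"""Model-derived bile-acid metrics per sample.

Two quantities are computed from a personalized community model:

* **Reaction abundance** — the abundance-weighted presence of a reaction
  across community members: ``RA(r) = sum_i A_i * [r in strain i]``, a value
  in [0, 1].  Summed over all reactions of the BA reaction classes it gives
  the total BA reaction abundance of a sample.

* **Fecal secretion potential (FSP)** — ``FSP_ij = A_i * v_j`` where ``A_i``
  is the relative abundance of strain *i* and ``v_j`` the absolute flux
  potential (mmol/gDW/day) of bile acid *j*: the FVA maximum of the relevant
  export reaction with community growth held in its corridor.  Summed over
  the secondary bile acids and all strains it gives the total secondary FSP.

The reaction-class taxonomy names the ten microbial BA reaction classes
(deconjugation by bile salt hydrolases, cholate ligation, 7alpha/7beta- and
3alpha-hydroxysteroid dehydrogenases, 3beta/6beta epimerization,
dehydroxylation, transport) and the secondary bile-acid set.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .community import AbundanceVector, CommunityModel, FECAL, BODY_FLUID
from .gem_core import LinearProblem, StrainModel, _get_lp

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionClass",
    "ReactionClassTaxonomy",
    "FSPRecord",
    "ReactionAbundanceProfile",
    "default_taxonomy",
    "reaction_abundance",
    "total_ba_reaction_abundance",
    "presence_from_models",
    "flux_potential",
    "strain_flux_potential",
    "fsp",
    "total_secondary_fsp",
    "fsp_records",
]

CATEGORIES = {
    "deconjugation",
    "dehydroxylation",
    "dehydrogenation",
    "epimerization",
    "ligation",
    "transport",
}


@dataclass
class ReactionClass:
    class_id: str
    description: str
    category: str
    member_reaction_ids: Set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(
                f"reaction class {self.class_id!r}: unknown category {self.category!r}"
            )


@dataclass
class ReactionClassTaxonomy:
    classes: Dict[str, ReactionClass]
    secondary_ba_ids: Set[str]

    def all_member_reactions(self) -> Set[str]:
        out: Set[str] = set()
        for cls in self.classes.values():
            out |= cls.member_reaction_ids
        return out

    def to_json(self, path) -> None:
        d = {
            "classes": {
                cid: {
                    "description": c.description,
                    "category": c.category,
                    "member_reaction_ids": sorted(c.member_reaction_ids),
                }
                for cid, c in sorted(self.classes.items())
            },
            "secondary_ba_ids": sorted(self.secondary_ba_ids),
        }
        Path(path).write_text(
            json.dumps(d, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path) -> "ReactionClassTaxonomy":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        classes = {
            cid: ReactionClass(
                cid, cd["description"], cd["category"], set(cd["member_reaction_ids"])
            )
            for cid, cd in d["classes"].items()
        }
        return cls(classes, set(d["secondary_ba_ids"]))


def default_taxonomy() -> ReactionClassTaxonomy:
    """The ten default microbial BA reaction classes and the secondary BA set.

    Membership mirrors the canonical gut BA transformation network: BSHs
    deconjugate glyco-/tauro-conjugates, the 7alpha-dehydroxylation pathway
    (cholate ligases BICoAL/BAIA) converts CA/CDCA to DCA/LCA,
    hydroxysteroid dehydrogenases and epimerases generate oxo-, urso- and
    hyo- forms, and transporters shuttle BAs across the membrane.
    """
    defs = [
        ("bsh_glyco", "bile salt hydrolase, glycine conjugates", "deconjugation",
         {"BSHG_GCA", "BSHG_GCDCA"}),
        ("bsh_tauro", "bile salt hydrolase, taurine conjugates", "deconjugation",
         {"BSHT_TCA", "BSHT_TCDCA"}),
        ("bicoal", "cholate/chenodeoxycholate CoA ligase (BICoAL)", "ligation",
         {"BICOAL_CA", "BICOAL_CDCA"}),
        ("baia", "bile acid 7alpha-dehydroxylation (BAIA)", "dehydroxylation",
         {"BAIA_DCA", "BAIA_LCA"}),
        ("hsdh_7alpha", "7alpha-hydroxysteroid dehydrogenase", "dehydrogenation",
         {"HSDH7A_CDCA"}),
        ("hsdh_7beta", "7beta-hydroxysteroid dehydrogenase (urso route)", "dehydrogenation",
         {"HSDH7B_UDCA"}),
        ("hsdh_3alpha", "3alpha-hydroxysteroid dehydrogenase", "dehydrogenation",
         {"HSDH3A_LCA"}),
        ("epim_3beta", "3beta epimerization (iso-BA formation)", "epimerization",
         {"EPIM3B_ISOLCA"}),
        ("epim_6beta", "6beta epimerization (hyo route)", "epimerization",
         {"EPIM6B_HDCA"}),
        ("ba_transport", "bile-acid membrane transport", "transport",
         {"T_ca", "T_cdca", "T_gca", "T_gcdca", "T_tca", "T_tcdca", "T_dca",
          "T_lca", "T_udca", "T_hdca", "T_oxolca7", "T_oxolca3", "T_isolca"}),
    ]
    classes = {cid: ReactionClass(cid, desc, cat, set(members)) for cid, desc, cat, members in defs}
    secondary = {
        "dca", "lca", "udca", "hdca",
        "gdca", "glca", "gudca", "ghdca",
        "tdca", "tlca", "tudca", "thdca",
    }
    return ReactionClassTaxonomy(classes, secondary)


@dataclass
class FSPRecord:
    sample_id: str
    ba_id: str
    strain_id: str  # a member strain id, or "community"
    A: float
    v: float

    @property
    def fsp(self) -> float:
        return self.A * self.v


@dataclass
class ReactionAbundanceProfile:
    sample_id: str
    values: Dict[str, float]
    total_ba_reaction_abundance: float


def presence_from_models(models: Sequence[StrainModel]) -> Dict[str, Set[str]]:
    """Per-strain set of reaction ids (un-namespaced)."""
    return {m.strain_id: {r.id for r in m.reactions} for m in models}


def reaction_abundance(
    abundance: AbundanceVector,
    presence: Mapping[str, Set[str]],
    reaction_id: str,
    strict: bool = False,
) -> float:
    """Abundance-weighted presence of one reaction, in [0, 1].

    ``abundance`` must already be renormalized over the modeled strains.
    An id carried by no strain contributes 0 (warns; ``strict=True`` raises).
    """
    missing = sorted(set(abundance.abundances) - set(presence))
    if missing:
        raise KeyError(f"presence map lacks member strains: {missing}")
    if not any(reaction_id in rxns for rxns in presence.values()):
        if strict:
            raise KeyError(f"reaction {reaction_id!r} carried by no strain")
        logger.warning("reaction %r carried by no strain; abundance 0", reaction_id)
        return 0.0
    return sum(
        a for sid, a in abundance.abundances.items() if reaction_id in presence[sid]
    )


def total_ba_reaction_abundance(
    abundance: AbundanceVector,
    presence: Mapping[str, Set[str]],
    taxonomy: ReactionClassTaxonomy,
) -> float:
    """Sum of reaction abundances over every reaction of every BA class."""
    if not taxonomy.classes:
        raise ValueError("empty taxonomy")
    total = 0.0
    for rid in sorted(taxonomy.all_member_reactions()):
        if any(rid in rxns for rxns in presence.values()):
            total += reaction_abundance(abundance, presence, rid)
    return total


def class_abundance_profile(
    abundance: AbundanceVector,
    presence: Mapping[str, Set[str]],
    taxonomy: ReactionClassTaxonomy,
) -> ReactionAbundanceProfile:
    """Per-class summed reaction abundance plus the total, for one sample."""
    values: Dict[str, float] = {}
    for cid, cls in sorted(taxonomy.classes.items()):
        values[cid] = sum(
            reaction_abundance(abundance, presence, rid)
            for rid in sorted(cls.member_reaction_ids)
            if any(rid in rxns for rxns in presence.values())
        )
    total = total_ba_reaction_abundance(abundance, presence, taxonomy)
    return ReactionAbundanceProfile(abundance.sample_id, values, total)


# ---------------------------------------------------------------------------
# Flux potentials
# ---------------------------------------------------------------------------


def _route_exchange(ba_id: str, route: str) -> str:
    comp = {"fecal": FECAL, "body_fluid": BODY_FLUID}.get(route)
    if comp is None:
        raise ValueError(f"route must be 'fecal' or 'body_fluid', got {route!r}")
    return f"EX_{ba_id}[{comp}]"


def flux_potential(
    community: CommunityModel,
    ba_id: str,
    route: str = "fecal",
    lp: Optional[LinearProblem] = None,
) -> float:
    """Community-level absolute flux potential of one BA (mmol/gDW/day).

    The FVA maximum of the BA's fecal (or body-fluid) exchange with the
    community growth corridor still enforced by the biomass bounds; clipped
    at 0 from below.
    """
    rid = _route_exchange(ba_id, route)
    lp = lp or _get_lp(community)
    if rid not in lp.rxn_index:
        raise KeyError(f"no {route} exchange for bile acid {ba_id!r} (expected {rid!r})")
    res = lp.solve({rid: 1.0}, "max")
    if res.status != "optimal":
        raise RuntimeError(f"flux potential LP for {ba_id!r}: status {res.status}")
    return max(0.0, res.objective_value)


def strain_flux_potential(
    community: CommunityModel,
    strain_id: str,
    ba_id: str,
    lp: Optional[LinearProblem] = None,
) -> float:
    """Flux potential of BA ``ba_id`` attributable to one strain.

    The FVA maximum of the strain's namespaced lumen export transporter
    (positive direction = export into the lumen).  A strain without a
    transporter for the BA contributes 0.
    """
    if strain_id not in community.member_strains:
        raise KeyError(f"strain {strain_id!r} is not a community member")
    rid = f"{strain_id}__T_{ba_id}"
    lp = lp or _get_lp(community)
    if rid not in lp.rxn_index:
        return 0.0
    res = lp.solve({rid: 1.0}, "max")
    if res.status != "optimal":
        raise RuntimeError(f"strain flux potential LP for {rid!r}: status {res.status}")
    return max(0.0, res.objective_value)


def fsp(A: float, v: float) -> float:
    """Fecal secretion potential of one BA in one strain: ``A * v``."""
    if not (0.0 <= A <= 1.0):
        raise ValueError(f"relative abundance must lie in [0, 1], got {A}")
    if not math.isfinite(v):
        raise ValueError(f"flux potential must be finite, got {v}")
    return A * v


def fsp_records(
    community: CommunityModel,
    taxonomy: ReactionClassTaxonomy,
    ba_ids: Optional[Iterable[str]] = None,
    lp: Optional[LinearProblem] = None,
) -> List[FSPRecord]:
    """Per-strain FSP records for the given BAs (default: secondary set)."""
    ids = sorted(ba_ids) if ba_ids is not None else sorted(taxonomy.secondary_ba_ids)
    lp = lp or _get_lp(community)
    records: List[FSPRecord] = []
    for ba in ids:
        for sid in community.member_strains:
            a = community.abundance.abundances[sid]
            rid = f"{sid}__T_{ba}"
            v = 0.0
            if rid in lp.rxn_index:
                v = strain_flux_potential(community, sid, ba, lp)
            records.append(FSPRecord(community.abundance.sample_id, ba, sid, a, v))
    return records


def total_secondary_fsp(
    community: CommunityModel,
    abundance: Optional[AbundanceVector] = None,
    taxonomy: Optional[ReactionClassTaxonomy] = None,
    lp: Optional[LinearProblem] = None,
) -> float:
    """Total fecal secretion potential of secondary BAs for one sample.

    ``sum_j sum_i A_i * v_j(i)`` over the taxonomy's secondary BA ids; the
    per-strain potentials come from :func:`strain_flux_potential`.
    """
    taxonomy = taxonomy or default_taxonomy()
    if not taxonomy.secondary_ba_ids:
        raise ValueError("taxonomy has no secondary BA ids")
    ab = abundance or community.abundance
    lp = lp or _get_lp(community)
    total = 0.0
    for ba in sorted(taxonomy.secondary_ba_ids):
        for sid in community.member_strains:
            rid = f"{sid}__T_{ba}"
            if rid not in lp.rxn_index:
                continue
            v = strain_flux_potential(community, sid, ba, lp)
            total += fsp(ab.abundances[sid], v)
    return total
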