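"""Synthetic cohorts and toy strain models.

Every downstream stage of the pipeline is exercised on data generated here,
so the generator encodes the structural assumptions of the analysis: a
three-group longitudinal cohort (controls and children who developed one or
multiple islet autoantibodies) sampled at 3, 6, 12, 18, 24 and 36 months of
age, a 33-bile-acid panel of primary and secondary species with glycine and
taurine conjugates, and 12 gut strains that carry bile-acid reaction
classes.

Bile-acid concentrations follow a log-normal generative model: a per-feature
baseline, a smooth age trend (primary BAs decline with age, secondary BAs
rise after the first year), a per-subject random intercept, programmed
group x timepoint effects injected additively on the log2 scale, and i.i.d.
residual noise.  Strain compositions are Dirichlet with age-dependent
concentration parameters and group-specific shifts on bile-acid-metabolizing
strains.  All randomness flows from a single mandatory seed; identical
configurations give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .ba_metrics import ReactionClassTaxonomy, default_taxonomy
from .community import DietSpec
from .gem_core import Metabolite, Reaction, StrainModel, validate_model

__all__ = [
    "BA_PANEL",
    "StrainSpec",
    "CohortConfig",
    "GroupEffect",
    "SyntheticCohort",
    "simulate_strain_gem",
    "simulate_cohort",
    "default_fixture_set",
    "default_diet",
    "default_cohort_config",
    "FixtureBundle",
    "write_cohort",
    "read_cohort",
    "write_metaphlan_table",
    "read_metaphlan_strains",
]

GROUPS = ("CTR", "P1Ab", "P2Ab")
DEFAULT_TIMEPOINTS = (3, 6, 12, 18, 24, 36)

# ---------------------------------------------------------------------------
# Bile-acid panel: 33 species measured in stool and serum.
# kind: primary | secondary; conjugation: none | glycine | taurine
# ---------------------------------------------------------------------------
BA_PANEL: List[Tuple[str, str, str]] = [
    ("CA", "primary", "none"),
    ("CDCA", "primary", "none"),
    ("HCA", "primary", "none"),
    ("aMCA", "primary", "none"),
    ("bMCA", "primary", "none"),
    ("wMCA", "primary", "none"),
    ("GCA", "primary", "glycine"),
    ("GCDCA", "primary", "glycine"),
    ("GHCA", "primary", "glycine"),
    ("TCA", "primary", "taurine"),
    ("TCDCA", "primary", "taurine"),
    ("THCA", "primary", "taurine"),
    ("TaMCA", "primary", "taurine"),
    ("TbMCA", "primary", "taurine"),
    ("TwMCA", "primary", "taurine"),
    ("DCA", "secondary", "none"),
    ("LCA", "secondary", "none"),
    ("UDCA", "secondary", "none"),
    ("HDCA", "secondary", "none"),
    ("DHCA", "secondary", "none"),
    ("7-oxo-DCA", "secondary", "none"),
    ("12-oxo-LCA", "secondary", "none"),
    ("3-oxo-LCA", "secondary", "none"),
    ("GDCA", "secondary", "glycine"),
    ("GLCA", "secondary", "glycine"),
    ("GUDCA", "secondary", "glycine"),
    ("GHDCA", "secondary", "glycine"),
    ("GDHCA", "secondary", "glycine"),
    ("TDCA", "secondary", "taurine"),
    ("TLCA", "secondary", "taurine"),
    ("TUDCA", "secondary", "taurine"),
    ("THDCA", "secondary", "taurine"),
    ("TDHCA", "secondary", "taurine"),
]

BA_KIND = {name: kind for name, kind, _ in BA_PANEL}


# ---------------------------------------------------------------------------
# Toy strain models
# ---------------------------------------------------------------------------

# Cytosolic transformation reactions per reaction class.  Metabolite ids use
# lowercase model names; CoA intermediates stay cytosolic (no transporter).
_CLASS_REACTIONS: Dict[str, List[Tuple[str, Dict[str, float]]]] = {
    "bsh_glyco": [
        ("BSHG_GCA", {"gca[c]": -1.0, "ca[c]": 1.0, "gly[c]": 1.0}),
        ("BSHG_GCDCA", {"gcdca[c]": -1.0, "cdca[c]": 1.0, "gly[c]": 1.0}),
    ],
    "bsh_tauro": [
        ("BSHT_TCA", {"tca[c]": -1.0, "ca[c]": 1.0, "tau[c]": 1.0}),
        ("BSHT_TCDCA", {"tcdca[c]": -1.0, "cdca[c]": 1.0, "tau[c]": 1.0}),
    ],
    "bicoal": [
        ("BICOAL_CA", {"ca[c]": -1.0, "cacoa[c]": 1.0}),
        ("BICOAL_CDCA", {"cdca[c]": -1.0, "cdcacoa[c]": 1.0}),
    ],
    "baia": [
        ("BAIA_DCA", {"cacoa[c]": -1.0, "dca[c]": 1.0}),
        ("BAIA_LCA", {"cdcacoa[c]": -1.0, "lca[c]": 1.0}),
    ],
    "hsdh_7alpha": [("HSDH7A_CDCA", {"cdca[c]": -1.0, "oxolca7[c]": 1.0})],
    "hsdh_7beta": [("HSDH7B_UDCA", {"oxolca7[c]": -1.0, "udca[c]": 1.0})],
    "hsdh_3alpha": [("HSDH3A_LCA", {"lca[c]": -1.0, "oxolca3[c]": 1.0})],
    "epim_3beta": [("EPIM3B_ISOLCA", {"oxolca3[c]": -1.0, "isolca[c]": 1.0})],
    "epim_6beta": [("EPIM6B_HDCA", {"cdca[c]": -1.0, "hdca[c]": 1.0})],
}

# CoA thioester intermediates never cross the membrane.
_INTERNAL_ONLY = {"cacoa", "cdcacoa"}

# Conjugation byproducts: transported and exchanged, but not bile acids.
_BYPRODUCTS = {"gly", "tau"}

# A strain carrying only the transport class shuttles the common BAs.
_DEFAULT_SHUTTLE = ("ca", "cdca", "dca", "lca")


@dataclass(frozen=True)
class StrainSpec:
    strain_id: str
    ba_classes: Tuple[str, ...]
    core_chain_length: int = 2


def simulate_strain_gem(spec: StrainSpec) -> StrainModel:
    """Build a toy strain model carrying the requested BA reaction classes.

    The model grows on glucose through a linear core chain into a biomass
    metabolite (consumed standalone by a ``DM_biomass`` demand, and by the
    community biomass reaction once merged), and carries, per class, the
    corresponding cytosolic BA transformations plus reversible membrane
    transporters and exchanges for every BA species it touches.
    Deterministic: equal specs give equal models.
    """
    known = set(_CLASS_REACTIONS) | {"ba_transport"}
    unknown = sorted(set(spec.ba_classes) - known)
    if unknown:
        raise ValueError(f"unknown reaction class ids: {unknown}")
    if spec.core_chain_length < 1:
        raise ValueError("core_chain_length must be >= 1")

    mets: Dict[str, Metabolite] = {}
    rxns: List[Reaction] = []

    def met(mid: str, comp: str, name: str = "") -> str:
        if mid not in mets:
            mets[mid] = Metabolite(mid, comp, name)
        return mid

    # --- glucose -> biomass core chain -------------------------------------
    met("glc[e]", "e", "glucose")
    met("glc[c]", "c", "glucose")
    rxns.append(Reaction("EX_glc[e]", {"glc[e]": -1.0}, -10.0, 1000.0))
    rxns.append(Reaction("GLCt", {"glc[e]": -1.0, "glc[c]": 1.0}, 0.0, 1000.0))
    prev = "glc[c]"
    for k in range(1, spec.core_chain_length):
        nxt = met(f"core{k}[c]", "c")
        rxns.append(Reaction(f"CORE{k}", {prev: -1.0, nxt: 1.0}, 0.0, 1000.0))
        prev = nxt
    met("biomass[c]", "c", "biomass")
    rxns.append(Reaction("BIOMASS", {prev: -1.0, "biomass[c]": 1.0}, 0.0, 1000.0))
    rxns.append(Reaction("DM_biomass", {"biomass[c]": -1.0}, 0.0, 1000.0))

    # --- bile-acid transformations -----------------------------------------
    touched: Set[str] = set()
    for cls in spec.ba_classes:
        for rid, stoich in _CLASS_REACTIONS.get(cls, []):
            for mid in stoich:
                base = mid[: mid.index("[")]
                met(mid, "c", base)
                if base not in _INTERNAL_ONLY and base not in _BYPRODUCTS:
                    touched.add(base)
            rxns.append(Reaction(rid, dict(stoich), 0.0, 1000.0, reaction_class=cls))
    if "ba_transport" in spec.ba_classes and not touched:
        touched |= set(_DEFAULT_SHUTTLE)

    for base in sorted(touched):
        met(f"{base}[c]", "c", base)
        met(f"{base}[e]", "e", base)
        rxns.append(
            Reaction(
                f"T_{base}",
                {f"{base}[c]": -1.0, f"{base}[e]": 1.0},
                -1000.0,
                1000.0,
                reaction_class="ba_transport",
            )
        )
        rxns.append(Reaction(f"EX_{base}[e]", {f"{base}[e]": -1.0}, -10.0, 1000.0))
    for base in sorted(_BYPRODUCTS):
        if f"{base}[c]" in mets:
            met(f"{base}[e]", "e", base)
            rxns.append(
                Reaction(f"T_{base}", {f"{base}[c]": -1.0, f"{base}[e]": 1.0}, -1000.0, 1000.0)
            )
            rxns.append(Reaction(f"EX_{base}[e]", {f"{base}[e]": -1.0}, -10.0, 1000.0))

    model = StrainModel(
        strain_id=spec.strain_id,
        metabolites=list(mets.values()),
        reactions=rxns,
        biomass_reaction_id="BIOMASS",
        compartments={"c", "e"},
    )
    validate_model(model)
    return model


# 12 strains: labels mirror abundant gut genera; class assignments cover all
# ten taxonomy classes, with cross-feeding in the urso route (7-oxo-LCA).
FIXTURE_STRAINS: List[Tuple[str, Tuple[str, ...]]] = [
    ("Clostridium_scindens", ("bicoal", "baia", "ba_transport")),
    ("Clostridium_hylemonae", ("bicoal", "baia", "ba_transport")),
    ("Eggerthella_lenta", ("hsdh_7alpha", "hsdh_3alpha", "epim_3beta", "ba_transport")),
    ("Ruminococcus_gnavus", ("hsdh_7alpha", "hsdh_7beta", "ba_transport")),
    ("Bifidobacterium_breve", ("bsh_glyco", "ba_transport")),
    ("Bifidobacterium_longum", ("bsh_glyco", "bsh_tauro", "ba_transport")),
    ("Lactobacillus_rhamnosus", ("bsh_tauro", "ba_transport")),
    ("Alistipes_putredinis", ("hsdh_7alpha", "ba_transport")),
    ("Roseburia_hominis", ("epim_6beta", "ba_transport")),
    ("Clostridium_bartlettii", ("epim_6beta", "hsdh_3alpha", "ba_transport")),
    ("Ruminococcus_torques", ("bsh_glyco", "ba_transport")),
    ("Bacteroides_uniformis", ("ba_transport",)),
]

FIXTURE_STRAIN_IDS = [sid for sid, _ in FIXTURE_STRAINS]

# Strains whose pathways produce secondary BAs (DCA/LCA/UDCA/HDCA).
SECONDARY_BA_PRODUCERS = (
    "Clostridium_scindens",
    "Clostridium_hylemonae",
    "Ruminococcus_gnavus",
    "Roseburia_hominis",
    "Clostridium_bartlettii",
)


def default_diet() -> DietSpec:
    """Average toy diet: limited glucose plus host-delivered primary BAs.

    Glucose is capped so the community growth optimum (0.8/day) falls inside
    the default growth corridor [0.4, 1.0]; primary BAs and their conjugates
    arrive at 5 mmol/gDW/day each, emulating host bile flow into the gut.
    """
    bounds: Dict[str, Tuple[float, float]] = {"EX_glc[u]": (-0.8, 1000.0)}
    for ba in ("ca", "cdca", "gca", "gcdca", "tca", "tcdca"):
        bounds[f"EX_{ba}[u]"] = (-5.0, 1000.0)
    return DietSpec(bounds)


# Lumen BA species given fecal/body-fluid routes in community models.
COMMUNITY_BA_METABOLITES = (
    "ca", "cdca", "gca", "gcdca", "tca", "tcdca",
    "dca", "lca", "udca", "hdca", "oxolca7", "oxolca3", "isolca",
)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupEffect:
    """A programmed group x timepoint shift, in within-group SD units.

    ``features`` is either an explicit tuple of feature ids or a selector:
    ``"secondary_bas"``, ``"primary_bas"`` (bile-acid tables) or
    ``"secondary_ba_producers"`` (abundance table).  ``size_sd`` is signed;
    on bile-acid tables one within-group SD is
    ``sqrt(subject_intercept_sd^2 + residual_sd^2)`` on the log2 scale, on
    the abundance table it is the nominal log2-abundance SD of the config.
    """

    features: Tuple[str, ...] | str
    group: str
    timepoints: Tuple[int, ...]
    size_sd: float
    table: str = "stool"  # stool | serum | abundance


@dataclass
class CohortConfig:
    seed: int
    n_ctr: int = 38
    n_p1ab: int = 23
    n_p2ab: int = 13
    timepoints: Tuple[int, ...] = DEFAULT_TIMEPOINTS
    n_ba: int = 33
    n_strains: int = 12
    # age-trend parameters (log2 units over the follow-up window)
    primary_decline_log2: float = 1.5
    secondary_rise_log2: float = 2.0
    rise_midpoint_month: float = 12.0
    rise_scale_months: float = 3.0
    # variance components (log2 scale)
    subject_intercept_sd: float = 0.8
    residual_sd: float = 1.0
    abundance_log2_sd: float = 1.0
    abundance_subject_sd: float = 0.4
    dirichlet_concentration: float = 50.0
    missing_rate: float = 0.3
    group_effects: Tuple[GroupEffect, ...] = ()

    def validate(self) -> None:
        if self.n_ctr <= 0 or self.n_p1ab <= 0 or self.n_p2ab <= 0:
            raise ValueError("subject counts must be positive")
        if list(self.timepoints) != sorted(self.timepoints):
            raise ValueError("timepoints must be sorted ascending")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_ba < 1 or self.n_strains < 1:
            raise ValueError("n_ba and n_strains must be >= 1")
        if self.subject_intercept_sd < 0 or self.residual_sd <= 0:
            raise ValueError("variance components must be positive")
        for eff in self.group_effects:
            if eff.group not in GROUPS:
                raise ValueError(f"group effect references unknown group {eff.group!r}")
            if not all(t in self.timepoints for t in eff.timepoints):
                raise ValueError(f"group effect timepoints {eff.timepoints} not scheduled")
            if not math.isfinite(eff.size_sd):
                raise ValueError("effect size must be finite")

    @property
    def within_group_sd(self) -> float:
        return math.hypot(self.subject_intercept_sd, self.residual_sd)


def default_cohort_config(seed: int) -> CohortConfig:
    return CohortConfig(seed=seed)


@dataclass
class SyntheticCohort:
    abundance: pd.DataFrame  # samples x strains, rows on the simplex
    stool_ba: pd.DataFrame  # samples x BAs, ng/mL
    serum_ba: pd.DataFrame  # samples x BAs, ng/mL
    metadata: pd.DataFrame  # one row per sample
    config: CohortConfig


def _ba_features(n_ba: int) -> List[Tuple[str, str]]:
    feats = [(name, kind) for name, kind, _ in BA_PANEL][:n_ba]
    for i in range(len(feats), n_ba):
        feats.append((f"ba_{i + 1:03d}", "primary" if i % 2 == 0 else "secondary"))
    return feats


def _strain_names(n: int) -> List[str]:
    names = FIXTURE_STRAIN_IDS[:n]
    for i in range(len(names), n):
        names.append(f"strain_{i + 1:02d}")
    return names


def _resolve_features(eff: GroupEffect, feats: Sequence[Tuple[str, str]], strains: Sequence[str]) -> List[str]:
    if isinstance(eff.features, str):
        sel = eff.features
        if sel == "secondary_bas":
            return [f for f, kind in feats if kind == "secondary"]
        if sel == "primary_bas":
            return [f for f, kind in feats if kind == "primary"]
        if sel == "secondary_ba_producers":
            return [s for s in strains if s in SECONDARY_BA_PRODUCERS]
        raise ValueError(f"unknown feature selector {eff.features!r}")
    return list(eff.features)


def _age_trend(kind: str, age: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    if kind == "primary":
        span = math.log(36.0) - math.log(3.0)
        return -cfg.primary_decline_log2 * (np.log(age) - math.log(3.0)) / span
    rise = 1.0 / (1.0 + np.exp(-(age - cfg.rise_midpoint_month) / cfg.rise_scale_months))
    rise0 = 1.0 / (1.0 + math.exp(-(3.0 - cfg.rise_midpoint_month) / cfg.rise_scale_months))
    return cfg.secondary_rise_log2 * (rise - rise0)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (abundances, stool/serum BAs, metadata)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    subjects: List[Tuple[str, str]] = []
    for group, n in (("CTR", config.n_ctr), ("P1Ab", config.n_p1ab), ("P2Ab", config.n_p2ab)):
        subjects += [(f"{group}_{i + 1:02d}", group) for i in range(n)]

    meta_rows = []
    for sub, group in subjects:
        gender = "F" if rng.random() < 0.5 else "M"
        bf_total = float(np.clip(rng.normal(9.0, 3.0), 2.0, 18.0))
        bf_excl = float(min(np.clip(rng.normal(4.0, 1.5), 0.5, 6.0), bf_total))
        solid = float(np.clip(rng.normal(5.0, 1.0), 3.0, 8.0))
        serocon = int(rng.integers(6, 25)) if group in ("P1Ab", "P2Ab") else np.nan
        meta_rows.append((sub, group, gender, round(bf_total, 1), round(bf_excl, 1), round(solid, 1), serocon))

    # sampling schedule with completely-at-random missingness
    sample_rows = []
    for (sub, group, gender, bf_total, bf_excl, solid, serocon) in meta_rows:
        for t in config.timepoints:
            if rng.random() < config.missing_rate:
                continue
            sample_rows.append(
                {
                    "sample_id": f"{sub}_m{t:02d}",
                    "subject_id": sub,
                    "group": group,
                    "age_months": t,
                    "gender": gender,
                    "bf_total_months": bf_total,
                    "bf_exclusive_months": bf_excl,
                    "solid_food_intro_months": solid,
                    "seroconversion_age_months": serocon,
                }
            )
    metadata = pd.DataFrame(sample_rows).set_index("sample_id")
    if metadata.empty:
        raise ValueError("missingness removed every scheduled sample")
    ages = metadata["age_months"].to_numpy(dtype=float)
    subj_idx = {sub: i for i, (sub, _) in enumerate(subjects)}
    row_subj = np.array([subj_idx[s] for s in metadata["subject_id"]])

    feats = _ba_features(config.n_ba)
    feat_ids = [f for f, _ in feats]
    within_sd = config.within_group_sd

    def ba_table() -> pd.DataFrame:
        baseline = rng.normal(6.0, 1.5, size=len(feats))
        intercepts = rng.normal(0.0, config.subject_intercept_sd, size=(len(subjects), len(feats)))
        noise = rng.normal(0.0, config.residual_sd, size=(len(metadata), len(feats)))
        log2 = np.empty((len(metadata), len(feats)))
        for j, (fid, kind) in enumerate(feats):
            log2[:, j] = baseline[j] + _age_trend(kind, ages, config) + intercepts[row_subj, j] + noise[:, j]
        return pd.DataFrame(log2, index=metadata.index, columns=feat_ids)

    stool_log2 = ba_table()
    serum_log2 = ba_table() - 1.0  # systemic levels run lower than stool

    strains = _strain_names(config.n_strains)
    base_w = {
        "Bifidobacterium_breve": 3.0,
        "Bifidobacterium_longum": 3.0,
        "Bacteroides_uniformis": 2.0,
        "Ruminococcus_gnavus": 1.0,
        "Lactobacillus_rhamnosus": 1.0,
    }
    age_coef = {}
    for s in strains:
        if s.startswith(("Clostridium", "Eggerthella", "Alistipes", "Roseburia")) or s == "Ruminococcus_torques":
            age_coef[s] = 1.2
        elif s.startswith("Bifidobacterium"):
            age_coef[s] = -0.8
        else:
            age_coef[s] = 0.0
    logw0 = np.array([math.log(base_w.get(s, 0.5)) for s in strains])
    gvec = np.array([age_coef[s] for s in strains])
    subj_strain = rng.normal(0.0, config.abundance_subject_sd, size=(len(subjects), len(strains)))

    logw = (
        logw0[None, :]
        + gvec[None, :] * ((ages[:, None] - 3.0) / 33.0)
        + subj_strain[row_subj, :]
    )

    # programmed group effects
    ln2 = math.log(2.0)
    for eff in config.group_effects:
        mask = (metadata["group"] == eff.group).to_numpy() & np.isin(
            metadata["age_months"].to_numpy(), list(eff.timepoints)
        )
        if eff.table == "abundance":
            cols = [strains.index(f) for f in _resolve_features(eff, feats, strains)]
            logw[np.ix_(mask, cols)] += eff.size_sd * config.abundance_log2_sd * ln2
        elif eff.table in ("stool", "serum"):
            target = stool_log2 if eff.table == "stool" else serum_log2
            cols = [feat_ids.index(f) for f in _resolve_features(eff, feats, strains)]
            target.iloc[mask, cols] += eff.size_sd * within_sd
        else:
            raise ValueError(f"unknown effect table {eff.table!r}")

    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    alpha = config.dirichlet_concentration * w / w.sum(axis=1, keepdims=True)
    comp = np.vstack([rng.dirichlet(a) for a in alpha])
    abundance = pd.DataFrame(comp, index=metadata.index, columns=strains)

    stool = pd.DataFrame(
        np.exp2(stool_log2.to_numpy()), index=metadata.index, columns=feat_ids
    )
    serum = pd.DataFrame(
        np.exp2(serum_log2.to_numpy()), index=metadata.index, columns=feat_ids
    )
    return SyntheticCohort(abundance, stool, serum, metadata.reset_index(), config)


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    strain_models: List[StrainModel]
    taxonomy: ReactionClassTaxonomy
    diet: DietSpec
    cohort_config: CohortConfig


def default_fixture_set(seed: int = 20221003) -> FixtureBundle:
    """Deterministic bundle: 12 strain models, taxonomy, toy diet, cohort config."""
    models = [simulate_strain_gem(StrainSpec(sid, classes)) for sid, classes in FIXTURE_STRAINS]
    return FixtureBundle(models, default_taxonomy(), default_diet(), default_cohort_config(seed))


# ---------------------------------------------------------------------------
# Table I/O (CSV + MetaPhlAn-style TSV dialect)
# ---------------------------------------------------------------------------

_GENUS_LINEAGE = {
    "Clostridium": ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae"),
    "Eggerthella": ("Actinobacteria", "Coriobacteriia", "Eggerthellales", "Eggerthellaceae"),
    "Ruminococcus": ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    "Bifidobacterium": ("Actinobacteria", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae"),
    "Lactobacillus": ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    "Alistipes": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae"),
    "Roseburia": ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Bacteroides": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
}


def _clade_string(strain: str) -> str:
    genus = strain.split("_")[0]
    phylum, cls, order, family = _GENUS_LINEAGE.get(
        genus, ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae")
    )
    return (
        f"k__Bacteria|p__{phylum}|c__{cls}|o__{order}|f__{family}"
        f"|g__{genus}|s__{strain}|t__{strain}_t1"
    )


def write_metaphlan_table(abundance: pd.DataFrame, path) -> None:
    """Strain-level MetaPhlAn-style TSV: clade rows, sample columns, percent values."""
    out = abundance.T * 100.0
    out.index = [_clade_string(s) for s in abundance.columns]
    out.index.name = "#clade_name"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_metaphlan_strains(path) -> pd.DataFrame:
    """Parse strain-level (``t__``) rows back to a samples x strains fraction table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    strain_rows = [i for i in df.index if "|t__" in i]
    df = df.loc[strain_rows]
    names = []
    for clade in strain_rows:
        s_part = [p for p in clade.split("|") if p.startswith("s__")][-1]
        names.append(s_part[3:])
    df.index = names
    return (df.T / 100.0).rename_axis("sample_id")


def write_cohort(cohort: SyntheticCohort, outdir) -> Dict[str, Path]:
    """Write all cohort tables; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "abundance": outdir / "abundance.csv",
        "abundance_metaphlan": outdir / "abundance_metaphlan.tsv",
        "stool_ba": outdir / "stool_ba.csv",
        "serum_ba": outdir / "serum_ba.csv",
        "metadata": outdir / "metadata.csv",
    }
    cohort.abundance.rename_axis("sample_id").to_csv(files["abundance"], float_format="%.10g")
    write_metaphlan_table(cohort.abundance, files["abundance_metaphlan"])
    for key in ("stool_ba", "serum_ba"):
        table = getattr(cohort, key)
        with open(files[key], "w", encoding="utf-8") as fh:
            fh.write("# concentrations in ng/mL\n")
            table.rename_axis("sample_id").to_csv(fh, float_format="%.10g")
    cohort.metadata.to_csv(files["metadata"], index=False, float_format="%.10g")
    return files


def read_cohort(datadir) -> SyntheticCohort:
    """Load cohort tables written by :func:`write_cohort`."""
    datadir = Path(datadir)
    abundance = pd.read_csv(datadir / "abundance.csv", index_col=0)
    stool = pd.read_csv(datadir / "stool_ba.csv", index_col=0, comment="#")
    serum = pd.read_csv(datadir / "serum_ba.csv", index_col=0, comment="#")
    metadata = pd.read_csv(datadir / "metadata.csv")
    return SyntheticCohort(abundance, stool, serum, metadata, config=None)
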