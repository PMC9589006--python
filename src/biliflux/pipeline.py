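"""End-to-end analysis pipeline.

Stages: simulate (or load) cohort tables -> validate -> per-sample community
models and BA metrics -> longitudinal statistics -> tidy CSV outputs plus a
JSON run manifest.  Each stage reads only files written by earlier stages,
so stages can be run individually (``biliflux simulate|validate|metrics|stats``)
or together (``biliflux run``).  Reruns with the same config and seed
produce byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ba_metrics import (
    ReactionClassTaxonomy,
    class_abundance_profile,
    default_taxonomy,
    presence_from_models,
)
from .community import (
    COMMUNITY_BIOMASS_ID,
    AbundanceVector,
    CommunityModel,
    CommunityOptions,
    DietSpec,
    build_community,
    renormalize_abundance,
)
from .gem_core import LinearProblem, StrainModel, _get_lp, read_model
from .stats import (
    DEFAULT_CONTRASTS,
    FeatureTable,
    ancova_differential,
    autoscale,
    bh_fdr,
    explained_variance,
    lmm_association,
    loess_fit,
    log2_transform,
    spearman_fdr,
    tukey_hsd,
)
from .synthetic import (
    COMMUNITY_BA_METABOLITES,
    CohortConfig,
    GroupEffect,
    SyntheticCohort,
    default_diet,
    default_fixture_set,
    read_cohort,
    simulate_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "StatsOptions",
    "PipelineError",
    "ValidationReport",
    "run_pipeline",
    "validate_inputs",
    "CommunityMetricsEngine",
    "secondary_fsp_recovery_study",
]

FLOAT_FMT = "%.12g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, exit_code: int = 3):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class StatsOptions:
    fdr_threshold: float = 0.05
    contrasts: Tuple[Tuple[str, str], ...] = DEFAULT_CONTRASTS
    timepoints: Tuple[int, ...] = (6, 12, 18, 24, 36)
    covariates: Tuple[str, ...] = (
        "bf_total_months",
        "bf_exclusive_months",
        "solid_food_intro_months",
    )
    ev_factors: Tuple[str, ...] = (
        "age_months",
        "group",
        "gender",
        "bf_total_months",
        "bf_exclusive_months",
        "solid_food_intro_months",
    )
    loess_span: float = 0.75
    loess_degree: int = 2


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 20221003
    simulate: Optional[CohortConfig] = None
    input_paths: Optional[Dict[str, str]] = None
    community: CommunityOptions = field(
        default_factory=lambda: CommunityOptions(ba_metabolites=COMMUNITY_BA_METABOLITES)
    )
    stats: StatsOptions = field(default_factory=StatsOptions)
    model_dir: Optional[Path] = None  # directory of strain-model JSON files
    taxonomy_path: Optional[Path] = None
    log_level: str = "info"

    def validate(self) -> None:
        if (self.simulate is None) == (self.input_paths is None):
            raise ValueError("exactly one of 'simulate' and 'input_paths' must be set")

    @classmethod
    def from_file(cls, path, outdir=None, seed=None) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text)
        return cls.from_dict(raw, outdir=outdir, seed=seed)

    @classmethod
    def from_dict(cls, raw: dict, outdir=None, seed=None) -> "PipelineConfig":
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            sim = dict(kwargs["simulate"])
            effects = tuple(
                GroupEffect(
                    tuple(e["features"]) if isinstance(e["features"], list) else e["features"],
                    e["group"],
                    tuple(e["timepoints"]),
                    float(e["size_sd"]),
                    e.get("table", "stool"),
                )
                for e in sim.pop("group_effects", [])
            )
            sim.setdefault("seed", kwargs.get("seed", 20221003))
            if "timepoints" in sim:
                sim["timepoints"] = tuple(sim["timepoints"])
            kwargs["simulate"] = CohortConfig(group_effects=effects, **sim)
        if "community" in kwargs and kwargs["community"] is not None:
            comm = dict(kwargs["community"])
            if "biomass_bounds" in comm:
                comm["biomass_bounds"] = tuple(comm["biomass_bounds"])
            comm.setdefault("ba_metabolites", COMMUNITY_BA_METABOLITES)
            comm["ba_metabolites"] = tuple(comm["ba_metabolites"])
            kwargs["community"] = CommunityOptions(**comm)
        if "stats" in kwargs and kwargs["stats"] is not None:
            st = dict(kwargs["stats"])
            for key in ("timepoints", "covariates", "ev_factors"):
                if key in st:
                    st[key] = tuple(st[key])
            if "contrasts" in st:
                st["contrasts"] = tuple(tuple(c) for c in st["contrasts"])
            kwargs["stats"] = StatsOptions(**st)
        if outdir is not None:
            kwargs["outdir"] = outdir
        if seed is not None:
            kwargs["seed"] = seed
        kwargs["outdir"] = Path(kwargs["outdir"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            return str(o)

        canon = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationEntry:
    check: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    entries: List[ValidationEntry]

    @property
    def all_passed(self) -> bool:
        return all(e.passed for e in self.entries)

    def to_dict(self) -> dict:
        return {
            "all_passed": self.all_passed,
            "entries": [dataclasses.asdict(e) for e in self.entries],
        }


def validate_inputs(cohort: SyntheticCohort) -> ValidationReport:
    """Concordance and sanity checks on the three cohort tables.

    Never raises: every problem becomes a report entry.
    """
    entries: List[ValidationEntry] = []
    meta_ids = set(cohort.metadata["sample_id"])
    for name, table in (("abundance", cohort.abundance), ("stool_ba", cohort.stool_ba),
                        ("serum_ba", cohort.serum_ba)):
        missing = sorted(meta_ids - set(table.index))
        extra = sorted(set(table.index) - meta_ids)
        ok = not missing and not extra
        detail = ""
        if not ok:
            detail = f"missing from {name}: {missing[:5]}; not in metadata: {extra[:5]}"
        entries.append(ValidationEntry(f"sample ids concordant ({name})", ok, detail))
    sums = cohort.abundance.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > 1e-6]
    entries.append(
        ValidationEntry(
            "abundance rows on the simplex",
            bad.empty,
            "" if bad.empty else f"row sums off 1: {dict(bad.head(5).round(4))}",
        )
    )
    for name, table in (("stool_ba", cohort.stool_ba), ("serum_ba", cohort.serum_ba)):
        neg = (table.to_numpy(dtype=float) < 0).any()
        entries.append(
            ValidationEntry(f"nonnegative concentrations ({name})", not neg,
                            "" if not neg else "negative concentrations found")
        )
    # schedule completeness: samples per subject never exceed scheduled visits
    counts = cohort.metadata.groupby("subject_id")["age_months"].nunique()
    dup = cohort.metadata.duplicated(subset=["subject_id", "age_months"]).any()
    entries.append(
        ValidationEntry("one sample per subject-timepoint", not dup,
                        "" if not dup else "duplicated subject x timepoint rows")
    )
    return ValidationReport(entries)


# ---------------------------------------------------------------------------
# Community metrics engine
# ---------------------------------------------------------------------------


class CommunityMetricsEngine:
    """Per-sample community modeling and BA metric extraction.

    Holds the strain models, diet, taxonomy and community options; for every
    sample it assembles the personalized community (same structure, sample-
    specific community-biomass weights) and computes reaction abundances,
    per-strain secondary-BA flux potentials, FSPs and their totals.

    Strain-BA pairs where the strain has no cytosolic reaction producing the
    BA are skipped without an LP call: a lone reversible transporter cannot
    sustain positive net export at steady state, so their flux potential is
    structurally zero.
    """

    def __init__(
        self,
        models: Sequence[StrainModel],
        diet: DietSpec,
        taxonomy: ReactionClassTaxonomy,
        options: Optional[CommunityOptions] = None,
    ):
        self.models = list(models)
        self.diet = diet
        self.taxonomy = taxonomy
        self.options = options or CommunityOptions(ba_metabolites=COMMUNITY_BA_METABOLITES)
        self.presence = presence_from_models(self.models)
        self.strain_ids = [m.strain_id for m in self.models]
        self._producers = self._producer_pairs()
        self._ba_with_route = set(self.options.ba_metabolites)
        self._template: Optional[Tuple[CommunityModel, LinearProblem, Dict[str, int]]] = None

    def _get_template(self):
        """Shared community LP; only the community-biomass column varies by
        sample, so its sparse entries are patched in place per sample."""
        if self._template is None:
            uniform = AbundanceVector(
                "template", {sid: 1.0 / len(self.strain_ids) for sid in self.strain_ids}
            )
            community = build_community(self.models, uniform, self.diet, self.options)
            lp = LinearProblem(community)
            lp.A_eq = lp.A_eq.tocsc()
            j = lp.rxn_index[COMMUNITY_BIOMASS_ID]
            start, end = lp.A_eq.indptr[j], lp.A_eq.indptr[j + 1]
            met_by_row = {i: m.id for i, m in enumerate(community.metabolites)}
            pos = {}
            for k, row in enumerate(lp.A_eq.indices[start:end]):
                sid = met_by_row[int(row)].split("__")[0]
                pos[sid] = int(start + k)
            self._template = (community, lp, pos)
        return self._template

    def _fast_lp_for(self, ab: AbundanceVector) -> Optional[LinearProblem]:
        """Template LP patched to this sample's abundances, or None if the
        sample drops a strain below the inclusion threshold."""
        if set(ab.abundances) != set(self.strain_ids):
            return None
        _, lp, pos = self._get_template()
        for sid, p in pos.items():
            lp.A_eq.data[p] = -ab.abundances[sid]
        return lp

    def _producer_pairs(self) -> Dict[str, List[str]]:
        """ba_id -> strains with a cytosolic reaction producing it."""
        out: Dict[str, List[str]] = {}
        for ba in sorted(self.taxonomy.secondary_ba_ids):
            met = f"{ba}[c]"
            producers = []
            for m in self.models:
                for r in m.reactions:
                    if r.id.startswith("T_") or r.is_exchange:
                        continue
                    if r.stoichiometry.get(met, 0.0) > 0:
                        producers.append(m.strain_id)
                        break
            out[ba] = producers
        return out

    def community_for(self, abundance: AbundanceVector) -> CommunityModel:
        return build_community(self.models, abundance, self.diet, self.options)

    def sample_metrics(self, abundance: AbundanceVector) -> dict:
        ab = renormalize_abundance(abundance, self.options.abundance_threshold)
        lp = self._fast_lp_for(ab)
        if lp is None:
            community = self.community_for(abundance)
            lp = _get_lp(community)
            ab = community.abundance
            members = community.member_strains
        else:
            members = self.strain_ids
        profile = class_abundance_profile(ab, self.presence, self.taxonomy)
        records = []
        total_fsp = 0.0
        for ba in sorted(self.taxonomy.secondary_ba_ids):
            for sid in self._producers[ba]:
                if sid not in members:
                    continue
                v = max(0.0, lp.solve({f"{sid}__T_{ba}": 1.0}, "max").objective_value)
                a = ab.abundances[sid]
                records.append((ab.sample_id, ba, sid, a, v, a * v))
                total_fsp += a * v
        potentials = {}
        for ba in sorted(self.taxonomy.secondary_ba_ids):
            if ba in self._ba_with_route:
                res = lp.solve({f"EX_{ba}[{'fe'}]": 1.0}, "max")
                potentials[ba] = max(0.0, res.objective_value)
            else:
                potentials[ba] = 0.0
        return {
            "sample_id": ab.sample_id,
            "class_abundance": profile.values,
            "total_ba_reaction_abundance": profile.total_ba_reaction_abundance,
            "fsp_records": records,
            "flux_potentials": potentials,
            "total_secondary_fsp": total_fsp,
        }

    def total_secondary_fsp_table(self, abundance_table: pd.DataFrame) -> pd.Series:
        """Total secondary FSP per sample (rows of a samples x strains table)."""
        pairs = [
            (ba, sid)
            for ba in sorted(self.taxonomy.secondary_ba_ids)
            for sid in self._producers[ba]
        ]
        out = {}
        for sample_id, row in abundance_table.iterrows():
            ab = renormalize_abundance(
                AbundanceVector(str(sample_id), row.to_dict()), self.options.abundance_threshold
            )
            lp = self._fast_lp_for(ab)
            if lp is None:
                community = self.community_for(ab)
                lp = _get_lp(community)
            total = 0.0
            for ba, sid in pairs:
                if sid not in ab.abundances:
                    continue
                v = max(0.0, lp.solve({f"{sid}__T_{ba}": 1.0}, "max").objective_value)
                total += ab.abundances[sid] * v
            out[str(sample_id)] = total
        return pd.Series(out, name="total_secondary_fsp")


def _load_models_taxonomy(config: PipelineConfig):
    if config.model_dir is not None:
        paths = sorted(Path(config.model_dir).glob("*.json"))
        models = [read_model(p) for p in paths]
    else:
        models = default_fixture_set(config.seed).strain_models
    taxonomy = (
        ReactionClassTaxonomy.from_json(config.taxonomy_path)
        if config.taxonomy_path
        else default_taxonomy()
    )
    return models, taxonomy


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_data(config: PipelineConfig) -> Path:
    datadir = Path(config.outdir) / "data"
    if config.simulate is not None:
        cohort_cfg = replace(config.simulate, seed=config.seed)
        cohort = simulate_cohort(cohort_cfg)
    else:
        cohort = read_cohort(Path(config.input_paths["datadir"]))
    write_cohort(cohort, datadir)
    return datadir


def stage_validate(config: PipelineConfig) -> ValidationReport:
    datadir = Path(config.outdir) / "data"
    cohort = read_cohort(datadir)
    report = validate_inputs(cohort)
    out = Path(config.outdir) / "validation.json"
    out.write_text(json.dumps(report.to_dict(), indent=2) + "\n", encoding="utf-8")
    if not report.all_passed:
        raise PipelineError("validate", "input validation failed", exit_code=2)
    return report


def stage_metrics(config: PipelineConfig) -> Path:
    datadir = Path(config.outdir) / "data"
    metricsdir = Path(config.outdir) / "metrics"
    metricsdir.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(datadir)
    models, taxonomy = _load_models_taxonomy(config)
    engine = CommunityMetricsEngine(models, default_diet(), taxonomy, config.community)

    class_rows, fsp_rows, fp_rows, summary_rows = [], [], [], []
    for sample_id in cohort.abundance.index:
        ab = AbundanceVector(str(sample_id), cohort.abundance.loc[sample_id].to_dict())
        m = engine.sample_metrics(ab)
        for cid, val in m["class_abundance"].items():
            class_rows.append((sample_id, cid, val))
        fsp_rows.extend(m["fsp_records"])
        for ba, v in m["flux_potentials"].items():
            fp_rows.append((sample_id, ba, v))
        summary_rows.append(
            (sample_id, m["total_ba_reaction_abundance"], m["total_secondary_fsp"])
        )

    pd.DataFrame(class_rows, columns=["sample_id", "class_id", "value"]).to_csv(
        metricsdir / "reaction_abundance.csv", index=False, float_format=FLOAT_FMT
    )
    pd.DataFrame(
        fsp_rows, columns=["sample_id", "ba_id", "strain_id", "A", "v", "fsp"]
    ).to_csv(metricsdir / "fsp.csv", index=False, float_format=FLOAT_FMT)
    pd.DataFrame(fp_rows, columns=["sample_id", "ba_id", "flux_potential"]).to_csv(
        metricsdir / "flux_potential.csv", index=False, float_format=FLOAT_FMT
    )
    pd.DataFrame(
        summary_rows,
        columns=["sample_id", "total_ba_reaction_abundance", "total_secondary_fsp"],
    ).to_csv(metricsdir / "sample_summary.csv", index=False, float_format=FLOAT_FMT)
    return metricsdir


def _log2_table(df: pd.DataFrame) -> FeatureTable:
    return log2_transform(FeatureTable(df, "raw"))


def stage_stats(config: PipelineConfig) -> Path:
    datadir = Path(config.outdir) / "data"
    metricsdir = Path(config.outdir) / "metrics"
    statsdir = Path(config.outdir) / "stats"
    statsdir.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(datadir)
    meta = cohort.metadata.set_index("sample_id")
    summary = pd.read_csv(metricsdir / "sample_summary.csv", index_col=0)
    opts = config.stats

    tables = {
        "stool_ba": _log2_table(cohort.stool_ba),
        "serum_ba": _log2_table(cohort.serum_ba),
        "microbiome": _log2_table(cohort.abundance),
    }

    # explained variance per factor
    ev_rows = []
    for name, table in tables.items():
        for ev in explained_variance(autoscale(table), meta, opts.ev_factors):
            ev_rows.append(
                (name, ev.factor, ev.median_marginal_r2, ev.is_confounder)
            )
    pd.DataFrame(
        ev_rows, columns=["table", "factor", "median_marginal_r2", "ev_above_10pct"]
    ).to_csv(statsdir / "explained_variance.csv", index=False, float_format=FLOAT_FMT)

    # per-timepoint ANCOVA differential analysis
    for name, table in tables.items():
        rows = []
        for t in opts.timepoints:
            if not (meta["age_months"] == t).any():
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = ancova_differential(
                        table, meta, t, covariates=opts.covariates, contrasts=opts.contrasts
                    )
            except ValueError as e:
                logger.warning("ANCOVA skipped for %s at t=%s: %s", name, t, e)
                continue
            for r in res:
                rows.append(
                    (r.feature, r.timepoint, f"{r.contrast[0]}_vs_{r.contrast[1]}",
                     r.log2_fc, r.F_stat, r.p, r.q)
                )
        pd.DataFrame(
            rows, columns=["feature", "timepoint", "contrast", "log2_fc", "F", "p", "q"]
        ).to_csv(statsdir / f"differential_{name}.csv", index=False, float_format=FLOAT_FMT)

    # Tukey HSD on the model-derived totals
    tk_rows = []
    merged = summary.join(meta, how="inner")
    for metric in ("total_ba_reaction_abundance", "total_secondary_fsp"):
        for t in opts.timepoints:
            sub = merged[merged["age_months"] == t]
            if sub.empty or sub["group"].value_counts().min() < 2 or sub["group"].nunique() < 2:
                continue
            try:
                res = tukey_hsd(sub[metric].to_numpy(), sub["group"].to_numpy())
            except ValueError as e:
                logger.warning("Tukey skipped for %s at t=%s: %s", metric, t, e)
                continue
            for c in res.comparisons:
                tk_rows.append(
                    (metric, t, c.group_a, c.group_b, c.mean_diff, c.q_stat, c.p_adj,
                     res.F_stat, res.p_anova)
                )
    pd.DataFrame(
        tk_rows,
        columns=["metric", "timepoint", "group_a", "group_b", "mean_diff", "q_stat",
                 "p_adj", "anova_F", "anova_p"],
    ).to_csv(statsdir / "tukey_model_outputs.csv", index=False, float_format=FLOAT_FMT)

    # mixed-model associations on stool BAs (age, gender, case status)
    lmm_rows = []
    stool = tables["stool_ba"]
    fixed = meta.loc[stool.data.index, ["age_months", "gender", "group"]]
    subjects = meta.loc[stool.data.index, "subject_id"]
    for feat in stool.data.columns:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lmm_association(stool.data[feat], fixed, subjects)
        for term in res.params.index:
            lmm_rows.append(
                (feat, term, res.params[term], res.se[term], res.pvalues[term],
                 res.variance_ratio, res.method)
            )
    pd.DataFrame(
        lmm_rows,
        columns=["feature", "term", "estimate", "se", "p", "variance_ratio", "method"],
    ).to_csv(statsdir / "lmm_stool.csv", index=False, float_format=FLOAT_FMT)

    # Spearman cross-correlation: stool BAs x strain abundances, per timepoint
    corr_rows = []
    for t in opts.timepoints:
        sel = meta["age_months"] == t
        ids = meta.index[sel]
        if len(ids) < 5:
            continue
        res = spearman_fdr(
            tables["stool_ba"].data.loc[ids], tables["microbiome"].data.loc[ids]
        )
        for ba in res.rho.index:
            for strain in res.rho.columns:
                corr_rows.append(
                    (t, ba, strain, res.rho.loc[ba, strain], res.p.loc[ba, strain],
                     res.q.loc[ba, strain])
                )
    pd.DataFrame(
        corr_rows, columns=["timepoint", "ba_id", "strain_id", "rho", "p", "q"]
    ).to_csv(statsdir / "correlations.csv", index=False, float_format=FLOAT_FMT)

    # loess age trends on stool BAs
    lo_rows = []
    ages = meta.loc[stool.data.index, "age_months"].to_numpy(dtype=float)
    for feat in stool.data.columns:
        fit = loess_fit(
            ages, stool.data[feat].to_numpy(), span=opts.loess_span,
            degree=opts.loess_degree, n_grid=25,
        )
        for xg, yg, lo, hi in zip(fit.x, fit.fitted, fit.lower, fit.upper):
            lo_rows.append((feat, xg, yg, lo, hi))
    pd.DataFrame(
        lo_rows, columns=["feature", "age_months", "fitted_log2", "lower95", "upper95"]
    ).to_csv(statsdir / "loess_stool.csv", index=False, float_format=FLOAT_FMT)
    return statsdir


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "pipeline_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
    }
    stages = [
        ("data", stage_data),
        ("validate", stage_validate),
        ("community_metrics", stage_metrics),
        ("stats", stage_stats),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            fn(config)
        except PipelineError:
            manifest["stages"].append({"stage": name, "status": "failed"})
            _write_manifest(outdir, manifest)
            raise
        except Exception as e:
            manifest["stages"].append({"stage": name, "status": "failed", "error": str(e)})
            _write_manifest(outdir, manifest)
            raise PipelineError(name, str(e)) from e
        manifest["stages"].append(
            {"stage": name, "status": "complete", "seconds": round(time.perf_counter() - t0, 3)}
        )
        logger.info("stage %s complete (%.2fs)", name, time.perf_counter() - t0)
    manifest["outputs"] = _output_checksums(outdir)
    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )


def _output_checksums(outdir: Path) -> Dict[str, str]:
    out = {}
    for p in sorted(outdir.rglob("*.csv")):
        out[str(p.relative_to(outdir))] = hashlib.md5(p.read_bytes()).hexdigest()
    return out


# ---------------------------------------------------------------------------
# Recovery simulation study (programmed secondary-FSP group effect)
# ---------------------------------------------------------------------------


def recovery_cohort_config(seed: int, effect_sd: float = -2.2) -> CohortConfig:
    """Desk-scale cohort with a programmed P2Ab reduction of secondary-BA
    producers at 6 and 12 months (drives down total secondary FSP)."""
    return CohortConfig(
        seed=seed,
        n_ctr=16,
        n_p1ab=16,
        n_p2ab=16,
        timepoints=(3, 6, 12, 18, 24),
        group_effects=(
            GroupEffect("secondary_ba_producers", "P2Ab", (6, 12), effect_sd, "abundance"),
        ),
    )


def secondary_fsp_recovery_study(
    seed: int,
    n_seeds: int = 100,
    effect_sd: float = -2.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Simulate cohorts with the programmed P2Ab effect and test recovery.

    For each replicate seed: simulate the cohort, compute the total
    secondary FSP of every sample from its personalized community model,
    then run Tukey HSD per timepoint.  Returns one row per seed x timepoint
    with the P2Ab-vs-P1Ab adjusted p, the realized standardized effect and
    whether the cell was flagged at ``alpha``.
    """
    bundle = default_fixture_set(seed)
    engine = CommunityMetricsEngine(
        bundle.strain_models,
        bundle.diet,
        bundle.taxonomy,
        CommunityOptions(ba_metabolites=COMMUNITY_BA_METABOLITES),
    )
    rows = []
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    for rep_seed in rep_seeds:
        cfg = recovery_cohort_config(int(rep_seed), effect_sd)
        cohort = simulate_cohort(cfg)
        fsp = engine.total_secondary_fsp_table(cohort.abundance)
        meta = cohort.metadata.set_index("sample_id")
        for t in cfg.timepoints:
            sub = meta[meta["age_months"] == t]
            vals = fsp.loc[sub.index]
            groups = sub["group"]
            res = tukey_hsd(vals.to_numpy(), groups.to_numpy())
            p_adj = res.p_adj("P2Ab", "P1Ab")
            v1 = vals[groups == "P1Ab"]
            v2 = vals[groups == "P2Ab"]
            pooled = np.sqrt(
                ((len(v1) - 1) * v1.var(ddof=1) + (len(v2) - 1) * v2.var(ddof=1))
                / (len(v1) + len(v2) - 2)
            )
            eff = (v1.mean() - v2.mean()) / pooled if pooled > 0 else np.nan
            rows.append(
                {
                    "seed": int(rep_seed),
                    "timepoint": t,
                    "affected": t in (6, 12),
                    "p_adj_p2ab_vs_p1ab": p_adj,
                    "flagged": p_adj < alpha,
                    "realized_effect_sd": eff,
                }
            )
    return pd.DataFrame(rows)
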