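# Methods

## Constraint-based core

A strain model is a stoichiometric reconstruction: metabolites with
compartment tags, reactions with flux bounds in mmol/gDW/day, and a biomass
reaction that produces an explicit `biomass[c]` metabolite.  Flux balance
analysis (FBA) solves `max/min v_obj` subject to `S v = 0`, `lb ≤ v ≤ ub`
and any extra linear inequalities, through scipy's HiGHS interface with a
primal feasibility tolerance of 1e-9; reported optima are checked against
mass balance at 1e-6 (standard double-precision LP practice).  Flux
variability analysis (FVA) brackets a reaction's flux range, optionally
with the objective held at a fraction of its optimum.  Degenerate optima
are allowed: every quantity the package reports is an objective value or
an FVA bound, never an individual flux of a degenerate vertex.
Infeasibility and unboundedness are reported as statuses, never clipped.

Models are serialized to a small JSON schema (sorted keys, two-space
indent, so equal models give byte-identical files).  SBML import/export,
genome-scale solves and loopless/thermodynamic variants are out of scope.

## Community assembly

For each sample, member strain models are merged with a `<strain>__`
namespace; their extracellular compartments fuse into one shared lumen
`u`.  Panel bile acids get lumen→fecal (`fe`) and lumen→body-fluid (`b`)
transport plus export-only exchanges, whether or not any member touches
them, so secretion queries and diets are always well-defined.  The
community biomass reaction consumes each member's biomass metabolite
weighted by its relative abundance (strains under a 1e-6 inclusion
threshold are dropped and the rest renormalized to the simplex), and is
bounded to a growth corridor of [0.4, 1.0]/day so secretion potentials are
comparable across samples.  Flux coupling inequalities
`|v_r| ≤ c·v_biomass(strain) + ε` with `c = 400`, `ε = 0.01` (configurable)
tie every strain reaction to its owner's growth — a strain that cannot
grow cannot carry flux beyond the ε slack.  The host is represented only
by the passive body-fluid compartment; host metabolism is out of scope.

The diet is a set of bounds on lumen exchanges; unlisted exchanges are
closed to uptake.  The shipped toy diet supplies glucose at 0.8
mmol/gDW/day — deliberately inside the growth corridor, so a one-member
community's biomass optimum equals the standalone strain optimum — and
5 mmol/gDW/day each of CA, CDCA, GCA, GCDCA, TCA and TCDCA, emulating host
bile flow.  The coupling sanity check (silencing one strain's biomass)
is run with the corridor's lower bound relaxed to 0, because the community
biomass reaction consumes every member's biomass metabolite and a forced
zero-growth member makes the corridor itself infeasible.

Sanity checks per community: LP feasibility, nonzero community biomass
optimum, presence of fecal BA exchanges, and a finite FVA range for each.

## Bile-acid metrics

*Reaction abundance* of reaction `r` is `Σᵢ Aᵢ·[r ∈ strain i]`; the total
BA reaction abundance sums this over the members of all ten reaction
classes.  The class taxonomy ships BSH glyco/tauro deconjugation, cholate
ligation (BICoAL), 7α-dehydroxylation (BAIA), 7α/7β/3α-hydroxysteroid
dehydrogenases, 3β and 6β epimerization, and BA transport; membership is a
reading of the canonical gut BA transformation network and is configurable.

*Flux potential* `v_j` of BA `j` is the FVA maximum of its fecal exchange
with the growth corridor still enforced (the body-fluid route is exposed
as an alternative).  The per-strain attribution `v_j(i)` is the FVA
maximum of strain *i*'s lumen export transporter for that BA; `FSPᵢⱼ =
Aᵢ·vⱼ(i)` and the total secondary FSP sums over the secondary BA set
(DCA, LCA, UDCA, HDCA and their glycine/taurine conjugates by default).
A strain with no cytosolic reaction producing a BA cannot sustain positive
net export at steady state (its only source would be its own transporter),
so those strain–BA pairs are zero by construction and the pipeline skips
their LPs.

## Statistics

Feature tables move through an explicit state machine: raw → log2 →
autoscaled.  The log2 pseudocount is half the smallest positive value per
feature (features with no positive values map their zeros to 0); this
choice is a convention for zero handling, made explicit and configurable.

*Explained variance*: each autoscaled feature is regressed on one factor at
a time; the factor summary is the median marginal R² across features, and
factors above 10 % are flagged as confounders (age is expected to dominate
in this design).

*Mixed models*: a random-intercept model fit by REML, with the single
variance ratio λ = σ²_subject/σ²_residual profiled by a bounded 1-D search;
the λ = 0 boundary (OLS) is always evaluated, so the fit degrades
gracefully when between-subject variance vanishes or every subject has one
observation.  Fixed-effect p-values are Wald (single-fit cost, standard in
the association tooling this mirrors).  The implementation is
cross-checked against statsmodels MixedLM in the test suite.

*Differential analysis*: per timepoint, each log2 feature is fit by OLS on
diet covariates (total breastfeeding, exclusive breastfeeding, solid-food
introduction) plus group; the group effect is the partial F against the
covariates-only model.  BH FDR is applied within each timepoint × table
family, matching per-timepoint reporting; log2 fold changes are
differences of covariate-adjusted group means.  Groups under n = 3 at a
timepoint are dropped with a warning.

*Tukey HSD*: one-way ANOVA MSE, Tukey–Kramer statistic
`q = |m_a − m_b| / sqrt(MSE/2·(1/n_a + 1/n_b))`, adjusted p from the
studentized-range distribution (scipy's numerical CDF, cross-checked
against a 10⁶-draw Monte-Carlo oracle at 0.01 and against the pooled
t-test identity at k = 2).

*Spearman*: average-rank correlation computed as Pearson on ranks, p by
the t approximation, BH across the full matrix; constant columns are
reported missing.

*Loess*: tricube-weighted local polynomials (degree 2, span 0.75 by
default), evaluated on a grid inside the observed x-range only; pointwise
95 % bands use the local weighted residual variance.

## Synthetic cohorts

The generator emulates the study structure: 38 CTR / 23 P1Ab / 13 P2Ab
children scheduled at 3, 6, 12, 18, 24 and 36 months; a 33-BA panel with
primary/secondary species and glycine/taurine conjugates; 12 strain models
labeled with abundant gut genera.  Concentrations are log-normal with a
per-feature baseline, smooth age trends (primary BAs decline ~1.5 log2
units over the follow-up, secondary BAs rise ~2 log2 units after month
12), per-subject random intercepts (SD 0.8), residual noise (SD 1.0) and
additive programmed group effects in within-group-SD units.  Compositions
are Dirichlet (concentration 50) with age-dependent weights — late
colonizers (Clostridium, Eggerthella, Alistipes, Roseburia, Ruminococcus)
rise with age, Bifidobacterium declines — subject-level multipliers, and
group-specific shifts on BA-metabolizing strains.  Missingness is
completely at random at rate 0.3, emulating the ~30 % of scheduled stool
samples absent in cohorts of this design; the true missingness mechanism
of real studies is unknown.  Seroconversion ages are uniform on 6–24
months and carried as metadata only.  All draws flow from one mandatory
seed; equal configs give byte-identical tables.

What passing tests show — and don't: the generator reproduces the
longitudinal, compositional and group-effect *structure* the analysis
assumes, not real biological covariance between BAs, nor taxon-specific
abundance distributions, nor informative missingness.  Recovery results
therefore demonstrate correctness of the pipeline's inference under its
own model, not field performance on real cohorts.

## Recovery study and problem sizes

The end-to-end recovery study programs a −2.2 within-group-SD shift on the
secondary-BA-producing strains in the P2Ab group at 6 and 12 months; this
propagates through the community models to a realized reduction of the
total secondary FSP of ≥ 1.5 within-group SD (measured, not assumed, by
the harness — typically ~2.5 SD).  Each replicate simulates a cohort of
16/16/16 subjects over months 3–24, computes every sample's total
secondary FSP from its personalized community model, and applies Tukey HSD
per timepoint; detection is the rate of adjusted p < 0.05 at the affected
cells over 100 replicate seeds, with months 3, 18 and 24 serving as
false-flag controls.  The 16/16/16 × 5-visit layout is the package's
declared desk-scale default for simulation studies; the full 74-child
layout is the default for single pipeline runs.

Numerical conventions: LP feasibility 1e-9 and residual checks 1e-6;
community metrics reuse one LP template per cohort (only the
community-biomass column differs between samples); exact ties in BH and
rank statistics use average ranks/stable sorts; all stochastic routines
take explicit seeds, pipeline default 20221003.

## Known limitations

Toy strain models have unit-stoichiometry pathways and a single carbon
source; AGORA-scale reconstructions, host (Recon3D-like) metabolism,
kinetic/dynamic FBA, permutation FDR and multi-random-effect models are
out of scope.  The taxonomy's class membership is configurable because the
exact reaction inventory of real strains varies; the diet is a declared
toy average, not an estimated one.
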