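# Methods

This note documents the mathematical model, the conventions, every tunable
parameter, what the synthetic data does and does not emulate, and the known
limitations of `cometab`.

## 1. Constraint-based model

A model is a stoichiometric matrix **S** (metabolites × reactions), flux
bounds `lb ≤ v ≤ ub`, and optional extra linear inequality rows over **v**.
The feasible region is

```
{ v : S·v = 0,  lb ≤ v ≤ ub,  A·v ≤ b }
```

- **FBA** maximises or minimises one component of **v** over this region.
- **FVA** reports the per-reaction minimum and maximum.

Metabolite identifiers are `base[tag]`, with the compartment in brackets:
`[c]` cytosol, `[e]` extracellular, `[luM]` shared microbial lumen, `[d]`
diet, `[fe]` faecal, `[luLI]` host large-intestinal lumen, `[bc]` blood,
`[u]` urine, plus organ tags (`[liver]`, …). Exchange reactions touch
exactly one metabolite; uptake is negative flux, secretion positive.

All solves go through `scipy.optimize.linprog(method="highs")` with fixed
options, so repeated solves are bit-identical. Infeasibility and
unboundedness are surfaced through solution status (and typed exceptions at
the API boundary), never as silent zeros. The test suite validates the LP
layer against an independent vertex-enumeration oracle and against cobrapy.

## 2. Pan-species models

The pan model of a species is the union of the reactions and metabolites of
its strain reconstructions:

- shared reactions must agree on stoichiometry (conflict = error);
- shared bounds take the union interval (widest lower/upper), preserving
  every strain capability;
- strain biomass reactions merge into a single `biomassPan` whose precursor
  coefficients are the **mean over the strains that carry each precursor**.
  This merge rule is a declared convention — nothing in the framework
  dictates it — and is therefore tested as specified behaviour.

## 3. Community models

For each sample, the community model is assembled from the pan models of
the species observed in that sample:

1. Reads are restricted to model-covered species; per-sample **coverage**
   (fraction of reads covered) is reported. Within each sample, species
   below the relative-abundance cutoff (default `1e-4`) are removed and the
   remainder renormalised to sum to one.
2. Every member's reactions/metabolites are namespaced `species__id`; its
   extracellular `[e]` metabolites are rewired to one shared lumen `[luM]`.
3. Each lumen metabolite gets a two-tier exchange:
   `EX_met[d] → DUt_met → met[luM] → UFEt_met → EX_met[fe]`, with uptake
   possible only through the diet tier and secretion only through the
   faecal tier.
4. `communityBiomass` consumes each member's biomass metabolite weighted by
   its relative abundance and is bounded to the community growth window
   (0.4–1.0 /day) so the coupling constraints below bind meaningfully.
5. **Coupling**: for every reaction *j* of member *i*,
   `v_j ≤ c·v_biomass,i` and `v_j ≥ −c·v_biomass,i` with `c = 400`. These
   compile to plain LP inequality rows. Consequence (tested): a member with
   zero biomass flux carries exactly zero flux through every reaction.

A community's **secretion profile** is the FVA maximum of each faecal
exchange under a given diet; negative maxima (forced consumption) are
floored at zero and flagged.

## 4. Diets

A diet maps metabolite base ids to available uptake in mmol/person/day.
Applying a diet opens the diet-facing exchanges (lower bound `−scale·flux`)
and closes uptake of everything else diet-facing; secretion bounds are
never touched. Diet-facing means the `[d]` compartment when present,
otherwise `[e]`. Diet entries without a matching exchange warn rather than
error, since realistic diet tables contain compounds small models omit.
`check_growth` reports each pan model's maximal biomass flux under a diet
so infeasible communities can be diagnosed before assembly.

## 5. Host integration and the co-metabolism decomposition

A host model is a multi-organ stoichiometric model with diet exchanges
feeding `[luLI]` and urine exchanges `EX_met[u]`. Attaching a community:

- removes the community's own `[d]`/`[fe]` tiers (keeping the community
  biomass sink), so microbes feed exclusively from the host lumen;
- adds one reversible transport `met[luM] ↔ met[luLI]` (`Micro_EX_met`) per
  metabolite present in both lumens;
- preserves all coupling rows.

For a target metabolite (formate), three maximisations define the
decomposition, all under the same diet:

| quantity | LP |
|---|---|
| `germfree_max` | max `EX_for[u]`, host alone |
| `personalised_max` | max `EX_for[u]`, host + community |
| `microbial_secretion_max` | max `Micro_EX_for`, host + community |

with `delta = personalised_max − germfree_max` and
`cometabolism_residual = delta − microbial_secretion_max`: the part of the
gain the host must synthesise itself from microbially supplied precursors.
A sample is a "high secretor" of a metabolite when its microbe→host
transport flux exceeds 30 mmol/person/day in the urine-maximising solution.

## 6. Screens

All screens run on a germ-free host under a fixed screening diet, scoring
the maximal urine target flux.

- **Supplementation**: each candidate metabolite is added to the diet at up
  to 300 mmol/d (max rule, never reducing existing supply); a candidate
  "increases" if the new maximum exceeds baseline by more than 1e-6.
- **Knockout**: each candidate reaction is deleted singly (bounds to zero);
  the fractional reduction of the maximum is reported and flagged when
  above 10 %.
- **Minimal set**: greedy forward selection (largest marginal reduction
  first) until the goal reduction is reached, followed by a backward pass
  dropping members not needed to stay above the goal. An exhaustive
  subset-enumeration oracle (`exhaustive_min_set`) verifies optimality on
  small candidate lists.
- **Annotation join**: knockout results are joined with a static
  reaction→gene→disease-association table; duplicate annotation rows are
  an error.

## 7. Statistics

- **Metabolite screen**: zeros are treated as missing; metabolites non-zero
  in fewer than 50 % of samples are excluded (recorded). Log concentration
  is regressed on group + covariates by OLS with HC3 robust covariance; the
  global group effect is a robust joint Wald test of all group dummies, and
  the case-vs-reference contrast is that dummy's robust test. BH-FDR across
  retained metabolites.
- **Fractional regression**: quasi-binomial logit GLM of each species'
  relative abundance on case status + covariates, sandwich SEs; species
  present in <50 % of samples excluded; non-convergence flagged, not
  raised.
- **Log-ratio test**: per sample, `log(Σ up-set counts / Σ down-set
  counts)` with pseudocount 0.5 added to every count, compared between the
  two groups with Welch's t-test.
- **Flux comparison**: OLS of one flux per sample on group + covariates
  (APOE4 genotype, sex) with robust SEs; constant covariate columns are
  dropped with a warning.
- **bh_fdr**: Benjamini–Hochberg step-up (statsmodels), order-preserving.

Calibration is part of acceptance: on null synthetic cohorts over 200
seeds, each test's type-I error must fall within the 95 % binomial CI of
the nominal 5 %, and power at the planted effect sizes (3-fold abundance
shift at n=24/24; −0.5 log metabolite shift at n=40/group) must be ≥80 %.

## 8. Parameters

All tunables live in `cometab.config.Config`; the config hash and seed are
recorded in each run's `manifest.json`.

| parameter | default | rationale |
|---|---|---|
| `coupling_factor` | 400 | community-modelling convention tying member fluxes to member biomass |
| `abundance_cutoff` | 1e-4 | drop species below this relative abundance per sample |
| `community_growth_lb/ub` | 0.4 / 1.0 per day | physiological community growth window; makes coupling bind |
| `supplement_amount` | 300 mmol/d | supplementation screen intake |
| `secretion_flux_threshold` | 30 mmol/person/day | "high secretor" cut |
| `ko_flag_threshold` | 0.10 | knockout flagged above 10 % reduction |
| `min_nonzero` | 0.5 | prevalence filter (metabolites and species) |
| `pseudocount` | 0.5 | log-ratio zero handling (convention; exposed) |
| `robust_cov` | HC3 | robust covariance flavour (convention; exposed) |
| `fdr_alpha` | 0.05 | nominal FDR level |
| `feasibility_tol` | 1e-6 | numeric feasibility tolerance |
| `solver` | highs | deterministic LP backend |

## 9. Synthetic data: what it does and does not emulate

The generators are pure functions of their spec + seed.

Emulated structure:

- **Toy microbes** — five trait archetypes (high/low formate secretors with
  and without precursor side-products, a plain commensal, a
  nitrogen-requiring species, a tryptophan producer), each built as a
  single strain passed through the pan-model builder.
- **Toy host** — a multi-organ host carrying four formate-producing
  branches (serine, formaldehyde, tryptophan, methionine-salvage), each a
  *diamond*: ≥2 feeder reactions converge on the substrate of a
  capacity-capped endpoint reaction and ≥2 parallel drain isozymes carry
  the product to formate. The endpoint is therefore each branch's unique
  single-reaction cut, which is why the minimal knockout set is exactly the
  four endpoints. Capacities (5, 3, 2, 1) plus a basal source (1) give a
  germ-free maximum of 12; deleting the endpoints leaves 1 (an 11/12 ≈
  92 % reduction). An ammonium-dependent side path stays closed under the
  screening diet, so ammonium supplementation raises the maximum even
  though ammonium carries no carbon.
- **Cohorts** — Dirichlet-multinomial counts (24 cases / 24 controls,
  log-normal library sizes around 5·10⁴ reads) with planted fold-3 shifts,
  plus matched metadata (sex, APOE4, age, BMI). Urine metabolomes are
  log-normal with weak covariate structure, planted case shifts, and
  random zeros.

Not emulated: genome-scale network size and redundancy, real taxonomic
composition and correlation structure, strain heterogeneity within
species, real enterotypes, absolute quantification, any real cohort's
effect sizes. Published headline percentages depend on full genome-scale
reconstructions and real metagenomes and are out of scope at desk scale;
correctness here is property-based (oracle equivalence, exact fixtures,
monotonicity, calibration, determinism).

## 10. Numerical choices

- One LP entry point; HiGHS with presolve, fixed options. No warm starts,
  no randomised algorithms, no threading: results are reproducible
  bit-for-bit.
- Comparisons against hand-derived values use 1e-6 absolute tolerance;
  "strictly increases" in screens means `> baseline + 1e-6`.
- Reports use fixed float formatting (`%.10g`) and sorted JSON keys so
  identical runs are byte-identical (tested).
- The SBML dialect drops extra constraint rows (coupling) because SBML-FBC
  core cannot express them; the tabular dialect preserves them and is the
  fixture format.

## 11. Resolved underspecifications

Choices made where the conventions were not fully dictated, all recorded in
`Config` or documented here:

- pseudocount 0.5 for the log-ratio test;
- HC3 as the robust covariance flavour;
- fractional regression via quasi-binomial IRLS (not beta regression);
- the global group test implemented as a joint robust Wald test of all
  group dummies plus the case-vs-reference contrast;
- the pan biomass merge rule (mean coefficient over carrying strains);
- knockout reductions floored at zero (a deletion that raises the optimum
  is numerically possible at tolerance level but not meaningful).

## 12. Limitations

- Toy scale: tens of reactions per model; runtimes and numerics do not
  probe genome-scale conditioning.
- Single-objective FBA; no flux sampling, no loopless constraints, no
  thermodynamic bounds.
- The coupling factor is a fixed scalar, not per-reaction.
- Sex enters only through host selection and as a covariate; the two toy
  hosts are structurally identical.
- The greedy minimal-set search guarantees minimality only with respect to
  its own greedy set; global optimality is verified exhaustively for small
  candidate lists only.
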