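# cometab

Personalised host–microbiome constraint-based modelling of urinary
co-metabolites, centred on formate.

## The scientific problem

Gut microbes ferment dietary substrates into small molecules — formate,
serine, tryptophan — that the host absorbs through the intestinal lumen and
either excretes directly or transforms further before excreting them in
urine. A urine metabolite can therefore fall in disease not because any
single organ fails, but because the joint host+microbiome network loses
capacity. Asking "how much urinary formate *could* this person's body plus
this person's microbiome produce?" is a constrained-optimisation question:
given a metagenomically measured community composition, a diet, and a
multi-organ host reconstruction, maximise the urine formate exchange flux
subject to steady-state mass balance.

`cometab` implements that pipeline end to end at desk scale:

1. **Pan-species models** (`cometab.pan`) — union the reactions of the
   strain reconstructions of one species, widen shared bounds, merge biomass
   reactions into `biomassPan`.
2. **Personalised communities** (`cometab.community`) — namespace each
   member's network, rewire extracellular metabolites into a shared
   microbial lumen `[luM]` with a two-tier diet→lumen→faecal exchange, add
   an abundance-weighted `communityBiomass`, and couple every member
   reaction to that member's biomass flux (|v| ≤ 400·v_biomass) so absent
   or non-growing species carry no flux.
3. **Host integration** (`cometab.host`) — attach a community to the host's
   large-intestinal lumen `[luLI]` and decompose the urine formate maximum
   into the germ-free capacity, the direct microbial contribution, and a
   co-metabolism residual the host synthesises from microbially supplied
   precursors.
4. **Screens** (`cometab.screens`) — diet supplementation, single-reaction
   knockouts with a 10 % flag threshold, and a greedy + exhaustive
   minimal-knockout-set search for the reactions that jointly abolish
   formate production.
5. **Cohort statistics** (`cometab.stats`) — robust (HC3) regression screens
   of urine metabolites, fractional (quasi-binomial logit) regressions of
   relative abundances, compositional log-ratio tests, and
   Benjamini–Hochberg FDR.
6. **Synthetic data** (`cometab.synthetic`) — deterministic toy microbes,
   a four-branch toy host, and Dirichlet-multinomial case/control cohorts,
   so the whole pipeline runs offline with no downloads.

All linear programming goes through one deterministic HiGHS-based layer
(`cometab.lp`); models round-trip through a diffable tabular dialect or
SBML L3+FBC (`cometab.io`).

## Worked example

The shipped hand-solvable fixture: a host with a basal formate source
(≤ 2 mmol/d) and a precursor→formate conversion, plus a one-species
community whose member ferments glucose to formate (≤ 3) and to the
precursor (≤ 4).

```python
from cometab import make_cometabolism_fixture, cometabolism_decomposition

host, community, diet = make_cometabolism_fixture()
rep = cometabolism_decomposition(host, community, diet, "for")
print(rep.germfree_max, rep.personalised_max,
      rep.microbial_secretion_max, rep.cometabolism_residual)
# 2.0 9.0 3.0 4.0
```

Germ-free the host manages 2; with the community attached the maximum rises
to 9, of which 3 arrive as microbial formate directly and 4 are made by the
host from the microbial precursor — the co-metabolism residual.

The knockout screens run on a toy host whose four formate branches end in
capacity-capped endpoint reactions (capacities 5, 3, 2, 1; basal source 1,
germ-free maximum 12):

```python
from cometab import make_toy_host, host_base_diet, minimal_set_search

host, diet = make_toy_host(), host_base_diet()
candidates = [r for r in host.base.reactions
              if "branch" in host.base.reactions[r].subsystem
              or "endpoint" in host.base.reactions[r].subsystem
              or host.base.reactions[r].subsystem == "ammonium path"]
print(minimal_set_search(host, diet, candidates, goal_reduction=0.85))
# (['PSP_L', 'SFGTH', 'TRPO2', 'DKMPPD'], 0.9166666666666666, True)
```

Exactly the four endpoint reactions — every feeder and drain has a redundant
twin — and deleting them removes 11/12 of the maximum.

## Command line

```sh
cometab all --seed 7 -o cometab_out        # full synthetic demonstration
cometab generate -o out --seed 7           # synthetic inputs only
cometab build-community -o out             # per-sample community models
cometab secretion -o out                   # FVA secretion capacities
cometab host-run -o out                    # personalised urine decomposition
cometab screens -o out                     # supplementation / knockout / minimal set
cometab stats -o out                       # cohort statistics
```

Every stage writes flat TSV/JSON reports plus a `manifest.json` recording
the configuration hash and seed; identical seeds give byte-identical
outputs. Numeric conventions (coupling factor 400, 10 % knockout flag,
300 mmol/d supplements, 50 % prevalence filters, pseudocount 0.5, HC3
covariances) live in `cometab.config.Config` and can be overridden with
`--config config.yaml`.

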