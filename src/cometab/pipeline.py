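"""End-to-end orchestration of the synthetic demonstration pipeline.

Each stage reads the files the previous stage wrote and writes flat
TSV/JSON reports, so the CLI subcommands can be run independently or via
``all``. Outputs are deterministic for a fixed seed (stable ordering, fixed
float formatting, no timestamps).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .community import build_community, filter_and_renormalize, secretion_profile, secretion_profile_frame
from .config import Config
from .diet import apply_diet, check_growth
from .errors import ValidationError
from .host import (
    HostModel,
    attach_community,
    cometabolism_decomposition,
    high_secretors,
    max_urine_secretion,
)
from .io import (
    AbundanceTable,
    read_abundances,
    read_diet,
    read_model,
    write_abundances,
    write_diet,
    write_model,
    write_report,
)
from .lp import solve_fba
from .screens import (
    annotate_with_ad,
    knockout_screen,
    minimal_set_search,
    read_annotations,
    supplementation_screen,
)
from .stats import compare_fluxes, fractional_regression, log_ratio_test, screen_metabolites
from . import synthetic

logger = logging.getLogger(__name__)

SECRETION_METABOLITES = ["for", "ser_L", "trp_L"]
PLANTED_UP = ("plain",)
PLANTED_DOWN = ("F_secretor_hi",)
COHORT_SPECIES = tuple(synthetic.DEFAULT_TRAITS) + ("uncov_1", "uncov_2")

# toy stand-in for the static disease-annotation table (synthetic; directions
# follow the sign structure of published gene-disease association tables)
SYNTHETIC_ANNOTATIONS = [
    ("PSP_L", "PSPH", "positive"),
    ("PSERT", "PSAT1", "positive"),
    ("PGCD", "PHGDH", "positive"),
    ("SFGTH", "ESD", "positive"),
    ("TRPO2", "TDO2", "negative"),
    ("FKYNH", "AFMID", "negative"),
    ("ALCD", "ADH1B", "none"),
    ("DKMPPD", "ENOPH1", "none"),
]


def _write_manifest(outdir: Path, config: Config, stage: str) -> None:
    path = outdir / "manifest.json"
    data = {}
    if path.exists():
        data = json.loads(path.read_text())
    data[stage] = {"config_hash": config.hash(), "seed": config.seed}
    data["config"] = config.to_dict()
    path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def _require(path: Path, producer: str):
    if not path.exists():
        raise ValidationError(
            f"missing input {path.name!r}; run the {producer!r} subcommand first"
        )
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_generate(outdir: str | Path, config: Config) -> None:
    """Write every synthetic input: diets, microbe models, cohort, host,
    annotation table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_diet(synthetic.make_diet("full"), outdir / "diet_full.tsv")
    write_diet(synthetic.make_diet("minimal"), outdir / "diet_minimal.tsv")
    write_diet(synthetic.host_run_diet(), outdir / "diet_host.tsv")
    write_diet(synthetic.host_base_diet(), outdir / "diet_screen.tsv")

    microbes = synthetic.make_toy_microbes(seed=config.seed)
    (outdir / "models").mkdir(exist_ok=True)
    for sp, model in microbes.items():
        write_model(model, outdir / "models" / sp)
    growth = check_growth(list(microbes.values()), synthetic.make_diet("full"),
                          min_growth=config.min_growth)
    write_report(growth, outdir / "growth_check.tsv")

    spec = synthetic.CohortSpec(
        n_cases=24, n_controls=24, n_species=len(COHORT_SPECIES),
        planted_up=PLANTED_UP, planted_down=PLANTED_DOWN,
        species_names=COHORT_SPECIES, seed=config.seed,
    )
    counts, metadata = synthetic.make_cohort(spec)
    write_abundances(counts, outdir / "counts.tsv")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t")

    host = synthetic.make_toy_host(synthetic.ToyHostSpec(sex="male"))
    write_model(host.base, outdir / "host_male")
    host_f = synthetic.make_toy_host(synthetic.ToyHostSpec(sex="female"))
    write_model(host_f.base, outdir / "host_female")

    ann = pd.DataFrame(SYNTHETIC_ANNOTATIONS,
                       columns=["reaction", "genes", "ad_association"])
    ann["evidence"] = "synthetic"
    ann.to_csv(outdir / "ad_annotations.tsv", sep="\t", index=False)
    _write_manifest(outdir, config, "generate")


def _load_host(outdir: Path, sex: str) -> HostModel:
    base = read_model(_require(outdir / f"host_{sex}", "generate"))
    return HostModel(base=base, sex=sex)


def _load_communities(outdir: Path, config: Config):
    comm_dir = _require(outdir / "communities", "build-community")
    abfile = _require(outdir / "abundances_filtered.tsv", "build-community")
    rel = read_abundances(abfile, mode="relative")
    models = {}
    for sample in rel.samples:
        base = read_model(comm_dir / sample)
        abundances = rel.values.loc[sample]
        abundances = abundances[abundances > 0]
        models[sample] = build_community(
            _load_pan_models(outdir), abundances,
            coupling_factor=config.coupling_factor, config=config,
            community_id=sample,
        )
        # sanity: the persisted model must match the rebuilt one structurally
        if set(base.reactions) != set(models[sample].base.reactions):
            raise ValidationError(f"stale community model on disk for {sample!r}")
    return models


def _load_pan_models(outdir: Path):
    models_dir = _require(outdir / "models", "generate")
    return {p.name: read_model(p) for p in sorted(models_dir.iterdir()) if p.is_dir()}


def stage_build_community(outdir: str | Path, config: Config) -> None:
    """Filter/renormalise the cohort abundances and build one community
    model per sample."""
    outdir = Path(outdir)
    counts = read_abundances(_require(outdir / "counts.tsv", "generate"), mode="counts")
    pan_models = _load_pan_models(outdir)
    filtered, coverage = filter_and_renormalize(
        counts, list(pan_models), cutoff=config.abundance_cutoff
    )
    write_abundances(filtered, outdir / "abundances_filtered.tsv")
    coverage.to_frame().to_csv(outdir / "coverage.tsv", sep="\t", float_format="%.10g")
    comm_dir = outdir / "communities"
    comm_dir.mkdir(exist_ok=True)
    for sample in filtered.samples:
        abundances = filtered.values.loc[sample]
        community = build_community(
            pan_models, abundances[abundances > 0],
            coupling_factor=config.coupling_factor, config=config,
            community_id=sample,
        )
        write_model(community.base, comm_dir / sample)
    _write_manifest(outdir, config, "build-community")


def stage_secretion(outdir: str | Path, config: Config) -> pd.DataFrame:
    """Maximal net secretion capacity per sample and metabolite."""
    outdir = Path(outdir)
    diet = read_diet(_require(outdir / "diet_full.tsv", "generate"))
    communities = _load_communities(outdir, config)
    profiles = {
        sample: secretion_profile(comm, diet, SECRETION_METABOLITES)
        for sample, comm in sorted(communities.items())
    }
    frame = secretion_profile_frame(profiles)
    frame.to_csv(outdir / "secretion_profiles.tsv", sep="\t", index=False,
                 float_format="%.10g")
    _write_manifest(outdir, config, "secretion")
    return frame


def stage_host_run(outdir: str | Path, config: Config) -> pd.DataFrame:
    """Attach each sample's community to the sex-matched host and decompose
    the urine formate maximum."""
    outdir = Path(outdir)
    diet = read_diet(_require(outdir / "diet_host.tsv", "generate"))
    metadata = pd.read_csv(_require(outdir / "metadata.tsv", "generate"),
                           sep="\t", index_col=0)
    hosts = {"male": _load_host(outdir, "male"), "female": _load_host(outdir, "female")}
    communities = _load_communities(outdir, config)
    rows = []
    secretor_counts: Dict[str, int] = {}
    for sample, community in sorted(communities.items()):
        sex = "female" if metadata.loc[sample, "sex"] == "F" else "male"
        host = hosts[sex]
        report = cometabolism_decomposition(host, community, diet, "for")
        combined = apply_diet(attach_community(host, community), diet)
        sol = solve_fba(combined, objective="EX_for[u]", sense="max")
        for met in high_secretors(sol, community, config.secretion_flux_threshold):
            secretor_counts[met] = secretor_counts.get(met, 0) + 1
        rows.append({
            "sample": sample, "sex": sex, "status": "ok",
            "germfree_max": report.germfree_max,
            "personalised_max": report.personalised_max,
            "microbial_secretion_max": report.microbial_secretion_max,
            "residual": report.cometabolism_residual,
        })
    df = pd.DataFrame(rows).set_index("sample")
    df.to_csv(outdir / "host_results.tsv", sep="\t", float_format="%.10g")
    write_report({"high_secretors": secretor_counts,
                  "threshold": config.secretion_flux_threshold},
                 outdir / "high_secretors.json")
    _write_manifest(outdir, config, "host-run")
    return df


def stage_cometabolism(outdir: str | Path, config: Config) -> None:
    """Write the analytically solvable decomposition fixture report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    host, community, diet = synthetic.make_cometabolism_fixture()
    report = cometabolism_decomposition(host, community, diet, "for")
    write_report(report, outdir / "cometabolism_fixture.json")
    _write_manifest(outdir, config, "cometabolism")


def stage_screens(outdir: str | Path, config: Config,
                  goal_reduction: float = 0.85) -> Dict[str, object]:
    """Supplementation, knockout and minimal-set screens on the germ-free
    host, plus the disease-annotation join."""
    outdir = Path(outdir)
    diet = read_diet(_require(outdir / "diet_screen.tsv", "generate"))
    host = _load_host(outdir, "male")

    candidates_met = ["ser_L", "trp_L", "meoh", "nh4", "lac_D"]
    supp = supplementation_screen(host, diet, candidates_met,
                                  amount=config.supplement_amount, target="for")
    supp.to_csv(outdir / "supplementation_screen.tsv", sep="\t", float_format="%.10g")

    candidate_rxns = [r for r in host.base.reactions
                      if host.base.reactions[r].subsystem.endswith("branch")
                      or "endpoint" in host.base.reactions[r].subsystem
                      or host.base.reactions[r].subsystem == "ammonium path"]
    pd.DataFrame({"reaction": candidate_rxns}).to_csv(
        outdir / "ko_candidates.tsv", sep="\t", index=False)
    ko = knockout_screen(host, diet, candidate_rxns, target="for",
                         flag_threshold=config.ko_flag_threshold)
    ko.to_frame().to_csv(outdir / "knockout_screen.tsv", sep="\t",
                         float_format="%.10g")

    min_set, achieved, reached = minimal_set_search(
        host, diet, candidate_rxns, target="for", goal_reduction=goal_reduction)
    write_report({"minimal_set": sorted(min_set), "achieved_reduction": achieved,
                  "goal_reduction": goal_reduction, "goal_reached": reached},
                 outdir / "minimal_set.json")

    annotations = read_annotations(_require(outdir / "ad_annotations.tsv", "generate"))
    joined, summary = annotate_with_ad(ko, annotations)
    joined.to_csv(outdir / "knockout_annotated.tsv", sep="\t", float_format="%.10g")
    write_report(summary, outdir / "annotation_summary.json")
    _write_manifest(outdir, config, "screens")
    return {"minimal_set": min_set, "achieved_reduction": achieved,
            "knockout": ko, "supplementation": supp, "summary": summary}


def stage_stats(outdir: str | Path, config: Config) -> Dict[str, object]:
    """Cohort statistics: abundance regressions, log-ratio test, flux
    comparison and the metabolite screen."""
    outdir = Path(outdir)
    counts = read_abundances(_require(outdir / "counts.tsv", "generate"), mode="counts")
    metadata = pd.read_csv(_require(outdir / "metadata.tsv", "generate"),
                           sep="\t", index_col=0)
    rel_all = counts.normalize()
    groups = metadata["group"]
    covariates = metadata[["APOE4"]].astype(float)

    frac = fractional_regression(rel_all.values, groups, covariates,
                                 min_presence=config.min_nonzero)
    frac.to_csv(outdir / "fractional_regression.tsv", sep="\t", float_format="%.10g")

    lr = log_ratio_test(counts.values, list(PLANTED_UP), list(PLANTED_DOWN),
                        groups, pseudocount=config.pseudocount)
    write_report({"t": lr["t"], "p": lr["p"], "group_means": lr["group_means"]},
                 outdir / "log_ratio_test.json")

    results = {"fractional": frac, "log_ratio": lr}
    host_path = outdir / "host_results.tsv"
    if host_path.exists():
        host_res = pd.read_csv(host_path, sep="\t", index_col=0)
        flux_cov = pd.concat(
            [covariates, (metadata["sex"] == "F").astype(float).rename("sex")], axis=1
        ).loc[host_res.index]
        fluxcmp = compare_fluxes(host_res["personalised_max"],
                                 groups.loc[host_res.index], flux_cov)
        fluxcmp.to_csv(outdir / "flux_comparison.tsv", sep="\t", float_format="%.10g")
        results["flux_comparison"] = fluxcmp

    conc, mgroups, mcov = synthetic.make_metabolite_cohort(
        n_per_group=40, shifted=(0, 1), low_prevalence=(5,), seed=config.seed)
    screen = screen_metabolites(conc, mgroups, mcov, min_nonzero=config.min_nonzero)
    screen.to_csv(outdir / "metabolite_screen.tsv", sep="\t", float_format="%.10g")
    results["metabolite_screen"] = screen
    _write_manifest(outdir, config, "stats")
    return results


def stage_all(outdir: str | Path, config: Config) -> None:
    """The full synthetic end-to-end demonstration."""
    stage_generate(outdir, config)
    stage_build_community(outdir, config)
    stage_secretion(outdir, config)
    stage_host_run(outdir, config)
    stage_cometabolism(outdir, config)
    stage_screens(outdir, config)
    stage_stats(outdir, config)
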