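"""Synthetic inputs for the whole pipeline.

Nothing here downloads anything: toy strain models with distinct
fermentation capabilities stand in for curated genome-scale reconstructions,
a toy multi-organ host carries the four-branch formate subnetwork (serine,
formaldehyde, tryptophan, and methionine-salvage routes, each ending in a
capacity-capped endpoint reaction), and case/control cohorts are drawn from
a Dirichlet-multinomial with planted fold-changes. Every generator is a
pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .community import CommunityModel, build_community
from .core import Metabolite, Reaction, StoichiometricModel
from .errors import ValidationError
from .host import HostModel
from .io import AbundanceTable, DietSpec
from .pan import PAN_BIOMASS_ID, build_pan_model

# ---------------------------------------------------------------------------
# toy microbes
# ---------------------------------------------------------------------------

DEFAULT_TRAITS: Dict[str, Dict] = {
    # formate secretor with a high serine side-product — drives co-metabolism
    "F_secretor_hi": {"formate_rate": 10.0, "precursors": {"ser_L": 40.0}},
    # plain formate secretor
    "F_secretor_lo": {"formate_rate": 5.0, "precursors": {}},
    # commensal without formate capability
    "plain": {"formate_rate": 0.0, "precursors": {}},
    # nitrogen-requiring species: fails on a carbon-only diet
    "needs_nh4": {"formate_rate": 0.0, "precursors": {}, "substrate_needs": ["nh4"]},
    # tryptophan producer feeding the host kynurenine branch
    "trp_producer": {"formate_rate": 0.0, "precursors": {"trp_L": 8.0}},
}


def make_toy_microbe(
    species_id: str,
    formate_rate: float = 0.0,
    precursors: Optional[Dict[str, float]] = None,
    substrate_needs: Sequence[str] = (),
) -> StoichiometricModel:
    """One toy strain model: glucose uptake, biomass, optional fermentation
    products secreted at bounded rates."""
    precursors = dict(precursors or {})
    m = StoichiometricModel(id=species_id)

    def exch(base: str) -> None:
        e = f"{base}[e]"
        if e not in m.metabolites:
            m.add_metabolite(Metabolite(e))
        m.add_reaction(Reaction(f"EX_{base}[e]", {e: -1.0}, -1000.0, 1000.0,
                                subsystem="exchange"))

    def met(base: str, tag: str = "c") -> str:
        mid = f"{base}[{tag}]"
        if mid not in m.metabolites:
            m.add_metabolite(Metabolite(mid))
        return mid

    exch("glc_D")
    met("glc_D")
    m.add_reaction(Reaction("GLCt", {"glc_D[e]": -1.0, "glc_D[c]": 1.0}, 0.0, 1000.0,
                            subsystem="transport"))
    biomass_stoich = {"glc_D[c]": -1.0}
    for need in substrate_needs:
        exch(need)
        met(need)
        m.add_reaction(Reaction(f"{need.upper()}t", {f"{need}[e]": -1.0, f"{need}[c]": 1.0},
                                0.0, 1000.0, subsystem="transport"))
        biomass_stoich[f"{need}[c]"] = -0.1
    m.add_reaction(Reaction("biomass", biomass_stoich, 0.0, 1000.0,
                            subsystem="biomass"))
    if formate_rate > 0:
        met("for")
        exch("for")
        m.add_reaction(Reaction("PFL", {"glc_D[c]": -1.0, "for[c]": 1.0},
                                0.0, formate_rate, subsystem="fermentation"))
        m.add_reaction(Reaction("FORt", {"for[c]": -1.0, "for[e]": 1.0}, 0.0, 1000.0,
                                subsystem="transport"))
    for prec, rate in sorted(precursors.items()):
        met(prec)
        exch(prec)
        m.add_reaction(Reaction(f"SYN_{prec}", {"glc_D[c]": -1.0, f"{prec}[c]": 1.0},
                                0.0, rate, subsystem="fermentation"))
        m.add_reaction(Reaction(f"{prec.upper()}tout", {f"{prec}[c]": -1.0, f"{prec}[e]": 1.0},
                                0.0, 1000.0, subsystem="transport"))
    m.objective = "biomass"
    m.validate()
    return m


def make_toy_microbes(
    n: Optional[int] = None,
    traits: Optional[Dict[str, Dict]] = None,
    seed: int = 0,
) -> Dict[str, StoichiometricModel]:
    """Pan models for ``n`` species (default: the five trait archetypes).

    With ``traits`` given, keys are species ids and values the keyword
    arguments of :func:`make_toy_microbe` (``formate_rate`` is drawn
    uniformly in [5, 15] when requested but unspecified). Deterministic for
    a fixed seed. Each species is built as a single strain and passed
    through :func:`build_pan_model` so downstream code sees real pan models.
    """
    rng = np.random.default_rng(seed)
    if traits is None:
        traits = dict(DEFAULT_TRAITS)
        if n is not None:
            if n < 1:
                raise ValidationError("need at least one species")
            while len(traits) < n:
                traits[f"extra_{len(traits)}"] = {
                    "formate_rate": float(rng.uniform(0, 10) * rng.integers(0, 2)),
                    "precursors": {},
                }
            traits = dict(list(traits.items())[:n])
    out = {}
    for sp, tr in traits.items():
        strain = make_toy_microbe(
            sp,
            formate_rate=tr.get("formate_rate", 0.0),
            precursors=tr.get("precursors"),
            substrate_needs=tr.get("substrate_needs", ()),
        )
        out[sp] = build_pan_model([strain], sp)
    return out


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design of a synthetic case/control cohort.

    Counts are Dirichlet-multinomial: a species' concentration parameter is
    multiplied by ``up_fold`` (cases) if planted up, divided by
    ``down_fold`` if planted down. ``reads_median``/``reads_sigma``
    parameterise the log-normal library-size distribution.
    """

    n_cases: int = 24
    n_controls: int = 24
    n_species: int = 40
    planted_up: Tuple[str, ...] = ()
    up_fold: float = 3.0
    planted_down: Tuple[str, ...] = ()
    down_fold: float = 3.0
    reads_median: float = 5e4
    reads_sigma: float = 0.25
    concentration: float = 100.0  # total Dirichlet mass: lower = more overdispersed
    apoe4_rate_cases: float = 0.5
    apoe4_rate_controls: float = 0.2
    species_names: Optional[Tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.up_fold <= 0 or self.down_fold <= 0:
            raise ValidationError("fold changes must be positive")
        for r in (self.apoe4_rate_cases, self.apoe4_rate_controls):
            if not 0 <= r <= 1:
                raise ValidationError("APOE4 rates must lie in [0, 1]")


def make_cohort(spec: CohortSpec) -> Tuple[AbundanceTable, pd.DataFrame]:
    """Draw gOTU-style counts and matched metadata for a case/control cohort."""
    rng = np.random.default_rng(spec.seed)
    if spec.species_names is not None:
        species = list(spec.species_names)
        if len(species) != spec.n_species:
            raise ValidationError("species_names length must equal n_species")
    else:
        species = [f"sp_{i + 1:02d}" for i in range(spec.n_species)]
    unknown = [s for s in tuple(spec.planted_up) + tuple(spec.planted_down)
               if s not in species]
    if unknown:
        raise ValidationError(f"planted species not in the species list: {unknown}")

    base = rng.lognormal(0.0, 1.0, spec.n_species)
    base = base / base.sum() * spec.concentration
    alpha_control = base
    alpha_case = base.copy()
    for i, sp in enumerate(species):
        if sp in spec.planted_up:
            alpha_case[i] *= spec.up_fold
        if sp in spec.planted_down:
            alpha_case[i] /= spec.down_fold

    samples, groups, rows = [], [], []
    mu = np.log(spec.reads_median)
    for g, n, alpha in (("AD", spec.n_cases, alpha_case),
                        ("control", spec.n_controls, alpha_control)):
        for i in range(n):
            sid = f"{'case' if g == 'AD' else 'ctrl'}_{i + 1:02d}"
            reads = int(round(rng.lognormal(mu, spec.reads_sigma)))
            p = rng.dirichlet(alpha)
            counts = rng.multinomial(reads, p)
            samples.append(sid)
            groups.append(g)
            rows.append(counts)
    values = pd.DataFrame(np.array(rows), index=samples, columns=species)
    table = AbundanceTable(values=values, mode="counts")

    n_total = len(samples)
    sex = np.where(np.arange(n_total) % 2 == 0, "F", "M")
    apoe = [
        int(rng.random() < (spec.apoe4_rate_cases if g == "AD" else spec.apoe4_rate_controls))
        for g in groups
    ]
    metadata = pd.DataFrame({
        "group": groups,
        "sex": sex,
        "APOE4": apoe,
        "age": np.round(rng.normal(70.0, 5.0, n_total), 1),
        "BMI": np.round(rng.normal(26.0, 3.0, n_total), 1),
    }, index=samples)
    return table, metadata


def make_metabolite_cohort(
    n_per_group: int = 40,
    n_metabolites: int = 49,
    shifted: Sequence[int] = (),
    log_shift: float = -0.5,
    sigma: float = 0.5,
    zero_rate: float = 0.1,
    low_prevalence: Sequence[int] = (),
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Synthetic urine-metabolome screen input.

    Log-normal concentrations with covariate structure (age, sex, BMI enter
    the mean weakly), an ``log_shift`` added to cases for the metabolites in
    ``shifted`` (column indices), and random zeros at ``zero_rate``
    (metabolites listed in ``low_prevalence`` get 60% zeros so the
    prevalence filter has something to drop). Returns (concentrations,
    groups, covariates).
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    groups = pd.Series(["AD"] * n_per_group + ["control"] * n_per_group,
                       index=[f"s{i:03d}" for i in range(n)])
    age = rng.normal(70, 5, n)
    sex = rng.integers(0, 2, n)
    bmi = rng.normal(26, 3, n)
    covariates = pd.DataFrame({"age": age, "sex": sex, "BMI": bmi}, index=groups.index)
    is_case = (groups == "AD").to_numpy().astype(float)
    data = {}
    for j in range(n_metabolites):
        mu = rng.normal(1.0, 0.5) + 0.01 * (age - 70) + 0.05 * sex
        if j in shifted:
            mu = mu + log_shift * is_case
        conc = np.exp(mu + rng.normal(0.0, sigma, n))
        zr = 0.6 if j in low_prevalence else zero_rate
        conc[rng.random(n) < zr] = 0.0
        data[f"met_{j + 1:02d}"] = conc
    return pd.DataFrame(data, index=groups.index), groups, covariates


# ---------------------------------------------------------------------------
# toy host
# ---------------------------------------------------------------------------

@dataclass
class ToyHostSpec:
    """Design of the toy multi-organ host.

    ``branches`` maps branch name to endpoint capacity (mmol/person/day):
    ``serine`` (3pg → ser_L via a phosphoserine-phosphatase-like endpoint),
    ``formaldehyde`` (methanol → formaldehyde → S-formylglutathione →
    formate via an S-formylglutathione-hydrolase-like endpoint),
    ``tryptophan`` (trp_L → N-formylkynurenine via a tryptophan-dioxygenase-
    like endpoint, formate released downstream), and ``methionine_salvage``
    (a diketo-methylthiopentane-degradation-like endpoint). ``basal`` is a
    diet-independent formate source.
    """

    sex: str = "male"
    organs: Tuple[str, ...] = ("liver", "brain", "kidney")
    branches: Dict[str, float] = field(default_factory=lambda: {
        "serine": 5.0, "formaldehyde": 3.0, "tryptophan": 2.0,
        "methionine_salvage": 1.0,
    })
    basal: float = 1.0
    with_nh4_path: bool = True

    def __post_init__(self) -> None:
        known = {"serine", "formaldehyde", "tryptophan", "methionine_salvage"}
        bad = set(self.branches) - known
        if bad:
            raise ValidationError(f"unknown branches: {sorted(bad)}")
        if self.sex not in ("male", "female"):
            raise ValidationError("sex must be 'male' or 'female'")


BRANCH_ENDPOINTS = {
    "serine": "PSP_L",
    "formaldehyde": "SFGTH",
    "tryptophan": "TRPO2",
    "methionine_salvage": "DKMPPD",
}

BRANCH_SUBSTRATES = {
    "serine": "3pg",
    "formaldehyde": "meoh",
    "tryptophan": "trp_L",
    "methionine_salvage": "dkmpp",
}


def make_toy_host(spec: ToyHostSpec = ToyHostSpec()) -> HostModel:
    """Build the toy whole-body-style host.

    Under a diet supplying every branch substrate in excess, the germ-free
    maximal urine formate flux equals the sum of the enabled branch
    capacities plus the basal source (each branch is a 1:1 linear chain
    capped only at its endpoint reaction).
    """
    organ = spec.organs[0] if spec.organs else "liver"
    m = StoichiometricModel(id=f"toy_host_{spec.sex}")

    def met(base: str, tag: str) -> str:
        mid = f"{base}[{tag}]"
        if mid not in m.metabolites:
            m.add_metabolite(Metabolite(mid))
        return mid

    def rxn(rid, stoich, lb=0.0, ub=1000.0, subsystem=""):
        m.add_reaction(Reaction(rid, stoich, lb, ub, subsystem=subsystem))

    def diet_route(base: str, absorb: bool = True) -> None:
        """EX_base[d] -> [luLI] (-> [bc] -> organ when absorbed)."""
        met(base, "d")
        met(base, "luLI")
        rxn(f"EX_{base}[d]", {f"{base}[d]": -1.0}, -1000.0, 1000.0, "exchange, diet")
        rxn(f"DUt_{base}", {f"{base}[d]": -1.0, f"{base}[luLI]": 1.0}, 0.0, 1000.0,
            "transport, diet")
        if absorb:
            absorb_route(base)

    def absorb_route(base: str) -> None:
        met(base, "luLI")
        met(base, "bc")
        met(base, organ)
        if f"LIt_{base}" not in m.reactions:
            rxn(f"LIt_{base}", {f"{base}[luLI]": -1.0, f"{base}[bc]": 1.0}, 0.0, 1000.0,
                "transport, absorption")
            rxn(f"{organ}Up_{base}", {f"{base}[bc]": -1.0, f"{base}[{organ}]": 1.0},
                0.0, 1000.0, "transport, organ uptake")

    # microbiome substrate: reaches the intestinal lumen only
    diet_route("glc_D", absorb=False)
    # nitrogen source (closed in the base diet; used by the ammonium path)
    diet_route("nh4", absorb=spec.with_nh4_path)

    # formate plumbing: lumen absorption, organ -> blood -> urine
    for tag in ("luLI", "bc", organ, "u"):
        met("for", tag)
    rxn("LIt_for", {"for[luLI]": -1.0, "for[bc]": 1.0}, 0.0, 1000.0,
        "transport, absorption")
    rxn("FORt_bc", {f"for[{organ}]": -1.0, "for[bc]": 1.0}, 0.0, 1000.0, "transport")
    rxn("FORt_u", {"for[bc]": -1.0, "for[u]": 1.0}, 0.0, 1000.0, "transport, renal")
    rxn("EX_for[u]", {"for[u]": -1.0}, 0.0, 1000.0, "exchange, urine")

    if spec.basal > 0:
        rxn("FOR_basal", {f"for[{organ}]": 1.0}, 0.0, spec.basal, "basal source")

    # serine can also arrive microbially or as a supplement, independent of
    # the branch endpoint
    diet_route("ser_L")

    # Each branch is a diamond: several feeder reactions converge on the
    # endpoint's substrate and parallel drains (isozymes) carry the product to
    # formate, so the capacity-capped endpoint is the branch's unique
    # single-reaction cut — mirroring why the four endpoints, not their
    # neighbours, form the minimal knockout set.
    caps = spec.branches
    if "serine" in caps:
        diet_route("3pg")
        diet_route("gly")
        for b in ("pser_L", "gly"):
            met(b, organ)
        rxn("PGCD", {f"3pg[{organ}]": -1.0, f"pser_L[{organ}]": 1.0}, 0.0, 1000.0,
            "serine branch")
        rxn("GLYPHOS", {f"gly[{organ}]": -1.0, f"pser_L[{organ}]": 1.0}, 0.0, 1000.0,
            "serine branch")
        rxn("PSP_L", {f"pser_L[{organ}]": -1.0, f"ser_L[{organ}]": 1.0},
            0.0, caps["serine"], "serine branch endpoint")
        rxn("SERFOR1", {f"ser_L[{organ}]": -1.0, f"for[{organ}]": 1.0},
            0.0, 1000.0, "serine branch")
        rxn("SERFOR2", {f"ser_L[{organ}]": -1.0, f"for[{organ}]": 1.0},
            0.0, 1000.0, "serine branch")
        if spec.with_nh4_path:
            # ammonium is not a carbon source but relieves this side path
            rxn("GLYFORN", {f"gly[{organ}]": -1.0, f"nh4[{organ}]": -1.0,
                            f"for[{organ}]": 1.0}, 0.0, 1000.0, "ammonium path")
    if "formaldehyde" in caps:
        diet_route("meoh")
        diet_route("sarcs")
        for b in ("fald", "gthrd", "Sfglutth"):
            met(b, organ)
        absorb_route("fald")
        rxn("ALCD", {f"meoh[{organ}]": -1.0, f"fald[{organ}]": 1.0}, 0.0, 1000.0,
            "formaldehyde branch")
        rxn("SARCOX", {f"sarcs[{organ}]": -1.0, f"fald[{organ}]": 1.0}, 0.0, 1000.0,
            "formaldehyde branch")
        rxn("FALDH1", {f"fald[{organ}]": -1.0, f"gthrd[{organ}]": -1.0,
                       f"Sfglutth[{organ}]": 1.0}, 0.0, 1000.0, "formaldehyde branch")
        rxn("FALDH2", {f"fald[{organ}]": -1.0, f"gthrd[{organ}]": -1.0,
                       f"Sfglutth[{organ}]": 1.0}, 0.0, 1000.0, "formaldehyde branch")
        rxn("SFGTH", {f"Sfglutth[{organ}]": -1.0, f"for[{organ}]": 1.0,
                      f"gthrd[{organ}]": 1.0}, 0.0, caps["formaldehyde"],
            "formaldehyde branch endpoint")
    if "tryptophan" in caps:
        diet_route("trp_L")
        for b in ("Lfmkynr", "lkynr"):
            met(b, organ)
        rxn("TRPO2", {f"trp_L[{organ}]": -1.0, f"Lfmkynr[{organ}]": 1.0},
            0.0, caps["tryptophan"], "tryptophan branch endpoint")
        rxn("FKYNH1", {f"Lfmkynr[{organ}]": -1.0, f"lkynr[{organ}]": 1.0,
                       f"for[{organ}]": 1.0}, 0.0, 1000.0, "tryptophan branch")
        rxn("FKYNH2", {f"Lfmkynr[{organ}]": -1.0, f"lkynr[{organ}]": 1.0,
                       f"for[{organ}]": 1.0}, 0.0, 1000.0, "tryptophan branch")
        rxn("DM_lkynr", {f"lkynr[{organ}]": -1.0}, 0.0, 1000.0, "demand")
    if "methionine_salvage" in caps:
        diet_route("dkmpp")
        met("2kmb", organ)
        rxn("DKMPPD", {f"dkmpp[{organ}]": -1.0, f"for[{organ}]": 1.0,
                       f"2kmb[{organ}]": 1.0}, 0.0, caps["methionine_salvage"],
            "methionine salvage endpoint")
        rxn("DM_2kmb", {f"2kmb[{organ}]": -1.0}, 0.0, 1000.0, "demand")

    # inert candidate for the supplementation screen
    diet_route("lac_D")

    m.objective = "EX_for[u]"
    m.validate()
    return HostModel(base=m, sex=spec.sex, organ_tags=list(spec.organs))


# ---------------------------------------------------------------------------
# diets
# ---------------------------------------------------------------------------

def make_diet(style: str = "full") -> DietSpec:
    """A small deterministic diet.

    ``minimal`` carries the carbon source only; ``full`` additionally
    supplies every toy branch substrate in excess, a nitrogen source, and
    the two bile-acid placeholder entries.
    """
    if style == "minimal":
        return DietSpec(entries={"glc_D": 60.0})
    if style == "full":
        return DietSpec(entries={
            "glc_D": 60.0,
            "nh4": 10.0,
            "3pg": 50.0,
            "gly": 50.0,
            "meoh": 50.0,
            "sarcs": 50.0,
            "trp_L": 50.0,
            "dkmpp": 50.0,
            "chola": 1.0,
            "cdchola": 1.0,
        })
    raise ValidationError(f"unknown diet style {style!r}")


def host_base_diet() -> DietSpec:
    """The germ-free screening diet: full diet minus ammonium, so the
    ammonium-dependent formate path stays closed until the supplementation
    screen opens it and the branch capacities alone set the germ-free
    maximum."""
    diet = make_diet("full")
    diet.entries.pop("nh4", None)
    return diet


def host_run_diet() -> DietSpec:
    """The host-microbiome simulation diet: like the full diet but with
    ammonium at a small, limiting amount — enough for nitrogen-requiring
    community members to grow, low enough that ammonium supplementation
    still raises the formate maximum."""
    diet = make_diet("full")
    diet.entries["nh4"] = 2.0
    return diet


# ---------------------------------------------------------------------------
# hand-solvable co-metabolism fixture
# ---------------------------------------------------------------------------

def make_cometabolism_fixture() -> Tuple[HostModel, CommunityModel, DietSpec]:
    """Host + one-species community with analytically known decomposition.

    The host has a basal formate source of 2 and converts the microbial
    precursor ``prec`` 1:1 into formate; the microbe ferments glucose to
    formate (≤ 3) and to ``prec`` (≤ 4). Hence germ-free max 2,
    personalised max 9, direct microbial secretion 3, co-metabolism
    residual 4.
    """
    m = StoichiometricModel(id="fixture_host")

    def met(mid: str) -> None:
        if mid not in m.metabolites:
            m.add_metabolite(Metabolite(mid))

    for mid in ("glc_D[d]", "glc_D[luLI]", "for[luLI]", "for[bc]", "for[liver]",
                "for[u]", "prec[luLI]", "prec[bc]", "prec[liver]"):
        met(mid)
    m.add_reaction(Reaction("EX_glc_D[d]", {"glc_D[d]": -1.0}, -1000.0, 1000.0))
    m.add_reaction(Reaction("DUt_glc_D", {"glc_D[d]": -1.0, "glc_D[luLI]": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("FOR_basal", {"for[liver]": 1.0}, 0.0, 2.0))
    m.add_reaction(Reaction("LIt_for", {"for[luLI]": -1.0, "for[bc]": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("LIt_prec", {"prec[luLI]": -1.0, "prec[bc]": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("liverUp_prec", {"prec[bc]": -1.0, "prec[liver]": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("PREC2FOR", {"prec[liver]": -1.0, "for[liver]": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("FORt_bc", {"for[liver]": -1.0, "for[bc]": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("FORt_u", {"for[bc]": -1.0, "for[u]": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("EX_for[u]", {"for[u]": -1.0}, 0.0, 1000.0))
    m.objective = "EX_for[u]"
    m.validate()
    host = HostModel(base=m, sex="male")

    microbe = make_toy_microbe("M", formate_rate=3.0, precursors={"prec": 4.0})
    pan = build_pan_model([microbe], "M")
    community = build_community({"M": pan}, {"M": 1.0}, community_id="fixture_community")
    diet = DietSpec(entries={"glc_D": 30.0})
    return host, community, diet
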