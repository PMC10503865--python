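import numpy as np
import pandas as pd
import pytest

from cometab.community import (
    COMMUNITY_BIOMASS_ID,
    CommunityModel,
    build_community,
    denamespace_id,
    filter_and_renormalize,
    namespace_id,
    secretion_profile,
    secretion_profile_frame,
)
from cometab.core import Metabolite, Reaction, StoichiometricModel
from cometab.errors import InfeasibleModelError, ValidationError
from cometab.io import AbundanceTable, DietSpec
from cometab.lp import fva, solve_fba
from cometab.pan import build_pan_model
from cometab.synthetic import make_toy_microbe


def _pan(sid, **kwargs):
    return build_pan_model([make_toy_microbe(sid, **kwargs)], sid)


class TestNamespacing:
    def test_roundtrip(self):
        assert denamespace_id(namespace_id("spA", "GLCt")) == ("spA", "GLCt")

    def test_non_namespaced_rejected(self):
        with pytest.raises(ValidationError):
            denamespace_id("GLCt")

    def test_species_with_separator_rejected(self):
        with pytest.raises(ValidationError):
            build_community({"a__b": _pan("a__b")}, {"a__b": 1.0})


class TestCommunityValidation:
    def test_abundances_must_sum_to_one(self):
        pans = {"A": _pan("A"), "B": _pan("B")}
        with pytest.raises(ValidationError):
            build_community(pans, {"A": 0.4, "B": 0.4})

    def test_missing_model_rejected(self):
        with pytest.raises(ValidationError, match="ghost"):
            build_community({"A": _pan("A")}, {"A": 0.5, "ghost": 0.5})

    def test_zero_abundance_species_skipped(self):
        pans = {"A": _pan("A"), "B": _pan("B")}
        comm = build_community(pans, {"A": 1.0, "B": 0.0})
        assert [sp for sp, _ in comm.species] == ["A"]
        assert not any(r.startswith("B__") for r in comm.base.reactions)


class TestCommunityStructure:
    def setup_method(self):
        self.pans = {
            "A": _pan("A", formate_rate=3.0),
            "B": _pan("B"),
        }
        self.comm = build_community(self.pans, {"A": 0.25, "B": 0.75})

    def test_species_reactions_namespaced(self):
        assert "A__GLCt" in self.comm.base.reactions
        assert "B__GLCt" in self.comm.base.reactions

    def test_extracellular_rewired_to_shared_lumen(self):
        assert "glc_D[luM]" in self.comm.base.metabolites
        assert "glc_D[e]" not in self.comm.base.metabolites
        # species-level boundary exchanges replaced by lumen plumbing
        assert "A__EX_glc_D[e]" not in self.comm.base.reactions

    def test_two_tier_exchange_per_lumen_metabolite(self):
        for rid in ("EX_glc_D[d]", "DUt_glc_D", "UFEt_glc_D", "EX_glc_D[fe]"):
            assert rid in self.comm.base.reactions
        for rid in ("EX_for[d]", "UFEt_for", "EX_for[fe]"):
            assert rid in self.comm.base.reactions

    def test_community_biomass_weighted_by_abundance(self):
        stoich = self.comm.base.reactions[COMMUNITY_BIOMASS_ID].stoichiometry
        assert stoich[self.comm.species_biomass["A"]] == pytest.approx(-0.25)
        assert stoich[self.comm.species_biomass["B"]] == pytest.approx(-0.75)
        assert stoich["microbeBiomass[luM]"] == 1.0

    def test_growth_window_bounds(self):
        cb = self.comm.base.reactions[COMMUNITY_BIOMASS_ID]
        assert cb.lower_bound == pytest.approx(0.4)
        assert cb.upper_bound == pytest.approx(1.0)

    def test_coupling_rows_cover_all_species_reactions(self):
        names = {c.name for c in self.comm.base.extra_constraints}
        for rid in self.comm.base.reactions:
            if "__" in rid and not rid.endswith("biomassPan"):
                assert f"couple_ub::{rid}" in names
                assert f"couple_lb::{rid}" in names
        # the species' own biomass reaction is not coupled to itself
        assert "couple_ub::A__biomassPan" not in names

    def test_community_grows_under_glucose(self):
        from cometab.diet import apply_diet

        model = apply_diet(self.comm.base, DietSpec(entries={"glc_D": 60.0}))
        sol = solve_fba(model, COMMUNITY_BIOMASS_ID, "max")
        assert sol.ok and sol.objective_value == pytest.approx(1.0, abs=1e-6)


class TestCouplingSemantics:
    def _cycle_community(self):
        """One species with an internal 2-cycle only bounded by coupling."""
        m = StoichiometricModel(id="C")
        m.add_metabolite(Metabolite("glc_D[e]"))
        m.add_metabolite(Metabolite("glc_D[c]"))
        m.add_metabolite(Metabolite("x[c]"))
        m.add_metabolite(Metabolite("y[c]"))
        m.add_reaction(Reaction("EX_glc_D[e]", {"glc_D[e]": -1.0}, -1000.0, 1000.0))
        m.add_reaction(Reaction("GLCt", {"glc_D[e]": -1.0, "glc_D[c]": 1.0}, 0.0, 1000.0))
        m.add_reaction(Reaction("biomass", {"glc_D[c]": -1.0}, 0.0, 1000.0))
        m.add_reaction(Reaction("CYC1", {"x[c]": -1.0, "y[c]": 1.0}, 0.0, 1e6))
        m.add_reaction(Reaction("CYC2", {"y[c]": -1.0, "x[c]": 1.0}, 0.0, 1e6))
        m.objective = "biomass"
        pan = build_pan_model([m], "C")
        return build_community({"C": pan}, {"C": 1.0})

    def test_flux_capped_at_coupling_factor_times_biomass(self):
        from cometab.diet import apply_diet

        comm = self._cycle_community()
        model = apply_diet(comm.base, DietSpec(entries={"glc_D": 60.0}))
        # fix the species biomass flux to a known value b
        b = 0.5
        model.reactions[COMMUNITY_BIOMASS_ID].lower_bound = b
        model.reactions[COMMUNITY_BIOMASS_ID].upper_bound = b
        res = fva(model, ["C__CYC1"])
        assert res.maximum("C__CYC1") == pytest.approx(400.0 * b, abs=1e-6)

    def test_zero_biomass_forces_zero_species_flux(self):
        from cometab.diet import apply_diet

        comm = self._cycle_community()
        model = apply_diet(comm.base, DietSpec(entries={"glc_D": 60.0}))
        model.reactions[COMMUNITY_BIOMASS_ID].lower_bound = 0.0
        model.reactions[COMMUNITY_BIOMASS_ID].upper_bound = 0.0
        rids = [r for r in model.reactions if r.startswith("C__")]
        res = fva(model, rids)
        for rid in rids:
            lo, hi = res[rid]
            assert lo == pytest.approx(0.0, abs=1e-6)
            assert hi == pytest.approx(0.0, abs=1e-6)


class TestFilterAndRenormalize:
    def _table(self):
        return AbundanceTable(
            values=pd.DataFrame(
                {"A": [800, 0], "B": [199, 500], "C": [1, 500], "X": [9000, 9000]},
                index=["s1", "s2"],
            ),
            mode="counts",
        )

    def test_coverage_and_cutoff(self):
        filtered, coverage = filter_and_renormalize(
            self._table(), ["A", "B", "C"], cutoff=1e-2
        )
        assert coverage.loc["s1"] == pytest.approx(1000 / 10000)
        # C has relative abundance 1/1000 in s1 -> cut, then renormalised
        assert filtered.values.loc["s1", "C"] == 0.0
        assert filtered.values.loc["s1", "A"] == pytest.approx(800 / 999)
        assert np.allclose(filtered.values.sum(axis=1), 1.0)

    def test_no_covered_species_rejected(self):
        with pytest.raises(ValidationError):
            filter_and_renormalize(self._table(), ["Z"])

    def test_zero_covered_sample_rejected(self):
        t = AbundanceTable(
            values=pd.DataFrame({"A": [10, 0], "X": [5, 5]}, index=["s1", "s2"]),
            mode="counts",
        )
        with pytest.raises(ValidationError, match="s2"):
            filter_and_renormalize(t, ["A"])


class TestSecretionProfile:
    def test_fixture_capacities(self, cometabolism_fixture):
        _, community, diet = cometabolism_fixture
        prof = secretion_profile(community, diet, ["for", "prec", "absent_met"])
        assert prof["for"] == pytest.approx(3.0, abs=1e-6)
        assert prof["prec"] == pytest.approx(4.0, abs=1e-6)
        assert prof["absent_met"] == 0.0
        assert prof.flagged == []

    def test_infeasible_diet_raises_with_hint(self, cometabolism_fixture):
        _, community, _ = cometabolism_fixture
        # no glucose: community biomass lower bound 0.4 cannot be met
        with pytest.raises(InfeasibleModelError, match="check_growth"):
            secretion_profile(community, DietSpec(), ["for"])

    def test_frame_layout(self, cometabolism_fixture):
        _, community, diet = cometabolism_fixture
        prof = secretion_profile(community, diet, ["for"])
        frame = secretion_profile_frame({"s1": prof})
        assert list(frame.columns) == ["sample", "metabolite", "max_secretion"]
        assert frame.iloc[0]["sample"] == "s1"
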