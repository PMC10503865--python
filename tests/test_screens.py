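import pytest

from cometab.errors import ValidationError
from cometab.io import DietSpec
from cometab.screens import (
    KnockoutReport,
    ReactionAnnotation,
    annotate_with_ad,
    exhaustive_min_set,
    knockout_screen,
    minimal_set_search,
    read_annotations,
    supplementation_screen,
)
from cometab.synthetic import BRANCH_ENDPOINTS, ToyHostSpec, make_toy_host

ENDPOINTS = sorted(BRANCH_ENDPOINTS.values())  # DKMPPD, PSP_L, SFGTH, TRPO2


def _candidates(host):
    return [r for r in host.base.reactions
            if host.base.reactions[r].subsystem.endswith("branch")
            or "endpoint" in host.base.reactions[r].subsystem
            or host.base.reactions[r].subsystem == "ammonium path"]


class TestSupplementationScreen:
    def test_expected_pattern(self, toy_host, screen_diet):
        res = supplementation_screen(
            toy_host, screen_diet, ["ser_L", "trp_L", "meoh", "nh4", "lac_D"],
            amount=300.0, target="for",
        )
        # serine feeds formate release directly; its diet route bypasses the
        # capacity-capped branch endpoint, so supply raises the maximum
        assert bool(res.loc["ser_L", "increases"])
        # ammonium is not a carbon source yet opens the ammonium-dependent path
        assert bool(res.loc["nh4", "increases"])
        # tryptophan and methanol routes are already saturated at their
        # endpoint capacities; lactate is inert
        assert not bool(res.loc["trp_L", "increases"])
        assert not bool(res.loc["meoh", "increases"])
        assert not bool(res.loc["lac_D", "increases"])
        assert (res["status"] == "ok").all()
        assert res["baseline"].to_numpy() == pytest.approx(12.0, abs=1e-6)

    def test_non_positive_amount_rejected(self, toy_host, screen_diet):
        with pytest.raises(ValidationError):
            supplementation_screen(toy_host, screen_diet, ["ser_L"], amount=0.0)


class TestKnockoutScreen:
    def test_exact_reductions(self, toy_host, screen_diet):
        ko = knockout_screen(toy_host, screen_diet, _candidates(toy_host), target="for")
        # germ-free baseline: branch capacities 5+3+2+1 plus basal 1
        assert ko.baseline == pytest.approx(12.0, abs=1e-6)
        assert ko.results["PSP_L"][1] == pytest.approx(5 / 12, abs=1e-6)
        assert ko.results["SFGTH"][1] == pytest.approx(3 / 12, abs=1e-6)
        assert ko.results["TRPO2"][1] == pytest.approx(2 / 12, abs=1e-6)
        assert ko.results["DKMPPD"][1] == pytest.approx(1 / 12, abs=1e-6)

    def test_flagging_follows_threshold(self, toy_host, screen_diet):
        ko = knockout_screen(toy_host, screen_diet, _candidates(toy_host),
                             target="for", flag_threshold=0.10)
        # only endpoints with capacity share > 10% are flagged; every feeder
        # and drain has a redundant twin, so their deletions change nothing
        assert ko.flagged == ["PSP_L", "SFGTH", "TRPO2"]
        for rid, (_, red) in ko.results.items():
            if rid not in ENDPOINTS:
                assert red == pytest.approx(0.0, abs=1e-6)

    def test_unknown_candidate_rejected(self, toy_host, screen_diet):
        with pytest.raises(ValidationError):
            knockout_screen(toy_host, screen_diet, ["NOPE"], target="for")

    def test_zero_baseline_rejected(self, screen_diet):
        host = make_toy_host(ToyHostSpec(basal=0.0, branches={}))
        with pytest.raises(ValidationError, match="meaningless"):
            knockout_screen(host, DietSpec(entries={"glc_D": 10.0}),
                            ["LIt_for"], target="for")

    def test_report_frame(self, toy_host, screen_diet):
        ko = knockout_screen(toy_host, screen_diet, ["PSP_L"], target="for")
        df = ko.to_frame()
        assert list(df.columns) == ["ko_flux", "reduction_fraction", "flagged"]
        assert df.loc["PSP_L", "ko_flux"] == pytest.approx(7.0, abs=1e-6)


class TestMinimalSetSearch:
    def test_finds_the_four_endpoints(self, toy_host, screen_diet):
        found, achieved, reached = minimal_set_search(
            toy_host, screen_diet, _candidates(toy_host),
            target="for", goal_reduction=0.85,
        )
        assert sorted(found) == ENDPOINTS
        assert reached
        assert achieved == pytest.approx(11 / 12, abs=1e-6)

    def test_agrees_with_exhaustive_oracle(self, toy_host, screen_diet):
        greedy, _, _ = minimal_set_search(
            toy_host, screen_diet, _candidates(toy_host),
            target="for", goal_reduction=0.85,
        )
        exact, exact_red = exhaustive_min_set(
            toy_host, screen_diet, ENDPOINTS + ["PGCD", "ALCD", "FKYNH1"],
            target="for", goal_reduction=0.85,
        )
        assert len(exact) == len(greedy) == 4
        assert sorted(exact) == ENDPOINTS
        assert exact_red == pytest.approx(11 / 12, abs=1e-6)

    def test_independent_capacity_profile(self, screen_diet):
        # second fixture: capacities (5, 3, 2), no basal source, goal 0.9:
        # all three endpoints are needed, reduction is total
        host = make_toy_host(ToyHostSpec(
            basal=0.0,
            branches={"serine": 5.0, "formaldehyde": 3.0, "tryptophan": 2.0},
        ))
        found, achieved, reached = minimal_set_search(
            host, screen_diet, _candidates(host), target="for", goal_reduction=0.9)
        assert reached
        assert sorted(found) == ["PSP_L", "SFGTH", "TRPO2"]
        assert achieved == pytest.approx(1.0, abs=1e-6)

    def test_unreachable_goal_reported(self, toy_host, screen_diet):
        # basal formate production cannot be knocked out from the candidates
        found, achieved, reached = minimal_set_search(
            toy_host, screen_diet, _candidates(toy_host),
            target="for", goal_reduction=0.99,
        )
        assert not reached
        assert achieved < 0.99

    def test_trivial_goal(self, toy_host, screen_diet):
        found, achieved, reached = minimal_set_search(
            toy_host, screen_diet, _candidates(toy_host),
            target="for", goal_reduction=0.0,
        )
        assert found == [] and reached


class TestAnnotations:
    def _report(self):
        return KnockoutReport(
            target="for", baseline=12.0,
            results={"PSP_L": (7.0, 5 / 12), "ALCD": (12.0, 0.0)},
            flag_threshold=0.10,
        )

    def test_join_and_summary(self):
        anns = [
            ReactionAnnotation("PSP_L", genes="PSPH", ad_association="positive"),
            ReactionAnnotation("ALCD", genes="ADH1B", ad_association="none"),
        ]
        df, summary = annotate_with_ad(self._report(), anns)
        assert df.loc["PSP_L", "ad_association"] == "positive"
        assert summary == {
            "n_candidates": 2, "n_flagged": 1,
            "n_annotated": 1, "n_flagged_and_annotated": 1,
        }

    def test_duplicate_annotations_rejected(self):
        anns = [ReactionAnnotation("PSP_L"), ReactionAnnotation("PSP_L")]
        with pytest.raises(ValidationError):
            annotate_with_ad(self._report(), anns)

    def test_bad_association_rejected(self):
        with pytest.raises(ValidationError):
            ReactionAnnotation("X", ad_association="maybe")

    def test_read_annotations(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "reaction\tgenes\tad_association\tevidence\n"
            "PSP_L\tPSPH\tpositive\tsynthetic\n"
            "ALCD\tADH1B\t\t\n"
        )
        anns = read_annotations(p)
        assert anns[0].ad_association == "positive"
        assert anns[1].ad_association == "none"
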