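import numpy as np
import pandas as pd
import pytest
from scipy import special

from cometab.errors import ValidationError
from cometab.stats import (
    bh_fdr,
    compare_fluxes,
    fractional_regression,
    log_ratio_test,
    screen_metabolites,
    welch_t,
)
from cometab.synthetic import CohortSpec, make_cohort, make_metabolite_cohort


def welch_reference(a, b):
    """Textbook Welch t statistic and two-sided p, written out explicitly."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * special.stdtr(df, -abs(t))
    return t, p


class TestBHFDR:
    def test_hand_example(self):
        # q_i = min_{j >= i} p_(j) * m / j: all three collapse to 0.03
        q = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_second_hand_example(self):
        q = bh_fdr([0.005, 0.04, 0.9])
        assert np.allclose(q, [0.015, 0.06, 0.9])

    def test_order_invariance(self, rng):
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        q = bh_fdr(p)
        q_perm = bh_fdr(p[perm])
        assert np.allclose(q[perm], q_perm)

    def test_monotone_in_p(self, rng):
        p = np.sort(rng.uniform(size=20))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValidationError):
            bh_fdr([0.5, np.nan])

    def test_empty(self):
        assert bh_fdr([]).size == 0


class TestWelch:
    def test_against_textbook_formula(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, 15)
            b = rng.normal(0.5, 2, 9)
            t, p = welch_t(a, b)
            t_ref, p_ref = welch_reference(a, b)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)


class TestScreenMetabolites:
    def test_recovers_planted_shift_and_prevalence_filter(self):
        conc, groups, cov = make_metabolite_cohort(
            n_per_group=40, n_metabolites=8, shifted=(0,), log_shift=-0.5,
            low_prevalence=(5,), seed=3,
        )
        res = screen_metabolites(conc, groups, cov)
        assert bool(res.loc["met_06", "excluded"])  # 60% zeros < 50% prevalence
        assert not bool(res.loc["met_01", "excluded"])
        # planted case decrease: negative estimate, small p
        assert res.loc["met_01", "estimate"] < 0
        assert res.loc["met_01", "p_case"] < 0.01
        assert res.loc["met_01", "q_case"] <= res.loc["met_01", "p_case"] * 7 + 1e-12
        assert np.isnan(res.loc["met_06", "q_case"])

    def test_zeros_treated_as_missing(self):
        conc = pd.DataFrame({
            "m1": [1.0, 2.0, 0.0, 1.5, 2.5, 1.2],
        }, index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["AD"] * 3 + ["control"] * 3, index=conc.index)
        res = screen_metabolites(conc, groups, min_nonzero=0.5)
        assert res.loc["m1", "n_used"] == 5

    def test_negative_concentrations_rejected(self):
        conc = pd.DataFrame({"m1": [-1.0, 2.0]}, index=["a", "b"])
        groups = pd.Series(["AD", "control"], index=conc.index)
        with pytest.raises(ValidationError):
            screen_metabolites(conc, groups)


class TestFractionalRegression:
    def test_recovers_planted_fold_change(self):
        spec = CohortSpec(n_cases=24, n_controls=24, n_species=10,
                          planted_up=("sp_01",), planted_down=("sp_02",), seed=11)
        counts, meta = make_cohort(spec)
        rel = counts.normalize()
        res = fractional_regression(rel.values, meta["group"],
                                    meta[["APOE4"]].astype(float))
        assert res.loc["sp_01", "estimate"] > 0
        assert res.loc["sp_02", "estimate"] < 0
        assert res.loc["sp_01", "p"] < 0.05
        assert res.loc["sp_02", "p"] < 0.05

    def test_presence_filter(self):
        rel = pd.DataFrame({
            "common": [0.5, 0.5, 0.5, 0.5],
            "rare": [0.5, 0.0, 0.0, 0.0],
            "rest": [0.0, 0.5, 0.5, 0.5],
        }, index=[f"s{i}" for i in range(4)])
        groups = pd.Series(["AD", "AD", "control", "control"], index=rel.index)
        res = fractional_regression(rel, groups, min_presence=0.5)
        assert bool(res.loc["rare", "excluded"])
        assert not bool(res.loc["common", "excluded"])

    def test_out_of_range_rejected(self):
        rel = pd.DataFrame({"a": [0.5, 1.5]}, index=["s1", "s2"])
        groups = pd.Series(["AD", "control"], index=rel.index)
        with pytest.raises(ValidationError):
            fractional_regression(rel, groups)


class TestLogRatioTest:
    def test_direction_of_planted_shift(self):
        spec = CohortSpec(n_cases=24, n_controls=24, n_species=10,
                          planted_up=("sp_01",), planted_down=("sp_02",), seed=11)
        counts, meta = make_cohort(spec)
        res = log_ratio_test(counts.values, ["sp_01"], ["sp_02"], meta["group"])
        # cases carry more of the up species relative to the down species
        assert res["group_means"]["AD"] > res["group_means"]["control"]
        assert res["p"] < 0.05

    def test_welch_is_the_underlying_test(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 100, size=(12, 4)),
                              index=[f"s{i}" for i in range(12)],
                              columns=list("abcd"))
        groups = pd.Series(["AD"] * 6 + ["control"] * 6, index=counts.index)
        res = log_ratio_test(counts, ["a"], ["b"], groups, pseudocount=0.5)
        lr = np.log((counts["a"] + 0.5) / (counts["b"] + 0.5))
        t_ref, p_ref = welch_reference(lr[:6], lr[6:])
        assert res["t"] == pytest.approx(t_ref, abs=1e-10)
        assert res["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_empty_sets_rejected(self):
        counts = pd.DataFrame({"a": [1, 2]}, index=["s1", "s2"])
        groups = pd.Series(["AD", "control"], index=counts.index)
        with pytest.raises(ValidationError):
            log_ratio_test(counts, [], ["a"], groups)

    def test_missing_species_rejected(self):
        counts = pd.DataFrame({"a": [1, 2]}, index=["s1", "s2"])
        groups = pd.Series(["AD", "control"], index=counts.index)
        with pytest.raises(ValidationError):
            log_ratio_test(counts, ["a"], ["ghost"], groups)

    def test_more_than_two_groups_rejected(self):
        counts = pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3]},
                              index=["s1", "s2", "s3"])
        groups = pd.Series(["AD", "control", "MCI"], index=counts.index)
        with pytest.raises(ValidationError):
            log_ratio_test(counts, ["a"], ["b"], groups)

    def test_degenerate_constant_ratio(self):
        counts = pd.DataFrame({"a": [2, 2, 2, 2], "b": [3, 3, 3, 3]},
                              index=[f"s{i}" for i in range(4)])
        groups = pd.Series(["AD", "AD", "control", "control"], index=counts.index)
        res = log_ratio_test(counts, ["a"], ["b"], groups)
        assert res["t"] == 0.0 and res["p"] == 1.0


class TestCompareFluxes:
    def test_recovers_group_difference(self, rng):
        n = 30
        groups = pd.Series(["AD"] * n + ["control"] * n,
                           index=[f"s{i}" for i in range(2 * n)])
        fluxes = pd.Series(
            np.r_[rng.normal(10, 1, n), rng.normal(15, 1, n)], index=groups.index
        )
        res = compare_fluxes(fluxes, groups)
        assert res.loc["group_AD", "estimate"] == pytest.approx(-5.0, abs=1.0)
        assert res.loc["group_AD", "p"] < 1e-6
        assert res.loc["group_AD", "ci_low"] < res.loc["group_AD", "estimate"] \
            < res.loc["group_AD", "ci_high"]

    def test_covariates_enter_the_design(self, rng):
        n = 40
        idx = [f"s{i}" for i in range(n)]
        groups = pd.Series(["AD"] * (n // 2) + ["control"] * (n // 2), index=idx)
        cov = pd.DataFrame({"age": rng.normal(70, 5, n)}, index=idx)
        fluxes = pd.Series(rng.normal(0, 1, n) + 0.5 * cov["age"], index=idx)
        res = compare_fluxes(fluxes, groups, cov)
        assert "age" in res.index
        assert res.loc["age", "estimate"] == pytest.approx(0.5, abs=0.1)
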