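"""Joint-genotype strata, RERI/AP/S, ratio of RRs, product-term test, CIs."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edcassoc import (
    FlgNullExposure,
    JointExposureTable,
    LogisticModel,
    RiskTableConfig,
    SimulationConfig,
    SiteExposure,
    UndefinedStatisticError,
    ValidationError,
    additive_interaction,
    interaction_cis,
    interaction_term_test,
    joint_strata,
    multiplicative_interaction,
    simulate_cohort,
    simulate_joint_counts,
    stratum_relative_risks,
)
from edcassoc.cohort import Site

from conftest import FLG2, HRNR

T5_FLG2 = JointExposureTable((71, 18, 3, 11), (70, 13, 2, 0))
T6_FLG2 = JointExposureTable((10, 12, 3, 3), (70, 13, 2, 0))


class TestJointStrata:
    def test_flg2_by_flg_eczema(self, flg2_flg_cohort):
        t = joint_strata(
            flg2_flg_cohort, SiteExposure(FLG2), FlgNullExposure(), "eczema", "all"
        )
        assert t.cases == (71, 18, 3, 11)
        assert t.controls == (70, 13, 2, 0)

    def test_flg2_by_flg_asthma(self, flg2_flg_cohort):
        t = joint_strata(
            flg2_flg_cohort, SiteExposure(FLG2), FlgNullExposure(), "asthma",
            "asthma_or_control",
        )
        assert t.cases == (10, 12, 3, 3)
        assert t.controls == (70, 13, 2, 0)

    def test_constant_second_factor_flagged(self, hrnr_cohort):
        from conftest import SITES, make_subject
        from edcassoc.cohort import Cohort

        subjects = tuple(
            make_subject(f"s{i}", eczema=i % 2 == 0, flg_null=False,
                         **{HRNR: "GC" if i % 3 == 0 else "GG"})
            for i in range(20)
        )
        cohort = Cohort(subjects, {HRNR: SITES[HRNR]})
        t = joint_strata(cohort, SiteExposure(HRNR), FlgNullExposure(), "eczema")
        assert t.cases[2] + t.controls[2] == 0
        assert any("empty stratum" in f for f in t.flags)

    def test_empty_reference_stratum_rejected(self):
        with pytest.raises(ValidationError, match="reference stratum"):
            JointExposureTable((0, 5, 5, 5), (3, 3, 3, 3))


class TestStratumRelativeRisks:
    def test_asthma_block_rrs(self):
        rrs = stratum_relative_risks(T6_FLG2)
        assert rrs.rr10.estimate == pytest.approx(3.84, abs=0.005)
        assert rrs.rr01.estimate == pytest.approx(4.80, abs=0.005)
        assert rrs.rr11.estimate == pytest.approx(8.00, abs=0.005)

    def test_eczema_block_rrs(self):
        rrs = stratum_relative_risks(T5_FLG2)
        assert rrs.rr10.estimate == pytest.approx(1.15, abs=0.005)
        assert rrs.rr01.estimate == pytest.approx(1.19, abs=0.005)
        assert rrs.rr11.estimate == pytest.approx(1.99, abs=0.005)

    def test_hrnr_eczema_block_rrs(self, hrnr_flg_cohort):
        t = joint_strata(
            hrnr_flg_cohort, SiteExposure(HRNR), FlgNullExposure(), "eczema"
        )
        rrs = stratum_relative_risks(t)
        assert rrs.rr10.estimate == pytest.approx(1.47, abs=0.005)
        assert rrs.rr01.estimate == pytest.approx(1.78, abs=0.005)
        assert rrs.rr11.estimate == pytest.approx(2.23, abs=0.005)

    def test_equal_risks_all_unity(self):
        rrs = stratum_relative_risks(JointExposureTable(
            (10, 20, 30, 40), (10, 20, 30, 40)))
        assert rrs.point() == pytest.approx((1.0, 1.0, 1.0))

    def test_zero_control_stratum_degenerate_ci(self):
        rrs = stratum_relative_risks(T6_FLG2)
        assert "degenerate" in rrs.rr11.flags[0]
        assert rrs.rr11.ci_lower < rrs.rr11.estimate

    def test_zero_case_stratum_undefined(self):
        with pytest.raises(UndefinedStatisticError, match="zero cases"):
            stratum_relative_risks(JointExposureTable(
                (10, 0, 3, 4), (10, 5, 3, 4)))


class TestAdditiveMeasures:
    def test_asthma_block(self):
        add = additive_interaction(stratum_relative_risks(T6_FLG2))
        assert add.reri == pytest.approx(0.36, abs=0.005)
        assert add.ap == pytest.approx(0.045, abs=0.0005)
        assert add.s == pytest.approx(1.05, abs=0.005)

    def test_eczema_block(self):
        add = additive_interaction(stratum_relative_risks(T5_FLG2))
        assert add.reri == pytest.approx(0.64, abs=0.005)
        assert add.ap == pytest.approx(0.32, abs=0.005)

    def test_perfect_additivity(self):
        add = additive_interaction((2.0, 3.0, 4.0))
        assert add.reri == pytest.approx(0.0)
        assert add.s == pytest.approx(1.0)

    def test_null_rrs(self):
        add = additive_interaction((1.0, 1.0, 1.0))
        assert add.reri == pytest.approx(0.0)
        assert add.ap == pytest.approx(0.0)
        assert add.s is None  # 0/0: undefined, reported as such

    def test_invalid_rrs_rejected(self):
        with pytest.raises(ValidationError):
            additive_interaction((1.0, -2.0, 3.0))


class TestMultiplicativeMeasures:
    def test_asthma_block_ratio(self):
        assert multiplicative_interaction(
            stratum_relative_risks(T6_FLG2)
        ) == pytest.approx(0.43, abs=0.005)

    def test_eczema_block_ratio(self):
        assert multiplicative_interaction(
            stratum_relative_risks(T5_FLG2)
        ) == pytest.approx(1.45, abs=0.005)

    def test_perfect_multiplicativity(self):
        assert multiplicative_interaction((2.0, 3.0, 6.0)) == pytest.approx(1.0)
        assert multiplicative_interaction((1.0, 1.0, 1.0)) == pytest.approx(1.0)

    @given(
        st.integers(1, 80), st.integers(1, 80), st.integers(1, 80),
        st.integers(1, 80), st.integers(1, 80), st.integers(1, 80),
        st.integers(1, 80), st.integers(1, 80),
    )
    def test_factor_swap_symmetry(self, c00, c10, c01, c11, k00, k10, k01, k11):
        t = JointExposureTable((c00, c10, c01, c11), (k00, k10, k01, k11))
        a1 = additive_interaction(stratum_relative_risks(t))
        a2 = additive_interaction(stratum_relative_risks(t.swap_factors()))
        assert a1.reri == pytest.approx(a2.reri, rel=1e-12)
        assert a1.ap == pytest.approx(a2.ap, rel=1e-12)
        m1 = multiplicative_interaction(stratum_relative_risks(t))
        m2 = multiplicative_interaction(stratum_relative_risks(t.swap_factors()))
        assert m1 == pytest.approx(m2, rel=1e-12)


class TestInteractionTermTest:
    def test_collinear_product_rejected(self):
        """When factor B is constant-true the product term duplicates A and
        must be dropped, not silently fitted."""
        from conftest import SITES, make_subject
        from edcassoc.cohort import Cohort

        subjects = tuple(
            make_subject(f"s{i}", eczema=i % 2 == 0, flg_null=True,
                         **{HRNR: "GC" if i % 3 == 0 else "GG"})
            for i in range(40)
        )
        cohort = Cohort(subjects, {HRNR: SITES[HRNR]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValidationError, match="dropped as degenerate"):
                interaction_term_test(
                    cohort, SiteExposure(HRNR), FlgNullExposure(), "eczema"
                )

    def test_power_under_strong_interaction(self):
        """Product log-odds ln 3 at n = 2000/2000: the Wald test should be
        close to certain to reject (Monte-Carlo power oracle, scaled to 60
        replicates for runtime)."""
        sites = {"s1": Site("A", "B"), "s2": Site("C", "D")}
        rejections = 0
        reps = 60
        for rep in range(reps):
            cfg = SimulationConfig(
                seed=90_000 + rep, n_cases=2000, n_controls=2000,
                sites=sites, allele_freq={"s1": 0.3, "s2": 0.3}, flg_null_freq=0.0,
                eczema_model=LogisticModel(
                    -1.2,
                    {"s1": ("dominant", math.log(2)), "s2": ("dominant", math.log(2))},
                    {("s1", "s2"): math.log(3)},
                ),
            )
            cohort = simulate_cohort(cfg)
            coef, _ = interaction_term_test(
                cohort, SiteExposure("s1"), SiteExposure("s2"), "eczema", method="mle"
            )
            rejections += coef.p < 0.05
        assert rejections / reps > 0.8


class TestInteractionCis:
    WELL_POPULATED = JointExposureTable((200, 80, 70, 90), (300, 60, 90, 40))

    def test_bootstrap_contains_point_estimate(self):
        add = additive_interaction(stratum_relative_risks(self.WELL_POPULATED))
        cis = interaction_cis(self.WELL_POPULATED, method="bootstrap",
                              reps=600, seed=7)
        assert cis["reri"][0] <= add.reri <= cis["reri"][1]
        assert cis["ap"][0] <= add.ap <= cis["ap"][1]

    def test_bootstrap_reproducible(self):
        a = interaction_cis(self.WELL_POPULATED, method="bootstrap", reps=400, seed=3)
        b = interaction_cis(self.WELL_POPULATED, method="bootstrap", reps=400, seed=3)
        assert a == b

    def test_delta_vs_bootstrap_agreement(self):
        """On a well-populated table the delta and bootstrap intervals agree
        within 15% relative width."""
        delta = interaction_cis(self.WELL_POPULATED, method="delta")
        boot = interaction_cis(self.WELL_POPULATED, method="bootstrap",
                               reps=4000, seed=11)
        for key in ("reri", "ap"):
            dw = delta[key][1] - delta[key][0]
            bw = boot[key][1] - boot[key][0]
            assert abs(dw - bw) / dw < 0.15

    def test_zero_cell_falls_back_to_bootstrap(self):
        with pytest.warns(UserWarning, match="falling back to bootstrap"):
            cis = interaction_cis(T6_FLG2, method="delta", reps=400, seed=5)
        assert "reri" in cis

    def test_too_few_bootstrap_reps_rejected(self):
        with pytest.raises(ValidationError, match="at least 200"):
            interaction_cis(self.WELL_POPULATED, method="bootstrap", reps=50, seed=1)

    def test_delta_reri_coverage_under_additive_null(self):
        """Risk-table simulation with exactly additive risks (RERI = 0): the
        delta-method RERI interval should cover 0 at close to the nominal
        95% rate."""
        risks = {(0, 0): 0.10, (1, 0): 0.20, (0, 1): 0.25, (1, 1): 0.35}
        covered = 0
        reps = 300
        for rep in range(reps):
            t = simulate_joint_counts(RiskTableConfig(
                seed=30_000 + rep, n=3000, p_a=0.4, p_b=0.4, risks=risks))
            lo, hi = interaction_cis(t, method="delta")["reri"]
            covered += lo <= 0.0 <= hi
        rate = covered / reps
        band = 2.576 * math.sqrt(0.95 * 0.05 / reps)
        assert abs(rate - 0.95) < band + 1e-9
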