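import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from plexdyn.cohort import CohortSpec, sample_cohort
from plexdyn.stats import (AnalysisConfig, annualized_change, bh_fdr,
                           fit_cross_sectional, fit_longitudinal,
                           run_associations, stepwise_select, zscore)


class TestAnnualizedChange:
    def test_closed_forms(self):
        assert annualized_change([(0.0, 10.0), (0.5, 12.0)]) == pytest.approx(4.0)
        assert annualized_change(
            [(0.0, 10.0), (1.0, 11.0), (1.5, 12.5)]) == pytest.approx(2.0)
        assert annualized_change([(0.0, 10.0)]) is None

    def test_non_increasing_times_error(self):
        with pytest.raises(ValueError, match="increasing"):
            annualized_change([(1.0, 5.0), (1.0, 6.0)])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.tuples(st.floats(-100, 100), st.floats(-100, 100),
                     st.floats(0.1, 10.0)))
    def test_single_interval_equals_two_point_slope(self, tv):
        v0, v1, dt = tv
        got = annualized_change([(0.0, v0), (dt, v1)])
        assert got == pytest.approx((v1 - v0) / dt, rel=1e-9, abs=1e-9)


class TestZscore:
    def test_exact_moments(self, rng):
        z = zscore(rng.uniform(5, 50, 100))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            zscore([3.0])
        with pytest.raises(ValueError):
            zscore([2.0, 2.0, 2.0])


class TestBhFdr:
    def test_worked_example(self):
        got = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])
        assert bh_fdr([0.5, 0.5]) == pytest.approx([0.5, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    def test_matches_brute_force_step_up_on_random_vectors(self, rng):
        """For every q, the step-up rejection set {i: p_(i) <= q i/m} must
        equal {i: adjusted_i <= q}; checked on 1000 random vectors, with
        statsmodels as a second independent reference."""
        for _ in range(1000):
            m = int(rng.integers(1, 21))
            p = np.round(rng.uniform(0, 1, m), 3)
            adj = bh_fdr(p)
            assert np.allclose(adj, multipletests(p, method="fdr_bh")[1])
            for q in (0.01, 0.05, 0.1, 0.25, 0.5):
                order = np.argsort(p)
                ps = p[order]
                passing = np.flatnonzero(ps <= q * np.arange(1, m + 1) / m)
                k = passing.max() + 1 if passing.size else 0
                brute = np.zeros(m, dtype=bool)
                brute[order[:k]] = True
                assert np.array_equal(adj <= q, brute)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 50)
        assert np.all(bh_fdr(p) >= p)


class TestCrossSectional:
    def test_outcome_identical_to_predictor(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=200)})
        df["y"] = df["x"]
        res = fit_cross_sectional(df, "y", "x", covariates=())
        assert res.beta_std == pytest.approx(1.0, abs=1e-10)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_large_sample_recovery(self, big_baseline_cohort):
        res = fit_cross_sectional(big_baseline_cohort.data, "lesion_ml",
                                  "nchpv")
        assert res.beta_std == pytest.approx(0.35, abs=0.02)
        res2 = fit_cross_sectional(big_baseline_cohort.data, "ndgmv", "nchpv")
        assert res2.beta_std == pytest.approx(-0.29, abs=0.02)

    def test_affine_invariance_of_standardized_beta(self, cohort422):
        df = cohort422.data
        a = fit_cross_sectional(df, "lesion_ml", "nchpv")
        df2 = df.copy()
        df2["nchpv"] = 1000.0 * df2["nchpv"] - 3.0
        df2["lesion_ml"] = 0.1 * df2["lesion_ml"] + 55.0
        b = fit_cross_sectional(df2, "lesion_ml", "nchpv")
        assert b.beta_std == pytest.approx(a.beta_std, rel=1e-9)
        assert b.se == pytest.approx(a.se, rel=1e-9)

    def test_null_effect_type_one_error_rate(self):
        """t1t2 -> sdmt has generating beta 0: the adjusted estimate should
        be non-significant (|beta| < 2 SE) in >= 93 of 100 seeded cohorts."""
        hits = 0
        for seed in range(100):
            table = sample_cohort(CohortSpec(seed=20000 + seed))
            res = fit_cross_sectional(table.data, "sdmt", "t1t2")
            hits += abs(res.beta_std) < 2 * res.se
        assert hits >= 93

    def test_collinear_design_rejected(self, cohort422):
        df = cohort422.data.copy()
        df["dup"] = df["nchpv"]
        with pytest.raises(ValueError, match="collinear|too few"):
            fit_cross_sectional(df, "lesion_ml", "nchpv",
                                covariates=("dup",))


class TestLongitudinal:
    def test_time_slope_recovery_within_wald_ci(self, cohort422):
        res = fit_longitudinal(cohort422.data, "nchpv")[0]
        assert res.ci_lo <= 0.45 <= res.ci_hi

    def test_interaction_recovery(self, cohort422):
        res = fit_longitudinal(cohort422.data, "ndgmv",
                               baseline_interaction="t1t2")
        inter = res[-1]
        assert inter.term == "time:t1t2_baseline"
        assert abs(inter.beta_std - (-0.25)) <= 2 * inter.se

    def test_null_slope_coverage(self):
        """sdmt has zero generating time slope; the 95% Wald CI should
        cover 0 in >= 90 of 100 small seeded cohorts."""
        cover = 0
        for seed in range(100):
            table = sample_cohort(CohortSpec(seed=30000 + seed,
                                             n_subjects=120))
            res = fit_longitudinal(table.data, "sdmt")[0]
            cover += res.ci_lo <= 0.0 <= res.ci_hi
        assert cover >= 90

    def test_degenerate_noise_free_model_matches_ols(self, cohort422, rng):
        """With (essentially) zero within-subject noise and no
        subject-level effects the mixed model degenerates and its fixed
        effects must coincide with plain OLS."""
        import statsmodels.formula.api as smf
        df = cohort422.data.copy()
        df["ytest"] = (50.0 + 5.0 * (0.3 * df["time_years"]
                                     + 0.05 * (df["age"] - 40.0))
                       + rng.normal(0, 1e-7, len(df)))
        res = fit_longitudinal(df, "ytest")[0]
        base = df[df.visit == 0]
        df["y_z"] = (df["ytest"] - base["ytest"].mean()) / base["ytest"].std()
        for c in ("age", "disease_duration"):
            bvals = df.groupby("subject_id")[c].transform("first")
            df[c + "_z"] = (bvals - base[c].mean()) / base[c].std()
        ols = smf.ols("y_z ~ time_years + age_z + C(gender) "
                      "+ disease_duration_z + C(dmt_class)", df).fit()
        assert res.beta_std == pytest.approx(ols.params["time_years"],
                                             abs=1e-6)

    def test_requires_repeated_measures(self, cohort422):
        base = cohort422.baseline()
        with pytest.raises(ValueError, match="visits"):
            fit_longitudinal(base, "nchpv")

    def test_ventricle_adjusted_time_effect_stays_positive(self, cohort422):
        cfg = AnalysisConfig(ventricle_adjust=True)
        res = fit_longitudinal(cohort422.data, "nchpv", config=cfg)[0]
        assert res.beta_std > 0
        assert res.p < 0.05


class TestStepwise:
    def test_strong_single_candidate_always_selected(self):
        picked = 0
        for seed in range(40):
            table = sample_cohort(CohortSpec(seed=40000 + seed))
            sel = stepwise_select(table.data, "lesion_ml", ["nchpv"])
            picked += any(r.term == "nchpv" for r in sel)
        assert picked == 40

    def test_null_candidates_rarely_selected(self):
        """With five null predictors of sdmt the per-candidate entry
        probability is ~enter_p; the mean number selected should stay
        near m * enter_p."""
        counts = []
        for seed in range(60):
            table = sample_cohort(CohortSpec(seed=50000 + seed))
            sel = stepwise_select(table.data, "sdmt",
                                  ["t1t2", "nlvv", "ncgmv", "nwmv", "bvmtr"])
            counts.append(len(sel))
        assert 0.0 <= np.mean(counts) <= 0.8

    def test_zero_candidates_gives_covariate_only_model(self, cohort422):
        assert stepwise_select(cohort422.data, "edss", []) == []


def test_run_associations_layout(cohort422):
    out = run_associations(
        cohort422.data,
        tables=("chp_time", "cross_sectional"))
    assert out["chp_time"]["nchpv"][0]["term"] == "time"
    cs = out["cross_sectional"]["nchpv"]["lesion_ml"]
    assert cs["p_fdr"] >= cs["p"]
    assert set(out["cross_sectional"]["nchpv"]) == {
        "nbv", "ncgmv", "ndgmv", "nwmv", "lesion_ml"}
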