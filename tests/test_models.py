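"""Descriptive statistics, stepwise fits, BCa bootstrap, imputation."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hs

import scoretodoor.models as m


def two_group_frame(x0, x1, name="v"):
    return pd.DataFrame(
        {
            "g": [0] * len(x0) + [1] * len(x1),
            name: np.concatenate([x0, x1]),
        }
    )


class TestDescribeCohort:
    def test_fisher_on_published_style_counts(self):
        """72/529 vs 23/103 events gives the exact two-sided p of 0.034."""
        x0 = np.r_[np.ones(72), np.zeros(457)]
        x1 = np.r_[np.ones(23), np.zeros(80)]
        out = m.describe_cohort(two_group_frame(x0, x1), "g")
        row = out[out.variable == "v"].iloc[0]
        assert row.test == "fisher_exact"
        assert row.p == pytest.approx(0.034, abs=5e-4)
        assert row.summary_g1 == "23 (22.3%)"

    def test_identical_continuous_values_give_p_one(self):
        out = m.describe_cohort(two_group_frame([3.0] * 10, [3.0] * 8), "g")
        row = out.iloc[0]
        assert row.p == 1.0 and row.note == "constant variable"

    def test_zero_cell_fisher_is_finite(self):
        x0 = np.zeros(40)
        x1 = np.r_[np.ones(6), np.zeros(4)]
        out = m.describe_cohort(two_group_frame(x0, x1), "g")
        p = out.iloc[0].p
        # oracle: exact hypergeometric point-probability sum for the 2x2 margin
        oracle = st.fisher_exact([[0, 40], [6, 4]], alternative="two-sided")[1]
        assert np.isfinite(p) and p == pytest.approx(oracle)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            m.describe_cohort(two_group_frame([1.0, 2.0], []), "g")

    def test_mann_whitney_matches_exact_enumeration_small_n(self):
        """Exact MWU p for n <= 8 equals full enumeration over assignments."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            n0, n1 = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            pooled = rng.permutation(rng.uniform(0, 1, n0 + n1))  # ties a.s. absent
            x0, x1 = pooled[:n0], pooled[n0:]
            u_obs = st.mannwhitneyu(x0, x1, alternative="two-sided", method="exact")
            # enumeration of all (n0+n1 choose n0) group assignments
            u_stats = []
            for comb in itertools.combinations(range(n0 + n1), n0):
                a = pooled[list(comb)]
                b = np.delete(pooled, list(comb))
                u = sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)
                u_stats.append(u)
            u_stats = np.array(u_stats)
            mu = n0 * n1 / 2
            p_enum = np.mean(np.abs(u_stats - mu) >= abs(u_obs.statistic - mu) - 1e-12)
            out = m.describe_cohort(two_group_frame(x0, x1), "g")
            assert out.iloc[0].p == pytest.approx(p_enum, abs=1e-9)

    def test_fisher_matches_hypergeometric_enumeration_small_n(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            n0, n1 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            x0, x1 = (rng.random(n0) < 0.5).astype(float), (rng.random(n1) < 0.5).astype(float)
            if len(np.unique(np.r_[x0, x1])) < 2:
                continue
            k0, k1 = int(x0.sum()), int(x1.sum())
            # point-probability method over the hypergeometric support
            K, N, n_ = k0 + k1, n0 + n1, n0
            support = range(max(0, K - n1), min(K, n0) + 1)
            pmf = {k: st.hypergeom.pmf(k, N, K, n_) for k in support}
            p_enum = sum(v for k, v in pmf.items() if v <= pmf[k0] * (1 + 1e-9))
            out = m.describe_cohort(two_group_frame(x0, x1), "g")
            assert out.iloc[0].p == pytest.approx(p_enum, rel=1e-6)


class TestScreen:
    def test_forced_exposure_survives_null_effect(self, cohort_medium):
        cohort = cohort_medium.copy()
        rng = np.random.default_rng(0)
        cohort["noise_exposure"] = rng.normal(size=len(cohort))
        spec = m.ModelSpec(outcome="cc_death", candidates=("age", "sofa_day1"),
                           forced=("noise_exposure",), family="logistic")
        model, screen = m.run_stepwise(cohort, spec, bootstrap_B=0)
        assert "noise_exposure" in list(model.terms.term)

    def test_perfect_predictor_dropped_with_warning(self, cohort_medium):
        cohort = cohort_medium.copy()
        cohort["oracle"] = cohort["cc_death"].astype(float)
        spec = m.ModelSpec(outcome="cc_death", candidates=("oracle",), forced=("std_hours",))
        with pytest.warns(UserWarning, match="oracle"):
            screen = m.univariable_screen(cohort, spec)
        assert "oracle" not in screen.retained
        assert not screen.dropped.empty

    def test_constant_candidate_dropped(self, cohort_medium):
        cohort = cohort_medium.copy()
        cohort["flat"] = 1.0
        spec = m.ModelSpec(outcome="cc_death", candidates=("flat",), forced=("std_hours",))
        with pytest.warns(UserWarning):
            screen = m.univariable_screen(cohort, spec)
        assert screen.dropped.iloc[0].reason == "constant predictor"


class TestFitMultivariable:
    def test_logistic_score_equations_vanish_at_optimum(self):
        """MLE first-order conditions hold, and coefficients match an
        independent optimiser, on 50 random small datasets."""
        from scipy.optimize import minimize
        from scipy.special import expit

        rng = np.random.default_rng(11)
        for _ in range(50):
            n = 200
            X = np.c_[np.ones(n), rng.normal(size=(n, 2))]
            beta_true = rng.normal(scale=0.7, size=3)
            y = (rng.random(n) < expit(X @ beta_true)).astype(float)
            df = pd.DataFrame({"y": y, "x1": X[:, 1], "x2": X[:, 2]})
            spec = m.ModelSpec(outcome="y", forced=("x1", "x2"), family="logistic")
            fit = m.fit_multivariable(df, spec, bootstrap_B=0)
            beta = fit.terms.set_index("term").beta
            b = beta[["const", "x1", "x2"]].to_numpy()
            # standardized score equations ~ 0
            score = X.T @ (y - expit(X @ b)) / n
            assert np.abs(score).max() < 1e-6

            def nll(bb):
                lp = X @ bb
                return np.sum(np.logaddexp(0, lp) - y * lp)

            ref = minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-9}).x
            np.testing.assert_allclose(b, ref, atol=1e-4)

    def test_log_linear_requires_positive_outcome(self, cohort_medium):
        cohort = cohort_medium.copy()
        cohort.loc[cohort.index[0], "cc_los_days"] = 0.0
        spec = m.ModelSpec(outcome="cc_los_days", forced=("std_hours",), family="log_linear")
        with pytest.raises(m.FitError, match="positive"):
            m.fit_multivariable(cohort, spec, bootstrap_B=0)

    def test_wald_fallback_labelled(self, cohort_medium):
        spec = m.ModelSpec(outcome="cc_death", forced=("std_hours",), family="logistic")
        fit = m.fit_multivariable(cohort_medium, spec, bootstrap_B=0)
        assert fit.ci_method == "wald"

    def test_bca_seeded_runs_reproducible(self, cohort_medium):
        spec = m.ModelSpec(outcome="cc_death", forced=("std_hours", "sofa_day1"))
        a = m.fit_multivariable(cohort_medium, spec, bootstrap_B=60, seed=9)
        b = m.fit_multivariable(cohort_medium, spec, bootstrap_B=60, seed=9)
        pd.testing.assert_frame_equal(a.terms, b.terms)
        assert a.ci_method == "bca"
        # effect transform sits inside its own interval
        t = a.terms.set_index("term").loc["std_hours"]
        assert t.ci_low <= t.effect <= t.ci_high


class TestBCa:
    def test_matches_scipy_bca_for_the_mean(self):
        """Our BCa interval for a smooth statistic agrees with
        scipy.stats.bootstrap's BCa on the same resamples' scale."""
        rng = np.random.default_rng(21)
        x = rng.lognormal(0.3, 0.6, 150)
        B = 4000
        idx = rng.integers(0, len(x), size=(B, len(x)))
        boot = x[idx].mean(axis=1)
        infl = (x - x.mean()) / len(x)
        lo, hi = m.bca_interval(x.mean(), boot, infl)
        ref = st.bootstrap(
            (x,), np.mean, n_resamples=B, method="BCa", confidence_level=0.95,
            random_state=np.random.default_rng(21),
        ).confidence_interval
        assert lo == pytest.approx(ref.low, rel=0.02)
        assert hi == pytest.approx(ref.high, rel=0.02)

    def test_degenerate_distribution_collapses(self):
        lo, hi = m.bca_interval(1.0, np.ones(100), np.zeros(10))
        assert lo == hi == 1.0


class TestPercentEffect:
    @pytest.mark.parametrize("beta, expected", [(0.012, 1.2), (0.0, 0.0), (-0.079, -7.6)])
    def test_examples(self, beta, expected):
        assert round(m.percent_effect(beta), 1) == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hs.floats(min_value=-99.0, max_value=500.0))
    def test_round_trip(self, p):
        beta = np.log1p(p / 100.0)
        assert m.percent_effect(beta) == pytest.approx(p, abs=1e-9)


class TestImputeMedian:
    def test_definition(self):
        df = pd.DataFrame({"v": [1.0, 2.0, np.nan, 4.0]})
        out = m.impute_median(df)
        assert out["v"].tolist() == [1.0, 2.0, 2.0, 4.0]

    def test_identity_without_missing(self, cohort_medium):
        pd.testing.assert_frame_equal(m.impute_median(cohort_medium), cohort_medium)

    def test_fully_missing_variable_rejected(self):
        with pytest.raises(ValueError, match="v"):
            m.impute_median(pd.DataFrame({"v": [np.nan, np.nan]}))

    def test_sensitivity_flags_stable_under_mcar_missingness(self, cohort_medium):
        """5% random missingness, median-imputed, leaves every final-model
        significance call unchanged."""
        rng = np.random.default_rng(14)
        holey = cohort_medium.copy()
        for col in ("charlson", "frailty", "sofa_day1"):
            mask = rng.random(len(holey)) < 0.05
            holey.loc[mask, col] = np.nan
        spec = m.spec_cc_mortality()
        complete, _ = m.run_stepwise(cohort_medium, spec, bootstrap_B=0)
        imputed, _ = m.run_stepwise(m.impute_median(holey), spec, bootstrap_B=0)
        cmp = m.compare_significance(complete, imputed)
        assert cmp["unchanged"].all(), cmp


def test_forced_exposure_type_one_error_near_nominal():
    """With a null exposure effect in the generating model, the forced
    exposure term reaches p < 0.05 in about 5% of replicates."""
    from scoretodoor.simulate import GeneratorConfig, assign_outcomes

    cfg = GeneratorConfig(seed=0, beta_std=0.0)
    rng = np.random.default_rng(606)
    hits, R, n = 0, 250, 1000
    for rep in range(R):
        truth = pd.DataFrame(
            {
                "patient_id": np.arange(n).astype(str),
                "std_hours": np.exp(rng.normal(np.log(6.3), 0.73, n)),
                "age": np.clip(rng.normal(65, 16, n), 18, 100),
                "sofa_day1": np.clip(np.round(np.exp(rng.normal(np.log(5), 0.73, n))), 0, 24),
                "niv_or_imv": rng.random(n) < 0.43,
                "sepsis": rng.random(n) < 0.36,
            }
        )
        out = assign_outcomes(truth, cfg, rng=int(rng.integers(2**31)))
        df = truth.merge(out, on="patient_id")
        spec = m.ModelSpec(outcome="cc_death", forced=("std_hours", "sofa_day1", "niv_or_imv"))
        fit = m.fit_multivariable(df, spec, bootstrap_B=0)
        hits += fit.terms.set_index("term").loc["std_hours", "p"] < 0.05
    rate = hits / R
    se = np.sqrt(0.05 * 0.95 / R)
    assert abs(rate - 0.05) < 4 * se, rate


class TestBlockSummary:
    def test_single_block(self):
        df = pd.DataFrame({"std_hours": [1.0, 1.5, 0.2], "cc_death": [0, 1, 0], "sofa_day1": [4, 5, 6]})
        out = m.block_summary(df)
        cc = out[out.variable == "cc_death"]
        assert len(cc) == 1 and cc.iloc[0]["mean"] == pytest.approx(1 / 3)

    def test_boundary_clipped_into_final_block(self):
        df = pd.DataFrame({"std_hours": [48.0, 55.0], "cc_death": [1, 0], "sofa_day1": [5, 5]})
        out = m.block_summary(df)
        cc = out[out.variable == "cc_death"].iloc[0]
        assert cc.block_start == 46.0 and cc.n == 2

    def test_single_member_block_has_no_ci(self):
        df = pd.DataFrame({"std_hours": [1.0, 10.0], "cc_death": [1, 0], "sofa_day1": [5, 6]})
        out = m.block_summary(df)
        assert out[out.n == 1]["ci_low"].isna().all()

    def test_uniform_mortality_recovered_within_binomial_error(self):
        rng = np.random.default_rng(5)
        n = 4000
        df = pd.DataFrame(
            {
                "std_hours": rng.uniform(0, 48, n),
                "cc_death": (rng.random(n) < 0.2).astype(float),
                "sofa_day1": rng.integers(2, 9, n),
            }
        )
        out = m.block_summary(df)
        cc = out[out.variable == "cc_death"]
        se = np.sqrt(0.2 * 0.8 / cc["n"])
        assert (np.abs(cc["mean"] - 0.2) < 4 * se).all()
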