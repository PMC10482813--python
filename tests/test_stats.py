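"""Progression regression, omnibus tests, mixed model, mechanical power."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from pao2osc import stats as st
from pao2osc import synthetic as syn


class TestProgressionRegression:
    def test_exact_linear_scores_give_r2_one(self):
        ranks = np.repeat([1, 2, 3, 4, 5], 4)
        scores = 2.0 * ranks - 3.0
        fit = st.progression_regression(scores, ranks)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_null_slope_confidence_coverage(self):
        rng = np.random.default_rng(0)
        covered = 0
        for _ in range(100):
            ranks = np.repeat([1, 2, 3, 4, 5], 17)[:84]
            scores = rng.normal(0, 1, 84)
            fit = scipy.stats.linregress(ranks, scores)
            covered += abs(fit.slope) <= 1.96 * fit.stderr
        assert covered >= 90

    def test_constant_ranks_rejected(self):
        with pytest.raises(ValueError):
            st.progression_regression(np.arange(5.0), np.ones(5))


class TestAnova:
    def test_textbook_example(self):
        values = np.array([1, 2, 3, 2, 3, 4, 6, 7, 8], dtype=float)
        groups = np.repeat(["a", "b", "c"], 3)
        f, p = st.anova_oneway(values, groups)
        assert f == pytest.approx(21.0)

    def test_identical_groups_give_zero_f(self):
        values = np.array([1.0, 2.0, 3.0] * 3)
        groups = np.repeat(["a", "b", "c"], 3)
        f, _ = st.anova_oneway(values, groups)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        f, pf = st.anova_oneway(np.r_[a, b], np.r_[["x"] * 12, ["y"] * 15])
        t, pt = scipy.stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, abs=1e-10)
        assert pf == pytest.approx(pt, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            st.anova_oneway(np.arange(4.0), np.zeros(4))


class TestChiSquare:
    def test_identical_row_proportions_give_zero(self):
        table = np.array([[10, 20, 30], [1, 2, 3]])
        chi2, p = st.chi_square_independence(table)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_2x2(self):
        chi2, _ = st.chi_square_independence(np.array([[10, 0], [0, 10]]))
        assert chi2 == pytest.approx(20.0)

    def test_reported_injury_distribution(self):
        # injured/uninjured counts per morphology cluster along the
        # progression; the omnibus test is significant at ~0.02
        table = np.array([[8, 5, 5, 3, 12], [17, 13, 4, 3, 3]])
        _, p = st.chi_square_independence(table)
        assert p == pytest.approx(0.02, abs=0.005)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        table = rng.integers(1, 30, (3, 4)).astype(float)
        chi2, _ = st.chi_square_independence(table)
        perm = table[[2, 0, 1]][:, [3, 1, 0, 2]]
        chi2p, _ = st.chi_square_independence(perm)
        assert chi2 == pytest.approx(chi2p, abs=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            st.chi_square_independence(np.array([[0, 0], [1, 2]]))


class TestMixedModel:
    def test_recovers_generating_intercept_sd(self):
        df = syn.simulate_progression_outcomes(animal_sd=0.75, seed=1234)
        fit = st.fit_mixed_progression(df)
        assert 0.3 <= fit.random_intercept_sd <= 1.3
        assert fit.n_groups == 7

    def test_zero_effect_generator_gives_null_slopes(self):
        rng_seeds = range(5)
        slopes = []
        for s in rng_seeds:
            df = syn.simulate_progression_outcomes(
                slopes={"pf_kpa": 0.0, "ppv_pct": 0.0}, animal_sd=0.5, seed=400 + s
            )
            fit = st.fit_mixed_progression(df)
            slopes.append(fit.fixed_effects["pf_kpa"])
        assert abs(np.mean(slopes)) < 0.05

    def test_single_animal_is_flagged_singular(self):
        df = syn.simulate_progression_outcomes(n_animals=1, n_conditions=30, seed=9)
        fit = st.fit_mixed_progression(df)
        assert fit.singular
        assert fit.random_intercept_sd == 0.0

    def test_fixed_effect_selection_prefers_true_covariates(self):
        df = syn.simulate_progression_outcomes(
            slopes={"pf_kpa": -0.08, "ppv_pct": 0.0}, animal_sd=0.5,
            noise_sd=0.3, seed=77,
        )
        best, table = st.select_fixed_effects(df, ("pf_kpa", "ppv_pct"))
        assert "pf_kpa" in best
        assert len(table) == 4  # all subsets of two candidates


class TestComparisonTable:
    @pytest.fixture()
    def cohort(self):
        rng = np.random.default_rng(3)
        n_per = 12
        rows = []
        for rank in range(1, 5):
            for i in range(n_per):
                # only the extreme cluster (rank 4) differs
                shift = 5.0 if rank == 4 else 0.0
                rows.append(
                    {
                        "progression_rank": rank,
                        "ppv_pct": 12.0 + shift + rng.normal(0, 1.5),
                        "co": 5.0 + rng.normal(0, 0.5),
                        "injured": bool(rng.integers(0, 2)),
                    }
                )
        return pd.DataFrame(rows)

    def test_table_layout(self, cohort):
        table = st.cluster_comparison_table(
            cohort, numeric=("ppv_pct", "co"), categorical=("injured",)
        )
        assert list(table["covariate"]) == ["ppv_pct", "co", "injured"]
        assert set(table["test"]) == {"anova", "chi_square"}
        assert table["p_value"].between(0, 1).all()

    def test_excluding_extreme_cluster_removes_significance(self, cohort):
        full = st.cluster_comparison_table(cohort, numeric=("ppv_pct",))
        sens = st.sensitivity_excluding_cluster(cohort, 4, numeric=("ppv_pct",))
        p_full = full.loc[full["covariate"] == "ppv_pct", "p_value"].iloc[0]
        p_sens = sens.loc[sens["covariate"] == "ppv_pct", "p_value"].iloc[0]
        assert p_full < 0.001
        assert p_sens > 0.05

    def test_retained_cluster_summaries_unchanged(self, cohort):
        full = st.cluster_comparison_table(cohort, numeric=("ppv_pct",))
        sens = st.sensitivity_excluding_cluster(cohort, 4, numeric=("ppv_pct",))
        for c in (1, 2, 3):
            assert full.loc[0, f"cluster_{c}"] == sens.loc[0, f"cluster_{c}"]

    def test_unknown_cluster_rejected(self, cohort):
        with pytest.raises(ValueError):
            st.sensitivity_excluding_cluster(cohort, 99, numeric=("ppv_pct",))


class TestMechanicalPower:
    def test_zero_tidal_volume_gives_zero(self):
        assert st.mechanical_power_pcv(10, 0.0, 18, 11) == 0.0

    def test_worked_example(self):
        mp = st.mechanical_power_pcv(rr=10, vt=0.397, delta_p_insp=18, peep=11)
        assert mp == pytest.approx(11.3, abs=0.05)

    def test_linearity_in_tidal_volume(self):
        assert st.mechanical_power_pcv(10, 0.8, 15, 5) == pytest.approx(
            2 * st.mechanical_power_pcv(10, 0.4, 15, 5)
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.mechanical_power_pcv(-1, 0.4, 15, 5)
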