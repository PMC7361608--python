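"""Effect sizes, ANOVA/MANOVA, logistic regression, association, correlation."""

import numpy as np
import pandas as pd
import pytest

from opinionet.stats import (
    chi_square_independence, difference_scores, eta_sq_ci, eta_sq_from_wilks,
    logistic_fit, oneway_anova, partial_eta_sq, pearson_corr, wilks_manova,
)


class TestEffectSizeConversions:
    @pytest.mark.parametrize("F, df1, df2, expected, dp", [
        (5.50, 1, 226, 0.024, 3),
        (5.94, 1, 226, 0.026, 3),
        (23.95, 2, 434, 0.10, 2),
        (21.50, 2, 434, 0.09, 2),
    ])
    def test_eta_sq_from_reported_f(self, F, df1, df2, expected, dp):
        assert round(partial_eta_sq(F, df1, df2), dp) == expected

    def test_eta_sq_null_and_errors(self):
        assert partial_eta_sq(0, 3, 100) == 0.0
        with pytest.raises(ValueError):
            partial_eta_sq(1.0, 0, 10)

    @pytest.mark.parametrize("lam, expected", [(0.33, 0.67), (0.85, 0.15), (1.0, 0.0)])
    def test_eta_sq_from_wilks(self, lam, expected):
        assert eta_sq_from_wilks(lam) == pytest.approx(expected)

    def test_wilks_out_of_range(self):
        for bad in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError):
                eta_sq_from_wilks(bad)


class TestEtaSqCI:
    def test_zero_f_floors_at_zero(self):
        lo, hi = eta_sq_ci(0.0, 1, 50, 0.90)
        assert lo == 0.0 and hi == 0.0

    def test_matches_reported_interval(self):
        lo, hi = eta_sq_ci(5.50, 1, 226, 0.90)
        assert lo == pytest.approx(0.002, abs=0.002)
        assert hi == pytest.approx(0.065, abs=0.002)

    def test_interval_brackets_point_estimate(self):
        lo, hi = eta_sq_ci(8.0, 2, 100, 0.90)
        point = partial_eta_sq(8.0, 2, 100)
        assert lo < point < hi

    def test_coverage_smoke(self):
        # a fast 200-replicate version of the full coverage simulation
        rng = np.random.default_rng(0)
        mus, sigma, n = np.array([-0.5, 0.0, 0.5]), 1.0, 20
        true_eta = (np.mean(mus ** 2)) / (np.mean(mus ** 2) + sigma ** 2)
        hits = 0
        for _ in range(200):
            groups = [rng.normal(mu, sigma, n) for mu in mus]
            res = oneway_anova(groups)
            lo, hi = eta_sq_ci(res.F, int(res.df1), int(res.df2), 0.90)
            hits += lo <= true_eta <= hi
        assert 0.85 <= hits / 200 <= 0.95


class TestOneWayAnova:
    def test_hand_decomposition(self):
        res = oneway_anova([[1, 2, 3], [4, 5, 6]])
        assert res.F == pytest.approx(13.5)
        assert (res.df1, res.df2) == (1, 4)
        assert res.eta_sq == pytest.approx(13.5 / (13.5 + 4))  # SSB/(SSB+SSW)

    def test_identical_groups_null(self):
        res = oneway_anova([[1, 2, 3], [1, 2, 3]])
        assert res.F == 0.0 and res.eta_sq == 0.0

    def test_eta_identity_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            groups = [rng.normal(rng.uniform(-1, 1), 1, rng.integers(5, 30))
                      for _ in range(3)]
            res = oneway_anova(groups)
            grand = np.concatenate(groups).mean()
            ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
            ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
            assert res.eta_sq == pytest.approx(ssb / (ssb + ssw), abs=1e-12)

    def test_zero_variance_everywhere_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            oneway_anova([[2, 2], [2, 2]])


# frozen 12-case, 2-outcome, 2-group table for the determinant oracle
MANOVA_Y = np.array([
    [2.1, 3.0], [1.8, 2.6], [2.4, 3.3], [2.0, 2.9], [2.2, 3.4], [1.9, 2.7],
    [3.1, 2.2], [3.4, 2.0], [2.9, 2.5], [3.3, 1.8], [3.0, 2.4], [3.2, 2.1],
])
MANOVA_G = [0] * 6 + [1] * 6


class TestWilksManova:
    def test_single_outcome_reduces_to_anova(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=30)
        groups = np.repeat([0, 1, 2], 10)
        manova = wilks_manova(y, groups)
        anova = oneway_anova([y[groups == g] for g in (0, 1, 2)])
        assert manova.F == pytest.approx(anova.F, rel=1e-12)
        assert manova.p == pytest.approx(anova.p, rel=1e-9)

    def test_lambda_matches_determinant_oracle(self):
        res = wilks_manova(MANOVA_Y, MANOVA_G)
        # independent oracle: explicit E and E+H determinants
        Y, g = MANOVA_Y, np.array(MANOVA_G)
        grand = Y.mean(axis=0)
        T = (Y - grand).T @ (Y - grand)  # total cross-products
        E = sum(((Y[g == v] - Y[g == v].mean(axis=0)).T
                 @ (Y[g == v] - Y[g == v].mean(axis=0))) for v in (0, 1))
        lam_oracle = np.linalg.det(E) / np.linalg.det(T)  # H = T - E
        assert res.wilks_lambda == pytest.approx(lam_oracle, abs=1e-10)
        assert res.eta_sq == pytest.approx(1 - lam_oracle, abs=1e-10)

    def test_against_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        df = pd.DataFrame(MANOVA_Y, columns=["y1", "y2"])
        df["g"] = MANOVA_G
        table = MANOVA.from_formula("y1 + y2 ~ C(g)", data=df).mv_test()
        stats = table.results["C(g)"]["stat"]
        res = wilks_manova(MANOVA_Y, MANOVA_G)
        assert res.wilks_lambda == pytest.approx(stats.loc["Wilks' lambda", "Value"], abs=1e-10)
        assert res.F == pytest.approx(stats.loc["Wilks' lambda", "F Value"], rel=1e-8)

    def test_rao_p_close_to_permutation_p(self):
        rng = np.random.default_rng(8)
        n = 40
        g = np.repeat([0, 1], n // 2)
        Y = rng.normal(size=(n, 2))
        Y[g == 1] += 0.5
        observed = wilks_manova(Y, g)
        perms = 0
        B = 400
        for _ in range(B):
            lam = wilks_manova(Y, rng.permutation(g)).wilks_lambda
            perms += lam <= observed.wilks_lambda
        assert abs(perms / B - observed.p) < 0.05

    def test_singular_error_matrix(self):
        Y = np.column_stack([np.arange(8.0), np.arange(8.0)])  # collinear DVs
        with pytest.raises(np.linalg.LinAlgError):
            wilks_manova(Y, [0, 0, 0, 0, 1, 1, 1, 1])


def test_difference_scores_shape_and_values():
    idx = ["a", "b", "c"]
    w1 = pd.DataFrame({"y": [1.0, 2.0, 3.0]}, index=idx)
    w2 = pd.DataFrame({"y": [2.0, 2.0, 5.0]}, index=idx)
    d = difference_scores([w1, w2])
    assert list(d.columns) == ["y_d1"]
    assert d["y_d1"].tolist() == [1.0, 0.0, 2.0]


class TestLogisticFit:
    def test_odds_ratio_is_exp_of_coefficient(self):
        # the reported B = .164 corresponds to OR = exp(.164) = 1.18
        assert round(float(np.exp(0.164)), 2) == 1.18
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 1))
        y = (rng.uniform(size=400) < 1 / (1 + np.exp(-0.8 * X[:, 0]))).astype(int)
        res = logistic_fit(X, y)
        assert res.or_["x1"] == pytest.approx(np.exp(res.params["x1"]))
        assert res.or_ci.loc["x1", "lo"] < res.or_["x1"] < res.or_ci.loc["x1", "hi"]

    def test_null_model_small_coefficients(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2000, 3))
        y = rng.integers(0, 2, size=2000)
        res = logistic_fit(X, y)
        assert np.abs(res.params.drop("intercept")).max() < 0.15
        assert res.model_chi_sq.p > 0.001

    @pytest.mark.parametrize("seed", range(3))
    def test_parameter_recovery_within_3_se(self, seed):
        rng = np.random.default_rng(seed)
        B = np.array([0.5, -1.0])
        X = rng.normal(size=(5000, 2))
        p = 1 / (1 + np.exp(-(X @ B)))
        y = (rng.uniform(size=5000) < p).astype(int)
        res = logistic_fit(X, y)
        for name, true in zip(["x1", "x2"], B):
            assert abs(res.params[name] - true) < 3 * res.se[name]
        assert 50 < res.pct_correct < 100

    def test_perfect_separation_raises(self):
        X = np.linspace(-2, 2, 40)[:, None]
        y = (X[:, 0] > 0).astype(int)
        with pytest.raises((ValueError, RuntimeError)):
            logistic_fit(X, y)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            logistic_fit(np.random.default_rng(0).normal(size=(10, 1)), np.ones(10))


class TestChiSquare:
    def test_perfect_independence(self):
        assert chi_square_independence([[5, 5], [5, 5]]).statistic == 0.0

    def test_diagonal_table(self):
        res = chi_square_independence([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0) and res.df == 1

    def test_df_for_2x3(self):
        assert chi_square_independence([[1, 2, 3], [4, 5, 6]]).df == 2

    def test_permutation_and_transpose_invariance(self):
        t = np.array([[12, 5, 9], [3, 14, 6]])
        base = chi_square_independence(t).statistic
        assert chi_square_independence(t[::-1]).statistic == pytest.approx(base)
        assert chi_square_independence(t[:, ::-1]).statistic == pytest.approx(base)
        assert chi_square_independence(t.T).statistic == pytest.approx(base)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_independence([[0, 0], [1, 2]])

    def test_matches_scipy(self):
        from scipy.stats import chi2_contingency

        t = [[12, 5, 9], [3, 14, 6]]
        res = chi_square_independence(t)
        ref = chi2_contingency(t, correction=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestPearson:
    def test_exact_linear_relations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_corr(x, x).r == 1.0
        res = pearson_corr(x, [-2 * v + 3 for v in x])
        assert res.r == -1.0 and res.p == 0.0

    def test_hand_value(self):
        res = pearson_corr([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)
        assert res.n == 4

    def test_matches_scipy(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(9)
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = pearson_corr(x, y)
        ref = pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 1, 1], [1, 2, 3])


def test_planted_compliance_effect_recovers_paper_scale_eta():
    """With a planted Cohen's d = 0.3 faction gap at n = 228, the estimated
    eta-squared should centre near 0.02 (between 0.01 and 0.05 in median)."""
    from opinionet.cohort import SyntheticConfig, generate_cohort
    from opinionet.survey import score_scale

    etas = []
    for seed in range(60):
        cfg = SyntheticConfig(n_participants=228, n_waves=1,
                              divergence_schedule=(0.9,), attrition_rate=0.0,
                              attention_fail_rate=0.0, seed=seed)
        waves, truth = generate_cohort(cfg)
        wave = waves[0]
        items = [s.item_id for s in wave.items if s.block == "compliance"]
        score = score_scale(wave, items, "compliance").per_participant_mean
        labels = truth.labels(wave.participant_ids)
        groups = [score.to_numpy()[labels == f] for f in (0, 1)]
        etas.append(oneway_anova(groups).eta_sq)
    assert 0.01 <= float(np.median(etas)) <= 0.05
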