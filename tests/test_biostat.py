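"""Statistical operations against hand arithmetic and enumeration oracles."""

import warnings
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from hgrisk.biostat import (
    InsufficientDataError,
    coefficient_of_variation,
    correlation_matrix,
    mann_whitney_exact,
    mann_whitney_size_contrast,
    normality_gate,
    ols_size_model,
    oneway_anova_tukey,
    pairwise_unadjusted_pvalues,
)
from hgrisk.survey import Specimen, Survey, TissueRecord, \
    assign_size_classes


def _mini_survey(tl, thg, species="Carassius gibelio", organ="muscle",
                 tw=None):
    tw = tw if tw is not None else [10.0 * t for t in tl]
    specs, recs = [], []
    for i, (length, weight, c) in enumerate(zip(tl, tw, thg)):
        sid = f"F{i}"
        specs.append(Specimen(sid, species, "prussian carp", "omnivore",
                              "ivaylovgrad", float(length), float(weight)))
        recs.append(TissueRecord(sid, organ, float(c)))
    return Survey(specs, recs)


class TestNormalityGate:
    def test_symmetric_sample_passes_untransformed(self):
        x = np.random.default_rng(42).normal(10, 1, size=50)
        transformed, out = normality_gate(x)
        assert not transformed
        assert out is x or np.array_equal(out, x)
        # agrees with the reference Shapiro-Wilk decision on this sample
        assert stats.shapiro(x)[1] >= 0.05

    def test_right_skewed_sample_log_transformed(self):
        x = np.random.default_rng(42).lognormal(0, 1.5, size=50)
        transformed, out = normality_gate(x)
        assert transformed
        assert np.allclose(out, np.log10(x))
        assert stats.shapiro(x)[1] < 0.05

    def test_too_small_sample_raises(self):
        with pytest.raises(InsufficientDataError):
            normality_gate([1.0, 2.0])

    def test_nonpositive_with_transform_raises(self):
        x = np.concatenate([
            np.random.default_rng(1).lognormal(0, 2, size=49), [0.0]])
        with pytest.raises(ValueError, match="non-positive"):
            normality_gate(x)


class TestCV:
    def test_constant_sample_zero(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_hand_arithmetic(self):
        # SD({1,2,3}) = 1 with n-1 denominator, mean 2 -> CV 50%
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(
            50.0)

    def test_moment_matched_lognormal_cv(self):
        """A lognormal matched to the pooled muscle moments (mean 0.044,
        SD 0.034) has CV near 77%."""
        mean, sd = 0.044, 0.034
        sigma2 = np.log(1 + (sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2
        x = np.random.default_rng(3).lognormal(mu, np.sqrt(sigma2), 20000)
        assert coefficient_of_variation(x) == pytest.approx(
            100 * sd / mean, rel=0.05)

    def test_zero_mean_raises(self):
        with pytest.raises(ValueError, match="zero mean"):
            coefficient_of_variation([-1.0, 1.0])


class TestAnovaTukey:
    def test_identical_groups_give_zero_f(self):
        res, _ = oneway_anova_tukey([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                                    ["a"] * 3 + ["b"] * 3, gate=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_sum_of_squares(self):
        # {1,2,3} vs {4,5,6}: SSB = 13.5 (df 1), SSW = 4 (df 4) -> F = 13.5
        res, _ = oneway_anova_tukey([1, 2, 3, 4, 5, 6],
                                    ["a"] * 3 + ["b"] * 3, gate=False)
        assert res.statistic == pytest.approx(13.5)

    def test_two_group_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = rng.normal(0, 1, 12)
            labels = np.array(["a"] * 5 + ["b"] * 7)
            res, _ = oneway_anova_tukey(x, labels, gate=False)
            t, _ = stats.ttest_ind(x[labels == "a"], x[labels == "b"])
            assert res.statistic == pytest.approx(t ** 2)

    def test_tukey_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(m, 1, 6) for m in (0, 0.5, 2)])
        labels = np.repeat(["a", "b", "c"], 6)
        _, tukey = oneway_anova_tukey(x, labels, gate=False)
        raw = pairwise_unadjusted_pvalues(x, labels)
        merged = tukey.merge(raw, on=["group1", "group2"])
        assert (merged.p_adj >= merged.p_raw - 1e-12).all()

    def test_species_effect_significant_on_synthetic_muscle(
            self, default_survey):
        df = default_survey.to_frame().query("organ == 'muscle'")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res, _ = oneway_anova_tukey(df.thg_mg_kg_ww, df.species)
        assert res.significant

    def test_undersized_group_raises(self):
        with pytest.raises(InsufficientDataError):
            oneway_anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"],
                               gate=False)


class TestCorrelationMatrix:
    def test_perfect_linearity_r_one(self):
        survey = _mini_survey([10, 20, 30, 40], [0.01, 0.02, 0.03, 0.04])
        mat = correlation_matrix(survey, "tl", "pearson")
        cell = mat[(mat.organ == "muscle")].iloc[0]
        assert cell.r == pytest.approx(1.0)

    def test_antimonotone_spearman_minus_one_pearson_above(self):
        survey = _mini_survey([1, 2, 3], [8, 4, 2])
        pear = correlation_matrix(survey, "tl", "pearson")
        spear = correlation_matrix(survey, "tl", "spearman")
        r = pear[pear.organ == "muscle"].iloc[0].r
        rho = spear[spear.organ == "muscle"].iloc[0].r
        assert rho == pytest.approx(-1.0)
        assert -1.0 < r < 0.0

    def test_small_cells_absent_not_zero(self):
        survey = _mini_survey([10, 20], [0.01, 0.02])
        mat = correlation_matrix(survey, "tl")
        cell = mat[mat.organ == "muscle"].iloc[0]
        assert np.isnan(cell.r) and cell.n == 2

    def test_synthetic_signs_match_configured_slopes(self, default_survey):
        mat = correlation_matrix(default_survey, "tl", "pearson")
        cg = mat[(mat.species == "Carassius gibelio")
                 & (mat.organ == "muscle")].iloc[0]
        pf = mat[(mat.species == "Perca fluviatilis")
                 & (mat.organ == "bones")].iloc[0]
        assert cg.r > 0
        assert pf.r < 0


class TestOlsSizeModel:
    def test_noiseless_tl_recovery(self):
        tl = [10.0, 15.0, 20.0, 25.0, 30.0]
        tw = [105.0, 160.0, 190.0, 260.0, 320.0]  # not collinear with TL
        thg = [0.002 * t + 0.01 for t in tl]
        survey = _mini_survey(tl, thg, tw=tw)
        fit = ols_size_model(survey, "Carassius gibelio")
        assert fit["params"]["tl_cm"] == pytest.approx(0.002, abs=1e-9)
        assert fit["params"]["tw_g"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equation_oracle(self):
        tl = np.array([10.0, 14.0, 21.0, 26.0, 33.0])
        tw = np.array([120.0, 150.0, 230.0, 240.0, 400.0])
        y = np.array([0.02, 0.031, 0.045, 0.04, 0.08])
        X = np.column_stack([np.ones(5), tl, tw])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        survey = _mini_survey(tl, y, tw=tw)
        fit = ols_size_model(survey, "Carassius gibelio")
        assert fit["params"]["const"] == pytest.approx(beta[0])
        assert fit["params"]["tl_cm"] == pytest.approx(beta[1])
        assert fit["params"]["tw_g"] == pytest.approx(beta[2])
        assert 0 < fit["diagnostics"]["max_leverage"] <= 1

    def test_collinear_design_drops_weight(self):
        tl = [10.0, 15.0, 20.0, 25.0, 30.0]
        tw = [100.0, 150.0, 200.0, 250.0, 300.0]  # exactly 10 x TL
        thg = [0.01, 0.02, 0.025, 0.03, 0.05]
        fit = ols_size_model(_mini_survey(tl, thg, tw=tw),
                             "Carassius gibelio")
        assert fit["dropped"] == ["tw_g"]
        assert "tw_g" not in fit["params"]

    def test_slope_recovery_on_inflated_synthetic(self, default_config):
        from dataclasses import replace
        from hgrisk.synthetic import generate_survey
        counts = {k: 100 for k in default_config.n_by_species_reservoir}
        cfg = replace(default_config, n_by_species_reservoir=counts,
                      noise_sd=0.15)
        survey = generate_survey(cfg, seed=21)
        fit = ols_size_model(survey, "Carassius gibelio", log_conc=True)
        beta = cfg.size_effect_slopes[("Carassius gibelio", "muscle")]
        # log10 response: configured natural-log slope / ln(10)
        assert fit["params"]["tl_cm"] == pytest.approx(
            beta / np.log(10), rel=0.10)


def _enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by brute force over assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    m = n1 * len(y)

    def u_stat(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        gt = sum((xi > ys).sum() + 0.5 * (xi == ys).sum() for xi in xs)
        return gt

    u_obs = min(u_stat(range(n1)), m - u_stat(range(n1)))
    count = total = 0
    for ix in combinations(range(len(pooled)), n1):
        u = u_stat(ix)
        if min(u, m - u) <= u_obs + 1e-9:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_balanced_interleaving_u_is_half_product(self):
        x = [1.0, 4.0, 5.0, 8.0]
        y = [2.0, 3.0, 6.0, 7.0]
        res = mann_whitney_exact(x, y)
        assert res.statistic == pytest.approx(8.0)  # n1*n2/2

    def test_fully_separated_exact_p(self):
        res = mann_whitney_exact([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 70)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6), rng.integers(2, 6)
        x = rng.normal(0, 1, n1)
        y = rng.normal(0.8, 1, n2)
        res = mann_whitney_exact(x, y)
        assert res.p_value == pytest.approx(_enumeration_p(x, y))

    def test_size_contrast_requires_both_classes(self, default_survey):
        with pytest.raises(InsufficientDataError):
            mann_whitney_size_contrast(default_survey, "Carassius gibelio")

    def test_size_contrast_on_assigned_classes(self, default_survey):
        survey = assign_size_classes(default_survey, "Carassius gibelio",
                                     reservoir="ivaylovgrad")
        res = mann_whitney_size_contrast(survey, "Carassius gibelio")
        assert 0 <= res.p_value <= 1
        assert res.n == 8
        assert res.statistic <= 16 / 2  # min-U convention caps at n1*n2/2
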