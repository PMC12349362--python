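"""Regression, ANOVA/Tukey letters, t-tests, correlations and level ratios."""

import numpy as np
import pandas as pd
import pytest

from rugosity.errors import (
    DegenerateDesignError,
    InsufficientReplicationError,
    InvalidParameterError,
    MeasurementWarning,
    UndefinedRatioError,
)
from rugosity.stats import (
    add_level_column,
    anova_tukey,
    compact_letter_display,
    fit_ri_sensory_regression,
    level_ratio,
    pairwise_ttest,
    pearson_matrix,
)
from rugosity.synthetic import PopulationConfig, generate_population


class TestRegression:
    def test_exact_linear_fit(self):
        x = np.linspace(0, 5, 20)
        table = pd.DataFrame({"ri_percent": x, "sensory_level": 1 + 0.5 * x})
        fit = fit_ri_sensory_regression(table)
        assert fit.beta0 == pytest.approx(1.0)
        assert fit.beta1 == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_hand_computed_r_squared(self):
        """Four points; r^2 from the definitional Pearson formula is 0.9."""
        table = pd.DataFrame({"ri_percent": [1, 2, 3, 4], "sensory_level": [1, 2, 2, 3]})
        fit = fit_ri_sensory_regression(table)
        # sum of xy deviations = 3, Sxx = 5, Syy = 2 -> r^2 = 9/10
        assert fit.r_squared == pytest.approx(0.9, abs=1e-12)

    def test_r2_equals_squared_pearson(self, default_population):
        fit = fit_ri_sensory_regression(default_population)
        r = np.corrcoef(default_population["ri_percent"], default_population["sensory_level"])[0, 1]
        assert fit.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_constant_x_degenerate(self):
        table = pd.DataFrame({"ri_percent": [2.0, 2.0, 2.0], "sensory_level": [1, 2, 3]})
        with pytest.raises(DegenerateDesignError):
            fit_ri_sensory_regression(table)


class TestAnovaTukey:
    def _table(self, means, sd, n, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for lvl, mu in enumerate(means, start=1):
            for v in rng.normal(mu, sd, n):
                rows.append({"level": lvl, "value": v})
        return pd.DataFrame(rows)

    def test_identical_groups_share_letter(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rows = [{"level": lvl, "value": v} for lvl in (1, 2, 3) for v in base]
        comp = anova_tukey(pd.DataFrame(rows), "value")
        assert comp.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert len(set(comp.letters.values())) == 1

    def test_outlier_group_gets_unique_letter(self):
        comp = anova_tukey(self._table([10, 10, 10, 50], sd=0.1, n=5), "value")
        letters = comp.letters
        assert set(letters[4]).isdisjoint(set(letters[1]) | set(letters[2]) | set(letters[3]))
        assert letters[1] == letters[2] == letters[3]

    def test_letters_consistent_with_adjusted_p(self):
        """Brute-force check of the letter-display contract on a mixed design."""
        comp = anova_tukey(self._table([10.0, 10.4, 12.0, 15.0], sd=0.8, n=6, seed=3), "value")
        padj = {(r.group1, r.group2): r.p_adj for r in comp.tukey.itertuples(index=False)}
        for (a, b), p in padj.items():
            share = bool(set(comp.letters[a]) & set(comp.letters[b]))
            if share:
                assert p >= comp.alpha
            else:
                assert p < comp.alpha
        assert all(len(v) >= 1 for v in comp.letters.values())

    def test_planted_monotone_trend(self):
        table = generate_population(PopulationConfig(n_fruits=120, seed=1).noise_free())
        table = add_level_column(table)
        comp = anova_tukey(table, "RF")
        means = [comp.means[lvl] for lvl in sorted(comp.groups)]
        assert np.all(np.diff(means) < 0)

    def test_insufficient_replication_rejected(self):
        table = pd.DataFrame({"level": [1, 1, 2], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(InsufficientReplicationError):
            anova_tukey(table, "value")


class TestCompactLetterDisplay:
    def test_transitive_chain(self):
        means = {"a": 3.0, "b": 2.0, "c": 1.0}
        reject = {("a", "c"): True, ("a", "b"): False, ("b", "c"): False}
        letters = compact_letter_display(["a", "b", "c"], reject, means)
        assert set(letters["a"]).isdisjoint(letters["c"])
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])

    def test_all_different(self):
        means = {1: 3.0, 2: 2.0, 3: 1.0}
        reject = {(a, b): True for a in means for b in means if a < b}
        letters = compact_letter_display([1, 2, 3], reject, means)
        assert len({frozenset(v) for v in letters.values()}) == 3
        assert letters[1] == "a"  # largest mean lettered first


class TestPairwiseTTest:
    def test_identical_groups(self):
        t, p = pairwise_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.01, 5)
        b = rng.normal(10, 0.01, 5)
        _, p = pairwise_ttest(a, b)
        assert p < 1e-3

    def test_hand_computed_pooled_t(self):
        # means 2.5 vs 3.5, pooled variance 5/3 -> t = -1 / sqrt((5/3)(1/2)) = -1.095445
        t, _ = pairwise_ttest([1, 2, 3, 4], [2, 3, 4, 5])
        assert t == pytest.approx(-1 / np.sqrt(5 / 6), abs=1e-12)

    def test_zero_variance_unequal_means(self):
        with pytest.raises(DegenerateDesignError):
            pairwise_ttest([1.0, 1.0], [2.0, 2.0])


class TestPearsonMatrix:
    def test_self_and_negated(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        table = pd.DataFrame({"x": x, "y": -x, "z": rng.normal(size=30)})
        res = pearson_matrix(table, ["x", "y", "z"])
        assert res.r.loc["x", "x"] == 1.0
        assert res.r.loc["x", "y"] == pytest.approx(-1.0)
        assert res.stars.loc["x", "y"] == "***"

    def test_matches_definitional_covariance(self, rng):
        table = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        res = pearson_matrix(table, list("abcd"))
        for i in "abcd":
            for j in "abcd":
                xi = table[i] - table[i].mean()
                xj = table[j] - table[j].mean()
                r_def = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert res.r.loc[i, j] == pytest.approx(r_def, abs=1e-12)

    def test_symmetry_and_star_thresholds(self, default_population):
        res = pearson_matrix(default_population, ["ri_percent", "RF", "PG", "SF"])
        assert np.allclose(res.r.to_numpy(), res.r.to_numpy().T, equal_nan=True)
        for a in res.p.columns:
            for b in res.p.columns:
                p = res.p.loc[a, b]
                star = res.stars.loc[a, b]
                if p < 0.001:
                    assert star == "***"
                elif p >= 0.05:
                    assert star == "ns"

    def test_constant_column_warns(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(MeasurementWarning):
            res = pearson_matrix(table, ["a", "b"])
        assert np.isnan(res.r.loc["a", "b"])


class TestLevelRatio:
    def test_equal_means(self):
        table = pd.DataFrame({"level": [1, 1, 4, 4], "RF": [5.0, 7.0, 6.0, 6.0]})
        assert level_ratio(table, "RF", 1, 4) == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        table = pd.DataFrame({"level": [1, 4], "RF": [65.5, 10.0]})
        assert level_ratio(table, "RF", 1, 4) == pytest.approx(6.55)

    def test_generator_ratio_exact_without_noise(self):
        table = generate_population(PopulationConfig(n_fruits=300, seed=2).noise_free())
        table = add_level_column(table)
        assert level_ratio(table, "RF", 1, 4) == pytest.approx(6.55)

    def test_zero_denominator(self):
        table = pd.DataFrame({"level": [1, 4], "RF": [5.0, 0.0]})
        with pytest.raises(UndefinedRatioError):
            level_ratio(table, "RF", 1, 4)

    def test_empty_group(self):
        table = pd.DataFrame({"level": [1, 1], "RF": [5.0, 6.0]})
        with pytest.raises(InvalidParameterError):
            level_ratio(table, "RF", 1, 4)
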