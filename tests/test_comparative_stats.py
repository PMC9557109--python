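"""Balanced two-way ANOVA, LSD letters, correlation/regression and difference ranges."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from maizetrial import (
    UnbalancedDesignError,
    lsd_letters,
    linear_regression,
    paired_difference_range,
    pct_difference_range,
    pearson,
    significance_stars,
    two_way_anova,
)
from maizetrial.data_model_io import DomainError


def balanced_frame(n_years=5, n_hyb=2, reps=3, seed=0, effects=True, noise=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for yi in range(n_years):
        for hi in range(n_hyb):
            mu = 10.0 + (yi * 0.7 + hi * 1.3 + yi * hi * 0.2 if effects else 0.0)
            for rep in range(reps):
                rows.append({"year": f"y{yi}", "hybrid": f"h{hi}",
                             "value": mu + rng.normal(0.0, noise)})
    return pd.DataFrame(rows)


def anova_oracle(df):
    """Brute-force balanced decomposition from cell/marginal means."""
    grand = df.value.mean()
    a_means = df.groupby("year").value.mean()
    b_means = df.groupby("hybrid").value.mean()
    cell = df.groupby(["year", "hybrid"]).value.mean()
    n = df.groupby(["year", "hybrid"]).size().iloc[0]
    a, b = len(a_means), len(b_means)
    ss_a = n * b * ((a_means - grand) ** 2).sum()
    ss_b = n * a * ((b_means - grand) ** 2).sum()
    ss_cell = n * ((cell - grand) ** 2).sum()
    ss_ab = ss_cell - ss_a - ss_b
    ss_tot = ((df.value - grand) ** 2).sum()
    ss_err = ss_tot - ss_cell
    df_a, df_b, df_ab, df_err = a - 1, b - 1, (a - 1) * (b - 1), a * b * (n - 1)
    ms_err = ss_err / df_err
    return {
        "year": (ss_a, df_a, (ss_a / df_a) / ms_err),
        "hybrid": (ss_b, df_b, (ss_b / df_b) / ms_err),
        "year:hybrid": (ss_ab, df_ab, (ss_ab / df_ab) / ms_err),
        "error": (ss_err, df_err, np.nan),
    }


class TestTwoWayAnova:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_mean_decomposition_oracle(self, seed):
        df = balanced_frame(seed=seed)
        aov = two_way_anova(df)
        oracle = anova_oracle(df)
        for effect in ("year", "hybrid", "year:hybrid"):
            ss, dof, f = oracle[effect]
            assert aov.table.loc[effect, "ss"] == pytest.approx(ss, abs=1e-9, rel=1e-9)
            assert aov.table.loc[effect, "df"] == dof
            assert aov.table.loc[effect, "F"] == pytest.approx(f, rel=1e-9)
        assert aov.table.loc["error", "ss"] == pytest.approx(oracle["error"][0], abs=1e-9)

    def test_ss_decomposition_conserves_total(self):
        df = balanced_frame(seed=3)
        aov = two_way_anova(df)
        grand = df.value.mean()
        assert aov.table.ss.sum() == pytest.approx(((df.value - grand) ** 2).sum(), rel=1e-9)

    def test_replicate_permutation_within_cells_changes_nothing(self):
        df = balanced_frame(seed=4)
        base = two_way_anova(df).table
        shuffled = df.sample(frac=1.0, random_state=1)  # row order is immaterial
        assert np.allclose(two_way_anova(shuffled).table[["ss", "F"]].values,
                           base[["ss", "F"]].values, equal_nan=True)

    def test_null_data_gives_zero_effect_ss(self):
        df = balanced_frame(effects=False, noise=0.0)
        df["value"] = 7.0
        aov = two_way_anova(df)
        for effect in ("year", "hybrid", "year:hybrid"):
            assert aov.table.loc[effect, "ss"] == pytest.approx(0.0, abs=1e-12)
            assert aov.f(effect) == 0.0

    def test_additive_noise_free_data_flags_zero_error(self):
        df = balanced_frame(n_years=2, n_hyb=2, effects=True, noise=0.0)
        aov = two_way_anova(df)
        assert aov.zero_error
        assert np.isinf(aov.f("year"))

    def test_rejects_unbalanced_and_single_replicate(self):
        df = balanced_frame()
        with pytest.raises(UnbalancedDesignError):
            two_way_anova(df.iloc[:-1])
        with pytest.raises(DomainError):
            two_way_anova(balanced_frame(reps=1))


class TestLsdLetters:
    def test_separated_and_tied_pairs(self):
        g = lsd_letters({"A": 10.0, "B": 2.0}, mse=1.0, df_error=4, n_per_mean=3)
        assert g.letters == {"A": "a", "B": "b"}
        g = lsd_letters({"A": 5.0, "B": 5.0}, mse=1.0, df_error=4, n_per_mean=3)
        assert g.letters == {"A": "a", "B": "a"}

    @pytest.mark.parametrize("seed", range(6))
    def test_grouping_matches_all_pairs_oracle(self, seed):
        """Two treatments share a letter exactly when an LSD pairwise test keeps them together."""
        rng = np.random.default_rng(seed)
        means = {f"t{i}": float(rng.uniform(0, 6)) for i in range(4)}
        mse, dfe, n = 1.4, 16, 3
        g = lsd_letters(means, mse, dfe, n)
        lsd = sps.t.ppf(0.975, dfe) * np.sqrt(2 * mse / n)
        for a, b in itertools.combinations(means, 2):
            share = bool(set(g.letters[a]) & set(g.letters[b]))
            assert share == (abs(means[a] - means[b]) <= lsd + 1e-12), (means, g.letters)

    def test_invalid_alpha(self):
        with pytest.raises(DomainError):
            lsd_letters({"A": 1.0, "B": 2.0}, 1.0, 4, 3, alpha=0.0)


class TestCorrelationRegression:
    def test_perfect_lines(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = pearson(x, x)
        assert r == pytest.approx(1.0)
        r, _ = pearson(x, [-2 * v + 3 for v in x])
        assert r == pytest.approx(-1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.1, 5.0), st.floats(-10.0, 10.0))
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(7)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r0, _ = pearson(x, y)
        r1, _ = pearson(scale * x + shift, y)
        assert r1 == pytest.approx(r0, abs=1e-9)
        r2, _ = pearson(-scale * x, y)
        assert r2 == pytest.approx(-r0, abs=1e-9)

    def test_regression_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = 2.5 * x - 1.0 + rng.normal(size=20)
        a, b, r = linear_regression(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert (a, b) == pytest.approx(tuple(beta), abs=1e-10)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_exact_line_and_degenerate_inputs(self):
        a, b, r = linear_regression([0.0, 1.0, 2.0], [3.0, 5.0, 7.0])
        assert (a, b, r) == pytest.approx((3.0, 2.0, 1.0))
        with pytest.raises(DomainError):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(DomainError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDifferenceRanges:
    def test_percent_range_bounds_every_year(self):
        focal = {"a": 110.0, "b": 126.0, "c": 103.0}
        ref = {"a": 100.0, "b": 120.0, "c": 100.0}
        per_year, lo, hi = pct_difference_range(focal, ref)
        assert lo <= min(per_year.values()) + 0.05 and hi >= max(per_year.values()) - 0.05
        assert per_year["a"] == pytest.approx(10.0)

    def test_identical_series_and_single_year(self):
        per_year, lo, hi = pct_difference_range({"a": 5.0}, {"a": 5.0})
        assert per_year == {"a": 0.0} and lo == hi == 0.0

    def test_paired_difference_and_pairing_error(self):
        per_year, lo, hi = paired_difference_range({"a": 10.0, "b": 12.0}, {"a": 7.0, "b": 13.0})
        assert per_year == {"a": 3.0, "b": -1.0} and (lo, hi) == (-1.0, 3.0)
        with pytest.raises(DomainError):
            paired_difference_range({"a": 1.0}, {"a": 1.0, "b": 2.0})


def test_significance_stars():
    assert significance_stars(0.002) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""
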