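"""Trial statistics: balanced two-way ANOVA, LSD letter groups, Pearson/OLS, difference ranges.

The field design is a balanced year x hybrid factorial with replicated plots;
main effects and their interaction are tested against the within-cell error
(fixed effects).  Hybrid means within a year are separated by the least
significant difference (LSD) at alpha = 0.05; two means share a letter iff
they differ by no more than the LSD.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .data_model_io import DomainError

__all__ = [
    "AnovaTable",
    "LsdGrouping",
    "UnbalancedDesignError",
    "two_way_anova",
    "lsd_letters",
    "pearson",
    "linear_regression",
    "pct_difference_range",
    "paired_difference_range",
    "significance_stars",
    "round_half_up",
]


class UnbalancedDesignError(ValueError):
    """Cell replicate counts are unequal; the balanced decomposition does not apply."""


@dataclass
class AnovaTable:
    """Fixed-effects two-way ANOVA: df, SS, MS, F and p per effect plus error.

    ``table`` is indexed by effect name ("year", "hybrid", "year:hybrid",
    "error") with columns df, ss, ms, F, p.  When the error SS is exactly
    zero (noise-free data) F is infinite for non-null effects and
    ``zero_error`` is set.
    """

    table: pd.DataFrame
    zero_error: bool = False

    def f(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


@dataclass
class LsdGrouping:
    """Mean separation: treatment labels (descending mean order), means, LSD, letters."""

    labels: list[str]
    means: list[float]
    lsd: float
    letters: dict[str, str]


def two_way_anova(data: pd.DataFrame, response: str = "value",
                  factor_a: str = "year", factor_b: str = "hybrid") -> AnovaTable:
    """Balanced fixed-effects two-way ANOVA with interaction.

    ``data`` holds one row per plot with the two factor columns and the
    response.  Requires >= 2 levels per factor, equal replicates per cell and
    >= 2 replicates (otherwise there is no error term).
    """
    df = data[[factor_a, factor_b, response]].copy()
    df.columns = ["A", "B", "y"]
    df["A"] = df["A"].astype(str)
    df["B"] = df["B"].astype(str)

    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise DomainError("need >= 2 levels in each factor")
    counts = df.groupby(["A", "B"]).size()
    if counts.nunique() != 1 or len(counts) != df["A"].nunique() * df["B"].nunique():
        raise UnbalancedDesignError(f"unequal cell sizes: {sorted(counts.unique())}")
    n_rep = int(counts.iloc[0])
    if n_rep < 2:
        raise DomainError("single replicate per cell: no error term")

    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=1)

    ss_err = float(aov.loc["Residual", "sum_sq"])
    ss_scale = max(1.0, float(df["y"].abs().max()) ** 2 * len(df))
    tol = 1e-12 * ss_scale
    zero_error = ss_err <= tol
    rows = {}
    name_map = {"C(A)": "year" if factor_a == "year" else factor_a,
                "C(B)": "hybrid" if factor_b == "hybrid" else factor_b}
    inter_name = f"{name_map['C(A)']}:{name_map['C(B)']}"
    for src, out in [("C(A)", name_map["C(A)"]), ("C(B)", name_map["C(B)"]),
                     ("C(A):C(B)", inter_name)]:
        ss = float(aov.loc[src, "sum_sq"])
        dof = float(aov.loc[src, "df"])
        ms = ss / dof
        if zero_error:
            fval = math.inf if ss > tol else 0.0
            pval = 0.0 if ss > tol else 1.0
        else:
            fval = float(aov.loc[src, "F"])
            pval = float(aov.loc[src, "PR(>F)"])
        rows[out] = dict(df=dof, ss=ss, ms=ms, F=fval, p=pval)
    dof_err = float(aov.loc["Residual", "df"])
    rows["error"] = dict(df=dof_err, ss=ss_err, ms=ss_err / dof_err, F=math.nan, p=math.nan)
    return AnovaTable(table=pd.DataFrame(rows).T[["df", "ss", "ms", "F", "p"]],
                      zero_error=zero_error)


def lsd_letters(means: Mapping[str, float], mse: float, df_error: float,
                n_per_mean: int, alpha: float = 0.05) -> LsdGrouping:
    """LSD mean separation with compact letters.

    LSD = t(1−alpha/2, df_error)·√(2·MSE/n).  Treatments are sorted by
    descending mean (ties by label); letter groups are the maximal runs of
    consecutive means whose extremes differ by at most the LSD, so two
    treatments share a letter iff |mean difference| ≤ LSD.
    """
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    if mse < 0 or df_error < 1 or n_per_mean < 2:
        raise DomainError("need mse >= 0, df_error >= 1, n >= 2")
    lsd = float(stats.t.ppf(1.0 - alpha / 2.0, df_error)) * math.sqrt(2.0 * mse / n_per_mean)

    order = sorted(means, key=lambda k: (-means[k], k))
    vals = [means[k] for k in order]
    m = len(order)

    # Letter groups are maximal runs [i, j] with vals[i] - vals[j] <= LSD.
    # With vals descending the run end j(i) is nondecreasing in i, so a run is
    # maximal exactly when its end advances past the previous run's end.
    tol = 1e-12 * max(1.0, abs(lsd))
    ends = []
    for i in range(m):
        j = i
        while j + 1 < m and vals[i] - vals[j + 1] <= lsd + tol:
            j += 1
        ends.append(j)
    runs = [(i, j) for i, j in enumerate(ends) if i == 0 or j > ends[i - 1]]
    letters = {k: "" for k in order}
    for letter, (i, j) in zip(string.ascii_lowercase, runs):
        for k in range(i, j + 1):
            letters[order[k]] += letter
    return LsdGrouping(labels=order, means=vals, lsd=lsd, letters=letters)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p (t transform, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DomainError("need equal-length sequences with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def linear_regression(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """OLS line y = a + b·x; returns (intercept a, slope b, correlation r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DomainError("need equal-length sequences with n >= 3")
    if np.ptp(x) == 0:
        raise DomainError("x is constant")
    res = stats.linregress(x, y)
    return float(res.intercept), float(res.slope), float(res.rvalue)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at 1 digit rounds to 0.1), as trial reports print."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def pct_difference_range(focal: Mapping[str, float], reference: Mapping[str, float]
                         ) -> tuple[dict[str, float], float, float]:
    """Per-year percent difference of a focal vs a reference hybrid, with its range.

    Returns ({year: raw %}, min %, max %); the min/max are rounded half-up to
    one decimal for report parity, per-year values keep full precision.
    """
    if set(focal) != set(reference):
        raise DomainError("focal and reference must cover the same years")
    per_year = {}
    for year in focal:
        ref = reference[year]
        if ref <= 0:
            raise DomainError(f"{year}: reference value must be positive, got {ref}")
        per_year[year] = 100.0 * (focal[year] - ref) / ref
    lo = round_half_up(min(per_year.values()), 1)
    hi = round_half_up(max(per_year.values()), 1)
    return per_year, lo, hi


def paired_difference_range(focal: Mapping[str, float], reference: Mapping[str, float]
                            ) -> tuple[dict[str, float], float, float]:
    """Per-year difference (focal − reference) in native units, with min/max (half-up, 1 dp)."""
    missing = set(focal) ^ set(reference)
    if missing:
        raise DomainError(f"years present on one side only: {sorted(missing)}")
    per_year = {year: focal[year] - reference[year] for year in focal}
    lo = round_half_up(min(per_year.values()), 1)
    hi = round_half_up(max(per_year.values()), 1)
    return per_year, lo, hi


def significance_stars(p: float) -> str:
    """Table notation: ** for p < 0.01, * for p < 0.05, empty otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
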