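"""Association statistics between rugosity and texture/biochemical indicators.

Covers the validation regression of sensory grade on the rugosity index,
per-level one-way ANOVA with Tukey HSD and a compact letter display, plain
two-group Student t-tests, the pairwise Pearson correlation matrix with
significance stars, and ratios of level means (e.g. the rupture-force ratio
between smooth and highly rugose fruits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .contour import DEFAULT_LEVEL_SCHEME, LevelScheme, classify_level
from .errors import (
    DegenerateDesignError,
    InsufficientReplicationError,
    InvalidParameterError,
    MeasurementWarning,
    UndefinedRatioError,
)

__all__ = [
    "RegressionFit",
    "GroupComparison",
    "CorrelationResult",
    "add_level_column",
    "fit_ri_sensory_regression",
    "anova_pvalue",
    "anova_tukey",
    "compact_letter_display",
    "pairwise_ttest",
    "pearson_matrix",
    "level_ratio",
]


@dataclass(frozen=True)
class RegressionFit:
    """Simple linear regression summary (sensory grade ~ RI)."""

    beta0: float
    beta1: float
    r_squared: float
    p_value_slope: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA with Tukey HSD letters for one indicator across levels."""

    indicator: str
    groups: tuple
    means: dict
    sems: dict
    ns: dict
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # columns: group1, group2, p_adj, reject
    letters: dict
    alpha: float


@dataclass(frozen=True)
class CorrelationResult:
    """Pairwise Pearson correlations with p-values and significance stars."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long-format ``var1,var2,r,p,stars`` table (upper triangle)."""
        rows = []
        cols = list(self.r.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rows.append(
                    {
                        "var1": a,
                        "var2": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "stars": self.stars.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def add_level_column(
    table: pd.DataFrame,
    ri_col: str = "ri_percent",
    scheme: LevelScheme = DEFAULT_LEVEL_SCHEME,
    out_col: str = "level",
) -> pd.DataFrame:
    """Classify each fruit's RI into a rugosity level (new ``level`` column)."""
    out = table.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MeasurementWarning)
        out[out_col] = [classify_level(v, scheme) for v in out[ri_col]]
    return out


def fit_ri_sensory_regression(
    table: pd.DataFrame,
    ri_col: str = "ri_percent",
    sensory_col: str = "sensory_level",
) -> RegressionFit:
    """OLS of sensory grade (Y) on rugosity index (X).

    The sensory grade is treated as numeric 1-4.  For simple regression the
    returned R-squared equals the squared Pearson correlation of X and Y.
    """
    sub = table[[ri_col, sensory_col]].dropna()
    x = sub[ri_col].to_numpy(float)
    y = sub[sensory_col].to_numpy(float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidParameterError("regression inputs must be finite")
    if x.size < 3:
        raise InvalidParameterError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("RI has zero variance; slope is unidentifiable")
    res = sps.linregress(x, y)
    return RegressionFit(
        beta0=float(res.intercept),
        beta1=float(res.slope),
        r_squared=float(res.rvalue**2),
        p_value_slope=float(res.pvalue),
        n=int(x.size),
    )


def _grouped_values(
    table: pd.DataFrame, indicator: str, group_col: str
) -> tuple[list, list[np.ndarray]]:
    sub = table[[group_col, indicator]].dropna()
    keys = sorted(sub[group_col].unique())
    values = [sub.loc[sub[group_col] == k, indicator].to_numpy(float) for k in keys]
    return keys, values


def anova_pvalue(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value for a list of group samples."""
    if len(groups) < 2:
        raise InsufficientReplicationError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise InsufficientReplicationError("every group needs at least two observations")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def compact_letter_display(
    groups: Sequence, reject: dict[tuple, bool], means: dict
) -> dict:
    """Insert-and-absorb compact letter display.

    ``reject[(a, b)]`` is True when groups a and b differ significantly.
    Guarantees: significantly different groups share no letter;
    non-significantly different groups share at least one.  Groups are
    lettered in order of descending mean so 'a' marks the largest mean.
    """
    ordered = sorted(groups, key=lambda g: (-means[g], str(g)))
    columns: list[set] = [set(ordered)]
    for a, b in combinations(ordered, 2):
        if not reject.get((a, b), reject.get((b, a), False)):
            continue
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb columns that became subsets of another
        columns = [
            c
            for i, c in enumerate(columns)
            if c and not any(i != j and c <= d and (c < d or i > j) for j, d in enumerate(columns))
        ]
    # deterministic letter order: columns sorted by their best (largest-mean) member
    rank = {g: i for i, g in enumerate(ordered)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        for g in ordered:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def anova_tukey(
    table: pd.DataFrame,
    indicator: str,
    group_col: str = "level",
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA followed by Tukey HSD with a compact letter display.

    Unequal group sizes are handled by the Tukey-Kramer adjustment (as
    implemented in statsmodels), appropriate for unbalanced level groups in a
    segregating population.
    """
    keys, values = _grouped_values(table, indicator, group_col)
    if len(keys) < 2:
        raise InsufficientReplicationError(
            f"{indicator}: need >= 2 groups, got {len(keys)}"
        )
    for k, v in zip(keys, values):
        if v.size < 2:
            raise InsufficientReplicationError(
                f"{indicator}: group {k!r} has {v.size} observation(s); need >= 2"
            )
    f, p = anova_pvalue(values)

    endog = np.concatenate(values)
    labels = np.concatenate([[str(k)] * v.size for k, v in zip(keys, values)])
    if np.ptp(endog) == 0:
        # all observations identical: Tukey is vacuous, everything shares a letter
        tukey_table = pd.DataFrame(
            [
                {"group1": a, "group2": b, "p_adj": 1.0, "reject": False}
                for a, b in combinations(keys, 2)
            ]
        )
    else:
        res = pairwise_tukeyhsd(endog, labels, alpha=alpha)
        frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        str2key = {str(k): k for k in keys}
        tukey_table = pd.DataFrame(
            {
                "group1": [str2key[str(v)] for v in frame["group1"]],
                "group2": [str2key[str(v)] for v in frame["group2"]],
                "p_adj": res.pvalues.astype(float),
                "reject": res.reject.astype(bool),
            }
        )
    reject = {
        (r.group1, r.group2): bool(r.reject) for r in tukey_table.itertuples(index=False)
    }
    means = {k: float(v.mean()) for k, v in zip(keys, values)}
    sems = {k: float(sps.sem(v)) if v.size > 1 else np.nan for k, v in zip(keys, values)}
    ns = {k: int(v.size) for k, v in zip(keys, values)}
    letters = compact_letter_display(keys, reject, means)
    return GroupComparison(
        indicator=indicator,
        groups=tuple(keys),
        means=means,
        sems=sems,
        ns=ns,
        f_statistic=f,
        p_value=p,
        tukey=tukey_table,
        letters=letters,
        alpha=alpha,
    )


def pairwise_ttest(
    group_a: np.ndarray,
    group_b: np.ndarray,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided Student's t-test between two groups (pooled variance by default).

    Set ``equal_var=False`` for the Welch variant.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicationError("each group needs at least two observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise DegenerateDesignError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pearson_matrix(table: pd.DataFrame, indicators: Sequence[str]) -> CorrelationResult:
    """Pairwise-complete Pearson correlations with significance stars.

    Stars follow the conventional thresholds 0.05 / 0.01 / 0.001 with no
    multiplicity correction across the matrix.  Pairs with fewer than three
    complete rows or a constant column are reported as missing with a
    warning.
    """
    cols = list(indicators)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    stars = pd.DataFrame("", index=cols, columns=cols)
    np.fill_diagonal(p.values, 0.0)
    for c in cols:
        stars.loc[c, c] = "***"
    for a, b in combinations(cols, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            warnings.warn(
                f"pair ({a}, {b}): fewer than 3 complete rows; correlation undefined",
                MeasurementWarning,
                stacklevel=2,
            )
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        xa = sub[a].to_numpy(float)
        xb = sub[b].to_numpy(float)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            warnings.warn(
                f"pair ({a}, {b}): constant column; correlation undefined",
                MeasurementWarning,
                stacklevel=2,
            )
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        res = sps.pearsonr(xa, xb)
        r.loc[a, b] = r.loc[b, a] = float(res.statistic)
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
        stars.loc[a, b] = stars.loc[b, a] = _stars(float(res.pvalue))
    return CorrelationResult(r=r, p=p, stars=stars)


def level_ratio(
    table: pd.DataFrame,
    indicator: str,
    level_a: int,
    level_b: int,
    group_col: str = "level",
) -> float:
    """Ratio of group means ``mean(level_a) / mean(level_b)`` for one indicator."""
    va = table.loc[table[group_col] == level_a, indicator].dropna().to_numpy(float)
    vb = table.loc[table[group_col] == level_b, indicator].dropna().to_numpy(float)
    if va.size == 0 or vb.size == 0:
        raise InvalidParameterError(
            f"{indicator}: empty group(s) for levels {level_a}/{level_b}"
        )
    denom = float(vb.mean())
    if denom == 0.0:
        raise UndefinedRatioError(f"{indicator}: level {level_b} mean is zero")
    return float(va.mean()) / denom
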