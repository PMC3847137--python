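"""Distribution-aware cohort statistics.

Implements the analysis battery applied to the four-cell cohort
(metabolic syndrome x prior myocardial infarction):

* :func:`choose_test` / :func:`compare_groups` — Shapiro-Wilk normality
  per group, then Welch t-test or one-way ANOVA for normal data and
  Mann-Whitney U or Kruskal-Wallis otherwise, all two-tailed.
* :func:`categorical_test` — chi-square for contingency tables, Fisher's
  exact test for 2x2 tables with any expected cell count below 5.
* :func:`fit_infarct_regression` — ordinary least squares for scar burden
  with a pairwise collinearity screen: a candidate predictor whose
  absolute correlation with an already-included predictor exceeds the
  threshold (default 0.7) is excluded and reported with its offending
  partner (mirrors dropping waist circumference and hypertension when
  indexed ITFV is in the model).
* :func:`bland_altman` — method-agreement analysis of paired repeated
  measurements: bias (mean difference, first minus second), SD of the
  differences (n-1 denominator), limits of agreement bias +/- 1.96 SD,
  and the Pearson correlation of the pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

DEFAULT_ALPHA_NORMALITY = 0.05
DEFAULT_COLLINEARITY_R = 0.7


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    normal: bool


@dataclass
class GroupComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    groups: list[GroupSummary]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:  # Shapiro-Wilk undefined for constant samples
        return False
    return bool(sps.shapiro(x).pvalue >= alpha)


def choose_test(samples: Sequence[np.ndarray],
                alpha_norm: float = DEFAULT_ALPHA_NORMALITY) -> str:
    """Pick the comparison test from arity and per-group normality.

    All groups Shapiro-Wilk-normal at ``alpha_norm``: "t" (2 groups) or
    "anova" (more).  Otherwise "mann-whitney" or "kruskal-wallis".
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    for arr in arrays:
        if len(arr) < 3:
            raise ValueError("each group needs n >= 3")
    all_normal = all(_is_normal(a, alpha_norm) for a in arrays)
    if len(arrays) == 2:
        return "t" if all_normal else "mann-whitney"
    return "anova" if all_normal else "kruskal-wallis"


def compare_groups(cohort: pd.DataFrame,
                   variable: str,
                   grouping: str = "group",
                   alpha_norm: float = DEFAULT_ALPHA_NORMALITY,
                   equal_var: bool = False) -> GroupComparisonResult:
    """Two-tailed comparison of ``variable`` across the levels of ``grouping``.

    The test is selected by :func:`choose_test`; the t-test defaults to
    the Welch (unequal-variance) form.  Missing values are dropped per
    subject.  If every group has zero variance the comparison is reported
    as degenerate instead of a test result.
    """
    if variable not in cohort.columns:
        raise ValueError(f"variable {variable!r} not in cohort")
    df = cohort[[grouping, variable]].dropna()
    labels = list(pd.unique(df[grouping]))
    arrays = [df.loc[df[grouping] == g, variable].to_numpy(float) for g in labels]

    summaries = [GroupSummary(label=str(g), n=len(a), mean=float(a.mean()),
                              sd=float(a.std(ddof=1)) if len(a) > 1 else 0.0,
                              median=float(np.median(a)), min=float(a.min()),
                              max=float(a.max()),
                              normal=bool(len(a) >= 3 and _is_normal(a, alpha_norm)))
                 for g, a in zip(labels, arrays)]

    if all(np.ptp(a) == 0 for a in arrays):
        return GroupComparisonResult(test_name="degenerate", statistic=math.nan,
                                     p_value=math.nan, groups=summaries,
                                     degenerate=True)

    name = choose_test(arrays, alpha_norm)
    if name == "t":
        res = sps.ttest_ind(arrays[0], arrays[1], equal_var=equal_var)
    elif name == "mann-whitney":
        res = sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
    elif name == "anova":
        res = sps.f_oneway(*arrays)
    else:
        res = sps.kruskal(*arrays)
    return GroupComparisonResult(test_name=name, statistic=float(res.statistic),
                                 p_value=float(res.pvalue), groups=summaries)


def categorical_test(table: np.ndarray) -> tuple[str, float, float]:
    """Chi-square or Fisher's exact test on an r x c count table.

    Fisher's exact test is used for 2x2 tables with any expected cell
    count below 5; otherwise the chi-square test.  Returns
    ``(test_name, statistic, p)`` (Fisher's statistic is the odds ratio).
    """
    table = np.asarray(table)
    if table.size == 0 or table.ndim != 2:
        raise ValueError("table must be a non-empty 2-D array of counts")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    total = table.sum()
    if total == 0:
        raise ValueError("empty table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if table.shape == (2, 2) and (expected < 5).any():
        odds, p = sps.fisher_exact(table)
        return "fisher", float(odds), float(p)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return "chi-square", float(chi2), float(p)


# ---------------------------------------------------------------------------
# Multivariable regression with collinearity screening
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    outcome: str
    included: list[str]
    excluded: list[tuple[str, str, float]]  # (predictor, partner, |r|)
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    n: int
    r_squared: float

    def __post_init__(self) -> None:
        overlap = set(self.included) & {name for name, _, _ in self.excluded}
        if overlap:
            raise ValueError(f"predictors both included and excluded: {overlap}")


def _encode_predictors(cohort: pd.DataFrame,
                       predictors: Sequence[str]) -> pd.DataFrame:
    """Numeric design columns: booleans to 0/1, categoricals to dummies."""
    cols = {}
    for name in predictors:
        if name not in cohort.columns:
            raise ValueError(f"predictor {name!r} not in cohort")
        col = cohort[name]
        if col.dtype == bool:
            cols[name] = col.astype(float)
        elif pd.api.types.is_numeric_dtype(col):
            cols[name] = col.astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for dname in dummies.columns:
                cols[dname] = dummies[dname].astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def fit_infarct_regression(cohort: pd.DataFrame,
                           outcome: str = "scar_pct",
                           predictors: Sequence[str] = ("indexed_itfv", "age",
                                                        "sex", "race", "bmi",
                                                        "diabetes", "gfr"),
                           collinearity_r: float = DEFAULT_COLLINEARITY_R,
                           ) -> RegressionResult:
    """OLS for ``outcome`` with a sequential pairwise collinearity screen.

    Candidates are considered in the order given; a candidate whose
    absolute Pearson correlation with an already-included predictor
    exceeds ``collinearity_r`` is excluded and listed with its partner
    (binary predictors are 0/1-coded, so the correlation is the
    point-biserial coefficient).  Rows with missing outcome or predictor
    values are dropped.
    """
    design = _encode_predictors(cohort, predictors)
    data = pd.concat([cohort[outcome].astype(float), design], axis=1).dropna()
    if len(data) <= design.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    y = data[outcome]

    included: list[str] = []
    excluded: list[tuple[str, str, float]] = []
    for name in design.columns:
        x = data[name].to_numpy()
        if np.ptp(x) == 0:
            excluded.append((name, "<constant>", math.nan))
            continue
        partner = None
        worst_r = 0.0
        for other in included:
            xo = data[other].to_numpy()
            r = abs(float(np.corrcoef(x, xo)[0, 1]))
            if r > collinearity_r and r > worst_r:
                partner, worst_r = other, r
        if partner is not None:
            excluded.append((name, partner, worst_r))
        else:
            included.append(name)

    X = sm.add_constant(data[included])
    model = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design after collinearity exclusions")
    return RegressionResult(
        outcome=outcome,
        included=included,
        excluded=excluded,
        coefficients={k: float(v) for k, v in model.params.items()},
        std_errors={k: float(v) for k, v in model.bse.items()},
        p_values={k: float(v) for k, v in model.pvalues.items()},
        n=int(model.nobs),
        r_squared=float(model.rsquared),
    )


# ---------------------------------------------------------------------------
# Method agreement (repeated measurements)
# ---------------------------------------------------------------------------

@dataclass
class AgreementResult:
    bias: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    pearson_r: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not self.lower_limit <= self.bias <= self.upper_limit:
            raise ValueError("limits must bracket the bias")
        if not (math.isnan(self.pearson_r) or -1.0 <= self.pearson_r <= 1.000001):
            raise ValueError("pearson_r must be in [-1, 1]")


def bland_altman(pairs: Sequence[tuple[float, float]]) -> AgreementResult:
    """Bland-Altman agreement of paired measurements (first minus second).

    bias = mean(A - B); limits of agreement = bias +/- 1.96 * SD(A - B)
    with the n-1 denominator; ``pearson_r`` is the correlation of A with B
    (1.0 when the two series are identical, including the constant case).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (A, B) tuples")
    if len(arr) < 2:
        raise ValueError("need at least 2 pairs")
    a, b = arr[:, 0], arr[:, 1]
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.array_equal(a, b):
        r = 1.0
    elif np.ptp(a) == 0 or np.ptp(b) == 0:
        r = math.nan  # correlation undefined against a constant series
    else:
        r = float(sps.pearsonr(a, b).statistic)
    return AgreementResult(bias=bias, sd_diff=sd,
                           lower_limit=bias - 1.96 * sd,
                           upper_limit=bias + 1.96 * sd,
                           pearson_r=r, n_pairs=len(arr))
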