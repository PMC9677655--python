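"""Statistical inference for input-output similarity and IEG densities.

The similarity comparison between housing groups follows the design of
the slice experiment: every cell contributes 10 (input, output)
similarity points, and the two housing groups (standard housing SH vs
enriched environment EE) are compared with an analysis of covariance of
``s_output`` on ``s_input`` with group as a factor.  Two models are
fitted: the parallel-lines model for the group (intercept) effect, and
the interaction model for slope heterogeneity; both p-values are
reported, the parallel-lines one as the headline group effect.

Immediate-early-gene (cFOS / NPAS4) cell densities are compared with a
two-way ANOVA (housing x condition) followed by Tukey HSD on the four
design cells; the unit of analysis is the per-animal mean density.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .spiketrains import ParameterError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: float
    p_value: float
    means: tuple[float, ...]
    n: tuple[int, ...]

    def __str__(self) -> str:  # compact report line
        return (
            f"{self.test}: t = {self.statistic:.4g}, df = {self.df:g}, "
            f"p = {self.p_value:.4g}"
        )


def two_sample_t(x, y) -> TestResult:
    """Classical two-sided two-sample t-test (pooled variance).

    Convention: with zero variance in both samples and equal means the
    test is reported as t = 0, p = 1 (logged); unequal means with zero
    variance report p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("two_sample_t needs n >= 2 per sample")
    df = x.size + y.size - 2
    if np.var(x) == 0 and np.var(y) == 0:
        if x.mean() == y.mean():
            logger.info("two_sample_t: zero variance, equal means -> p = 1")
            return TestResult(
                "two_sample_t", 0.0, df, 1.0, (x.mean(), y.mean()), (x.size, y.size)
            )
        logger.info("two_sample_t: zero variance, unequal means -> p = 0")
        return TestResult(
            "two_sample_t",
            float(np.inf) if x.mean() > y.mean() else float(-np.inf),
            df,
            0.0,
            (x.mean(), y.mean()),
            (x.size, y.size),
        )
    t, p = st.ttest_ind(x, y, equal_var=True)
    return TestResult(
        "two_sample_t",
        float(t),
        df,
        float(p),
        (float(x.mean()), float(y.mean())),
        (x.size, y.size),
    )


def one_sample_t(x, mu: float) -> TestResult:
    """Two-sided one-sample t-test against a hypothesized mean.

    Used for the discrimination index against the chance level 0.5.
    Zero-variance samples equal to ``mu`` report t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ParameterError("one_sample_t needs n >= 2")
    if np.var(x) == 0:
        if x.mean() == mu:
            logger.info("one_sample_t: constant sample at mu -> p = 1")
            return TestResult(
                "one_sample_t", 0.0, x.size - 1, 1.0, (float(x.mean()),), (x.size,)
            )
        return TestResult(
            "one_sample_t",
            float(np.inf) if x.mean() > mu else float(-np.inf),
            x.size - 1,
            0.0,
            (float(x.mean()),),
            (x.size,),
        )
    t, p = st.ttest_1samp(x, mu)
    return TestResult(
        "one_sample_t", float(t), x.size - 1, float(p), (float(x.mean()),), (x.size,)
    )


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AncovaResult:
    groups: tuple[str, str]
    slopes: dict[str, float]      # per-group simple-regression slopes
    intercepts: dict[str, float]  # per-group simple-regression intercepts
    p_group: float                # parallel-lines group (intercept) effect
    p_interaction: float          # slope-heterogeneity test
    group_offset: float           # fitted offset of group[1] vs group[0]
    common_slope: float           # slope of the parallel-lines model
    n: dict[str, int]

    def __str__(self) -> str:
        return (
            f"ANCOVA {self.groups[1]} vs {self.groups[0]}: "
            f"group p = {self.p_group:.4g}, interaction p = {self.p_interaction:.4g}"
        )


def ancova_compare(points: pd.DataFrame) -> AncovaResult:
    """ANCOVA of output similarity on input similarity across groups.

    ``points`` needs columns ``s_input``, ``s_output`` and ``group``
    with exactly two group levels and at least 3 points each.  Rows
    with undefined (NaN) similarity are dropped with a log message.
    """
    required = {"s_input", "s_output", "group"}
    missing = required - set(points.columns)
    if missing:
        raise ParameterError(f"points table is missing columns {sorted(missing)}")
    df = points.dropna(subset=["s_input", "s_output"])
    n_dropped = len(points) - len(df)
    if n_dropped:
        logger.info("ancova_compare: %d undefined points dropped", n_dropped)
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ParameterError(
            f"ANCOVA needs exactly 2 groups, got {levels!r}"
        )
    counts = df["group"].value_counts()
    if counts.min() < 3:
        raise ParameterError("ANCOVA needs at least 3 points per group")
    x = df["s_input"].to_numpy(float)
    y = df["s_output"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ParameterError("degenerate covariate: s_input is constant")
    g = (df["group"] == levels[1]).to_numpy(float)

    # parallel-lines model: y ~ 1 + x + g
    X1 = np.column_stack([np.ones_like(x), x, g])
    fit1 = sm.OLS(y, X1).fit()
    # interaction model: y ~ 1 + x + g + x:g
    X2 = np.column_stack([np.ones_like(x), x, g, x * g])
    fit2 = sm.OLS(y, X2).fit()

    slopes: dict[str, float] = {}
    intercepts: dict[str, float] = {}
    n: dict[str, int] = {}
    for lev in levels:
        m = df["group"] == lev
        res = st.linregress(x[m.to_numpy()], y[m.to_numpy()])
        slopes[lev] = float(res.slope)
        intercepts[lev] = float(res.intercept)
        n[lev] = int(m.sum())

    return AncovaResult(
        groups=(levels[0], levels[1]),
        slopes=slopes,
        intercepts=intercepts,
        p_group=float(fit1.pvalues[2]),
        p_interaction=float(fit2.pvalues[3]),
        group_offset=float(fit1.params[2]),
        common_slope=float(fit1.params[1]),
        n=n,
    )


# ---------------------------------------------------------------------------
# two-way ANOVA + Tukey
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    table: pd.DataFrame       # statsmodels type-II ANOVA table
    p_housing: float
    p_condition: float
    p_interaction: float
    cell_means: pd.DataFrame  # group x condition mean of the response
    tukey: pd.DataFrame       # pairwise Tukey HSD over the 4 cells
    zero_variance: bool = False


def two_way_anova_tukey(
    data: pd.DataFrame,
    response: str = "density",
    housing: str = "group",
    condition: str = "condition",
) -> AnovaResult:
    """Two-way ANOVA (housing x condition) with Tukey HSD post hoc.

    ``data`` holds one row per analysis unit (per-animal mean density
    by convention).  All four design cells must be populated.  When the
    response has zero variance every p-value is reported as 1 (logged).
    """
    for col in (response, housing, condition):
        if col not in data.columns:
            raise ParameterError(f"column {col!r} missing from ANOVA table")
    h_levels = sorted(data[housing].unique())
    c_levels = sorted(data[condition].unique())
    if len(h_levels) != 2 or len(c_levels) != 2:
        raise ParameterError(
            f"two-way design needs 2x2 levels, got {h_levels} x {c_levels}"
        )
    for h, c in itertools.product(h_levels, c_levels):
        if not len(data[(data[housing] == h) & (data[condition] == c)]):
            raise ValidationError(f"empty design cell ({h}, {c})")

    y = data[response].to_numpy(float)
    cell_means = (
        data.groupby([housing, condition])[response].mean().unstack(condition)
    )
    cells = data[housing].astype(str) + ":" + data[condition].astype(str)

    if np.var(y) == 0:
        logger.info("two_way_anova_tukey: zero response variance -> all p = 1")
        table = pd.DataFrame(
            {
                "sum_sq": [0.0, 0.0, 0.0, 0.0],
                "df": [1.0, 1.0, 1.0, float(len(y) - 4)],
                "F": [0.0, 0.0, 0.0, np.nan],
                "PR(>F)": [1.0, 1.0, 1.0, np.nan],
            },
            index=[housing, condition, f"{housing}:{condition}", "Residual"],
        )
        tukey = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p-adj", "lower", "upper", "reject"]
        )
        return AnovaResult(table, 1.0, 1.0, 1.0, cell_means, tukey, zero_variance=True)

    gh = (data[housing] == h_levels[1]).to_numpy(float)
    gc = (data[condition] == c_levels[1]).to_numpy(float)
    import statsmodels.formula.api as smf

    frame = pd.DataFrame({"y": y, "h": gh, "c": gc})
    fit = smf.ols("y ~ h * c", data=frame).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    tuk = pairwise_tukeyhsd(endog=y, groups=cells.to_numpy())
    tukey = pd.DataFrame(
        tuk.summary().data[1:], columns=[str(c) for c in tuk.summary().data[0]]
    )
    return AnovaResult(
        table=table,
        p_housing=float(table.loc["h", "PR(>F)"]),
        p_condition=float(table.loc["c", "PR(>F)"]),
        p_interaction=float(table.loc["h:c", "PR(>F)"]),
        cell_means=cell_means,
        tukey=tukey,
    )
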