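"""Attribute importance, subgroup comparisons, and sample-size planning.

For each respondent, an attribute's importance is the range of their
part-worth utilities for that attribute divided by the sum of the ranges
over all attributes, times 100 — so every respondent's importances sum to
100%. Averages across respondents are reported with t-based confidence
intervals; subgroup differences come from univariable ordinary least
squares of importance on a covariate (binary contrast or continuous), with
a stricter alpha conventionally used for these secondary comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .partworths import PartWorthSet

__all__ = [
    "importance_per_respondent",
    "summarize_importance",
    "subgroup_regression",
    "sample_size_for_ci",
    "CovariateContrast",
]


def importance_per_respondent(partworths: PartWorthSet) -> pd.DataFrame:
    """Per-respondent attribute importance (%), rows summing to 100.

    Respondents whose utility ranges are all zero have undefined importances
    and are dropped with a warning.
    """
    ranges = partworths.ranges()
    totals = ranges.sum(axis=1)
    degenerate = totals <= 0
    if degenerate.any():
        bad = list(ranges.index[degenerate])
        warnings.warn(
            f"dropping {len(bad)} respondent(s) with all-zero utility ranges: "
            f"{bad[:5]}",
            stacklevel=2,
        )
        ranges = ranges[~degenerate]
        totals = totals[~degenerate]
    return ranges.div(totals, axis=0) * 100.0


def summarize_importance(
    table: pd.DataFrame, confidence: float = 0.95
) -> pd.DataFrame:
    """Across-respondent mean importance with a t-interval per attribute.

    Returns a frame indexed by attribute with columns
    ``mean``, ``ci_low``, ``ci_high``, ``n``.
    """
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 respondents to summarise")
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    half = tcrit * sd / math.sqrt(n)
    return pd.DataFrame(
        {
            "mean": mean,
            "ci_low": mean - half,
            "ci_high": mean + half,
            "n": n,
        }
    )


@dataclass(frozen=True)
class CovariateContrast:
    """How to turn a covariate column into a regressor.

    ``kind='binary'`` compares ``group1`` against ``group2`` membership
    (each a set of category labels, or a predicate); the OLS coefficient is
    then the group-1 minus group-2 mean difference. ``kind='continuous'``
    regresses on the numeric value divided by ``per`` (e.g. age per 10
    years).
    """

    column: str
    kind: str = "binary"
    group1: object = None
    group2: object = None
    per: float = 1.0
    label: str | None = None

    def design_vector(self, covariates: pd.DataFrame) -> pd.Series:
        col = covariates[self.column]
        if self.kind == "continuous":
            return pd.to_numeric(col, errors="coerce") / self.per
        in1 = self._member(col, self.group1)
        in2 = self._member(col, self.group2) if self.group2 is not None else ~in1
        x = pd.Series(np.nan, index=col.index)
        x[in2] = 0.0
        x[in1] = 1.0
        return x

    @staticmethod
    def _member(col: pd.Series, group) -> pd.Series:
        if callable(group):
            return col.map(group).astype(bool)
        if isinstance(group, (set, frozenset, list, tuple)):
            return col.isin(list(group))
        return col == group


def subgroup_regression(
    table: pd.DataFrame,
    covariates: pd.DataFrame,
    contrast: CovariateContrast,
    confidence: float = 0.99,
) -> pd.DataFrame:
    """Univariable OLS of each attribute's importance on one covariate.

    Returns one row per attribute: ``coef`` (mean importance difference for a
    binary contrast), confidence-interval bounds at ``confidence``
    (conventionally 99% for these secondary comparisons), ``p_value`` and
    ``n``. Respondents missing the covariate are dropped.
    """
    x = contrast.design_vector(covariates).reindex(table.index)
    keep = x.notna()
    x = x[keep]
    if x.nunique() < 2:
        raise ValueError(
            f"covariate {contrast.column!r} is degenerate (single group/value)"
        )
    if contrast.kind == "binary":
        for g, lab in ((1.0, "group1"), (0.0, "group2")):
            if (x == g).sum() < 2:
                raise ValueError(f"{lab} of {contrast.column!r} has <2 respondents")
    sub = table.loc[x.index]
    X = sm.add_constant(x.to_numpy())
    rows = []
    for attr in table.columns:
        fit = sm.OLS(sub[attr].to_numpy(), X).fit()
        lo, hi = fit.conf_int(alpha=1 - confidence)[1]
        rows.append(
            {
                "attribute": attr,
                "coef": fit.params[1],
                "ci_low": lo,
                "ci_high": hi,
                "p_value": fit.pvalues[1],
                "n": int(fit.nobs),
            }
        )
    out = pd.DataFrame(rows).set_index("attribute")
    out.attrs["contrast"] = contrast.label or contrast.column
    return out


def sample_size_for_ci(
    sd: float, half_width: float, confidence: float = 0.95
) -> int:
    """Respondents needed for a mean CI of given half-width.

    Inverts the normal-theory interval: n = ceil((z * sd / half_width)^2).
    """
    if sd <= 0 or half_width <= 0:
        raise ValueError("sd and half_width must be positive")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return int(math.ceil((z * sd / half_width) ** 2))
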