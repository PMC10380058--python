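"""Group comparisons on genotype scores.

The omnibus test regresses the score on group indicators, which for a
categorical predictor is one-way ANOVA: F with (k-1, N-k) degrees of
freedom. Pairwise contrasts use the pooled-variance two-sample t test with
nA + nB - 2 degrees of freedom (the convention identified by the published
df). Effect sizes come from a tertile split of the pooled score
distribution: samples in the top third versus bottom third form a 2x2 table
per group pair, summarised by an odds ratio with a Woolf log-normal 95% CI
(Haldane-Anscombe 0.5 correction when a cell is empty).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateGroupError, UndefinedStatisticError

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "OmnibusResult",
    "PairwiseT",
    "ComparisonResult",
    "TertileSplit",
    "ORResult",
    "group_summaries",
    "omnibus_f",
    "pairwise_t",
    "compare_groups",
    "tertile_split",
    "tertile_or",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class OmnibusResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class PairwiseT:
    group_a: str
    group_b: str
    t: float
    df: int
    p: float
    mean_diff: float
    zero_variance: bool = False


@dataclass
class ComparisonResult:
    score_field: str
    groups: list[GroupSummary]
    omnibus: OmnibusResult
    pairwise: list[PairwiseT]


@dataclass
class TertileSplit:
    """Assignment of each sample to the low/middle/high third of a score set.

    Cuts are the empirical 1/3 and 2/3 quantiles (linear interpolation) of
    the basis values; strictly below the lower cut is ``low``, strictly above
    the upper cut is ``high``, everything else — including ties at either cut
    — is ``middle``.
    """

    lower_cut: float
    upper_cut: float
    assignment: dict[str, str]
    basis: str = "pooled"

    def members(self, category: str) -> list[str]:
        return [s for s, c in self.assignment.items() if c == category]


@dataclass(frozen=True)
class ORResult:
    group_a: str
    group_b: str
    a_high: int
    a_low: int
    b_high: int
    b_low: int
    or_value: float
    ci_low: float
    ci_high: float
    corrected: bool


def group_summaries(
    values: Mapping[str, np.ndarray] | Mapping[str, Sequence[float]]
) -> list[GroupSummary]:
    out = []
    for label, v in values.items():
        arr = np.asarray(v, dtype=float)
        out.append(GroupSummary(
            label=label, n=arr.size, mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            min=float(arr.min()), max=float(arr.max()),
        ))
    return out


def omnibus_f(values: Mapping[str, Sequence[float]]) -> OmnibusResult:
    """One-way ANOVA F across groups (regression on group indicators).

    Degenerate all-equal data returns F = 0, p = 1 rather than NaN.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    if len(groups) < 2:
        raise DegenerateGroupError("omnibus test requires at least 2 groups")
    for label, arr in groups.items():
        if arr.size < 2:
            raise DegenerateGroupError(f"group {label!r} has n={arr.size} < 2")
    k = len(groups)
    n_total = sum(arr.size for arr in groups.values())
    df1, df2 = k - 1, n_total - k
    pooled = np.concatenate(list(groups.values()))
    grand = pooled.mean()
    ss_between = sum(arr.size * (arr.mean() - grand) ** 2 for arr in groups.values())
    ss_within = sum(((arr - arr.mean()) ** 2).sum() for arr in groups.values())
    if ss_within == 0.0:
        if ss_between == 0.0:
            return OmnibusResult(F=0.0, df1=df1, df2=df2, p=1.0)
        return OmnibusResult(F=math.inf, df1=df1, df2=df2, p=0.0)
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return OmnibusResult(F=float(F), df1=df1, df2=df2, p=p)


def pairwise_t(
    scores_a: Sequence[float], scores_b: Sequence[float],
    group_a: str = "A", group_b: str = "B",
) -> PairwiseT:
    """Pooled-variance (Student's) two-sample t test, two-sided."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateGroupError("both groups need n >= 2 for the t test")
    df = a.size + b.size - 2
    mean_diff = float(a.mean() - b.mean())
    pooled_var = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    if pooled_var == 0.0:
        if mean_diff == 0.0:
            return PairwiseT(group_a, group_b, t=0.0, df=df, p=1.0,
                             mean_diff=0.0, zero_variance=True)
        t = math.inf if mean_diff > 0 else -math.inf
        return PairwiseT(group_a, group_b, t=t, df=df, p=0.0,
                         mean_diff=mean_diff, zero_variance=True)
    res = stats.ttest_ind(a, b, equal_var=True)
    return PairwiseT(group_a, group_b, t=float(res.statistic), df=df,
                     p=float(res.pvalue), mean_diff=mean_diff)


def compare_groups(
    values: Mapping[str, Sequence[float]], score_field: str = "tgs"
) -> ComparisonResult:
    """Omnibus F plus all pairwise pooled-t contrasts over the given groups."""
    omnibus = omnibus_f(values)
    labels = list(values)
    pairwise = [
        pairwise_t(values[a], values[b], a, b)
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    ]
    return ComparisonResult(
        score_field=score_field,
        groups=group_summaries(values),
        omnibus=omnibus,
        pairwise=pairwise,
    )


def tertile_split(
    scores: Mapping[str, float],
    basis_values: Sequence[float] | None = None,
    basis: str = "pooled",
) -> TertileSplit:
    """Split samples into thirds at the 1/3 and 2/3 empirical quantiles.

    ``scores`` maps sample id to score. The cuts are computed on
    ``basis_values`` when given (e.g. a two-group subset for a
    per-comparison split), otherwise on the pooled ``scores`` values.
    """
    if len(scores) < 3:
        raise UndefinedStatisticError("tertile split requires at least 3 scored samples")
    base = np.asarray(
        list(scores.values()) if basis_values is None else basis_values, dtype=float
    )
    lower = float(np.quantile(base, 1.0 / 3.0))
    upper = float(np.quantile(base, 2.0 / 3.0))
    if lower == upper:
        logger.warning("tertile cuts coincide (%g); all samples assigned 'middle'", lower)
    assignment = {}
    for sid, v in scores.items():
        if v < lower:
            assignment[sid] = "low"
        elif v > upper:
            assignment[sid] = "high"
        else:
            assignment[sid] = "middle"
    return TertileSplit(lower_cut=lower, upper_cut=upper,
                        assignment=assignment, basis=basis)


def tertile_or(
    split: TertileSplit,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> ORResult:
    """High-vs-low third odds ratio of group A relative to group B.

    OR = (A_high * B_low) / (A_low * B_high); middle-third samples drop out.
    The CI is Woolf's log-normal interval; a zero cell triggers the
    Haldane-Anscombe 0.5-per-cell correction (flagged via ``corrected``).
    """
    cells = {"a_high": 0, "a_low": 0, "b_high": 0, "b_low": 0}
    for sid, cat in split.assignment.items():
        if cat == "middle" or sid not in groups:
            continue
        g = groups[sid]
        if g == group_a:
            cells["a_high" if cat == "high" else "a_low"] += 1
        elif g == group_b:
            cells["b_high" if cat == "high" else "b_low"] += 1
    a, b = cells["a_high"], cells["a_low"]
    c, d = cells["b_high"], cells["b_low"]
    if a + b == 0:
        raise UndefinedStatisticError(
            f"group {group_a!r} has no samples in the high or low third"
        )
    if c + d == 0:
        raise UndefinedStatisticError(
            f"group {group_b!r} has no samples in the high or low third"
        )
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    or_value = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    ci_low = math.exp(math.log(or_value) - z * se)
    ci_high = math.exp(math.log(or_value) + z * se)
    return ORResult(
        group_a=group_a, group_b=group_b,
        a_high=a, a_low=b, b_high=c, b_low=d,
        or_value=float(or_value), ci_low=float(ci_low), ci_high=float(ci_high),
        corrected=corrected,
    )
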