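"""Condition-level summaries and significance testing.

Per-cell recruitment ratios are pooled across pseudo-experiments (the assay
reports 60 cells pooled from three independent experiments without a mixed
model).  Each condition is summarised by the mean R, a Student-t 95%
confidence interval, and the percentage of positive cells.  Between-
condition testing is one-way ANOVA followed by Bonferroni-corrected
pairwise t-tests against a reference condition (the no-cytoplasmic-tail
control in the assay), using the pooled ANOVA error term — the convention
of the Prism-style Bonferroni post-hoc.  Star codes follow the usual
figure-legend convention: * p < 0.05, ** p < 0.01, *** p < 0.001 on the
adjusted p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import InsufficientDataError, InvalidParameterError
from .quantify import RecruitmentRecord

__all__ = [
    "ConditionSummary",
    "PosthocResult",
    "AnovaResult",
    "summarize_condition",
    "summarize_cohort",
    "anova_with_bonferroni",
    "star_code",
]


@dataclass
class ConditionSummary:
    condition: str
    n: int
    mean_ratio: float
    ci95: tuple[float, float]
    percent_positive: float


@dataclass
class PosthocResult:
    pair: tuple[str, str]  # (condition, reference)
    t_statistic: float
    raw_p: float
    adjusted_p: float
    significant_at: str  # "***", "**", "*" or "ns"


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    posthoc: list[PosthocResult]


def star_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize_condition(records: Sequence[RecruitmentRecord], condition: str | None = None) -> ConditionSummary:
    """Mean R, t-based 95% CI, and percent positive for one condition."""
    if len(records) < 2:
        raise InsufficientDataError("need at least 2 records to summarise a condition")
    label = condition if condition is not None else records[0].condition
    ratios = np.array([r.ratio for r in records], dtype=np.float64)
    positives = np.array([bool(r.positive) for r in records])
    n = len(ratios)
    mean = float(ratios.mean())
    sd = float(ratios.std(ddof=1))
    half = float(sstats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
    return ConditionSummary(
        condition=label,
        n=n,
        mean_ratio=mean,
        ci95=(mean - half, mean + half),
        percent_positive=100.0 * float(positives.sum()) / n,
    )


def summarize_cohort(records: Sequence[RecruitmentRecord]) -> pd.DataFrame:
    """One summary row per condition, as a DataFrame."""
    frame_rows = []
    by_condition: dict[str, list[RecruitmentRecord]] = {}
    for r in records:
        by_condition.setdefault(r.condition, []).append(r)
    for label, recs in by_condition.items():
        s = summarize_condition(recs, label)
        frame_rows.append(
            {
                "condition": s.condition,
                "n": s.n,
                "mean_R": s.mean_ratio,
                "ci95_low": s.ci95[0],
                "ci95_high": s.ci95[1],
                "percent_positive": s.percent_positive,
            }
        )
    return pd.DataFrame(frame_rows)


def anova_with_bonferroni(
    groups: Mapping[str, Sequence[float]],
    reference: str,
    comparisons: str = "reference",
) -> AnovaResult:
    """One-way ANOVA plus Bonferroni-corrected post-hoc t-tests.

    Pairwise tests use the pooled within-group mean square as the error
    term (df = N - k).  ``comparisons="reference"`` tests every condition
    against ``reference`` (the default, matching versus-control figure
    legends); ``comparisons="all_pairs"`` tests every pair.  The Bonferroni
    factor is the number of comparisons actually performed.
    """
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups for ANOVA")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise InsufficientDataError(f"group {k!r} has fewer than 2 values")
    if comparisons not in ("reference", "all_pairs"):
        raise InvalidParameterError(f"unknown comparisons mode {comparisons!r}")
    if comparisons == "reference" and reference not in arrays:
        raise InvalidParameterError(f"reference condition {reference!r} not among groups")

    k = len(arrays)
    sizes = {name: a.size for name, a in arrays.items()}
    n_total = sum(sizes.values())
    means = {name: a.mean() for name, a in arrays.items()}
    grand = sum(a.sum() for a in arrays.values()) / n_total
    ss_between = sum(sizes[name] * (means[name] - grand) ** 2 for name in arrays)
    ss_within = sum(((a - means[name]) ** 2).sum() for name, a in arrays.items())
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        # All groups internally constant: F degenerates.
        f_stat = math.inf if ss_between > 0 else float("nan")
        p_value = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = float(ms_between / ms_within)
        p_value = float(sstats.f.sf(f_stat, df_between, df_within))

    if comparisons == "reference":
        pairs = [(name, reference) for name in arrays if name != reference]
    else:
        pairs = list(itertools.combinations(arrays, 2))
    m = len(pairs)
    posthoc: list[PosthocResult] = []
    for a_name, b_name in pairs:
        na, nb = sizes[a_name], sizes[b_name]
        if ms_within == 0:
            t_stat = math.inf if means[a_name] != means[b_name] else 0.0
            raw = 0.0 if means[a_name] != means[b_name] else 1.0
        else:
            se = math.sqrt(ms_within * (1.0 / na + 1.0 / nb))
            t_stat = float((means[a_name] - means[b_name]) / se)
            raw = float(2.0 * sstats.t.sf(abs(t_stat), df_within))
        adjusted = min(1.0, m * raw)
        posthoc.append(
            PosthocResult(
                pair=(a_name, b_name),
                t_statistic=t_stat,
                raw_p=raw,
                adjusted_p=adjusted,
                significant_at=star_code(adjusted),
            )
        )
    return AnovaResult(
        f_statistic=f_stat,
        p_value=p_value,
        df_between=df_between,
        df_within=df_within,
        posthoc=posthoc,
    )
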