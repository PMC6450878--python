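#!/usr/bin/env python
"""Condition-level summaries and significance of the recruiting-vs-control contrast.

Aggregates results/records.csv into per-condition means with 95% confidence
intervals and percent-positive, runs one-way ANOVA with a Bonferroni
post-hoc against the control condition, and renders the dot plot and
percent-positive figures.
"""

from pathlib import Path

import pandas as pd

from optiquant.pipeline import _dot_plot, _percent_positive_plot
from optiquant.quantify import RecruitmentRecord
from optiquant.stats import anova_with_bonferroni, summarize_cohort

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FIGURES = ROOT / "scratch" / "figures"
REFERENCE = "control"


def main() -> None:
    df = pd.read_csv(RESULTS / "records.csv")
    records = [
        RecruitmentRecord(
            cell_id=str(r.cell_id), condition=str(r.condition), experiment=str(r.experiment),
            max_roi2=float(r.max_roi2), mean_roi1=float(r.mean_roi1),
            ratio=float(r.R), positive=bool(r.positive),
        )
        for r in df.itertuples()
    ]
    summary = summarize_cohort(records)
    summary.to_csv(RESULTS / "condition_summary.csv", index=False)
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    groups = {c: g["R"].to_list() for c, g in df.groupby("condition")}
    res = anova_with_bonferroni(groups, REFERENCE)
    lines = [
        f"one-way ANOVA: F({res.df_between}, {res.df_within}) = {res.f_statistic:.1f}, "
        f"p = {res.p_value:.3g}"
    ]
    for ph in res.posthoc:
        lines.append(
            f"{ph.pair[0]} vs {ph.pair[1]}: Bonferroni-adjusted p = {ph.adjusted_p:.3g} "
            f"[{ph.significant_at}]"
        )
    report = "\n".join(lines)
    (RESULTS / "anova_report.txt").write_text(report + "\n")
    print(report)

    FIGURES.mkdir(parents=True, exist_ok=True)
    _dot_plot(df, summary, FIGURES / "recruitment_dotplot.png")
    _percent_positive_plot(summary, FIGURES / "percent_positive.png")
    print(f"figures -> {FIGURES}")


if __name__ == "__main__":
    main()
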