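"""Condition summaries, ANOVA and the Bonferroni post-hoc."""

import numpy as np
import pytest
from scipy import stats as sstats

from optiquant.errors import InsufficientDataError, InvalidParameterError
from optiquant.quantify import CohortField, RecruitmentRecord, quantify_cohort
from optiquant.simulate import SimulationParams, simulate_cohort
from optiquant.stats import (
    anova_with_bonferroni,
    star_code,
    summarize_cohort,
    summarize_condition,
)


def _records(ratios, positives=None, condition="c"):
    if positives is None:
        positives = [r >= 2.0 for r in ratios]
    return [
        RecruitmentRecord(f"cell{i}", condition, "exp1", r * 10, 10.0, r, p)
        for i, (r, p) in enumerate(zip(ratios, positives))
    ]


def test_percent_positive_matches_published_fractions():
    """51/60 positive cells -> 85%; 10/60 -> ~17% at the reported precision."""
    recs = _records([3.0] * 51 + [1.0] * 9)
    assert summarize_condition(recs).percent_positive == pytest.approx(85.0)
    recs = _records([3.0] * 10 + [1.0] * 50)
    pct = summarize_condition(recs).percent_positive
    assert pct == pytest.approx(100 * 10 / 60)
    assert round(pct) == 17


def test_percent_positive_is_mean_of_indicator():
    rng = np.random.default_rng(3)
    ratios = rng.uniform(0.5, 4.0, size=37)
    recs = _records(list(ratios))
    s = summarize_condition(recs)
    assert s.percent_positive == pytest.approx(100.0 * np.mean([r.positive for r in recs]))


def test_identical_ratios_give_degenerate_ci():
    s = summarize_condition(_records([2.5] * 10))
    assert s.ci95 == (pytest.approx(2.5), pytest.approx(2.5))


def test_ci_contains_mean_and_matches_t_interval():
    rng = np.random.default_rng(4)
    ratios = list(rng.normal(2.0, 0.4, size=60))
    s = summarize_condition(_records(ratios))
    lo, hi = sstats.t.interval(0.95, 59, loc=np.mean(ratios), scale=sstats.sem(ratios))
    assert s.ci95[0] == pytest.approx(lo)
    assert s.ci95[1] == pytest.approx(hi)
    assert s.ci95[0] <= s.mean_ratio <= s.ci95[1]


def test_single_record_is_insufficient():
    with pytest.raises(InsufficientDataError):
        summarize_condition(_records([2.0]))


def test_summarize_cohort_one_row_per_condition():
    recs = _records([2.0, 3.0, 1.0], condition="a") + _records([1.0, 1.2], condition="b")
    df = summarize_cohort(recs)
    assert set(df["condition"]) == {"a", "b"}
    assert df.loc[df["condition"] == "a", "n"].item() == 3


def test_f_equals_t_squared_for_two_groups():
    rng = np.random.default_rng(5)
    a = rng.normal(3.0, 0.5, 30)
    b = rng.normal(2.5, 0.5, 25)
    res = anova_with_bonferroni({"a": a, "b": b}, "b")
    t, _ = sstats.ttest_ind(a, b)  # pooled-variance t-test
    assert res.f_statistic == pytest.approx(t**2)
    assert len(res.posthoc) == 1
    assert res.posthoc[0].adjusted_p == pytest.approx(res.posthoc[0].raw_p)


def test_omnibus_matches_independent_f_oneway():
    rng = np.random.default_rng(6)
    groups = {k: rng.normal(m, 0.3, 20) for k, m in [("x", 1.0), ("y", 1.2), ("z", 1.1)]}
    res = anova_with_bonferroni(groups, "x")
    f_ref, p_ref = sstats.f_oneway(*groups.values())
    assert res.f_statistic == pytest.approx(f_ref)
    assert res.p_value == pytest.approx(p_ref)


def test_bonferroni_adjustment_is_m_times_raw_capped():
    rng = np.random.default_rng(7)
    groups = {f"g{i}": rng.normal(1.0, 0.5, 10) for i in range(6)}
    res = anova_with_bonferroni(groups, "g0")
    assert len(res.posthoc) == 5
    for ph in res.posthoc:
        assert ph.adjusted_p == pytest.approx(min(1.0, 5 * ph.raw_p))
        assert ph.adjusted_p >= ph.raw_p


def test_all_pairs_mode_counts_comparisons():
    rng = np.random.default_rng(8)
    groups = {f"g{i}": rng.normal(1.0, 0.5, 10) for i in range(4)}
    res = anova_with_bonferroni(groups, "g0", comparisons="all_pairs")
    assert len(res.posthoc) == 6
    for ph in res.posthoc:
        assert ph.adjusted_p == pytest.approx(min(1.0, 6 * ph.raw_p))


def test_star_codes_follow_figure_convention():
    assert star_code(0.0005) == "***"
    assert star_code(0.005) == "**"
    assert star_code(0.04) == "*"
    assert star_code(0.2) == "ns"


def test_undersized_group_rejected():
    with pytest.raises(InsufficientDataError):
        anova_with_bonferroni({"a": [1.0], "b": [1.0, 2.0]}, "b")
    with pytest.raises(InsufficientDataError):
        anova_with_bonferroni({"a": [1.0, 2.0]}, "a")


def test_unknown_reference_rejected():
    with pytest.raises(InvalidParameterError):
        anova_with_bonferroni({"a": [1.0, 2.0], "b": [1.0, 2.0]}, "zzz")


def test_simulated_contrast_is_highly_significant():
    """A recruiting (E=3) versus a non-recruiting (E=1) cohort separates
    decisively even at modest n."""
    p = SimulationParams(field_shape=(128, 128), cell_radius=40.0)
    cells = simulate_cohort(
        [("e3", p), ("e1", SimulationParams(field_shape=(128, 128), cell_radius=40.0,
                                            enrichment_factor=1.0))],
        12,
        seed=31,
    )
    records, _ = quantify_cohort(
        [CohortField(c.cell_id, c.condition, c.experiment, c.field) for c in cells]
    )
    groups = {}
    for r in records:
        groups.setdefault(r.condition, []).append(r.ratio)
    res = anova_with_bonferroni(groups, "e1")
    assert res.posthoc[0].adjusted_p < 0.001
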