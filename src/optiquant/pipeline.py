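"""End-to-end orchestration: simulate -> segment -> quantify -> stats -> report.

A run is fully described by a :class:`RunConfig` (conditions with simulation
parameters, segmentation settings, positivity threshold, reference
condition, master seed) and is deterministic given that seed.  The run
directory contains the per-cell records, exclusions, condition summaries,
the ANOVA/post-hoc report, per-condition figures (dot plot of per-cell R
with mean and 95% CI whiskers; percent-positive bars), and a JSON manifest
logging versions, seed and parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .io import exclusions_frame, records_frame
from .quantify import CohortField, quantify_cohort
from .segment import SegmentationParams
from .simulate import SimulationParams, simulate_cohort
from .stats import AnovaResult, anova_with_bonferroni, summarize_cohort

__all__ = ["RunConfig", "run_pipeline", "demo_config"]

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationParams)}
_SEG_FIELDS = {f.name for f in dataclasses.fields(SegmentationParams)}


@dataclass
class RunConfig:
    conditions: dict[str, dict]  # label -> SimulationParams overrides
    reference: str
    n_cells: int = 60
    seed: int = 7
    threshold: float = 2.0
    strict: bool = False
    segmentation: dict = field(default_factory=dict)
    experiment_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def validate(self) -> None:
        if not self.conditions:
            raise ConfigError("conditions: at least one condition is required")
        for label, overrides in self.conditions.items():
            if not isinstance(overrides, dict):
                raise ConfigError(f"conditions.{label}: expected a mapping of parameter overrides")
            unknown = set(overrides) - _SIM_FIELDS
            if unknown:
                raise ConfigError(f"conditions.{label}: unknown parameter(s) {sorted(unknown)}")
        if self.reference not in self.conditions:
            raise ConfigError(f"reference: {self.reference!r} is not a configured condition")
        if not self.threshold > 0:
            raise ConfigError("threshold: must be > 0")
        if self.n_cells < 1:
            raise ConfigError("n_cells: must be >= 1")
        unknown = set(self.segmentation) - _SEG_FIELDS
        if unknown:
            raise ConfigError(f"segmentation: unknown parameter(s) {sorted(unknown)}")
        if len(self.experiment_factors) != 3:
            raise ConfigError("experiment_factors: must have length 3")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
        if "conditions" not in data or "reference" not in data:
            raise ConfigError("conditions/reference: both are required")
        cfg = cls(**{**data, "experiment_factors": tuple(data.get("experiment_factors", (1.0, 1.0, 1.0)))})
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def simulation_params(self, label: str) -> SimulationParams:
        overrides = dict(self.conditions[label])
        if "field_shape" in overrides:
            overrides["field_shape"] = tuple(overrides["field_shape"])
        if "cell_center" in overrides and overrides["cell_center"] is not None:
            overrides["cell_center"] = tuple(overrides["cell_center"])
        return SimulationParams(**overrides)

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(**self.segmentation)


def demo_config(n_cells: int = 60, seed: int = 7) -> RunConfig:
    """Two-condition demo: a recruiting tail (E=3) versus a control (E=1)."""
    return RunConfig(
        conditions={
            "recruiting": {"enrichment_factor": 3.0},
            "control": {"enrichment_factor": 1.0},
        },
        reference="control",
        n_cells=n_cells,
        seed=seed,
    )


def _dot_plot(records: pd.DataFrame, summary: pd.DataFrame, path: Path) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.4 * len(summary) + 1.5, 4))
    rng = np.random.default_rng(0)  # cosmetic jitter only
    for i, row in summary.reset_index(drop=True).iterrows():
        vals = records.loc[records["condition"] == row["condition"], "R"].to_numpy()
        x = i + rng.uniform(-0.15, 0.15, size=vals.size)
        ax.plot(x, vals, "o", ms=3, alpha=0.6)
        ax.errorbar(
            i,
            row["mean_R"],
            yerr=[[row["mean_R"] - row["ci95_low"]], [row["ci95_high"] - row["mean_R"]]],
            fmt="_",
            color="black",
            capsize=6,
            ms=20,
        )
    ax.set_xticks(range(len(summary)), summary["condition"])
    ax.set_ylabel("recruitment ratio R")
    ax.axhline(2.0, ls="--", lw=0.8, color="gray")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _percent_positive_plot(summary: pd.DataFrame, path: Path) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(summary) + 1.5, 4))
    ax.bar(summary["condition"], summary["percent_positive"], color="#4878d0")
    ax.set_ylabel("% cells with R >= threshold")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _report_text(config: RunConfig, anova: AnovaResult) -> str:
    lines = [
        "One-way ANOVA across conditions",
        f"  F({anova.df_between}, {anova.df_within}) = {anova.f_statistic:.4g}, p = {anova.p_value:.4g}",
        f"Bonferroni post-hoc versus reference '{config.reference}' "
        f"({len(anova.posthoc)} comparison(s)):",
    ]
    for ph in anova.posthoc:
        lines.append(
            f"  {ph.pair[0]} vs {ph.pair[1]}: t = {ph.t_statistic:.4g}, "
            f"raw p = {ph.raw_p:.4g}, adjusted p = {ph.adjusted_p:.4g} [{ph.significant_at}]"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute a full run; returns a dict of output paths and key results."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    figures = out / "figures"
    figures.mkdir(exist_ok=True)

    conditions = [(label, config.simulation_params(label)) for label in config.conditions]
    cohort = simulate_cohort(
        conditions, config.n_cells, config.seed, experiment_factors=config.experiment_factors
    )
    items = [
        CohortField(c.cell_id, c.condition, c.experiment, c.field) for c in cohort
    ]
    records, exclusions = quantify_cohort(
        items,
        threshold=config.threshold,
        strict=config.strict,
        segmentation=config.segmentation_params(),
    )
    records_df = records_frame(records)
    records_df.to_csv(out / "records.csv", index=False)
    exclusions_frame(exclusions).to_csv(out / "exclusions.csv", index=False)

    summary = summarize_cohort(records)
    summary.to_csv(out / "summary.csv", index=False)

    groups = {
        label: records_df.loc[records_df["condition"] == label, "R"].to_list()
        for label in config.conditions
        if (records_df["condition"] == label).sum() >= 2
    }
    anova = anova_with_bonferroni(groups, config.reference)
    (out / "stats_report.txt").write_text(_report_text(config, anova))
    pd.DataFrame(
        [
            {
                "condition": ph.pair[0],
                "reference": ph.pair[1],
                "t": ph.t_statistic,
                "raw_p": ph.raw_p,
                "adjusted_p": ph.adjusted_p,
                "significant_at": ph.significant_at,
            }
            for ph in anova.posthoc
        ]
    ).to_csv(out / "posthoc.csv", index=False)

    _dot_plot(records_df, summary, figures / "recruitment_dotplot.png")
    _percent_positive_plot(summary, figures / "percent_positive.png")

    import scipy
    import skimage

    manifest = {
        "package": {"optiquant": __version__},
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": {
            "conditions": config.conditions,
            "reference": config.reference,
            "n_cells": config.n_cells,
            "threshold": config.threshold,
            "strict": config.strict,
            "segmentation": config.segmentation,
            "experiment_factors": list(config.experiment_factors),
        },
        "n_records": len(records),
        "exclusions": [dataclasses.asdict(e) for e in exclusions],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "out_dir": out,
        "records": records_df,
        "summary": summary,
        "anova": anova,
        "exclusions": exclusions,
    }
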