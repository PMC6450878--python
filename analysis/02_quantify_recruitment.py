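#!/usr/bin/env python
"""Segment ROIs and compute the recruitment ratio R for the simulated cohort.

Reads the TIFF fields written by 01_simulate_cohort.py, segments the cell
(ROI1, from the protein-of-interest channel) and the attachment site (ROI2,
from the receptor channel), computes R = max(ROI2)/mean(ROI1) per cell, and
writes the per-cell records to results/records.csv.  Cells where either ROI
cannot be found are excluded with the reason logged.
"""

from pathlib import Path

from optiquant.io import (
    exclusions_frame,
    read_channel_config,
    read_field_tiff,
    records_frame,
)
from optiquant.quantify import CohortField, quantify_cohort

ROOT = Path(__file__).resolve().parents[1]
FIELDS = ROOT / "scratch" / "fields"
RESULTS = ROOT / "results"


def main() -> None:
    order = read_channel_config(FIELDS / "channels.yaml")
    items = []
    for tif in sorted(FIELDS.glob("*.tif")):
        if tif.name.endswith("_mask.tif"):
            continue
        condition, index = tif.stem.rsplit("_", 1)
        experiment = f"exp{int(index) % 3 + 1}"
        items.append(
            CohortField(tif.stem, condition, experiment, read_field_tiff(tif, order))
        )
    records, exclusions = quantify_cohort(items)
    RESULTS.mkdir(exist_ok=True)
    df = records_frame(records)
    df.to_csv(RESULTS / "records.csv", index=False)
    exclusions_frame(exclusions).to_csv(RESULTS / "exclusions.csv", index=False)
    print(f"{len(records)} cells quantified, {len(exclusions)} excluded")
    for condition, group in df.groupby("condition"):
        print(
            f"  {condition}: mean R = {group['R'].mean():.2f}, "
            f"{100 * group['positive'].mean():.0f}% positive (R >= 2)"
        )
    print(f"records -> {RESULTS / 'records.csv'}")


if __name__ == "__main__":
    main()
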