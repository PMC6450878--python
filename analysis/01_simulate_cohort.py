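#!/usr/bin/env python
"""Simulate the two-condition demo cohort and write it to disk as TIFFs.

Conditions: a recruiting tail (enrichment E = 3, the regime of a wild-type
talin-binding tail) versus a non-recruiting control (E = 1, the regime of a
tail-less control), 60 cells each from three pseudo-experiments, default
blur and noise.  Fields go to scratch/fields/ as multi-page TIFFs with a
channel-order sidecar plus ground-truth masks; later stages read them back
from disk like real acquisitions.
"""

from pathlib import Path

from optiquant.io import write_channel_config, write_field_tiff, write_mask_tiff
from optiquant.pipeline import demo_config
from optiquant.simulate import simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "fields"


def main() -> None:
    cfg = demo_config(n_cells=60, seed=7)
    conditions = [(label, cfg.simulation_params(label)) for label in cfg.conditions]
    cohort = simulate_cohort(conditions, cfg.n_cells, cfg.seed)
    OUT.mkdir(parents=True, exist_ok=True)
    write_channel_config(OUT / "channels.yaml")
    for cell in cohort:
        write_field_tiff(cell.field, OUT / f"{cell.cell_id}.tif")
        write_mask_tiff(cell.truth.cell_mask, OUT / f"{cell.cell_id}_cell_mask.tif")
        write_mask_tiff(cell.truth.cluster_mask, OUT / f"{cell.cell_id}_cluster_mask.tif")
    per_condition = {label: sum(c.condition == label for c in cohort) for label, _ in conditions}
    print(f"wrote {len(cohort)} fields to {OUT}")
    for label, n in per_condition.items():
        print(f"  {label}: {n} cells (enrichment E = "
              f"{cfg.simulation_params(label).enrichment_factor})")


if __name__ == "__main__":
    main()
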