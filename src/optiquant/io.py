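"""TIFF and sidecar-config IO for fields, masks and records.

A field is stored as a multi-page TIFF (one page per channel); the page ->
channel mapping lives in a small YAML sidecar next to the images, so the
quantification stages never have to guess acquisition channel order.
Masks are single-page 8-bit TIFFs (0/255), which also makes hand-drawn
ROIs importable from any image editor.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError
from .quantify import Exclusion, RecruitmentRecord
from .simulate import CHANNEL_NAMES, FieldImage

__all__ = [
    "write_field_tiff",
    "read_field_tiff",
    "write_channel_config",
    "read_channel_config",
    "write_mask_tiff",
    "read_mask_tiff",
    "records_frame",
    "exclusions_frame",
]


def write_channel_config(path: str | Path, channel_order: tuple[str, ...] = CHANNEL_NAMES) -> None:
    Path(path).write_text(yaml.safe_dump({"channel_order": list(channel_order)}))


def read_channel_config(path: str | Path) -> tuple[str, ...]:
    data = yaml.safe_load(Path(path).read_text())
    try:
        order = tuple(data["channel_order"])
    except (TypeError, KeyError) as err:
        raise ConfigError(f"channel config {path}: missing key 'channel_order'") from err
    for name in order:
        if name not in CHANNEL_NAMES:
            raise ConfigError(f"channel config {path}: unknown channel {name!r}")
    return order


def write_field_tiff(
    field: FieldImage, path: str | Path, channel_order: tuple[str, ...] = CHANNEL_NAMES
) -> None:
    stack = np.stack([field.channels[name] for name in channel_order]).astype(np.float32)
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_field_tiff(path: str | Path, channel_order: tuple[str, ...] = CHANNEL_NAMES) -> FieldImage:
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(channel_order):
        raise ConfigError(
            f"{path}: {stack.shape[0]} pages but {len(channel_order)} channels configured"
        )
    return FieldImage(
        channels={name: stack[i].astype(np.float64) for i, name in enumerate(channel_order)}
    )


def write_mask_tiff(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)) > 0


def records_frame(records: list[RecruitmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "condition": r.condition,
                "experiment": r.experiment,
                "max_roi2": r.max_roi2,
                "mean_roi1": r.mean_roi1,
                "R": r.ratio,
                "positive": bool(r.positive) if r.positive is not None else None,
            }
            for r in records
        ]
    )


def exclusions_frame(exclusions: list[Exclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": e.cell_id,
                "condition": e.condition,
                "reason": e.reason,
                "detail": e.detail,
            }
            for e in exclusions
        ],
        columns=["cell_id", "condition", "reason", "detail"],
    )
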