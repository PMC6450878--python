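"""The recruitment ratio R, positivity calls, and line-scan profiles.

R for one cell is the maximum protein-of-interest intensity inside the
attachment-site ROI (ROI2) divided by the mean intensity over the whole-cell
ROI (ROI1), both measured in the same channel:

    R = max(POI | ROI2) / mean(POI | ROI1)

R >= 2 — a two-fold local enrichment over the mean cellular distribution —
is scored as positive recruitment.  The maximum is taken on raw (unsmoothed)
pixels, no background subtraction is applied, and ROI2 pixels lying inside
ROI1 contribute to the ROI1 mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import (
    InvalidParameterError,
    NoCellError,
    NoClusterError,
    UndefinedRatioError,
)
from .segment import CellRoi, ClusterRoi, SegmentationParams, segment_cell, segment_clusters
from .simulate import FieldImage

__all__ = [
    "RecruitmentRecord",
    "LineScanProfile",
    "CohortField",
    "Exclusion",
    "compute_ratio",
    "classify_positive",
    "line_scan",
    "quantify_cohort",
]

POSITIVITY_THRESHOLD = 2.0


@dataclass
class RecruitmentRecord:
    """One analysed cell. ``positive`` stays ``None`` until classified."""

    cell_id: str
    condition: str
    experiment: str
    max_roi2: float
    mean_roi1: float
    ratio: float
    positive: bool | None = None


@dataclass
class LineScanProfile:
    """Per-channel intensity along a segment, relative to each channel's max.

    ``positions`` are distances in pixels from the first endpoint.  Channels
    that are identically zero along the segment are reported as all-zero
    (no division by zero).
    """

    positions: np.ndarray
    profiles: dict[str, np.ndarray]

    def to_frame(self):
        """Tabular form: one ``position`` column plus one column per channel."""
        import pandas as pd

        data = {"position": self.positions}
        data.update(self.profiles)
        return pd.DataFrame(data)


@dataclass
class CohortField:
    """Input unit for :func:`quantify_cohort`; ROIs are segmented when absent."""

    cell_id: str
    condition: str
    experiment: str
    field: FieldImage
    roi1: CellRoi | None = None
    roi2: ClusterRoi | None = None


@dataclass
class Exclusion:
    """A cell dropped from analysis, with the reason logged."""

    cell_id: str
    condition: str
    reason: str
    detail: str = ""


def compute_ratio(
    poi_channel: np.ndarray,
    roi1: CellRoi,
    roi2: ClusterRoi,
    cell_id: str = "",
    condition: str = "",
    experiment: str = "",
    background_offset: float = 0.0,
) -> RecruitmentRecord:
    """Compute R = max(POI|ROI2) / mean(POI|ROI1) for one cell.

    ``background_offset`` optionally subtracts a constant background (clipped
    at zero) before measuring; the default of 0 measures raw intensities.
    """
    img = np.asarray(poi_channel, dtype=np.float64)
    if background_offset:
        img = np.clip(img - background_offset, 0.0, None)
    if not roi1.mask.any():
        raise InvalidParameterError("ROI1 is empty")
    if not roi2.mask.any():
        raise InvalidParameterError("ROI2 is empty")
    mean_roi1 = float(img[roi1.mask].mean())
    if mean_roi1 <= 0:
        raise UndefinedRatioError("mean ROI1 intensity is not positive; R undefined")
    max_roi2 = float(img[roi2.mask].max())
    return RecruitmentRecord(
        cell_id=cell_id,
        condition=condition,
        experiment=experiment,
        max_roi2=max_roi2,
        mean_roi1=mean_roi1,
        ratio=max_roi2 / mean_roi1,
    )


def classify_positive(ratio: float, threshold: float = POSITIVITY_THRESHOLD, strict: bool = False) -> bool:
    """Score a ratio as positive recruitment.

    The default boundary is inclusive (``R >= threshold``); ``strict=True``
    switches to ``R > threshold``.
    """
    if not ratio > 0:
        raise InvalidParameterError(f"ratio must be positive, got {ratio}")
    if threshold <= 0:
        raise InvalidParameterError("threshold must be positive")
    return ratio > threshold if strict else ratio >= threshold


def line_scan(
    fieldimg: FieldImage,
    p0: tuple[float, float],
    p1: tuple[float, float],
    n_samples: int = 100,
) -> LineScanProfile:
    """Bilinearly sample all channels along the segment p0 -> p1.

    Each channel is normalised to its own maximum along the segment, so
    profiles lie in [0, 1] and peak at 1 wherever the raw maximum is
    positive.
    """
    if n_samples < 2:
        raise InvalidParameterError("n_samples must be >= 2")
    shape = fieldimg.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= shape[0] - 1 and 0 <= p[1] <= shape[1] - 1):
            raise InvalidParameterError(f"endpoint {p} outside the field {shape}")
    rows = np.linspace(p0[0], p1[0], n_samples)
    cols = np.linspace(p0[1], p1[1], n_samples)
    length = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    positions = np.linspace(0.0, length, n_samples)
    profiles: dict[str, np.ndarray] = {}
    for name, channel in fieldimg.channels.items():
        values = ndi.map_coordinates(
            np.asarray(channel, dtype=np.float64), [rows, cols], order=1
        )
        peak = values.max()
        profiles[name] = values / peak if peak > 0 else values
    return LineScanProfile(positions=positions, profiles=profiles)


def quantify_cohort(
    items: list[CohortField],
    threshold: float = POSITIVITY_THRESHOLD,
    strict: bool = False,
    segmentation: SegmentationParams | None = None,
) -> tuple[list[RecruitmentRecord], list[Exclusion]]:
    """Apply ROI segmentation and the ratio to every cell of a cohort.

    Per-cell failures (no cell, no cluster, undefined ratio) never abort the
    cohort; they become :class:`Exclusion` entries with the reason logged.
    """
    seg = segmentation or SegmentationParams()
    records: list[RecruitmentRecord] = []
    exclusions: list[Exclusion] = []
    for item in items:
        try:
            roi1 = item.roi1 or segment_cell(
                item.field.channels["poi"], min_area=seg.min_area, smooth_sigma=seg.smooth_sigma
            )
            roi2 = item.roi2 or segment_clusters(
                item.field.channels["receptor"],
                roi1,
                quantile=seg.cluster_quantile,
                dilation_radius=seg.dilation_radius,
                bacteria_channel=item.field.channels.get("bacteria")
                if seg.use_bacteria_channel
                else None,
            )
            record = compute_ratio(
                item.field.channels["poi"],
                roi1,
                roi2,
                cell_id=item.cell_id,
                condition=item.condition,
                experiment=item.experiment,
            )
            record.positive = classify_positive(record.ratio, threshold=threshold, strict=strict)
            records.append(record)
        except (NoCellError, NoClusterError, UndefinedRatioError) as err:
            exclusions.append(
                Exclusion(
                    cell_id=item.cell_id,
                    condition=item.condition,
                    reason=type(err).__name__,
                    detail=str(err),
                )
            )
    return records, exclusions
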