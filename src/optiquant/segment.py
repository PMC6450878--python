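"""Automated stand-ins for the hand-drawn quantification ROIs.

ROI1 — the whole-cell outline — is recovered from the protein-of-interest
channel by Gaussian smoothing, Otsu thresholding, hole filling, and keeping
the largest connected component.  ROI2 — the clustered-receptor attachment
site — is recovered from the receptor channel by a high-intensity quantile
threshold (cluster pixels are a tiny area fraction, where Otsu is unstable),
morphological dilation to the micron scale of a bacterium, and restriction
to components touching the (dilated) cell mask.  All surviving attachment
components are unioned into a single ROI2 per cell, so each cell yields one
recruitment ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .errors import InvalidParameterError, NoCellError, NoClusterError

__all__ = [
    "CellRoi",
    "ClusterRoi",
    "SegmentationParams",
    "segment_cell",
    "segment_clusters",
]


@dataclass
class CellRoi:
    """ROI1: boolean mask of the cell footprint."""

    mask: np.ndarray

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class ClusterRoi:
    """ROI2: union of all attachment-site components for one cell."""

    mask: np.ndarray
    n_components: int

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables for both ROI detectors (pixel units)."""

    smooth_sigma: float = 2.0
    min_area: int = 500
    cluster_quantile: float = 0.995
    dilation_radius: int = 3
    use_bacteria_channel: bool = False


def segment_cell(
    poi_channel: np.ndarray,
    min_area: int = 500,
    smooth_sigma: float = 2.0,
) -> CellRoi:
    """Segment the cell outline (ROI1) from the POI channel.

    Raises :class:`NoCellError` on a constant image or when no connected
    component reaches ``min_area`` pixels.
    """
    img = np.asarray(poi_channel, dtype=np.float64)
    if img.ndim != 2:
        raise InvalidParameterError("poi_channel must be a 2D image")
    if img.max() == img.min():
        raise NoCellError("constant image: no cell to segment")
    smoothed = ndi.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    if smoothed.max() == smoothed.min():
        raise NoCellError("constant image after smoothing: no cell to segment")
    mask = smoothed > threshold_otsu(smoothed)
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask)
    if n == 0:
        raise NoCellError("no foreground component found")
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes))
    if sizes[best] < min_area:
        raise NoCellError(f"largest component ({sizes[best]} px) below min_area={min_area}")
    return CellRoi(mask=labels == best + 1)


def segment_clusters(
    receptor_channel: np.ndarray,
    cell: CellRoi,
    quantile: float = 0.995,
    dilation_radius: int = 3,
    bacteria_channel: np.ndarray | None = None,
) -> ClusterRoi:
    """Segment the attachment site (ROI2) from the receptor channel.

    Pixels above the given intensity quantile are dilated by
    ``dilation_radius`` and grouped into connected components; only
    components overlapping the dilated cell mask survive, and all survivors
    are unioned into one ROI.  When ``bacteria_channel`` is given, candidate
    pixels are additionally required to lie near particle signal (bead /
    bacteria fixtures).

    Raises :class:`NoClusterError` when nothing survives — such cells are
    excluded from analysis, since only cells with receptor-bound particles
    are scored.
    """
    img = np.asarray(receptor_channel, dtype=np.float64)
    if img.shape != cell.mask.shape:
        raise InvalidParameterError("receptor channel and cell mask shapes differ")
    if not 0 < quantile < 1:
        raise InvalidParameterError("quantile must be in (0, 1)")
    threshold = np.quantile(img, quantile)
    raw = img > threshold
    if bacteria_channel is not None:
        bac = np.asarray(bacteria_channel, dtype=np.float64)
        bac_mask = bac > np.quantile(bac, quantile)
        raw &= ndi.binary_dilation(bac_mask, structure=disk(dilation_radius))
    if not raw.any():
        raise NoClusterError("no pixel above the cluster intensity quantile")

    selem = disk(dilation_radius) if dilation_radius > 0 else None
    candidate = ndi.binary_dilation(raw, structure=selem) if selem is not None else raw
    cell_dilated = ndi.binary_dilation(cell.mask, structure=selem) if selem is not None else cell.mask

    labels, n = ndi.label(candidate)
    keep = np.zeros_like(candidate, dtype=bool)
    n_kept = 0
    for lab in range(1, n + 1):
        component = labels == lab
        if (component & cell_dilated).any():
            keep |= component
            n_kept += 1
    if n_kept == 0:
        raise NoClusterError("no cluster component touches the cell")
    return ClusterRoi(mask=keep, n_components=n_kept)
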