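"""Synthetic multichannel fluorescence fields with known ground truth.

Each simulated field of view emulates one adherent cell expressing a
clusterable chimeric receptor together with a fluorescent protein of
interest (POI).  Three channels are rendered:

``bacteria``
    the particle stain (multivalent ligand: microcolony of bacteria or an
    antibody-coated bead), non-zero only on the attachment-site footprint;
``receptor``
    the clustered-receptor stain, concentrated on the attachment site with
    a dim membrane signal over the whole cell;
``poi``
    the protein of interest: a diffuse cytosolic pool plus local enrichment
    at the attachment site.

POI enrichment is modelled as *mass-conserving relocation*: attachment-site
pixels are raised to ``E * c`` while the remaining cell interior is depleted
pro rata, so the mean POI intensity over the whole cell footprint stays
exactly ``c`` (plus background ``b``).  This mirrors recruitment of a finite
cytosolic pool and makes the ideal, noise-free recruitment ratio over the
ground-truth masks equal ``(E*c + b) / (c + b)`` exactly — and exactly ``E``
when ``b = 0``.

Rendering order: ideal intensities -> Gaussian PSF blur -> Poisson shot
noise -> additive Gaussian read noise (clipped at zero) -> optional
quantization to the acquisition bit depth.  With a fixed seed the output is
bit-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import InvalidGeometryError, InvalidParameterError

CHANNEL_NAMES = ("bacteria", "receptor", "poi")

__all__ = [
    "CHANNEL_NAMES",
    "SimulationParams",
    "FieldImage",
    "GroundTruth",
    "SimulatedCell",
    "simulate_field",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated field.

    Intensities are in photon counts per pixel; lengths in pixels.  The
    default 256x256 field is a scaled-down stand-in for a 1024x1024, 8-bit
    confocal acquisition; pass ``field_shape=(1024, 1024)`` (and a
    proportionally larger ``cell_radius``) to mirror the full format.
    """

    field_shape: tuple[int, int] = (256, 256)
    cell_center: tuple[float, float] | None = None  # defaults to field centre
    cell_radius: float = 80.0
    baseline_intensity: float = 40.0  # c: POI photons/px inside the cell
    enrichment_factor: float = 3.0  # E: ideal cluster-peak / cell-mean POI
    cluster_geometry: str = "microcolony"  # or "bead"
    n_spots: int = 6  # diffraction-limited spots per microcolony
    spot_radius: float = 4.0  # ~1 um bacterium at the emulated pixel size
    bead_radius: float = 4.0  # ~1 um polystyrene bead
    cluster_angle: float = 0.6  # radians; position on the cell perimeter
    cluster_offset: float = 0.0  # radial offset from the perimeter (+: outward)
    receptor_gain: float = 4.0  # receptor concentration factor at the cluster
    receptor_membrane_fraction: float = 0.08  # dim whole-cell receptor signal
    bacteria_gain: float = 3.0  # particle-stain brightness relative to c
    background_level: float = 0.0  # b: photons/px outside the cell
    psf_sigma: float = 2.0  # Gaussian PSF sigma; 0 disables blur
    poisson_noise: bool = True
    gaussian_read_sd: float = 2.0  # camera read noise; 0 disables
    quantize: bool = False  # round/clip to bit_depth (off: float output)
    bit_depth: int = 8
    seed: int = 0

    def validate(self) -> None:
        r, c = self.field_shape
        if r <= 0 or c <= 0:
            raise InvalidParameterError(f"field_shape must be positive, got {self.field_shape}")
        if self.enrichment_factor < 0:
            raise InvalidParameterError(f"enrichment_factor must be >= 0, got {self.enrichment_factor}")
        if self.baseline_intensity <= 0:
            raise InvalidParameterError("baseline_intensity must be > 0")
        if self.cell_radius <= 0:
            raise InvalidParameterError("cell_radius must be > 0")
        if self.background_level < 0:
            raise InvalidParameterError("background_level must be >= 0")
        if self.cluster_geometry not in ("microcolony", "bead"):
            raise InvalidParameterError(f"unknown cluster_geometry {self.cluster_geometry!r}")
        if self.bit_depth <= 0:
            raise InvalidParameterError("bit_depth must be > 0")

    @property
    def resolved_center(self) -> tuple[float, float]:
        if self.cell_center is not None:
            return self.cell_center
        return (self.field_shape[0] / 2.0, self.field_shape[1] / 2.0)


@dataclass
class FieldImage:
    """One field of view: named 2D intensity channels of equal shape."""

    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise InvalidParameterError(f"channel shapes differ: {shapes}")
        for name in self.channels:
            if name not in CHANNEL_NAMES:
                raise InvalidParameterError(f"unknown channel name {name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class GroundTruth:
    """Simulator-side truth used by oracles and parameter-recovery tests."""

    cell_mask: np.ndarray
    cluster_mask: np.ndarray
    enrichment_factor: float
    baseline_intensity: float


@dataclass
class SimulatedCell:
    """One cohort member: a field, its truth, and its provenance labels."""

    cell_id: str
    condition: str
    experiment: str
    field: FieldImage
    truth: GroundTruth


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _apply_noise(ideal: np.ndarray, params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    img = ideal
    if params.psf_sigma > 0:
        img = ndi.gaussian_filter(img, params.psf_sigma)
    if params.poisson_noise:
        img = rng.poisson(np.clip(img, 0.0, None)).astype(np.float64)
    if params.gaussian_read_sd > 0:
        img = img + rng.normal(0.0, params.gaussian_read_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    if params.quantize:
        img = np.clip(np.rint(img), 0, 2**params.bit_depth - 1)
    return img


def simulate_field(params: SimulationParams) -> tuple[FieldImage, GroundTruth]:
    """Render one field and its ground truth.

    Raises
    ------
    InvalidParameterError
        if any parameter is outside its domain (e.g. ``enrichment_factor < 0``).
    InvalidGeometryError
        if the attachment-site footprint does not overlap the cell, or the
        requested enrichment exceeds the relocatable cytosolic pool.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = params.field_shape
    center = params.resolved_center
    cell = _disk_mask(shape, center, params.cell_radius)
    if not cell.any():
        raise InvalidGeometryError("cell footprint is empty (cell outside the field?)")

    anchor = (
        center[0] + (params.cell_radius + params.cluster_offset) * math.sin(params.cluster_angle),
        center[1] + (params.cell_radius + params.cluster_offset) * math.cos(params.cluster_angle),
    )
    if params.cluster_geometry == "bead":
        cluster = _disk_mask(shape, anchor, params.bead_radius)
    else:
        cluster = np.zeros(shape, dtype=bool)
        jitter = rng.normal(0.0, params.spot_radius, size=(params.n_spots, 2))
        for dy, dx in jitter:
            cluster |= _disk_mask(shape, (anchor[0] + dy, anchor[1] + dx), params.spot_radius)

    overlap = cluster & cell
    if not overlap.any():
        raise InvalidGeometryError("cluster footprint does not overlap the cell footprint")

    c = params.baseline_intensity
    b = params.background_level
    E = params.enrichment_factor
    cell_area = int(cell.sum())
    in_area = int(overlap.sum())
    if E * in_area >= cell_area:
        raise InvalidGeometryError(
            "enrichment exceeds the relocatable pool: E * cluster_area >= cell_area"
        )
    # Deplete the non-cluster interior so the whole-cell mean stays exactly c.
    interior_level = c * (cell_area - E * in_area) / (cell_area - in_area)

    poi = np.full(shape, b, dtype=np.float64)
    poi[cell] = interior_level + b
    poi[cluster] = E * c + b

    receptor = np.zeros(shape, dtype=np.float64)
    receptor[cell] = params.receptor_membrane_fraction * params.receptor_gain * c
    receptor[cluster] = params.receptor_gain * c

    bacteria = np.zeros(shape, dtype=np.float64)
    bacteria[cluster] = params.bacteria_gain * c

    channels = {
        "bacteria": _apply_noise(bacteria, params, rng),
        "receptor": _apply_noise(receptor, params, rng),
        "poi": _apply_noise(poi, params, rng),
    }
    truth = GroundTruth(
        cell_mask=cell,
        cluster_mask=cluster,
        enrichment_factor=E,
        baseline_intensity=c,
    )
    return FieldImage(channels=channels), truth


def simulate_cohort(
    conditions: Sequence[tuple[str, SimulationParams]] | Mapping[str, SimulationParams],
    n_cells: int,
    seed: int,
    experiment_factors: Sequence[float] = (1.0, 1.0, 1.0),
) -> list[SimulatedCell]:
    """Simulate ``n_cells`` fields per condition.

    Per-field seeds are derived deterministically from the master ``seed``;
    the experiment-of-origin label cycles over three pseudo-experiments
    (``exp1``..``exp3``), emulating cohorts pooled from three independent
    experiments.  ``experiment_factors`` optionally applies a multiplicative
    intensity factor (on baseline and background) per pseudo-experiment; the
    default simulates no batch effect.
    """
    if isinstance(conditions, Mapping):
        conditions = list(conditions.items())
    else:
        conditions = list(conditions)
    if not conditions:
        raise InvalidParameterError("conditions must be non-empty")
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    if len(experiment_factors) != 3:
        raise InvalidParameterError("experiment_factors must have length 3")

    master = np.random.default_rng(seed)
    cells: list[SimulatedCell] = []
    for label, params in conditions:
        for i in range(n_cells):
            child_seed = int(master.integers(0, 2**31 - 1))
            exp_idx = i % 3
            f = float(experiment_factors[exp_idx])
            p = replace(
                params,
                seed=child_seed,
                baseline_intensity=params.baseline_intensity * f,
                background_level=params.background_level * f,
            )
            fld, truth = simulate_field(p)
            cells.append(
                SimulatedCell(
                    cell_id=f"{label}_{i:03d}",
                    condition=label,
                    experiment=f"exp{exp_idx + 1}",
                    field=fld,
                    truth=truth,
                )
            )
    return cells
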