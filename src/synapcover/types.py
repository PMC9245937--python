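"""Domain containers shared across the pipeline.

Coordinate convention: images are 2D arrays indexed ``[row, col]``;
point coordinates are 0-based ``(x, y) = (col, row)``. Areas are reported
in µm² using the per-image pixel calibration (``pixel_size`` µm/pixel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

#: Channel roles an ImageStack may carry.
CHANNEL_ROLES = ("neurofilament", "gad", "synaptophysin", "dapi", "rgb")

#: The four image-QC deletion reasons, plus "pass".
QC_PASS = "pass"
QC_REASONS = ("poor_contrast", "multi_process", "incorrect_neuron", "two_neurons")
QC_STATUSES = (QC_PASS,) + QC_REASONS


@dataclass
class ImageStack:
    """Calibrated multi-channel 2D image.

    ``channels`` maps a role (see :data:`CHANNEL_ROLES`) to a 2D array;
    the ``rgb`` role holds an (H, W, 3) array. All channels must share
    the same height and width.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float  # µm / pixel
    case_id: str = ""
    image_id: str = ""

    def __post_init__(self):
        if not self.channels:
            raise InvalidInputError("ImageStack requires at least one channel")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise InvalidParameterError(f"pixel_size must be > 0, got {self.pixel_size}")
        shapes = {role: ch.shape[:2] for role, ch in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise InvalidInputError(f"channels differ in height×width: {shapes}")
        for role in self.channels:
            if role not in CHANNEL_ROLES:
                raise InvalidInputError(f"unknown channel role {role!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[:2]


@dataclass
class GroundTruth:
    """Planted truth for one synthetic image (testing plumbing only)."""

    soma_polygon: np.ndarray  # (n_vertices, 2) float, (x, y) px
    soma_area_um2: float
    puncta_centroids: np.ndarray  # (n, 2) float, (x, y) px
    n_membrane_puncta: int
    planted_coverage: float  # puncta / µm²
    intensity_scale: float
    degenerate_kind: str = "none"
    # exact positive-pixel count, for DAB images
    positive_pixels: Optional[int] = None


@dataclass
class NeuronMask:
    """Segmented perikaryon.

    The segmented region is partitioned into an interior and its
    8-connected outline: ``boundary`` pixels are region pixels with at
    least one 8-neighbour outside the region; ``interior`` is the region
    minus the boundary ring. The full segmented area is the sum of both.
    """

    interior: np.ndarray  # bool (H, W)
    boundary: np.ndarray  # bool (H, W), disjoint from interior
    pixel_size: float
    component_count: int
    solidity: float = float("nan")

    @property
    def region(self) -> np.ndarray:
        """Full segmented region (interior ∪ boundary)."""
        return self.interior | self.boundary

    @property
    def interior_area_um2(self) -> float:
        return float(self.interior.sum()) * self.pixel_size**2

    @property
    def boundary_area_um2(self) -> float:
        return float(self.boundary.sum()) * self.pixel_size**2


@dataclass
class Punctum:
    centroid: tuple[float, float]  # (x, y) px
    area_px: int
    mask: np.ndarray  # (k, 2) int array of (row, col) pixel coordinates
    peak_intensity: float


@dataclass
class PunctaSet:
    puncta: list[Punctum]
    shape: tuple[int, int]  # image height × width the detections refer to

    def __len__(self) -> int:
        return len(self.puncta)

    @property
    def centroids(self) -> np.ndarray:
        if not self.puncta:
            return np.empty((0, 2))
        return np.array([p.centroid for p in self.puncta])


@dataclass
class DABQuantResult:
    """Chromogen quantification: DAB-positive pixels per assessed area."""

    positive_pixels: int
    assessed_area_mm2: float

    @property
    def expression(self) -> float:
        """Millions of positive pixels per mm²."""
        return self.positive_pixels / 1e6 / self.assessed_area_mm2


@dataclass
class CoverageResult:
    """Per-neuron coverage record: C' = N_s / A(d).

    ``area_ad_um2`` is the area of the segmented neuron (interior plus
    delineated boundary); coverage is expressed as puncta per µm²
    neuronal membrane. QC-failed neurons are retained with their status
    so deletion bookkeeping stays reproducible.
    """

    n_synapses: int
    area_ad_um2: float
    coverage: float
    neuron_size_um2: float
    qc_status: str
    case_id: str = ""
    image_id: str = ""


@dataclass
class QCReport:
    n_photographed: int
    n_deleted: int
    deleted_by_reason: dict[str, int]
    n_retained: int
    percent_deleted: float  # stored unrounded; round for display

    @classmethod
    def from_counts(cls, n_photographed: int, deleted_by_reason: dict[str, int]) -> "QCReport":
        if n_photographed <= 0:
            raise InvalidParameterError("n_photographed must be positive")
        n_deleted = int(sum(deleted_by_reason.values()))
        return cls(
            n_photographed=int(n_photographed),
            n_deleted=n_deleted,
            deleted_by_reason=dict(deleted_by_reason),
            n_retained=int(n_photographed) - n_deleted,
            percent_deleted=100.0 * n_deleted / n_photographed,
        )


@dataclass
class CaseRecord:
    """One post-mortem case in the cohort table."""

    case_id: str
    group: str  # "MS" | "control"
    genotype: str  # "DRB15_pos" | "DRB15_neg" | "not_applicable"
    age_death: float  # years
    sex: str  # "M" | "F"
    pm_interval: float  # hours
    disease_duration: Optional[float]  # years; absent for controls
    fibrinogen: float  # arbitrary burden units
    iba1: float  # millions of pixels / mm²
    cd68: float
    tmem119: float
    gfap: float
    cd3: float  # cells / mm²
    cd8: float
    neuron_density: float  # neurons / mm²
    mean_coverage: Optional[float] = None  # puncta / µm²
    mean_neuron_size: Optional[float] = None  # µm²


@dataclass
class StatResult:
    kind: str  # "spearman" | "linear_model"
    estimate: float  # correlation r or standardized coefficient β
    p_value: float
    n: int
    outcome: str = ""
    predictor: str = ""
    covariates: list[str] = field(default_factory=list)
    stratum: str = ""
    transform: str = "none"  # applied to the outcome: "none" | "log"


@dataclass
class GroupContrast:
    group_a: str  # reference group
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    percent_difference: float  # 100 × (mean_a − mean_b) / mean_a
    adjusted_p: float
    n_a: int = 0
    n_b: int = 0
    outcome: str = ""


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    tool_version: str
    input_paths: list[str]
    output_paths: list[str]
    started: str
    finished: str
    stages: list[str] = field(default_factory=list)
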