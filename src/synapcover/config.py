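"""Parameter sets and pipeline configuration.

Every tunable of the simulator, the segmentation/detection stages, the
coverage computation and the QC rules lives here with its default, so a
run can be reproduced from the resolved configuration alone. Lengths are
in µm unless the name says pixels; intensities are fractions of full
scale (images are unit-interval floats).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from typing import Optional

import yaml

from .errors import ConfigurationError


@dataclass
class NormalizationParams:
    """Percentile rescale applied per fluorescence channel."""

    low_pct: float = 1.0
    high_pct: float = 99.0


@dataclass
class SegmentationParams:
    """Neuron-boundary segmentation (threshold → close → fill → size filter)."""

    threshold: str | float = "otsu"  # "otsu" or a fixed value in [0, 1]
    r_close_um: float = 0.6  # closing radius
    min_soma_area_um2: float = 100.0  # components below this are discarded
    # Otsu separability floor (inter-class / total variance): below this the
    # channel is structureless (pure noise) and thresholding is meaningless
    otsu_separability_min: float = 0.85


@dataclass
class PunctumParams:
    """Punctum detection (top-hat → robust threshold → watershed split)."""

    r_tophat_um: float = 1.2  # top-hat structuring radius
    smooth_sigma_um: float = 0.10  # pre-detection Gaussian smoothing
    threshold_k: float = 5.0  # background median + k · robust SD
    min_punctum_px: int = 3
    max_punctum_diameter_um: float = 1.5  # upper size bound as disc diameter
    peak_min_distance_um: float = 0.2  # local-maximum suppression radius


@dataclass
class QCParams:
    contrast_min: float = 0.15  # p99 − p1 of raw red channel, full-scale units
    solidity_min: float = 0.80


@dataclass
class CoverageParams:
    band_halfwidth_um: float = 0.5  # membrane band half-width


@dataclass
class SimulationParams:
    """Synthetic confocal image generation defaults.

    Soma areas and membrane punctum densities default to the layer-5
    pyramidal values the pipeline is designed to recover (somata in the
    ~400–530 µm² range ringed by ~0.30–0.35 puncta/µm²).
    """

    pixel_size_um: float = 0.2
    soma_area_um2: float = 450.0
    coverage: float = 0.32  # puncta per µm² of neuron area
    noise_sd: float = 0.03  # additive Gaussian, full-scale fraction
    punctum_fwhm_um: float = 0.26  # rendered width ≈ diffraction-limited FWHM
    #                                (0.51·λ/NA ≈ 0.24 µm for a far-red dye at 1.4 NA)
    punctum_min_separation_um: float = 0.5  # hard-core centre distance
    placement_band_halfwidth_um: float = 0.6  # centroid offset from boundary
    soma_intensity: float = 0.8
    n_vertices_range: tuple[int, int] = (8, 12)
    radial_jitter: float = 0.22  # fractional radius jitter of the polygon
    margin_um: float = 4.0  # image border margin around the soma
    intensity_scale_range: tuple[float, float] = (0.6, 1.4)  # per-case drift
    max_placement_attempts: int = 100000


@dataclass
class DABParams:
    od_threshold: float = 0.15  # DAB optical-density cut after deconvolution


@dataclass
class PipelineConfig:
    """Resolved configuration for an end-to-end run."""

    pixel_size_um: Optional[float] = None  # required; never defaulted silently
    seed: int = 0
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    punctum: PunctumParams = field(default_factory=PunctumParams)
    qc: QCParams = field(default_factory=QCParams)
    coverage: CoverageParams = field(default_factory=CoverageParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    dab: DABParams = field(default_factory=DABParams)
    # simulation layout for the `run` pipeline
    n_ms_cases: int = 3
    n_control_cases: int = 2
    neurons_per_case: int = 10
    ms_coverage: float = 0.299
    control_coverage: float = 0.348
    ms_soma_area_um2: float = 403.0
    control_soma_area_um2: float = 531.0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTION_TYPES = {
    "normalization": NormalizationParams,
    "segmentation": SegmentationParams,
    "punctum": PunctumParams,
    "qc": QCParams,
    "coverage": CoverageParams,
    "simulation": SimulationParams,
    "dab": DABParams,
}


def _build_section(cls, mapping, path):
    allowed = {f.name for f in fields(cls)}
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigurationError(
            f"unknown keys in config section {path!r}", [f"{path}.{k}" for k in unknown]
        )
    kwargs = dict(mapping)
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(path: str, require_pixel_size: bool = True) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    ``pixel_size_um`` must be stated explicitly: the physical calibration
    is never guessed at the pipeline level.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    return config_from_dict(raw, require_pixel_size=require_pixel_size)


def config_from_dict(raw: dict, require_pixel_size: bool = True) -> PipelineConfig:
    top_fields = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - top_fields)
    if unknown:
        raise ConfigurationError("unknown top-level config keys", unknown)
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigurationError(f"section {key!r} must be a mapping", [key])
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    if require_pixel_size:
        if cfg.pixel_size_um is None:
            raise ConfigurationError("missing required config key", ["pixel_size_um"])
        if not cfg.pixel_size_um > 0:
            raise ConfigurationError("pixel_size_um must be > 0", ["pixel_size_um"])
    # keep the per-stage simulator calibration consistent with the pipeline one
    if cfg.pixel_size_um is not None:
        cfg.simulation.pixel_size_um = cfg.pixel_size_um
    return cfg


def dump_config(cfg: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
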