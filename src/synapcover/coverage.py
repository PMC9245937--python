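"""Coverage statistic C' = N_s / A(d), neuron size, and image QC.

Combines the neuron and punctum segmentations: a punctum counts toward
N_s when its mask intersects the membrane band (the dilated neuron
boundary), and A(d) is the area of the segmented neuron — interior plus
delineated boundary, in µm². Coverage is expressed as puncta per µm²
neuronal membrane. Neurons that fail quality control keep their records
(with the failure reason) so deletion bookkeeping stays reproducible.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .config import CoverageParams, PipelineConfig, QCParams, SegmentationParams
from .errors import (
    CaseExcludedError,
    DegenerateChannelError,
    EmptyInputError,
    InvalidInputError,
    InvalidPairingError,
    InvalidParameterError,
    NoNeuronFoundError,
)
from .imgproc import detect_puncta, normalize_intensity, segment_neuron
from .types import (
    QC_PASS,
    QC_REASONS,
    CoverageResult,
    ImageStack,
    NeuronMask,
    PunctaSet,
    QCReport,
)

logger = logging.getLogger(__name__)


def membrane_band(neuron: NeuronMask, band_halfwidth_um: float) -> np.ndarray:
    """Dilate the boundary pixel set by the band half-width (binary mask)."""
    if band_halfwidth_um < 0:
        raise InvalidParameterError(
            f"band_halfwidth_um must be >= 0, got {band_halfwidth_um}"
        )
    # ceil: the discrete band must cover the full physical half-width
    radius = int(math.ceil(band_halfwidth_um / neuron.pixel_size - 1e-9))
    if radius == 0:
        return neuron.boundary.copy()
    return ndi.binary_dilation(neuron.boundary, structure=disk(radius))


def count_membrane_synapses(
    neuron: NeuronMask,
    puncta: PunctaSet,
    band_halfwidth_um: float = 0.5,
) -> int:
    """Number of puncta whose mask intersects the membrane band.

    Each punctum is counted at most once, however many of its pixels
    fall inside the band.
    """
    if neuron.interior.shape != puncta.shape:
        raise InvalidPairingError(
            f"neuron mask shape {neuron.interior.shape} does not match "
            f"puncta image shape {puncta.shape}"
        )
    band = membrane_band(neuron, band_halfwidth_um)
    count = 0
    for p in puncta.puncta:
        if band[p.mask[:, 0], p.mask[:, 1]].any():
            count += 1
    return count


def compute_neuron_size(neuron: NeuronMask) -> float:
    """Neuron size in µm²: interior area plus delineated-boundary area."""
    return neuron.interior_area_um2 + neuron.boundary_area_um2


def compute_coverage(
    neuron: NeuronMask,
    puncta: PunctaSet,
    band_halfwidth_um: float = 0.5,
    qc_status: str = QC_PASS,
    case_id: str = "",
    image_id: str = "",
) -> CoverageResult:
    """C' = N_s / A(d) for one neuron.

    A(d) is the full segmented-neuron area (interior + boundary), the
    same quantity reported as neuron size.
    """
    area_ad = neuron.interior_area_um2 + neuron.boundary_area_um2
    if area_ad <= 0:
        raise NoNeuronFoundError("segmented neuron has zero area")
    n_s = count_membrane_synapses(neuron, puncta, band_halfwidth_um)
    return CoverageResult(
        n_synapses=n_s,
        area_ad_um2=area_ad,
        coverage=n_s / area_ad,
        neuron_size_um2=compute_neuron_size(neuron),
        qc_status=qc_status,
        case_id=case_id,
        image_id=image_id,
    )


def qc_evaluate(
    image: ImageStack,
    neuron: Union[NeuronMask, Exception, None],
    qc_params: Optional[QCParams] = None,
    seg_params: Optional[SegmentationParams] = None,
) -> str:
    """Image quality control; always returns a status.

    Checked in priority order: (i) poor contrast — the raw neurofilament
    channel's robust dynamic range (p99 − p1, full-scale units) is below
    the contrast floor; (ii) two neurons — at least two components
    survived the soma-size filter; (iii) multiple processes — the
    retained component's solidity is below the floor; (iv) incorrect
    neuron — segmentation found no component of soma size; else pass.
    """
    qc_params = qc_params or QCParams()
    if "neurofilament" not in image.channels:
        raise InvalidInputError("qc_evaluate requires a 'neurofilament' channel")
    raw = image.channels["neurofilament"]
    p1, p99 = np.percentile(raw, [1, 99])
    if p99 - p1 < qc_params.contrast_min:
        return "poor_contrast"
    if isinstance(neuron, NeuronMask):
        if neuron.component_count >= 2:
            return "two_neurons"
        if neuron.solidity < qc_params.solidity_min:
            return "multi_process"
        return QC_PASS
    if neuron is None or isinstance(neuron, (NoNeuronFoundError, DegenerateChannelError)):
        return "incorrect_neuron"
    raise InvalidInputError(f"cannot interpret neuron argument {neuron!r}")


def quantify_image(
    image: ImageStack,
    config: Optional[PipelineConfig] = None,
) -> CoverageResult:
    """Run the full per-image pipeline: normalize → segment → detect → C'.

    QC-failed images still yield a record (with NaN coverage when no
    neuron could be segmented) so the deletion bookkeeping is exact.
    """
    config = config or PipelineConfig(pixel_size_um=image.pixel_size)
    px = image.pixel_size
    neuron: Union[NeuronMask, Exception, None] = None
    norm = None
    try:
        norm = normalize_intensity(image, config.normalization.low_pct,
                                   config.normalization.high_pct)
        neuron = segment_neuron(norm.channels["neurofilament"], px,
                                config.segmentation)
    except (DegenerateChannelError, NoNeuronFoundError) as err:
        neuron = err
    status = qc_evaluate(image, neuron, config.qc, config.segmentation)
    if not isinstance(neuron, NeuronMask):
        logger.debug("image %s failed QC (%s): no neuron", image.image_id, status)
        return CoverageResult(
            n_synapses=0, area_ad_um2=float("nan"), coverage=float("nan"),
            neuron_size_um2=float("nan"), qc_status=status,
            case_id=image.case_id, image_id=image.image_id,
        )
    green_role = "gad" if "gad" in image.channels else "synaptophysin"
    puncta = detect_puncta(norm.channels[green_role], px, config.punctum)
    result = compute_coverage(
        neuron, puncta, config.coverage.band_halfwidth_um,
        qc_status=status, case_id=image.case_id, image_id=image.image_id,
    )
    if status != QC_PASS:
        logger.debug("image %s failed QC: %s", image.image_id, status)
    return result


def summarize_qc(results: list[CoverageResult]) -> QCReport:
    """Deletion bookkeeping over a set of per-neuron results.

    Reason counts always sum to the number of deletions and retained +
    deleted equals the number photographed.
    """
    if not results:
        raise EmptyInputError("summarize_qc requires at least one result")
    by_reason = {reason: 0 for reason in QC_REASONS}
    for r in results:
        if r.qc_status != QC_PASS:
            by_reason[r.qc_status] += 1
    by_reason = {k: v for k, v in by_reason.items() if v}
    return QCReport.from_counts(len(results), by_reason)


def aggregate_case(
    results: list[CoverageResult],
    case_id: str,
) -> tuple[float, float, int]:
    """Unweighted case means of coverage and neuron size over passing neurons.

    Raises :class:`CaseExcludedError` when no neuron passed QC; the
    caller drops the case from cohort tables.
    """
    passing = [r for r in results
               if r.case_id == case_id and r.qc_status == QC_PASS]
    if not passing:
        raise CaseExcludedError(f"case {case_id!r} has no QC-passing neurons")
    mean_cov = float(np.mean([r.coverage for r in passing]))
    mean_size = float(np.mean([r.neuron_size_um2 for r in passing]))
    return mean_cov, mean_size, len(passing)
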