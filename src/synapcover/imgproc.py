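"""Intensity normalization and segmentation stages.

Implements parts (i) and (ii) of the coverage algorithm — neuron-boundary
segmentation from the neurofilament channel and punctum segmentation from
the synaptic channel — plus colour-deconvolution extraction of
DAB-positive pixels from brightfield RGB images.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hed
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk, white_tophat
from skimage.segmentation import watershed

from .config import DABParams, NormalizationParams, PunctumParams, SegmentationParams
from .errors import (
    DegenerateChannelError,
    InvalidInputError,
    InvalidParameterError,
    NoNeuronFoundError,
)
from .types import DABQuantResult, ImageStack, NeuronMask, Punctum, PunctaSet

#: channels the percentile rescale applies to (brightfield RGB is left alone)
_FLUORESCENCE_ROLES = ("neurofilament", "gad", "synaptophysin", "dapi")


def normalize_intensity(
    image: ImageStack,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
) -> ImageStack:
    """Per-channel percentile rescale onto [0, 1].

    Each fluorescence channel is linearly mapped so that its ``low_pct``
    percentile goes to 0 and its ``high_pct`` percentile to 1, then
    clipped. This removes per-case multiplicative intensity drift (time
    in formalin, post-mortem interval, tissue pH all shift absolute
    fluorescence): any clipping-free rescaling of the input leaves the
    output unchanged.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise InvalidParameterError(
            f"require 0 <= low_pct < high_pct <= 100, got ({low_pct}, {high_pct})"
        )
    channels = {}
    for role, ch in image.channels.items():
        if role not in _FLUORESCENCE_ROLES:
            channels[role] = ch
            continue
        lo, hi = np.percentile(ch, [low_pct, high_pct])
        if hi - lo <= 1e-12:
            raise DegenerateChannelError(
                f"channel {role!r} is constant between the {low_pct} and "
                f"{high_pct} percentiles; cannot normalize"
            )
        channels[role] = np.clip((ch.astype(float) - lo) / (hi - lo), 0.0, 1.0)
    return ImageStack(channels=channels, pixel_size=image.pixel_size,
                      case_id=image.case_id, image_id=image.image_id)


def segment_neuron(
    red_channel: np.ndarray,
    pixel_size: float,
    params: Optional[SegmentationParams] = None,
) -> NeuronMask:
    """Segment the perikaryon from the (normalized) neurofilament channel.

    Threshold (Otsu by default) → morphological closing → hole filling →
    removal of components below the minimum soma area → the largest
    surviving component becomes the neuron. ``component_count`` reports
    how many components survived the size filter (before the
    largest-component selection), which the QC stage uses to flag images
    containing two neurons.
    """
    params = params or SegmentationParams()
    if not pixel_size > 0:
        raise InvalidParameterError(f"pixel_size must be > 0, got {pixel_size}")
    if params.threshold == "otsu":
        thresh = threshold_otsu(red_channel)
        # separability guard: Otsu on a structureless (noise-only) channel
        # still returns a cut, but its between-class variance fraction is low
        above = red_channel > thresh
        w1 = above.mean()
        if 0 < w1 < 1:
            mu0 = red_channel[~above].mean()
            mu1 = red_channel[above].mean()
            eta = w1 * (1 - w1) * (mu1 - mu0) ** 2 / red_channel.var()
            if eta < params.otsu_separability_min:
                raise NoNeuronFoundError(
                    f"channel has no threshold-separable structure "
                    f"(separability {eta:.2f} < {params.otsu_separability_min})"
                )
    else:
        thresh = float(params.threshold)
    binary = red_channel > thresh
    r_close = max(1, int(round(params.r_close_um / pixel_size)))
    binary = closing(binary, disk(r_close))
    binary = ndi.binary_fill_holes(binary)

    labels = label(binary, connectivity=1)
    min_px = params.min_soma_area_um2 / pixel_size**2
    props = [p for p in regionprops(labels) if p.area >= min_px]
    if not props:
        raise NoNeuronFoundError(
            f"no component reached {params.min_soma_area_um2} µm² "
            f"({min_px:.0f} px at {pixel_size} µm/px)"
        )
    largest = max(props, key=lambda p: p.area)
    region = labels == largest.label

    # inner 8-connected outline: region pixels with an 8-neighbour outside
    eroded = ndi.binary_erosion(region, structure=np.ones((3, 3)), border_value=0)
    boundary = region & ~eroded
    interior = region & eroded
    return NeuronMask(
        interior=interior,
        boundary=boundary,
        pixel_size=pixel_size,
        component_count=len(props),
        solidity=float(largest.solidity),
    )


def detect_puncta(
    green_channel: np.ndarray,
    pixel_size: float,
    params: Optional[PunctumParams] = None,
) -> PunctaSet:
    """Detect synaptic puncta in the (normalized) synaptic channel.

    Top-hat background suppression, a robust background threshold
    (median + k·1.4826·MAD of the suppressed image), then a
    local-maximum-seeded watershed that splits touching puncta; pieces
    outside the allowed pixel-area range are discarded. Counting puncta
    rather than summing their area sidesteps the ill-defined synapse
    boundary. An empty result is valid.
    """
    params = params or PunctumParams()
    if not pixel_size > 0:
        raise InvalidParameterError(f"pixel_size must be > 0, got {pixel_size}")
    r_tophat = max(1, int(round(params.r_tophat_um / pixel_size)))
    # "crosses" decomposition is exact for a disk and much faster
    flat = white_tophat(green_channel.astype(float),
                        disk(r_tophat, decomposition="crosses"))
    sigma = params.smooth_sigma_um / pixel_size
    smooth = ndi.gaussian_filter(flat, sigma) if sigma > 0 else flat

    med = float(np.median(smooth))
    mad = float(np.median(np.abs(smooth - med)))
    # floor guards the noise-free case, where the MAD collapses to zero
    thresh = max(med + params.threshold_k * 1.4826 * mad, 0.1)
    mask = smooth > thresh
    if not mask.any():
        return PunctaSet(puncta=[], shape=green_channel.shape)

    min_distance = max(1, int(round(params.peak_min_distance_um / pixel_size)))
    peaks = peak_local_max(smooth, min_distance=min_distance,
                           threshold_abs=thresh, exclude_border=False)
    markers = np.zeros(smooth.shape, int)
    # plateau ties resolved by lexicographic (row, col) order: peak_local_max
    # returns sorted coordinates, and earlier markers keep lower labels
    for i, (r, c) in enumerate(sorted(map(tuple, peaks)), start=1):
        markers[r, c] = i
    pieces = watershed(-smooth, markers=markers, mask=mask)

    max_px = math.pi * (params.max_punctum_diameter_um / 2 / pixel_size) ** 2
    puncta = []
    for prop in regionprops(pieces, intensity_image=green_channel):
        if not (params.min_punctum_px <= prop.area <= max_px):
            continue
        coords = prop.coords  # (k, 2) (row, col)
        cy, cx = prop.centroid
        puncta.append(Punctum(
            centroid=(float(cx), float(cy)),
            area_px=int(prop.area),
            mask=coords.astype(np.int32),
            peak_intensity=float(prop.intensity_max),
        ))
    return PunctaSet(puncta=puncta, shape=green_channel.shape)


def quantify_dab(
    rgb_image: ImageStack,
    assessed_area_mm2: float,
    params: Optional[DABParams] = None,
) -> DABQuantResult:
    """Count DAB-positive pixels by colour deconvolution.

    The RGB image is unmixed into haematoxylin/eosin/DAB optical
    densities; pixels whose DAB density exceeds the threshold are
    positive. Expression is reported as millions of positive pixels per
    mm² of assessed tissue.
    """
    params = params or DABParams()
    if "rgb" not in rgb_image.channels:
        raise InvalidInputError("quantify_dab requires an 'rgb' channel")
    if not assessed_area_mm2 > 0:
        raise InvalidParameterError(
            f"assessed_area_mm2 must be > 0, got {assessed_area_mm2}"
        )
    hed = rgb2hed(rgb_image.channels["rgb"])
    positive = hed[..., 2] > params.od_threshold
    return DABQuantResult(
        positive_pixels=int(positive.sum()),
        assessed_area_mm2=float(assessed_area_mm2),
    )
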