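"""Synthetic confocal-like image generation with exact planted ground truth.

Renders two-/three-channel images of a layer-5 pyramidal soma (red:
neurofilament fill, green: GAD+ puncta on the membrane band, blue:
nuclear disc) and RGB brightfield-like DAB images, standing in for tissue
imagery so the quantitation pipeline can be validated against known truth.

Geometry is generated in µm and only rasterized at the requested pixel
calibration, so planted areas and punctum counts do not depend on the
pixel size. All randomness flows through a single seeded generator:
identical seed and parameters give bit-identical output.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hed2rgb
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .config import DABParams, SimulationParams
from .errors import InvalidParameterError, PlacementError
from .types import GroundTruth, ImageStack


# ---------------------------------------------------------------------------
# geometry helpers (µm coordinates, soma centred at the origin)
# ---------------------------------------------------------------------------

def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (n, 2) vertices."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _make_soma_polygon(rng: np.random.Generator, area_um2: float,
                       params: SimulationParams) -> np.ndarray:
    """Irregular convex-ish polygon of exactly the requested area (µm)."""
    n_lo, n_hi = params.n_vertices_range
    n = int(rng.integers(n_lo, n_hi + 1))
    angles = 2 * np.pi * (np.arange(n) + rng.uniform(-0.35, 0.35, n)) / n
    radii = 1.0 + params.radial_jitter * rng.uniform(-1, 1, n)
    verts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    verts *= math.sqrt(area_um2 / _polygon_area(verts))
    return verts


def _perimeter_edges(vertices: np.ndarray):
    """Edge vectors, lengths and cumulative arc length of a closed polygon."""
    nxt = np.roll(vertices, -1, axis=0)
    edges = nxt - vertices
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    return edges, lengths, cum


def _place_membrane_puncta(rng: np.random.Generator, vertices: np.ndarray,
                           n: int, params: SimulationParams) -> np.ndarray:
    """Uniform hard-core placement of punctum centroids on the membrane band.

    Positions are drawn uniformly along the polygon perimeter with a
    uniform normal offset within ± the placement band half-width, and
    accepted only if at least the minimum separation from every
    previously accepted centroid. Raises :class:`PlacementError` naming
    the attempted count when the band cannot hold that many centroids.
    """
    if n == 0:
        return np.empty((0, 2))
    edges, lengths, cum = _perimeter_edges(vertices)
    total = cum[-1]
    min_sep2 = params.punctum_min_separation_um ** 2
    band = params.placement_band_halfwidth_um
    placed = np.empty((n, 2))
    k = 0
    for _ in range(params.max_placement_attempts):
        s = rng.uniform(0, total)
        i = min(np.searchsorted(cum, s, side="right") - 1, len(lengths) - 1)
        t = (s - cum[i]) / lengths[i]
        point = vertices[i] + t * edges[i]
        normal = np.array([edges[i, 1], -edges[i, 0]]) / lengths[i]
        cand = point + rng.uniform(-band, band) * normal
        if k and (((placed[:k] - cand) ** 2).sum(axis=1).min() < min_sep2):
            continue
        placed[k] = cand
        k += 1
        if k == n:
            return placed
    raise PlacementError(attempted=n, placed=k)


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def _um_to_px(points_um: np.ndarray, centre_px: float, pixel_size: float) -> np.ndarray:
    """Map (x, y) µm coordinates (soma-centred) to (x, y) pixel coordinates."""
    return points_um / pixel_size + centre_px


def _rasterize_polygon(vertices_px: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = draw_polygon(vertices_px[:, 1], vertices_px[:, 0], shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def _add_gaussian_blobs(image: np.ndarray, centroids_px: np.ndarray,
                        peaks: np.ndarray, sigma_px: float) -> None:
    """Accumulate isotropic Gaussian blobs in place."""
    reach = int(math.ceil(4 * sigma_px))
    h, w = image.shape
    for (cx, cy), peak in zip(centroids_px, peaks):
        r0, r1 = max(int(cy) - reach, 0), min(int(cy) + reach + 1, h)
        c0, c1 = max(int(cx) - reach, 0), min(int(cx) + reach + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        image[r0:r1, c0:c1] += peak * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2)
        )


def _finish_channel(channel: np.ndarray, intensity_scale: float,
                    noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Apply multiplicative intensity drift, clip, add noise, clip again."""
    out = np.clip(channel * intensity_scale, 0.0, 1.0)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, out.shape)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# public renderers
# ---------------------------------------------------------------------------

def render_neuron_image(
    soma_area_um2: float,
    coverage: float,
    pixel_size: float,
    noise_sd: float = 0.03,
    intensity_scale: float = 1.0,
    seed: int = 0,
    params: Optional[SimulationParams] = None,
    case_id: str = "",
    image_id: str = "",
) -> tuple[ImageStack, GroundTruth]:
    """Render one soma with ``round(coverage × soma_area_um2)`` membrane puncta.

    Channels: red (neurofilament) is the filled soma polygon, green (gad)
    the membrane puncta, blue (dapi) a nuclear disc inside the soma. The
    planted punctum count is exact; centroids lie within the placement
    band around the polygon boundary.
    """
    params = params or SimulationParams()
    if not soma_area_um2 > 0:
        raise InvalidParameterError(f"soma_area_um2 must be > 0, got {soma_area_um2}")
    if not pixel_size > 0:
        raise InvalidParameterError(f"pixel_size must be > 0, got {pixel_size}")
    if coverage < 0:
        raise InvalidParameterError(f"coverage must be >= 0, got {coverage}")

    rng = np.random.default_rng(seed)
    verts_um = _make_soma_polygon(rng, soma_area_um2, params)
    n_puncta = int(round(coverage * soma_area_um2))
    centroids_um = _place_membrane_puncta(rng, verts_um, n_puncta, params)
    peaks = rng.uniform(0.6, 1.0, n_puncta)

    r_max = float(np.hypot(verts_um[:, 0], verts_um[:, 1]).max())
    side_um = 2 * (r_max + params.margin_um)
    n_px = int(math.ceil(side_um / pixel_size))
    centre = n_px / 2.0
    shape = (n_px, n_px)

    verts_px = _um_to_px(verts_um, centre, pixel_size)
    soma_mask = _rasterize_polygon(verts_px, shape)

    red = soma_mask.astype(float) * params.soma_intensity
    red = gaussian_filter(red, 0.5)  # mild optical softening of the edge

    green = np.zeros(shape)
    if n_puncta:
        sigma_px = params.punctum_fwhm_um / 2.3548 / pixel_size
        _add_gaussian_blobs(green, _um_to_px(centroids_um, centre, pixel_size),
                            peaks, sigma_px)

    blue = np.zeros(shape)
    nuc_r_px = 0.4 * math.sqrt(soma_area_um2 / math.pi) / pixel_size
    cx, cy = verts_px.mean(axis=0)
    rr, cc = draw_disk((cy, cx), nuc_r_px, shape=shape)
    blue[rr, cc] = 0.7

    stack = ImageStack(
        channels={
            "neurofilament": _finish_channel(red, intensity_scale, noise_sd, rng),
            "gad": _finish_channel(green, intensity_scale, noise_sd, rng),
            "dapi": _finish_channel(blue, intensity_scale, noise_sd, rng),
        },
        pixel_size=pixel_size,
        case_id=case_id,
        image_id=image_id,
    )
    truth = GroundTruth(
        soma_polygon=verts_px,
        soma_area_um2=soma_area_um2,
        puncta_centroids=_um_to_px(centroids_um, centre, pixel_size),
        n_membrane_puncta=n_puncta,
        planted_coverage=n_puncta / soma_area_um2,
        intensity_scale=intensity_scale,
        degenerate_kind="none",
    )
    return stack, truth


DEGENERATE_KINDS = ("poor_contrast", "multi_process", "two_neurons", "incorrect_neuron")


def render_degenerate_image(
    kind: str,
    seed: int = 0,
    pixel_size: float = 0.2,
    params: Optional[SimulationParams] = None,
    case_id: str = "",
    image_id: str = "",
) -> tuple[ImageStack, GroundTruth]:
    """Render an image exhibiting one of the four QC deletion defects.

    poor_contrast — red dynamic range compressed below the QC contrast
    threshold; multi_process — soma with thin elongated appendages that
    drive solidity below threshold; two_neurons — two disjoint somata
    each above the minimum soma area; incorrect_neuron — a fragment
    below the minimum soma area.
    """
    params = params or SimulationParams()
    if kind not in DEGENERATE_KINDS:
        raise InvalidParameterError(
            f"unknown degenerate kind {kind!r}; expected one of {DEGENERATE_KINDS}"
        )
    rng = np.random.default_rng(seed)

    if kind == "poor_contrast":
        import dataclasses

        dim = dataclasses.replace(params, soma_intensity=0.06, noise_sd=0.01)
        stack, truth = render_neuron_image(
            params.soma_area_um2, params.coverage, pixel_size,
            noise_sd=0.01, intensity_scale=1.0,
            seed=int(rng.integers(2**31)), params=dim,
            case_id=case_id, image_id=image_id,
        )
        truth.degenerate_kind = kind
        return stack, truth

    if kind == "incorrect_neuron":
        stack, truth = render_neuron_image(
            60.0, params.coverage, pixel_size,
            noise_sd=params.noise_sd, intensity_scale=1.0,
            seed=int(rng.integers(2**31)), params=params,
            case_id=case_id, image_id=image_id,
        )
        truth.degenerate_kind = kind
        return stack, truth

    if kind == "two_neurons":
        area = 300.0
        sub = []
        for _ in range(2):
            s, t = render_neuron_image(
                area, params.coverage, pixel_size,
                noise_sd=0.0, intensity_scale=1.0,
                seed=int(rng.integers(2**31)), params=params,
            )
            sub.append((s, t))
        h = max(s.shape[0] for s, _ in sub)
        w = sum(s.shape[1] for s, _ in sub)
        channels = {}
        for role in ("neurofilament", "gad", "dapi"):
            canvas = np.zeros((h, w))
            x0 = 0
            for s, _ in sub:
                sh, sw = s.shape
                canvas[:sh, x0:x0 + sw] = s.channels[role]
                x0 += sw
            canvas = np.clip(canvas + rng.normal(0, params.noise_sd, canvas.shape), 0, 1)
            channels[role] = canvas
        stack = ImageStack(channels=channels, pixel_size=pixel_size,
                           case_id=case_id, image_id=image_id)
        t0 = sub[0][1]
        truth = GroundTruth(
            soma_polygon=t0.soma_polygon,
            soma_area_um2=2 * area,
            puncta_centroids=t0.puncta_centroids,
            n_membrane_puncta=t0.n_membrane_puncta + sub[1][1].n_membrane_puncta,
            planted_coverage=float("nan"),
            intensity_scale=1.0,
            degenerate_kind=kind,
        )
        return stack, truth

    # multi_process: soma plus thin radiating appendages on a wider canvas
    import dataclasses

    wide = dataclasses.replace(params, margin_um=12.0)
    stack, truth = render_neuron_image(
        params.soma_area_um2, params.coverage, pixel_size,
        noise_sd=0.0, intensity_scale=1.0,
        seed=int(rng.integers(2**31)), params=wide,
        case_id=case_id, image_id=image_id,
    )
    red = stack.channels["neurofilament"].copy()
    shape = red.shape
    centre_px = truth.soma_polygon.mean(axis=0)
    proc_len_px = 0.45 * shape[0]
    proc_halfwidth_px = max(1, int(round(0.4 / pixel_size)))
    # four well-spread jittered arms so the convex hull always inflates
    base = rng.uniform(0, 2 * np.pi)
    for angle in base + 2 * np.pi * np.arange(4) / 4 + rng.uniform(-0.25, 0.25, 4):
        direction = np.array([math.cos(angle), math.sin(angle)])
        normal = np.array([-direction[1], direction[0]]) * proc_halfwidth_px
        tip = centre_px + direction * proc_len_px
        quad = np.array([centre_px + normal, tip + normal, tip - normal, centre_px - normal])
        rr, cc = draw_polygon(quad[:, 1], quad[:, 0], shape)
        red[rr, cc] = np.maximum(red[rr, cc], params.soma_intensity)
    red = np.clip(red + np.random.default_rng(seed + 1).normal(0, params.noise_sd, shape), 0, 1)
    stack.channels["neurofilament"] = red
    truth.degenerate_kind = kind
    return stack, truth


def render_dab_image(
    positive_fraction: float,
    area_mm2: float,
    pixel_size: float,
    seed: int = 0,
    case_id: str = "",
    image_id: str = "",
) -> tuple[ImageStack, GroundTruth]:
    """Render an RGB DAB/haematoxylin image with an exact positive-pixel count.

    A smoothed random field is thresholded at the quantile giving exactly
    ``round(positive_fraction × n_pixels)`` DAB-positive (brown) pixels;
    the remainder is haematoxylin-blue. Colours are composed in
    haematoxylin/DAB optical-density space and converted to RGB, so the
    standard colour-deconvolution route recovers the planted mask.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise InvalidParameterError(
            f"positive_fraction must be in [0, 1], got {positive_fraction}"
        )
    if not area_mm2 > 0:
        raise InvalidParameterError(f"area_mm2 must be > 0, got {area_mm2}")
    if not pixel_size > 0:
        raise InvalidParameterError(f"pixel_size must be > 0, got {pixel_size}")
    rng = np.random.default_rng(seed)
    side_um = math.sqrt(area_mm2) * 1000.0
    n_side = int(round(side_um / pixel_size))
    shape = (n_side, n_side)
    n_pixels = n_side * n_side
    n_pos = int(round(positive_fraction * n_pixels))

    mask = np.zeros(n_pixels, bool)
    if 0 < n_pos < n_pixels:
        field = gaussian_filter(rng.standard_normal(shape), sigma=5.0).ravel()
        mask[np.argpartition(-field, n_pos - 1)[:n_pos]] = True
    elif n_pos == n_pixels:
        mask[:] = True
    mask = mask.reshape(shape)

    hed = np.zeros(shape + (3,))
    hed[..., 0] = np.where(mask, 0.10, 0.50) + 0.05 * rng.random(shape)
    hed[..., 2] = np.where(mask, 0.70, 0.02) + 0.05 * rng.random(shape)
    rgb = hed2rgb(hed)

    stack = ImageStack(channels={"rgb": rgb}, pixel_size=pixel_size,
                       case_id=case_id, image_id=image_id)
    truth = GroundTruth(
        soma_polygon=np.empty((0, 2)),
        soma_area_um2=float("nan"),
        puncta_centroids=np.empty((0, 2)),
        n_membrane_puncta=0,
        planted_coverage=float("nan"),
        intensity_scale=1.0,
        degenerate_kind="none",
        positive_pixels=int(mask.sum()),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# case-level convenience generator
# ---------------------------------------------------------------------------

def simulate_case(
    case_id: str,
    n_neurons: int,
    coverage: float,
    soma_area_mean_um2: float,
    pixel_size: float,
    seed: int,
    params: Optional[SimulationParams] = None,
    soma_area_cv: float = 0.15,
    coverage_jitter_sd: float = 0.08,
) -> list[tuple[ImageStack, GroundTruth]]:
    """Render the image set for one synthetic case.

    One multiplicative intensity-drift factor is drawn per case (emulating
    fixation/post-mortem confounders); per-neuron soma areas are
    log-normal around the case mean and per-neuron planted coverage is
    jittered around the case value with zero-mean relative noise.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    scale = rng.uniform(*params.intensity_scale_range)
    out = []
    for j in range(n_neurons):
        sigma = math.sqrt(math.log(1 + soma_area_cv**2))
        area = soma_area_mean_um2 * math.exp(rng.normal(-sigma**2 / 2, sigma))
        cov = max(coverage * (1 + coverage_jitter_sd * rng.normal()), 0.0)
        stack, truth = render_neuron_image(
            area, cov, pixel_size,
            noise_sd=params.noise_sd, intensity_scale=scale,
            seed=int(rng.integers(2**31)), params=params,
            case_id=case_id, image_id=f"{case_id}_n{j:03d}",
        )
        out.append((stack, truth))
    return out
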