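"""Shared fixtures and helpers for the synapcover test suite."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from synapcover.config import PipelineConfig


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig(pixel_size_um=0.2)


def match_detections(true_xy: np.ndarray, det_xy: np.ndarray,
                     max_dist_px: float = 2.0) -> tuple[int, int, int]:
    """One-to-one matching of detections to planted centroids.

    Returns (true positives, false positives, false negatives).
    """
    if len(det_xy) == 0:
        return 0, 0, len(true_xy)
    if len(true_xy) == 0:
        return 0, len(det_xy), 0
    dist = np.linalg.norm(true_xy[:, None, :] - det_xy[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(np.minimum(dist, 5 * max_dist_px))
    tp = int((dist[rows, cols] < max_dist_px).sum())
    return tp, len(det_xy) - tp, len(true_xy) - tp


@pytest.fixture
def matcher():
    return match_detections
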