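"""Reading and writing the pipeline's on-disk formats.

Images travel as multi-page TIFF, one page per channel with the channel
role (and calibration) recorded in the page description tag as JSON, so
a stack written by the simulator round-trips without a side channel.
Tables are CSV with documented column order.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidInputError
from .types import CHANNEL_ROLES, CoverageResult, GroundTruth, ImageStack

_CHANNEL_ORDER = ["neurofilament", "gad", "synaptophysin", "dapi", "rgb"]


def write_image_stack(stack: ImageStack, path: str) -> None:
    """Write one page per channel; role and calibration in the description."""
    with tifffile.TiffWriter(path) as tif:
        for role in _CHANNEL_ORDER:
            if role not in stack.channels:
                continue
            desc = json.dumps({
                "role": role,
                "pixel_size_um": stack.pixel_size,
                "case_id": stack.case_id,
                "image_id": stack.image_id,
            })
            data = stack.channels[role].astype(np.float32)
            tif.write(data, description=desc,
                      photometric="rgb" if role == "rgb" else "minisblack")


def read_image_stack(
    path: str,
    role_map: Optional[dict[int, str]] = None,
    pixel_size: Optional[float] = None,
) -> ImageStack:
    """Read a multi-page TIFF into an ImageStack.

    Channel roles are resolved from the per-page JSON description written
    by :func:`write_image_stack`; for foreign files a ``role_map``
    (page index → role) and explicit ``pixel_size`` may be supplied.
    """
    try:
        tif = tifffile.TiffFile(path)
    except Exception as err:  # noqa: BLE001 - surface the path in the error
        raise InvalidInputError(f"cannot read TIFF {path!r}: {err}") from err
    channels: dict[str, np.ndarray] = {}
    px = pixel_size
    case_id = image_id = ""
    with tif:
        for idx, page in enumerate(tif.pages):
            role = None
            desc = page.description
            if desc:
                try:
                    meta = json.loads(desc)
                    role = meta.get("role")
                    px = px or meta.get("pixel_size_um")
                    case_id = case_id or meta.get("case_id", "")
                    image_id = image_id or meta.get("image_id", "")
                except (ValueError, AttributeError):
                    role = None
            if role is None and role_map is not None:
                role = role_map.get(idx)
            if role is None or role not in CHANNEL_ROLES:
                raise InvalidInputError(
                    f"cannot resolve channel role for page {idx} of {path!r}; "
                    f"provide a role_map"
                )
            channels[role] = page.asarray()
    if px is None:
        raise InvalidInputError(
            f"no pixel size recorded in {path!r}; pass pixel_size explicitly"
        )
    return ImageStack(channels=channels, pixel_size=float(px),
                      case_id=case_id, image_id=image_id)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["image_id", "case_id", "n_synapses", "area_ad_um2",
                  "coverage", "neuron_size_um2", "qc_status"]

GROUND_TRUTH_COLUMNS = ["image_id", "soma_area_um2", "n_membrane_puncta",
                        "planted_coverage", "degenerate_kind"]


def results_to_frame(results: list[CoverageResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(r, c) for c in RESULT_COLUMNS} for r in results],
        columns=RESULT_COLUMNS,
    )


def write_results_csv(results: list[CoverageResult], path: str) -> None:
    results_to_frame(results).to_csv(path, index=False)


def write_ground_truth_csv(truths: list[tuple[str, GroundTruth]], path: str) -> None:
    rows = [{
        "image_id": image_id,
        "soma_area_um2": t.soma_area_um2,
        "n_membrane_puncta": t.n_membrane_puncta,
        "planted_coverage": t.planted_coverage,
        "degenerate_kind": t.degenerate_kind,
    } for image_id, t in truths]
    pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS).to_csv(path, index=False)


def list_image_files(images_dir: str) -> list[str]:
    return sorted(
        os.path.join(images_dir, f)
        for f in os.listdir(images_dir)
        if f.lower().endswith((".tif", ".tiff"))
    )
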