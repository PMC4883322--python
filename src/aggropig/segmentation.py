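"""Standing-pig segmentation from single top-view depth frames.

A depth frame is converted to a height-above-floor map; pixels at least
``standing_mm`` above the pen floor are grouped into 8-connected
components. Each sufficiently large component becomes a pig region with
its barycenter (mean pixel coordinate), tight axis-aligned bounding
rectangle, area and median body height. Lying pigs fall below the height
threshold and are deliberately never segmented: resting animals do not
take part in the interactions this pipeline scores, so only standing
regions proceed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .depth_io import DepthFrame, SequenceMeta

__all__ = [
    "PigRegion",
    "SegmentationParams",
    "height_map",
    "segment_pigs",
    "classify_posture",
    "regions_to_rows",
]

#: Height (mm above floor) at or above which a region counts as standing.
DEFAULT_STANDING_MM = 250.0
#: Minimum component size kept, ~half the smallest simulated pig ellipse.
DEFAULT_MIN_AREA_PX = 600


@dataclass(frozen=True)
class SegmentationParams:
    standing_mm: float = DEFAULT_STANDING_MM
    min_area_px: int = DEFAULT_MIN_AREA_PX

    def __post_init__(self) -> None:
        if self.standing_mm <= 0:
            raise ValueError(f"standing_mm must be positive, got {self.standing_mm}")
        if self.min_area_px < 1:
            raise ValueError(f"min_area_px must be >= 1, got {self.min_area_px}")


@dataclass
class PigRegion:
    """One connected set of standing-height pixels in a frame.

    ``pixels`` is an (N, 2) array of (row, col) coordinates; ``barycenter``
    their arithmetic mean; ``rect`` the tight axis-aligned
    (min_row, min_col, max_row, max_col) box (inclusive bounds).
    """

    pixels: np.ndarray
    barycenter: tuple[float, float]
    rect: tuple[int, int, int, int]
    area: int
    median_height_mm: float
    posture: str  # "standing" | "lying"

    def __post_init__(self) -> None:
        if self.area != len(self.pixels) or self.area <= 0:
            raise ValueError("area must equal the (positive) pixel count")
        r, c = self.barycenter
        min_r, min_c, max_r, max_c = self.rect
        if not (min_r <= r <= max_r and min_c <= c <= max_c):
            raise ValueError("barycenter must lie inside rect")


def height_map(frame: DepthFrame, meta: SequenceMeta) -> np.ndarray:
    """Per-pixel height above the pen floor, in millimetres.

    ``floor_depth_mm - depth`` where a depth reading exists; 0 where the
    sensor reported no return (depth 0); clipped below at 0 so floor
    pixels whose noisy reading lies beyond the floor plane stay at 0.
    """
    depth = np.asarray(frame.values, dtype=np.float64)
    heights = np.clip(meta.floor_depth_mm - depth, 0.0, None)
    heights[depth == 0] = 0.0
    return heights


def classify_posture(median_height_mm: float, standing_mm: float = DEFAULT_STANDING_MM) -> str:
    """Standing/lying decision: standing iff median height >= threshold."""
    return "standing" if median_height_mm >= standing_mm else "lying"


def segment_pigs(
    heights: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> list[PigRegion]:
    """8-connected components of ``heights >= standing_mm``, area-filtered.

    Returns regions ordered by their first (scan-order) pixel. An empty
    frame (nothing standing) yields an empty list.
    """
    mask = np.asarray(heights) >= params.standing_mm
    labels = measure.label(mask, connectivity=2)
    regions: list[PigRegion] = []
    for props in measure.regionprops(labels):
        if props.area < params.min_area_px:
            continue
        coords = props.coords  # (N, 2) row, col
        med = float(np.median(heights[coords[:, 0], coords[:, 1]]))
        min_r, min_c, max_r, max_c = props.bbox[0], props.bbox[1], props.bbox[2] - 1, props.bbox[3] - 1
        regions.append(
            PigRegion(
                pixels=coords,
                barycenter=(float(props.centroid[0]), float(props.centroid[1])),
                rect=(min_r, min_c, max_r, max_c),
                area=int(props.area),
                median_height_mm=med,
                posture=classify_posture(med, params.standing_mm),
            )
        )
    return regions


def regions_to_rows(frame_index: int, regions: list[PigRegion]) -> list[dict]:
    """Flatten regions for CSV export (one dict per region)."""
    rows = []
    for i, reg in enumerate(regions):
        rows.append(
            {
                "frame": frame_index,
                "region_id": i,
                "barycenter_row": reg.barycenter[0],
                "barycenter_col": reg.barycenter[1],
                "min_row": reg.rect[0],
                "min_col": reg.rect[1],
                "max_row": reg.rect[2],
                "max_col": reg.rect[3],
                "area": reg.area,
                "median_height_mm": reg.median_height_mm,
                "posture": reg.posture,
            }
        )
    return rows
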