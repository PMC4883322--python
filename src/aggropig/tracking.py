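"""Identity tracking of pig regions across frames.

Pigs are tracked by their region barycenters: consecutive positions of
the same animal are close, so a greedy one-to-one matcher pairs active
tracks with current-frame regions in ascending order of Euclidean
distance, accepting only pairs closer than a threshold. Unmatched
regions open new tracks; tracks unmatched for ``max_gap`` consecutive
frames are retired. When two formerly separate pigs press into a single
oversized blob, both tracks adopt the blob's barycenter and the frames
are flagged "merged" so the episode stage can treat them as contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .depth_io import SequenceMeta
from .segmentation import PigRegion

__all__ = [
    "Track",
    "TrackingParams",
    "match_regions",
    "compute_speeds",
    "track_sequence",
    "tracks_to_rows",
]


@dataclass(frozen=True)
class TrackingParams:
    #: Max barycenter displacement (px) joining a track to a region.
    max_dist_px: float = 30.0
    #: Consecutive missed frames after which a track deactivates.
    max_gap: int = 5
    #: Area factor over the median single-pig area marking a merged blob.
    merged_area_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.max_dist_px <= 0:
            raise ValueError(f"max_dist_px must be positive, got {self.max_dist_px}")
        if self.max_gap < 0:
            raise ValueError(f"max_gap must be >= 0, got {self.max_gap}")


@dataclass
class Track:
    """One pig identity: a time-indexed barycenter sequence.

    ``points`` holds (frame_index, (row, col)) with strictly increasing
    frame indices. ``merged_frames`` marks frames where the position came
    from a shared (merged) blob rather than the pig's own region.
    """

    id: int
    points: list[tuple[int, tuple[float, float]]] = field(default_factory=list)
    active: bool = True
    misses: int = 0
    merged_frames: set[int] = field(default_factory=set)

    def add_point(self, frame_index: int, barycenter: tuple[float, float]) -> None:
        if self.points and frame_index <= self.points[-1][0]:
            raise ValueError("frame indices must be strictly increasing")
        self.points.append((frame_index, barycenter))
        self.misses = 0

    @property
    def last_point(self) -> tuple[int, tuple[float, float]]:
        return self.points[-1]

    def position_at(self, frame_index: int) -> tuple[float, float] | None:
        for f, p in self.points:
            if f == frame_index:
                return p
        return None


def _euclidean(a: tuple[float, float], b: tuple[float, float]) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def match_regions(
    active_tracks: list[Track],
    regions: list[PigRegion],
    max_dist_px: float,
) -> tuple[dict[int, int], list[int]]:
    """Greedy one-to-one assignment of tracks to regions.

    Candidate (track, region) pairs with barycenter distance
    <= ``max_dist_px`` are taken in ascending distance order, each track
    and region used at most once. Distance ties break on lower track id,
    then lower region index, for determinism.

    Returns ``(assignment, new_regions)`` where ``assignment`` maps
    track id -> region index and ``new_regions`` lists indices of
    regions left unmatched (these should open new tracks).
    """
    candidates = []
    for t in active_tracks:
        for j, reg in enumerate(regions):
            d = _euclidean(t.last_point[1], reg.barycenter)
            if d <= max_dist_px:
                candidates.append((d, t.id, j))
    candidates.sort()

    assignment: dict[int, int] = {}
    used_regions: set[int] = set()
    for d, tid, j in candidates:
        if tid in assignment or j in used_regions:
            continue
        assignment[tid] = j
        used_regions.add(j)
    new_regions = [j for j in range(len(regions)) if j not in used_regions]
    return assignment, new_regions


def compute_speeds(track: Track, meta: SequenceMeta) -> list[float]:
    """Per-step speeds along a track.

    Speed between consecutive recorded points is Euclidean displacement
    (px) divided by the frame gap, times fps — i.e. px/s. When the meta
    carries a ``px_per_cm`` calibration, speeds are returned in cm/s.
    Tracks with fewer than two points yield an empty list.
    """
    if len(track.points) < 2:
        return []
    speeds = []
    for (f0, p0), (f1, p1) in zip(track.points, track.points[1:]):
        gap = f1 - f0
        v = _euclidean(p0, p1) / gap * meta.fps
        if meta.px_per_cm is not None:
            v /= meta.px_per_cm
        speeds.append(v)
    return speeds


def track_sequence(
    regions_by_frame: list[list[PigRegion]],
    params: TrackingParams = TrackingParams(),
) -> list[Track]:
    """Run the matcher over a whole sequence of per-frame region lists.

    Frame t's regions are matched against tracks active at t; unmatched
    regions start fresh ids; a track missing for more than ``max_gap``
    frames is deactivated. The merged-blob rule then attaches each still
    unmatched, recently seen track to a nearby oversized region (area >
    ``merged_area_factor`` x running median single-pig area), flagging
    those frames as merged on every track sharing the blob.
    """
    tracks: list[Track] = []
    next_id = 0
    single_areas: list[int] = []  # areas of 1:1-matched regions

    for t, regions in enumerate(regions_by_frame):
        active = [tr for tr in tracks if tr.active]
        assignment, new_regions = match_regions(active, regions, params.max_dist_px)

        region_claims: dict[int, list[int]] = {}  # region idx -> track ids
        for tid, j in assignment.items():
            region_claims.setdefault(j, []).append(tid)

        by_id = {tr.id: tr for tr in tracks}
        for tid, j in assignment.items():
            by_id[tid].add_point(t, regions[j].barycenter)

        # Merged-blob rule: a lost track near an oversized region rides
        # along on that region's barycenter.
        med_area = float(np.median(single_areas)) if single_areas else None
        unmatched = [tr for tr in active if tr.id not in assignment]
        for tr in unmatched:
            attached = False
            if med_area is not None:
                for j, reg in enumerate(regions):
                    big = reg.area > params.merged_area_factor * med_area
                    near = (
                        _euclidean(tr.last_point[1], reg.barycenter)
                        <= 2 * params.max_dist_px
                    )
                    if big and near:
                        tr.add_point(t, reg.barycenter)
                        tr.merged_frames.add(t)
                        for other_tid in region_claims.get(j, []):
                            by_id[other_tid].merged_frames.add(t)
                        region_claims.setdefault(j, []).append(tr.id)
                        attached = True
                        break
            if not attached:
                tr.misses += 1
                if tr.misses > params.max_gap:
                    tr.active = False

        for j in new_regions:
            tr = Track(id=next_id)
            next_id += 1
            tr.add_point(t, regions[j].barycenter)
            tracks.append(tr)
            region_claims.setdefault(j, []).append(tr.id)

        for j, claimants in region_claims.items():
            if len(claimants) == 1:
                single_areas.append(regions[j].area)

    return tracks


def tracks_to_rows(tracks: list[Track], meta: SequenceMeta) -> list[dict]:
    """Flatten tracks for CSV export: one row per (track, frame)."""
    rows = []
    for tr in tracks:
        speeds = compute_speeds(tr, meta)
        for i, (f, (r, c)) in enumerate(tr.points):
            rows.append(
                {
                    "track_id": tr.id,
                    "frame": f,
                    "row": r,
                    "col": c,
                    "speed_px_s": speeds[i - 1] if i > 0 else np.nan,
                    "merged_flag": f in tr.merged_frames,
                }
            )
    return rows
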