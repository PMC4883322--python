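"""Contact detection and interaction-episode segmentation.

An interaction episode is a maximal run of frames during which two
standing pigs stay in close physical contact for at least one second.
Contact at a frame means either the two barycenters are within
``contact_dist_px`` of each other or the pigs were fused into one
merged blob at that frame. Short breaks in contact (up to
``max_gap_frames``) are bridged so momentary tracking dropouts do not
split one bout into two.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .depth_io import SequenceMeta
from .tracking import Track, _euclidean

__all__ = [
    "InteractionEpisode",
    "EpisodeParams",
    "contact_pairs",
    "segment_episodes",
    "episodes_to_rows",
]

#: 1.2 x mean simulated pig body length (56 px) on the ground plane.
DEFAULT_CONTACT_DIST_PX = 67.2
#: Minimum bout duration in seconds for an episode to count.
DEFAULT_MIN_DURATION_S = 1.0
#: Contact runs separated by gaps up to this many frames are bridged.
DEFAULT_MAX_GAP_FRAMES = 5


@dataclass(frozen=True)
class EpisodeParams:
    contact_dist_px: float = DEFAULT_CONTACT_DIST_PX
    min_duration_s: float = DEFAULT_MIN_DURATION_S
    max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES

    def __post_init__(self) -> None:
        if self.contact_dist_px <= 0:
            raise ValueError("contact_dist_px must be positive")
        if self.min_duration_s <= 0:
            raise ValueError("min_duration_s must be positive")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


@dataclass
class InteractionEpisode:
    """A contact bout between exactly two tracked pigs.

    ``start_frame``/``end_frame`` are an inclusive interval;
    ``duration_s`` counts frames, so a 30-frame bout at 30 fps is 1 s.
    """

    episode_id: int
    track_ids: tuple[int, int]
    start_frame: int
    end_frame: int
    duration_s: float
    label: str | None = None  # normal | knocking | chasing

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be >= start_frame")
        if len(set(self.track_ids)) != 2:
            raise ValueError("an episode involves exactly 2 distinct tracks")


def contact_pairs(
    tracks: list[Track],
    contact_dist_px: float = DEFAULT_CONTACT_DIST_PX,
) -> dict[int, set[tuple[int, int]]]:
    """Per-frame sets of track-id pairs in contact.

    A pair is in contact at frame t iff both tracks have a position at t
    and either their barycenter distance is <= ``contact_dist_px`` or at
    least one of them is flagged merged at t (fused blob, distance 0).
    Pair keys are ordered (low id, high id). Frames with no contact are
    omitted from the result.
    """
    positions: dict[int, dict[int, tuple[float, float]]] = {}
    for tr in tracks:
        for f, p in tr.points:
            positions.setdefault(f, {})[tr.id] = p

    result: dict[int, set[tuple[int, int]]] = {}
    for f, by_id in positions.items():
        for a, b in combinations(sorted(by_id), 2):
            ta = next(t for t in tracks if t.id == a)
            tb = next(t for t in tracks if t.id == b)
            merged = f in ta.merged_frames and f in tb.merged_frames
            if merged or _euclidean(by_id[a], by_id[b]) <= contact_dist_px:
                result.setdefault(f, set()).add((a, b))
    return result


def segment_episodes(
    pairs_by_frame: dict[int, set[tuple[int, int]]],
    meta: SequenceMeta,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES,
) -> list[InteractionEpisode]:
    """Turn per-frame contact into episodes of sufficient duration.

    For each pair, contact frames are grouped into maximal runs, bridging
    gaps of at most ``max_gap_frames`` missing frames; a run spanning
    frames [s, e] lasts (e - s + 1)/fps seconds and becomes an episode
    iff that duration is >= ``min_duration_s`` (inclusive threshold).
    Episodes are ordered by (start_frame, pair).
    """
    frames_per_pair: dict[tuple[int, int], list[int]] = {}
    for f in sorted(pairs_by_frame):
        for pair in pairs_by_frame[f]:
            frames_per_pair.setdefault(pair, []).append(f)

    episodes: list[InteractionEpisode] = []
    for pair, frames in frames_per_pair.items():
        run_start = frames[0]
        prev = frames[0]
        runs = []
        for f in frames[1:]:
            if f - prev > max_gap_frames + 1:
                runs.append((run_start, prev))
                run_start = f
            prev = f
        runs.append((run_start, prev))
        for s, e in runs:
            duration = (e - s + 1) / meta.fps
            if duration >= min_duration_s:
                episodes.append(
                    InteractionEpisode(
                        episode_id=-1,
                        track_ids=pair,
                        start_frame=s,
                        end_frame=e,
                        duration_s=duration,
                    )
                )
    episodes.sort(key=lambda ep: (ep.start_frame, ep.track_ids))
    for i, ep in enumerate(episodes):
        ep.episode_id = i
    return episodes


def episodes_to_rows(episodes: list[InteractionEpisode]) -> list[dict]:
    return [
        {
            "episode_id": ep.episode_id,
            "track_a": ep.track_ids[0],
            "track_b": ep.track_ids[1],
            "start_frame": ep.start_frame,
            "end_frame": ep.end_frame,
            "duration_s": ep.duration_s,
            "label": ep.label if ep.label is not None else "",
        }
        for ep in episodes
    ]
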