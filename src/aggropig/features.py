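"""Five-dimensional activity descriptor for an interaction episode.

Per episode the descriptor is (v_min, v_max, v_mean, v_std, dist): the
minimum, maximum, mean and population standard deviation of the pooled
per-step speeds of BOTH interacting pigs over the episode interval, and
the mean barycenter distance between the two pigs across episode frames.
Merged-blob frames contribute distance 0 (the animals share one blob).
Units are px and px/s unless the sequence carries a px-per-cm
calibration, in which case cm and cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .depth_io import SequenceMeta
from .episodes import InteractionEpisode
from .tracking import Track, _euclidean

__all__ = [
    "FeatureVector",
    "InsufficientDataError",
    "extract_features",
    "features_to_table",
    "table_to_feature_matrix",
]

FEATURE_COLUMNS = ["v_min", "v_max", "v_mean", "v_std", "dist"]


class InsufficientDataError(ValueError):
    """Episode too short to carry any speed information."""


@dataclass(frozen=True)
class FeatureVector:
    v_min: float
    v_max: float
    v_mean: float
    v_std: float
    dist: float
    episode_id: int = -1
    label: str | None = None

    def __post_init__(self) -> None:
        if not (self.v_min <= self.v_mean <= self.v_max):
            raise ValueError("speed statistics must satisfy min <= mean <= max")
        if self.v_std < 0 or self.dist < 0:
            raise ValueError("v_std and dist must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.v_min, self.v_max, self.v_mean, self.v_std, self.dist])


def _steps_within(
    track: Track, start: int, end: int, meta: SequenceMeta
) -> list[float]:
    """Per-step speeds of one track restricted to [start, end]."""
    pts = [(f, p) for f, p in track.points if start <= f <= end]
    speeds = []
    for (f0, p0), (f1, p1) in zip(pts, pts[1:]):
        v = _euclidean(p0, p1) / (f1 - f0) * meta.fps
        if meta.px_per_cm is not None:
            v /= meta.px_per_cm
        speeds.append(v)
    return speeds


def extract_features(
    episode: InteractionEpisode,
    tracks: list[Track],
    meta: SequenceMeta,
) -> FeatureVector:
    """Compute the 5-feature descriptor for one episode.

    Both tracks must cover the episode interval (merged frames count as
    coverage). Speeds from the two pigs are pooled into one sample;
    v_std is the population (divide-by-n) standard deviation. Distance
    is averaged over frames where both positions exist, taking 0 on
    merged frames.
    """
    if episode.end_frame - episode.start_frame < 1:
        raise InsufficientDataError(
            f"episode {episode.episode_id} spans < 2 frames"
        )
    a, b = episode.track_ids
    track_a = next(t for t in tracks if t.id == a)
    track_b = next(t for t in tracks if t.id == b)

    speeds = _steps_within(track_a, episode.start_frame, episode.end_frame, meta)
    speeds += _steps_within(track_b, episode.start_frame, episode.end_frame, meta)
    if not speeds:
        raise InsufficientDataError(
            f"episode {episode.episode_id}: no speed steps inside interval"
        )

    pos_a = dict(track_a.points)
    pos_b = dict(track_b.points)
    dists = []
    for f in range(episode.start_frame, episode.end_frame + 1):
        if f in track_a.merged_frames and f in track_b.merged_frames:
            dists.append(0.0)
        elif f in pos_a and f in pos_b:
            d = _euclidean(pos_a[f], pos_b[f])
            if meta.px_per_cm is not None:
                d /= meta.px_per_cm
            dists.append(d)

    v = np.asarray(speeds)
    return FeatureVector(
        v_min=float(v.min()),
        v_max=float(v.max()),
        v_mean=float(v.mean()),
        v_std=float(v.std()),  # population SD
        dist=float(np.mean(dists)),
        episode_id=episode.episode_id,
        label=episode.label,
    )


def features_to_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """One row per episode: episode_id, the 5 features, label."""
    rows = [
        {
            "episode_id": fv.episode_id,
            **dict(zip(FEATURE_COLUMNS, fv.as_array())),
            "label": fv.label if fv.label is not None else "",
        }
        for fv in vectors
    ]
    return pd.DataFrame(rows, columns=["episode_id", *FEATURE_COLUMNS, "label"])


def table_to_feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature table into (X, labels) for the classifier."""
    X = table[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    y = table["label"].to_numpy()
    return X, y
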