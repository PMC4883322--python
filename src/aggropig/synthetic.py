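"""Synthetic top-view depth-video generator with ground truth.

Real pen recordings of pig aggression are private, so every pipeline
stage is exercised on simulated depth video instead: a flat pen floor at
a fixed camera distance, rigid elliptical pig bodies rendered at lying
or standing height, i.i.d. Gaussian depth noise and a small fraction of
dropout (zero) pixels mimicking time-of-flight shadow.

Behaviors are expressed purely through kinematics — which is all the
five-feature descriptor can see:

- ``rest``            two lying pigs, no motion (below the standing
                      threshold, so segmentation must find nothing);
- ``walk_alone``      one standing pig on a smooth arc at moderate speed;
- ``walk_together``   two standing pigs side by side on concentric arcs
                      at moderate speed and stable separation (the
                      "normal interaction" class);
- ``knocking``        head-to-body knocking: an attacker perpendicular
                      to a near-stationary receiver, lunging repeatedly
                      — short displacement, high burst speed, high speed
                      spread;
- ``chasing``         one pig pursuing another along the same arc at
                      high sustained speed with a small gap.

Every episode carries exact ground-truth barycenters per pig and, for
two-pig interactions, the true episode interval and label; output is a
pure function of the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .depth_io import DepthFrame, SequenceMeta, write_depth_sequence
from .episodes import InteractionEpisode
from .tracking import Track

__all__ = [
    "SimConfig",
    "GroundTruth",
    "BEHAVIORS",
    "simulate_episode",
    "iter_corpus",
    "generate_corpus",
    "ground_truth_tracks",
    "ground_truth_features",
]

BEHAVIORS = ("rest", "walk_alone", "walk_together", "knocking", "chasing")
#: Behavior used for the "normal interaction" class of the corpus.
NORMAL_BEHAVIOR = "walk_together"


@dataclass(frozen=True)
class SimConfig:
    """The stated world of the simulator.

    Geometry mirrors the reference sensor (512 x 424 px at 30 fps over a
    pen floor ~2.5 m below the camera). Pig bodies are 56 x 28 px
    ellipses, backs ~400 mm above the floor when standing and ~150 mm
    when lying, straddling the 250 mm standing threshold. Speed ranges
    (px/s) put the normal class well below the aggressive classes:
    chasing has high sustained speed, knocking has high-amplitude bursts
    (high v_max / v_std) around a near-constant small gap.
    ``separation`` scales the kinematic contrast between aggressive and
    normal classes (1 = default world; smaller values make the classes
    harder to tell apart for robustness testing).
    """

    arena_height_px: int = 424
    arena_width_px: int = 512
    fps: float = 30.0
    floor_depth_mm: float = 2500.0

    pig_semi_major_px: float = 28.0
    pig_semi_minor_px: float = 14.0
    standing_height_mm: float = 400.0
    lying_height_mm: float = 150.0
    standing_threshold_mm: float = 250.0

    noise_sd_mm: float = 10.0
    dropout_frac: float = 0.01

    duration_s_range: tuple[float, float] = (1.5, 2.5)
    walk_speed_px_s: tuple[float, float] = (15.0, 35.0)
    walk_separation_px: tuple[float, float] = (40.0, 55.0)
    knock_base_dist_px: tuple[float, float] = (51.0, 55.0)
    knock_amp_px: tuple[float, float] = (5.0, 7.0)
    knock_freq_hz: tuple[float, float] = (2.8, 3.5)
    knock_recoil: float = 0.6
    chase_speed_px_s: tuple[float, float] = (90.0, 140.0)
    # nose-to-tail center gap: above one body length (no blob fusion),
    # below the 1.2x-body-length contact distance
    chase_gap_px: tuple[float, float] = (60.0, 65.0)
    separation: float = 1.0

    n_normal: int = 215
    n_knocking: int = 61
    n_chasing: int = 54
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.standing_height_mm
            > self.standing_threshold_mm
            > self.lying_height_mm
        ):
            raise ValueError(
                "need standing height > standing threshold > lying height"
            )
        for name in (
            "arena_height_px",
            "arena_width_px",
            "fps",
            "floor_depth_mm",
            "pig_semi_major_px",
            "pig_semi_minor_px",
            "noise_sd_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout_frac < 1:
            raise ValueError("dropout_frac must be in [0, 1)")
        if self.separation <= 0:
            raise ValueError("separation must be positive")

    def meta(self) -> SequenceMeta:
        return SequenceMeta(
            fps=self.fps, depth_scale=1.0, floor_depth_mm=self.floor_depth_mm
        )

    @property
    def body_length_px(self) -> float:
        return 2 * self.pig_semi_major_px


@dataclass
class GroundTruth:
    """Exact per-frame kinematics and episode labeling of one simulation.

    ``positions[pig_id]`` is an (n_frames, 2) array of (row, col)
    barycenters; ``headings`` the body-axis angle per frame (radians);
    ``standing`` whether the pig is upright (and hence segmentable).
    ``episode`` is (start_frame, end_frame, label, (id_a, id_b)) for
    two-pig interactions, else None.
    """

    n_frames: int
    positions: dict[int, np.ndarray]
    headings: dict[int, np.ndarray]
    standing: dict[int, bool]
    episode: tuple[int, int, str, tuple[int, int]] | None = None
    behavior: str = ""


def _uniform(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    return float(rng.uniform(*lo_hi))


def _n_frames(config: SimConfig, rng: np.random.Generator) -> int:
    return int(round(_uniform(rng, config.duration_s_range) * config.fps))


def _arc_path(
    rng: np.random.Generator,
    config: SimConfig,
    n: int,
    speed: float,
    radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Constant-speed motion along a circular arc that stays in-arena.

    Returns (positions, headings, radius, theta). Arcs keep fast paths
    inside the pen without sharp turns.
    """
    h, w = config.arena_height_px, config.arena_width_px
    margin = config.pig_semi_major_px + 8
    if radius is None:
        radius = float(rng.uniform(110, min(h, w) / 2 - margin - 40))
    cr = h / 2 + rng.uniform(-25, 25)
    cc = w / 2 + rng.uniform(-25, 25)
    theta0 = rng.uniform(0, 2 * np.pi)
    direction = rng.choice([-1.0, 1.0])
    omega = direction * speed / radius
    t = np.arange(n) / config.fps
    theta = theta0 + omega * t
    rows = cr + radius * np.sin(theta)
    cols = cc + radius * np.cos(theta)
    pos = np.column_stack([rows, cols])
    # tangent direction of motion
    headings = np.arctan2(
        np.gradient(rows) if n > 1 else np.zeros(n),
        np.gradient(cols) if n > 1 else np.ones(n),
    )
    return pos, headings, radius, theta


def _clip_to_arena(pos: np.ndarray, config: SimConfig) -> np.ndarray:
    margin = config.pig_semi_major_px + 2
    lo = np.array([margin, margin])
    hi = np.array(
        [config.arena_height_px - 1 - margin, config.arena_width_px - 1 - margin]
    )
    clipped = np.clip(pos, lo, hi)
    if not np.allclose(clipped, pos):
        warnings.warn("behavior path left the arena; positions clipped")
    return clipped


def _simulate_kinematics(
    behavior: str, config: SimConfig, rng: np.random.Generator
) -> GroundTruth:
    """Ground-truth barycenter paths for one episode (no rendering)."""
    if behavior not in BEHAVIORS:
        raise ValueError(f"unknown behavior {behavior!r}; expected one of {BEHAVIORS}")
    n = _n_frames(config, rng)
    sep_scale = config.separation
    jitter_sd = 0.3  # px, small in-place body sway

    if behavior == "rest":
        h, w = config.arena_height_px, config.arena_width_px
        p0 = np.array([h / 2 + rng.uniform(-60, 60), w / 2 + rng.uniform(-120, -60)])
        p1 = np.array([h / 2 + rng.uniform(-60, 60), w / 2 + rng.uniform(60, 120)])
        gt = GroundTruth(
            n_frames=n,
            positions={0: np.tile(p0, (n, 1)), 1: np.tile(p1, (n, 1))},
            headings={
                0: np.full(n, rng.uniform(0, np.pi)),
                1: np.full(n, rng.uniform(0, np.pi)),
            },
            standing={0: False, 1: False},
            behavior=behavior,
        )
    elif behavior == "walk_alone":
        speed = _uniform(rng, config.walk_speed_px_s)
        pos, head, _, _ = _arc_path(rng, config, n, speed)
        pos = pos + rng.normal(0, jitter_sd, pos.shape)
        gt = GroundTruth(
            n_frames=n,
            positions={0: pos},
            headings={0: head},
            standing={0: True},
            behavior=behavior,
        )
    elif behavior == "walk_together":
        speed = _uniform(rng, config.walk_speed_px_s)
        sep = _uniform(rng, config.walk_separation_px)
        radius = float(rng.uniform(110, 136))
        # angular rate from the mid radius so both pigs move ~speed;
        # the companion walks the inner concentric arc (stays in-arena)
        pos, head, radius, theta = _arc_path(
            rng, config, n, speed * radius / (radius - sep / 2), radius=radius
        )
        center = pos - radius * np.column_stack([np.sin(theta), np.cos(theta)])
        pos2 = center + (radius - sep) * np.column_stack(
            [np.sin(theta), np.cos(theta)]
        )
        pos = pos + rng.normal(0, jitter_sd, pos.shape)
        pos2 = pos2 + rng.normal(0, jitter_sd, pos2.shape)
        gt = GroundTruth(
            n_frames=n,
            positions={0: pos, 1: pos2},
            headings={0: head, 1: head.copy()},
            standing={0: True, 1: True},
            episode=(0, n - 1, "normal", (0, 1)),
            behavior=behavior,
        )
    elif behavior == "knocking":
        h, w = config.arena_height_px, config.arena_width_px
        anchor = np.array(
            [h / 2 + rng.uniform(-80, 80), w / 2 + rng.uniform(-120, 120)]
        )
        phi = rng.uniform(0, 2 * np.pi)  # receiver body axis
        nvec = np.array([np.cos(phi), -np.sin(phi)])  # unit normal to the axis
        base = _uniform(rng, config.knock_base_dist_px)
        amp = _uniform(rng, config.knock_amp_px) * min(sep_scale, 1.0)
        freq = _uniform(rng, config.knock_freq_hz) * sep_scale
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / config.fps
        lunge = amp * np.abs(np.sin(2 * np.pi * freq * t + phase))
        # attacker presses in along the normal; receiver is shoved back
        attacker = anchor + np.outer(base - lunge, nvec)
        receiver = anchor - np.outer(config.knock_recoil * lunge, nvec)
        attacker = attacker + rng.normal(0, jitter_sd, attacker.shape)
        receiver = receiver + rng.normal(0, jitter_sd, receiver.shape)
        head_att = np.full(n, np.arctan2(-nvec[0], -nvec[1]))
        gt = GroundTruth(
            n_frames=n,
            positions={0: receiver, 1: attacker},
            headings={0: np.full(n, np.arctan2(np.sin(phi), np.cos(phi))), 1: head_att},
            standing={0: True, 1: True},
            episode=(0, n - 1, "knocking", (0, 1)),
            behavior=behavior,
        )
    else:  # chasing
        walk_mid = float(np.mean(config.walk_speed_px_s))
        speed = walk_mid + (
            _uniform(rng, config.chase_speed_px_s) - walk_mid
        ) * sep_scale
        gap = _uniform(rng, config.chase_gap_px)
        pos, head, radius, theta = _arc_path(rng, config, n, speed)
        dtheta = (gap / radius) * np.sign(theta[-1] - theta[0] if n > 1 else 1.0)
        theta_f = theta - dtheta
        center = pos - radius * np.column_stack([np.sin(theta), np.cos(theta)])
        follower = center + radius * np.column_stack(
            [np.sin(theta_f), np.cos(theta_f)]
        )
        pos = pos + rng.normal(0, jitter_sd, pos.shape)
        follower = follower + rng.normal(0, jitter_sd, follower.shape)
        head_f = np.arctan2(
            np.gradient(follower[:, 0]) if n > 1 else np.zeros(n),
            np.gradient(follower[:, 1]) if n > 1 else np.ones(n),
        )
        gt = GroundTruth(
            n_frames=n,
            positions={0: pos, 1: follower},
            headings={0: head, 1: head_f},
            standing={0: True, 1: True},
            episode=(0, n - 1, "chasing", (0, 1)),
            behavior=behavior,
        )

    for pid in gt.positions:
        gt.positions[pid] = _clip_to_arena(gt.positions[pid], config)
    return gt


def _render(
    gt: GroundTruth, config: SimConfig, rng: np.random.Generator
) -> list[DepthFrame]:
    """Rasterize ground truth into noisy 16-bit depth frames."""
    shape = (config.arena_height_px, config.arena_width_px)
    frames = []
    for f in range(gt.n_frames):
        depth = rng.normal(config.floor_depth_mm, config.noise_sd_mm, shape)
        for pid, pos in gt.positions.items():
            height = (
                config.standing_height_mm
                if gt.standing[pid]
                else config.lying_height_mm
            )
            rr, cc = draw_ellipse(
                pos[f, 0],
                pos[f, 1],
                config.pig_semi_minor_px,
                config.pig_semi_major_px,
                shape=shape,
                # skimage rotates clockwise in (row, col); headings are
                # atan2(d_row, d_col), hence the sign flip
                rotation=-gt.headings[pid][f],
            )
            depth[rr, cc] = (
                config.floor_depth_mm
                - height
                + rng.normal(0, config.noise_sd_mm, rr.shape)
            )
        if config.dropout_frac > 0:
            depth[rng.random(shape) < config.dropout_frac] = 0.0
        values = np.clip(np.rint(depth), 0, 65535).astype(np.uint16)
        frames.append(DepthFrame(values=values, index=f))
    return frames


def simulate_episode(
    behavior: str, config: SimConfig, seed: int | np.random.Generator
) -> tuple[list[DepthFrame], GroundTruth]:
    """One rendered behavior episode; bit-identical for equal seeds."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    gt = _simulate_kinematics(behavior, config, rng)
    frames = _render(gt, config, rng)
    return frames, gt


def _corpus_plan(config: SimConfig) -> list[tuple[str, int]]:
    """(behavior, per-episode seed) list derived from the master seed."""
    labels = (
        [NORMAL_BEHAVIOR] * config.n_normal
        + ["knocking"] * config.n_knocking
        + ["chasing"] * config.n_chasing
    )
    if min(config.n_normal, config.n_knocking, config.n_chasing) < 1:
        raise ValueError("need at least one episode per class")
    seeds = np.random.SeedSequence(config.seed).generate_state(len(labels))
    return [(b, int(s) % 2**31) for b, s in zip(labels, seeds)]


def iter_corpus(config: SimConfig):
    """Yield (episode_index, behavior, frames, GroundTruth) lazily.

    The default composition mirrors the labeled field corpus: 330
    episodes = 215 normal + 61 knocking + 54 chasing. Rendering one
    episode at a time keeps memory flat for full-size corpora.
    """
    for i, (behavior, seed) in enumerate(_corpus_plan(config)):
        frames, gt = simulate_episode(behavior, config, seed)
        yield i, behavior, frames, gt


def ground_truth_tracks(gt: GroundTruth) -> list[Track]:
    """Ground-truth kinematics as Track objects (standing pigs only)."""
    tracks = []
    for pid, pos in gt.positions.items():
        if not gt.standing[pid]:
            continue
        tr = Track(id=pid)
        for f in range(gt.n_frames):
            tr.add_point(f, (float(pos[f, 0]), float(pos[f, 1])))
        tracks.append(tr)
    return tracks


def ground_truth_features(gt: GroundTruth, config: SimConfig):
    """Five-feature descriptor straight from ground truth (no rendering).

    Used to validate the rendered pipeline against the designed
    kinematics, and as a fast source of labeled feature vectors.
    """
    from .features import extract_features

    if gt.episode is None:
        raise ValueError("ground truth has no two-pig episode")
    start, end, label, pair = gt.episode
    ep = InteractionEpisode(
        episode_id=0,
        track_ids=pair,
        start_frame=start,
        end_frame=end,
        duration_s=(end - start + 1) / config.fps,
        label=label,
    )
    return extract_features(ep, ground_truth_tracks(gt), config.meta())


def generate_corpus(config: SimConfig, path: str | Path) -> Path:
    """Write a corpus to disk in the sequence-directory format.

    Layout: ``<path>/ep_<i>/`` holds the PGM frames and ``meta.json`` of
    episode i; ``ground_truth_tracks.csv`` and
    ``ground_truth_episodes.csv`` at the corpus root hold exact
    barycenters and episode labels.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = config.meta()
    track_rows = []
    episode_rows = []
    for i, behavior, frames, gt in iter_corpus(config):
        ep_dir = path / f"ep_{i:04d}"
        write_depth_sequence(frames, meta, ep_dir)
        for pid, pos in gt.positions.items():
            for f in range(gt.n_frames):
                track_rows.append(
                    {
                        "episode_dir": ep_dir.name,
                        "pig_id": pid,
                        "frame": f,
                        "row": pos[f, 0],
                        "col": pos[f, 1],
                        "standing": gt.standing[pid],
                    }
                )
        if gt.episode is not None:
            start, end, label, pair = gt.episode
            episode_rows.append(
                {
                    "episode_dir": ep_dir.name,
                    "behavior": behavior,
                    "label": label,
                    "start_frame": start,
                    "end_frame": end,
                    "pig_a": pair[0],
                    "pig_b": pair[1],
                }
            )
    pd.DataFrame(track_rows).to_csv(path / "ground_truth_tracks.csv", index=False)
    pd.DataFrame(episode_rows).to_csv(path / "ground_truth_episodes.csv", index=False)
    return path
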