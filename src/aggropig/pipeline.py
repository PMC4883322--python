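"""End-to-end orchestration: segment -> track -> episodes -> features -> SVM.

The pipeline functions here are the library-level counterpart of the
command-line subcommands: they take frame sequences (from disk or the
simulator), push them through every stage with one parameter bundle,
and return/write the standard artifacts (episode, feature, prediction
CSVs and a metrics JSON).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify
from .classify import KernelSpec, STAGE1_KERNEL, STAGE2_KERNEL
from .depth_io import DepthFrame, SequenceMeta, read_depth_sequence
from .episodes import (
    EpisodeParams,
    InteractionEpisode,
    contact_pairs,
    episodes_to_rows,
    segment_episodes,
)
from .features import extract_features, features_to_table, table_to_feature_matrix
from .segmentation import SegmentationParams, height_map, segment_pigs
from .synthetic import SimConfig, iter_corpus
from .tracking import Track, TrackingParams, track_sequence

logger = logging.getLogger("aggropig")

__all__ = [
    "PipelineParams",
    "RunConfig",
    "process_sequence",
    "build_feature_dataset",
    "evaluate_corpus",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineParams:
    """Parameter bundle for the geometric stages."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    episodes: EpisodeParams = field(default_factory=EpisodeParams)


@dataclass
class RunConfig:
    """Full run description for the CLI (YAML-backed)."""

    input_path: str | None = None
    output_dir: str = "aggropig_out"
    params: PipelineParams = field(default_factory=PipelineParams)
    sim: SimConfig = field(default_factory=SimConfig)
    stage1_kernel: KernelSpec = STAGE1_KERNEL
    stage2_kernel: KernelSpec = STAGE2_KERNEL
    folds: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        cfg.input_path = raw.get("input_path", cfg.input_path)
        cfg.output_dir = raw.get("output_dir", cfg.output_dir)
        cfg.folds = int(raw.get("folds", cfg.folds))
        cfg.seed = int(raw.get("seed", cfg.seed))
        if "segmentation" in raw:
            cfg.params = PipelineParams(
                segmentation=SegmentationParams(**raw.get("segmentation", {})),
                tracking=TrackingParams(**raw.get("tracking", {})),
                episodes=EpisodeParams(**raw.get("episodes", {})),
            )
        elif "tracking" in raw or "episodes" in raw:
            cfg.params = PipelineParams(
                tracking=TrackingParams(**raw.get("tracking", {})),
                episodes=EpisodeParams(**raw.get("episodes", {})),
            )
        if "sim" in raw:
            cfg.sim = SimConfig(**raw["sim"])
        if "stage1_kernel" in raw:
            cfg.stage1_kernel = KernelSpec(**raw["stage1_kernel"])
        if "stage2_kernel" in raw:
            cfg.stage2_kernel = KernelSpec(**raw["stage2_kernel"])
        return cfg

    def snapshot(self) -> dict:
        return {
            "input_path": self.input_path,
            "output_dir": self.output_dir,
            "segmentation": vars(self.params.segmentation),
            "tracking": vars(self.params.tracking),
            "episodes": vars(self.params.episodes),
            "stage1_kernel": vars(self.stage1_kernel),
            "stage2_kernel": vars(self.stage2_kernel),
            "folds": self.folds,
            "seed": self.seed,
        }


def process_sequence(
    frames: list[DepthFrame],
    meta: SequenceMeta,
    params: PipelineParams = PipelineParams(),
) -> tuple[list, list[Track], list[InteractionEpisode]]:
    """Segment, track and episode-segment one frame sequence."""
    regions_by_frame = [
        segment_pigs(height_map(f, meta), params.segmentation) for f in frames
    ]
    tracks = track_sequence(regions_by_frame, params.tracking)
    pairs = contact_pairs(tracks, params.episodes.contact_dist_px)
    eps = segment_episodes(
        pairs,
        meta,
        params.episodes.min_duration_s,
        params.episodes.max_gap_frames,
    )
    return regions_by_frame, tracks, eps


def _best_episode(
    eps: list[InteractionEpisode], start: int, end: int
) -> InteractionEpisode | None:
    """Detected episode with the largest frame overlap with [start, end]."""
    best, best_ov = None, 0
    for ep in eps:
        ov = min(ep.end_frame, end) - max(ep.start_frame, start) + 1
        if ov > best_ov:
            best, best_ov = ep, ov
    return best


def build_feature_dataset(
    config: SimConfig, params: PipelineParams = PipelineParams()
) -> pd.DataFrame:
    """Run the full pipeline over a simulated corpus into a feature table.

    Each simulated episode is rendered, segmented, tracked and
    episode-segmented; the detected episode best overlapping the true
    interval supplies the 5-feature vector, labeled with the ground
    truth class. Episodes the pipeline fails to detect are dropped with
    a warning count (the acceptance analysis treats detection failures
    as errors of the world, not of the classifier).
    """
    meta = config.meta()
    rows = []
    missed = 0
    t0 = time.perf_counter()
    for i, behavior, frames, gt in iter_corpus(config):
        _, tracks, eps = process_sequence(frames, meta, params)
        start, end, label, _ = gt.episode
        ep = _best_episode(eps, start, end)
        if ep is None:
            missed += 1
            continue
        ep.label = label
        fv = extract_features(ep, tracks, meta)
        rows.append(fv)
    if missed:
        logger.warning("pipeline missed %d simulated episodes", missed)
    logger.info(
        "processed %d episodes in %.1f s", len(rows), time.perf_counter() - t0
    )
    table = features_to_table(rows)
    table["episode_id"] = np.arange(len(table))
    return table


def evaluate_corpus(
    table: pd.DataFrame,
    stage1_kernel: KernelSpec = STAGE1_KERNEL,
    stage2_kernel: KernelSpec = STAGE2_KERNEL,
    folds: int = 10,
    seed: int = 0,
) -> dict:
    """Cross-validate both stages on a labeled feature table.

    Stage 1 sees the whole table (aggressive vs normal); stage 2 only
    the aggressive episodes (knocking vs chasing). Returns a JSON-ready
    dict of full-precision and displayed metrics.
    """
    X, y = table_to_feature_matrix(table)
    det = classify.cross_validate(X, y, stage=1, spec=stage1_kernel, k=folds, seed=seed)
    agg = table[table["label"] != "normal"]
    Xa, ya = table_to_feature_matrix(agg)
    cls = classify.cross_validate(Xa, ya, stage=2, spec=stage2_kernel, k=folds, seed=seed)
    return {
        "detection": {
            "counts": {"TP": det.TP, "FP": det.FP, "TN": det.TN, "FN": det.FN},
            "ADR": det.ADR,
            "FPR": det.FPR,
            "FNR": det.FNR,
            "display": det.display(),
        },
        "classification": {
            "precision": cls.precision,
            "recall": cls.recall,
            "macro_precision": cls.macro_precision,
            "macro_recall": cls.macro_recall,
            "display": cls.display(),
        },
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the whole pipeline per the run config; returns artifacts.

    With ``input_path`` set, processes that on-disk sequence; otherwise
    simulates the configured corpus. Always writes episodes.csv,
    features.csv and (for labeled corpora) predictions.csv plus
    metrics.json, each alongside a config snapshot.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if config.input_path is not None:
        frames, meta = read_depth_sequence(config.input_path)
        logger.info("processing %s (%d frames)", config.input_path, len(frames))
        _, tracks, eps = process_sequence(frames, meta, config.params)
        ep_table = pd.DataFrame(episodes_to_rows(eps))
        fvs = [
            extract_features(ep, tracks, meta)
            for ep in eps
            if ep.end_frame > ep.start_frame
        ]
        table = features_to_table(fvs)
    else:
        logger.info("simulating corpus (seed %d)", config.sim.seed)
        table = build_feature_dataset(config.sim, config.params)
        ep_table = table[["episode_id", "label"]]

    ep_path = out / "episodes.csv"
    ep_table.to_csv(ep_path, index=False)
    artifacts["episodes"] = ep_path
    ft_path = out / "features.csv"
    table.to_csv(ft_path, index=False)
    artifacts["features"] = ft_path

    if "label" in table.columns and (table["label"] != "").all() and len(table):
        metrics = evaluate_corpus(
            table,
            config.stage1_kernel,
            config.stage2_kernel,
            config.folds,
            config.seed,
        )
        metrics["config"] = config.snapshot()
        mt_path = out / "metrics.json"
        mt_path.write_text(json.dumps(metrics, indent=1, sort_keys=True))
        artifacts["metrics"] = mt_path

    (out / "config.json").write_text(
        json.dumps(config.snapshot(), indent=1, sort_keys=True)
    )
    return artifacts
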