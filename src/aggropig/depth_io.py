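"""Reading and writing top-view depth-frame sequences.

A sequence on disk is a directory of 16-bit binary PGM (P5) frames with
zero-padded numeric filenames (``000000.pgm``, ``000001.pgm``, ...) that
define frame order, plus a ``meta.json`` sidecar describing the recording
geometry. Stored pixel values times ``depth_scale`` give camera-to-surface
distance in millimetres; the value 0 encodes a missing sensor return
(time-of-flight shadow or dropout) and is ignored downstream.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "DepthFrame",
    "SequenceMeta",
    "FormatError",
    "ConfigurationError",
    "read_depth_sequence",
    "write_depth_sequence",
]

META_FILENAME = "meta.json"
_FRAME_RE = re.compile(r"^(\d+)\.pgm$")
_MAX_STORED = 65535  # 16-bit PGM maxval


class FormatError(ValueError):
    """Frame files are malformed or mutually inconsistent."""


class ConfigurationError(ValueError):
    """The sequence directory lacks required metadata."""


@dataclass(frozen=True)
class SequenceMeta:
    """Acquisition parameters shared by every frame of a sequence.

    Parameters
    ----------
    fps
        Frame rate of the recording (frames per second).
    depth_scale
        Millimetres per stored pixel unit (1.0 for a sensor reporting mm).
    floor_depth_mm
        Camera-to-pen-floor distance; heights above the floor are computed
        against this plane.
    px_per_cm
        Optional ground-plane calibration. When set, speeds and distances
        can be reported in cm instead of px.
    """

    fps: float
    depth_scale: float = 1.0
    floor_depth_mm: float = 2500.0
    px_per_cm: float | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.depth_scale <= 0:
            raise ValueError(f"depth_scale must be positive, got {self.depth_scale}")
        if self.floor_depth_mm <= 0:
            raise ValueError(
                f"floor_depth_mm must be positive, got {self.floor_depth_mm}"
            )
        if self.px_per_cm is not None and self.px_per_cm <= 0:
            raise ValueError(f"px_per_cm must be positive, got {self.px_per_cm}")

    def to_dict(self) -> dict:
        d = {
            "fps": self.fps,
            "depth_scale": self.depth_scale,
            "floor_depth_mm": self.floor_depth_mm,
        }
        if self.px_per_cm is not None:
            d["px_per_cm"] = self.px_per_cm
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceMeta":
        try:
            return cls(
                fps=float(d["fps"]),
                depth_scale=float(d.get("depth_scale", 1.0)),
                floor_depth_mm=float(d["floor_depth_mm"]),
                px_per_cm=(
                    float(d["px_per_cm"]) if d.get("px_per_cm") is not None else None
                ),
            )
        except KeyError as exc:  # missing mandatory key
            raise ConfigurationError(f"meta.json missing key {exc}") from exc


@dataclass
class DepthFrame:
    """One top-view depth map.

    ``values`` holds per-pixel camera-to-surface distance in millimetres;
    0 marks an invalid reading. ``index`` is the 0-based frame ordinal.
    Coordinates are (row, col) with row 0 at the top of the image.
    """

    values: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise FormatError(f"depth frame must be 2-D, got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise FormatError("depth values must be non-negative")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _check_consistent(frames: list[DepthFrame]) -> tuple[int, int]:
    if not frames:
        raise FormatError("sequence contains no frames")
    shape = frames[0].shape
    for f in frames:
        if f.shape != shape:
            raise FormatError(
                f"inconsistent frame dimensions: {f.shape} vs {shape}"
            )
    return shape


def read_depth_sequence(path: str | Path) -> tuple[list[DepthFrame], SequenceMeta]:
    """Read a directory of 16-bit PGM frames plus ``meta.json``.

    Frames are returned sorted by their numeric filename ordinal, with
    stored units converted to millimetres via ``meta.depth_scale``
    (integer dtype is preserved when the scale is exactly 1).
    """
    path = Path(path)
    meta_path = path / META_FILENAME
    if not meta_path.is_file():
        raise ConfigurationError(f"missing {META_FILENAME} in {path}")
    meta = SequenceMeta.from_dict(json.loads(meta_path.read_text()))

    entries = []
    for p in path.iterdir():
        m = _FRAME_RE.match(p.name)
        if m:
            entries.append((int(m.group(1)), p))
    if not entries:
        raise FormatError(f"no .pgm frames found in {path}")
    entries.sort()

    frames = []
    for ordinal, p in entries:
        stored = np.asarray(Image.open(p)).astype(np.uint16)
        if meta.depth_scale == 1.0:
            values: np.ndarray = stored
        else:
            values = stored.astype(np.float64) * meta.depth_scale
        frames.append(DepthFrame(values=values, index=ordinal))
    _check_consistent(frames)
    return frames, meta


def write_depth_sequence(
    frames: list[DepthFrame], meta: SequenceMeta, path: str | Path
) -> Path:
    """Write frames as 16-bit PGM files plus ``meta.json``; returns the dir.

    Millimetre values are divided by ``meta.depth_scale`` for storage and
    must then fit in 16 bits; values that do not raise a range error.
    """
    _check_consistent(frames)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = len(str(max(len(frames) - 1, 1)))
    width = max(width, 6)  # stable zero-padding for typical sequence sizes
    for i, frame in enumerate(frames):
        stored = np.asarray(frame.values, dtype=np.float64) / meta.depth_scale
        rounded = np.rint(stored)
        if np.any(rounded > _MAX_STORED):
            raise ValueError(
                f"frame {i}: depth exceeds 16-bit range after scaling "
                f"(max stored value {rounded.max():.0f} > {_MAX_STORED})"
            )
        arr = rounded.astype(np.uint16)
        Image.fromarray(arr).save(path / f"{i:0{width}d}.pgm", format="PPM")
    (path / META_FILENAME).write_text(json.dumps(meta.to_dict(), indent=1))
    return path
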