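"""Frame acquisition: turn a recording into an ordered frame stream.

A session recording is either a video file (decoded through imageio's
codec backends when available) or a directory of image frames in
lexicographic filename order — the tested, codec-free path. Colour
frames are reduced to grayscale with the ITU-R BT.601 luma weights
before any downstream stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .errors import EmptyInputError

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")
_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass
class Frame:
    index: int
    timestamp_s: float
    pixels: np.ndarray


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """BT.601 luma conversion; grayscale input passes through untouched."""
    if pixels.ndim == 2:
        return pixels
    rgb = pixels[..., :3].astype(float)
    return np.rint(rgb @ _BT601).astype(np.uint8)


def _list_frame_files(directory: Path) -> list[Path]:
    return sorted(p for p in directory.iterdir()
                  if p.suffix.lower() in IMAGE_EXTENSIONS)


def _read_video(path: Path) -> list[np.ndarray]:
    try:
        return [np.asarray(f) for f in iio.imiter(path)]
    except Exception as exc:  # codec/back-end errors are I/O errors here
        raise IOError(f"cannot decode video source {path}: {exc}") from exc


def _subsample_indices(n: int, native_fps: float, target_fps: float) -> np.ndarray:
    """Nearest-timestamp frame selection for fps reduction."""
    duration = n / native_fps
    n_target = int(round(duration * target_fps))
    times = np.arange(n_target) / target_fps
    return np.clip(np.rint(times * native_fps).astype(int), 0, n - 1)


def extract_frames(
    source: str | Path,
    target_fps: float | str = "native",
    native_fps: float = 10.0,
) -> list[Frame]:
    """Read a recording into an ordered list of grayscale frames.

    ``source`` is a video file or a directory of images (lexicographic
    order). ``target_fps="native"`` keeps every frame; a numeric target
    below the native rate subsamples by nearest-timestamp selection.
    ``native_fps`` supplies timestamps for directory sources, which
    carry no rate metadata.
    """
    path = Path(source)
    if not path.exists():
        raise IOError(f"no such source: {path}")
    if path.is_dir():
        files = _list_frame_files(path)
        if not files:
            raise EmptyInputError(f"no image frames in directory {path}")
        rasters = [np.asarray(iio.imread(f)) for f in files]
    else:
        rasters = _read_video(path)
        if not rasters:
            raise EmptyInputError(f"zero decodable frames in {path}")

    indices = np.arange(len(rasters))
    if target_fps != "native":
        target = float(target_fps)
        if target <= 0:
            raise ValueError("target_fps must be positive or 'native'")
        if target < native_fps:
            indices = _subsample_indices(len(rasters), native_fps, target)
    return [
        Frame(index=k, timestamp_s=i / native_fps,
              pixels=to_grayscale(rasters[i]))
        for k, i in enumerate(indices)
    ]


def count_frames(source: str | Path, native_fps: float = 10.0) -> int:
    """Number of native frames in a source; 0 (with a warning) when the
    source exists but holds no frames."""
    try:
        return len(extract_frames(source, "native", native_fps))
    except EmptyInputError:
        warnings.warn(f"source {source} contains no frames")
        return 0
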