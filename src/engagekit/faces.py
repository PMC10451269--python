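"""Face detection and 68-point landmark extraction.

Two backends satisfy the same contract:

* ``"synthetic"`` (default, self-contained): built for the schematic
  faces of :mod:`engagekit.synthetic`. Detection thresholds the frame
  and takes the largest connected component (the filled face ellipse),
  then inverts the known ellipse-to-face-box proportions. Landmark
  extraction recovers the expression from mouth-band pixel statistics
  — corner drop is linear in valence, band area linear in arousal, each
  calibrated by rendering the template at the detected box size — and
  instantiates the face template at the recovered (valence, arousal).
* ``"pretrained"``: any external detector/landmarker pair (e.g. a
  dlib-style 68-point model) plugged in as callables; nothing is
  bundled.

Landmarks use the iBUG-300W ordering throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Optional

import numpy as np
from skimage.measure import label as _cc_label
from skimage.measure import regionprops

from . import facegeom
from .errors import ConfigurationError, DegenerateGeometryError, ExtractionError
from .facegeom import (
    FACE_CX, FACE_CY, FACE_RX, FACE_RY,
    map_to_box, mouth_stats, render_mouth_mask, template_landmarks,
)
from .video_io import Frame

MIN_FACE_AREA_PX = 200  # components smaller than this are not a face


@dataclass(frozen=True)
class FaceBox:
    x: int
    y: int
    w: int
    h: int
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"face box must have positive size: {self}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x, self.y, self.w, self.h)


# --- synthetic backend -------------------------------------------------------

def _detect_synthetic(pixels: np.ndarray) -> Optional[FaceBox]:
    mask = pixels > facegeom.FACE_THRESHOLD
    if not mask.any():
        return None
    labels = _cc_label(mask)
    regions = regionprops(labels)
    best = max(regions, key=lambda r: r.area)
    if best.area < MIN_FACE_AREA_PX:
        return None
    r0, c0, r1, c1 = best.bbox
    # the component is the filled face ellipse; invert its known extent
    # within the unit face box to recover the box itself (the -1 strips
    # the extra pixel a rasterized ellipse adds to its analytic extent)
    ew, eh = c1 - c0 - 1, r1 - r0 - 1
    fw = ew / (2 * FACE_RX)
    fh = eh / (2 * FACE_RY)
    fx = c0 - (FACE_CX - FACE_RX) * fw
    fy = r0 - (FACE_CY - FACE_RY) * fh
    fill = best.area / (np.pi * (ew / 2) * (eh / 2))
    return FaceBox(x=int(round(fx)), y=int(round(fy)),
                   w=int(round(fw)), h=int(round(fh)),
                   score=float(np.clip(fill, 0.0, 1.0)))


@lru_cache(maxsize=64)
def _mouth_calibration(w: int, h: int) -> tuple[float, float, float, float]:
    """Linear response of the mouth statistics at a given box size.

    Returns (drop0, drop_slope, area0, area_slope) such that
    ``corner_drop ~ drop0 + drop_slope * valence`` and
    ``area ~ area0 + area_slope * arousal``.
    """
    def stats(v: float, a: float) -> tuple[float, float]:
        lm = map_to_box(template_landmarks(v, a), 0, 0, w, h)
        return mouth_stats(render_mouth_mask(lm, (h, w)))

    drop_m, _ = stats(-1.0, 0.0)
    drop_p, _ = stats(1.0, 0.0)
    _, area_m = stats(0.0, -1.0)
    _, area_p = stats(0.0, 1.0)
    drop_slope = (drop_p - drop_m) / 2.0
    area_slope = (area_p - area_m) / 2.0
    if drop_slope == 0.0 or area_slope == 0.0:
        raise ExtractionError(f"face box {w}x{h} too small to resolve expression")
    return ((drop_p + drop_m) / 2.0, drop_slope,
            (area_p + area_m) / 2.0, area_slope)


def _extract_synthetic(pixels: np.ndarray, box: FaceBox) -> np.ndarray:
    img_h, img_w = pixels.shape[:2]
    x0, y0 = max(box.x, 0), max(box.y, 0)
    x1, y1 = min(box.x + box.w, img_w), min(box.y + box.h, img_h)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"face box {box} lies outside the frame")
    crop = pixels[y0:y1, x0:x1]
    mouth = crop >= facegeom.MOUTH_THRESHOLD
    if mouth.sum() < 20:
        raise ExtractionError("no resolvable mouth region in face box")
    corner_drop, area = mouth_stats(mouth)
    drop0, drop_slope, area0, area_slope = _mouth_calibration(box.w, box.h)
    v = float(np.clip((corner_drop - drop0) / drop_slope, -1.0, 1.0))
    a = float(np.clip((area - area0) / area_slope, -1.0, 1.0))
    return map_to_box(template_landmarks(v, a), box.x, box.y, box.w, box.h)


# --- backend registry --------------------------------------------------------

#: a backend is a pair of callables: detect(pixels) -> FaceBox | None,
#: landmarks(pixels, FaceBox) -> (68, 2) array
DetectorFn = Callable[[np.ndarray], Optional[FaceBox]]
LandmarkFn = Callable[[np.ndarray, FaceBox], np.ndarray]

_BACKENDS: dict[str, tuple[DetectorFn, LandmarkFn]] = {
    "synthetic": (_detect_synthetic, _extract_synthetic),
}


def register_backend(name: str, detector: DetectorFn,
                     landmarker: LandmarkFn) -> None:
    """Plug in an external (e.g. pretrained) detector/landmarker pair."""
    _BACKENDS[name] = (detector, landmarker)


def _resolve(backend: str) -> tuple[DetectorFn, LandmarkFn]:
    try:
        return _BACKENDS[backend]
    except KeyError:
        raise ConfigurationError(
            f"unknown face backend {backend!r}; known: {sorted(_BACKENDS)}")


def detect_face(frame: Frame | np.ndarray,
                backend: str = "synthetic") -> Optional[FaceBox]:
    """Highest-scoring face box in a frame, or ``None`` when no face.

    When several candidate components exist the largest-area one wins.
    """
    detector, _ = _resolve(backend)
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if pixels.size == 0:
        raise ValueError("empty frame")
    return detector(pixels)


def extract_landmarks(frame: Frame | np.ndarray, box: FaceBox,
                      backend: str = "synthetic") -> np.ndarray:
    """68 landmark coordinates (frame pixels, iBUG-300W order) for a
    detected face box."""
    _, landmarker = _resolve(backend)
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    lm = np.asarray(landmarker(pixels, box), dtype=float)
    if lm.shape != (68, 2) or not np.isfinite(lm).all():
        raise ExtractionError(f"backend returned invalid landmarks: {lm.shape}")
    return lm


def normalize_landmarks(landmarks: np.ndarray) -> np.ndarray:
    """Canonical similarity frame: inter-ocular midpoint at the origin,
    inter-ocular axis horizontal, inter-ocular distance (left-eye
    centroid 36-41 to right-eye centroid 42-47) equal to 1. Cancels any
    similarity transform of the input; idempotent up to floating-point
    tolerance."""
    lm = np.asarray(landmarks, dtype=float)
    if lm.shape != (68, 2):
        raise ValueError(f"expected (68, 2) landmarks, got {lm.shape}")
    left = lm[36:42].mean(axis=0)
    right = lm[42:48].mean(axis=0)
    delta = right - left
    iod = float(np.linalg.norm(delta))
    if iod < 1e-12:
        raise DegenerateGeometryError("coincident eye centroids")
    centered = (lm - (left + right) / 2.0) / iod
    c, s = delta / iod
    rot = np.array([[c, s], [-s, c]])
    return centered @ rot.T
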