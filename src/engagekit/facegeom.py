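"""Parametric schematic face shared by the synthetic renderer and the
synthetic landmark backend.

The face lives in a canonical unit box ``[0, 1] x [0, 1]`` (x rightward,
y downward). Expression is controlled by the two circumplex coordinates:

* valence lifts the mouth corners (smile) — the mouth midline is the
  parabola ``y(s) = y0 - SMILE_AMP * valence * s**2`` with ``s`` the
  signed horizontal position in ``[-1, 1]`` across the mouth;
* arousal opens the eyes and the mouth — eye vertical radius and lip
  band thickness grow linearly with arousal.

Both couplings are strictly monotone, so the rendered expression is an
invertible encoding of (valence, arousal) that the landmark backend can
recover from pixel statistics alone.

Landmarks follow the iBUG-300W 68-point ordering: jaw 0-16, brows 17-26,
nose 27-35, eyes 36-47, mouth 48-67.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import line as _draw_line
from skimage.draw import polygon as _draw_polygon

# canonical unit-box geometry -------------------------------------------------
FACE_CX, FACE_CY = 0.5, 0.5
FACE_RX, FACE_RY = 0.42, 0.48

EYE_L = (0.34, 0.40)
EYE_R = (0.66, 0.40)
EYE_RX = 0.08
EYE_RY_MIN = 0.030
EYE_RY_GAIN = 0.020  # ry = MIN + GAIN * (arousal + 1) / 2

MOUTH_CX, MOUTH_CY = 0.5, 0.80
MOUTH_HALF_W = 0.20
SMILE_AMP = 0.13     # mouth-corner rise per unit valence (unit face height)
LIP_MIN = 0.024
LIP_GAIN = 0.048     # lip half-thickness = MIN + GAIN * (arousal + 1) / 2
INNER_FRAC = 0.40    # inner-lip gap as a fraction of lip half-thickness

# grayscale intensity levels (uint8); the mouth is the brightest structure so
# a single threshold isolates it for expression recovery
LEVELS = {
    "bg": 10,
    "face": 90,
    "jaw": 60,
    "brow": 50,
    "nose": 70,
    "eye": 200,
    "mouth": 255,
    "inner": 30,
}
MOUTH_THRESHOLD = 240  # pixels >= this belong to the (outer) mouth band
FACE_THRESHOLD = 40    # pixels > this belong to the face region

_JAW_T = np.linspace(0.0, math.pi, 17)
_OUTER_S = np.array([-1.0, -2 / 3, -1 / 3, 0.0, 1 / 3, 2 / 3, 1.0])
_INNER_S = np.array([-0.85, -0.45, 0.0, 0.45, 0.85])


def template_landmarks(valence: float, arousal: float) -> np.ndarray:
    """Return the 68 landmarks for an expression, in unit-box coordinates.

    Parameters
    ----------
    valence, arousal:
        Circumplex coordinates, each finite and in ``[-1, 1]``.

    Returns
    -------
    ``(68, 2)`` float array of (x, y) points inside the unit box.
    """
    v, a = float(valence), float(arousal)
    if not (math.isfinite(v) and math.isfinite(a)):
        raise ValueError("valence/arousal must be finite")
    if not (-1.0 <= v <= 1.0 and -1.0 <= a <= 1.0):
        raise ValueError(f"valence/arousal out of [-1, 1]: ({v}, {a})")

    pts = np.empty((68, 2), dtype=float)

    # jaw: lower half of the face ellipse, left ear -> chin -> right ear
    pts[0:17, 0] = FACE_CX - FACE_RX * np.cos(_JAW_T)
    pts[0:17, 1] = FACE_CY + FACE_RY * np.sin(_JAW_T)

    # brows: shallow arches above the eyes
    arch = 0.025 * np.sin(np.linspace(0.0, math.pi, 5))
    pts[17:22, 0] = np.linspace(0.24, 0.44, 5)
    pts[17:22, 1] = 0.31 - arch
    pts[22:27, 0] = np.linspace(0.56, 0.76, 5)
    pts[22:27, 1] = 0.31 - arch

    # nose: vertical bridge and base arc
    pts[27:31, 0] = 0.5
    pts[27:31, 1] = np.linspace(0.40, 0.58, 4)
    pts[31:36, 0] = np.linspace(0.44, 0.56, 5)
    pts[31:36, 1] = 0.625 + 0.01 * np.sin(np.linspace(0.0, math.pi, 5))

    # eyes: hexagons on an ellipse whose vertical radius opens with arousal
    ery = EYE_RY_MIN + EYE_RY_GAIN * (a + 1.0) / 2.0
    ang = np.deg2rad([180.0, 120.0, 60.0, 0.0, 300.0, 240.0])
    for (ecx, ecy), base in ((EYE_L, 36), (EYE_R, 42)):
        pts[base:base + 6, 0] = ecx + EYE_RX * np.cos(ang)
        pts[base:base + 6, 1] = ecy - ery * np.sin(ang)

    # mouth: outer lip band around the smile parabola, inner lip gap
    thick = LIP_MIN + LIP_GAIN * (a + 1.0) / 2.0
    gap = INNER_FRAC * thick

    def midline(s: np.ndarray) -> np.ndarray:
        return MOUTH_CY - SMILE_AMP * v * s**2

    s = _OUTER_S
    half = thick * np.sqrt(np.clip(1.0 - s**2, 0.0, None))
    pts[48:55, 0] = MOUTH_CX + MOUTH_HALF_W * s
    pts[48:55, 1] = midline(s) - half
    pts[55:60, 0] = MOUTH_CX + MOUTH_HALF_W * s[5:0:-1]
    pts[55:60, 1] = (midline(s) + half)[5:0:-1]

    si = _INNER_S
    ihalf = gap * np.sqrt(np.clip(1.0 - (si / _INNER_S[-1]) ** 2, 0.0, None))
    pts[60:65, 0] = MOUTH_CX + MOUTH_HALF_W * si
    pts[60:65, 1] = midline(si) - ihalf
    pts[65:68, 0] = MOUTH_CX + MOUTH_HALF_W * si[3:0:-1]
    pts[65:68, 1] = (midline(si) + ihalf)[3:0:-1]

    return pts


def map_to_box(landmarks: np.ndarray, x: float, y: float,
               w: float, h: float) -> np.ndarray:
    """Affinely map unit-box landmarks into a pixel face box."""
    out = np.asarray(landmarks, dtype=float).copy()
    out[:, 0] = x + out[:, 0] * w
    out[:, 1] = y + out[:, 1] * h
    return out


def _poly_fill(canvas: np.ndarray, pts: np.ndarray, level: int) -> None:
    rr, cc = _draw_polygon(pts[:, 1], pts[:, 0], shape=canvas.shape)
    canvas[rr, cc] = level


def _polyline(canvas: np.ndarray, pts: np.ndarray, level: int) -> None:
    p = np.rint(pts).astype(int)
    for (x0, y0), (x1, y1) in zip(p[:-1], p[1:]):
        rr, cc = _draw_line(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
        canvas[rr[keep], cc[keep]] = level


def draw_face(canvas: np.ndarray, landmarks_px: np.ndarray,
              box: tuple[float, float, float, float]) -> None:
    """Draw the schematic face onto ``canvas`` (uint8, modified in place).

    The face fill ellipse is derived from the face box; every feature is
    drawn from the (possibly noise-jittered) landmark coordinates so that
    positional landmark noise is visible in the rendered image.
    """
    x, y, w, h = box
    rr, cc = _draw_ellipse(y + FACE_CY * h, x + FACE_CX * w,
                           FACE_RY * h, FACE_RX * w, shape=canvas.shape)
    canvas[rr, cc] = LEVELS["face"]

    lm = landmarks_px
    _polyline(canvas, lm[0:17], LEVELS["jaw"])
    _polyline(canvas, lm[17:22], LEVELS["brow"])
    _polyline(canvas, lm[22:27], LEVELS["brow"])
    _polyline(canvas, lm[27:31], LEVELS["nose"])
    _polyline(canvas, lm[31:36], LEVELS["nose"])
    _poly_fill(canvas, lm[36:42], LEVELS["eye"])
    _poly_fill(canvas, lm[42:48], LEVELS["eye"])
    _poly_fill(canvas, lm[48:60], LEVELS["mouth"])
    _poly_fill(canvas, lm[60:68], LEVELS["inner"])


def render_mouth_mask(landmarks_px: np.ndarray,
                      shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the outer mouth band (outer polygon minus inner)."""
    canvas = np.zeros(shape, dtype=np.uint8)
    _poly_fill(canvas, landmarks_px[48:60], LEVELS["mouth"])
    _poly_fill(canvas, landmarks_px[60:68], LEVELS["inner"])
    return canvas >= MOUTH_THRESHOLD


def mouth_stats(mask: np.ndarray) -> tuple[float, float]:
    """Expression statistics of a mouth mask.

    Returns ``(corner_drop, area)`` where ``corner_drop`` is the mean row
    of outer-column pixels minus the mean row of central-column pixels
    (linear in valence: vertical shear of a band symmetric about its
    midline) and ``area`` is the pixel count (linear in arousal: shear
    preserves per-column counts, thickness scales them).
    """
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        return 0.0, 0.0
    xl, xr = xs.min(), xs.max()
    half_w = max((xr - xl) / 2.0, 1.0)
    s = (xs - (xl + xr) / 2.0) / half_w
    outer = np.abs(s) >= 0.5
    if not outer.any() or outer.all():
        return 0.0, float(xs.size)
    corner_drop = float(ys[outer].mean() - ys[~outer].mean())
    return corner_drop, float(xs.size)
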