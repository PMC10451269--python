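"""Per-frame engagement classifier.

The network follows the published layer recipe exactly: two convolution
layers with 32 filters and (3, 3) kernels, a third with 64 filters and
(3, 3) kernels, a ReLU after every convolution, a 2x2 max-pool after
every ReLU, then flatten and a 2-way dense head
(engagement / non-engagement).

Its input is a 64x64 single-channel raster of the normalized 68-point
landmark set: each landmark is stamped as a small Gaussian blob into a
fixed canonical window, which turns the saved (x, y) coordinates into
an image the convolutional stack can consume while staying invariant to
face position and scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .emotion import EngagementLabel
from .errors import ConfigurationError
from .faces import normalize_landmarks
from .metrics import FrameLabelRecord
from .nn import Adam, Conv2D, Dense, Flatten, MaxPool2x2, ReLU, Sequential, cross_entropy_grad

# canonical window (normalized landmark units: inter-ocular distance = 1,
# origin at the inter-ocular midpoint) that the raster covers
WINDOW_X = (-1.6, 1.6)
WINDOW_Y = (-1.0, 2.6)
BLOB_SIGMA_PX = 1.0

CONV_FILTERS = (32, 32, 64)
KERNEL = 3
N_CLASSES = 2
# class indices into the 2-way head
NOT_ENGAGED, ENGAGED = 0, 1


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture description; filter counts and kernel size are part
    of the published recipe and are validated, not tunable."""

    input_size: tuple[int, int] = (64, 64)
    conv_filters: tuple[int, int, int] = CONV_FILTERS
    kernel: tuple[int, int] = (KERNEL, KERNEL)
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.conv_filters) != CONV_FILTERS:
            raise ConfigurationError(
                f"conv filter counts are fixed at {CONV_FILTERS}")
        if tuple(self.kernel) != (KERNEL, KERNEL):
            raise ConfigurationError(f"kernel size is fixed at (3, 3)")
        h, w = self.input_size
        if h < 32 or w < 32:
            raise ConfigurationError(
                "input below the receptive-field minimum (32x32) of the "
                "three conv+pool blocks")

    def to_dict(self) -> dict:
        return {"input_size": list(self.input_size),
                "conv_filters": list(self.conv_filters),
                "kernel": list(self.kernel), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierSpec":
        return cls(input_size=tuple(d["input_size"]),
                   conv_filters=tuple(d["conv_filters"]),
                   kernel=tuple(d["kernel"]), seed=int(d["seed"]))


def _gauss_stamp(sigma: float) -> np.ndarray:
    r = max(int(round(3 * sigma)), 1)
    g = np.arange(-r, r + 1)
    gx, gy = np.meshgrid(g, g)
    return np.exp(-(gx**2 + gy**2) / (2 * sigma**2)), r


def rasterize_landmarks(landmarks: np.ndarray,
                        size: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Render normalized landmarks as Gaussian blobs on a zero background.

    The canonical window maps to the raster; landmarks falling outside
    the window are clipped onto its border and counted in a warning.
    Output intensities span [0, 1] for any non-empty input.
    """
    lm = np.asarray(landmarks, dtype=float)
    if lm.size == 0:
        raise ValueError("empty landmark set")
    if lm.ndim != 2 or lm.shape[1] != 2 or not np.isfinite(lm).all():
        raise ValueError(f"invalid landmark array of shape {lm.shape}")
    h, w = size
    if h < 32 or w < 32:
        raise ValueError("raster size must be at least 32x32")

    xs = (lm[:, 0] - WINDOW_X[0]) / (WINDOW_X[1] - WINDOW_X[0]) * (w - 1)
    ys = (lm[:, 1] - WINDOW_Y[0]) / (WINDOW_Y[1] - WINDOW_Y[0]) * (h - 1)
    n_clipped = int(((xs < 0) | (xs > w - 1) | (ys < 0) | (ys > h - 1)).sum())
    if n_clipped:
        warnings.warn(f"{n_clipped} landmark(s) outside the canonical "
                      "window were clipped")
        xs = np.clip(xs, 0, w - 1)
        ys = np.clip(ys, 0, h - 1)

    stamp, r = _gauss_stamp(BLOB_SIGMA_PX)
    canvas = np.zeros((h + 2 * r, w + 2 * r), dtype=np.float32)
    for x, y in zip(np.rint(xs).astype(int), np.rint(ys).astype(int)):
        canvas[y:y + 2 * r + 1, x:x + 2 * r + 1] = np.maximum(
            canvas[y:y + 2 * r + 1, x:x + 2 * r + 1], stamp)
    raster = canvas[r:-r, r:-r]
    peak = raster.max()
    return raster / peak if peak > 0 else raster


def build_classifier(spec: ClassifierSpec) -> Sequential:
    """Instantiate the layer sequence with seed-reproducible weights."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.input_size
    layers: list = []
    channels = 1
    for f in spec.conv_filters:
        layers += [Conv2D(channels, f, KERNEL, rng), ReLU(), MaxPool2x2()]
        channels = f
        h, w = (h - KERNEL + 1) // 2, (w - KERNEL + 1) // 2
        if h < 1 or w < 1:
            raise ConfigurationError("input too small for three conv+pool blocks")
    layers += [Flatten(), Dense(h * w * channels, N_CLASSES, rng)]
    return Sequential(layers)


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    model: Sequential
    history: list[dict] = field(default_factory=list)

    def predict_labels(self, rasters: np.ndarray,
                       batch_size: int = 256) -> list[EngagementLabel]:
        """Arg-max decision over the 2-way head; ties resolve to
        not-engaged."""
        x = np.asarray(rasters, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2:] != tuple(self.spec.input_size):
            raise ValueError(
                f"raster size {x.shape[2:]} does not match spec "
                f"{self.spec.input_size}")
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.model.forward(x[i:i + batch_size], train=False)
            engaged = logits[:, ENGAGED] > logits[:, NOT_ENGAGED]
            out.extend(EngagementLabel.ENGAGED if e else EngagementLabel.NOT_ENGAGED
                       for e in engaged)
        return out


def _labels_to_indices(labels: Sequence[EngagementLabel | int]) -> np.ndarray:
    idx = np.array([
        (l if isinstance(l, (int, np.integer))
         else (ENGAGED if l is EngagementLabel.ENGAGED else NOT_ENGAGED))
        for l in labels
    ], dtype=np.int64)
    return idx


def train_classifier(
    model: Sequential,
    rasters: np.ndarray,
    labels: Sequence[EngagementLabel | int],
    epochs: int = 5,
    seed: int = 0,
    spec: Optional[ClassifierSpec] = None,
    batch_size: int = 32,
    lr: float = 1e-3,
    val_fraction: float = 0.2,
) -> TrainedClassifier:
    """Minimize 2-class cross-entropy with Adam on a shuffled 80/20 split.

    History records per-epoch mean training loss and train/validation
    accuracy. Deterministic given (model seed, data, ``seed``).
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    y = _labels_to_indices(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    x = np.asarray(rasters, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None, :, :]
    if len(x) != len(y):
        raise ValueError("rasters and labels must have equal length")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(x))
    n_val = int(round(val_fraction * len(x)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]

    opt = Adam(model.params, lr=lr)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(len(xt))
        losses, hits, seen = [], 0, 0
        for i in range(0, len(xt), batch_size):
            sel = order[i:i + batch_size]
            logits = model.forward(xt[sel], train=True)
            loss, grad = cross_entropy_grad(logits, yt[sel])
            model.backward(grad)
            opt.step(model.grads)
            losses.append(loss)
            hits += int((logits.argmax(axis=1) == yt[sel]).sum())
            seen += len(sel)
        entry = {"epoch": epoch + 1,
                 "loss": float(np.mean(losses)),
                 "train_accuracy": hits / seen}
        if len(xv):
            logits = model.forward(xv, train=False)
            entry["val_accuracy"] = float((logits.argmax(axis=1) == yv).mean())
        history.append(entry)

    return TrainedClassifier(spec=spec or ClassifierSpec(), model=model,
                             history=history)


def classify_frames(
    trained: TrainedClassifier,
    landmark_sets: Sequence[Optional[np.ndarray]],
) -> list[FrameLabelRecord]:
    """One record per input frame, order preserving.

    ``landmark_sets`` holds a (68, 2) pixel-coordinate array per frame,
    or ``None`` for frames where no face was found; those records carry
    ``face_present=False`` and no label (the metrics layer applies the
    no-face policy).
    """
    face_idx = [i for i, lm in enumerate(landmark_sets) if lm is not None]
    labels: dict[int, EngagementLabel] = {}
    if face_idx:
        rasters = np.stack([
            rasterize_landmarks(normalize_landmarks(landmark_sets[i]),
                                trained.spec.input_size)
            for i in face_idx
        ])
        for i, lab in zip(face_idx, trained.predict_labels(rasters)):
            labels[i] = lab
    return [
        FrameLabelRecord(index=i, face_present=i in labels,
                         label=labels.get(i))
        for i in range(len(landmark_sets))
    ]


def make_landmark_dataset(
    n: int,
    seed: int,
    noise_px: float = 0.0,
    spec: Optional[ClassifierSpec] = None,
    va_margin: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Training pairs straight from the face template.

    Samples engaged/not-engaged balanced at random, draws a VA point
    from the corresponding quadrant(s), instantiates the template in a
    reference face box, jitters it with ``noise_px`` Gaussian landmark
    noise, then normalizes and rasterizes. Returns ``(rasters, labels)``
    with labels as class indices.
    """
    from .facegeom import map_to_box, template_landmarks
    from .synthetic import FACE_ASPECT, sample_va

    spec = spec or ClassifierSpec()
    rng = np.random.default_rng(seed)
    ref_h = 100.0
    ref_w = FACE_ASPECT * ref_h
    rasters = np.empty((n, *spec.input_size), dtype=np.float32)
    y = np.empty(n, dtype=np.int64)
    for i in range(n):
        engaged = bool(rng.integers(2))
        va = sample_va(rng, engaged, va_margin)
        lm = map_to_box(template_landmarks(va.valence, va.arousal),
                        0.0, 0.0, ref_w, ref_h)
        if noise_px > 0:
            lm = lm + rng.normal(0.0, noise_px, size=lm.shape)
        rasters[i] = rasterize_landmarks(normalize_landmarks(lm),
                                         spec.input_size)
        y[i] = ENGAGED if engaged else NOT_ENGAGED
    return rasters, y


def save_checkpoint(trained: TrainedClassifier, path: str | Path) -> Path:
    """Single-file checkpoint: spec + weights + training history."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    arrays = {f"param_{i}": p for i, p in enumerate(trained.model.params)}
    np.savez(
        path,
        spec_json=np.frombuffer(
            json.dumps(trained.spec.to_dict()).encode(), dtype=np.uint8),
        history_json=np.frombuffer(
            json.dumps(trained.history).encode(), dtype=np.uint8),
        **arrays,
    )
    return path


def load_checkpoint(path: str | Path) -> TrainedClassifier:
    with np.load(path) as data:
        spec = ClassifierSpec.from_dict(
            json.loads(bytes(data["spec_json"]).decode()))
        history = json.loads(bytes(data["history_json"]).decode())
        model = build_classifier(spec)
        for i, p in enumerate(model.params):
            saved = data[f"param_{i}"]
            if saved.shape != p.shape:
                raise ValueError(f"checkpoint parameter {i} has shape "
                                 f"{saved.shape}, expected {p.shape}")
            p[...] = saved
    return TrainedClassifier(spec=spec, model=model, history=history)
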