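"""Face/landmark frontend: 68-point geometry to eyelid gap and mouth aspect ratio.

The geometry follows the iBUG 300-W 68-point convention (1-based indices):
eyes occupy indices 37-48, the mouth 49-68.  The eyelid gap of an eye is
the mean of two vertical upper-lid/lower-lid landmark distances; the mouth
aspect ratio (mar) is the mean inner-lip opening height divided by the
inner mouth width.  Both quantities are translation-invariant, and mar is
additionally invariant under uniform scaling.

Face detection and landmark localization are delegated to pluggable
backends.  Built-in backend names ("haar", "hog") lazily import OpenCV /
dlib and consume their pretrained models; custom backends (any callable
``image -> (68, 2) array or None``) can be registered with
:func:`register_backend`, which is also how the test-suite exercises the
contract without camera input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Union

import numpy as np

from .errors import DegenerateLandmarkError, MissingBackendError, StreamParseError
from .stream import StateStream

# landmark index pairs (1-based, iBUG convention)
RIGHT_EYE_PAIRS = ((38, 42), (39, 41))
LEFT_EYE_PAIRS = ((44, 48), (45, 47))
MOUTH_HEIGHT_PAIRS = ((62, 68), (63, 67), (64, 66))
MOUTH_CORNERS = (61, 65)


@dataclass(frozen=True)
class LandmarkSet:
    """68 facial landmark coordinates in pixels, 1-based iBUG indexing."""

    points: np.ndarray  # shape (68, 2), float

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (68, 2):
            raise ValueError(f"expected 68 (x, y) landmarks, got shape {pts.shape}")
        if not np.isfinite(pts).all():
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def point(self, index: int) -> np.ndarray:
        """Landmark by its 1-based iBUG index."""
        if not 1 <= index <= 68:
            raise IndexError(f"landmark index {index} outside 1..68")
        return self.points[index - 1]


def eyelid_gap(lm: LandmarkSet, side: str) -> float:
    """Mean vertical distance between the upper- and lower-eyelid landmark pairs.

    ``side="right"`` uses pairs (38, 42) and (39, 41); ``side="left"`` uses
    (44, 48) and (45, 47).  Result is in pixels and non-negative; 0 means a
    fully closed eye.
    """
    try:
        pairs = {"right": RIGHT_EYE_PAIRS, "left": LEFT_EYE_PAIRS}[side]
    except KeyError:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}") from None
    dists = [abs(lm.point(u)[1] - lm.point(l)[1]) for u, l in pairs]
    return float(np.mean(dists))


def mouth_aspect_ratio(lm: LandmarkSet) -> float:
    """Inner-lip mouth aspect ratio mar = Height / Width.

    Height is the mean vertical distance over the inner-lip pairs (62, 68),
    (63, 67), (64, 66); Width is the Euclidean distance between the inner
    mouth corners 61 and 65.
    """
    height = float(np.mean([abs(lm.point(u)[1] - lm.point(l)[1])
                            for u, l in MOUTH_HEIGHT_PAIRS]))
    width = float(np.linalg.norm(lm.point(MOUTH_CORNERS[0]) - lm.point(MOUTH_CORNERS[1])))
    if width <= 0:
        raise DegenerateLandmarkError("mouth width is zero; cannot form aspect ratio")
    return height / width


# -- detection backends ----------------------------------------------

BackendFn = Callable[[np.ndarray], Optional[np.ndarray]]
_BACKENDS: dict[str, BackendFn] = {}


def register_backend(name: str, fn: BackendFn) -> None:
    """Register a detector backend: ``image -> (68, 2) landmark array or None``.

    The backend is responsible for detecting the largest face and running
    landmark localization on it; ``None`` signals "no face found".
    """
    _BACKENDS[name] = fn


def available_backends() -> tuple[str, ...]:
    return tuple(sorted(_BACKENDS))


def _builtin_backend(name: str) -> BackendFn:
    # Lazily build the OpenCV/dlib based pipelines. These libraries and the
    # pretrained model assets (Haar cascade XML / HOG face detector +
    # shape_predictor_68_face_landmarks.dat) must be installed by the user.
    if name == "haar":
        try:
            import cv2  # noqa: F401
        except ImportError as exc:
            raise MissingBackendError(
                "backend 'haar' needs opencv-python and the pretrained "
                "'haarcascade_frontalface_default.xml' cascade plus a 68-point "
                "landmark model; install them or register_backend() a custom one"
            ) from exc
    elif name == "hog":
        try:
            import dlib  # noqa: F401
        except ImportError as exc:
            raise MissingBackendError(
                "backend 'hog' needs dlib and the pretrained "
                "'shape_predictor_68_face_landmarks.dat' asset; install them "
                "or register_backend() a custom one") from exc
    raise MissingBackendError(f"no backend named {name!r}; "
                              f"registered: {available_backends()}")


def detect_landmarks(frame: np.ndarray,
                     backend: Union[str, BackendFn] = "hog") -> Optional[LandmarkSet]:
    """Detect the largest face in ``frame`` and return its 68 landmarks.

    Returns ``None`` when no face is found.  ``backend`` is a registered
    backend name or a callable.
    """
    if callable(backend):
        fn = backend
    elif backend in _BACKENDS:
        fn = _BACKENDS[backend]
    else:
        fn = _builtin_backend(backend)
    pts = fn(np.asarray(frame))
    return None if pts is None else LandmarkSet(np.asarray(pts, dtype=float))


def video_to_stream(source: Union[str, Iterable[np.ndarray]],
                    backend: Union[str, BackendFn] = "hog",
                    fps: float = 30.0,
                    sample_fps: Optional[float] = None,
                    rescale: Optional[float] = None) -> StateStream:
    """Convert a video (file path or iterable of frames) into a StateStream.

    One record per processed frame; frames with no detected face yield
    records with absent gap/mar measurements.  ``sample_fps`` subsamples the
    native rate; ``rescale`` (0 < r <= 1) shrinks frames before detection
    for speed, with landmark coordinates mapped back to the original
    resolution.
    """
    if isinstance(source, str):
        try:
            import imageio.v3 as iio
        except ImportError as exc:  # pragma: no cover - env dependent
            raise StreamParseError("reading video containers requires imageio") from exc
        try:
            frames = iio.imiter(source)
            meta = iio.immeta(source)
            fps = float(meta.get("fps", fps))
        except (OSError, ValueError) as exc:
            raise StreamParseError(f"cannot decode video {source}: {exc}") from exc
    else:
        frames = source

    step = 1 if sample_fps is None else max(1, round(fps / sample_fps))
    out_fps = fps / step
    rows = {"t": [], "left_gap": [], "right_gap": [], "mar": []}
    for i, frame in enumerate(frames):
        if i % step:
            continue
        frame = np.asarray(frame)
        det_frame = frame
        if rescale is not None and 0 < rescale < 1:
            stride = max(1, round(1 / rescale))
            det_frame = frame[::stride, ::stride]
        lm = detect_landmarks(det_frame, backend=backend)
        if lm is not None and det_frame is not frame:
            lm = LandmarkSet(lm.points * (frame.shape[0] / det_frame.shape[0]))
        rows["t"].append(i / fps)
        if lm is None:
            rows["left_gap"].append(np.nan)
            rows["right_gap"].append(np.nan)
            rows["mar"].append(np.nan)
        else:
            rows["left_gap"].append(eyelid_gap(lm, "left"))
            rows["right_gap"].append(eyelid_gap(lm, "right"))
            rows["mar"].append(mouth_aspect_ratio(lm))
    if not rows["t"]:
        raise StreamParseError("video yielded no frames")
    return StateStream.from_arrays(np.asarray(rows["t"]), nominal_fps=out_fps,
                                   left_gap=np.asarray(rows["left_gap"]),
                                   right_gap=np.asarray(rows["right_gap"]),
                                   mar=np.asarray(rows["mar"]),
                                   meta={"source": "video", "backend": str(backend)})
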