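"""Sliding-window drowsiness indicators: PERCLOS, ECD and AOT.

All three indicators are computed over a temporal window (default one
minute) that slides forward once per second:

* PERCLOS — fraction of frames in the window with eyes closed;
* ECD — mean duration (s) of the maximal eyes-closed runs in the window,
  0 when there are none;
* AOT — mean duration (s) of yawns in the window, where a yawn is a
  mouth-open run longer than 3 s and its duration is counted only past
  those first 3 s; 0 when there are no yawns.

Runs are measured as run-length x nominal frame period (frame-count
arithmetic), with an option to use timestamp differences on irregular
streams.  Runs clipped by the window edges count only their in-window
portion, which keeps every window self-contained and bounds ECD/AOT by the
window length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, StreamValidationError
from .stream import StateStream


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry and the yawn qualification time."""

    window_s: float = 60.0
    stride_s: float = 1.0
    yawn_min_s: float = 3.0
    eye_combine: str = "all"            # how left/right closed flags merge
    duration_mode: str = "frames"       # "frames" or "timestamps"

    def __post_init__(self):
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not 0 < self.stride_s <= self.window_s:
            raise ValueError("stride_s must lie in (0, window_s]")
        if self.yawn_min_s < 0:
            raise ValueError("yawn_min_s must be non-negative")
        if self.eye_combine not in ("all", "any"):
            raise ValueError("eye_combine must be 'all' or 'any'")
        if self.duration_mode not in ("frames", "timestamps"):
            raise ValueError("duration_mode must be 'frames' or 'timestamps'")


@dataclass(frozen=True)
class IndicatorSample:
    """The three indicators at one emission instant."""

    t: float
    perclos: float
    ecd: float
    aot: float
    n_frames: int
    p_intervals: int
    n_yawns: int


def perclos(closed: Sequence[bool], n: Optional[int] = None) -> float:
    """Fraction of the n window frames in which the eyes are closed."""
    closed = np.asarray(closed, dtype=bool)
    if n is None:
        n = closed.size
    if n < 1:
        raise StreamValidationError("PERCLOS is undefined on an empty window")
    return float(closed.sum()) / n


def _runs(mask: np.ndarray) -> List[tuple]:
    """(start, length) of each maximal True run, in frame indices."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [mask.size]))
    return [(int(s), int(e - s)) for s, e in zip(starts, ends) if mask[s]]


def _run_durations(mask: np.ndarray, t: Optional[np.ndarray],
                   period: float, mode: str) -> np.ndarray:
    runs = _runs(mask)
    if not runs:
        return np.empty(0)
    if mode == "timestamps" and t is not None:
        # a run of frames i..j covers t[i] .. t[j] + one frame period
        return np.array([t[s + ln - 1] - t[s] + period for s, ln in runs])
    return np.array([ln * period for _, ln in runs])


def closed_intervals(closed: Sequence[bool], period: float,
                     t: Optional[np.ndarray] = None,
                     mode: str = "frames") -> np.ndarray:
    """Durations (s) of the maximal eyes-closed runs in the window."""
    return _run_durations(np.asarray(closed, dtype=bool), t, period, mode)


def ecd(closed: Sequence[bool], period: float,
        t: Optional[np.ndarray] = None, mode: str = "frames") -> float:
    """Mean eyes-closed interval duration; 0 when there is no closed interval.

    In frame mode the mean is computed from integer frame counts
    (``total_closed_frames * period / n_intervals``) so it is exactly
    reproducible regardless of summation order.
    """
    if mode == "frames":
        runs = _runs(np.asarray(closed, dtype=bool))
        if not runs:
            return 0.0
        return sum(ln for _, ln in runs) * period / len(runs)
    durations = closed_intervals(closed, period, t, mode)
    return float(durations.mean()) if durations.size else 0.0


def detect_yawns(mouth_open: Sequence[bool], period: float,
                 yawn_min_s: float = 3.0,
                 t: Optional[np.ndarray] = None, mode: str = "frames") -> np.ndarray:
    """Yawn durations (s) in the window.

    A maximal mouth-open run of length L > ``yawn_min_s`` contributes a
    yawn of duration L - ``yawn_min_s``; shorter runs contribute nothing.
    """
    lengths = _run_durations(np.asarray(mouth_open, dtype=bool), t, period, mode)
    return lengths[lengths > yawn_min_s + 1e-12] - yawn_min_s


def aot(mouth_open: Sequence[bool], period: float, yawn_min_s: float = 3.0,
        t: Optional[np.ndarray] = None, mode: str = "frames") -> float:
    """Mean yawn duration; 0 when the window contains no yawn.

    Frame mode uses integer frame counts for exact reproducibility:
    ``mean(L_i - m) = total_frames * period / n - m``.
    """
    if mode == "frames":
        lens = [ln for _, ln in _runs(np.asarray(mouth_open, dtype=bool))
                if ln * period > yawn_min_s + 1e-12]
        if not lens:
            return 0.0
        return sum(lens) * period / len(lens) - yawn_min_s
    yawns = detect_yawns(mouth_open, period, yawn_min_s, t, mode)
    return float(yawns.mean()) if yawns.size else 0.0


def eyes_closed_track(stream: StateStream, combine: str = "all") -> np.ndarray:
    """Combined eyes-closed bool track from the per-eye binary columns."""
    left = stream.binary_column("left_closed")
    right = stream.binary_column("right_closed")
    return (left & right) if combine == "all" else (left | right)


def window_sample(t_emit: float, closed: np.ndarray, mouth: np.ndarray,
                  period: float, cfg: WindowConfig,
                  t: Optional[np.ndarray] = None) -> IndicatorSample:
    """Indicators for a single, already-sliced window ending at ``t_emit``."""
    durations = closed_intervals(closed, period, t, cfg.duration_mode)
    yawns = detect_yawns(mouth, period, cfg.yawn_min_s, t, cfg.duration_mode)
    return IndicatorSample(
        t=t_emit,
        perclos=perclos(closed),
        ecd=ecd(closed, period, t, cfg.duration_mode),
        aot=aot(mouth, period, cfg.yawn_min_s, t, cfg.duration_mode),
        n_frames=int(closed.size),
        p_intervals=int(durations.size),
        n_yawns=int(yawns.size),
    )


def sliding_indicators(stream: StateStream,
                       cfg: WindowConfig = WindowConfig()) -> List[IndicatorSample]:
    """One :class:`IndicatorSample` per stride point.

    Emission instants are ``t0 + window_s, t0 + window_s + stride_s, ...``
    up to the stream's covered duration; the window ending at ``t_emit``
    contains the frames whose coverage interval ends in
    ``(t_emit - window_s, t_emit]``, i.e. frame start times in
    ``[t_emit - window_s, t_emit)``.
    """
    if not stream.is_binarized:
        raise StreamValidationError("sliding_indicators needs a binarized stream")
    t0 = float(stream.t[0])
    total = stream.duration - t0
    if total + 1e-9 < cfg.window_s:
        raise InsufficientDataError(
            f"stream covers {total:g}s but the window is {cfg.window_s:g}s")
    closed = eyes_closed_track(stream, cfg.eye_combine)
    mouth = stream.binary_column("mouth_open")
    t = stream.t
    period = stream.frame_period
    eps = period * 1e-6
    n_emit = int(np.floor((total - cfg.window_s) / cfg.stride_s + 1e-9)) + 1
    samples: List[IndicatorSample] = []
    for k in range(n_emit):
        te = t0 + cfg.window_s + k * cfg.stride_s
        i0 = np.searchsorted(t, te - cfg.window_s - eps, side="left")
        i1 = np.searchsorted(t, te - eps, side="left")
        samples.append(window_sample(te, closed[i0:i1], mouth[i0:i1],
                                     period, cfg, t[i0:i1]))
    return samples


def indicators_to_frame(samples: Sequence[IndicatorSample]) -> pd.DataFrame:
    """Samples as a DataFrame with the canonical output columns."""
    return pd.DataFrame([s.__dict__ for s in samples],
                        columns=["t", "perclos", "ecd", "aot",
                                 "n_frames", "p_intervals", "n_yawns"])
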