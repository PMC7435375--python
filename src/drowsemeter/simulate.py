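"""Synthetic facial-state stream generator with ground-truth labels.

The simulator emulates a scripted drowsiness-simulation session: the
driver's eye and mouth behaviour is generated per segment of a plan
(``[(label, duration_s), ...]``) by three independent renewal processes —

* **blinks**: short closures with exponential durations,
* **sustained closures**: longer closures with gamma-distributed durations
  (drowsy/severe regimes),
* **yawns**: mouth-open episodes with gamma-distributed durations.

Within each process the gap between the end of one event and the start of
the next is exponential with mean ``60/rate - mean_duration`` (floored at
a small refractory time), so the long-run closed-time fraction of a single
process is exactly ``rate * mean_duration / 60``.  Events are rendered to
per-frame binary states; :func:`render_continuous` then turns the binary
track into noisy eyelid-gap/mar signals so the calibration stage can be
exercised end to end.

What this emulates — and what it does not: the stream has realistic event
statistics and exact labels, but none of the imaging failure modes of real
video (landmark jitter, occlusion, illumination).  Pipeline accuracy on
simulated streams therefore measures the indicator/FIS chain, not the
vision frontend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import CalibrationProfile
from .errors import StreamValidationError
from .stream import StateStream

MIN_GAP_S = 0.2  # refractory floor between successive events of one process


@dataclass(frozen=True)
class RegimeParams:
    """Event-process rates (per minute) and mean durations (s) for one regime."""

    blink_rate: float = 15.0
    blink_duration_mean_s: float = 0.2
    sustained_rate: float = 0.0
    sustained_duration_mean_s: float = 3.0
    sustained_duration_shape: float = 6.0   # gamma shape; higher = narrower
    yawn_rate: float = 0.0
    yawn_duration_mean_s: float = 6.0
    yawn_duration_shape: float = 6.0

    def __post_init__(self):
        for name in ("blink_rate", "sustained_rate", "yawn_rate"):
            if getattr(self, name) < 0:
                raise StreamValidationError(f"{name} must be non-negative")
        for name in ("blink_duration_mean_s", "sustained_duration_mean_s",
                     "yawn_duration_mean_s"):
            if getattr(self, name) <= 0:
                raise StreamValidationError(f"{name} must be positive")


#: Default regime presets.  Chosen so each regime's renewal-theory mean
#: indicators land inside the intended fuzzy terms of the default FIS:
#: Normal  -> PERCLOS ~0.05, ECD ~0.2 s            (all Low)
#: Drowsy  -> PERCLOS ~0.27, ECD ~2.4 s            (both eye indicators Medium)
#: Severe  -> PERCLOS ~0.95, ECD ~tens of seconds  (both eye indicators High)
#: These are presets of this package, not measured values.
PRESETS: Dict[str, RegimeParams] = {
    "Normal": RegimeParams(blink_rate=15.0, blink_duration_mean_s=0.2),
    # drowsy eye closures are slow and long; short reflex blinks nearly
    # disappear, so the closed-interval statistics are dominated by the
    # sustained closures and the mean interval sits in the ECD Medium core
    "Drowsy": RegimeParams(blink_rate=1.0, blink_duration_mean_s=0.3,
                           sustained_rate=6.0, sustained_duration_mean_s=2.7,
                           yawn_rate=0.5, yawn_duration_mean_s=6.0),
    # severe drowsiness: long microsleeps, eyes closed most of the time
    "Severe": RegimeParams(blink_rate=0.0, blink_duration_mean_s=0.2,
                           sustained_rate=1.5, sustained_duration_mean_s=38.0,
                           sustained_duration_shape=8.0,
                           yawn_rate=1.0, yawn_duration_mean_s=10.0),
}


@dataclass
class SimulationParams:
    """Plan and process parameters for one simulation run."""

    plan: Sequence[Tuple[str, float]] = (("Normal", 120.0),)
    fps: float = 30.0
    seed: int = 0
    regimes: Dict[str, RegimeParams] = field(default_factory=lambda: dict(PRESETS))

    def __post_init__(self):
        if self.fps <= 0:
            raise StreamValidationError("fps must be positive")
        for label, dur in self.plan:
            if dur <= 0:
                raise StreamValidationError(f"segment {label!r} has non-positive duration")
            if label not in self.regimes:
                raise StreamValidationError(f"no regime parameters for label {label!r}")


@dataclass
class LabeledStream:
    """A binary stream plus its per-second ground-truth label track."""

    stream: StateStream
    truth: pd.DataFrame  # columns: t (second mark), label
    params: Optional[SimulationParams] = None


def _draw_events(rng: np.random.Generator, t0: float, t1: float,
                 rate_per_min: float, mean_s: float,
                 shape: Optional[float]) -> List[Tuple[float, float]]:
    """(start, end) event intervals of one renewal process, clipped to [t0, t1).

    The process starts in its stationary state: with probability
    ``duration/(duration+gap)`` the segment begins inside an event whose
    residual duration follows the equilibrium (length-biased) distribution,
    otherwise inside a gap whose residual is exponential (memoryless).
    This makes the closed-time fraction stationary from the first frame of
    a segment instead of ramping up over the first inter-event gap.
    """
    if rate_per_min <= 0:
        return []
    gap_mean = max(60.0 / rate_per_min - mean_s, MIN_GAP_S)

    def draw_duration() -> float:
        if shape is None:
            return rng.exponential(mean_s)
        return rng.gamma(shape, mean_s / shape)

    events = []
    frac = mean_s / (mean_s + gap_mean)
    if rng.random() < frac:
        # inside an event: length-biased duration (gamma shape k -> k+1 at the
        # same scale), uniform elapsed phase -> exact equilibrium residual
        k = 1.0 if shape is None else float(shape)
        residual = rng.uniform() * rng.gamma(k + 1.0, mean_s / k)
        events.append((t0, min(t0 + residual, t1)))
        cursor = t0 + residual + rng.exponential(gap_mean)
    else:
        cursor = t0 + rng.exponential(gap_mean)
    while cursor < t1:
        dur = draw_duration()
        events.append((cursor, min(cursor + dur, t1)))
        cursor = cursor + dur + rng.exponential(gap_mean)
    return events


def _paint(mask: np.ndarray, events: List[Tuple[float, float]], fps: float) -> None:
    n = mask.size
    for start, end in events:
        i0 = int(np.ceil(start * fps - 1e-9))
        i1 = int(np.ceil(end * fps - 1e-9))
        mask[max(i0, 0):min(i1, n)] = True


def simulate(params: SimulationParams) -> LabeledStream:
    """Render the plan to a per-frame binary stream with ground-truth labels.

    Deterministic for a fixed seed: a single PCG64 generator drives every
    draw, with segments processed in plan order and processes in the fixed
    order blink, sustained closure, yawn.
    """
    rng = np.random.default_rng(params.seed)
    total = float(sum(d for _, d in params.plan))
    n = int(round(total * params.fps))
    closed = np.zeros(n, dtype=bool)
    mouth = np.zeros(n, dtype=bool)
    cursor = 0.0
    seconds: List[Tuple[int, str, int]] = []
    for seg_idx, (label, dur) in enumerate(params.plan):
        reg = params.regimes[label]
        t0, t1 = cursor, cursor + dur
        _paint(closed, _draw_events(rng, t0, t1, reg.blink_rate,
                                    reg.blink_duration_mean_s, None), params.fps)
        _paint(closed, _draw_events(rng, t0, t1, reg.sustained_rate,
                                    reg.sustained_duration_mean_s,
                                    reg.sustained_duration_shape), params.fps)
        _paint(mouth, _draw_events(rng, t0, t1, reg.yawn_rate,
                                   reg.yawn_duration_mean_s,
                                   reg.yawn_duration_shape), params.fps)
        # second s belongs to the segment covering the interval (s-1, s]
        seconds.extend((s, label, seg_idx)
                       for s in range(int(round(t0)) + 1, int(round(t1)) + 1))
        cursor = t1
    t = np.arange(n) / params.fps
    stream = StateStream.from_arrays(t, nominal_fps=params.fps,
                                     left_closed=closed, right_closed=closed.copy(),
                                     mouth_open=mouth,
                                     meta={"source": "simulate", "seed": params.seed})
    truth = pd.DataFrame(seconds, columns=["t", "label", "segment"])
    return LabeledStream(stream=stream, truth=truth, params=params)


def expected_perclos(regime: RegimeParams) -> float:
    """Stationary closed-time fraction implied by the regime parameters.

    Each closure process contributes the fraction ``duration / cycle`` where
    the mean cycle is ``mean_duration + mean_gap`` (``= 60/rate`` when the
    gap is not floored); independent processes combine as a union:
    ``1 - prod(1 - f_i)``.  Clamped to [0, 1].
    """
    fractions = []
    for rate, mean in ((regime.blink_rate, regime.blink_duration_mean_s),
                       (regime.sustained_rate, regime.sustained_duration_mean_s)):
        if rate <= 0:
            continue
        gap = max(60.0 / rate - mean, MIN_GAP_S)
        fractions.append(mean / (mean + gap))
    closed = 1.0 - float(np.prod([1.0 - f for f in fractions])) if fractions else 0.0
    return min(max(closed, 0.0), 1.0)


def render_continuous(stream: StateStream,
                      profile: Optional[CalibrationProfile] = None,
                      closed_gap_fraction: float = 0.1,
                      closed_mar: float = 0.3,
                      open_mar: float = 1.0,
                      noise_sd: float = 0.0,
                      seed: int = 0) -> Tuple[StateStream, CalibrationProfile]:
    """Turn a binary stream into continuous gap/mar signals.

    Open frames get a gap near the profile's open reference, closed frames
    near ``closed_gap_fraction`` of it (default 10%, inside the 5-15% band
    a closed eyelid leaves); mouth-open frames get ``open_mar`` (above the
    0.7 threshold), others ``closed_mar``.  Gaussian noise with standard
    deviation ``noise_sd`` (as a fraction of each signal's open reference)
    is added; with ``noise_sd=0`` classification with the generating
    profile recovers the binary track exactly.

    Returns ``(continuous_stream, generating_profile)``.
    """
    if profile is None:
        profile = CalibrationProfile(open_gap_ref_left=10.0, open_gap_ref_right=10.0,
                                     open_mar_ref=open_mar)
    rng = np.random.default_rng(seed)
    n = len(stream)
    left = stream.binary_column("left_closed")
    right = stream.binary_column("right_closed")
    mouth = stream.binary_column("mouth_open")

    def gaps(closed_mask, ref):
        base = np.where(closed_mask, closed_gap_fraction * ref, ref)
        if noise_sd > 0:
            base = base + rng.normal(0.0, noise_sd * ref, size=n)
        return np.clip(base, 0.0, None)

    mar = np.where(mouth, open_mar, closed_mar)
    if noise_sd > 0:
        mar = mar + rng.normal(0.0, noise_sd * open_mar, size=n)
    out = StateStream.from_arrays(
        stream.t, nominal_fps=stream.nominal_fps,
        left_gap=gaps(left, profile.open_gap_ref_left),
        right_gap=gaps(right, profile.open_gap_ref_right),
        mar=np.clip(mar, 0.0, None),
        label=stream.df["label"].to_numpy() if "label" in stream.df.columns else None,
        meta=dict(stream.meta) | {"rendered": True})
    return out, profile


def plan_from_proportions(n_normal: int, n_drowsy: int, n_severe: int,
                          segment_s: float = 60.0,
                          sessions: int = 4) -> List[Tuple[str, float]]:
    """A drive-like segment plan in the given proportions.

    The segments are arranged as ``sessions`` repeated progressions
    Normal -> Drowsy -> Severe, emulating alertness degrading over a drive;
    counts must divide evenly across sessions.
    """
    if any(c % sessions for c in (n_normal, n_drowsy, n_severe)):
        raise StreamValidationError("segment counts must divide evenly across sessions")
    plan: List[Tuple[str, float]] = []
    for _ in range(sessions):
        plan += [("Normal", segment_s)] * (n_normal // sessions)
        plan += [("Drowsy", segment_s)] * (n_drowsy // sessions)
        plan += [("Severe", segment_s)] * (n_severe // sessions)
    return plan
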