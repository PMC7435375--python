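"""Personalized calibration and frame-state classification.

Eye/mouth anatomy differs between drivers, so a fixed eyelid-gap threshold
does not transfer.  The system therefore starts with a setup window
(default one minute) during which the driver sits in front of the camera;
for each eye (and for mar) the mean of the top 5% of measured values is
taken as that driver's personal "open" reference.  At 30 fps a one-minute
window yields 1800 values per signal, so 90 values enter each average.

Frame classification then applies two rules:

* an eye counts as closed when its gap falls below 20% of that eye's open
  reference (both thresholds configurable);
* the mouth counts as open when mar exceeds 0.7 (strictly), the fixed
  literature threshold — optionally replaced by a ratio of the calibrated
  open-mouth mar.

Whether "eyes closed" requires both eyes (default, robust to winks and
single-eye landmark glitches) or either eye is configurable.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Tuple

import numpy as np
import yaml

from .errors import CalibrationError, ConfigError, InsufficientDataError, MissingCalibrationError
from .stream import BINARY_COLS, FrameRecord, StateStream


@dataclass
class CalibrationProfile:
    """Per-driver open-eye/open-mouth references and classification thresholds."""

    open_gap_ref_left: float
    open_gap_ref_right: float
    open_mar_ref: Optional[float] = None
    eye_closed_ratio: float = 0.2
    mar_open_threshold: float = 0.7
    mar_mode: str = "absolute"          # "absolute": mar > mar_open_threshold
    mar_open_ratio: float = 0.5         # "relative": mar > ratio * open_mar_ref
    eye_combine: str = "all"            # "all": both eyes closed; "any": either
    calibration_duration_s: float = 60.0
    top_fraction: float = 0.05
    n_samples: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.open_gap_ref_left <= 0 or self.open_gap_ref_right <= 0:
            raise CalibrationError("open-eye references must be positive")
        if not 0 < self.eye_closed_ratio < 1:
            raise CalibrationError("eye_closed_ratio must lie in (0, 1)")
        if not 0 < self.top_fraction <= 1:
            raise CalibrationError("top_fraction must lie in (0, 1]")
        if self.eye_combine not in ("all", "any"):
            raise CalibrationError("eye_combine must be 'all' or 'any'")
        if self.mar_mode not in ("absolute", "relative"):
            raise CalibrationError("mar_mode must be 'absolute' or 'relative'")
        if self.mar_mode == "relative" and self.open_mar_ref is None:
            raise CalibrationError("relative mar_mode requires open_mar_ref")

    @property
    def effective_mar_threshold(self) -> float:
        if self.mar_mode == "relative":
            return self.mar_open_ratio * float(self.open_mar_ref)
        return self.mar_open_threshold

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CalibrationProfile":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: not a calibration profile mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


def top_fraction_mean(values: np.ndarray, top_fraction: float) -> Tuple[float, int]:
    """Mean of the ``ceil(top_fraction * N)`` largest values; returns (mean, k).

    Deterministic and permutation-invariant: a pure order statistic + mean.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    n = values.size
    if n == 0:
        raise CalibrationError("no usable values to calibrate from")
    k = math.ceil(top_fraction * n)
    top = np.partition(values, n - k)[n - k:]
    return float(top.mean()), k


def calibrate(stream: StateStream, duration_s: float = 60.0,
              top_fraction: float = 0.05, **profile_kwargs) -> CalibrationProfile:
    """Build a :class:`CalibrationProfile` from the first ``duration_s`` seconds.

    For each eye (and mar, when present) the values collected in the window
    are sorted and the top ``ceil(top_fraction * N)`` averaged, N counting
    only frames with a usable measurement.  Raises
    :class:`InsufficientDataError` when the stream is shorter than the
    window and :class:`CalibrationError` when it has no continuous
    measurements.
    """
    if stream.duration + 1e-9 < duration_s:
        raise InsufficientDataError(
            f"calibration needs {duration_s:g}s of stream, got {stream.duration:g}s")
    t0 = float(stream.t[0])
    window = stream.df[stream.t < t0 + duration_s - 1e-9]
    refs = {}
    counts = {}
    for col, key in (("left_gap", "left"), ("right_gap", "right")):
        if col not in window.columns:
            raise CalibrationError(
                f"stream has no continuous {col} measurements; calibration impossible")
        refs[key], counts[key] = _ref_and_count(window[col], top_fraction)
    mar_ref = None
    if "mar" in window.columns and window["mar"].notna().any():
        mar_ref, counts["mar"] = _ref_and_count(window["mar"], top_fraction)
    n_samples = {f"n_{k}": int(window[c].notna().sum())
                 for c, k in (("left_gap", "left"), ("right_gap", "right"), ("mar", "mar"))
                 if c in window.columns}
    n_samples.update({f"k_{k}": v for k, v in counts.items()})
    return CalibrationProfile(open_gap_ref_left=refs["left"],
                              open_gap_ref_right=refs["right"],
                              open_mar_ref=mar_ref,
                              calibration_duration_s=duration_s,
                              top_fraction=top_fraction,
                              n_samples=n_samples,
                              **profile_kwargs)


def _ref_and_count(series, top_fraction) -> Tuple[float, int]:
    mean, k = top_fraction_mean(series.to_numpy(), top_fraction)
    return mean, k


def classify_frame(rec: FrameRecord,
                   profile: Optional[CalibrationProfile] = None) -> Tuple[bool, bool]:
    """Classify one frame into ``(eyes_closed, mouth_open)``.

    Pre-binarized states pass through unchanged.  Continuous measurements
    need a profile: an eye is closed when its gap is below
    ``eye_closed_ratio`` times that eye's reference; the per-eye flags are
    combined per ``profile.eye_combine``; the mouth is open when mar
    strictly exceeds the effective threshold.  Frames missing a measurement
    classify as open (least drowsy) for that feature.
    """
    combine = all if profile is None or profile.eye_combine == "all" else any

    if rec.left_closed is not None or rec.right_closed is not None:
        flags = [f for f in (rec.left_closed, rec.right_closed) if f is not None]
        eyes_closed = combine(flags)
    else:
        if rec.left_gap is None and rec.right_gap is None:
            eyes_closed = False
        else:
            if profile is None:
                raise MissingCalibrationError(
                    "continuous measurements need a calibration profile; run calibrate()")
            flags = []
            if rec.left_gap is not None:
                flags.append(rec.left_gap < profile.eye_closed_ratio * profile.open_gap_ref_left)
            if rec.right_gap is not None:
                flags.append(rec.right_gap < profile.eye_closed_ratio * profile.open_gap_ref_right)
            eyes_closed = combine(flags)

    if rec.mouth_open is not None:
        mouth_open = rec.mouth_open
    elif rec.mar is not None:
        thr = profile.effective_mar_threshold if profile is not None else 0.7
        mouth_open = rec.mar > thr
    else:
        mouth_open = False
    return bool(eyes_closed), bool(mouth_open)


def binarize_stream(stream: StateStream,
                    profile: Optional[CalibrationProfile] = None) -> StateStream:
    """Vectorized :func:`classify_frame` over a whole stream.

    Returns a stream in which every record carries the three binary state
    columns.  Idempotent: already-binarized streams are returned unchanged.
    """
    if stream.is_binarized:
        return stream
    df = stream.df.copy()
    have_gaps = any(c in df.columns for c in ("left_gap", "right_gap"))
    have_flags = any(c in df.columns for c in ("left_closed", "right_closed"))
    if have_gaps and profile is None and not have_flags:
        raise MissingCalibrationError(
            "continuous measurements need a calibration profile; run calibrate()")

    def eye_flags(gap_col, flag_col, ref):
        if flag_col in df.columns and df[flag_col].notna().all():
            return df[flag_col].to_numpy(dtype=bool)
        if gap_col in df.columns:
            gaps = df[gap_col].to_numpy(dtype=float)
            closed = gaps < profile.eye_closed_ratio * ref
            closed[np.isnan(gaps)] = False  # faceless frame -> least drowsy
            if flag_col in df.columns:  # fill only the gaps in a partial column
                known = df[flag_col].notna().to_numpy()
                closed[known] = df[flag_col].fillna(False).to_numpy(dtype=bool)[known]
            return closed
        if flag_col in df.columns:
            return df[flag_col].fillna(False).to_numpy(dtype=bool)
        return np.zeros(len(df), dtype=bool)

    left_ref = profile.open_gap_ref_left if profile else 1.0
    right_ref = profile.open_gap_ref_right if profile else 1.0
    df["left_closed"] = eye_flags("left_gap", "left_closed", left_ref)
    df["right_closed"] = eye_flags("right_gap", "right_closed", right_ref)

    if "mouth_open" in df.columns and df["mouth_open"].notna().all():
        pass
    elif "mar" in df.columns:
        mar = df["mar"].to_numpy(dtype=float)
        thr = profile.effective_mar_threshold if profile is not None else 0.7
        mouth = mar > thr
        mouth[np.isnan(mar)] = False
        if "mouth_open" in df.columns:
            known = df["mouth_open"].notna().to_numpy()
            mouth[known] = df["mouth_open"].fillna(False).to_numpy(dtype=bool)[known]
        df["mouth_open"] = mouth
    else:
        df["mouth_open"] = df.get("mouth_open", np.zeros(len(df), dtype=bool))
        df["mouth_open"] = df["mouth_open"].fillna(False)
    for c in BINARY_COLS:
        df[c] = df[c].astype(bool)
    return StateStream(df, nominal_fps=stream.nominal_fps, meta=dict(stream.meta))
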