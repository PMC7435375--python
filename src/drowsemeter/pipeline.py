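"""End-to-end processing chain: stream -> calibration -> indicators -> FIS.

The chain mirrors the five-block architecture of a camera-based drowsiness
monitor (acquisition, face detection, facial-state determination,
indicator computation, level estimation); here the acquisition/detection
stages are represented by the input stream, which may come from the
landmark frontend, a log file, or the simulator.

The first drowsiness level is emitted at ``t = window_s``: the indicator
definitions presuppose a full window, so no partial-window output exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import pandas as pd

from .calibration import CalibrationProfile, binarize_stream, calibrate
from .errors import MissingCalibrationError
from .fuzzy import FISConfig, default_config, infer
from .indicators import IndicatorSample, WindowConfig, indicators_to_frame, sliding_indicators
from .stream import StateStream, read_stream

logger = logging.getLogger("drowsemeter")


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs besides the input stream."""

    fis: FISConfig = field(default_factory=default_config)
    profile: Optional[CalibrationProfile] = None
    window: WindowConfig = field(default_factory=WindowConfig)
    calibrate_from_start: bool = False   # derive the profile from the first minute
    calibration_duration_s: float = 60.0


def levels_frame(samples: List[IndicatorSample], fis: FISConfig) -> pd.DataFrame:
    """Run FIS inference over an indicator series.

    Returns one row per emission: ``t, label, state, crisp, deg_low,
    deg_medium, deg_high`` plus the indicator values.  Inference is
    stateless per sample (no hysteresis).
    """
    rows = []
    for s in samples:
        level = infer(s.perclos, s.ecd, s.aot, fis)
        rows.append({
            "t": s.t, "label": level.label, "state": level.state,
            "crisp": level.crisp,
            "deg_low": level.memberships["Low"],
            "deg_medium": level.memberships["Medium"],
            "deg_high": level.memberships["High"],
            "perclos": s.perclos, "ecd": s.ecd, "aot": s.aot,
        })
    return pd.DataFrame(rows)


def run_pipeline(source: Union[str, StateStream],
                 cfg: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Process a stream file or StateStream into per-second drowsiness levels.

    Pre-binarized streams skip calibration entirely.  Continuous streams
    need ``cfg.profile``, or ``cfg.calibrate_from_start`` to derive one
    from the stream's first minute.  Raises
    :class:`~drowsemeter.errors.MissingCalibrationError` with a pointer to
    the ``calibrate`` command otherwise.
    """
    cfg = cfg or PipelineConfig()
    stream = read_stream(source) if isinstance(source, str) else source
    logger.info("pipeline: %d frames at %.3g fps", len(stream), stream.nominal_fps)

    if stream.is_binarized:
        logger.info("stream is pre-binarized; calibration skipped")
        binary = stream
    else:
        profile = cfg.profile
        if profile is None and cfg.calibrate_from_start:
            profile = calibrate(stream, duration_s=cfg.calibration_duration_s)
            logger.info("calibrated from stream start: refs L=%.3g R=%.3g",
                        profile.open_gap_ref_left, profile.open_gap_ref_right)
        if profile is None:
            raise MissingCalibrationError(
                "continuous stream without a calibration profile; run the "
                "'calibrate' command first or set calibrate_from_start")
        binary = binarize_stream(stream, profile)

    samples = sliding_indicators(binary, cfg.window)
    logger.info("computed %d indicator samples", len(samples))
    return levels_frame(samples, cfg.fis)


def alarm_events(levels: pd.DataFrame, min_state: str = "Drowsy",
                 debounce_s: int = 0) -> List[Tuple[float, str]]:
    """Alarm hook: ``(timestamp, state)`` events when the level escalates.

    An alarm fires when the state reaches ``min_state`` or above and, with
    ``debounce_s > 0``, has persisted that many consecutive seconds.  The
    output is an event list, not hardware I/O.
    """
    order = {"Normal": 0, "Drowsy": 1, "Severe": 2}
    threshold = order[min_state]
    events = []
    run = 0
    prev_fired = False
    for t, state in zip(levels["t"], levels["state"]):
        if order[state] >= threshold:
            run += 1
            if run > debounce_s and not prev_fired:
                events.append((float(t), str(state)))
                prev_fired = True
        else:
            run = 0
            prev_fired = False
    return events


__all__ = ["PipelineConfig", "run_pipeline", "levels_frame", "alarm_events",
           "indicators_to_frame"]
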