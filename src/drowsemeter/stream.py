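"""Canonical data model and I/O for per-frame facial-state time series.

A :class:`StateStream` holds one row per video frame: a timestamp ``t``
(seconds from stream start), continuous measurements (eyelid gaps for the
left/right eye and the mouth aspect ratio ``mar``) and/or pre-binarized
states (``left_closed``, ``right_closed``, ``mouth_open``).  Streams are
interchanged as plain CSV or JSONL with a fixed column vocabulary so that
logs from any landmark frontend can be fed into the pipeline.

Timestamps are stored, frame indices are always derived: a real capture
drops frames, and the arithmetic downstream only needs ``t`` and the
nominal frame rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import StreamParseError, StreamValidationError

#: continuous measurement columns (floats, NaN = absent)
CONTINUOUS_COLS = ("left_gap", "right_gap", "mar")
#: pre-binarized state columns (pandas nullable boolean)
BINARY_COLS = ("left_closed", "right_closed", "mouth_open")
#: full column vocabulary, in canonical order
ALL_COLS = ("t",) + CONTINUOUS_COLS + BINARY_COLS + ("label",)


@dataclass
class FrameRecord:
    """One frame's worth of facial-state information."""

    t: float
    left_gap: Optional[float] = None
    right_gap: Optional[float] = None
    mar: Optional[float] = None
    left_closed: Optional[bool] = None
    right_closed: Optional[bool] = None
    mouth_open: Optional[bool] = None
    label: Optional[str] = None

    @property
    def has_continuous(self) -> bool:
        return any(v is not None for v in (self.left_gap, self.right_gap, self.mar))

    @property
    def has_binary(self) -> bool:
        return any(v is not None for v in (self.left_closed, self.right_closed, self.mouth_open))


def _nullable_bool(values) -> pd.arrays.BooleanArray:
    return pd.array(values, dtype="boolean")


@dataclass
class StateStream:
    """An ordered per-frame facial-state time series.

    Parameters
    ----------
    df
        One row per frame.  Must contain ``t``; other columns are optional
        and drawn from :data:`ALL_COLS`.
    nominal_fps
        Nominal capture rate in frames per second.  Inferred from the
        median inter-frame interval when not given.
    meta
        Free-form provenance tags.
    """

    df: pd.DataFrame
    nominal_fps: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "t" not in df.columns:
            raise StreamValidationError("stream is missing the mandatory 't' column")
        df["t"] = df["t"].astype(float)
        for col in CONTINUOUS_COLS:
            if col in df.columns:
                df[col] = df[col].astype(float)
        for col in BINARY_COLS:
            if col in df.columns and df[col].dtype != "boolean":
                df[col] = _nullable_bool(df[col])
        order = [c for c in ALL_COLS if c in df.columns]
        self.df = df[order].reset_index(drop=True)
        if self.nominal_fps is None:
            self.nominal_fps = self._infer_fps()
        self.validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[FrameRecord],
                     nominal_fps: Optional[float] = None,
                     meta: Optional[dict] = None) -> "StateStream":
        rows = []
        for r in records:
            row = {"t": r.t}
            for col in CONTINUOUS_COLS + BINARY_COLS + ("label",):
                v = getattr(r, col)
                if v is not None:
                    row[col] = v
            rows.append(row)
        df = pd.DataFrame(rows)
        for col in BINARY_COLS:
            if col in df.columns:
                df[col] = _nullable_bool(df[col].where(df[col].notna(), pd.NA))
        return cls(df, nominal_fps=nominal_fps, meta=meta or {})

    @classmethod
    def from_arrays(cls, t: np.ndarray, nominal_fps: Optional[float] = None,
                    meta: Optional[dict] = None, **columns) -> "StateStream":
        data = {"t": np.asarray(t, dtype=float)}
        for name, values in columns.items():
            if values is None:
                continue
            if name not in CONTINUOUS_COLS + BINARY_COLS + ("label",):
                raise StreamValidationError(f"unknown stream column {name!r}")
            if name in BINARY_COLS:
                data[name] = _nullable_bool(values)
            else:
                data[name] = values
        return cls(pd.DataFrame(data), nominal_fps=nominal_fps, meta=meta or {})

    # -- basic properties ---------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def t(self) -> np.ndarray:
        return self.df["t"].to_numpy()

    @property
    def frame_period(self) -> float:
        return 1.0 / float(self.nominal_fps)

    @property
    def duration(self) -> float:
        """Covered duration: last timestamp plus one frame period."""
        return float(self.t[-1]) + self.frame_period

    @property
    def is_binarized(self) -> bool:
        """True when every frame carries all three binary state flags."""
        return all(c in self.df.columns and not self.df[c].isna().any()
                   for c in BINARY_COLS)

    def binary_column(self, name: str, fill: bool = False) -> np.ndarray:
        """Binary state column as a plain bool array; missing values -> ``fill``."""
        if name not in BINARY_COLS:
            raise ValueError(f"{name!r} is not a binary state column")
        if name not in self.df.columns:
            return np.full(len(self.df), fill, dtype=bool)
        return self.df[name].fillna(fill).to_numpy(dtype=bool)

    def records(self) -> Iterator[FrameRecord]:
        cols = [c for c in ALL_COLS if c in self.df.columns]
        for row in self.df.itertuples(index=False):
            kw = {}
            for col, v in zip(cols, row):
                if v is pd.NA or (isinstance(v, float) and math.isnan(v)):
                    continue
                kw[col] = bool(v) if col in BINARY_COLS else v
            yield FrameRecord(**kw)

    # -- validation ---------------------------------------------------

    def _infer_fps(self) -> float:
        if len(self.df) < 2:
            return 30.0
        dt = float(np.median(np.diff(self.t)))
        if dt <= 0:
            return 30.0
        fps = 1.0 / dt
        return round(fps) if abs(fps - round(fps)) < 0.05 * fps else fps

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            raise StreamValidationError("stream contains no frames")
        t = self.t
        if t[0] < 0:
            raise StreamValidationError("timestamps must be non-negative")
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            row = int(bad[0]) + 1
            raise StreamValidationError(
                f"timestamps must be strictly increasing; violation at row {row} "
                f"(t={t[row]:g} after t={t[row - 1]:g})")
        present = np.zeros(len(df), dtype=bool)
        for col in CONTINUOUS_COLS:
            if col in df.columns:
                vals = df[col].to_numpy()
                if np.nanmin(vals, initial=0.0) < 0:
                    raise StreamValidationError(f"column {col!r} contains negative values")
                present |= ~np.isnan(vals)
        for col in BINARY_COLS:
            if col in df.columns:
                present |= df[col].notna().to_numpy()
        has_any_col = any(c in df.columns for c in CONTINUOUS_COLS + BINARY_COLS)
        if not has_any_col:
            raise StreamValidationError(
                "stream has neither continuous measurement nor binary state columns")
        if not present.all():
            # all-absent rows are legal: they are frames where no face was
            # detected; downstream stages treat them as missing data
            n_missing = int((~present).sum())
            warnings.warn(f"{n_missing} frame(s) carry no measurements "
                          "(no face detected)", stacklevel=2)
        if len(df) >= 2 and self.nominal_fps:
            med = float(np.median(np.diff(t)))
            nominal = 1.0 / self.nominal_fps
            if not (0.8 * nominal <= med <= 1.2 * nominal):
                warnings.warn(
                    f"median inter-frame interval {med:.4f}s deviates >20% from "
                    f"nominal 1/{self.nominal_fps:g}s", stacklevel=2)


# -- file I/O ---------------------------------------------------------


def _infer_dialect(path: str, dialect: Optional[str]) -> str:
    if dialect is not None:
        return dialect
    p = str(path).lower()
    return "jsonl" if p.endswith((".jsonl", ".ndjson", ".json")) else "csv"


def read_stream(path, dialect: Optional[str] = None,
                nominal_fps: Optional[float] = None) -> StateStream:
    """Read a stream file in the canonical CSV or JSONL dialect.

    Missing optional columns yield absent fields; empty cells / JSON nulls
    are absent values.  Raises :class:`StreamParseError` on malformed input
    and :class:`StreamValidationError` on invariant violations.
    """
    dialect = _infer_dialect(path, dialect)
    try:
        if dialect == "csv":
            df = pd.read_csv(path, dtype={c: "boolean" for c in BINARY_COLS} |
                             {"label": "string"})
        elif dialect == "jsonl":
            df = pd.read_json(path, orient="records", lines=True)
        else:
            raise StreamParseError(f"unknown dialect {dialect!r}")
    except (ValueError, OSError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise StreamParseError(f"could not parse {path} as {dialect}: {exc}") from exc
    if len(df) == 0 or "t" not in df.columns:
        raise StreamParseError(f"{path}: empty stream (no rows or no 't' column)")
    if "label" in df.columns:
        df["label"] = df["label"].astype(object).where(df["label"].notna(), None)
    drop = [c for c in df.columns if c in CONTINUOUS_COLS + BINARY_COLS
            and df[c].isna().all()]
    return StateStream(df.drop(columns=drop), nominal_fps=nominal_fps)


def write_stream(stream: StateStream, path, dialect: Optional[str] = None) -> None:
    """Write a stream; ``read_stream(write_stream(s))`` reproduces ``s``.

    Columns that are entirely absent are not written; partially absent
    values appear as empty CSV cells / JSON nulls.
    """
    dialect = _infer_dialect(path, dialect)
    df = stream.df.copy()
    df = df.drop(columns=[c for c in df.columns if c != "t" and df[c].isna().all()])
    if dialect == "csv":
        df.to_csv(path, index=False, float_format="%.12g")
    elif dialect == "jsonl":
        df.to_json(path, orient="records", lines=True, double_precision=12)
    else:
        raise StreamParseError(f"unknown dialect {dialect!r}")
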