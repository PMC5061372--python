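"""Reading, writing and validation of spiral traces and cohort metadata.

On-disk formats are plain UTF-8 CSV:

* trace files: header ``subject_id,hand,trial,t,x,y,p`` with one pen sample
  per row (t in seconds, x/y in cm, p in 0-255 pressure units);
* cohort files: header ``subject_id,group,age,sex,handedness,duration,subtype``.

Raw tablets report integer points; at an acquisition resolution of 1,000
points/cm the ``points_per_cm`` argument of :func:`read_traces` converts
point coordinates to the cm units all spatial indices are defined in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

HANDS = ("dominant", "nondominant")
GROUPS = ("PD", "control")
SEXES = ("M", "F")
HANDEDNESS = ("right", "left")
SUBTYPES = ("TD", "intermediate", "PIGD")

TRACE_COLUMNS = ["subject_id", "hand", "trial", "t", "x", "y", "p"]
COHORT_COLUMNS = ["subject_id", "group", "age", "sex", "handedness", "duration", "subtype"]

MIN_SAMPLES = 50
MAX_TRIALS = 10

#: pen-lift heuristic: a time gap larger than this multiple of the median
#: sampling interval splits a record into strokes.
PEN_LIFT_GAP_FACTOR = 5.0


class SpiralFormatError(ValueError):
    """A file does not conform to the trace/cohort CSV dialect."""


class SpiralValidationError(ValueError):
    """Data violates a trace or metadata invariant."""


@dataclass
class SpiralTrace:
    """One drawn spiral: time-ordered (t, x, y, pressure) samples.

    Invariants (enforced by :meth:`validate`): t strictly increasing, at
    least ``MIN_SAMPLES`` samples, finite coordinates, trial in 1..10.
    """

    subject_id: str
    hand: str
    trial: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    p: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.p is None:
            self.p = np.full_like(self.t, 128.0)
        self.p = np.asarray(self.p, dtype=float)

    def __len__(self) -> int:
        return self.t.size

    def validate(self) -> "SpiralTrace":
        if self.hand not in HANDS:
            raise SpiralValidationError(
                f"{self.subject_id}: unknown hand label {self.hand!r}")
        if not (1 <= int(self.trial) <= MAX_TRIALS):
            raise SpiralValidationError(
                f"{self.subject_id}: trial {self.trial} outside 1..{MAX_TRIALS}")
        n = len(self)
        if not (self.x.size == self.y.size == self.p.size == n):
            raise SpiralValidationError(f"{self.subject_id}: ragged channels")
        if n < MIN_SAMPLES:
            raise SpiralValidationError(
                f"{self.subject_id}: only {n} samples (< {MIN_SAMPLES})")
        dt = np.diff(self.t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise SpiralValidationError(
                f"{self.subject_id} hand={self.hand} trial={self.trial}: "
                f"time not strictly increasing at row {int(bad[0]) + 1}")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise SpiralValidationError(f"{self.subject_id}: non-finite coordinates")
        return self

    def longest_stroke(self) -> "SpiralTrace":
        """Return the longest contiguous pen-down segment.

        A gap in t exceeding ``PEN_LIFT_GAP_FACTOR`` times the median
        sampling interval is treated as a pen lift. Spirals are drawn in a
        single stroke in practice, so this is a robustness guard only.
        """
        dt = np.diff(self.t)
        if dt.size == 0:
            return self
        cut = PEN_LIFT_GAP_FACTOR * float(np.median(dt))
        breaks = np.nonzero(dt > cut)[0]
        if breaks.size == 0:
            return self
        bounds = np.concatenate(([0], breaks + 1, [len(self)]))
        lengths = np.diff(bounds)
        k = int(np.argmax(lengths))
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        return SpiralTrace(self.subject_id, self.hand, int(self.trial),
                           self.t[lo:hi], self.x[lo:hi], self.y[lo:hi], self.p[lo:hi])


@dataclass(frozen=True)
class SubjectMeta:
    """Covariates for one subject."""

    subject_id: str
    group: str
    age: float
    sex: str
    handedness: str
    disease_duration: Optional[float] = None
    subtype_label: Optional[str] = None

    def validate(self) -> "SubjectMeta":
        if self.group not in GROUPS:
            raise SpiralValidationError(
                f"{self.subject_id}: unknown group label {self.group!r}")
        if self.sex not in SEXES:
            raise SpiralValidationError(f"{self.subject_id}: unknown sex {self.sex!r}")
        if self.handedness not in HANDEDNESS:
            raise SpiralValidationError(
                f"{self.subject_id}: unknown handedness {self.handedness!r}")
        if not (self.age > 0 and math.isfinite(self.age)):
            raise SpiralValidationError(f"{self.subject_id}: age must be positive")
        has_dur = self.disease_duration is not None
        if self.group == "PD" and not has_dur:
            raise SpiralValidationError(
                f"{self.subject_id}: PD subject without disease duration")
        if self.group == "control" and has_dur:
            raise SpiralValidationError(
                f"{self.subject_id}: control subject with disease duration")
        if self.subtype_label is not None and self.subtype_label not in SUBTYPES:
            raise SpiralValidationError(
                f"{self.subject_id}: unknown subtype {self.subtype_label!r}")
        return self


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SpiralFormatError(f"{path}: missing column(s) {', '.join(missing)}")


def read_traces(path, points_per_cm: Optional[float] = None) -> list[SpiralTrace]:
    """Read spiral traces from a trace CSV.

    Parameters
    ----------
    path
        Trace CSV with header ``subject_id,hand,trial,t,x,y,p``.
    points_per_cm
        If given, x and y are divided by this factor (raw tablet points to
        cm; digitizing tablets commonly resolve 1,000 points/cm).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, TRACE_COLUMNS, path)
    traces: list[SpiralTrace] = []
    for (sid, hand, trial), grp in df.groupby(
            ["subject_id", "hand", "trial"], sort=True):
        x = grp["x"].to_numpy(float)
        y = grp["y"].to_numpy(float)
        if points_per_cm:
            x = x / points_per_cm
            y = y / points_per_cm
        tr = SpiralTrace(str(sid), str(hand), int(trial),
                         grp["t"].to_numpy(float), x, y, grp["p"].to_numpy(float))
        traces.append(tr.validate())
    return traces


def write_traces(traces: Iterable[SpiralTrace], path) -> Path:
    """Write traces to a trace CSV (re-readable losslessly to 1e-6)."""
    path = Path(path)
    frames = []
    seen: set[tuple[str, str, int]] = set()
    for tr in traces:
        tr.validate()
        key = (tr.subject_id, tr.hand, int(tr.trial))
        if key in seen:
            raise SpiralValidationError(f"duplicate trace {key}")
        seen.add(key)
        frames.append(pd.DataFrame({
            "subject_id": tr.subject_id, "hand": tr.hand, "trial": int(tr.trial),
            "t": tr.t, "x": tr.x, "y": tr.y, "p": tr.p,
        }))
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=TRACE_COLUMNS)
    out.to_csv(path, index=False, float_format="%.6f")
    return path


def read_cohort_meta(path) -> list[SubjectMeta]:
    """Read subject metadata; one validated record per subject_id."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "subtype": str})
    _require_columns(df, COHORT_COLUMNS, path)
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise SpiralValidationError(f"duplicate subject_id {dup.iloc[0]!r}")
    records = []
    for row in df.itertuples(index=False):
        duration = None if pd.isna(row.duration) else float(row.duration)
        subtype = None if pd.isna(row.subtype) else str(row.subtype)
        records.append(SubjectMeta(
            subject_id=str(row.subject_id), group=str(row.group),
            age=float(row.age), sex=str(row.sex), handedness=str(row.handedness),
            disease_duration=duration, subtype_label=subtype,
        ).validate())
    return records


def write_cohort_meta(records: Iterable[SubjectMeta], path) -> Path:
    path = Path(path)
    rows = []
    for m in records:
        m.validate()
        rows.append({
            "subject_id": m.subject_id, "group": m.group, "age": m.age,
            "sex": m.sex, "handedness": m.handedness,
            "duration": m.disease_duration if m.disease_duration is not None else "",
            "subtype": m.subtype_label if m.subtype_label is not None else "",
        })
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)
    return path
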