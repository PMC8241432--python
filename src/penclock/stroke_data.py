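"""Data model and I/O for timestamped pen-stroke clock drawings.

A digital ballpoint pen samples its position on dot-pattern paper at a
nominal 80 Hz while a participant draws a clock.  The drawing decomposes
into *strokes* — maximal pen-down intervals — each carrying a component
label (clock face, number, hand, ...).  This module defines the in-memory
model (:class:`PenSample`, :class:`Stroke`, :class:`ClockDrawing`) and two
plain-text serializations: a flat CSV with a ``stroke_id`` column and a
nested JSON document.  No vendor binary format is supported.

Units: time in milliseconds from the first pen-down sample; coordinates in
millimeters, page convention (y increases downward).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

#: Admissible stroke component labels.  Classification of unlabeled strokes
#: is out of scope; labels are carried, never inferred.
COMPONENTS = ("clockface", "number", "hand", "other", "unlabeled")

#: Test conditions: draw a stated time from memory vs copy a model clock.
CONDITIONS = ("command", "copy")

#: Pen spatial resolution quoted by the vendor, for reference only.
PEN_RESOLUTION_MM = 0.002 * 25.4  # 0.002 inches

#: Nominal sampling rate of the digital pen.
NOMINAL_SAMPLING_HZ = 80.0

CSV_HEADER = ["participant_id", "condition", "stroke_id", "component",
              "t_ms", "x_mm", "y_mm"]


class StrokeDataError(ValueError):
    """Malformed or invariant-violating stroke data."""


class PenSample(NamedTuple):
    """One pen position sample: time (ms), x (mm), y (mm, downward)."""

    t: float
    x: float
    y: float


@dataclass
class Stroke:
    """One maximal pen-down interval.

    Parameters
    ----------
    t, x, y
        Equal-length arrays of sample times (ms) and positions (mm).
        Time must be strictly increasing; at least two samples.
    component
        One of :data:`COMPONENTS`.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    component: str = "unlabeled"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise StrokeDataError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise StrokeDataError("a stroke needs at least 2 samples")
        if self.component not in COMPONENTS:
            raise StrokeDataError(
                f"unknown component {self.component!r}; expected one of {COMPONENTS}")
        if not np.all(np.isfinite(self.t)):
            raise StrokeDataError("non-finite timestamps")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise StrokeDataError("non-finite coordinates")
        if self.t[0] < 0:
            raise StrokeDataError("negative timestamp")
        if not np.all(np.diff(self.t) > 0):
            raise StrokeDataError("timestamps within a stroke must be strictly increasing")

    @property
    def samples(self) -> list[PenSample]:
        return [PenSample(t, x, y) for t, x, y in zip(self.t, self.x, self.y)]

    @property
    def t_start(self) -> float:
        return float(self.t[0])

    @property
    def t_end(self) -> float:
        return float(self.t[-1])

    @property
    def duration(self) -> float:
        """Pen-down (ink) duration of this stroke, ms."""
        return self.t_end - self.t_start

    @property
    def length(self) -> float:
        """Polyline ink length, mm."""
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    def centroid(self) -> tuple[float, float]:
        return float(self.x.mean()), float(self.y.mean())

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ClockDrawing:
    """A full clock drawing: ordered, non-overlapping strokes.

    The time origin is the first sample of the first stroke.
    """

    participant_id: str
    condition: str
    strokes: list[Stroke] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise StrokeDataError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if len(self.strokes) < 1:
            raise StrokeDataError("a drawing needs at least one stroke")
        for prev, cur in zip(self.strokes, self.strokes[1:]):
            if cur.t_start < prev.t_end:
                raise StrokeDataError(
                    f"stroke starting at t={cur.t_start} overlaps stroke "
                    f"ending at t={prev.t_end}; strokes must be ordered and disjoint")

    @property
    def t_start(self) -> float:
        return self.strokes[0].t_start

    @property
    def t_end(self) -> float:
        return self.strokes[-1].t_end

    @property
    def duration(self) -> float:
        """Total completion time, ms."""
        return self.t_end - self.t_start

    def iter_samples(self) -> Iterator[PenSample]:
        for s in self.strokes:
            yield from s.samples

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) over all samples, mm."""
        xs = np.concatenate([s.x for s in self.strokes])
        ys = np.concatenate([s.y for s in self.strokes])
        return float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    # repr round-trips floats exactly; integers print without trailing .0 noise
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def read_drawing(path, dialect: str = "csv") -> ClockDrawing:
    """Read a clock drawing from a stroke file.

    Parameters
    ----------
    path
        File path.
    dialect
        ``"csv"`` — flat table, header
        ``participant_id,condition,stroke_id,component,t_ms,x_mm,y_mm``,
        one row per sample, samples contiguous per stroke;
        ``"json"`` — one object with ``participant_id``, ``condition`` and
        ``strokes: [{component, samples: [[t, x, y], ...]}]``.

    Raises
    ------
    StrokeDataError
        On malformed records (naming the line and field), non-monotone
        time, overlapping strokes, or an empty file.
    """
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "json":
        return _read_json(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv(path) -> ClockDrawing:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise StrokeDataError(f"{path}: empty file") from None
        if header != CSV_HEADER:
            raise StrokeDataError(
                f"{path}: line 1: bad header {header!r}, expected {CSV_HEADER}")
        pid = cond = None
        groups: list[tuple[str, str, list[tuple[float, float, float]]]] = []
        seen_ids: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_HEADER):
                raise StrokeDataError(
                    f"{path}: line {lineno}: expected {len(CSV_HEADER)} fields, got {len(row)}")
            rpid, rcond, sid, comp, t_s, x_s, y_s = row
            if pid is None:
                pid, cond = rpid, rcond
            elif (rpid, rcond) != (pid, cond):
                raise StrokeDataError(
                    f"{path}: line {lineno}: participant/condition change mid-file")
            try:
                t, x, y = float(t_s), float(x_s), float(y_s)
            except ValueError as exc:
                raise StrokeDataError(
                    f"{path}: line {lineno}: non-numeric t_ms/x_mm/y_mm: {exc}") from None
            if not groups or groups[-1][0] != sid:
                if sid in seen_ids:
                    raise StrokeDataError(
                        f"{path}: line {lineno}: stroke_id {sid!r} not contiguous")
                seen_ids.add(sid)
                groups.append((sid, comp, []))
            elif groups[-1][1] != comp:
                raise StrokeDataError(
                    f"{path}: line {lineno}: component changes within stroke {sid!r}")
            groups[-1][2].append((t, x, y))
        if pid is None:
            raise StrokeDataError(f"{path}: no sample rows")
    strokes = []
    for sid, comp, samples in groups:
        arr = np.array(samples)
        try:
            strokes.append(Stroke(arr[:, 0], arr[:, 1], arr[:, 2], component=comp))
        except StrokeDataError as exc:
            raise StrokeDataError(f"{path}: stroke {sid!r}: {exc}") from None
    return ClockDrawing(participant_id=pid, condition=cond, strokes=strokes)


def _read_json(path) -> ClockDrawing:
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise StrokeDataError(f"{path}: empty file")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise StrokeDataError(f"{path}: invalid JSON: {exc}") from None
    for key in ("participant_id", "condition", "strokes"):
        if key not in doc:
            raise StrokeDataError(f"{path}: missing field {key!r}")
    strokes = []
    for i, sd in enumerate(doc["strokes"]):
        try:
            arr = np.array(sd["samples"], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise StrokeDataError("samples must be [t, x, y] triples")
            strokes.append(Stroke(arr[:, 0], arr[:, 1], arr[:, 2],
                                  component=sd.get("component", "unlabeled")))
        except (KeyError, StrokeDataError, ValueError) as exc:
            raise StrokeDataError(f"{path}: stroke {i}: {exc}") from None
    return ClockDrawing(participant_id=str(doc["participant_id"]),
                        condition=doc["condition"], strokes=strokes)


def write_drawing(drawing: ClockDrawing, path, dialect: str = "csv") -> None:
    """Write a drawing so that ``read_drawing`` recovers it exactly.

    Floats are written with round-tripping precision; ``read ∘ write`` is
    the identity on the data model.
    """
    if not isinstance(drawing, ClockDrawing):
        raise StrokeDataError("write_drawing expects a ClockDrawing")
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(CSV_HEADER)
            for sid, stroke in enumerate(drawing.strokes):
                for t, x, y in zip(stroke.t, stroke.x, stroke.y):
                    w.writerow([drawing.participant_id, drawing.condition,
                                sid, stroke.component, _fmt(t), _fmt(x), _fmt(y)])
    elif dialect == "json":
        doc = {
            "participant_id": drawing.participant_id,
            "condition": drawing.condition,
            "strokes": [
                {"component": s.component,
                 "samples": [[t, x, y] for t, x, y in
                             zip(s.t.tolist(), s.x.tolist(), s.y.tolist())]}
                for s in drawing.strokes
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
            fh.write("\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Sampling-quality report
# ---------------------------------------------------------------------------

@dataclass
class SamplingReport:
    """Advisory sampling-quality summary (never mutates the drawing)."""

    nominal_hz: float
    n_gaps: int
    median_gap_ms: float
    outlier_fraction: float  # fraction of within-stroke gaps > 3x nominal


def validate_sampling(drawing: ClockDrawing,
                      nominal_hz: float = NOMINAL_SAMPLING_HZ) -> SamplingReport:
    """Report the median within-stroke inter-sample gap and the fraction of
    gaps exceeding three times the nominal period."""
    if nominal_hz <= 0:
        raise ValueError("nominal_hz must be positive")
    gaps = np.concatenate([np.diff(s.t) for s in drawing.strokes])
    nominal_ms = 1000.0 / nominal_hz
    return SamplingReport(
        nominal_hz=nominal_hz,
        n_gaps=len(gaps),
        median_gap_ms=float(np.median(gaps)),
        outlier_fraction=float(np.mean(gaps > 3.0 * nominal_ms)),
    )
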