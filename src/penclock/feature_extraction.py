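"""Graphomotor and temporal feature extraction from clock drawings.

Features are computed from stroke timing and geometry only, through an
extensible registry.  The default registry covers four families:

* drawing efficiency — completion time, ink vs think time, the
  "Think than Ink" percentage, stroke counts, latencies around the clock
  face and the first hand;
* simple motor — ink length, mean and peak pen speed;
* information processing speed — inter-stroke latencies;
* spatial reasoning — clock-face area/circularity/centering from a
  least-squares circle fit, number placement error, hand angle error,
  bounding-box area.

A feature that is undefined for a drawing (e.g. no hand strokes) is
recorded as missing, never silently zero.  Time features are in
milliseconds, lengths in mm, speeds in mm/s, angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .stroke_data import ClockDrawing, Stroke
from .synthetic_cohort import HOUR_HAND_TURNS, MINUTE_HAND_TURNS
from . import stats_core

__all__ = [
    "CircleFit",
    "fit_circle",
    "FeatureVector",
    "FeatureMatrix",
    "DEFAULT_REGISTRY",
    "extract_features",
    "build_feature_matrix",
    "normalize_features",
]


class GeometryError(ValueError):
    """Degenerate geometry (too few / collinear points)."""


@dataclass
class CircleFit:
    center_x: float
    center_y: float
    radius: float
    rms_residual: float


def fit_circle(points) -> CircleFit:
    """Algebraic least-squares circle (Kåsa linearization).

    Solves ``x^2 + y^2 = 2 a x + 2 b y + c`` in least squares; the centre
    is ``(a, b)`` and ``r = sqrt(c + a^2 + b^2)``.  Exact for points lying
    on a circle (including the three-point circumcircle).

    Raises
    ------
    GeometryError
        For fewer than three points or (near-)collinear configurations.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise GeometryError("fit_circle needs >= 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    # collinear points make the system rank deficient (scale-relative check)
    if rank < 3 or sv[-1] < 1e-9 * sv[0]:
        raise GeometryError("points are collinear; no circle fit")
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0:
        raise GeometryError("degenerate circle fit (non-positive radius)")
    r = math.sqrt(r2)
    resid = np.hypot(x - cx, y - cy) - r
    return CircleFit(center_x=float(cx), center_y=float(cy), radius=float(r),
                     rms_residual=float(np.sqrt(np.mean(resid ** 2))))


# ---------------------------------------------------------------------------
# Feature functions
# ---------------------------------------------------------------------------

def _strokes(drawing: ClockDrawing, component: str) -> list[Stroke]:
    return [s for s in drawing.strokes if s.component == component]


def _ink_time(d: ClockDrawing) -> float:
    return sum(s.duration for s in d.strokes)


def _gaps(d: ClockDrawing) -> list[float]:
    return [b.t_start - a.t_end for a, b in zip(d.strokes, d.strokes[1:])]


def _clockface_fit(d: ClockDrawing) -> CircleFit | None:
    faces = _strokes(d, "clockface")
    if not faces:
        return None
    pts = np.column_stack([faces[0].x, faces[0].y])
    try:
        return fit_circle(pts)
    except GeometryError:
        return None


def f_total_completion_time(d):
    return d.duration


def f_ink_time(d):
    return _ink_time(d)


def f_think_time(d):
    return d.duration - _ink_time(d)


def f_percent_think(d):
    return 100.0 * (d.duration - _ink_time(d)) / d.duration if d.duration > 0 else None


def f_stroke_count(d):
    return float(len(d.strokes))


def f_total_ink_length(d):
    return sum(s.length for s in d.strokes)


def f_mean_pen_speed(d):
    ink = _ink_time(d)
    return 1000.0 * f_total_ink_length(d) / ink if ink > 0 else None


def f_peak_pen_speed(d):
    peak = 0.0
    for s in d.strokes:
        v = 1000.0 * np.hypot(np.diff(s.x), np.diff(s.y)) / np.diff(s.t)
        peak = max(peak, float(v.max()))
    return peak


def f_mean_inter_stroke_latency(d):
    gaps = _gaps(d)
    return float(np.mean(gaps)) if gaps else None


def f_max_inter_stroke_latency(d):
    gaps = _gaps(d)
    return float(np.max(gaps)) if gaps else None


def f_pre_first_hand_latency(d):
    """Pause immediately before the first hand stroke."""
    hands = [i for i, s in enumerate(d.strokes) if s.component == "hand"]
    if not hands or hands[0] == 0:
        return None
    i = hands[0]
    return d.strokes[i].t_start - d.strokes[i - 1].t_end


def f_post_clock_face_latency(d):
    """Pause after the clock-face stroke ends, before the next stroke."""
    faces = [i for i, s in enumerate(d.strokes) if s.component == "clockface"]
    if not faces or faces[0] == len(d.strokes) - 1:
        return None
    i = faces[0]
    return d.strokes[i + 1].t_start - d.strokes[i].t_end


def f_clock_face_area(d):
    fit = _clockface_fit(d)
    return math.pi * fit.radius ** 2 if fit else None


def f_clock_face_circularity(d):
    fit = _clockface_fit(d)
    return fit.rms_residual / fit.radius if fit else None


def f_clock_face_center_offset(d):
    fit = _clockface_fit(d)
    if fit is None:
        return None
    x0, y0, x1, y1 = d.bounding_box()
    return math.hypot(fit.center_x - (x0 + x1) / 2, fit.center_y - (y0 + y1) / 2)


def f_number_count(d):
    return float(len(_strokes(d, "number")))


def f_mean_number_radial_error(d):
    fit = _clockface_fit(d)
    numbers = _strokes(d, "number")
    if fit is None or not numbers:
        return None
    errs = []
    for s in numbers:
        cx, cy = s.centroid()
        errs.append(abs(math.hypot(cx - fit.center_x, cy - fit.center_y) - fit.radius))
    return float(np.mean(errs))


def f_hand_count(d):
    return float(len(_strokes(d, "hand")))


def _hand_angle(stroke: Stroke, cx: float, cy: float) -> float:
    """Clockwise angle from 12 o'clock of the hand tip, radians in [0, 2pi)."""
    dx = stroke.x - cx
    dy = stroke.y - cy
    tip = int(np.argmax(np.hypot(dx, dy)))
    # page y is down: 12 o'clock is -y; clockwise angle = atan2(dx, -dy)
    return float(np.arctan2(dx[tip], -dy[tip]) % (2 * np.pi))


def f_hand_angle_error(d):
    """Mean absolute angular deviation (degrees) from the ten-past-eleven
    targets, hands assigned to targets to minimize total error."""
    fit = _clockface_fit(d)
    hands = _strokes(d, "hand")
    if fit is None or not hands:
        return None
    targets = [2 * math.pi * HOUR_HAND_TURNS, 2 * math.pi * MINUTE_HAND_TURNS]
    angles = [_hand_angle(s, fit.center_x, fit.center_y) for s in hands]

    def circ_diff(a, b):
        return abs((a - b + math.pi) % (2 * math.pi) - math.pi)

    if len(hands) >= 2:
        a0, a1 = angles[0], angles[1]
        direct = circ_diff(a0, targets[0]) + circ_diff(a1, targets[1])
        swapped = circ_diff(a0, targets[1]) + circ_diff(a1, targets[0])
        err = min(direct, swapped) / 2.0
    else:
        err = min(circ_diff(angles[0], t) for t in targets)
    return math.degrees(err)


def f_drawing_bounding_box_area(d):
    x0, y0, x1, y1 = d.bounding_box()
    return (x1 - x0) * (y1 - y0)


#: Default registry, in column order.  Keys are feature names; values map
#: a drawing to a float or None (missing).
DEFAULT_REGISTRY: dict[str, Callable[[ClockDrawing], float | None]] = {
    "total_completion_time": f_total_completion_time,
    "ink_time": f_ink_time,
    "think_time": f_think_time,
    "percent_think": f_percent_think,
    "stroke_count": f_stroke_count,
    "total_ink_length": f_total_ink_length,
    "mean_pen_speed": f_mean_pen_speed,
    "peak_pen_speed": f_peak_pen_speed,
    "mean_inter_stroke_latency": f_mean_inter_stroke_latency,
    "max_inter_stroke_latency": f_max_inter_stroke_latency,
    "pre_first_hand_latency": f_pre_first_hand_latency,
    "post_clock_face_latency": f_post_clock_face_latency,
    "clock_face_area": f_clock_face_area,
    "clock_face_circularity": f_clock_face_circularity,
    "clock_face_center_offset": f_clock_face_center_offset,
    "number_count": f_number_count,
    "mean_number_radial_error": f_mean_number_radial_error,
    "hand_count": f_hand_count,
    "hand_angle_error": f_hand_angle_error,
    "drawing_bounding_box_area": f_drawing_bounding_box_area,
}


@dataclass
class FeatureVector:
    participant_id: str
    condition: str
    values: dict[str, float | None] = field(default_factory=dict)


def extract_features(drawing: ClockDrawing,
                     registry: dict[str, Callable] | None = None) -> FeatureVector:
    """Compute every registered feature for one drawing."""
    if registry is None:
        registry = DEFAULT_REGISTRY
    if not registry:
        raise ValueError("feature registry is empty")
    values = {}
    for name, fn in registry.items():
        v = fn(drawing)
        values[name] = None if v is None else float(v)
    return FeatureVector(participant_id=drawing.participant_id,
                         condition=drawing.condition, values=values)


@dataclass
class FeatureMatrix:
    """Participants x features, raw and rank-INT-normalized views.

    Columns carry a ``_command`` / ``_copy`` suffix: the two test
    conditions are treated as distinct features throughout.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame | None = None


def build_feature_matrix(drawings: list[ClockDrawing],
                         registry: dict[str, Callable] | None = None) -> FeatureMatrix:
    """Row-aligned raw feature matrix, indexed by participant id.

    One drawing per (participant, condition); duplicates are an error.
    Missing feature values propagate as NaN.
    """
    if registry is None:
        registry = DEFAULT_REGISTRY
    seen = set()
    per_participant: dict[str, dict[str, float]] = {}
    conditions = []
    for d in drawings:
        key = (d.participant_id, d.condition)
        if key in seen:
            raise ValueError(f"duplicate drawing for {key}")
        seen.add(key)
        if d.condition not in conditions:
            conditions.append(d.condition)
        fv = extract_features(d, registry)
        row = per_participant.setdefault(d.participant_id, {})
        for name, v in fv.values.items():
            row[f"{name}_{d.condition}"] = np.nan if v is None else v
    columns = [f"{name}_{cond}" for cond in conditions for name in registry]
    raw = pd.DataFrame.from_dict(per_participant, orient="index")
    raw = raw.reindex(columns=columns)
    raw.index.name = "participant_id"
    return FeatureMatrix(raw=raw)


def normalize_features(raw: pd.DataFrame) -> pd.DataFrame:
    """Rank-based inverse normal transform, column-wise (the V matrix).

    Constant or nearly-empty columns are returned as all-NaN; the
    association scan excludes them with a warning.
    """
    out = {}
    for col in raw.columns:
        try:
            out[col] = stats_core.rank_inverse_normal(raw[col].to_numpy())
        except stats_core.StatsError:
            out[col] = np.full(len(raw), np.nan)
    return pd.DataFrame(out, index=raw.index)
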