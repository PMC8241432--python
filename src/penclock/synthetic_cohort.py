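"""Synthetic community-cohort generator for end-to-end testing.

Emulates a community-based aging-cohort sample: continuous age, sex, a four-level
education variable, a latent cognition score ``g``, an 18-test
neuropsychological battery whose scores load on ``g``, a low-prevalence
MCI label assigned to the lowest-``g`` tail, and parametric digital
clock drawings whose kinematics (pen speed, inter-stroke pauses, clock
face radius, tremor) depend monotonically on ``g``.

A single latent variable drives both the drawings and the test battery,
so that downstream association scans see shared cognitive variance; all
loadings are configuration, and setting every loading to zero yields an
exact global null.  Everything is deterministic under ``(config, seed)``.

The battery's default means and SDs are the whole-sample values of the
cohort the generator emulates (e.g. Logical Memory—Immediate Recall
12 (3); Trail Making B 88 (73) seconds).  Trail Making tests are
generated lognormal — positive seconds, higher = worse, right-skewed as
observed — and every other test is an integer score with higher = better.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .stroke_data import ClockDrawing, Stroke

__all__ = [
    "NP_TESTS",
    "NP_TEST_NAMES",
    "TIMED_TESTS",
    "EDUCATION_LEVELS",
    "CohortConfig",
    "ParticipantRecord",
    "generate_cohort",
    "generate_np_scores",
    "generate_drawing",
    "generate_null_features",
    "cohort_to_frame",
]

EDUCATION_LEVELS = ("no_high_school", "high_school", "some_college", "college_plus")

#: The 18-test battery: name -> (population mean, SD).  Trail Making tests
#: are in seconds (higher = worse); all others are points (higher = better).
NP_TESTS: dict[str, tuple[float, float]] = {
    "Logical Memory—Immediate Recall": (12.0, 3.0),
    "Logical Memory—Delayed Recall": (12.0, 4.0),
    "Logical Memory—Recognition": (10.0, 1.0),
    "Visual Reproduction—Immediate Recall": (8.0, 3.0),
    "Visual Reproduction—Delayed Recall": (8.0, 3.0),
    "Visual Reproduction—Recognition": (3.0, 1.0),
    "Paired Associate Learning—Immediate Recall": (15.0, 4.0),
    "Paired Associate Learning—Delayed Recall": (9.0, 1.0),
    "Paired Associate Learning—Recognition": (10.0, 2.0),
    "Digit Span—Forward": (7.0, 1.0),
    "Digit Span—Backward": (5.0, 1.0),
    "Similarities": (17.0, 3.0),
    "Boston Naming Test—30-item version": (26.0, 7.0),
    "Trail Making Test A": (32.0, 17.0),
    "Trail Making Test B": (88.0, 73.0),
    "Hooper Visual Organization Test": (25.0, 3.0),
    "Verbal Fluency": (41.0, 12.0),
    "Verbal Fluency—Animal": (19.0, 6.0),
}

NP_TEST_NAMES = tuple(NP_TESTS)

#: Positive-seconds, higher-is-worse tests.
TIMED_TESTS = ("Trail Making Test A", "Trail Making Test B")


@dataclass
class ParticipantRecord:
    participant_id: str
    age: float
    sex: str  # "female" | "male"
    education: str  # one of EDUCATION_LEVELS
    mci: int  # 0/1
    np_scores: dict[str, float | None] = field(default_factory=dict)


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    ``test_loading`` is the fraction of each test's SD explained by latent
    cognition ``g`` (signs handled per test direction); ``age_loading`` is
    the weight of standardized age in ``g = -a * z_age + sqrt(1 - a^2) * e``.
    Kinematic loadings enter through exponential links, e.g. pen speed
    ``v = base_speed * exp(speed_loading * g)``, so lower ``g`` gives a
    slower pen, longer pauses and a smaller clock face.
    """

    n_participants: int = 2062
    seed: int = 0
    # covariates
    age_mean: float = 62.0
    age_sd: float = 13.0
    pct_female: float = 0.516
    education_proportions: tuple[float, ...] = (
        229 / 2062, 386 / 2062, 551 / 2062, 896 / 2062)
    mci_prevalence: float = 36 / 2062
    # latent structure
    age_loading: float = 0.35
    test_loading: float = 0.5
    missing_rate: float = 0.01
    # drawing kinematics
    sampling_hz: float = 80.0
    base_radius_mm: float = 22.5
    radius_loading: float = 0.08
    base_speed_mm_s: float = 40.0
    speed_loading: float = 0.15
    base_pause_ms: float = 1200.0
    pause_loading: float = 0.30
    pause_jitter_sd: float = 0.15
    #: person-level kinematic idiosyncrasy, as a multiple of each loading:
    #: 1.0 makes latent cognition explain ~half the variance of each log
    #: kinematic parameter, so drawing features are informative but
    #: imperfect proxies of cognition
    kinematic_noise_scale: float = 1.0
    tremor_mm: float = 0.15
    copy_pause_scale: float = 0.6
    copy_speed_scale: float = 1.1

    def validate(self) -> None:
        bad = []
        if self.n_participants < 1:
            bad.append("n_participants")
        if not 0 < self.mci_prevalence < 1:
            bad.append("mci_prevalence")
        if not 0 <= self.pct_female <= 1:
            bad.append("pct_female")
        if (len(self.education_proportions) != len(EDUCATION_LEVELS)
                or any(p < 0 for p in self.education_proportions)
                or abs(sum(self.education_proportions) - 1.0) > 1e-6):
            bad.append("education_proportions")
        if self.age_sd <= 0:
            bad.append("age_sd")
        if not 0 <= abs(self.age_loading) <= 1:
            bad.append("age_loading")
        if not 0 <= abs(self.test_loading) < 1:
            bad.append("test_loading")
        if not 0 <= self.missing_rate < 1:
            bad.append("missing_rate")
        if self.base_radius_mm <= 0:
            bad.append("base_radius_mm")
        if self.base_speed_mm_s <= 0:
            bad.append("base_speed_mm_s")
        if self.sampling_hz <= 0:
            bad.append("sampling_hz")
        if self.base_pause_ms < 0:
            bad.append("base_pause_ms")
        if self.tremor_mm < 0:
            bad.append("tremor_mm")
        if self.kinematic_noise_scale < 0:
            bad.append("kinematic_noise_scale")
        if bad:
            raise ValueError(f"invalid CohortConfig fields: {bad}")


# ---------------------------------------------------------------------------
# Cohort and battery
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> tuple[list[ParticipantRecord], np.ndarray]:
    """Generate participants and their latent cognition scores.

    ``g = -a * z(age) + sqrt(1 - a^2) * e`` with ``e ~ N(0, 1)``, so ``g``
    is standard normal and negatively correlated with age.  MCI labels go
    to the ``round(prevalence * n)`` lowest-``g`` participants, which makes
    the MCI subgroup older and lower-scoring by construction.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xC0)))
    n = config.n_participants

    age = rng.normal(config.age_mean, config.age_sd, size=n)
    age = np.clip(age, 25.0, 100.0)
    sex = np.where(rng.random(n) < config.pct_female, "female", "male")
    edu = rng.choice(EDUCATION_LEVELS, size=n,
                     p=np.asarray(config.education_proportions)
                     / sum(config.education_proportions))

    a = config.age_loading
    z_age = (age - config.age_mean) / config.age_sd
    g = -a * z_age + np.sqrt(1.0 - a * a) * rng.normal(size=n)

    n_mci = int(round(config.mci_prevalence * n))
    mci = np.zeros(n, dtype=int)
    mci[np.argsort(g)[:n_mci]] = 1

    records = []
    for i in range(n):
        pid = f"P{i:05d}"
        scores = generate_np_scores(float(g[i]), config, rng)
        records.append(ParticipantRecord(
            participant_id=pid, age=float(age[i]), sex=str(sex[i]),
            education=str(edu[i]), mci=int(mci[i]), np_scores=scores))
    return records, g


def generate_np_scores(g: float, config: CohortConfig,
                       rng: np.random.Generator) -> dict[str, float | None]:
    """One participant's 18 test scores given latent cognition ``g``.

    Point-scored tests: ``score = mean + rho * sd * g + sqrt(1 - rho^2) * sd * eps``,
    rounded to integers and floored at zero.  Timed tests are lognormal
    with the target mean/SD and a *negative* loading on ``g`` (worse
    cognition, longer seconds).  Each score is independently missing at
    the configured rate.
    """
    rho = config.test_loading
    scores: dict[str, float | None] = {}
    for name, (mean, sd) in NP_TESTS.items():
        if rng.random() < config.missing_rate:
            scores[name] = None
            continue
        latent = -rho * g if name in TIMED_TESTS else rho * g
        zval = latent + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal()
        if name in TIMED_TESTS:
            # lognormal with mean `mean` and SD `sd` on the seconds scale
            cv2 = (sd / mean) ** 2
            sigma = np.sqrt(np.log1p(cv2))
            mu = np.log(mean) - sigma * sigma / 2.0
            scores[name] = float(np.exp(mu + sigma * zval))
        else:
            scores[name] = float(max(0.0, round(mean + sd * zval)))
    return scores


def cohort_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Tabular view: one row per participant, covariates then test scores."""
    rows = []
    for r in records:
        row = {"participant_id": r.participant_id, "age": r.age, "sex": r.sex,
               "education": r.education, "mci": r.mci}
        for name in NP_TEST_NAMES:
            v = r.np_scores.get(name)
            row[name] = np.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parametric clock drawings
# ---------------------------------------------------------------------------

#: Page position of the clock centre, mm.
CLOCK_CENTER = (60.0, 60.0)

#: Command time "ten past eleven": minute hand at the 2 o'clock position,
#: hour hand one sixth of the way from 11 toward 12.
HOUR_HAND_TURNS = (11.0 + 10.0 / 60.0) / 12.0
MINUTE_HAND_TURNS = 10.0 / 60.0
HOUR_HAND_LENGTH = 0.55   # fraction of clock-face radius
MINUTE_HAND_LENGTH = 0.85
NUMBER_RING = 0.78        # numbers sit at this fraction of the radius


def _clock_point(turns: float, radius: float) -> np.ndarray:
    """Position at `turns` of a full clockwise revolution from 12 o'clock
    (page coordinates, y down)."""
    th = 2.0 * np.pi * turns
    return np.array([CLOCK_CENTER[0] + radius * np.sin(th),
                     CLOCK_CENTER[1] - radius * np.cos(th)])


def _resample_path(points: np.ndarray, speed_mm_s: float, hz: float,
                   t0_ms: float, tremor_mm: float,
                   rng: np.random.Generator, component: str) -> Stroke:
    """Trace a polyline at constant pen speed, sampled on the pen's clock."""
    seg = np.hypot(*np.diff(points, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    length = cum[-1]
    duration_ms = length / speed_mm_s * 1000.0
    dt = 1000.0 / hz
    n = max(2, int(np.floor(duration_ms / dt)) + 1)
    t = t0_ms + np.arange(n) * dt
    d = np.minimum(np.arange(n) * dt / 1000.0 * speed_mm_s, length)
    x = np.interp(d, cum, points[:, 0])
    y = np.interp(d, cum, points[:, 1])
    if tremor_mm > 0:
        x = x + rng.normal(0.0, tremor_mm, size=n)
        y = y + rng.normal(0.0, tremor_mm, size=n)
    return Stroke(t, x, y, component=component)


def _number_glyph(turns: float, radius: float) -> np.ndarray:
    """A small chevron standing in for a numeral (timing/position only)."""
    c = _clock_point(turns, radius * NUMBER_RING)
    return c + np.array([[-1.2, 1.6], [0.0, -1.6], [1.2, 1.6]])


def generate_drawing(participant_id: str, g: float, condition: str,
                     config: CohortConfig) -> ClockDrawing:
    """Emit one parametric clock drawing for a participant.

    Strokes, in order: the clock-face circle; twelve number glyphs placed
    clockwise from 12; the hour then minute hand set to ten past eleven.
    Lower latent cognition gives a smaller radius, slower pen, longer
    inter-stroke pauses and (unchanged) tremor — hence longer completion
    time and a higher think:ink ratio.  Deterministic under
    ``(config, participant_id, condition)``.
    """
    if condition not in ("command", "copy"):
        raise ValueError(f"unknown condition {condition!r}")
    config.validate()
    gc = float(np.clip(g, -3.0, 3.0))
    # stable per-person kinematic idiosyncrasy, independent of g and shared
    # across conditions: pens differ between people far more than cognition
    # alone predicts
    trait_rng = np.random.default_rng(np.random.SeedSequence(
        (config.seed, 0xE0, zlib.crc32(participant_id.encode()))))
    k = config.kinematic_noise_scale
    eps_r, eps_v, eps_p = trait_rng.normal(size=3)
    radius = config.base_radius_mm * np.exp(
        config.radius_loading * (gc + k * eps_r))
    speed = config.base_speed_mm_s * np.exp(
        config.speed_loading * (gc + k * eps_v))
    pause = config.base_pause_ms * np.exp(
        -config.pause_loading * (gc + k * eps_p))
    if condition == "copy":
        # copying a model clock needs less recall: shorter pauses, faster pen
        pause *= config.copy_pause_scale
        speed *= config.copy_speed_scale
    if radius <= 0 or speed <= 0:
        raise ValueError("non-positive radius or pen speed")

    key = zlib.crc32(f"{participant_id}|{condition}".encode())
    ss = np.random.SeedSequence((config.seed, 0xD0, key))
    rng_pause, rng_tremor = [np.random.default_rng(s) for s in ss.spawn(2)]

    # paths: circle, 12 chevrons clockwise from 12, hour hand, minute hand
    theta = np.linspace(0.0, 2.0 * np.pi, 181)
    circle = np.column_stack([CLOCK_CENTER[0] + radius * np.sin(theta),
                              CLOCK_CENTER[1] - radius * np.cos(theta)])
    paths: list[tuple[np.ndarray, str]] = [(circle, "clockface")]
    for hour in range(12):
        paths.append((_number_glyph(hour / 12.0, radius), "number"))
    center = np.array(CLOCK_CENTER)
    paths.append((np.vstack([center, _clock_point(HOUR_HAND_TURNS,
                                                  HOUR_HAND_LENGTH * radius)]), "hand"))
    paths.append((np.vstack([center, _clock_point(MINUTE_HAND_TURNS,
                                                  MINUTE_HAND_LENGTH * radius)]), "hand"))

    # fixed-count pause jitters first, so the pause stream is identical
    # across g values at the same seed (tremor consumption varies with g)
    jitter = np.exp(rng_pause.normal(0.0, config.pause_jitter_sd, size=len(paths)))

    strokes: list[Stroke] = []
    t_cursor = 0.0
    for i, (pts, comp) in enumerate(paths):
        if i > 0:
            gap = pause * jitter[i]
            t_cursor = strokes[-1].t_end + gap
        s = _resample_path(pts, speed, config.sampling_hz, t_cursor,
                           config.tremor_mm, rng_tremor, comp)
        strokes.append(s)
    return ClockDrawing(participant_id=participant_id, condition=condition,
                        strokes=strokes)


# ---------------------------------------------------------------------------
# Feature-level null simulator
# ---------------------------------------------------------------------------

def generate_null_features(n: int, n_features: int,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Raw feature matrix with no cognitive signal.

    Columns are independent standard-lognormal draws (right-skewed, as raw
    graphomotor features are), independent of any outcome.  Used for
    type-I-error calibration of the association scan at feature counts
    beyond the drawing registry's catalog.
    """
    vals = np.exp(rng.normal(size=(n, n_features)))
    return pd.DataFrame(vals, columns=[f"f{j:03d}" for j in range(n_features)])
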