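"""Two-point recovery models for bounded cognitive test scores.

Early-phase recovery of global cognition after stroke, measured on the
Mini-Mental State Examination (MMSE, integer scores 0-30), is modeled with
two candidate laws on the day-since-onset axis ``t``:

* logarithmic:  ``f(t) = a + b * ln(t)`` — rapid early gain that plateaus;
* linear:       ``f(t) = a + b * t``.

Each patient's model is *tailored* from exactly two early assessments: the
score change between the anchors (delta MMSE) fixes the slope ``b`` and the
first anchor then fixes the intercept ``a``, so the fitted curve passes
exactly through both points.  Because ``ln`` is concave, the linear model
tailored to the same two points always forecasts above the logarithmic one
at later days — the mechanism by which linear extrapolation overestimates
recovery.

Days are counted from stroke onset and must be >= 1 (an assessment on the
day of onset is encoded as day 1); ``ln(0)`` is undefined, so the
logarithmic model has no day-0 value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Union

MMSE_MIN = 0
MMSE_MAX = 30


class ModelKind(str, Enum):
    """Functional form of a recovery curve."""

    LOGARITHMIC = "logarithmic"
    LINEAR = "linear"


class DegenerateAnchorError(ValueError):
    """Raised when the two anchor assessments fall on the same day."""


def _check_day(day: Union[int, float]) -> int:
    if isinstance(day, bool) or int(day) != day:
        raise ValueError(f"day must be an integer, got {day!r}")
    day = int(day)
    if day < 1:
        raise ValueError(f"day must be >= 1 (days since onset), got {day}")
    return day


def _check_score(score: Union[int, float]) -> int:
    if isinstance(score, bool) or int(score) != score:
        raise ValueError(f"MMSE score must be an integer, got {score!r}")
    score = int(score)
    if not MMSE_MIN <= score <= MMSE_MAX:
        raise ValueError(
            f"MMSE score must be in [{MMSE_MIN}, {MMSE_MAX}], got {score}"
        )
    return score


@dataclass(frozen=True)
class Observation:
    """A single MMSE assessment: integer day since onset (>=1), integer score 0-30."""

    day: int
    score: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "day", _check_day(self.day))
        object.__setattr__(self, "score", _check_score(self.score))


@dataclass(frozen=True)
class AssessmentSeries:
    """One patient's longitudinal observations, strictly increasing in day."""

    patient_id: str
    observations: tuple

    def __post_init__(self) -> None:
        obs = tuple(
            o if isinstance(o, Observation) else Observation(*o)
            for o in self.observations
        )
        days = [o.day for o in obs]
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise ValueError(
                f"observations for patient {self.patient_id!r} must be "
                f"strictly increasing in day, got days {days}"
            )
        object.__setattr__(self, "observations", obs)

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def days(self) -> list:
        return [o.day for o in self.observations]

    @property
    def scores(self) -> list:
        return [o.score for o in self.observations]


@dataclass(frozen=True)
class RecoveryModel:
    """A fitted recovery curve: kind plus intercept ``a`` and slope ``b``.

    ``intercept_a`` is in MMSE points; ``slope_b`` is in points per unit of
    transformed time (per ln-day for the logarithmic kind, per day for the
    linear kind).  For the logarithmic kind ``a`` equals the modeled score
    at day 1, since ``ln(1) = 0``.
    """

    kind: ModelKind
    intercept_a: float
    slope_b: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ModelKind(self.kind))
        for name in ("intercept_a", "slope_b"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            object.__setattr__(self, name, v)

    def predict(self, day: Union[int, float], clamp: bool = False) -> float:
        """Model value at ``day`` (>= 1); optionally truncated into [0, 30]."""
        return predict(self, day, clamp=clamp)

    def to_dict(self) -> dict:
        return {"kind": self.kind.value, "a": self.intercept_a, "b": self.slope_b}

    @classmethod
    def from_dict(cls, record: dict) -> "RecoveryModel":
        return cls(
            kind=ModelKind(record["kind"]),
            intercept_a=float(record["a"]),
            slope_b=float(record["b"]),
        )


def _coerce_obs(p) -> Observation:
    return p if isinstance(p, Observation) else Observation(*p)


def delta_mmse(p1, p2) -> int:
    """Score change between two anchor assessments (may be negative)."""
    p1, p2 = _coerce_obs(p1), _coerce_obs(p2)
    if p1.day >= p2.day:
        raise ValueError(
            f"anchor days must satisfy day1 < day2, got {p1.day} and {p2.day}"
        )
    return p2.score - p1.score


def fit_two_point(p1, p2, kind: ModelKind) -> RecoveryModel:
    """Tailor a recovery model exactly through two anchor assessments.

    The slope is ``delta_score / (ln(day2) - ln(day1))`` for the logarithmic
    kind and ``delta_score / (day2 - day1)`` for the linear kind; the
    intercept is solved so the model reproduces the first anchor.  The
    returned model therefore interpolates both anchors exactly.  A zero
    score change yields a flat model; a negative change yields a declining
    one (declining patients are representable, not rejected).
    """
    p1, p2 = _coerce_obs(p1), _coerce_obs(p2)
    kind = ModelKind(kind)
    if p1.day == p2.day:
        raise DegenerateAnchorError(
            f"anchor assessments share day {p1.day}; cannot identify a slope"
        )
    if p1.day > p2.day:
        raise ValueError(
            f"anchor days must satisfy day1 < day2, got {p1.day} and {p2.day}"
        )
    delta = p2.score - p1.score
    if kind is ModelKind.LOGARITHMIC:
        b = delta / (math.log(p2.day) - math.log(p1.day))
        a = p1.score - b * math.log(p1.day)
    else:
        b = delta / (p2.day - p1.day)
        a = p1.score - b * p1.day
    return RecoveryModel(kind=kind, intercept_a=a, slope_b=b)


def predict(model: RecoveryModel, day: Union[int, float], clamp: bool = False) -> float:
    """Evaluate a recovery model at a forecast day (>= 1).

    Predictions are returned as real numbers; rounding to the integer MMSE
    scale is a display concern (see :func:`round_score`).  With ``clamp``
    the value is truncated into the instrument range [0, 30] — the ceiling
    and floor are real properties of the test, not of the model.
    """
    if day < 1:
        raise ValueError(f"forecast day must be >= 1, got {day}")
    if model.kind is ModelKind.LOGARITHMIC:
        value = model.intercept_a + model.slope_b * math.log(day)
    else:
        value = model.intercept_a + model.slope_b * day
    if clamp:
        value = min(MMSE_MAX, max(MMSE_MIN, value))
    return value


def round_score(value: float) -> int:
    """Round a real-valued prediction onto the integer MMSE scale, clamped."""
    return int(min(MMSE_MAX, max(MMSE_MIN, round(value))))
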