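"""Virtual cohorts: interpatient parameter sampling and meal schedules.

Interpatient variability is emulated by drawing each model parameter
independently from a normal distribution centered on the population mean
with a standard deviation of 5% of that mean; non-positive draws are
redrawn (truncation by redraw -- at a 5% coefficient of variation the
effect is negligible but it guarantees physical parameters).

The daily meal protocol is three meals with normally distributed times
and carbohydrate amounts:

=========  ==============  ==================
meal       time (hh:mm)    carbohydrate (g)
=========  ==============  ==================
breakfast  07:30 +/- 0:30  42.00 +/- 3.50
lunch      12:30 +/- 0:30  66.00 +/- 5.50
dinner     19:30 +/- 0:30  51.00 +/- 4.25
=========  ==============  ==================

Days are drawn independently.  Carbohydrates are converted from grams
to mg here, so the patient model receives ``CH`` in its stated units.
All sampling is a pure function of the configured seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError
from .patient import PARAM_NAMES, IVPParameters, MealEvent

Seed = int | tuple[int, ...]

MG_PER_G = 1000.0


def _rng(seed: Seed, *extra: int) -> np.random.Generator:
    """Deterministic generator keyed by a seed plus integer sub-keys."""
    entropy = list(seed) if isinstance(seed, tuple) else [int(seed)]
    entropy.extend(int(k) for k in extra)
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class CohortConfig:
    """Interpatient sampling setup.

    Each parameter of each patient is drawn from
    ``Normal(mean, sd_fraction * mean)`` around ``base_means``.
    """

    n_patients: int = 20
    sd_fraction: float = 0.05
    base_means: IVPParameters = field(default_factory=IVPParameters)
    seed: Seed = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidInputError(f"n_patients must be >= 1, got {self.n_patients!r}")
        if not (0.0 <= self.sd_fraction < 1.0):
            raise InvalidInputError(
                f"sd_fraction must be in [0, 1), got {self.sd_fraction!r}")


@dataclass(frozen=True)
class MealSpec:
    """Distribution of one daily meal: time [min from midnight], carbs [g]."""

    time_mean_min: float
    time_sd_min: float
    carbs_mean_g: float
    carbs_sd_g: float

    def __post_init__(self) -> None:
        if self.time_sd_min < 0.0 or self.carbs_sd_g < 0.0:
            raise InvalidInputError("meal standard deviations must be >= 0")
        if self.carbs_mean_g <= 0.0:
            raise InvalidInputError("mean carbohydrate amount must be > 0")
        if not (0.0 <= self.time_mean_min < 1440.0):
            raise InvalidInputError("mean meal time must lie within the day")


BREAKFAST = MealSpec(450.0, 30.0, 42.0, 3.50)
LUNCH = MealSpec(750.0, 30.0, 66.0, 5.50)
DINNER = MealSpec(1170.0, 30.0, 51.0, 4.25)


@dataclass(frozen=True)
class MealScheduleConfig:
    """Meal protocol: per-meal distributions, number of days and seed."""

    meals: tuple[MealSpec, ...] = (BREAKFAST, LUNCH, DINNER)
    days: int = 7
    seed: Seed = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise InvalidInputError(f"days must be >= 1, got {self.days!r}")
        if len(self.meals) == 0:
            raise InvalidInputError("at least one meal per day is required")


def sample_patient(config: CohortConfig, patient_index: int) -> IVPParameters:
    """Draw one virtual patient's parameters.

    Deterministic given ``(config.seed, patient_index)``; independent
    truncated-normal draws per parameter (non-positive values redrawn).
    """
    if patient_index < 0:
        raise InvalidInputError(f"patient_index must be >= 0, got {patient_index!r}")
    rng = _rng(config.seed, patient_index)
    values = {}
    for name in PARAM_NAMES:
        mean = getattr(config.base_means, name)
        sd = config.sd_fraction * mean
        if sd == 0.0:
            values[name] = mean
            continue
        draw = rng.normal(mean, sd)
        while draw <= 0.0:
            draw = rng.normal(mean, sd)
        values[name] = draw
    return IVPParameters(**values)


def sample_meal_schedule(config: MealScheduleConfig) -> list[MealEvent]:
    """Draw the full meal list for one patient over ``config.days`` days.

    Per day, meal times and carbohydrate amounts are drawn independently
    from their normal distributions.  A day's times are redrawn as a
    block if they are not strictly increasing or fall outside the day;
    a carbohydrate draw is redrawn if non-positive.  Deterministic given
    the seed.
    """
    rng = _rng(config.seed)
    events: list[MealEvent] = []
    for day in range(config.days):
        while True:
            times = [rng.normal(m.time_mean_min, m.time_sd_min) for m in config.meals]
            in_day = all(0.0 <= t < 1440.0 for t in times)
            ordered = all(a < b for a, b in zip(times, times[1:]))
            if in_day and ordered:
                break
        for spec, t in zip(config.meals, times):
            carbs_g = rng.normal(spec.carbs_mean_g, spec.carbs_sd_g)
            while carbs_g <= 0.0:
                carbs_g = rng.normal(spec.carbs_mean_g, spec.carbs_sd_g)
            events.append(MealEvent(time=day * 1440.0 + t, carbs=carbs_g * MG_PER_G))
    return events


def meal_arrays(meals: Sequence[MealEvent]) -> tuple[np.ndarray, np.ndarray]:
    """Meals as time-sorted (times, carbs) arrays for the fast kernel."""
    order = sorted(range(len(meals)), key=lambda i: meals[i].time)
    times = np.array([meals[i].time for i in order], dtype=float)
    carbs = np.array([meals[i].carbs for i in order], dtype=float)
    return times, carbs
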