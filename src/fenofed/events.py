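"""Dose and meal event schedules.

An :class:`EventSchedule` lists the bolus events of one simulated occasion:
drug doses (added to the stomach drug compartment) and meals (calories added
to the stomach calorie compartment).  The meal's food type selects the
apparent-volume covariate for the occasion.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import NamedTuple

__all__ = ["FoodType", "DoseEvent", "MealEvent", "EventSchedule", "StateVector"]


class FoodType(IntEnum):
    """Meal category of an occasion (codes used in dataset files)."""

    FASTED = 0
    STANDARD = 1
    HIGH_FAT = 2


class DoseEvent(NamedTuple):
    time: float     # h
    amount: float   # mg fenofibrate


class MealEvent(NamedTuple):
    time: float       # h
    calories: float   # kcal
    food_type: FoodType


class StateVector(NamedTuple):
    """Model state: drug amounts (mg) and calories (calorie-units)."""

    x1: float  # drug in stomach
    x2: float  # drug in duodenum
    x3: float  # fenofibric acid in central compartment
    x4: float  # calories in stomach
    x5: float  # calories in duodenum


@dataclass(frozen=True)
class EventSchedule:
    """Doses and meals of one occasion, validated and time-sorted."""

    dose_events: tuple[DoseEvent, ...] = ()
    meal_events: tuple[MealEvent, ...] = ()

    def __post_init__(self) -> None:
        doses = tuple(DoseEvent(float(t), float(a)) for t, a in self.dose_events)
        meals = tuple(
            MealEvent(float(t), float(c), FoodType(ft))
            for t, c, ft in self.meal_events
        )
        for t, a in doses:
            if t < 0:
                raise ValueError("dose times must be >= 0")
            if a <= 0:
                raise ValueError("dose amounts must be > 0")
        for t, c, ft in meals:
            if t < 0:
                raise ValueError("meal times must be >= 0")
            if c < 0:
                raise ValueError("meal calories must be >= 0")
            if ft == FoodType.FASTED and c != 0:
                raise ValueError("FASTED meals must carry zero calories")
        if any(doses[i].time > doses[i + 1].time for i in range(len(doses) - 1)):
            doses = tuple(sorted(doses, key=lambda e: e.time))
        if any(meals[i].time > meals[i + 1].time for i in range(len(meals) - 1)):
            meals = tuple(sorted(meals, key=lambda e: e.time))
        object.__setattr__(self, "dose_events", doses)
        object.__setattr__(self, "meal_events", meals)

    # ------------------------------------------------------------------
    @property
    def food_type(self) -> FoodType:
        """Occasion food type: the first fed meal's type, else FASTED."""
        for ev in self.meal_events:
            if ev.food_type != FoodType.FASTED:
                return ev.food_type
        return FoodType.FASTED

    @property
    def fed(self) -> bool:
        return self.food_type != FoodType.FASTED

    def fed_meal_times(self) -> tuple[float, ...]:
        return tuple(ev.time for ev in self.meal_events
                     if ev.food_type != FoodType.FASTED)

    def total_dose(self) -> float:
        return sum(ev.amount for ev in self.dose_events)

    def total_calories(self) -> float:
        return sum(ev.calories for ev in self.meal_events)

    def event_times(self) -> tuple[float, ...]:
        return tuple(sorted({ev.time for ev in self.dose_events}
                            | {ev.time for ev in self.meal_events}))

    # convenience constructors -----------------------------------------
    @classmethod
    def single_dose(
        cls,
        dose_mg: float = 250.0,
        food_type: FoodType = FoodType.FASTED,
        calories: float = 0.0,
        dose_time: float = 0.0,
        meal_time: float = 0.0,
    ) -> "EventSchedule":
        """Single oral dose, optionally after a meal (default both at t=0)."""
        meals: tuple[MealEvent, ...] = ()
        if food_type != FoodType.FASTED:
            meals = (MealEvent(meal_time, calories, food_type),)
        return cls(
            dose_events=(DoseEvent(dose_time, dose_mg),),
            meal_events=meals,
        )

    @classmethod
    def daily(
        cls,
        n_days: int,
        dose_mg: float = 250.0,
        food_type: FoodType = FoodType.FASTED,
        calories: float = 0.0,
        interval: float = 24.0,
    ) -> "EventSchedule":
        """Once-daily dosing for ``n_days`` days, each with its meal."""
        doses = tuple(DoseEvent(k * interval, dose_mg) for k in range(n_days))
        meals: tuple[MealEvent, ...] = ()
        if food_type != FoodType.FASTED:
            meals = tuple(
                MealEvent(k * interval, calories, food_type)
                for k in range(n_days)
            )
        return cls(dose_events=doses, meal_events=meals)
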