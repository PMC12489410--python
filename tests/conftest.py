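import numpy as np
import pytest
from hypothesis import settings

from sharedplate.food_data import (FoodCompositionTable, FoodItem,
                                   NutrientProfile, RetentionFactorTable)
from sharedplate.intake_records import (EaterRoster, EatingOccasion, Household,
                                        IntakeRecordSet, Participant,
                                        RecordingDay, Serving)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rice_water_fcd():
    """Two-food table for recipe hand calculations: rice and water."""
    panel = ("energy", "thiamine")
    foods = {
        "rice": FoodItem("rice", "Rice, raw", "cereals",
                         NutrientProfile({"energy": 350.0, "thiamine": 0.4})),
        "water": FoodItem("water", "Water", "beverages",
                          NutrientProfile({"energy": 0.0, "thiamine": 0.0})),
    }
    return FoodCompositionTable(foods=foods, nutrient_panel=panel)


@pytest.fixture
def boil_retention():
    return RetentionFactorTable({("thiamine", "boiled"): 0.5})


def own_serving(pid, item="rice", grams=100.0, status="eaten_completely",
                leftover=0.0):
    return Serving(serving_type="own", item_ref=item, served_amount=grams,
                   leftover_amount=leftover, consumption_status=status,
                   eaters=EaterRoster(frozenset({pid})))


def simple_day(pid, period, day_index, n_servings=1, **serving_kw):
    """A recording day with n own-plate servings (0 = day without data)."""
    occasions = ()
    if n_servings:
        occasions = (EatingOccasion(
            f"{pid}_{period}_{day_index}",
            tuple(own_serving(pid, **serving_kw) for _ in range(n_servings))),)
    return RecordingDay(period=period, day_index=day_index, occasions=occasions)


def roster_records():
    """Six participants exercising every inclusion-rule day/period pattern.

    Returns (records, expected_included_ids).
    """
    def days(pid, v1, recall, v2, with_food=True):
        out = []
        for period, n in (("visida1", v1), ("recall", recall), ("visida2", v2)):
            for d in range(1, n + 1):
                out.append(simple_day(pid, period, d,
                                      n_servings=1 if with_food else 0))
        return tuple(out)

    households = (
        # mother 3/3/0 days -> included; her child has full day records but
        # zero servings anywhere -> excluded
        Household("H1", (
            Participant("P1", "H1", "mother", "rural", days("P1", 3, 3, 0)),
            Participant("P3", "H1", "child", "rural",
                        days("P3", 3, 3, 3, with_food=False)))),
        # only one period with 2-3 days -> excluded
        Household("H2", (
            Participant("P2", "H2", "mother", "urban", days("P2", 1, 3, 1)),)),
        # two periods with exactly 2 days -> included; child with one good
        # period only -> excluded
        Household("H3", (
            Participant("P4", "H3", "mother", "semirural", days("P4", 2, 2, 0)),
            Participant("P5", "H3", "child", "semirural", days("P5", 3, 0, 0)))),
        # all three periods complete -> included
        Household("H4", (
            Participant("P6", "H4", "mother", "rural", days("P6", 2, 3, 2)),)),
    )
    return IntakeRecordSet(households), {"P1", "P4", "P6"}
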