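import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sharedplate.food_data import ReferencePortionTable
from sharedplate.intake_records import (AnalystEstimateSet, EaterRoster,
                                        EatingOccasion, Household,
                                        IntakeRecordSet, Participant,
                                        RecipeRecord, RecordingDay, Serving)
from sharedplate.nutrient_engine import (EngineError, PortionRegistry,
                                         apportion_shared,
                                         compute_daily_intakes,
                                         consumed_amount, impute_portion,
                                         period_means, recipe_profile,
                                         reconcile_portion)
from sharedplate.synthetic_data import SimulationConfig, generate_records

from conftest import own_serving, simple_day


# ---------------------------------------------------------------------------
# reconciliation


@pytest.mark.parametrize("grams,expected", [
    ((100.0, 110.0), 105.0),          # 9.5% apart -> mean
    ((80.0, 80.0), 80.0),             # identical
    ((120.0,), 120.0),                # single estimate at face value
    ((100.0, 150.0, 120.0), 120.0),   # 40% apart -> third analyst decides
    ((100.0, 150.0), None),           # 40% apart, no reviewer -> unresolved
])
def test_reconcile_portion(grams, expected):
    est = AnalystEstimateSet(tuple((f"A{i}", g) for i, g in enumerate(grams)))
    assert reconcile_portion(est) == expected


def test_reconcile_requires_estimates():
    with pytest.raises(EngineError):
        reconcile_portion(AnalystEstimateSet(()))


def test_reconcile_near_threshold_uses_mean():
    # 22/89 ~ 24.7% relative difference: still within the 25% tolerance
    est = AnalystEstimateSet((("A1", 100.0), ("A2", 78.0)))
    assert reconcile_portion(est) == pytest.approx(89.0)


# ---------------------------------------------------------------------------
# imputation hierarchy


def make_registry():
    reg = PortionRegistry()
    for g in (150.0, 200.0, 250.0):
        reg.add("rice", "M1", "mother", False, g)
    reg.add("fish", "M2", "mother", False, 100.0)
    reg.add("fish", "M3", "mother", False, 300.0)
    reg.add("egg", "C1", "child", False, 120.0)
    return reg


def test_impute_same_participant_median():
    grams, level = impute_portion("rice", "M1", "mother", make_registry())
    assert (grams, level) == (200.0, 1)


def test_impute_same_role_median():
    grams, level = impute_portion("fish", "M9", "mother", make_registry())
    assert (grams, level) == (200.0, 2)


def test_impute_single_resolved_portion():
    grams, level = impute_portion("egg", "C1", "child", make_registry())
    assert (grams, level) == (120.0, 1)


def test_impute_reference_portion_fallback():
    fallback = ReferencePortionTable({"soup": [("bowl", 250.0)]})
    grams, level = impute_portion("soup", "M1", "mother", make_registry(),
                                  fallback)
    assert (grams, level) == (250.0, 3)


def test_impute_exhausted_names_item():
    with pytest.raises(EngineError, match="soup"):
        impute_portion("soup", "M1", "mother", make_registry())


# ---------------------------------------------------------------------------
# recipes


def boiled_rice_recipe(final_weight=None):
    return RecipeRecord("r1", "H1", (("rice", 100.0, "boiled"),
                                     ("water", 200.0, None)),
                        final_weight=final_weight)


def test_recipe_profile_hand_calculation(rice_water_fcd, boil_retention):
    prof = recipe_profile(boiled_rice_recipe(), rice_water_fcd, boil_retention)
    # totals: 350 kcal, 0.4 mg * 0.5 retention; per-100 g basis 300 g
    assert prof.get("energy") == pytest.approx(350.0 / 3.0, abs=1e-9)
    assert prof.get("thiamine") == pytest.approx(0.2 / 3.0, abs=1e-9)


def test_recipe_with_measured_final_weight(rice_water_fcd, boil_retention):
    prof = recipe_profile(boiled_rice_recipe(final_weight=250.0),
                          rice_water_fcd, boil_retention)
    assert prof.get("energy") == pytest.approx(140.0, abs=1e-9)


def test_single_ingredient_no_losses_is_identity(rice_water_fcd, boil_retention):
    recipe = RecipeRecord("r2", "H1", (("rice", 123.0, None),))
    prof = recipe_profile(recipe, rice_water_fcd, boil_retention)
    assert prof.get("energy") == pytest.approx(350.0)
    assert prof.get("thiamine") == pytest.approx(0.4)


def test_unknown_ingredient_is_an_error(rice_water_fcd, boil_retention):
    recipe = RecipeRecord("r3", "H1", (("quinoa", 50.0, None),))
    with pytest.raises(EngineError, match="quinoa"):
        recipe_profile(recipe, rice_water_fcd, boil_retention)


# ---------------------------------------------------------------------------
# leftovers and shared plates


def test_consumed_amount_cases():
    base = dict(serving_type="own", item_ref="rice",
                eaters=EaterRoster(frozenset({"M1"})))
    partial = Serving(served_amount=400.0, leftover_amount=100.0,
                      consumption_status="partial", **base)
    assert consumed_amount(partial) == 300.0
    eaten = Serving(served_amount=250.0, **base)
    assert consumed_amount(eaten) == 250.0
    refused = Serving(served_amount=250.0, leftover_amount=250.0,
                      consumption_status="not_consumed", **base)
    assert consumed_amount(refused) == 0.0


def test_shared_plate_even_split_examples():
    # one participating adult + two non-participating adults -> one third
    roster = EaterRoster(frozenset({"M1"}), n_nonparticipant_adults=2)
    assert apportion_shared(300.0, roster) == {"M1": 100.0}
    # sole eater takes everything
    assert apportion_shared(180.0, EaterRoster(frozenset({"M1"}))) == \
        {"M1": 180.0}
    # mother + child + two bystanders: even quarters, adult or child alike
    roster = EaterRoster(frozenset({"M1", "C1"}), n_nonparticipant_adults=2)
    assert apportion_shared(400.0, roster) == {"M1": 100.0, "C1": 100.0}


@given(total=st.floats(0.0, 1e6), n_participants=st.integers(1, 4),
       n_adults=st.integers(0, 6), n_children=st.integers(0, 6))
def test_shared_plate_mass_conservation(total, n_participants, n_adults,
                                        n_children):
    roster = EaterRoster(frozenset(f"P{i}" for i in range(n_participants)),
                         n_nonparticipant_adults=n_adults,
                         n_nonparticipant_children=n_children)
    shares = apportion_shared(total, roster)
    discarded = (total / roster.total_eaters) * (n_adults + n_children)
    assert sum(shares.values()) + discarded == pytest.approx(total, rel=1e-12,
                                                             abs=1e-9)


# ---------------------------------------------------------------------------
# daily intakes end to end


def two_person_household(servings_m, servings_c=(), recipes=()):
    occ_m = (EatingOccasion("om", tuple(servings_m)),) if servings_m else ()
    occ_c = (EatingOccasion("oc", tuple(servings_c)),) if servings_c else ()
    return IntakeRecordSet((Household("H1", (
        Participant("M1", "H1", "mother", "rural",
                    (RecordingDay("visida1", 1, occasions=occ_m),)),
        Participant("C1", "H1", "child", "rural",
                    (RecordingDay("visida1", 1, occasions=occ_c),)),
    ), recipes=tuple(recipes)),))


def test_daily_intake_simple_scaling(rice_water_fcd, boil_retention):
    records = two_person_household([own_serving("M1", "rice", 200.0)])
    daily = compute_daily_intakes(records, rice_water_fcd, boil_retention)
    by_pid = {(d.participant_id): d for d in daily}
    assert by_pid["M1"].nutrients["energy"] == pytest.approx(700.0)
    assert by_pid["C1"].nutrients["energy"] == 0.0  # recorded day, no intake


def test_daily_intake_with_shared_recipe(rice_water_fcd, boil_retention):
    # own 200 g of rice (700 kcal) + one third of a 300 g shared dish of a
    # 100 kcal/100 g recipe (+100 kcal)
    recipe = RecipeRecord("soup", "H1", (("rice", 100.0, None),
                                         ("water", 250.0, None)))
    shared = Serving(serving_type="shared", item_ref="soup",
                     served_amount=300.0,
                     eaters=EaterRoster(frozenset({"M1"}),
                                        n_nonparticipant_adults=2))
    records = two_person_household(
        [own_serving("M1", "rice", 200.0), shared], recipes=[recipe])
    daily = compute_daily_intakes(records, rice_water_fcd, boil_retention)
    m1 = next(d for d in daily if d.participant_id == "M1")
    assert m1.nutrients["energy"] == pytest.approx(800.0)


def test_shared_serving_credits_other_participants_day(rice_water_fcd,
                                                       boil_retention):
    shared = Serving(serving_type="shared", item_ref="rice",
                     served_amount=300.0,
                     eaters=EaterRoster(frozenset({"M1", "C1"}),
                                        n_nonparticipant_adults=1))
    records = two_person_household([shared])
    daily = compute_daily_intakes(records, rice_water_fcd, boil_retention)
    c1 = next(d for d in daily if d.participant_id == "C1")
    assert c1.nutrients["energy"] == pytest.approx(350.0)  # 100 g share


def test_empty_day_gives_zero_vector(rice_water_fcd, boil_retention):
    refused = own_serving("M1", "rice", 250.0, status="not_consumed",
                          leftover=250.0)
    records = two_person_household([refused])
    daily = compute_daily_intakes(records, rice_water_fcd, boil_retention)
    assert all(v == 0.0 for d in daily for v in d.nutrients.values())


def test_unresolved_portion_imputed_from_same_participant(rice_water_fcd,
                                                          boil_retention):
    disagreeing = Serving(
        serving_type="own", item_ref="rice",
        served_amount=AnalystEstimateSet((("A1", 100.0), ("A2", 300.0))),
        eaters=EaterRoster(frozenset({"M1"})))
    resolved = [own_serving("M1", "rice", g) for g in (150.0, 200.0, 250.0)]
    records = two_person_household(resolved + [disagreeing])
    daily = compute_daily_intakes(records, rice_water_fcd, boil_retention)
    m1 = next(d for d in daily if d.participant_id == "M1")
    # 150+200+250 resolved + 200 imputed median = 800 g of rice
    assert m1.nutrients["energy"] == pytest.approx(800.0 * 3.5)


def _scale_amount(amount, factor):
    if isinstance(amount, AnalystEstimateSet):
        return AnalystEstimateSet(
            tuple((a, g * factor) for a, g in amount.estimates),
            None if amount.resolution is None else amount.resolution * factor)
    return amount * factor


def _scale_records(records, factor):
    households = []
    for hh in records.households:
        participants = []
        for p in hh.participants:
            days = []
            for day in p.days:
                occasions = tuple(
                    dataclasses.replace(occ, servings=tuple(
                        dataclasses.replace(
                            s,
                            served_amount=_scale_amount(s.served_amount, factor),
                            leftover_amount=_scale_amount(s.leftover_amount,
                                                          factor))
                        for s in occ.servings))
                    for occ in day.occasions)
                days.append(dataclasses.replace(day, occasions=occasions))
            participants.append(dataclasses.replace(p, days=tuple(days)))
        households.append(dataclasses.replace(
            hh, participants=tuple(participants)))
    return IntakeRecordSet(tuple(households))


def test_scaling_linearity():
    sim = generate_records(SimulationConfig(n_households=4, seed=21))
    daily1 = compute_daily_intakes(sim.records, sim.fcd, sim.rf)
    daily2 = compute_daily_intakes(_scale_records(sim.records, 2.0),
                                   sim.fcd, sim.rf)
    for d1, d2 in zip(daily1, daily2):
        for n in d1.nutrients:
            assert d2.nutrients[n] == pytest.approx(2.0 * d1.nutrients[n],
                                                    rel=1e-9, abs=1e-9)


def test_serving_order_invariance():
    sim = generate_records(SimulationConfig(n_households=4, seed=22))
    reversed_records = IntakeRecordSet(tuple(
        dataclasses.replace(hh, participants=tuple(
            dataclasses.replace(p, days=tuple(
                dataclasses.replace(day, occasions=tuple(
                    dataclasses.replace(occ,
                                        servings=occ.servings[::-1])
                    for occ in day.occasions[::-1]))
                for day in p.days))
            for p in hh.participants))
        for hh in sim.records.households))
    daily1 = compute_daily_intakes(sim.records, sim.fcd, sim.rf)
    daily2 = compute_daily_intakes(reversed_records, sim.fcd, sim.rf)
    for d1, d2 in zip(daily1, daily2):
        assert d1.participant_id == d2.participant_id
        for n in d1.nutrients:
            assert d2.nutrients[n] == pytest.approx(d1.nutrients[n], rel=1e-9,
                                                    abs=1e-9)


# ---------------------------------------------------------------------------
# period means


def days_with_energy(values):
    from sharedplate.nutrient_engine import DailyIntake
    return [DailyIntake("M1", "mother", "rural", "visida1", i + 1,
                        {"energy": v}) for i, v in enumerate(values)]


@pytest.mark.parametrize("values,expected", [
    ([600.0, 900.0], 750.0),
    ([600.0, 900.0, 900.0], 800.0),
    ([700.0], 700.0),
])
def test_period_means(values, expected):
    out = period_means(days_with_energy(values))
    assert len(out) == 1
    assert out[0].nutrients["energy"] == pytest.approx(expected)
    assert out[0].n_days == len(values)
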