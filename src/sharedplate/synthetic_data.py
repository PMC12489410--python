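"""Synthetic two-method dietary studies with known ground truth.

The generator emulates the validation-study design: three sites,
mother+child households, three recording periods (image-voice record,
24-h recall, image-voice record again) of up to three nonconsecutive days
including one weekend day, shared and own-plate servings, home recipes,
analyst portion-estimate sets, household withdrawal, and a systematic
between-method bias encoded in the per-period true means.  Nutrient
values follow the variance-component model

    y_ijk = mu_period(j) + a_i + b_ij + e_ijk

with participant intercepts a_i, period-within-participant intercepts
b_ij, and day-level residuals whose SD grows with the predicted value —
the structure the weighted mixed model downstream is built to handle.

Two entry points: :func:`generate_long` emits the model's long dataset
directly (for the statistics machinery); :func:`generate_records` emits a
fully valid hierarchical record set together with analytically computed
true intakes, so the nutrient engine's output can be compared to truth
exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .food_data import (FoodCompositionTable, FoodItem, MOTHER_PANEL,
                        NutrientProfile, ReferencePortionTable,
                        RetentionFactorTable)
from .intake_records import (AnalystEstimateSet, EaterRoster, EatingOccasion,
                             Household, IntakeRecordSet, Participant, PERIODS,
                             RecipeRecord, RecordingDay, Serving, SITES)
from .nutrient_engine import recipe_profile

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated study.

    Defaults reproduce the validation study's conditions: 148 households
    across three sites, 27.7% withdrawal, 3 recording days per period,
    energy period means of (1406, 1712, 1424) kcal for mothers and
    (617, 793, 646) kcal for children (the recall period higher than both
    image-voice periods), and a residual SD that increases linearly with
    the predicted intake.
    """

    n_households: int = 148
    site_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    withdrawal_rate: float = 0.277
    days_per_period: int = 3
    nutrient_panel: tuple[str, ...] = MOTHER_PANEL
    #: nutrient -> (mu_visida1, mu_recall, mu_visida2), mother scale
    true_period_means: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"energy": (1406.0, 1712.0, 1424.0)})
    #: nutrient -> period means on the child scale (records generation)
    child_period_means: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"energy": (617.0, 793.0, 646.0)})
    sd_participant: float | Mapping[str, float] = 550.0
    sd_period_within: float | Mapping[str, float] = 250.0
    #: residual SD(pred) polynomial coefficients, low order first;
    #: length 2 = linear, length 4 = cubic
    residual_sd_coef: tuple[float, ...] = (100.0, 0.1)
    shared_plate_rate: float = 0.5
    recipe_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_households < 0:
            raise ConfigError("n_households must be >= 0")
        if abs(sum(self.site_proportions) - 1.0) > 1e-9:
            raise ConfigError("site_proportions must sum to 1")
        for name in ("withdrawal_rate", "shared_plate_rate", "recipe_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 2 <= self.days_per_period <= 3:
            raise ConfigError("days_per_period must be 2 or 3")
        if len(self.residual_sd_coef) not in (2, 4):
            raise ConfigError("residual_sd_coef must be linear (2 coefficients)"
                              " or cubic (4)")
        if self.residual_sd_coef[0] < 0:
            raise ConfigError("residual SD intercept must be >= 0")
        for nut in self.true_period_means:
            if self._sd(self.sd_participant, nut) < 0 \
                    or self._sd(self.sd_period_within, nut) < 0:
                raise ConfigError("all SDs must be >= 0")

    @staticmethod
    def _sd(value, nutrient: str) -> float:
        if isinstance(value, Mapping):
            return float(value[nutrient])
        return float(value)

    def residual_sd(self, pred: np.ndarray) -> np.ndarray:
        sd = np.zeros_like(pred, dtype=float)
        for k, c in enumerate(self.residual_sd_coef):
            sd += c * np.asarray(pred, dtype=float) ** k
        return np.maximum(sd, 0.0)


@dataclass
class LongSimulation:
    """Output of :func:`generate_long`: model-level data plus the truth."""

    day_data: pd.DataFrame       # participant_id, period, day_index, nutrient, value
    period_data: pd.DataFrame    # participant_id, period, nutrient, value
    truth: dict

    def long_for(self, nutrient: str) -> pd.DataFrame:
        """One-nutrient long dataset (participant_id, period, value)."""
        sub = self.period_data[self.period_data["nutrient"] == nutrient]
        return sub[["participant_id", "period", "value"]].reset_index(drop=True)


def generate_long(config: SimulationConfig) -> LongSimulation:
    """Draw the mixed model's long dataset directly from its parameters.

    One participant per household; withdrawn households keep only the
    first recording period.  Deterministic for a given seed.  Negative
    simulated intakes are truncated at 0 and counted; the count is in the
    truth record and a warning fires if the rate exceeds 1%.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_households
    nd = config.days_per_period
    withdrawn = rng.random(n) < config.withdrawal_rate
    pids = [f"P{i:04d}" for i in range(n)]

    day_rows = []
    n_truncated = 0
    n_values = 0
    for nutrient, mus in config.true_period_means.items():
        sp = config._sd(config.sd_participant, nutrient)
        spp = config._sd(config.sd_period_within, nutrient)
        a = rng.normal(0.0, sp, size=n)
        for j, period in enumerate(PERIODS):
            b = rng.normal(0.0, spp, size=n)
            pred = mus[j] + a + b
            sd_e = config.residual_sd(pred)
            for day in range(1, nd + 1):
                e = rng.normal(0.0, 1.0, size=n) * sd_e
                y = pred + e
                n_truncated += int(np.sum(y < 0))
                n_values += n
                y = np.maximum(y, 0.0)
                keep = (j == 0) | ~withdrawn
                for i in np.flatnonzero(keep):
                    day_rows.append((pids[i], period, day, nutrient, y[i]))

    day_df = pd.DataFrame(day_rows, columns=["participant_id", "period",
                                             "day_index", "nutrient", "value"])
    if len(day_df):
        period_df = (day_df.groupby(["participant_id", "period", "nutrient"],
                                    sort=False, as_index=False)["value"].mean())
    else:
        period_df = pd.DataFrame(columns=["participant_id", "period",
                                          "nutrient", "value"])
    if n_values and n_truncated / n_values > 0.01:
        log.warning("truncated %.2f%% of simulated values at 0; consider "
                    "revising the configuration",
                    100.0 * n_truncated / n_values)
    truth = {
        "true_period_means": {k: list(v)
                              for k, v in config.true_period_means.items()},
        "sd_participant": config.sd_participant,
        "sd_period_within": config.sd_period_within,
        "residual_sd_coef": list(config.residual_sd_coef),
        "n_participants": n,
        "n_withdrawn": int(withdrawn.sum()),
        "n_truncated": n_truncated,
        "seed": config.seed,
    }
    return LongSimulation(day_df, period_df, truth)


# ---------------------------------------------------------------------------
# Toy food data


def toy_fcd(panel: Sequence[str] = MOTHER_PANEL) -> FoodCompositionTable:
    """A small illustrative food-composition table (per-100 g values)."""
    data = {
        # id: (name, group, {nutrient: per-100 g})
        "rice_cooked": ("Rice, cooked", "cereals", {
            "energy": 130, "protein": 2.7, "fat": 0.3, "carbohydrate": 28.2,
            "fiber": 0.4, "thiamine": 0.02, "niacin": 0.4, "folate_dfe": 3,
            "calcium": 10, "phosphorus": 43, "sodium": 1, "potassium": 35,
            "iron": 0.2, "zinc": 0.5}),
        "rice_raw": ("Rice, raw", "cereals", {
            "energy": 360, "protein": 6.6, "fat": 0.6, "carbohydrate": 79,
            "fiber": 1.0, "thiamine": 0.41, "riboflavin": 0.05, "niacin": 4.3,
            "vitamin_b6": 0.3, "folate_dfe": 9, "calcium": 9,
            "phosphorus": 108, "sodium": 1, "potassium": 86, "iron": 0.8,
            "zinc": 1.2}),
        "fish_fried": ("Fish, fried", "fish", {
            "energy": 199, "protein": 22.5, "fat": 11.2, "vitamin_a_re": 20,
            "thiamine": 0.08, "riboflavin": 0.1, "niacin": 3.5,
            "vitamin_b6": 0.3, "vitamin_b12": 2.1, "calcium": 45,
            "phosphorus": 250, "sodium": 90, "potassium": 380, "iron": 0.9,
            "zinc": 0.8}),
        "fish_raw": ("Fish, raw", "fish", {
            "energy": 110, "protein": 20.0, "fat": 3.0, "vitamin_a_re": 15,
            "thiamine": 0.1, "riboflavin": 0.09, "niacin": 3.0,
            "vitamin_b6": 0.35, "vitamin_b12": 2.4, "calcium": 40,
            "phosphorus": 220, "sodium": 70, "potassium": 360, "iron": 0.8,
            "zinc": 0.7}),
        "greens_boiled": ("Leafy greens, boiled", "vegetables", {
            "energy": 25, "protein": 2.5, "fat": 0.3, "carbohydrate": 3.5,
            "fiber": 2.2, "vitamin_a_re": 280, "thiamine": 0.06,
            "riboflavin": 0.12, "niacin": 0.6, "vitamin_b6": 0.15,
            "vitamin_c": 20, "folate_dfe": 90, "calcium": 95,
            "phosphorus": 40, "sodium": 25, "potassium": 310, "iron": 1.8,
            "zinc": 0.4}),
        "greens_raw": ("Leafy greens, raw", "vegetables", {
            "energy": 28, "protein": 2.9, "fat": 0.4, "carbohydrate": 3.8,
            "fiber": 2.4, "vitamin_a_re": 320, "thiamine": 0.08,
            "riboflavin": 0.14, "niacin": 0.7, "vitamin_b6": 0.18,
            "vitamin_c": 45, "folate_dfe": 130, "calcium": 100,
            "phosphorus": 45, "sodium": 20, "potassium": 340, "iron": 2.0,
            "zinc": 0.45}),
        "egg_boiled": ("Egg, boiled", "eggs", {
            "energy": 155, "protein": 12.6, "fat": 10.6, "carbohydrate": 1.1,
            "vitamin_a_re": 150, "thiamine": 0.07, "riboflavin": 0.5,
            "niacin": 0.06, "vitamin_b6": 0.12, "vitamin_b12": 1.1,
            "folate_dfe": 44, "calcium": 50, "phosphorus": 172,
            "sodium": 124, "potassium": 126, "iron": 1.2, "zinc": 1.0}),
        "oil": ("Vegetable oil", "fats", {"energy": 884, "fat": 100}),
        "banana": ("Banana", "fruit", {
            "energy": 89, "protein": 1.1, "fat": 0.3, "carbohydrate": 22.8,
            "fiber": 2.6, "vitamin_a_re": 3, "thiamine": 0.03,
            "riboflavin": 0.07, "niacin": 0.7, "vitamin_b6": 0.37,
            "vitamin_c": 8.7, "folate_dfe": 20, "calcium": 5,
            "phosphorus": 22, "sodium": 1, "potassium": 358, "iron": 0.3,
            "zinc": 0.2}),
        "fish_sauce": ("Fish sauce", "condiments", {
            "energy": 35, "protein": 5.1, "carbohydrate": 3.6,
            "calcium": 43, "phosphorus": 7, "sodium": 7850,
            "potassium": 288, "iron": 0.8, "zinc": 0.2}),
        "water": ("Water", "beverages", {}),
        "rice_wine": ("Rice wine", "beverages", {
            "energy": 134, "carbohydrate": 5.0, "alcohol": 16.0}),
    }
    foods = {}
    for fid, (name, group, values) in data.items():
        profile = NutrientProfile({n: float(values.get(n, 0.0)) for n in panel})
        foods[fid] = FoodItem(fid, name, group, profile,
                              measures={"serving_spoon": 60.0, "bowl": 250.0})
    return FoodCompositionTable(foods=foods, nutrient_panel=tuple(panel),
                                missing_counts={})


def toy_retention() -> RetentionFactorTable:
    """Illustrative ingredient-level retention factors by cooking method."""
    return RetentionFactorTable({
        ("thiamine", "boiled"): 0.55,
        ("thiamine", "fried"): 0.80,
        ("riboflavin", "boiled"): 0.85,
        ("vitamin_c", "boiled"): 0.50,
        ("vitamin_c", "fried"): 0.75,
        ("folate_dfe", "boiled"): 0.70,
        ("vitamin_b6", "boiled"): 0.80,
    })


def toy_reference_portions() -> ReferencePortionTable:
    return ReferencePortionTable({
        "rice_cooked": [("small bowl", 150.0), ("large bowl", 300.0)],
        "fish_fried": [("piece", 80.0)],
        "greens_boiled": [("serving", 100.0)],
        "egg_boiled": [("egg", 50.0)],
        "banana": [("fruit", 100.0)],
    })


# ---------------------------------------------------------------------------
# Full record-set generation


@dataclass
class RecordsSimulation:
    records: IntakeRecordSet
    truth_daily: pd.DataFrame    # participant_id, role, period, day_index, <nutrients>
    fcd: FoodCompositionTable
    rf: RetentionFactorTable
    reference_portions: ReferencePortionTable
    truth: dict


#: foods the generator serves directly (positive energy density)
_SERVABLE = ("rice_cooked", "fish_fried", "greens_boiled", "egg_boiled",
             "banana")


def generate_records(config: SimulationConfig,
                     fcd: FoodCompositionTable | None = None,
                     rf: RetentionFactorTable | None = None) -> RecordsSimulation:
    """Generate a complete, valid record set with exact embedded truth.

    Serving amounts are constructed so that each participant-day's energy
    follows the variance-component model; the true nutrient totals are
    accumulated analytically during generation using the same leftover,
    reconciliation-mean and even-split rules the nutrient engine applies,
    so engine output can be compared to the embedded truth to float
    precision.  Withdrawn households record only the first period.
    """
    config.validate()
    if "energy" not in config.true_period_means:
        raise ConfigError("records generation needs an 'energy' entry in "
                          "true_period_means")
    rng = np.random.default_rng(config.seed)
    fcd = fcd if fcd is not None else toy_fcd(config.nutrient_panel)
    rf = rf if rf is not None else toy_retention()
    panel = fcd.nutrient_panel
    mus_mother = config.true_period_means["energy"]
    mus_child = config.child_period_means.get("energy", mus_mother)
    sp = config._sd(config.sd_participant, "energy")
    spp = config._sd(config.sd_period_within, "energy")

    households = []
    truth_rows = []
    n_truncated = 0
    n_withdrawn = 0
    analyst_seq = 0

    for h in range(config.n_households):
        hid = f"H{h:03d}"
        site = str(rng.choice(SITES, p=config.site_proportions))
        withdrawn = rng.random() < config.withdrawal_rate
        n_withdrawn += int(withdrawn)
        periods = PERIODS[:1] if withdrawn else PERIODS
        mother_id, child_id = f"{hid}M", f"{hid}C"

        recipe = RecipeRecord(
            recipe_id=f"{hid}_soup", household_id=hid,
            ingredients=(
                ("rice_raw", float(rng.uniform(150, 300)), "boiled"),
                ("fish_raw", float(rng.uniform(80, 200)), "boiled"),
                ("greens_raw", float(rng.uniform(50, 150)), "boiled"),
                ("water", float(rng.uniform(300, 600)), None),
            ),
            final_weight=None)
        recipe_prof = recipe_profile(recipe, fcd, rf)

        def profile_of(item_ref):
            return recipe_prof if item_ref == recipe.recipe_id \
                else fcd.profile(item_ref)

        # a_i for both participants, shared across periods
        a = {mother_id: rng.normal(0.0, sp), child_id: rng.normal(0.0, sp / 2.0)}
        truth: dict[tuple[str, str, int], dict[str, float]] = {}
        days_by_pid: dict[str, list[RecordingDay]] = {mother_id: [],
                                                      child_id: []}

        for period in periods:
            weekend_day = int(rng.integers(1, config.days_per_period + 1))
            b = {pid: rng.normal(0.0, spp) for pid in (mother_id, child_id)}
            for day_index in range(1, config.days_per_period + 1):
                day_servings: dict[str, list[Serving]] = {mother_id: [],
                                                          child_id: []}
                for pid, role, mus in ((mother_id, "mother", mus_mother),
                                       (child_id, "child", mus_child)):
                    truth.setdefault((pid, period, day_index),
                                     {n: 0.0 for n in panel})
                    pred = mus[PERIODS.index(period)] + a[pid] + b[pid]
                    sd_e = float(config.residual_sd(np.array([pred]))[0])
                    target = pred + rng.normal(0.0, 1.0) * sd_e
                    if target <= 0:
                        n_truncated += 1
                        target = 1.0
                    n_servings = 2 if role == "child" else 3
                    parts = rng.dirichlet(np.ones(n_servings)) * target

                    for part_energy in parts:
                        shared = (role == "mother"
                                  and rng.random() < config.shared_plate_rate)
                        if rng.random() < config.recipe_rate:
                            item_ref = recipe.recipe_id
                        else:
                            item_ref = str(rng.choice(_SERVABLE))
                        prof = profile_of(item_ref)
                        epg = prof.get("energy") / 100.0
                        consumed_own = float(part_energy) / epg

                        if shared:
                            child_in = (not withdrawn or period == "visida1") \
                                and rng.random() < 0.6
                            pid_set = {mother_id} | ({child_id} if child_in
                                                     else set())
                            roster = EaterRoster(
                                participant_ids=frozenset(pid_set),
                                n_nonparticipant_adults=int(rng.integers(1, 3)),
                                n_nonparticipant_children=int(rng.integers(0, 2)))
                            consumed_total = consumed_own * roster.total_eaters
                        else:
                            roster = EaterRoster(frozenset({pid}))
                            consumed_total = consumed_own

                        # leftover / consumption status
                        u = rng.random()
                        if u < 0.05:
                            status, served, leftover = \
                                "not_consumed", consumed_total, consumed_total
                            consumed_total = 0.0
                        elif u < 0.35:
                            frac = float(rng.uniform(0.05, 0.3))
                            served = consumed_total / (1.0 - frac)
                            leftover = served - consumed_total
                            consumed_total = served - leftover  # engine order
                            status = "partial"
                        else:
                            status, served, leftover = \
                                "eaten_completely", consumed_total, 0.0

                        # analyst-estimate pathway for the served amount
                        served_amount: float | AnalystEstimateSet = served
                        if served > 0 and rng.random() < 0.4:
                            analyst_seq += 1
                            if rng.random() < 0.8:
                                delta = float(rng.uniform(0.01, 0.12))
                                e1 = served * (1.0 + delta)
                                e2 = served * (1.0 - delta)
                                served_amount = AnalystEstimateSet(
                                    (("A1", e1), ("A2", e2)))
                                resolved = (e1 + e2) / 2.0  # engine's mean rule
                            else:
                                e1 = served * 1.4
                                e2 = served * 0.9
                                served_amount = AnalystEstimateSet(
                                    (("A1", e1), ("A2", e2), ("A3", served)))
                                resolved = served
                            # keep truth consistent with the resolved value
                            if status == "partial":
                                leftover = min(leftover, resolved)
                                consumed_total = resolved - leftover
                            elif status == "eaten_completely":
                                consumed_total = resolved
                            served = resolved

                        serving = Serving(
                            serving_type="shared" if shared else "own",
                            item_ref=item_ref, served_amount=served_amount,
                            leftover_amount=float(leftover),
                            consumption_status=status, eaters=roster)
                        day_servings[pid].append(serving)

                        if consumed_total > 0:
                            if shared:
                                share = consumed_total / roster.total_eaters
                                eaters = roster.participant_ids
                            else:
                                share, eaters = consumed_total, {pid}
                            scale = share / 100.0
                            for epid in eaters:
                                acc = truth.setdefault(
                                    (epid, period, day_index),
                                    {n: 0.0 for n in panel})
                                for n in panel:
                                    acc[n] += prof.get(n) * scale

                for pid in (mother_id, child_id):
                    servings = day_servings[pid]
                    occasions = []
                    if servings:
                        half = max(1, len(servings) // 2)
                        chunks = [servings[:half], servings[half:]]
                        occasions = [
                            EatingOccasion(f"{pid}_{period}_d{day_index}_o{k}",
                                           tuple(chunk))
                            for k, chunk in enumerate(chunks) if chunk]
                    days_by_pid[pid].append(RecordingDay(
                        period=period, day_index=day_index,
                        is_weekend=day_index == weekend_day,
                        occasions=tuple(occasions)))

        # dropped training day before the first image-voice period
        if rng.random() < 0.5 and "visida1" in periods:
            days_by_pid[mother_id].insert(0, RecordingDay(
                period="visida1", day_index=0, training=True,
                occasions=(EatingOccasion(f"{mother_id}_training", (Serving(
                    serving_type="own", item_ref="rice_cooked",
                    served_amount=200.0,
                    eaters=EaterRoster(frozenset({mother_id}))),)),)))

        households.append(Household(
            household_id=hid,
            participants=(
                Participant(mother_id, hid, "mother", site,
                            tuple(days_by_pid[mother_id])),
                Participant(child_id, hid, "child", site,
                            tuple(days_by_pid[child_id])),
            ),
            recipes=(recipe,)))

        for (pid, period, day_index), nutrients in sorted(truth.items()):
            role = "mother" if pid.endswith("M") else "child"
            truth_rows.append({"participant_id": pid, "role": role,
                               "site": site, "period": period,
                               "day_index": day_index, **nutrients})

    records = IntakeRecordSet(tuple(households))
    truth_daily = pd.DataFrame(
        truth_rows, columns=["participant_id", "role", "site", "period",
                             "day_index", *panel])
    truth = {
        "n_households": config.n_households,
        "n_withdrawn": n_withdrawn,
        "n_truncated": n_truncated,
        "seed": config.seed,
        "true_period_means": {k: list(v)
                              for k, v in config.true_period_means.items()},
        "child_period_means": {k: list(v)
                               for k, v in config.child_period_means.items()},
    }
    return RecordsSimulation(records, truth_daily, fcd, rf,
                             toy_reference_portions(), truth)
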