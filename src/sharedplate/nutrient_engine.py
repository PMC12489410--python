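"""From validated records to per-participant daily and per-period intakes.

The computation chain per serving is: resolve amounts (analyst
reconciliation, then median imputation when reconciliation fails), build
per-100 g nutrient profiles (foods directly from the composition table,
home recipes with ingredient-level retention factors), subtract leftovers,
split shared plates evenly over all eaters, and sum within each
participant-day.  Period intakes are arithmetic means over a period's
recorded days.
"""
from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .food_data import (FoodCompositionTable, NutrientProfile,
                        ReferencePortionTable, RetentionFactorTable,
                        retention_lookup)
from .intake_records import (AnalystEstimateSet, EaterRoster, IntakeRecordSet,
                             PERIODS, RecipeRecord, Serving)

log = logging.getLogger(__name__)


class EngineError(ValueError):
    """Unrecoverable problem while computing intakes (unknown item, ...)."""


@dataclass
class DailyIntake:
    """Absolute nutrient amounts consumed by one participant on one day."""

    participant_id: str
    role: str
    site: str
    period: str
    day_index: int
    nutrients: dict[str, float]


@dataclass
class PeriodIntake:
    """Mean daily nutrient intake over a recording period's recorded days."""

    participant_id: str
    role: str
    site: str
    period: str
    nutrients: dict[str, float]
    n_days: int


# ---------------------------------------------------------------------------
# Amount resolution


def reconcile_portion(est: AnalystEstimateSet,
                      threshold: float = 0.25) -> float | None:
    """Reconcile blinded analyst estimates into a single gram value.

    One estimate is taken at face value.  Two estimates agreeing within
    the relative-difference threshold (|a-b| / mean(a,b), default 25%)
    are combined by their arithmetic mean; if they disagree beyond it,
    the third (reviewing) analyst's value decides.  Disagreement with no
    third estimate returns None, which triggers imputation.
    """
    if est.resolution is not None:
        return est.resolution
    values = [g for _a, g in est.estimates]
    if not values:
        raise EngineError("estimate set with zero estimates")
    if len(values) == 1:
        return values[0]
    a, b = values[0], values[1]
    mean_ab = (a + b) / 2.0
    if abs(a - b) / mean_ab <= threshold:
        return mean_ab
    if len(values) >= 3:
        return values[2]
    return None


@dataclass
class PortionRegistry:
    """Resolved (non-imputed) portions collected for median imputation.

    Medians are taken only over directly resolved portions so imputed
    values never feed back into later imputations.
    """

    by_participant: dict[tuple[str, str], list[float]] = field(default_factory=dict)
    by_shared: dict[str, list[float]] = field(default_factory=dict)
    by_role: dict[tuple[str, str], list[float]] = field(default_factory=dict)

    def add(self, item_ref: str, participant_id: str, role: str,
            shared: bool, grams: float) -> None:
        if shared:
            self.by_shared.setdefault(item_ref, []).append(grams)
        else:
            self.by_participant.setdefault((item_ref, participant_id), []) \
                .append(grams)
        self.by_role.setdefault((item_ref, role), []).append(grams)


def impute_portion(item_ref: str, participant_id: str, role: str,
                   registry: PortionRegistry,
                   fallback: ReferencePortionTable | None = None,
                   shared: bool = False) -> tuple[float, int]:
    """Impute an unresolved portion, returning (grams, hierarchy level).

    Level 1: median of the participant's own resolved portions of the same
    item (or of the same shared-serving context for shared plates).
    Level 2: median over all resolved portions of the item from the same
    participant type (mother or child).  Level 3: the reference-portion
    default.  All three empty is an error naming the item.
    """
    pool = (registry.by_shared.get(item_ref, []) if shared
            else registry.by_participant.get((item_ref, participant_id), []))
    if pool:
        return float(statistics.median(pool)), 1
    pool = registry.by_role.get((item_ref, role), [])
    if pool:
        return float(statistics.median(pool)), 2
    if fallback is not None:
        grams = fallback.default_grams(item_ref)
        if grams is not None:
            return grams, 3
    raise EngineError(f"cannot impute a portion for item {item_ref!r}: "
                      "no resolved portions and no reference default")


# ---------------------------------------------------------------------------
# Recipes, leftovers, apportioning


def recipe_profile(recipe: RecipeRecord, fcd: FoodCompositionTable,
                   rf: RetentionFactorTable) -> NutrientProfile:
    """Per-100 g nutrient profile of a prepared recipe.

    Ingredient nutrients are scaled by grams/100 and by the cooking-method
    retention factor; the per-100 g basis is the measured final weight
    when present, else the raw ingredient mass sum.
    """
    totals = {n: 0.0 for n in fcd.nutrient_panel}
    mass = 0.0
    for food_id, grams, method in recipe.ingredients:
        if food_id not in fcd:
            raise EngineError(f"recipe {recipe.recipe_id!r}: unknown ingredient "
                              f"food_id {food_id!r}")
        profile = fcd.profile(food_id)
        for n in totals:
            totals[n] += (grams / 100.0) * profile.get(n) \
                * retention_lookup(rf, n, method)
        mass += grams
    basis = recipe.final_weight if recipe.final_weight is not None else mass
    return NutrientProfile({n: v * 100.0 / basis for n, v in totals.items()})


def consumed_amount(serving: Serving,
                    served_g: float | None = None,
                    leftover_g: float | None = None) -> float:
    """Grams actually consumed from a serving with resolved amounts.

    Resolved gram values may be passed explicitly when the serving still
    carries analyst-estimate sets.
    """
    if served_g is None:
        if not isinstance(serving.served_amount, float):
            raise EngineError("served amount not resolved to grams")
        served_g = serving.served_amount
    if serving.consumption_status == "eaten_completely":
        return served_g
    if serving.consumption_status == "not_consumed":
        return 0.0
    if leftover_g is None:
        if not isinstance(serving.leftover_amount, float):
            raise EngineError("leftover amount not resolved to grams")
        leftover_g = serving.leftover_amount
    if leftover_g > served_g:
        raise EngineError(f"leftover {leftover_g} g exceeds served {served_g} g")
    return served_g - leftover_g


def apportion_shared(consumed_total: float,
                     roster: EaterRoster) -> dict[str, float]:
    """Split a shared serving evenly over everyone who ate from it.

    Every eater — participant or not, adult or child — counts as one
    equal share; only the shares of listed study participants are
    returned, the rest is discarded.
    """
    if consumed_total < 0:
        raise EngineError("consumed total must be >= 0")
    share = consumed_total / roster.total_eaters
    return {pid: share for pid in roster.participant_ids}


# ---------------------------------------------------------------------------
# Daily and period intakes


def _resolve_amount(amount, threshold: float) -> float | None:
    if isinstance(amount, AnalystEstimateSet):
        return reconcile_portion(amount, threshold)
    return float(amount)


def compute_daily_intakes(records: IntakeRecordSet,
                          fcd: FoodCompositionTable,
                          rf: RetentionFactorTable,
                          fallback: ReferencePortionTable | None = None,
                          threshold: float = 0.25) -> list[DailyIntake]:
    """Compute absolute daily nutrient intakes for every participant-day.

    Two passes: first all directly given or reconcilable amounts are
    resolved and collected into the imputation registry; then unresolved
    amounts are imputed from medians of resolved ones.  Recipe profiles
    are built once per recipe and reused across the household's occasions.
    Training days are dropped.  Shared servings credit every listed
    participant an even share, keyed to the (period, day_index) of the day
    record the serving appears on.
    """
    panel = fcd.nutrient_panel
    participants = {p.participant_id: p for p in records.participants()}
    recipes = records.recipes()
    profile_cache: dict[str, NutrientProfile] = {}

    def item_profile(item_ref: str, path: str) -> NutrientProfile:
        if item_ref in profile_cache:
            return profile_cache[item_ref]
        if item_ref in fcd:
            prof = fcd.profile(item_ref)
        elif item_ref in recipes:
            prof = recipe_profile(recipes[item_ref], fcd, rf)
        else:
            raise EngineError(f"{path}: item_ref {item_ref!r} is neither a food "
                              "nor a household recipe")
        profile_cache[item_ref] = prof
        return prof

    # Pass 1: resolve what can be resolved, fill the imputation registry.
    registry = PortionRegistry()
    resolved: dict[int, tuple[float | None, float | None]] = {}
    servings = []
    for hh, owner, day, occ, s in records.iter_servings():
        if day.training:
            continue
        servings.append((hh, owner, day, occ, s))
        served = _resolve_amount(s.served_amount, threshold)
        leftover = _resolve_amount(s.leftover_amount, threshold)
        resolved[id(s)] = (served, leftover)
        if served is not None:
            registry.add(s.item_ref, owner.participant_id, owner.role,
                         s.serving_type == "shared", served)

    # Pass 2: impute unresolved amounts from resolved medians.
    imputed_counts = {1: 0, 2: 0, 3: 0}
    totals: dict[tuple[str, str, int], dict[str, float]] = {}
    for p in participants.values():
        for day in p.days:
            if not day.training:
                totals[(p.participant_id, day.period, day.day_index)] = \
                    {n: 0.0 for n in panel}

    for hh, owner, day, occ, s in servings:
        path = (f"{owner.participant_id}/{day.period}/day{day.day_index}/"
                f"{occ.occasion_id}/{s.item_ref}")
        served, leftover = resolved[id(s)]
        try:
            if served is None:
                served, level = impute_portion(
                    s.item_ref, owner.participant_id, owner.role, registry,
                    fallback, shared=s.serving_type == "shared")
                imputed_counts[level] += 1
            if leftover is None:
                if s.consumption_status == "not_consumed":
                    leftover = served
                else:
                    leftover, level = impute_portion(
                        s.item_ref, owner.participant_id, owner.role, registry,
                        fallback, shared=s.serving_type == "shared")
                    leftover = min(leftover, served)
                    imputed_counts[level] += 1
            consumed = consumed_amount(s, served, leftover)
            profile = item_profile(s.item_ref, path)
        except EngineError as exc:
            raise EngineError(f"{path}: {exc}") from None

        shares = (apportion_shared(consumed, s.eaters)
                  if s.serving_type == "shared"
                  else {next(iter(s.eaters.participant_ids)): consumed})
        for pid, grams in shares.items():
            if pid not in participants:
                continue
            key = (pid, day.period, day.day_index)
            if key not in totals:
                totals[key] = {n: 0.0 for n in panel}
            acc = totals[key]
            scale = grams / 100.0
            for n in panel:
                acc[n] += profile.get(n) * scale

    if any(imputed_counts.values()):
        log.info("imputed portions by hierarchy level: %s", imputed_counts)

    out = []
    for (pid, period, day_index), nutrients in sorted(totals.items()):
        p = participants[pid]
        out.append(DailyIntake(pid, p.role, p.site, period, day_index, nutrients))
    return out


def period_means(daily: Iterable[DailyIntake]) -> list[PeriodIntake]:
    """Arithmetic mean of each participant's daily intakes per period."""
    groups: dict[tuple[str, str], list[DailyIntake]] = {}
    for d in daily:
        groups.setdefault((d.participant_id, d.period), []).append(d)
    out = []
    for (pid, period), days in sorted(groups.items()):
        n = len(days)
        nutrients = {
            nut: sum(d.nutrients[nut] for d in days) / n
            for nut in days[0].nutrients
        }
        first = days[0]
        out.append(PeriodIntake(pid, first.role, first.site, period, nutrients, n))
    return out


def daily_frame(daily: Sequence[DailyIntake],
                panel: Sequence[str]) -> pd.DataFrame:
    """Tidy daily-intake table: one row per participant-day."""
    rows = [
        {"participant_id": d.participant_id, "role": d.role, "site": d.site,
         "period": d.period, "day_index": d.day_index,
         **{n: d.nutrients.get(n, 0.0) for n in panel}}
        for d in daily
    ]
    return pd.DataFrame(rows, columns=["participant_id", "role", "site",
                                       "period", "day_index", *panel])


def period_frame(periods: Sequence[PeriodIntake],
                 panel: Sequence[str]) -> pd.DataFrame:
    """Tidy per-period table: one row per participant-period."""
    rows = [
        {"participant_id": p.participant_id, "role": p.role, "site": p.site,
         "period": p.period, "n_days": p.n_days,
         **{n: p.nutrients.get(n, 0.0) for n in panel}}
        for p in periods
    ]
    return pd.DataFrame(rows, columns=["participant_id", "role", "site",
                                       "period", "n_days", *panel])
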