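"""Food-composition tables, household measures, and cooking-retention factors.

All nutrient amounts are stored per 100 g of edible portion.  Units follow
the convention of the analysis tables: energy in kcal; protein, fat,
carbohydrate, fiber and alcohol in g; vitamins and minerals in mg or µg as
configured by the nutrient panel of the run.  The panel itself is run
configuration (adult and child analyses use different panels), never
hard-coded into the computation.
"""
from __future__ import annotations

import csv
import logging
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: Default 20-nutrient panel used for adult (mother) analyses.
MOTHER_PANEL: tuple[str, ...] = (
    "energy", "protein", "fat", "carbohydrate", "fiber", "alcohol",
    "vitamin_a_re", "thiamine", "riboflavin", "niacin", "vitamin_b6",
    "vitamin_b12", "vitamin_c", "folate_dfe", "calcium", "phosphorus",
    "sodium", "potassium", "iron", "zinc",
)

#: Default 19-nutrient child panel: the adult panel without alcohol.
CHILD_PANEL: tuple[str, ...] = tuple(n for n in MOTHER_PANEL if n != "alcohol")


class FoodDataError(ValueError):
    """Invalid food-composition input (bad value, duplicate id, ...)."""


def _check_amount(value: float, context: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise FoodDataError(
            f"nutrient amount must be finite and >= 0: {context} = {value!r}"
        )
    return value


@dataclass(frozen=True)
class NutrientProfile:
    """Per-100 g nutrient amounts over a fixed nutrient panel.

    ``values`` maps nutrient name to the amount contained in 100 g of
    edible portion.  All amounts are finite and non-negative.
    """

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        clean = {}
        for name, v in self.values.items():
            clean[name] = _check_amount(v, name)
        object.__setattr__(self, "values", clean)

    def get(self, nutrient: str) -> float:
        return self.values.get(nutrient, 0.0)

    def scale(self, factor: float) -> "NutrientProfile":
        return NutrientProfile({n: v * factor for n, v in self.values.items()})

    def nutrients(self) -> tuple[str, ...]:
        return tuple(self.values)


@dataclass(frozen=True)
class FoodItem:
    """A single food with its per-100 g profile and household measures."""

    food_id: str
    name: str
    group: str
    profile: NutrientProfile
    #: household-measure label -> grams of edible portion per measure
    measures: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, grams in self.measures.items():
            if not (float(grams) > 0):
                raise FoodDataError(
                    f"measure weight must be > 0: food {self.food_id!r}, "
                    f"measure {label!r} = {grams!r}"
                )
        object.__setattr__(self, "measures", dict(self.measures))


@dataclass(frozen=True)
class RetentionFactorTable:
    """Nutrient retention factors by (nutrient, cooking method).

    Factors are the fraction of the nutrient retained after cooking,
    applied at the ingredient level; an absent pair means no loss (1.0),
    so lookup is total and never raises.
    """

    factors: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for (nutrient, method), f in self.factors.items():
            f = float(f)
            if not (0.0 <= f <= 1.0):
                raise FoodDataError(
                    f"retention factor must be in [0, 1]: "
                    f"({nutrient!r}, {method!r}) = {f!r}"
                )
            clean[(nutrient, method)] = f
        object.__setattr__(self, "factors", clean)

    def lookup(self, nutrient: str, method: str | None) -> float:
        if method is None:
            return 1.0
        return self.factors.get((nutrient, method), 1.0)


def retention_lookup(table: RetentionFactorTable, nutrient: str,
                     method: str | None) -> float:
    """Retention factor for a (nutrient, cooking-method) pair; 1.0 if absent."""
    return table.lookup(nutrient, method)


@dataclass(frozen=True)
class ReferencePortionTable:
    """Reference portions (label -> grams) per food, the last imputation level."""

    entries: Mapping[str, Sequence[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[tuple[str, float], ...]] = {}
        for food_id, portions in self.entries.items():
            labels = [lab for lab, _ in portions]
            if len(labels) != len(set(labels)):
                raise FoodDataError(f"duplicate portion labels for food {food_id!r}")
            for lab, grams in portions:
                if not (float(grams) > 0):
                    raise FoodDataError(
                        f"reference portion must be > 0: food {food_id!r}, "
                        f"label {lab!r} = {grams!r}"
                    )
            clean[food_id] = tuple((lab, float(g)) for lab, g in portions)
        object.__setattr__(self, "entries", clean)

    def default_grams(self, food_id: str) -> float | None:
        """Median reference portion for a food, or None if unknown."""
        portions = self.entries.get(food_id)
        if not portions:
            return None
        return float(statistics.median(g for _, g in portions))


@dataclass
class FoodCompositionTable:
    """A validated food-composition table over a fixed nutrient panel."""

    foods: dict[str, FoodItem]
    nutrient_panel: tuple[str, ...]
    #: per-nutrient count of foods whose value was missing and imputed as 0
    missing_counts: dict[str, int] = field(default_factory=dict)

    def __contains__(self, food_id: str) -> bool:
        return food_id in self.foods

    def __getitem__(self, food_id: str) -> FoodItem:
        return self.foods[food_id]

    def __len__(self) -> int:
        return len(self.foods)

    def profile(self, food_id: str) -> NutrientProfile:
        return self.foods[food_id].profile


_META_COLUMNS = ("food_id", "name", "group")


def load_fcd(path: str | Path, nutrient_panel: Sequence[str],
             measures_path: str | Path | None = None) -> FoodCompositionTable:
    """Load a food-composition CSV into a validated table.

    The CSV has columns ``food_id,name,group`` plus one column per nutrient.
    Foods missing a panel nutrient (absent column or empty cell) get 0 for
    it, with a warning counted per nutrient.  Duplicate ``food_id`` or a
    negative nutrient value is a hard error naming the offending row/column.
    Household measures may be supplied in a companion CSV
    ``food_id,measure_label,grams``.
    """
    panel = tuple(nutrient_panel)
    path = Path(path)
    missing_counts: dict[str, int] = {n: 0 for n in panel}
    measures: dict[str, dict[str, float]] = {}
    if measures_path is not None:
        with open(measures_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                measures.setdefault(row["food_id"], {})[row["measure_label"]] = \
                    float(row["grams"])

    foods: dict[str, FoodItem] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _META_COLUMNS:
            if col not in header:
                raise FoodDataError(f"FCD {path} is missing column {col!r}")
        for row in reader:
            food_id = row["food_id"]
            if food_id in foods:
                raise FoodDataError(f"duplicate food_id {food_id!r} in {path}")
            values = {}
            for nutrient in panel:
                raw = row.get(nutrient)
                if raw is None or raw.strip() == "":
                    values[nutrient] = 0.0
                    missing_counts[nutrient] += 1
                    continue
                v = float(raw)
                if not math.isfinite(v) or v < 0:
                    raise FoodDataError(
                        f"negative or non-finite value in {path}: food "
                        f"{food_id!r}, column {nutrient!r} = {raw!r}"
                    )
                values[nutrient] = v
            foods[food_id] = FoodItem(
                food_id=food_id,
                name=row.get("name", ""),
                group=row.get("group", ""),
                profile=NutrientProfile(values),
                measures=measures.get(food_id, {}),
            )
    for nutrient, count in missing_counts.items():
        if count:
            log.warning("FCD %s: %d foods missing %r, imputed as 0",
                        path, count, nutrient)
    return FoodCompositionTable(foods=foods, nutrient_panel=panel,
                                missing_counts=missing_counts)


def write_fcd(table: FoodCompositionTable, path: str | Path,
              measures_path: str | Path | None = None) -> None:
    """Write a table back to the CSV dialect read by :func:`load_fcd`.

    Numeric values are written with ``repr`` so a load/write cycle
    round-trips them exactly.
    """
    panel = table.nutrient_panel
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_META_COLUMNS) + list(panel))
        for food in table.foods.values():
            writer.writerow(
                [food.food_id, food.name, food.group]
                + [repr(food.profile.get(n)) for n in panel]
            )
    if measures_path is not None:
        with open(measures_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["food_id", "measure_label", "grams"])
            for food in table.foods.values():
                for label, grams in food.measures.items():
                    writer.writerow([food.food_id, label, repr(grams)])


def load_retention(path: str | Path) -> RetentionFactorTable:
    """Load a retention-factor CSV ``nutrient,cooking_method,factor``.

    A factor outside [0, 1] is rejected here, at load time, so that
    lookups never have to re-validate.
    """
    factors: dict[tuple[str, str], float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            factors[(row["nutrient"], row["cooking_method"])] = float(row["factor"])
    return RetentionFactorTable(factors)


def write_retention(table: RetentionFactorTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["nutrient", "cooking_method", "factor"])
        for (nutrient, method), f in table.factors.items():
            writer.writerow([nutrient, method, repr(f)])
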