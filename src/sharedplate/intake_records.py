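"""Hierarchical two-method dietary records and the analysis inclusion filter.

The record hierarchy is household -> participant -> recording day ->
eating occasion -> serving.  Servings are either "own plate" (one eater)
or "shared plate" (two or more eaters, participant and non-participant);
amounts may be given directly in grams or as sets of blinded analyst
estimates to be reconciled downstream.  The JSON schema accepted by
:func:`read_records` is documented in ``records.schema.json``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

PERIODS: tuple[str, ...] = ("visida1", "recall", "visida2")
ROLES: tuple[str, ...] = ("mother", "child")
SITES: tuple[str, ...] = ("rural", "semirural", "urban")
STATUSES: tuple[str, ...] = ("eaten_completely", "not_consumed", "partial")


class RecordValidationError(ValueError):
    """Schema or invariant violation, carrying the JSON path to the node."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


@dataclass(frozen=True)
class AnalystEstimateSet:
    """Independent blinded portion estimates for one amount.

    ``estimates`` holds (analyst_id, grams) in the order the estimates
    were made; an optional third estimate is the reviewing analyst's
    final decision when the first two disagree by more than the
    reconciliation threshold.  ``resolution`` caches a resolved gram
    value if one has already been decided.
    """

    estimates: tuple[tuple[str, float], ...]
    resolution: float | None = None

    def __post_init__(self) -> None:
        for analyst, grams in self.estimates:
            if not (float(grams) > 0):
                raise RecordValidationError(
                    f"estimate[{analyst}]", f"estimate grams must be > 0, got {grams!r}")


Amount = float | AnalystEstimateSet


@dataclass(frozen=True)
class EaterRoster:
    """Who ate from a serving: study participants plus bystander counts."""

    participant_ids: frozenset[str]
    n_nonparticipant_adults: int = 0
    n_nonparticipant_children: int = 0

    @property
    def total_eaters(self) -> int:
        return (len(self.participant_ids) + self.n_nonparticipant_adults
                + self.n_nonparticipant_children)

    def __post_init__(self) -> None:
        object.__setattr__(self, "participant_ids", frozenset(self.participant_ids))
        if self.n_nonparticipant_adults < 0 or self.n_nonparticipant_children < 0:
            raise RecordValidationError("eaters", "nonparticipant counts must be >= 0")
        if self.total_eaters < 1:
            raise RecordValidationError("eaters", "a serving needs at least one eater")


@dataclass(frozen=True)
class Serving:
    serving_type: str                 # "own" | "shared"
    item_ref: str                     # food_id or recipe_id
    served_amount: Amount
    eaters: EaterRoster
    leftover_amount: Amount = 0.0
    consumption_status: str = "eaten_completely"

    def __post_init__(self) -> None:
        if self.serving_type not in ("own", "shared"):
            raise RecordValidationError("serving_type",
                                        f"unknown serving type {self.serving_type!r}")
        if self.consumption_status not in STATUSES:
            raise RecordValidationError("consumption_status",
                                        f"unknown status {self.consumption_status!r}")
        if self.serving_type == "own":
            if (len(self.eaters.participant_ids) != 1
                    or self.eaters.n_nonparticipant_adults
                    or self.eaters.n_nonparticipant_children):
                raise RecordValidationError(
                    "eaters", "an own-plate serving has exactly one eater, "
                    "the participant")
        if (self.consumption_status == "eaten_completely"
                and isinstance(self.leftover_amount, float)
                and self.leftover_amount != 0.0):
            raise RecordValidationError(
                "leftover_amount", "eaten_completely implies zero leftover")
        if isinstance(self.served_amount, float) and self.served_amount < 0:
            raise RecordValidationError("served_amount", "must be >= 0")
        if (isinstance(self.served_amount, float)
                and isinstance(self.leftover_amount, float)
                and self.leftover_amount > self.served_amount):
            raise RecordValidationError(
                "leftover_amount",
                f"leftover {self.leftover_amount} g exceeds served "
                f"{self.served_amount} g")


@dataclass(frozen=True)
class EatingOccasion:
    occasion_id: str
    servings: tuple[Serving, ...]

    def __post_init__(self) -> None:
        if not self.servings:
            raise RecordValidationError(self.occasion_id,
                                        "an eating occasion has >= 1 serving")


@dataclass(frozen=True)
class RecordingDay:
    """One recorded day for one participant.

    ``day_index`` is 1..3 for analysis days; the dropped training/test day
    carries ``training=True`` and the reserved index 0.
    """

    period: str
    day_index: int
    is_weekend: bool = False
    training: bool = False
    occasions: tuple[EatingOccasion, ...] = ()

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise RecordValidationError("period", f"unknown period {self.period!r}")
        if self.training:
            if self.day_index != 0:
                raise RecordValidationError("day_index",
                                            "training day uses day_index 0")
        elif not 1 <= self.day_index <= 3:
            raise RecordValidationError("day_index",
                                        f"day_index must be 1..3, got {self.day_index}")


@dataclass(frozen=True)
class Participant:
    participant_id: str
    household_id: str
    role: str
    site: str
    days: tuple[RecordingDay, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise RecordValidationError("role", f"unknown role {self.role!r}")
        if self.site not in SITES:
            raise RecordValidationError("site", f"unknown site {self.site!r}")
        seen: set[tuple[str, int]] = set()
        for day in self.days:
            if day.training:
                continue
            key = (day.period, day.day_index)
            if key in seen:
                raise RecordValidationError(
                    "days", f"duplicate day_index {day.day_index} in period "
                    f"{day.period!r}")
            seen.add(key)


@dataclass(frozen=True)
class RecipeRecord:
    """A home recipe: raw ingredients with cooking methods.

    ``final_weight`` is the measured weight of the prepared dish when
    available; otherwise the per-100 g basis falls back to the raw
    ingredient mass sum.
    """

    recipe_id: str
    household_id: str
    ingredients: tuple[tuple[str, float, str | None], ...]  # (food_id, grams, method)
    final_weight: float | None = None

    def __post_init__(self) -> None:
        if not self.ingredients:
            raise RecordValidationError(self.recipe_id, "recipe needs >= 1 ingredient")
        for food_id, grams, _method in self.ingredients:
            if not (float(grams) > 0):
                raise RecordValidationError(
                    self.recipe_id, f"ingredient {food_id!r} grams must be > 0")
        if self.final_weight is not None and not (self.final_weight > 0):
            raise RecordValidationError(self.recipe_id, "final_weight must be > 0")


@dataclass(frozen=True)
class Household:
    household_id: str
    participants: tuple[Participant, ...]
    recipes: tuple[RecipeRecord, ...] = ()

    def __post_init__(self) -> None:
        n_mothers = sum(1 for p in self.participants if p.role == "mother")
        n_children = sum(1 for p in self.participants if p.role == "child")
        if n_mothers != 1 or n_children > 1:
            raise RecordValidationError(
                self.household_id,
                f"a household has exactly one mother and at most one child "
                f"(got {n_mothers} mothers, {n_children} children)")


@dataclass(frozen=True)
class IntakeRecordSet:
    households: tuple[Household, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for hh in self.households:
            for p in hh.participants:
                if p.participant_id in seen:
                    raise RecordValidationError(
                        p.participant_id, "duplicate participant_id in record set")
                seen.add(p.participant_id)

    def participants(self) -> Iterator[Participant]:
        for hh in self.households:
            yield from hh.participants

    def participant(self, participant_id: str) -> Participant:
        for p in self.participants():
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    def recipes(self) -> dict[str, RecipeRecord]:
        out: dict[str, RecipeRecord] = {}
        for hh in self.households:
            for r in hh.recipes:
                out[r.recipe_id] = r
        return out

    def iter_servings(self) -> Iterator[tuple[Household, Participant, RecordingDay,
                                              EatingOccasion, Serving]]:
        for hh in self.households:
            for p in hh.participants:
                for day in p.days:
                    for occ in day.occasions:
                        for s in occ.servings:
                            yield hh, p, day, occ, s


# ---------------------------------------------------------------------------
# JSON (de)serialization


def _amount_to_json(amount: Amount):
    if isinstance(amount, AnalystEstimateSet):
        return {
            "estimates": [{"analyst_id": a, "grams": g} for a, g in amount.estimates],
            "resolution": amount.resolution,
        }
    return amount


def _amount_from_json(node, path: str) -> Amount:
    if isinstance(node, (int, float)) and not isinstance(node, bool):
        return float(node)
    if isinstance(node, str):
        try:
            return float(node)  # grams stored as decimal strings round-trip
        except ValueError:
            raise RecordValidationError(path, f"bad gram amount {node!r}") from None
    if isinstance(node, dict) and "estimates" in node:
        try:
            ests = tuple((e["analyst_id"], float(e["grams"]))
                         for e in node["estimates"])
        except (KeyError, TypeError, ValueError) as exc:
            raise RecordValidationError(path, f"bad estimate set: {exc}") from None
        res = node.get("resolution")
        return AnalystEstimateSet(ests, None if res is None else float(res))
    raise RecordValidationError(path, f"amount must be grams or an estimate set, "
                                      f"got {type(node).__name__}")


def _build(cls, path: str, **kwargs):
    """Construct a record node, re-anchoring validation errors at *path*."""
    try:
        return cls(**kwargs)
    except RecordValidationError as exc:
        raise RecordValidationError(f"{path}.{exc.path}", exc.args[0].split(": ", 1)[-1]) \
            from None


def records_from_dict(doc: dict) -> IntakeRecordSet:
    if not isinstance(doc, dict) or "households" not in doc:
        raise RecordValidationError("$", "document must have a 'households' array")
    households = []
    for hi, hh in enumerate(doc["households"]):
        hpath = f"$.households[{hi}]"
        participants = []
        for pi, p in enumerate(hh.get("participants", [])):
            ppath = f"{hpath}.participants[{pi}]"
            days = []
            for di, d in enumerate(p.get("days", [])):
                dpath = f"{ppath}.days[{di}]"
                occasions = []
                for oi, o in enumerate(d.get("occasions", [])):
                    opath = f"{dpath}.occasions[{oi}]"
                    servings = []
                    for si, s in enumerate(o.get("servings", [])):
                        spath = f"{opath}.servings[{si}]"
                        eaters = s.get("eaters", {})
                        roster = _build(
                            EaterRoster, spath,
                            participant_ids=frozenset(eaters.get("participant_ids", [])),
                            n_nonparticipant_adults=int(
                                eaters.get("n_nonparticipant_adults", 0)),
                            n_nonparticipant_children=int(
                                eaters.get("n_nonparticipant_children", 0)),
                        )
                        servings.append(_build(
                            Serving, spath,
                            serving_type=s.get("serving_type", "own"),
                            item_ref=s["item_ref"],
                            served_amount=_amount_from_json(
                                s["served_amount"], f"{spath}.served_amount"),
                            leftover_amount=_amount_from_json(
                                s.get("leftover_amount", 0.0),
                                f"{spath}.leftover_amount"),
                            consumption_status=s.get("consumption_status",
                                                     "eaten_completely"),
                            eaters=roster,
                        ))
                    occasions.append(_build(
                        EatingOccasion, opath,
                        occasion_id=o.get("occasion_id", f"occ{oi}"),
                        servings=tuple(servings)))
                days.append(_build(
                    RecordingDay, dpath,
                    period=d["period"], day_index=int(d["day_index"]),
                    is_weekend=bool(d.get("is_weekend", False)),
                    training=bool(d.get("training", False)),
                    occasions=tuple(occasions)))
            participants.append(_build(
                Participant, ppath,
                participant_id=p["participant_id"],
                household_id=hh["household_id"],
                role=p["role"], site=p["site"], days=tuple(days)))
        recipes = []
        for ri, r in enumerate(hh.get("recipes", [])):
            rpath = f"{hpath}.recipes[{ri}]"
            recipes.append(_build(
                RecipeRecord, rpath,
                recipe_id=r["recipe_id"], household_id=hh["household_id"],
                ingredients=tuple((i["food_id"], float(i["grams"]),
                                   i.get("cooking_method"))
                                  for i in r["ingredients"]),
                final_weight=(None if r.get("final_weight") is None
                              else float(r["final_weight"]))))
        households.append(_build(
            Household, hpath,
            household_id=hh["household_id"],
            participants=tuple(participants), recipes=tuple(recipes)))
    return IntakeRecordSet(tuple(households))


def records_to_dict(records: IntakeRecordSet) -> dict:
    return {
        "households": [
            {
                "household_id": hh.household_id,
                "participants": [
                    {
                        "participant_id": p.participant_id,
                        "role": p.role,
                        "site": p.site,
                        "days": [
                            {
                                "period": d.period,
                                "day_index": d.day_index,
                                "is_weekend": d.is_weekend,
                                "training": d.training,
                                "occasions": [
                                    {
                                        "occasion_id": o.occasion_id,
                                        "servings": [
                                            {
                                                "serving_type": s.serving_type,
                                                "item_ref": s.item_ref,
                                                "served_amount":
                                                    _amount_to_json(s.served_amount),
                                                "leftover_amount":
                                                    _amount_to_json(s.leftover_amount),
                                                "consumption_status":
                                                    s.consumption_status,
                                                "eaters": {
                                                    "participant_ids":
                                                        sorted(s.eaters.participant_ids),
                                                    "n_nonparticipant_adults":
                                                        s.eaters.n_nonparticipant_adults,
                                                    "n_nonparticipant_children":
                                                        s.eaters.n_nonparticipant_children,
                                                },
                                            }
                                            for s in o.servings
                                        ],
                                    }
                                    for o in d.occasions
                                ],
                            }
                            for d in p.days
                        ],
                    }
                    for p in hh.participants
                ],
                "recipes": [
                    {
                        "recipe_id": r.recipe_id,
                        "ingredients": [
                            {"food_id": fid, "grams": g, "cooking_method": m}
                            for fid, g, m in r.ingredients
                        ],
                        "final_weight": r.final_weight,
                    }
                    for r in hh.recipes
                ],
            }
            for hh in records.households
        ]
    }


def read_records(path: str | Path) -> IntakeRecordSet:
    """Read and fully validate a records JSON document."""
    with open(path, encoding="utf-8") as fh:
        return records_from_dict(json.load(fh))


def write_records(records: IntakeRecordSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records_to_dict(records), fh, indent=1)


# ---------------------------------------------------------------------------
# Inclusion filter


def days_with_intake(records: IntakeRecordSet) -> dict[str, dict[str, set[int]]]:
    """Per participant and period, the analysis days with any consumed intake.

    A day counts for participant *p* when any non-training day in *p*'s
    household at that (period, day_index) contains a serving whose eater
    roster includes *p* and whose status is not ``not_consumed``.  Scanning
    at household scope matters because a child's intake may be recorded
    entirely through shared servings on the mother's day records.
    """
    out: dict[str, dict[str, set[int]]] = {
        p.participant_id: {per: set() for per in PERIODS}
        for p in records.participants()
    }
    for _hh, _owner, day, _occ, s in records.iter_servings():
        if day.training or s.consumption_status == "not_consumed":
            continue
        for pid in s.eaters.participant_ids:
            if pid in out:
                out[pid][day.period].add(day.day_index)
    return out


def inclusion_filter(records: IntakeRecordSet) -> tuple[set[str], dict[str, str]]:
    """Apply the analysis inclusion rule.

    A participant is included iff at least 2 of the 3 recording periods
    have 2 or 3 recorded days of food/beverage intake data; children with
    no intake data at all are excluded with a distinct reason.  The result
    is order-independent over participants and idempotent.
    """
    day_map = days_with_intake(records)
    included: set[str] = set()
    report: dict[str, str] = {}
    for p in records.participants():
        periods = day_map[p.participant_id]
        total_days = sum(len(v) for v in periods.values())
        good = sum(1 for v in periods.values() if len(v) in (2, 3))
        if p.role == "child" and total_days == 0:
            report[p.participant_id] = "excluded: no food or beverage intake data"
            continue
        if good >= 2:
            included.add(p.participant_id)
            report[p.participant_id] = f"included: {good} periods with 2-3 days"
        else:
            report[p.participant_id] = (
                f"excluded: only {good} period(s) with 2-3 recorded days")
    return included, report
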