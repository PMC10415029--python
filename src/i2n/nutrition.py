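"""Consumed-amount, weight, energy, and nutrient arithmetic.

The chain is: consumed amount = initial − leftover (in the initial portion's
units, routed through grams when the two portions differ); consumed weight =
amount × portion gram weight; every nutrient then scales linearly from its
per-100 g value. All amounts are exact rationals, so item, episode, and daily
totals agree exactly — floats appear only at display time.

Nutrients a source database does not state are *skipped* in totals and
reported as completeness flags; imputing zero would silently bias sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from fractions import Fraction
from typing import TYPE_CHECKING

from .errors import ResolutionError, ValidationError
from .food_db import FoodRecord, FoodRegistry, PortionOption, get_portion_options

if TYPE_CHECKING:  # pragma: no cover
    from .annotation import AEEp, DayAnnotation, FoodItemEntry

__all__ = [
    "ConsumedQuantity",
    "AEEpSummary",
    "DailySummary",
    "consumed_amount",
    "amount_to_grams",
    "energy_and_nutrients",
    "consumed_quantity",
    "summarize_aeep",
    "summarize_day",
]


@dataclass(frozen=True)
class ConsumedQuantity:
    """What one annotated food contributed, with completeness flags."""

    amount: Fraction  # in `portion` units
    portion: str
    grams: Fraction
    energy_kcal: Fraction
    nutrients: dict[str, Fraction]  # nutrient name -> amount in consumed grams
    units: dict[str, str]
    missing: frozenset[str]  # nutrients absent from the source record


@dataclass(frozen=True)
class AEEpSummary:
    meal_label: str
    start: datetime | None
    end: datetime | None
    n_foods: int
    energy_kcal: Fraction
    weight_g: Fraction
    nutrients: dict[str, Fraction]
    incomplete_nutrients: frozenset[str]


@dataclass(frozen=True)
class DailySummary:
    n_aeep: int
    n_foods: int
    weight_g: Fraction
    energy_kcal: Fraction
    nutrients: dict[str, Fraction]
    incomplete_nutrients: frozenset[str]
    db_usage: dict[str, tuple[int, float]]  # name -> (item count, percent)


def amount_to_grams(amount: Fraction | int, portion: PortionOption) -> Fraction:
    """Convert an amount in portion units to grams via the portion weight."""
    amount = Fraction(amount)
    if amount < 0:
        raise ValueError("amount must be >= 0")
    return amount * portion.gram_weight


def consumed_amount(
    initial_amount: Fraction | int,
    initial_portion: PortionOption,
    leftover_amount: Fraction | int = 0,
    leftover_portion: PortionOption | None = None,
) -> Fraction:
    """Consumed amount = initial − leftover, in the initial portion's units.

    When the leftover was recorded in a different household measure, both are
    converted to grams and the difference is expressed back in the initial
    portion's units; for same-unit records this reduces exactly to direct
    subtraction (1 cup − 1/3 cup = 2/3 cup).
    """
    initial_amount = Fraction(initial_amount)
    leftover_amount = Fraction(leftover_amount)
    if initial_amount <= 0:
        raise ValueError("initial amount must be > 0")
    if leftover_amount < 0:
        raise ValueError("leftover amount must be >= 0")
    if leftover_portion is None:
        leftover_portion = initial_portion
    initial_g = amount_to_grams(initial_amount, initial_portion)
    leftover_g = amount_to_grams(leftover_amount, leftover_portion)
    if leftover_g > initial_g:
        raise ValidationError(
            f"leftover ({float(leftover_g):g} g) exceeds initial ({float(initial_g):g} g)"
        )
    return (initial_g - leftover_g) / initial_portion.gram_weight


def energy_and_nutrients(grams: Fraction | int, record: FoodRecord) -> ConsumedQuantity:
    """Scale a record's per-100 g values to a consumed weight in grams."""
    grams = Fraction(grams)
    if grams < 0:
        raise ValueError("grams must be >= 0")
    scale = grams / 100
    nv = record.nutrients
    nutrients = {
        name: value * scale for name, value in nv.values.items() if name != "energy"
    }
    return ConsumedQuantity(
        amount=grams,
        portion="gram",
        grams=grams,
        energy_kcal=nv.energy_kcal * scale,
        nutrients=nutrients,
        units=dict(nv.units),
        missing=frozenset() if grams == 0 else nv.missing,
    )


def consumed_quantity(
    record: FoodRecord,
    initial_amount: Fraction | int,
    initial_portion_label: str,
    leftover_amount: Fraction | int = 0,
    leftover_portion_label: str | None = None,
) -> ConsumedQuantity:
    """Full chain from (initial, leftover) portions to energy and nutrients."""
    initial_portion = record.find_portion(initial_portion_label)
    leftover_portion = (
        record.find_portion(leftover_portion_label)
        if leftover_portion_label is not None
        else initial_portion
    )
    amount = consumed_amount(initial_amount, initial_portion, leftover_amount, leftover_portion)
    grams = amount_to_grams(amount, initial_portion)
    scaled = energy_and_nutrients(grams, record)
    return ConsumedQuantity(
        amount=amount,
        portion=initial_portion.label,
        grams=grams,
        energy_kcal=scaled.energy_kcal,
        nutrients=scaled.nutrients,
        units=scaled.units,
        missing=scaled.missing,
    )


def _quantity_for_entry(entry: "FoodItemEntry", registry: FoodRegistry) -> ConsumedQuantity:
    try:
        record = registry.resolve(entry.food_ref)
    except ResolutionError as exc:
        raise ResolutionError(f"food item {entry.food_ref} cannot be resolved: {exc}") from exc
    return consumed_quantity(
        record,
        entry.initial_amount,
        entry.initial_portion,
        entry.leftover_amount,
        entry.leftover_portion,
    )


def summarize_aeep(aeep: "AEEp", registry: FoodRegistry) -> AEEpSummary:
    """Sum one annotated eating episode's items (exact rational sums)."""
    energy = Fraction(0)
    weight = Fraction(0)
    nutrients: dict[str, Fraction] = {}
    incomplete: set[str] = set()
    for entry in aeep.items:
        q = _quantity_for_entry(entry, registry)
        energy += q.energy_kcal
        weight += q.grams
        for name, value in q.nutrients.items():
            nutrients[name] = nutrients.get(name, Fraction(0)) + value
        incomplete |= q.missing
    return AEEpSummary(
        meal_label=aeep.meal_label,
        start=aeep.start,
        end=aeep.end,
        n_foods=len(aeep.items),
        energy_kcal=energy,
        weight_g=weight,
        nutrients=nutrients,
        incomplete_nutrients=frozenset(incomplete),
    )


def summarize_day(day: "DayAnnotation", registry: FoodRegistry) -> DailySummary:
    """Daily totals as exact sums over the episode summaries, plus database
    usage (count and percent of annotated items drawn from each source)."""
    summaries = [summarize_aeep(aeep, registry) for aeep in day.aeeps]
    energy = sum((s.energy_kcal for s in summaries), Fraction(0))
    weight = sum((s.weight_g for s in summaries), Fraction(0))
    nutrients: dict[str, Fraction] = {}
    incomplete: set[str] = set()
    for s in summaries:
        for name, value in s.nutrients.items():
            nutrients[name] = nutrients.get(name, Fraction(0)) + value
        incomplete |= s.incomplete_nutrients

    counts: dict[str, int] = {}
    for aeep in day.aeeps:
        for entry in aeep.items:
            counts[entry.food_ref[0]] = counts.get(entry.food_ref[0], 0) + 1
    n_items = sum(counts.values())
    usage = {
        name: (c, 100.0 * c / n_items) for name, c in sorted(counts.items())
    } if n_items else {}

    return DailySummary(
        n_aeep=len(day.aeeps),
        n_foods=sum(s.n_foods for s in summaries),
        weight_g=weight,
        energy_kcal=energy,
        nutrients=nutrients,
        incomplete_nutrients=frozenset(incomplete),
        db_usage=usage,
    )
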