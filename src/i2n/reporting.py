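"""Tabular exports: item detail, episode summaries, daily summary, DB usage.

Reports render at three levels — one row per annotated food item, one per
AEEp, one per day — plus the true/false SDEEp tallies and the annotation
duration in hh:mm:ss. CSV is canonical; XLSX mirrors the same three tables
as sheets. Grams, kcal, and nutrient cells render at 2 decimals; portion
amounts at 4 significant digits.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import pandas as pd

from .amounts import format_amount
from .annotation import DayAnnotation
from .errors import EmptyReportError
from .food_db import FoodRegistry
from .nutrition import summarize_aeep, summarize_day
from .sensor_events import sdeep_status_counts

__all__ = [
    "format_duration",
    "item_table",
    "aeep_summary_table",
    "daily_summary_table",
    "export_report",
    "db_usage_report",
]


def format_duration(seconds: float) -> str:
    """Render a duration as hh:mm:ss (1093 s -> ``00:18:13``)."""
    if seconds < 0:
        raise ValueError("duration must be >= 0")
    total = int(round(seconds))
    h, rem = divmod(total, 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


def _num(x: Fraction) -> float:
    return round(float(x), 2)


def _nutrient_columns(day: DayAnnotation, registry: FoodRegistry, pinned: list[str] | None) -> list[str]:
    if pinned is not None:
        return list(pinned)
    # declaration order of the first registered database's dialect, then any extras
    seen: list[str] = []
    names = registry.list_databases()
    maps = {n: registry.database(n) for n in names}
    from .food_db import builtin_dialects

    dialects = builtin_dialects()
    for name in names:
        d = dialects.get(maps[name].dialect)
        if d is not None:
            for nut in d.nutrient_names:
                if nut not in seen:
                    seen.append(nut)
    for aeep in day.aeeps:
        for entry in aeep.items:
            if entry.consumed:
                for nut in entry.consumed.nutrients:
                    if nut not in seen:
                        seen.append(nut)
    return seen


def item_table(
    day: DayAnnotation, registry: FoodRegistry, nutrients: list[str] | None = None
) -> pd.DataFrame:
    """One row per annotated food item, with derived consumed quantities."""
    cols = _nutrient_columns(day, registry, nutrients)
    rows = []
    for aeep in day.aeeps:
        for entry in aeep.items:
            record = registry.resolve(entry.food_ref)
            from .nutrition import consumed_quantity

            q = consumed_quantity(
                record,
                entry.initial_amount,
                entry.initial_portion,
                entry.leftover_amount,
                entry.leftover_portion,
            )
            row = {
                "participant_id": day.project.participant_id,
                "day_id": day.project.day_id.isoformat(),
                "aeep_id": aeep.aeep_id,
                "meal_label": aeep.meal_label,
                "aeep_start": aeep.start.isoformat() if aeep.start else "",
                "aeep_end": aeep.end.isoformat() if aeep.end else "",
                "source_db": entry.food_ref[0],
                "food_id": entry.food_ref[1],
                "food_form": entry.form,
                "group": record.group,
                "description": record.description,
                "initial_amount": format_amount(entry.initial_amount),
                "initial_portion": entry.initial_portion,
                "leftover_amount": format_amount(entry.leftover_amount),
                "leftover_portion": entry.leftover_portion or entry.initial_portion,
                "consumed_amount": format_amount(q.amount),
                "consumed_portion": q.portion,
                "consumed_g": _num(q.grams),
                "energy_kcal": _num(q.energy_kcal),
            }
            for nut in cols:
                row[nut] = _num(q.nutrients[nut]) if nut in q.nutrients else None
            rows.append(row)
    base_cols = [
        "participant_id", "day_id", "aeep_id", "meal_label", "aeep_start", "aeep_end",
        "source_db", "food_id", "food_form", "group", "description",
        "initial_amount", "initial_portion", "leftover_amount", "leftover_portion",
        "consumed_amount", "consumed_portion", "consumed_g", "energy_kcal",
    ]
    return pd.DataFrame(rows, columns=base_cols + cols)


def aeep_summary_table(
    day: DayAnnotation, registry: FoodRegistry, nutrients: list[str] | None = None
) -> pd.DataFrame:
    """One row per AEEp: label, span, item count, energy, weight, nutrients."""
    cols = _nutrient_columns(day, registry, nutrients)
    rows = []
    for aeep in day.aeeps:
        s = summarize_aeep(aeep, registry)
        row = {
            "participant_id": day.project.participant_id,
            "day_id": day.project.day_id.isoformat(),
            "aeep_id": aeep.aeep_id,
            "meal_label": s.meal_label,
            "start": s.start.isoformat() if s.start else "",
            "end": s.end.isoformat() if s.end else "",
            "n_foods": s.n_foods,
            "energy_kcal": _num(s.energy_kcal),
            "consumed_g": _num(s.weight_g),
            "incomplete_nutrients": ";".join(sorted(s.incomplete_nutrients)),
        }
        for nut in cols:
            row[nut] = _num(s.nutrients[nut]) if nut in s.nutrients else None
        rows.append(row)
    base_cols = [
        "participant_id", "day_id", "aeep_id", "meal_label", "start", "end",
        "n_foods", "energy_kcal", "consumed_g", "incomplete_nutrients",
    ]
    return pd.DataFrame(rows, columns=base_cols + cols)


def daily_summary_table(
    day: DayAnnotation, registry: FoodRegistry, nutrients: list[str] | None = None
) -> pd.DataFrame:
    """Single-row daily summary with SDEEp tallies and annotation duration."""
    cols = _nutrient_columns(day, registry, nutrients)
    s = summarize_day(day, registry)
    tallies = sdeep_status_counts(day.sdeeps)
    duration = day.duration_seconds
    row = {
        "participant_id": day.project.participant_id,
        "day_id": day.project.day_id.isoformat(),
        "n_aeep": s.n_aeep,
        "n_foods": s.n_foods,
        "consumed_g": _num(s.weight_g),
        "energy_kcal": _num(s.energy_kcal),
        "true_sdeep": tallies["true"],
        "false_sdeep": tallies["false"],
        "unreviewed_sdeep": tallies["unreviewed"],
        "annotation_duration": format_duration(duration) if duration is not None else "",
        "incomplete_nutrients": ";".join(sorted(s.incomplete_nutrients)),
        "db_usage": ";".join(
            f"{name}:{count}({pct:.1f}%)" for name, (count, pct) in s.db_usage.items()
        ),
    }
    for nut in cols:
        row[nut] = _num(s.nutrients[nut]) if nut in s.nutrients else None
    base_cols = [
        "participant_id", "day_id", "n_aeep", "n_foods", "consumed_g", "energy_kcal",
        "true_sdeep", "false_sdeep", "unreviewed_sdeep", "annotation_duration",
        "incomplete_nutrients", "db_usage",
    ]
    return pd.DataFrame([row], columns=base_cols + cols)


def export_report(
    day: DayAnnotation,
    registry: FoodRegistry,
    out: str | Path,
    fmt: str = "csv",
    nutrients: list[str] | None = None,
) -> dict[str, Path]:
    """Write the three report tables.

    ``fmt="csv"`` writes ``items.csv``, ``aeep_summary.csv``, and
    ``daily_summary.csv`` into the directory ``out``; ``fmt="xlsx"`` writes a
    single workbook at ``out`` with one sheet per table.
    """
    tables = {
        "items": item_table(day, registry, nutrients),
        "aeep_summary": aeep_summary_table(day, registry, nutrients),
        "daily_summary": daily_summary_table(day, registry, nutrients),
    }
    out = Path(out)
    written: dict[str, Path] = {}
    if fmt == "csv":
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            target = out / f"{name}.csv"
            table.to_csv(target, index=False)
            written[name] = target
    elif fmt == "xlsx":
        out.parent.mkdir(parents=True, exist_ok=True)
        with pd.ExcelWriter(out, engine="openpyxl") as writer:
            for name, table in tables.items():
                table.to_excel(writer, sheet_name=name, index=False)
                written[name] = out
    else:
        raise ValueError(f"format must be csv or xlsx, got {fmt!r}")
    return written


def db_usage_report(days: list[DayAnnotation]) -> pd.DataFrame:
    """Database-use frequency over one or more annotated days.

    Counts every annotated food item by source database; percent is
    100·count/total. Raises :class:`EmptyReportError` when no day has any
    annotated item.
    """
    counts: dict[str, int] = {}
    for day in days:
        for aeep in day.aeeps:
            for entry in aeep.items:
                counts[entry.food_ref[0]] = counts.get(entry.food_ref[0], 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise EmptyReportError("no annotated food items to report on")
    rows = [
        {"database": name, "items": c, "percent": 100.0 * c / total}
        for name, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["database", "items", "percent"])
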