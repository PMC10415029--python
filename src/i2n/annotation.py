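"""Annotator-created eating episodes (AEEps) and their food items.

A day's annotation holds the reviewed sensor-detected episodes (with their
true/false verdicts) and the episodes the annotator actually records: each
AEEp carries a meal label, a time span, the image ids that document it, and
the food items identified in those images. Time spans may be set explicitly
or auto-populated from the linked images' timestamps. The whole annotation
persists as versioned JSON and reloads field-for-field identical, with all
amounts kept as exact fractions.

Headless use replaces the interactive review loop with an *annotation
script*: a JSON document of SDEEp verdicts and AEEp/item commands applied in
one batch (see :func:`apply_annotation_script`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from fractions import Fraction
from pathlib import Path
from typing import NamedTuple

from .amounts import parse_amount
from .errors import DataFormatError, ValidationError
from .food_db import FoodRecord, FoodRegistry
from .nutrition import ConsumedQuantity, consumed_quantity
from .sensor_events import (
    ImageRecord,
    Project,
    SDEEp,
    episodes_from_labels,
    mark_sdeep,
)

__all__ = [
    "FOOD_FORMS",
    "SCHEMA_VERSION",
    "AnnotationWarning",
    "FoodItemEntry",
    "AEEp",
    "DayAnnotation",
    "TimeLookup",
    "create_aeep",
    "link_image",
    "lookup_by_time",
    "add_food_item",
    "save_annotation",
    "load_annotation",
    "apply_annotation_script",
]

FOOD_FORMS = ("solid", "liquid", "semi-solid")
SCHEMA_VERSION = 1


class AnnotationWarning(UserWarning):
    """Non-fatal annotation oddity (overlapping AEEps, shared images)."""


@dataclass
class FoodItemEntry:
    """One annotated food: database reference, portions, derived quantities."""

    food_ref: tuple[str, str]  # (source_db, food_id)
    form: str
    initial_amount: Fraction
    initial_portion: str
    leftover_amount: Fraction = Fraction(0)
    leftover_portion: str | None = None
    consumed: ConsumedQuantity | None = None

    def __post_init__(self) -> None:
        if self.form not in FOOD_FORMS:
            raise ValidationError(f"food form must be one of {FOOD_FORMS}, got {self.form!r}")
        if self.initial_amount <= 0:
            raise ValidationError("initial amount must be > 0")
        if self.leftover_amount < 0:
            raise ValidationError("leftover amount must be >= 0")


@dataclass
class AEEp:
    """An annotator-created eating episode."""

    aeep_id: int
    meal_label: str
    start: datetime | None = None
    end: datetime | None = None
    linked_image_ids: set[str] = field(default_factory=set)
    items: list[FoodItemEntry] = field(default_factory=list)
    start_explicit: bool = False
    end_explicit: bool = False

    def contains(self, t: datetime) -> bool:
        return self.start is not None and self.end is not None and self.start <= t < self.end


@dataclass
class DayAnnotation:
    """One participant-day's full annotation state."""

    project: Project
    sdeeps: list[SDEEp] = field(default_factory=list)
    aeeps: list[AEEp] = field(default_factory=list)
    annotation_started: datetime | None = None
    annotation_finished: datetime | None = None

    @property
    def duration_seconds(self) -> float | None:
        if self.annotation_started is None or self.annotation_finished is None:
            return None
        return (self.annotation_finished - self.annotation_started).total_seconds()

    def image(self, image_id: str) -> ImageRecord:
        for im in self.project.images:
            if im.image_id == image_id:
                return im
        raise ValueError(f"image {image_id!r} is not in this project")


def create_aeep(
    day: DayAnnotation,
    meal_label: str,
    start: datetime | None = None,
    end: datetime | None = None,
) -> AEEp:
    """Append a new AEEp; omitted times stay unset until images are linked.

    Meal labels are free text; breakfast/lunch/dinner/snack are the common
    cases, not an enumeration.
    """
    if start is not None and end is not None and start > end:
        raise ValueError("AEEp start after end")
    aeep = AEEp(
        aeep_id=1 + max((a.aeep_id for a in day.aeeps), default=0),
        meal_label=meal_label,
        start=start,
        end=end,
        start_explicit=start is not None,
        end_explicit=end is not None,
    )
    day.aeeps.append(aeep)
    _warn_on_overlap(day, aeep)
    return aeep


def _warn_on_overlap(day: DayAnnotation, aeep: AEEp) -> None:
    if aeep.start is None or aeep.end is None:
        return
    for other in day.aeeps:
        if other is aeep or other.start is None or other.end is None:
            continue
        if aeep.start < other.end and other.start < aeep.end:
            warnings.warn(
                f"AEEp {aeep.aeep_id} overlaps AEEp {other.aeep_id} in time",
                AnnotationWarning,
                stacklevel=3,
            )


def link_image(day: DayAnnotation, aeep: AEEp, image: ImageRecord | str) -> AEEp:
    """Associate a project image with an AEEp (set semantics).

    Unset start/end auto-populate from the linked images: start is the
    earliest linked timestamp, end the latest plus the capture interval, so a
    single linked image yields an episode one interval long. Re-linking the
    same image set is idempotent.
    """
    image_id = image if isinstance(image, str) else image.image_id
    img = day.image(image_id)  # raises ValueError for foreign images
    for other in day.aeeps:
        if other is not aeep and image_id in other.linked_image_ids:
            warnings.warn(
                f"image {image_id!r} is already linked to AEEp {other.aeep_id}",
                AnnotationWarning,
                stacklevel=2,
            )
    aeep.linked_image_ids.add(img.image_id)
    _autopopulate_times(day, aeep)
    _warn_on_overlap(day, aeep)
    return aeep


def _autopopulate_times(day: DayAnnotation, aeep: AEEp) -> None:
    stamps = [day.image(i).timestamp for i in aeep.linked_image_ids]
    if not stamps:
        return
    if not aeep.start_explicit:
        aeep.start = min(stamps)
    if not aeep.end_explicit:
        aeep.end = max(stamps) + timedelta(seconds=day.project.capture_interval)


class TimeLookup(NamedTuple):
    image: ImageRecord | None
    sdeep: SDEEp | None
    aeeps: list[AEEp]


def lookup_by_time(day: DayAnnotation, t: datetime) -> TimeLookup:
    """The time link: resolve an instant to the image captured at or before
    it, the SDEEp containing it (if any), and every AEEp containing it."""
    project = day.project
    if t < project.start or t > project.end:
        raise ValueError(f"instant {t.isoformat()} is outside this day")
    image = None
    for im in project.images:
        if im.timestamp <= t:
            image = im
        else:
            break
    sdeep = next((ep for ep in day.sdeeps if ep.contains(t)), None)
    aeeps = [a for a in day.aeeps if a.contains(t)]
    return TimeLookup(image=image, sdeep=sdeep, aeeps=aeeps)


def add_food_item(
    aeep: AEEp,
    record: FoodRecord,
    form: str,
    initial_amount: object,
    initial_portion: str,
    leftover_amount: object = 0,
    leftover_portion: str | None = None,
) -> FoodItemEntry:
    """Attach a food item; amounts accept decimals and fractions ("1/3").

    An omitted leftover means everything served was consumed. The consumed
    amount, grams, energy, and nutrients are derived immediately and stored
    on the entry.
    """
    initial = parse_amount(initial_amount)
    leftover = parse_amount(leftover_amount) if leftover_amount is not None else Fraction(0)
    quantity = consumed_quantity(record, initial, initial_portion, leftover, leftover_portion)
    entry = FoodItemEntry(
        food_ref=record.ref,
        form=form,
        initial_amount=initial,
        initial_portion=record.find_portion(initial_portion).label,
        leftover_amount=leftover,
        leftover_portion=(
            record.find_portion(leftover_portion).label if leftover_portion is not None else None
        ),
        consumed=quantity,
    )
    aeep.items.append(entry)
    return entry


# ---------------------------------------------------------------------------
# persistence


def _frac(x: Fraction) -> str:
    return str(x)


def _quantity_to_doc(q: ConsumedQuantity) -> dict:
    return {
        "amount": _frac(q.amount),
        "portion": q.portion,
        "grams": _frac(q.grams),
        "energy_kcal": _frac(q.energy_kcal),
        "nutrients": {k: _frac(v) for k, v in q.nutrients.items()},
        "units": dict(q.units),
        "missing": sorted(q.missing),
    }


def _quantity_from_doc(doc: dict) -> ConsumedQuantity:
    return ConsumedQuantity(
        amount=Fraction(doc["amount"]),
        portion=doc["portion"],
        grams=Fraction(doc["grams"]),
        energy_kcal=Fraction(doc["energy_kcal"]),
        nutrients={k: Fraction(v) for k, v in doc["nutrients"].items()},
        units=dict(doc["units"]),
        missing=frozenset(doc["missing"]),
    )


def save_annotation(day: DayAnnotation, path: str | Path) -> None:
    """Persist a day's annotation as versioned JSON (exact round-trip)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "project": json.loads(_project_json(day.project)),
        "annotation_started": _iso_or_none(day.annotation_started),
        "annotation_finished": _iso_or_none(day.annotation_finished),
        "sdeeps": [
            {
                "episode_id": ep.episode_id,
                "start": ep.start.isoformat(),
                "end": ep.end.isoformat(),
                "status": ep.status,
            }
            for ep in day.sdeeps
        ],
        "aeeps": [
            {
                "aeep_id": a.aeep_id,
                "meal_label": a.meal_label,
                "start": _iso_or_none(a.start),
                "end": _iso_or_none(a.end),
                "start_explicit": a.start_explicit,
                "end_explicit": a.end_explicit,
                "linked_image_ids": sorted(a.linked_image_ids),
                "items": [
                    {
                        "source_db": e.food_ref[0],
                        "food_id": e.food_ref[1],
                        "form": e.form,
                        "initial_amount": _frac(e.initial_amount),
                        "initial_portion": e.initial_portion,
                        "leftover_amount": _frac(e.leftover_amount),
                        "leftover_portion": e.leftover_portion,
                        "consumed": _quantity_to_doc(e.consumed) if e.consumed else None,
                    }
                    for e in a.items
                ],
            }
            for a in day.aeeps
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def _project_json(project: Project) -> str:
    # same schema as the standalone project file, embedded for self-containment
    doc = {
        "participant_id": project.participant_id,
        "day_id": project.day_id.isoformat(),
        "capture_interval_s": project.capture_interval,
        "images": [
            {
                "image_id": im.image_id,
                "timestamp": im.timestamp.isoformat(),
                "label": im.intake_label,
                **({"path": im.path} if im.path is not None else {}),
            }
            for im in project.images
        ],
    }
    return json.dumps(doc)


def _iso_or_none(t: datetime | None) -> str | None:
    return t.isoformat() if t is not None else None


def _dt_or_none(s: str | None) -> datetime | None:
    return datetime.fromisoformat(s) if s is not None else None


def load_annotation(path: str | Path) -> DayAnnotation:
    """Reload a saved annotation; schema-version mismatch is a format error."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"annotation file {path} is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema_version") != SCHEMA_VERSION:
        raise DataFormatError(
            f"annotation file {path} has schema version {doc.get('schema_version')!r}, "
            f"expected {SCHEMA_VERSION}"
        )
    try:
        p = doc["project"]
        project = Project(
            participant_id=str(p["participant_id"]),
            day_id=date.fromisoformat(p["day_id"]),
            capture_interval=float(p["capture_interval_s"]),
            images=[
                ImageRecord(
                    image_id=str(e["image_id"]),
                    timestamp=datetime.fromisoformat(e["timestamp"]),
                    intake_label=int(e["label"]),
                    path=e.get("path"),
                )
                for e in p["images"]
            ],
        )
        sdeeps = [
            SDEEp(
                episode_id=int(e["episode_id"]),
                start=datetime.fromisoformat(e["start"]),
                end=datetime.fromisoformat(e["end"]),
                status=e["status"],
            )
            for e in doc["sdeeps"]
        ]
        aeeps = []
        for a in doc["aeeps"]:
            aeeps.append(
                AEEp(
                    aeep_id=int(a["aeep_id"]),
                    meal_label=a["meal_label"],
                    start=_dt_or_none(a["start"]),
                    end=_dt_or_none(a["end"]),
                    start_explicit=bool(a["start_explicit"]),
                    end_explicit=bool(a["end_explicit"]),
                    linked_image_ids=set(a["linked_image_ids"]),
                    items=[
                        FoodItemEntry(
                            food_ref=(e["source_db"], e["food_id"]),
                            form=e["form"],
                            initial_amount=Fraction(e["initial_amount"]),
                            initial_portion=e["initial_portion"],
                            leftover_amount=Fraction(e["leftover_amount"]),
                            leftover_portion=e["leftover_portion"],
                            consumed=_quantity_from_doc(e["consumed"]) if e["consumed"] else None,
                        )
                        for e in a["items"]
                    ],
                )
            )
        return DayAnnotation(
            project=project,
            sdeeps=sdeeps,
            aeeps=aeeps,
            annotation_started=_dt_or_none(doc["annotation_started"]),
            annotation_finished=_dt_or_none(doc["annotation_finished"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise DataFormatError(f"annotation file {path} malformed: {exc}") from exc


# ---------------------------------------------------------------------------
# headless annotation scripts


def apply_annotation_script(
    project: Project,
    registry: FoodRegistry,
    script: dict,
    merge_gap: float = 60.0,
    min_images: int = 1,
) -> DayAnnotation:
    """Apply a batch annotation script to a project.

    The script is a JSON-shaped dict::

        {
          "merge_gap": 60, "min_images": 1,          # optional overrides
          "annotation_started": "...", "annotation_finished": "...",
          "sdeep_verdicts": [{"episode_id": 1, "verdict": "true"}, ...],
          "aeeps": [
            {"meal_label": "lunch",
             "start": "...", "end": "...",           # optional
             "link_images": ["img_0042", ...],       # optional
             "items": [
               {"source_db": "...", "food_id": "...", "form": "solid",
                "initial_amount": "1", "initial_portion": "cup",
                "leftover_amount": "1/3", "leftover_portion": "cup"}, ...
             ]}, ...
          ]
        }
    """
    merge_gap = float(script.get("merge_gap", merge_gap))
    min_images = int(script.get("min_images", min_images))
    day = DayAnnotation(
        project=project,
        sdeeps=episodes_from_labels(project, merge_gap=merge_gap, min_images=min_images),
        annotation_started=_dt_or_none(script.get("annotation_started")),
        annotation_finished=_dt_or_none(script.get("annotation_finished")),
    )
    by_id = {ep.episode_id: ep for ep in day.sdeeps}
    for v in script.get("sdeep_verdicts", []):
        eid = int(v["episode_id"])
        if eid not in by_id:
            raise ValueError(f"annotation script marks unknown SDEEp {eid}")
        mark_sdeep(by_id[eid], v["verdict"])
    for spec in script.get("aeeps", []):
        aeep = create_aeep(
            day,
            spec["meal_label"],
            start=_dt_or_none(spec.get("start")),
            end=_dt_or_none(spec.get("end")),
        )
        for image_id in spec.get("link_images", []):
            link_image(day, aeep, image_id)
        for item in spec.get("items", []):
            record = registry.resolve((item["source_db"], item["food_id"]))
            add_food_item(
                aeep,
                record,
                form=item["form"],
                initial_amount=item["initial_amount"],
                initial_portion=item["initial_portion"],
                leftover_amount=item.get("leftover_amount", 0),
                leftover_portion=item.get("leftover_portion"),
            )
    return day
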