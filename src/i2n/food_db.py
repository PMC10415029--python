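"""Food-composition databases: loading, registration, and name search.

National food-composition tables (USDA Standard Reference, FNDDS, branded
food products, FAO country tables) all publish per-100 g nutrient values but
in mutually incompatible CSV schemas. This module maps each supported schema
("dialect") onto one unified record model via a declarative column map, lets
several databases be registered side by side, and ranks name searches across
them. No cross-database nutrient standardization is attempted: values are
carried exactly as the source table states them, per 100 g of edible portion.
"""

from __future__ import annotations

import csv
import importlib.resources
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .amounts import try_parse_amount
from .errors import (
    ConfigurationError,
    EmptyDatabaseError,
    NoDatabaseError,
    RegistryConflictError,
    ResolutionError,
)

__all__ = [
    "PortionOption",
    "NutrientVector",
    "FoodRecord",
    "FoodDatabase",
    "FoodRegistry",
    "DialectMap",
    "builtin_dialects",
    "load_dialect_maps",
    "load_database",
    "get_portion_options",
]

GRAM_LABEL = "gram"
_KCAL_PER_KJ = Fraction(1000, 4184)  # exact: 1 kcal = 4.184 kJ


@dataclass(frozen=True)
class PortionOption:
    """One household measure and its weight in grams per 1.0 unit."""

    label: str
    gram_weight: Fraction

    def __post_init__(self) -> None:
        if self.gram_weight <= 0:
            raise ValueError(f"portion {self.label!r} has non-positive gram weight")


@dataclass(frozen=True)
class NutrientVector:
    """Per-100 g nutrient values of one food.

    ``values`` always contains the ``"energy"`` key (kcal). Nutrients the
    source row does not state appear in ``missing``, never as zeros.
    """

    values: Mapping[str, Fraction]
    units: Mapping[str, str]
    missing: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if "energy" not in self.values:
            raise ValueError("NutrientVector requires an energy value")
        for name, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative nutrient value for {name}")

    @property
    def energy_kcal(self) -> Fraction:
        return self.values["energy"]

    def get(self, name: str) -> Fraction | None:
        return self.values.get(name)


@dataclass(frozen=True)
class FoodRecord:
    """One food from one source database, on the per-100 g basis."""

    food_id: str
    source_db: str
    description: str
    group: str
    nutrients: NutrientVector
    portions: tuple[PortionOption, ...] = ()

    @property
    def ref(self) -> tuple[str, str]:
        return (self.source_db, self.food_id)

    def find_portion(self, label: str) -> PortionOption:
        """Resolve a portion label (case-insensitive), including ``gram``."""
        for opt in get_portion_options(self):
            if opt.label.casefold() == label.strip().casefold():
                return opt
        raise ValueError(
            f"unknown portion {label!r} for food {self.food_id!r} in {self.source_db!r}"
        )


def get_portion_options(record: FoodRecord) -> list[PortionOption]:
    """Portion options of a record, with a synthesized 1 g ``gram`` option.

    Databases do not always list grams among their household measures; a
    ``gram`` option with gram_weight 1 is appended whenever absent so that
    every food can be quantified directly in grams.
    """
    options = list(record.portions)
    if not any(o.label.casefold() == GRAM_LABEL for o in options):
        options.append(PortionOption(GRAM_LABEL, Fraction(1)))
    return options


# ---------------------------------------------------------------------------
# dialect column maps


@dataclass(frozen=True)
class DialectMap:
    """Declarative mapping from one CSV schema onto the unified model."""

    name: str
    id_col: str
    description_col: str
    group_col: str | None
    energy_col: str
    energy_unit: str  # "kcal" or "kJ"
    nutrient_cols: tuple[tuple[str, str, str], ...]  # (unified name, column, unit)
    portion_cols: tuple[tuple[str, str], ...]  # (label column, weight column)

    @property
    def nutrient_names(self) -> tuple[str, ...]:
        return tuple(n for n, _, _ in self.nutrient_cols)


def _dialect_from_mapping(name: str, raw: Mapping) -> DialectMap:
    try:
        energy = raw["energy"]
        nutrients = tuple(
            (str(n), str(spec["column"]), str(spec["unit"]))
            for n, spec in raw.get("nutrients", {}).items()
        )
        portions = tuple(
            (str(p["label"]), str(p["weight"])) for p in raw.get("portions", [])
        )
        return DialectMap(
            name=name,
            id_col=str(raw["id"]),
            description_col=str(raw["description"]),
            group_col=str(raw["group"]) if raw.get("group") else None,
            energy_col=str(energy["column"]),
            energy_unit=str(energy["unit"]),
            nutrient_cols=nutrients,
            portion_cols=portions,
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed dialect map {name!r}: {exc}") from exc


def load_dialect_maps(path: str | Path) -> dict[str, DialectMap]:
    """Load user-supplied dialect column maps from a YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"dialect config {path} is not a mapping")
    return {name: _dialect_from_mapping(name, spec) for name, spec in raw.items()}


def builtin_dialects() -> dict[str, DialectMap]:
    """The four shipped dialects: ``sr``, ``fndds``, ``branded``, ``fao``."""
    ref = importlib.resources.files("i2n").joinpath("data/dialects.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return {name: _dialect_from_mapping(name, spec) for name, spec in raw.items()}


# ---------------------------------------------------------------------------
# loading


@dataclass
class FoodDatabase:
    """One loaded food-composition database."""

    name: str
    dialect: str
    records: list[FoodRecord] = field(default_factory=list)
    skipped_rows: int = 0
    skip_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def record_count(self) -> int:
        return len(self.records)

    def get(self, food_id: str) -> FoodRecord:
        for rec in self.records:
            if rec.food_id == food_id:
                return rec
        raise ResolutionError(f"food {food_id!r} not in database {self.name!r}")


def _to_kcal(value: Fraction, unit: str) -> Fraction:
    if unit == "kcal":
        return value
    if unit in ("kJ", "kj"):
        return value * _KCAL_PER_KJ
    raise ConfigurationError(f"unsupported energy unit {unit!r}")


def load_database(
    path: str | Path,
    dialect: str,
    name: str,
    dialect_maps: Mapping[str, DialectMap] | None = None,
) -> FoodDatabase:
    """Load a food-composition CSV into a :class:`FoodDatabase`.

    Every well-formed row becomes one record. Rows missing an id, a
    description, or a parseable non-negative energy value are skipped and
    counted by reason; non-numeric nutrient cells become missing values.
    Energy is standardized to kcal here, so downstream arithmetic never sees
    the source unit.
    """
    maps = dict(dialect_maps) if dialect_maps is not None else builtin_dialects()
    if dialect not in maps:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; known: {sorted(maps)}"
        )
    d = maps[dialect]
    path = Path(path)
    try:
        fh = open(path, "r", encoding="utf-8", newline="")
    except OSError as exc:
        raise OSError(f"cannot read database file {path}: {exc}") from exc

    db = FoodDatabase(name=name, dialect=dialect)
    seen_ids: set[str] = set()
    with fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for required in (d.id_col, d.description_col, d.energy_col):
            if required not in header:
                raise ConfigurationError(
                    f"dialect {dialect!r} expects column {required!r}, "
                    f"absent from {path.name}"
                )
        for row in reader:
            rec = _record_from_row(row, d, name)
            if isinstance(rec, str):  # skip reason
                db.skipped_rows += 1
                db.skip_reasons[rec] = db.skip_reasons.get(rec, 0) + 1
                continue
            if rec.food_id in seen_ids:
                db.skipped_rows += 1
                db.skip_reasons["duplicate_id"] = db.skip_reasons.get("duplicate_id", 0) + 1
                continue
            seen_ids.add(rec.food_id)
            db.records.append(rec)
    if db.record_count == 0:
        raise EmptyDatabaseError(f"{path} yielded zero valid records for dialect {dialect!r}")
    return db


def _record_from_row(row: Mapping[str, str], d: DialectMap, db_name: str) -> FoodRecord | str:
    food_id = (row.get(d.id_col) or "").strip()
    description = (row.get(d.description_col) or "").strip()
    if not food_id:
        return "missing_id"
    if not description:
        return "missing_description"
    energy = try_parse_amount(row.get(d.energy_col) or "")
    if energy is None:
        return "missing_energy"
    group = (row.get(d.group_col) or "").strip() if d.group_col else ""

    values: dict[str, Fraction] = {"energy": _to_kcal(energy, d.energy_unit)}
    units: dict[str, str] = {"energy": "kcal"}
    missing: set[str] = set()
    for nut, col, unit in d.nutrient_cols:
        parsed = try_parse_amount(row.get(col) or "")
        if parsed is None:
            missing.add(nut)
        else:
            values[nut] = parsed
            units[nut] = unit

    portions: list[PortionOption] = []
    for label_col, weight_col in d.portion_cols:
        label = (row.get(label_col) or "").strip()
        weight = try_parse_amount(row.get(weight_col) or "")
        if label and weight is not None and weight > 0:
            portions.append(PortionOption(label, weight))

    return FoodRecord(
        food_id=food_id,
        source_db=db_name,
        description=description,
        group=group,
        nutrients=NutrientVector(values=values, units=units, missing=frozenset(missing)),
        portions=tuple(portions),
    )


# ---------------------------------------------------------------------------
# registry and search

_TOKEN = re.compile(r"[^\W_]+", re.UNICODE)


def _normalize(text: str) -> str:
    return " ".join(text.casefold().split())


@dataclass
class FoodRegistry:
    """Several databases registered side by side, searchable by food name."""

    _dbs: dict[str, tuple[FoodDatabase, int]] = field(default_factory=dict)

    def register(self, db: FoodDatabase, priority: int | None = None) -> "FoodRegistry":
        """Register a database; lower ``priority`` ranks earlier in searches."""
        if db.name in self._dbs:
            raise RegistryConflictError(f"database {db.name!r} already registered")
        if priority is None:
            priority = 1 + max((p for _, p in self._dbs.values()), default=0)
        self._dbs[db.name] = (db, priority)
        return self

    def list_databases(self) -> list[str]:
        """Database names in priority order (ties by registration order)."""
        order = {name: i for i, name in enumerate(self._dbs)}
        return sorted(self._dbs, key=lambda n: (self._dbs[n][1], order[n]))

    def database(self, name: str) -> FoodDatabase:
        try:
            return self._dbs[name][0]
        except KeyError:
            raise ResolutionError(f"no database named {name!r}") from None

    def priority(self, name: str) -> int:
        return self._dbs[name][1]

    def resolve(self, ref: tuple[str, str]) -> FoodRecord:
        """Resolve a (source_db, food_id) reference to its record."""
        source_db, food_id = ref
        return self.database(source_db).get(food_id)

    def record_counts(self) -> dict[str, int]:
        return {name: self.database(name).record_count for name in self.list_databases()}

    def search(self, query: str, databases: Iterable[str] | None = None) -> list[FoodRecord]:
        """Rank foods matching ``query`` across the selected databases.

        Case-insensitive match on the description, in four tiers: exact
        match, then prefix, then all query tokens present, then substring.
        Ties break on (database priority, food_id ascending), which makes
        repeated searches fully deterministic.
        """
        if not self._dbs:
            raise NoDatabaseError("no databases registered")
        q = _normalize(query)
        if not q:
            raise ValueError("empty search query")
        if databases is None:
            names = self.list_databases()
        else:
            names = list(databases)
            for n in names:
                if n not in self._dbs:
                    raise ValueError(f"unknown database {n!r} in search subset")
        tokens = _TOKEN.findall(q)

        ranked: list[tuple[int, int, str, FoodRecord]] = []
        for name in names:
            db, prio = self._dbs[name]
            for rec in db.records:
                desc = _normalize(rec.description)
                tier = _match_tier(desc, q, tokens)
                if tier is not None:
                    ranked.append((tier, prio, rec.food_id, rec))
        ranked.sort(key=lambda t: t[:3])
        return [rec for *_key, rec in ranked]


def _match_tier(desc: str, query: str, tokens: list[str]) -> int | None:
    if desc == query:
        return 0
    if desc.startswith(query):
        return 1
    if tokens and all(t in desc for t in tokens):
        return 2
    if query in desc:
        return 3
    return None
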