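"""Shared fixtures: toy databases, label-built projects, annotated days."""

from __future__ import annotations

import csv
from datetime import date, datetime, timedelta, timezone
from pathlib import Path

import pytest

from i2n.food_db import FoodRegistry, load_database
from i2n.sensor_events import ImageRecord, Project
from i2n.synthetic import make_toy_database

TZ = timezone(timedelta(hours=-5))
DAY_START = datetime(2023, 7, 27, 8, 0, 0, tzinfo=TZ)


@pytest.fixture(scope="session")
def toy_db_dir(tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("toydbs")
    for dialect in ("sr", "fndds", "branded", "fao"):
        make_toy_database(dialect, 30, 42, d / f"{dialect}.csv")
    return d


@pytest.fixture()
def toy_registry(toy_db_dir: Path) -> FoodRegistry:
    registry = FoodRegistry()
    for i, dialect in enumerate(("sr", "fndds", "branded"), start=1):
        db = load_database(toy_db_dir / f"{dialect}.csv", dialect, f"toy-{dialect}")
        registry.register(db, priority=i)
    return registry


@pytest.fixture()
def make_project():
    """Build a project from a 0/1 label sequence on a regular capture grid."""

    def build(labels, interval: float = 15.0, participant: str = "p01") -> Project:
        images = [
            ImageRecord(
                image_id=f"img_{i:05d}",
                timestamp=DAY_START + timedelta(seconds=i * interval),
                intake_label=int(lab),
            )
            for i, lab in enumerate(labels)
        ]
        return Project(
            participant_id=participant,
            day_id=date(2023, 7, 27),
            capture_interval=interval,
            images=images,
        )

    return build


def write_sr_csv(path: Path, rows: list[dict]) -> Path:
    """Write a minimal SR-dialect CSV; rows give id/description and optionals."""
    fields = [
        "NDB_No", "Shrt_Desc", "FdGrp_Desc", "Energ_Kcal",
        "Protein_(g)", "Lipid_Tot_(g)", "Carbohydrt_(g)",
        "GmWt_Desc1", "GmWt_1", "GmWt_Desc2", "GmWt_2",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for row in rows:
            writer.writerow({f: row.get(f, "") for f in fields})
    return path
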