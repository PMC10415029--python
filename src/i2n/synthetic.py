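"""Synthetic study inputs: toy food databases and simulated participant-days.

Two generators cover everything the rest of the package consumes:

* toy food-composition CSVs in each supported dialect, all encoding the same
  seeded ground-truth food table, so that dialect-equivalence and search
  behaviour can be checked end to end without any real database download;
* simulated wearable-camera days — an image every ``capture_interval``
  seconds across the waking day with per-image Bernoulli label noise around
  known true eating episodes. The defaults mirror the capture regime of the
  studies this tool targets: a 15 s interval, ≈3,009 images per day, and
  three true episodes totalling 204 in-episode images (≈6.8 % of the day).

An episode-level evaluator scores detected episodes against the ground truth
under an interval-overlap rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from decimal import Decimal
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import csv
import numpy as np

from .food_db import DialectMap, FoodRegistry, builtin_dialects
from .sensor_events import ImageRecord, Project, SDEEp

__all__ = [
    "ToyFood",
    "toy_foods",
    "write_toy_database",
    "make_toy_database",
    "SimulationParams",
    "study_day_params",
    "simulate_day",
    "DetectionScore",
    "evaluate_detection",
    "random_annotated_day",
]


# ---------------------------------------------------------------------------
# toy food databases

_BASES = [
    "Rice, white, cooked", "Rice, brown, cooked", "Bread, whole wheat", "Bread, white",
    "Chicken, breast, roasted", "Chicken, thigh, stewed", "Beef, ground, cooked",
    "Fish, tilapia, fried", "Fish, salmon, baked", "Egg, whole, boiled",
    "Milk, whole", "Milk, skim", "Yogurt, plain", "Cheese, cheddar",
    "Beans, black, cooked", "Beans, kidney, cooked", "Lentils, cooked",
    "Maize, porridge", "Cassava, boiled", "Plantain, fried", "Yam, boiled",
    "Potato, mashed", "Potato, baked", "Sweet potato, roasted",
    "Apple, raw", "Banana, raw", "Orange, raw", "Mango, raw", "Pineapple, raw",
    "Tomato, raw", "Onion, raw", "Spinach, cooked", "Cabbage, cooked",
    "Carrot, raw", "Peanut butter", "Peanuts, roasted", "Groundnut soup",
    "Okra stew", "Jollof rice", "Fufu", "Kenkey", "Banku", "Waakye",
    "Soda, cola", "Juice, orange", "Tea, sweetened", "Coffee, with milk",
    "Oatmeal, cooked", "Pasta, cooked", "Pizza, cheese", "Hamburger, plain",
]

_GROUPS = [
    "Cereal Grains and Pasta", "Poultry Products", "Beef Products", "Finfish",
    "Dairy and Egg Products", "Legumes", "Vegetables", "Fruits", "Beverages",
    "Baked Products", "Mixed Dishes",
]

_PORTION_POOL = [
    ("cup", 240), ("tablespoon", 15), ("teaspoon", 5), ("slice", 28),
    ("piece", 60), ("serving", 150), ("bowl", 300), ("glass", 250),
]

_OPTIONAL_NUTRIENTS = ("fiber", "calcium", "iron", "vitamin_c")


@dataclass(frozen=True)
class ToyFood:
    """Ground-truth row shared by every dialect encoding of a toy database."""

    index: int
    description: str
    group: str
    energy_kcal: int
    nutrients: dict[str, Fraction | None]  # None = absent from the source
    portions: tuple[tuple[str, int], ...]  # (label, gram weight)


def toy_foods(n_foods: int, seed: int) -> list[ToyFood]:
    """Deterministic ground-truth food table (same seed → same table)."""
    if n_foods < 1:
        raise ValueError("n_foods must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(_BASES))
    foods = []
    for i in range(n_foods):
        if i < len(_BASES):
            desc = _BASES[order[i]]
        else:
            desc = f"{_BASES[order[i % len(_BASES)]]}, variant {i // len(_BASES)}"
        group = _GROUPS[int(rng.integers(len(_GROUPS)))]
        energy = int(rng.integers(20, 550))
        nutrients: dict[str, Fraction | None] = {
            # one decimal place so every dialect encodes the value exactly
            "protein": Fraction(int(rng.integers(0, 400)), 10),
            "fat": Fraction(int(rng.integers(0, 350)), 10),
            "carbohydrate": Fraction(int(rng.integers(0, 800)), 10),
        }
        for nut in _OPTIONAL_NUTRIENTS:
            if rng.random() < 0.15:
                nutrients[nut] = None
            elif nut == "calcium":
                nutrients[nut] = Fraction(int(rng.integers(0, 1400)))
            else:
                nutrients[nut] = Fraction(int(rng.integers(0, 300)), 10)
        k = int(rng.integers(1, 4))
        picks = rng.choice(len(_PORTION_POOL), size=k, replace=False)
        portions = tuple(_PORTION_POOL[int(p)] for p in sorted(picks))
        foods.append(
            ToyFood(
                index=i,
                description=desc,
                group=group,
                energy_kcal=energy,
                nutrients=nutrients,
                portions=portions,
            )
        )
    return foods


def _food_id(dialect: str, index: int) -> str:
    return {
        "sr": f"{10001 + index:05d}",
        "fndds": f"{11000001 + index}",
        "branded": f"{345001 + index}",
        "fao": f"{1001 + index:04d}",
    }[dialect]


def _decimal_str(x: Fraction, thousands: bool = False) -> str:
    d = Decimal(x.numerator) / Decimal(x.denominator)
    s = format(d.normalize(), ",f" if thousands else "f")
    return s


def write_toy_database(dialect: str, foods: Sequence[ToyFood], path: str | Path) -> Path:
    """Encode a ground-truth food table as a CSV in the given dialect.

    The branded dialect stores energy in kJ (integer kcal × 4.184, exact to
    three decimals); the SR dialect writes thousands separators for values
    ≥ 1000, exercising the loader's number parsing.
    """
    dialects = builtin_dialects()
    if dialect not in dialects:
        raise ValueError(f"unknown dialect {dialect!r}")
    d: DialectMap = dialects[dialect]
    path = Path(path)

    header = [d.id_col, d.description_col]
    if d.group_col:
        header.append(d.group_col)
    header.append(d.energy_col)
    nutrient_cols = {name: col for name, col, _unit in d.nutrient_cols}
    header.extend(nutrient_cols.values())
    for label_col, weight_col in d.portion_cols:
        header.extend([label_col, weight_col])

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=header)
        writer.writeheader()
        for food in foods:
            row: dict[str, str] = {
                d.id_col: _food_id(dialect, food.index),
                d.description_col: food.description,
            }
            if d.group_col:
                row[d.group_col] = food.group
            if d.energy_unit == "kJ":
                kj = Decimal(food.energy_kcal) * Decimal("4.184")
                row[d.energy_col] = format(kj.normalize(), "f")
            else:
                row[d.energy_col] = str(food.energy_kcal)
            thousands = dialect == "sr"
            for name, col in nutrient_cols.items():
                value = food.nutrients.get(name)
                row[col] = "" if value is None else _decimal_str(
                    value, thousands=thousands and value >= 1000
                )
            for (label_col, weight_col), portion in zip(d.portion_cols, food.portions):
                row[label_col] = portion[0]
                row[weight_col] = str(portion[1])
            writer.writerow(row)
    return path


def make_toy_database(
    dialect: str, n_foods: int, seed: int, path: str | Path
) -> tuple[Path, list[ToyFood]]:
    """Write a toy dialect CSV and return (path, ground-truth table)."""
    foods = toy_foods(n_foods, seed)
    return write_toy_database(dialect, foods, path), foods


# ---------------------------------------------------------------------------
# simulated participant-days

DAY_START = time(7, 0)


@dataclass(frozen=True)
class SimulationParams:
    """Conditions of one simulated wearable-camera day.

    ``true_episodes`` are (start offset, duration) pairs in seconds from the
    day start, snapped to the capture grid; inside them each image is
    intake-labeled with probability 1−``fn_rate``, outside with probability
    ``fp_rate`` (independent per-image Bernoulli noise).
    """

    seed: int
    day_length_s: float = 45_135.0  # 3,009 images at a 15 s interval
    capture_interval: float = 15.0
    true_episodes: tuple[tuple[float, float], ...] = (
        (7_200.0, 900.0),  # breakfast: 60 images
        (18_000.0, 1_260.0),  # lunch: 84 images
        (32_400.0, 900.0),  # dinner: 60 images
    )
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    participant_id: str = "sim"
    day_id: date = date(2023, 7, 27)

    def __post_init__(self) -> None:
        if not (0 <= self.fp_rate <= 1 and 0 <= self.fn_rate <= 1):
            raise ValueError("fp_rate and fn_rate must lie in [0, 1]")
        if self.capture_interval <= 0 or self.day_length_s <= 0:
            raise ValueError("capture_interval and day_length_s must be positive")
        eps = sorted(self.snapped_episodes())
        for (s, e), (s2, e2) in zip(eps, eps[1:]):
            if s2 < e:
                raise ValueError("true episodes must not overlap")
        for s, e in eps:
            if s < 0 or e > self.day_length_s:
                raise ValueError("true episodes must lie within the day")

    def snapped_episodes(self) -> list[tuple[float, float]]:
        """Episodes as (start_s, end_s), snapped to the capture grid."""
        dt = self.capture_interval
        out = []
        for start, dur in self.true_episodes:
            s = round(start / dt) * dt
            d = max(1, round(dur / dt)) * dt
            out.append((s, s + d))
        return out


def study_day_params(seed: int, fp_rate: float = 0.0, fn_rate: float = 0.0, **kw) -> SimulationParams:
    """Params under the default study-like conditions with given noise."""
    return SimulationParams(seed=seed, fp_rate=fp_rate, fn_rate=fn_rate, **kw)


def simulate_day(params: SimulationParams) -> tuple[Project, list[SDEEp]]:
    """Simulate one labeled day; returns the project and ground-truth episodes.

    Ground-truth boundaries use the same convention as the segmenter: an
    episode runs from its first in-episode capture to its last plus one
    capture interval, so noise-free recovery is exact.
    """
    rng = np.random.default_rng(params.seed)
    dt = params.capture_interval
    n_images = int(params.day_length_s // dt)
    day_start = datetime.combine(params.day_id, DAY_START, tzinfo=timezone.utc)
    episodes_s = params.snapped_episodes()

    images = []
    for i in range(n_images):
        offset = i * dt
        inside = any(s <= offset < e for s, e in episodes_s)
        p_one = (1.0 - params.fn_rate) if inside else params.fp_rate
        label = int(rng.random() < p_one)
        images.append(
            ImageRecord(
                image_id=f"img_{i:05d}",
                timestamp=day_start + timedelta(seconds=offset),
                intake_label=label,
            )
        )
    project = Project(
        participant_id=params.participant_id,
        day_id=params.day_id,
        capture_interval=dt,
        images=images,
    )
    truth = [
        SDEEp(
            episode_id=k + 1,
            start=day_start + timedelta(seconds=s),
            end=day_start + timedelta(seconds=e),
        )
        for k, (s, e) in enumerate(sorted(episodes_s))
    ]
    return project, truth


# ---------------------------------------------------------------------------
# detection scoring


@dataclass(frozen=True)
class DetectionScore:
    """Episode-level detection quality under an interval-overlap rule."""

    n_truth: int
    n_detected: int
    matched_truth: int
    matched_detected: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool
    recall_defined: bool
    image_confusion: dict[str, int] | None = None  # tp/fp/fn/tn over images


def _overlap_s(a: SDEEp, b: SDEEp) -> float:
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    return max(0.0, (hi - lo).total_seconds())


def evaluate_detection(
    ground_truth: Sequence[SDEEp],
    detected: Sequence[SDEEp],
    min_overlap_frac: float = 0.0,
    project: Project | None = None,
) -> DetectionScore:
    """Score detected episodes against ground truth.

    A pair matches when it overlaps in time; with ``min_overlap_frac`` > 0
    the overlap must additionally cover that fraction of the shorter of the
    two intervals. Undefined precision (nothing detected) or recall (no truth
    episodes) is reported as 0 with the corresponding ``*_defined`` flag
    cleared. With a project given, per-image occupancy confusion counts are
    included (they sum to the image total).
    """

    def matches(gt: SDEEp, det: SDEEp) -> bool:
        o = _overlap_s(gt, det)
        if o <= 0:
            return False
        if min_overlap_frac > 0:
            shorter = min(gt.duration_s, det.duration_s)
            return shorter == 0 or o >= min_overlap_frac * shorter
        return True

    matched_truth = sum(1 for gt in ground_truth if any(matches(gt, d) for d in detected))
    matched_det = sum(1 for d in detected if any(matches(gt, d) for gt in ground_truth))

    recall_defined = len(ground_truth) > 0
    precision_defined = len(detected) > 0
    recall = matched_truth / len(ground_truth) if recall_defined else 0.0
    precision = matched_det / len(detected) if precision_defined else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0

    confusion = None
    if project is not None:
        confusion = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for im in project.images:
            t = any(ep.contains(im.timestamp) for ep in ground_truth)
            d = any(ep.contains(im.timestamp) for ep in detected)
            key = "tp" if (t and d) else "fp" if d else "fn" if t else "tn"
            confusion[key] += 1

    return DetectionScore(
        n_truth=len(ground_truth),
        n_detected=len(detected),
        matched_truth=matched_truth,
        matched_detected=matched_det,
        precision=precision,
        recall=recall,
        f1=f1,
        precision_defined=precision_defined,
        recall_defined=recall_defined,
        image_confusion=confusion,
    )


# ---------------------------------------------------------------------------
# randomly annotated days (for conservation-style checks)

_AMOUNTS = (
    Fraction(1), Fraction(2), Fraction(1, 2), Fraction(3, 4),
    Fraction(1, 3), Fraction(2, 3), Fraction(3, 2),
)
_LEFT_FRACTIONS = (Fraction(0), Fraction(0), Fraction(1, 4), Fraction(1, 3), Fraction(1, 2))


def random_annotated_day(registry: FoodRegistry, seed: int, n_aeep: int | None = None):
    """Simulate a day and annotate it with random foods from the registry.

    Every SDEEp is marked true, one AEEp is created per episode (meal labels
    cycling through the canonical four), and 1–4 random foods with random
    exact-fraction portions are attached to each. Leftovers are occasionally
    recorded in grams rather than the initial portion to exercise the
    mixed-unit path.
    """
    from .annotation import DayAnnotation, add_food_item, create_aeep, link_image
    from .sensor_events import episodes_from_labels, images_in_episode, mark_sdeep

    rng = np.random.default_rng(seed)
    project, _truth = simulate_day(study_day_params(seed=seed))
    day = DayAnnotation(project=project, sdeeps=episodes_from_labels(project))
    if n_aeep is not None:
        day.sdeeps = day.sdeeps[:n_aeep]

    db_names = registry.list_databases()
    meal_cycle = ("breakfast", "lunch", "dinner", "snack")
    for k, ep in enumerate(day.sdeeps):
        mark_sdeep(ep, True)
        aeep = create_aeep(day, meal_cycle[k % 4])
        episode_images = images_in_episode(project, ep)
        for im in (episode_images[0], episode_images[-1]):
            link_image(day, aeep, im)
        for _ in range(int(rng.integers(1, 5))):
            db = registry.database(db_names[int(rng.integers(len(db_names)))])
            record = db.records[int(rng.integers(db.record_count))]
            portions = [p.label for p in record.portions] or ["gram"]
            initial_portion = portions[int(rng.integers(len(portions)))]
            initial = _AMOUNTS[int(rng.integers(len(_AMOUNTS)))]
            left_frac = _LEFT_FRACTIONS[int(rng.integers(len(_LEFT_FRACTIONS)))]
            if rng.random() < 0.2:
                # leftover recorded in grams
                grams = initial * record.find_portion(initial_portion).gram_weight
                add_food_item(
                    aeep, record, form=("solid", "liquid", "semi-solid")[int(rng.integers(3))],
                    initial_amount=initial, initial_portion=initial_portion,
                    leftover_amount=grams * left_frac, leftover_portion="gram",
                )
            else:
                add_food_item(
                    aeep, record, form=("solid", "liquid", "semi-solid")[int(rng.integers(3))],
                    initial_amount=initial, initial_portion=initial_portion,
                    leftover_amount=initial * left_frac, leftover_portion=None,
                )
    start = project.start
    day.annotation_started = start
    day.annotation_finished = start + timedelta(seconds=int(rng.integers(600, 1800)))
    return day
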