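"""AEEp lifecycle: creation, image linking, time links, items, persistence."""

import warnings
from datetime import timedelta
from fractions import Fraction

import pytest

from conftest import DAY_START
from i2n.annotation import (
    AnnotationWarning,
    DayAnnotation,
    add_food_item,
    apply_annotation_script,
    create_aeep,
    link_image,
    load_annotation,
    lookup_by_time,
    save_annotation,
)
from i2n.errors import DataFormatError, ValidationError
from i2n.sensor_events import episodes_from_labels
from i2n.synthetic import random_annotated_day


@pytest.fixture()
def day(make_project):
    project = make_project([0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 1, 1, 0, 0])
    return DayAnnotation(project=project, sdeeps=episodes_from_labels(project, merge_gap=0))


def test_create_aeep_with_explicit_times(day):
    start, end = DAY_START, DAY_START + timedelta(minutes=5)
    aeep = create_aeep(day, "lunch", start=start, end=end)
    assert (aeep.meal_label, aeep.start, aeep.end) == ("lunch", start, end)
    with pytest.raises(ValueError):
        create_aeep(day, "dinner", start=end, end=start)


def test_aeep_ids_are_distinct_and_sequential(day):
    a = create_aeep(day, "breakfast")
    b = create_aeep(day, "snack")
    assert (a.aeep_id, b.aeep_id) == (1, 2)


def test_linking_autopopulates_start_and_end(make_project):
    # images at 12:00:00 and 12:05:00 with a 15 s interval
    project = make_project([1] * 21, interval=15)
    day = DayAnnotation(project=project)
    aeep = create_aeep(day, "lunch")
    link_image(day, aeep, project.images[0])
    link_image(day, aeep, project.images[20])
    assert aeep.start == project.images[0].timestamp
    assert aeep.end == project.images[20].timestamp + timedelta(seconds=15)


def test_single_linked_image_spans_one_interval(day):
    aeep = create_aeep(day, "snack")
    link_image(day, aeep, day.project.images[3])
    assert aeep.end - aeep.start == timedelta(seconds=15)
    assert aeep.start == day.project.images[3].timestamp


def test_relinking_is_idempotent_set_semantics(day):
    aeep = create_aeep(day, "snack")
    link_image(day, aeep, day.project.images[2])
    link_image(day, aeep, day.project.images[2])
    assert aeep.linked_image_ids == {"img_00002"}
    start, end = aeep.start, aeep.end
    link_image(day, aeep, day.project.images[2])
    assert (aeep.start, aeep.end) == (start, end)


def test_foreign_image_is_an_argument_error(day):
    aeep = create_aeep(day, "snack")
    with pytest.raises(ValueError):
        link_image(day, aeep, "img_99999")


def test_image_shared_between_aeeps_warns(day):
    a = create_aeep(day, "lunch")
    b = create_aeep(day, "drink")
    link_image(day, a, day.project.images[2])
    with pytest.warns(AnnotationWarning):
        link_image(day, b, day.project.images[2])


def test_overlapping_aeeps_warn_but_are_allowed(day):
    create_aeep(day, "lunch", start=DAY_START, end=DAY_START + timedelta(minutes=10))
    with pytest.warns(AnnotationWarning):
        create_aeep(day, "drink", start=DAY_START + timedelta(minutes=5),
                    end=DAY_START + timedelta(minutes=15))
    assert len(day.aeeps) == 2


# ---------------------------------------------------------------------------
# time links


def test_lookup_inside_and_between_sdeeps(day):
    inside = day.sdeeps[0].start
    hit = lookup_by_time(day, inside)
    assert hit.sdeep is day.sdeeps[0]
    between = day.sdeeps[0].end + timedelta(seconds=30)
    assert lookup_by_time(day, between).sdeep is None


def test_lookup_returns_the_image_captured_at_each_timestamp(day):
    for im in day.project.images:
        assert lookup_by_time(day, im.timestamp).image is im


def test_lookup_outside_the_day_is_an_argument_error(day):
    with pytest.raises(ValueError):
        lookup_by_time(day, DAY_START - timedelta(hours=1))


# ---------------------------------------------------------------------------
# food items


def test_worked_example_consumed_two_thirds_cup(day, toy_registry):
    record = next(r for r in toy_registry.database("toy-sr").records
                  if any(p.label == "cup" for p in r.portions))
    aeep = create_aeep(day, "lunch")
    entry = add_food_item(aeep, record, "semi-solid", "1", "cup", "1/3", "cup")
    assert entry.consumed.amount == Fraction(2, 3)
    assert entry.consumed.portion == "cup"


def test_omitted_leftover_means_fully_consumed(day, toy_registry):
    record = toy_registry.database("toy-sr").records[0]
    aeep = create_aeep(day, "lunch")
    entry = add_food_item(aeep, record, "solid", "150", "gram")
    assert entry.leftover_amount == 0
    assert entry.consumed.grams == 150


def test_leftover_exceeding_initial_is_a_validation_error(day, toy_registry):
    record = next(r for r in toy_registry.database("toy-sr").records
                  if any(p.label == "cup" for p in r.portions))
    aeep = create_aeep(day, "lunch")
    with pytest.raises(ValidationError):
        add_food_item(aeep, record, "liquid", "1", "cup", "2", "cup")


def test_unknown_portion_label_is_an_argument_error(day, toy_registry):
    record = toy_registry.database("toy-sr").records[0]
    aeep = create_aeep(day, "lunch")
    with pytest.raises(ValueError):
        add_food_item(aeep, record, "solid", "1", "hogshead")


# ---------------------------------------------------------------------------
# persistence


def test_round_trip_preserves_everything(toy_registry, tmp_path):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        day = random_annotated_day(toy_registry, seed=23)
    save_annotation(day, tmp_path / "a.json")
    loaded = load_annotation(tmp_path / "a.json")
    assert loaded == day
    assert [ep.status for ep in loaded.sdeeps] == [ep.status for ep in day.sdeeps]


def test_truncated_annotation_file_is_a_format_error(toy_registry, tmp_path):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        day = random_annotated_day(toy_registry, seed=23)
    save_annotation(day, tmp_path / "a.json")
    text = (tmp_path / "a.json").read_text()
    (tmp_path / "a.json").write_text(text[: len(text) // 2])
    with pytest.raises(DataFormatError):
        load_annotation(tmp_path / "a.json")


def test_schema_version_mismatch_is_a_format_error(toy_registry, tmp_path):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        day = random_annotated_day(toy_registry, seed=23)
    save_annotation(day, tmp_path / "a.json")
    text = (tmp_path / "a.json").read_text().replace('"schema_version": 1', '"schema_version": 99', 1)
    (tmp_path / "a.json").write_text(text)
    with pytest.raises(DataFormatError):
        load_annotation(tmp_path / "a.json")


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_round_trip_identity_over_generated_days(toy_registry, tmp_path, seed):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        day = random_annotated_day(toy_registry, seed=seed)
    save_annotation(day, tmp_path / f"{seed}.json")
    assert load_annotation(tmp_path / f"{seed}.json") == day


def test_deleting_an_aeep_never_mutates_the_project(day):
    aeep = create_aeep(day, "lunch")
    link_image(day, aeep, day.project.images[2])
    images_before = list(day.project.images)
    day.aeeps.remove(aeep)
    assert day.project.images == images_before


# ---------------------------------------------------------------------------
# headless annotation scripts


def test_apply_annotation_script_end_to_end(make_project, toy_registry):
    project = make_project([0, 1, 1, 1, 0, 0, 0, 0, 0, 1, 1, 0])
    record = next(r for r in toy_registry.database("toy-sr").records
                  if any(p.label == "cup" for p in r.portions))
    script = {
        "merge_gap": 0,
        "sdeep_verdicts": [
            {"episode_id": 1, "verdict": "true"},
            {"episode_id": 2, "verdict": "false"},
        ],
        "aeeps": [
            {
                "meal_label": "lunch",
                "link_images": ["img_00001", "img_00003"],
                "items": [
                    {"source_db": "toy-sr", "food_id": record.food_id, "form": "solid",
                     "initial_amount": "1", "initial_portion": "cup",
                     "leftover_amount": "1/3", "leftover_portion": "cup"}
                ],
            }
        ],
    }
    day = apply_annotation_script(project, toy_registry, script)
    assert [ep.status for ep in day.sdeeps] == ["true", "false"]
    (aeep,) = day.aeeps
    assert aeep.linked_image_ids == {"img_00001", "img_00003"}
    assert aeep.items[0].consumed.amount == Fraction(2, 3)
    with pytest.raises(ValueError):
        apply_annotation_script(project, toy_registry,
                                {"sdeep_verdicts": [{"episode_id": 9, "verdict": "true"}]})
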