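"""Episode segmentation, review metrics, and the brute-force merge oracle."""

from datetime import timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import DAY_START
from i2n.errors import DataFormatError, ValidationError
from i2n.sensor_events import (
    ImageRecord,
    Project,
    ReviewMetrics,
    SDEEp,
    dropped_intake_images,
    episodes_from_labels,
    images_in_episode,
    load_project,
    mark_sdeep,
    review_metrics,
    round_half_away,
    save_project,
    sdeep_status_counts,
)


def oracle_episodes(project, merge_gap, min_images):
    """Independent brute force: enumerate label-1 runs, merge pairwise until
    fixpoint, then drop small episodes. Returns (start, end) pairs."""
    interval = project.capture_interval
    runs, current = [], []
    for im in project.images:
        if im.intake_label == 1:
            current.append(im)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    changed = True
    while changed:  # merge adjacent pairs until fixpoint
        changed = False
        i = 0
        while i < len(runs) - 1:
            gap = (runs[i + 1][0].timestamp - runs[i][-1].timestamp).total_seconds() - interval
            if gap <= merge_gap:
                runs[i : i + 2] = [runs[i] + runs[i + 1]]
                changed = True
            else:
                i += 1
    return [
        (r[0].timestamp, r[-1].timestamp + timedelta(seconds=interval))
        for r in runs
        if len(r) >= min_images
    ]


# ---------------------------------------------------------------------------
# project validation and persistence


def test_project_round_trips_through_json(make_project, tmp_path):
    project = make_project([0, 1, 1, 0, 1], interval=10)
    save_project(project, tmp_path / "p.json")
    assert load_project(tmp_path / "p.json") == project


def test_out_of_range_label_is_a_validation_error(make_project):
    with pytest.raises(ValidationError):
        make_project([0, 1, 2])


def test_duplicate_timestamps_are_a_validation_error(make_project):
    project = make_project([0, 1])
    images = [project.images[0], project.images[0]]
    with pytest.raises(ValidationError):
        Project("p", project.day_id, 15, images)


def test_truncated_project_file_is_a_format_error(tmp_path):
    (tmp_path / "bad.json").write_text('{"participant_id": "p", ')
    with pytest.raises(DataFormatError):
        load_project(tmp_path / "bad.json")


# ---------------------------------------------------------------------------
# segmentation


def test_all_zero_labels_yield_no_episodes(make_project):
    assert episodes_from_labels(make_project([0] * 50)) == []


def test_single_run_becomes_one_episode_with_end_extended(make_project):
    project = make_project([0, 0, 1, 1, 1, 0, 0], interval=15)
    (ep,) = episodes_from_labels(project)
    assert ep.start == project.images[2].timestamp
    assert ep.end == project.images[4].timestamp + timedelta(seconds=15)
    assert ep.status == "unreviewed"


def test_runs_within_merge_gap_merge_and_small_episodes_drop(make_project):
    # two runs split by two non-intake captures: 15 s interval -> gap 30 s
    project = make_project([1, 1, 0, 0, 1, 1])
    assert len(episodes_from_labels(project, merge_gap=30)) == 1
    assert len(episodes_from_labels(project, merge_gap=29)) == 2
    # min_images filters on the merged episode's intake-image count
    assert len(episodes_from_labels(project, merge_gap=29, min_images=3)) == 0
    assert len(episodes_from_labels(project, merge_gap=30, min_images=3)) == 1


def test_dropped_intake_images_are_reported_not_lost(make_project):
    project = make_project([1, 0, 0, 0, 0, 0, 1, 1, 1])
    episodes = episodes_from_labels(project, merge_gap=0, min_images=2)
    assert len(episodes) == 1
    dropped = dropped_intake_images(project, episodes)
    assert [im.image_id for im in dropped] == ["img_00000"]
    covered = sum(len(images_in_episode(project, ep)) for ep in episodes)
    assert covered + len(dropped) >= project.n_intake_labeled


@settings(derandomize=True, max_examples=300, deadline=None)
@given(
    labels=st.lists(st.integers(0, 1), min_size=1, max_size=120),
    merge_gap=st.sampled_from([0.0, 15.0, 30.0, 60.0, 120.0]),
    min_images=st.integers(1, 4),
)
def test_segmentation_matches_brute_force_oracle(labels, merge_gap, min_images):
    from conftest import DAY_START
    from datetime import date

    images = [
        ImageRecord(f"i{i}", DAY_START + timedelta(seconds=15 * i), lab)
        for i, lab in enumerate(labels)
    ]
    project = Project("p", date(2023, 7, 27), 15, images)
    got = [(ep.start, ep.end) for ep in episodes_from_labels(project, merge_gap, min_images)]
    assert got == oracle_episodes(project, merge_gap, min_images)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(labels=st.lists(st.integers(0, 1), min_size=1, max_size=120),
       merge_gap=st.sampled_from([0.0, 45.0, 90.0]))
def test_episodes_are_disjoint_and_cover_every_intake_image(labels, merge_gap):
    from datetime import date

    images = [
        ImageRecord(f"i{i}", DAY_START + timedelta(seconds=15 * i), lab)
        for i, lab in enumerate(labels)
    ]
    project = Project("p", date(2023, 7, 27), 15, images)
    episodes = episodes_from_labels(project, merge_gap=merge_gap, min_images=1)
    for im in project.images:
        containing = [ep for ep in episodes if ep.contains(im.timestamp)]
        assert len(containing) <= 1
        if im.intake_label == 1:
            assert len(containing) == 1


def test_images_in_episode_selects_half_open_interval(make_project):
    project = make_project([0] * 5 + [1] * 5 + [0] * 5)
    (ep,) = episodes_from_labels(project)
    selected = images_in_episode(project, ep)
    assert [im.image_id for im in selected] == [f"img_{i:05d}" for i in range(5, 10)]


def test_foreign_episode_is_an_argument_error(make_project):
    project = make_project([1, 1])
    foreign = SDEEp(1, DAY_START + timedelta(days=2), DAY_START + timedelta(days=2, hours=1))
    with pytest.raises(ValueError):
        images_in_episode(project, foreign)


# ---------------------------------------------------------------------------
# review metrics


def test_published_us_counts_reproduce_the_reported_percentages():
    m = ReviewMetrics.from_counts(180_520, 12_267)
    assert m.pct_reviewed == pytest.approx(6.80, abs=0.005)
    assert m.display_pct_reviewed == 7
    assert m.pct_reduction == pytest.approx(93.20, abs=0.005)


@pytest.mark.parametrize(
    ("total", "detected", "reviewed", "reduction"),
    [(100, 100, 100.0, 0.0), (100, 0, 0.0, 100.0)],
)
def test_review_metric_edge_cases(total, detected, reviewed, reduction):
    m = ReviewMetrics.from_counts(total, detected)
    assert (m.pct_reviewed, m.pct_reduction) == (reviewed, reduction)


def test_reviewed_and_reduction_sum_to_exactly_100(make_project):
    rng = np.random.default_rng(0)
    projects = [make_project(rng.integers(0, 2, size=60)) for _ in range(3)]
    episodes = [episodes_from_labels(p) for p in projects]
    m = review_metrics(projects, episodes)
    assert m.pct_reviewed + m.pct_reduction == 100.0
    assert m.total_images == 180
    assert 0 <= m.detected_images <= m.total_images


def test_zero_total_images_is_an_arithmetic_error():
    with pytest.raises(ZeroDivisionError):
        ReviewMetrics.from_counts(0, 0)


def test_display_rounding_is_half_away_from_zero():
    assert round_half_away(6.5) == 7
    assert round_half_away(6.49) == 6
    assert round_half_away(-6.5) == -7


# ---------------------------------------------------------------------------
# verdicts


def test_last_verdict_wins_and_counts_are_conserved(make_project):
    project = make_project([1, 1, 0, 0, 0, 0, 0, 1, 1])
    episodes = episodes_from_labels(project, merge_gap=0)
    assert len(episodes) == 2
    mark_sdeep(episodes[0], "false")
    mark_sdeep(episodes[0], True)
    assert episodes[0].status == "true"
    counts = sdeep_status_counts(episodes)
    assert counts == {"true": 1, "false": 0, "unreviewed": 1}
    assert sum(counts.values()) == len(episodes)
    with pytest.raises(ValueError):
        mark_sdeep(episodes[1], "maybe")
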