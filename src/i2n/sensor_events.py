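"""Participant-day projects and sensor-detected eating episodes.

A wearable camera captures one egocentric image every ``capture_interval``
seconds (10–15 s in the studies this tool targets); an upstream food-intake
classifier labels every image 0 (non-intake) or 1 (intake). This module
turns those per-image labels into sensor-detected eating episodes (SDEEps),
selects the images an annotator actually needs to review, and quantifies the
resulting reduction of review burden.

Segmentation rule: maximal runs of consecutive label-1 images form candidate
episodes; two runs are merged when the non-intake time between them — from
the end of one run's last intake capture (its timestamp plus the capture
interval) to the next run's first intake timestamp — is at most ``merge_gap``
seconds; merged episodes containing fewer than ``min_images`` intake images
are then dropped. An episode spans from its first intake image's timestamp to
its last intake image's timestamp plus the capture interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path

from .errors import DataFormatError, ValidationError

__all__ = [
    "ImageRecord",
    "Project",
    "SDEEp",
    "ReviewMetrics",
    "load_project",
    "save_project",
    "episodes_from_labels",
    "dropped_intake_images",
    "images_in_episode",
    "review_metrics",
    "mark_sdeep",
    "sdeep_status_counts",
    "round_half_away",
]

SDEEP_STATUSES = ("unreviewed", "true", "false")


@dataclass(frozen=True)
class ImageRecord:
    image_id: str
    timestamp: datetime
    intake_label: int
    path: str | None = None


@dataclass
class Project:
    """One participant-day: ordered image stream with binary intake labels."""

    participant_id: str
    day_id: date
    capture_interval: float  # seconds
    images: list[ImageRecord]

    def __post_init__(self) -> None:
        if self.capture_interval <= 0:
            raise ValidationError("capture_interval must be positive")
        if not self.images:
            raise ValidationError("a project needs at least one image")
        for img in self.images:
            if img.intake_label not in (0, 1):
                raise ValidationError(
                    f"image {img.image_id!r} has label {img.intake_label!r}, expected 0 or 1"
                )
        self.images = sorted(self.images, key=lambda im: im.timestamp)
        for prev, cur in zip(self.images, self.images[1:]):
            if cur.timestamp <= prev.timestamp:
                raise ValidationError(
                    f"timestamps not strictly increasing at image {cur.image_id!r}"
                )

    @property
    def start(self) -> datetime:
        return self.images[0].timestamp

    @property
    def end(self) -> datetime:
        """End of the day's coverage: last capture plus one interval."""
        from datetime import timedelta

        return self.images[-1].timestamp + timedelta(seconds=self.capture_interval)

    @property
    def n_intake_labeled(self) -> int:
        return sum(im.intake_label for im in self.images)


@dataclass
class SDEEp:
    """A sensor-detected eating episode, verifiable as true or false."""

    episode_id: int
    start: datetime
    end: datetime
    status: str = "unreviewed"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("episode start after end")
        if self.status not in SDEEP_STATUSES:
            raise ValidationError(f"bad SDEEp status {self.status!r}")

    def contains(self, t: datetime) -> bool:
        return self.start <= t < self.end

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


# ---------------------------------------------------------------------------
# project persistence (JSON)


def save_project(project: Project, path: str | Path) -> None:
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
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_project(path: str | Path) -> Project:
    """Load a project file (JSON; timestamps ISO 8601 with offset)."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"project file {path} is not valid JSON: {exc}") from exc
    try:
        images = [
            ImageRecord(
                image_id=str(e["image_id"]),
                timestamp=datetime.fromisoformat(e["timestamp"]),
                intake_label=int(e["label"]),
                path=e.get("path"),
            )
            for e in doc["images"]
        ]
        return Project(
            participant_id=str(doc["participant_id"]),
            day_id=date.fromisoformat(doc["day_id"]),
            capture_interval=float(doc["capture_interval_s"]),
            images=images,
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise DataFormatError(f"project file {path} malformed: {exc}") from exc


# ---------------------------------------------------------------------------
# episode segmentation


def episodes_from_labels(
    project: Project, merge_gap: float = 60.0, min_images: int = 1
) -> list[SDEEp]:
    """Derive SDEEp boundaries from the per-image intake labels.

    ``merge_gap`` (seconds) tolerates short within-meal pauses; ``min_images``
    drops merged episodes carried by fewer intake images than that. All-zero
    labels yield an empty list. Intake images dropped by ``min_images`` can be
    recovered with :func:`dropped_intake_images`.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    if min_images < 1:
        raise ValueError("min_images must be >= 1")
    interval = project.capture_interval

    # maximal runs of consecutive label-1 images: (first_ts, last_ts, count)
    runs: list[tuple[datetime, datetime, int]] = []
    current: list[ImageRecord] = []
    for img in project.images:
        if img.intake_label == 1:
            current.append(img)
        elif current:
            runs.append((current[0].timestamp, current[-1].timestamp, len(current)))
            current = []
    if current:
        runs.append((current[0].timestamp, current[-1].timestamp, len(current)))

    merged: list[tuple[datetime, datetime, int]] = []
    for run in runs:
        if merged:
            gap = (run[0] - merged[-1][1]).total_seconds() - interval
            if gap <= merge_gap:
                first, _last, n = merged[-1]
                merged[-1] = (first, run[1], n + run[2])
                continue
        merged.append(run)

    episodes: list[SDEEp] = []
    for first, last, n in merged:
        if n < min_images:
            continue
        episodes.append(
            SDEEp(
                episode_id=len(episodes) + 1,
                start=first,
                end=last + _td(interval),
            )
        )
    return episodes


def _td(seconds: float):
    from datetime import timedelta

    return timedelta(seconds=seconds)


def dropped_intake_images(project: Project, episodes: list[SDEEp]) -> list[ImageRecord]:
    """Intake-labeled images not covered by any episode (min_images casualties)."""
    return [
        im
        for im in project.images
        if im.intake_label == 1 and not any(ep.contains(im.timestamp) for ep in episodes)
    ]


def images_in_episode(project: Project, episode: SDEEp) -> list[ImageRecord]:
    """All project images with ``start <= timestamp < end``, in time order."""
    if episode.start > project.end or episode.end < project.start:
        raise ValueError("episode does not belong to this project's day")
    return [im for im in project.images if episode.contains(im.timestamp)]


# ---------------------------------------------------------------------------
# review-efficiency metrics


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ReviewMetrics:
    """How much image review the sensor guidance saves.

    ``pct_reviewed`` and ``pct_reduction`` are exact (they sum to 100);
    the ``display_*`` properties apply the integer rounding used in reports.
    """

    total_images: int
    detected_images: int
    intake_labeled_images: int | None = None

    def __post_init__(self) -> None:
        if self.total_images <= 0:
            raise ZeroDivisionError("review metrics need at least one image")
        if not 0 <= self.detected_images <= self.total_images:
            raise ValidationError("detected image count outside [0, total]")

    @property
    def pct_reviewed(self) -> float:
        return 100.0 * self.detected_images / self.total_images

    @property
    def pct_reduction(self) -> float:
        return 100.0 - self.pct_reviewed

    @property
    def display_pct_reviewed(self) -> int:
        return round_half_away(self.pct_reviewed)

    @property
    def display_pct_reduction(self) -> int:
        return round_half_away(self.pct_reduction)

    @classmethod
    def from_counts(cls, total_images: int, detected_images: int) -> "ReviewMetrics":
        """Metrics straight from study-level totals (e.g. published counts)."""
        return cls(total_images=total_images, detected_images=detected_images)


def review_metrics(
    projects: list[Project], episodes: list[list[SDEEp]]
) -> ReviewMetrics:
    """Aggregate review burden over one or more participant-days.

    ``detected_images`` counts images falling inside episode boundaries —
    the images an annotator is guided to review; the count of individually
    intake-labeled images is carried alongside for comparison.
    """
    if not projects:
        raise ValueError("need at least one project")
    if len(projects) != len(episodes):
        raise ValueError("projects and episode lists must align")
    total = sum(len(p.images) for p in projects)
    detected = 0
    labeled = 0
    for project, eps in zip(projects, episodes):
        labeled += project.n_intake_labeled
        for im in project.images:
            if any(ep.contains(im.timestamp) for ep in eps):
                detected += 1
    return ReviewMetrics(
        total_images=total, detected_images=detected, intake_labeled_images=labeled
    )


# ---------------------------------------------------------------------------
# review verdicts


def mark_sdeep(episode: SDEEp, verdict: bool | str) -> SDEEp:
    """Record the annotator's verdict on an SDEEp; the last verdict wins."""
    if isinstance(verdict, bool):
        status = "true" if verdict else "false"
    else:
        status = str(verdict).casefold()
    if status not in ("true", "false"):
        raise ValueError(f"verdict must be true or false, got {verdict!r}")
    episode.status = status
    return episode


def sdeep_status_counts(episodes: list[SDEEp]) -> dict[str, int]:
    counts = {s: 0 for s in SDEEP_STATUSES}
    for ep in episodes:
        counts[ep.status] += 1
    return counts
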