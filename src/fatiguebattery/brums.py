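"""Brunel Mood Scale (BRUMS) representation, scoring and quality checks.

The BRUMS is a 24-item mood adjective checklist rated 0 ("not at all") to 4
("extremely").  The items partition into six subscales — anger, confusion,
depression, fatigue, tension, vigor — of four items each, so every subscale
score is an integer sum in 0..16.

The published item wording is licensed and is not shipped here: the default
item table uses synthetic placeholder labels (``item01`` .. ``item24``) with
an interleaved item-to-subscale assignment, and any user-supplied mapping
with the same 4-items-per-subscale structure can be passed to
:func:`score_brums` or loaded from CSV with :func:`load_item_map`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

SUBSCALES = ("anger", "confusion", "depression", "fatigue", "tension", "vigor")
N_ITEMS = 24
MAX_RATING = 4
MAX_SUBSCALE = 16
MIN_SECONDS_PER_ITEM = 1.0

UNIFORM_EXTREME = "UNIFORM_EXTREME"
TOO_FAST = "TOO_FAST"

#: Placeholder item table: 24 synthetic labels, subscales interleaved the way
#: mood checklists mix their items on the page.
DEFAULT_ITEM_MAP: dict[str, str] = {
    f"item{i + 1:02d}": SUBSCALES[i % len(SUBSCALES)] for i in range(N_ITEMS)
}


class InvalidFormError(ValueError):
    """The questionnaire response sheet is malformed."""


class InvalidMappingError(ValueError):
    """The item-to-subscale table is not a 4-per-subscale partition."""


@dataclass(frozen=True, slots=True)
class BrumsForm:
    """One completed questionnaire: labels in presentation order, ratings, timing."""

    item_order: tuple[str, ...]
    item_ratings: tuple[int, ...]
    completion_time_s: float

    def ratings_by_label(self) -> dict[str, int]:
        return dict(zip(self.item_order, self.item_ratings))


@dataclass(frozen=True, slots=True)
class SubscaleScores:
    anger: int
    confusion: int
    depression: int
    fatigue: int
    tension: int
    vigor: int

    def as_dict(self) -> dict[str, int]:
        return {s: getattr(self, s) for s in SUBSCALES}


def _validate_form(form: BrumsForm) -> None:
    if len(form.item_order) != N_ITEMS or len(form.item_ratings) != N_ITEMS:
        raise InvalidFormError(
            f"expected {N_ITEMS} items, got {len(form.item_order)} labels "
            f"and {len(form.item_ratings)} ratings"
        )
    if len(set(form.item_order)) != N_ITEMS:
        raise InvalidFormError("item labels must be unique")
    for label, r in zip(form.item_order, form.item_ratings):
        if not isinstance(r, (int,)) or not 0 <= r <= MAX_RATING:
            raise InvalidFormError(f"rating for {label!r} must be an integer in 0..4, got {r!r}")


def _validate_mapping(mapping: Mapping[str, str], labels: Sequence[str]) -> None:
    if set(mapping) != set(labels):
        raise InvalidMappingError("mapping labels do not match the form's items")
    counts: dict[str, int] = {}
    for sub in mapping.values():
        if sub not in SUBSCALES:
            raise InvalidMappingError(f"unknown subscale {sub!r}")
        counts[sub] = counts.get(sub, 0) + 1
    if any(counts.get(s, 0) != 4 for s in SUBSCALES):
        raise InvalidMappingError(
            f"each subscale needs exactly 4 items, got {counts}"
        )


def score_brums(
    form: BrumsForm, mapping: Mapping[str, str] = DEFAULT_ITEM_MAP
) -> SubscaleScores:
    """Sum the four item ratings of each subscale.

    Scoring is invariant to the presentation order of the items; each score
    is an integer in 0..16.
    """
    _validate_form(form)
    _validate_mapping(mapping, form.item_order)
    totals = {s: 0 for s in SUBSCALES}
    for label, rating in zip(form.item_order, form.item_ratings):
        totals[mapping[label]] += rating
    return SubscaleScores(**totals)


def brums_quality_flags(form: BrumsForm) -> set[str]:
    """Engagement flags used by participant exclusion.

    ``UNIFORM_EXTREME``: every item carries the same extreme rating (all 0 or
    all 4), the signature of a participant clicking through the form.
    ``TOO_FAST``: the form was completed in under one second per item (24 s).
    """
    flags: set[str] = set()
    ratings = form.item_ratings
    if ratings and (all(r == 0 for r in ratings) or all(r == MAX_RATING for r in ratings)):
        flags.add(UNIFORM_EXTREME)
    if form.completion_time_s < N_ITEMS * MIN_SECONDS_PER_ITEM:
        flags.add(TOO_FAST)
    return flags


def load_item_map(path: str | Path) -> dict[str, str]:
    """Read an item-to-subscale table from a two-column CSV (label, subscale)."""
    mapping: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"label", "subscale"} <= set(reader.fieldnames):
            raise InvalidMappingError("item map CSV needs 'label' and 'subscale' columns")
        for row in reader:
            mapping[row["label"]] = row["subscale"]
    _validate_mapping(mapping, list(mapping))
    return mapping
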