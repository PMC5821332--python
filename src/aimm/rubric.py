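"""The weighted MISS instrument: 50 regulatory indicators, optimal total 100.

The Midwifery Integration Scoring System (MISS) is a weighted composite
instrument scoring a US jurisdiction's regulatory environment for midwifery.
Each item offers a small set of ordered response options (e.g. "Prohibited"
... "Licensed"); the selected option contributes its point value to the
composite, and a jurisdiction answering every item at its most favourable
option scores exactly 100.

This module defines the instrument's data model, a YAML/JSON file dialect
with loader/writer, a validator that reports *every* invariant violation,
and :func:`derive_points`, which turns importance weights (0-4 Delphi scale)
and within-item favourability ranks into point values that sum to the
target total.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "DOMAINS",
    "MIDWIFE_TYPES",
    "ResponseOption",
    "RubricItem",
    "Rubric",
    "RubricError",
    "RubricParseError",
    "RubricValidationError",
    "load_rubric",
    "load_canonical_rubric",
    "write_rubric",
    "validate_rubric",
    "derive_points",
]

#: The seven regulatory domains of midwifery integration.
DOMAINS = (
    "scope of practice",
    "autonomy",
    "governance",
    "referral & medications access",
    "patient safety",
    "quality",
    "access across birth settings",
)

#: US midwifery credentials the instrument covers.
MIDWIFE_TYPES = ("CNM", "CM", "CPM")

#: Sum-to-target tolerance for rubrics with derived (computed) points.
DERIVED_TOL = 1e-9
#: Looser tolerance for hand-transcribed rubrics (rounding in transcription).
TRANSCRIBED_TOL = 0.5


class RubricError(Exception):
    """Base class for rubric errors."""


class RubricParseError(RubricError):
    """The file could not be parsed into the rubric dialect."""


class RubricValidationError(RubricError):
    """One or more instrument invariants are violated.

    Carries the full list of violations, not just the first.
    """

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            "rubric failed validation with %d violation(s):\n  - %s"
            % (len(self.violations), "\n  - ".join(self.violations))
        )


@dataclass(frozen=True)
class ResponseOption:
    """One answer option of a rubric item.

    ``raw_rank`` orders options by favourability (0 = most restrictive);
    ``points`` is the composite contribution when the option is selected.
    """

    code: str
    label: str
    raw_rank: int
    points: float


@dataclass
class RubricItem:
    """A single regulatory indicator with its ordered response options."""

    item_id: str
    stem: str
    domain: str
    midwife_types: tuple[str, ...]
    importance_weight: int
    options: list[ResponseOption]

    def max_points(self) -> float:
        return max(o.points for o in self.options)

    def min_points(self) -> float:
        return min(o.points for o in self.options)

    def option(self, code: str) -> ResponseOption:
        for o in self.options:
            if o.code == code:
                return o
        raise KeyError(f"item {self.item_id!r} has no option code {code!r}")

    def best_option(self) -> ResponseOption:
        return max(self.options, key=lambda o: (o.points, o.raw_rank))

    def worst_option(self) -> ResponseOption:
        return min(self.options, key=lambda o: (o.points, o.raw_rank))


@dataclass
class Rubric:
    """The full instrument.

    ``sum_tolerance`` controls how tightly the sum of per-item maxima must
    match ``target_total`` (tight for derived points, loose for
    hand-transcribed values).
    """

    version: str
    items: list[RubricItem]
    target_total: float = 100.0
    sum_tolerance: float = DERIVED_TOL

    def optimal_total(self) -> float:
        return sum(it.max_points() for it in self.items)

    def item(self, item_id: str) -> RubricItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"no item {item_id!r} in rubric")

    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]


# ---------------------------------------------------------------------------
# validation

def validate_rubric(rubric: Rubric) -> list[str]:
    """Check every instrument invariant; return all violations found.

    Returns an empty list iff the rubric is valid. Each violation message
    names the offending item and the rule broken.
    """
    v: list[str] = []
    seen: dict[str, int] = {}
    for pos, it in enumerate(rubric.items):
        if it.item_id in seen:
            v.append(
                f"duplicate item_id {it.item_id!r} at positions "
                f"{seen[it.item_id]} and {pos}"
            )
        else:
            seen[it.item_id] = pos
        if it.domain not in DOMAINS:
            v.append(f"item {it.item_id!r}: unknown domain {it.domain!r}")
        for mt in it.midwife_types:
            if mt not in MIDWIFE_TYPES:
                v.append(f"item {it.item_id!r}: unknown midwife type {mt!r}")
        if it.importance_weight not in (0, 1, 2, 3, 4):
            v.append(
                f"item {it.item_id!r}: importance_weight "
                f"{it.importance_weight!r} not in 0..4"
            )
        if len(it.options) < 2:
            v.append(f"item {it.item_id!r}: fewer than 2 response options")
        codes = [o.code for o in it.options]
        if len(set(codes)) != len(codes):
            v.append(f"item {it.item_id!r}: duplicate option codes")
        if it.options:
            if it.max_points() <= 0:
                v.append(f"item {it.item_id!r}: max option points not > 0")
            ordered = sorted(it.options, key=lambda o: o.raw_rank)
            for a, b in zip(ordered, ordered[1:]):
                if b.points < a.points:
                    v.append(
                        f"item {it.item_id!r}: points decrease from option "
                        f"{a.code!r} (rank {a.raw_rank}) to {b.code!r} "
                        f"(rank {b.raw_rank}); must be non-decreasing in "
                        "raw_rank"
                    )
            for o in it.options:
                if o.raw_rank < 0:
                    v.append(
                        f"item {it.item_id!r} option {o.code!r}: "
                        "negative raw_rank"
                    )
                if o.points < 0:
                    v.append(
                        f"item {it.item_id!r} option {o.code!r}: "
                        "negative points"
                    )
    if rubric.items:
        total = rubric.optimal_total()
        if abs(total - rubric.target_total) > rubric.sum_tolerance:
            v.append(
                f"optimal total {total!r} differs from target_total "
                f"{rubric.target_total!r} by more than tolerance "
                f"{rubric.sum_tolerance!r}"
            )
    else:
        v.append("rubric has no items")
    return v


def _require_valid(rubric: Rubric) -> Rubric:
    violations = validate_rubric(rubric)
    if violations:
        raise RubricValidationError(violations)
    return rubric


# ---------------------------------------------------------------------------
# point derivation

def derive_points(
    items: Iterable[RubricItem], target_total: float = 100.0
) -> Rubric:
    """Assign point values proportional to weight x favourability rank.

    point(i, k) = c * importance_weight_i * raw_rank_ik, with the constant c
    chosen so the per-item maxima sum exactly to ``target_total``:

        c = target_total / sum_i(importance_weight_i * max_k raw_rank_ik)

    The published instrument states that item scores are weighted and summed
    to an optimal 100 but not the weight-to-point mapping; this proportional
    convention is this package's explicit, documented choice. Rubric files
    may instead carry pre-computed point values directly.
    """
    items = list(items)
    denom = sum(
        it.importance_weight * max(o.raw_rank for o in it.options)
        for it in items
    )
    if denom <= 0:
        raise RubricError(
            "degenerate instrument: all importance_weight x max raw_rank "
            "products are zero"
        )
    c = target_total / denom
    new_items = [
        replace(
            it,
            options=[
                replace(o, points=c * it.importance_weight * o.raw_rank)
                for o in it.options
            ],
        )
        for it in items
    ]
    return _require_valid(
        Rubric(
            version="derived",
            items=new_items,
            target_total=target_total,
            sum_tolerance=DERIVED_TOL,
        )
    )


# ---------------------------------------------------------------------------
# file dialect (YAML or JSON)

def _parse_points(raw) -> float:
    # points are written as decimal strings for bit-exact round-trips
    return float(raw)


def _item_from_mapping(d: dict, where: str) -> RubricItem:
    try:
        options = [
            ResponseOption(
                code=str(o["code"]),
                label=str(o["label"]),
                raw_rank=int(o["raw_rank"]),
                points=_parse_points(o["points"]) if "points" in o else math.nan,
            )
            for o in d["options"]
        ]
        return RubricItem(
            item_id=str(d["id"]),
            stem=str(d["stem"]),
            domain=str(d["domain"]),
            midwife_types=tuple(d.get("midwife_types", MIDWIFE_TYPES)),
            importance_weight=int(d["weight"]),
            options=options,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise RubricParseError(f"malformed item at {where}: {exc!r}") from exc


def load_rubric(
    path: str | Path,
    sum_tolerance: float | None = None,
) -> Rubric:
    """Load and validate a rubric from a YAML or JSON file.

    Items may carry pre-computed ``points`` per option (as a transcription
    of the published instrument does) or omit them entirely, in which case
    points are derived from weights and ranks via :func:`derive_points`.
    ``sum_tolerance`` defaults to tight (1e-9) for derived rubrics and loose
    (0.5) for pre-pointed ones, and may be overridden for hand-transcribed
    files.

    Raises :class:`RubricParseError` on malformed files (naming the item)
    and :class:`RubricValidationError` listing every invariant violation.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            doc = json.loads(text)
        else:
            doc = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise RubricParseError(f"cannot parse {path.name}: {exc}") from exc
    if not isinstance(doc, dict) or "items" not in doc:
        raise RubricParseError(
            f"{path.name}: expected a mapping with top-level 'items'"
        )
    items = [
        _item_from_mapping(d, f"{path.name} items[{i}]")
        for i, d in enumerate(doc["items"])
    ]
    target = float(doc.get("target_total", 100.0))
    have_points = [
        all(not math.isnan(o.points) for o in it.options) for it in items
    ]
    if all(have_points):
        tol = TRANSCRIBED_TOL if sum_tolerance is None else sum_tolerance
        rubric = Rubric(
            version=str(doc.get("version", "unversioned")),
            items=items,
            target_total=target,
            sum_tolerance=tol,
        )
        return _require_valid(rubric)
    if any(have_points):
        bad = [it.item_id for it, hp in zip(items, have_points) if not hp]
        raise RubricParseError(
            f"{path.name}: items {bad} mix pointed and unpointed options; "
            "either all options carry points or none do"
        )
    rubric = derive_points(items, target_total=target)
    rubric.version = str(doc.get("version", "derived"))
    if sum_tolerance is not None:
        rubric.sum_tolerance = sum_tolerance
    return rubric


def write_rubric(rubric: Rubric, path: str | Path) -> None:
    """Write a rubric in the YAML/JSON dialect read by :func:`load_rubric`.

    Point values are serialized as shortest-round-trip decimal strings so
    that load(write(r)) reproduces them bit-exactly.
    """
    path = Path(path)
    doc = {
        "version": rubric.version,
        "target_total": rubric.target_total,
        "items": [
            {
                "id": it.item_id,
                "stem": it.stem,
                "domain": it.domain,
                "midwife_types": list(it.midwife_types),
                "weight": it.importance_weight,
                "options": [
                    {
                        "code": o.code,
                        "label": o.label,
                        "raw_rank": o.raw_rank,
                        "points": repr(o.points),
                    }
                    for o in it.options
                ],
            }
            for it in rubric.items
        ],
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    else:
        path.write_text(
            yaml.safe_dump(doc, sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )


def load_canonical_rubric() -> Rubric:
    """Load the packaged 50-item instrument.

    Six items (with their option labels and printed point values) are
    transcribed from the published sample-indicator table; the remaining 44
    are synthetic stand-ins — the full supplementary instrument is not
    publicly distributed — constructed so that the 50-item count and the
    optimal total of 100 hold exactly.
    """
    return load_rubric(
        Path(__file__).parent / "data" / "miss_rubric_synthetic.yaml",
        sum_tolerance=TRANSCRIBED_TOL,
    )
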