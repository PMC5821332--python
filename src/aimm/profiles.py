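"""Score jurisdiction regulatory profiles, rank them, assign quartiles.

A :class:`StateProfile` records which response option a jurisdiction
selects on each rubric item; scoring sums the selected options' points
into a composite (0-100 on the canonical instrument) with per-domain
subtotals. Ranking is competition-style descending; quartile categories
(very_low/low/moderate/high) follow the percentile bands 1-24th, 25-49th,
50-74th and 75-100th.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .rubric import Rubric

__all__ = [
    "JURISDICTIONS",
    "QUARTILE_LABELS",
    "StateProfile",
    "MissScore",
    "ScoringError",
    "score_profile",
    "rank_jurisdictions",
    "assign_quartiles",
    "quartile_labels_for",
    "read_profiles_csv",
    "write_profiles_csv",
    "write_scores_csv",
    "read_scores_csv",
]

log = logging.getLogger(__name__)

#: 50 US states plus the District of Columbia.
JURISDICTIONS = (
    "AL", "AK", "AZ", "AR", "CA", "CO", "CT", "DE", "DC", "FL", "GA", "HI",
    "ID", "IL", "IN", "IA", "KS", "KY", "LA", "ME", "MD", "MA", "MI", "MN",
    "MS", "MO", "MT", "NE", "NV", "NH", "NJ", "NM", "NY", "NC", "ND", "OH",
    "OK", "OR", "PA", "RI", "SC", "SD", "TN", "TX", "UT", "VT", "VA", "WA",
    "WV", "WI", "WY",
)

#: Quartile categories, lowest to highest integration.
QUARTILE_LABELS = ("very_low", "low", "moderate", "high")


class ScoringError(Exception):
    """Profile cannot be scored (missing responses, bad codes, ...)."""


@dataclass
class StateProfile:
    """One jurisdiction's selected response per rubric item.

    ``provenance`` optionally records, per item, whether the response came
    straight from statute or was adjusted by state regulatory experts to
    reflect on-the-ground implementation.
    """

    jurisdiction: str
    responses: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)

    def validate(self, rubric: Rubric, strict_codes: bool = False) -> list[str]:
        """Return violations; ``strict_codes`` also enforces the fixed
        51-jurisdiction code set (real-data mode)."""
        v = []
        if strict_codes and self.jurisdiction not in JURISDICTIONS:
            v.append(f"unknown jurisdiction code {self.jurisdiction!r}")
        for item_id, code in self.responses.items():
            try:
                rubric.item(item_id).option(code)
            except KeyError as exc:
                v.append(str(exc))
        return v


@dataclass
class MissScore:
    """Composite score for one jurisdiction; rank/quartile set later."""

    jurisdiction: str
    total: float
    by_domain: dict[str, float]
    rank: int | None = None
    quartile: str | None = None


def score_profile(
    rubric: Rubric,
    profile: StateProfile,
    *,
    missing: str = "strict",
) -> MissScore:
    """Sum the points of the selected option on every rubric item.

    ``missing='strict'`` (default) raises :class:`ScoringError` listing all
    rubric items the profile leaves unanswered; ``missing='impute_lowest'``
    scores each unanswered item at its minimum-point option — the
    conservative reading that an unverifiable condition is the most
    restrictive — logging a warning per imputed item.
    """
    if missing not in ("strict", "impute_lowest"):
        raise ValueError(f"unknown missing policy {missing!r}")
    absent = [it.item_id for it in rubric.items
              if it.item_id not in profile.responses]
    if absent and missing == "strict":
        raise ScoringError(
            f"profile {profile.jurisdiction!r} missing responses for "
            f"{len(absent)} item(s): {absent}"
        )
    total = 0.0
    by_domain: dict[str, float] = {}
    for it in rubric.items:
        if it.item_id in profile.responses:
            opt = it.option(profile.responses[it.item_id])
        else:
            opt = it.worst_option()
            log.warning(
                "jurisdiction %s: item %s unanswered, imputing lowest "
                "option %r (%g points)",
                profile.jurisdiction, it.item_id, opt.code, opt.points,
            )
        total += opt.points
        by_domain[it.domain] = by_domain.get(it.domain, 0.0) + opt.points
    return MissScore(
        jurisdiction=profile.jurisdiction, total=total, by_domain=by_domain
    )


def rank_jurisdictions(scores: Sequence[MissScore]) -> list[MissScore]:
    """Order scores descending and assign competition ranks.

    Tied totals share the minimum rank of the tied block ("1224" ranking);
    within a tie, display order is alphabetical by jurisdiction code.
    """
    if not scores:
        raise ScoringError("no scores to rank")
    seen = set()
    for s in scores:
        if s.jurisdiction in seen:
            raise ScoringError(f"duplicate jurisdiction {s.jurisdiction!r}")
        seen.add(s.jurisdiction)
    ordered = sorted(scores, key=lambda s: (-s.total, s.jurisdiction))
    out = []
    for pos, s in enumerate(ordered):
        if pos > 0 and s.total == ordered[pos - 1].total:
            rank = out[-1].rank
        else:
            rank = pos + 1
        out.append(replace(s, rank=rank))
    return out


def quartile_labels_for(values: Sequence[float]) -> list[str]:
    """Quartile category per value using the strictly-below percentile.

    p = 100 * (# values strictly below) / n; bands are very_low (p < 25),
    low (25 <= p < 50), moderate (50 <= p < 75), high (p >= 75). On n
    distinct values divisible by 4 this yields four equal groups.
    """
    n = len(values)
    if n < 4:
        raise ScoringError(f"need >= 4 values for quartiles, got {n}")
    labels = []
    for v in values:
        p = 100.0 * sum(1 for w in values if w < v) / n
        if p < 25:
            labels.append("very_low")
        elif p < 50:
            labels.append("low")
        elif p < 75:
            labels.append("moderate")
        else:
            labels.append("high")
    return labels


def assign_quartiles(scores: Sequence[MissScore]) -> list[MissScore]:
    """Attach a quartile category to every score (requires >= 4 scores)."""
    labels = quartile_labels_for([s.total for s in scores])
    return [replace(s, quartile=q) for s, q in zip(scores, labels)]


# ---------------------------------------------------------------------------
# CSV dialects

def read_profiles_csv(path: str | Path) -> list[StateProfile]:
    """Read the long-format profiles CSV:
    ``jurisdiction,item_id,option_code[,provenance]``."""
    df = pd.read_csv(path, dtype=str)
    required = {"jurisdiction", "item_id", "option_code"}
    if not required.issubset(df.columns):
        raise ScoringError(
            f"profiles CSV {path} missing columns "
            f"{sorted(required - set(df.columns))}"
        )
    profiles = []
    for code, grp in df.groupby("jurisdiction", sort=True):
        responses = dict(zip(grp["item_id"], grp["option_code"]))
        prov = {}
        if "provenance" in grp.columns:
            prov = {
                i: p for i, p in zip(grp["item_id"], grp["provenance"])
                if isinstance(p, str) and p
            }
        profiles.append(StateProfile(str(code), responses, prov))
    return profiles


def write_profiles_csv(
    profiles: Iterable[StateProfile], path: str | Path
) -> None:
    rows = [
        {
            "jurisdiction": p.jurisdiction,
            "item_id": item_id,
            "option_code": code,
            "provenance": p.provenance.get(item_id, ""),
        }
        for p in profiles
        for item_id, code in p.responses.items()
    ]
    pd.DataFrame(
        rows, columns=["jurisdiction", "item_id", "option_code", "provenance"]
    ).to_csv(path, index=False)


def write_scores_csv(scores: Sequence[MissScore], path: str | Path) -> None:
    """Write ``jurisdiction,total,rank,quartile`` plus one column per
    domain subtotal (domains in canonical order of first appearance)."""
    domains: list[str] = []
    for s in scores:
        for d in s.by_domain:
            if d not in domains:
                domains.append(d)
    rows = []
    for s in scores:
        row = {
            "jurisdiction": s.jurisdiction,
            "total": s.total,
            "rank": s.rank,
            "quartile": s.quartile,
        }
        for d in domains:
            row[f"domain:{d}"] = s.by_domain.get(d, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scores_csv(path: str | Path) -> list[MissScore]:
    df = pd.read_csv(path)
    scores = []
    for _, row in df.iterrows():
        by_domain = {
            c[len("domain:"):]: float(row[c])
            for c in df.columns if c.startswith("domain:")
        }
        scores.append(
            MissScore(
                jurisdiction=str(row["jurisdiction"]),
                total=float(row["total"]),
                by_domain=by_domain,
                rank=None if pd.isna(row.get("rank")) else int(row["rank"]),
                quartile=(
                    None if pd.isna(row.get("quartile"))
                    else str(row["quartile"])
                ),
            )
        )
    return scores
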