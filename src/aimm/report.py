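"""Report-card assembly: per-jurisdiction scores, access metrics, outcome
rates and extreme-quartile flags.

The report card is a static export of what the interactive integration
maps display: each jurisdiction's composite score, rank and quartile
shade, workforce density and access proportions, and a per-outcome flag
marking jurisdictions in the extreme quartiles — green (favourable) for
the lowest quartile of an adverse rate or the highest quartile of a
favourable rate, red (unfavourable) for the converse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .profiles import MissScore, quartile_labels_for
from .workforce import StateVitalRecord, access_proportions, density_per_1000

__all__ = ["OUTCOME_DIRECTIONS", "ReportCard", "ReportError",
           "build_report_card"]

#: Whether a high rate of the outcome is adverse or favourable. Editable:
#: pass a custom mapping to build_report_card for additional outcomes.
OUTCOME_DIRECTIONS: dict[str, str] = {
    "cesarean": "adverse",
    "induction": "adverse",
    "preterm_birth": "adverse",
    "low_birth_weight": "adverse",
    "neonatal_mortality": "adverse",
    "svb": "favourable",
    "vbac": "favourable",
    "breastfeeding_at_birth": "favourable",
    "breastfeeding_6mo": "favourable",
}


class ReportError(Exception):
    pass


@dataclass
class ReportCard:
    """Tabular report card; ``table`` has one row per jurisdiction."""

    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        doc = {
            row["jurisdiction"]: {
                k: v for k, v in row.items() if k != "jurisdiction"
            }
            for row in self.table.to_dict(orient="records")
        }
        Path(path).write_text(
            json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8"
        )


def build_report_card(
    scores: Sequence[MissScore],
    records: Iterable[StateVitalRecord],
    directions: Mapping[str, str] | None = None,
) -> ReportCard:
    """Join scores with vital records and flag extreme quartiles.

    Every outcome present in the records must have a direction entry
    ('adverse' or 'favourable'); an unknown outcome raises, asking for
    one. Flags are 'favourable', 'unfavourable' or '' (middle quartiles).
    """
    directions = dict(OUTCOME_DIRECTIONS if directions is None else directions)
    by_state = {r.jurisdiction: r for r in records}
    joined = [(s, by_state[s.jurisdiction]) for s in scores
              if s.jurisdiction in by_state]
    if not joined:
        raise ReportError("no jurisdictions in common between scores and "
                          "vital records")
    outcome_names = sorted({o for _, r in joined for o in r.outcomes})
    for name in outcome_names:
        if directions.get(name) not in ("adverse", "favourable"):
            raise ReportError(
                f"no direction entry for outcome {name!r}; add "
                "'adverse' or 'favourable' to the directions table"
            )

    rows = []
    for s, r in joined:
        props = access_proportions(r)
        row = {
            "jurisdiction": s.jurisdiction,
            "miss_total": s.total,
            "miss_rank": s.rank,
            "miss_quartile": s.quartile,
            "density_CNM_CM": density_per_1000(
                r.midwife_counts.get("CNM_CM", 0), r.births_total
            ),
            "density_CPM_other": density_per_1000(
                r.midwife_counts.get("CPM_other", 0), r.births_total
            ),
            "pct_midwife_all_settings":
                100.0 * props[("all_midwife", "all_settings")],
            "pct_midwife_community":
                100.0 * props[("all_midwife", "community")],
        }
        for name in outcome_names:
            row[name] = r.outcomes.get(name)
        rows.append(row)
    df = pd.DataFrame(rows)

    for name in outcome_names:
        quartiles = quartile_labels_for(df[name].tolist())
        adverse = directions[name] == "adverse"
        flags = []
        for q in quartiles:
            if (adverse and q == "very_low") or (not adverse and q == "high"):
                flags.append("favourable")
            elif (adverse and q == "high") or (not adverse and q == "very_low"):
                flags.append("unfavourable")
            else:
                flags.append("")
        df[f"{name}_quartile"] = quartiles
        df[f"{name}_flag"] = flags
    return ReportCard(table=df)
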