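"""Midwifery workforce density and consumer-access metrics.

Density is midwives per 1000 live births, computed separately for the
CNM/CM group and for CPMs and other direct-entry midwives. Access is the
proportion of all births attended by each midwife group in each setting
(hospital, home, freestanding birth center); "community" births are home
plus birth-center births.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CREDENTIAL_GROUPS",
    "SETTINGS",
    "OUTCOME_NAMES",
    "StateVitalRecord",
    "VitalsError",
    "density_per_1000",
    "access_proportions",
    "community_birth_change",
    "read_vitals_csv",
    "write_vitals_csv",
]

#: Midwife credential bins used on US birth certificates.
CREDENTIAL_GROUPS = ("CNM_CM", "CPM_other")
#: Birth settings.
SETTINGS = ("hospital", "home", "birth_center")

#: Outcome rate columns carried per jurisdiction-year. All are percentages
#: of births except neonatal_mortality (deaths within 27 days per 1000
#: live births).
OUTCOME_NAMES = (
    "svb",                    # spontaneous vaginal birth %
    "vbac",                   # vaginal birth after cesarean %
    "induction",              # labour induction %
    "preterm_birth",          # birth before 37 weeks %
    "low_birth_weight",       # < 2500 g %
    "cesarean",               # all cesarean sections %
    "neonatal_mortality",     # deaths <= 27 days per 1000 births
    "breastfeeding_at_birth", # exclusive breastfeeding at birth %
    "breastfeeding_6mo",      # breastfeeding at 6 months %
)


class VitalsError(Exception):
    """Inconsistent or degenerate vital/workforce data."""


@dataclass
class StateVitalRecord:
    """Births, workforce and outcome rates for one jurisdiction-year."""

    jurisdiction: str
    year: int
    births_total: int
    midwife_counts: dict[str, int]
    births_by_attendant_setting: dict[tuple[str, str], int]
    pct_black_births: float
    outcomes: dict[str, float]
    community_birth_rate: float = 0.0

    def validate(self) -> list[str]:
        v = []
        if self.births_total < 0:
            v.append(f"{self.jurisdiction}: negative births_total")
        for g, c in self.midwife_counts.items():
            if c < 0:
                v.append(f"{self.jurisdiction}: negative count for {g}")
        cell_sum = sum(self.births_by_attendant_setting.values())
        if cell_sum > self.births_total:
            v.append(
                f"{self.jurisdiction}: attendant-setting births {cell_sum} "
                f"exceed total {self.births_total}"
            )
        if not 0 <= self.pct_black_births <= 100:
            v.append(f"{self.jurisdiction}: pct_black_births out of [0, 100]")
        return v


def density_per_1000(midwife_count: int, births_total: int) -> float:
    """Midwives per 1000 live births: count / births x 1000."""
    if births_total <= 0:
        raise VitalsError(
            f"density undefined for births_total={births_total}"
        )
    return midwife_count / births_total * 1000.0


def access_proportions(record: StateVitalRecord) -> dict:
    """Per-(credential group, setting) birth proportions plus aggregates.

    Returns a mapping with one key per (group, setting) cell and two
    aggregate keys: ``("all_midwife", "all_settings")`` — all
    midwife-attended births in any location — and
    ``("all_midwife", "community")`` — midwife-led births at home or in a
    birth center.
    """
    if record.births_total <= 0:
        raise VitalsError(
            f"{record.jurisdiction}: proportions undefined for "
            f"births_total={record.births_total}"
        )
    cells = record.births_by_attendant_setting
    if sum(cells.values()) > record.births_total:
        raise VitalsError(
            f"{record.jurisdiction}: attendant-setting births exceed "
            "births_total"
        )
    out = {
        (g, s): cells.get((g, s), 0) / record.births_total
        for g in CREDENTIAL_GROUPS
        for s in SETTINGS
    }
    out[("all_midwife", "all_settings")] = sum(
        out[(g, s)] for g in CREDENTIAL_GROUPS for s in SETTINGS
    )
    out[("all_midwife", "community")] = sum(
        out[(g, s)] for g in CREDENTIAL_GROUPS for s in ("home", "birth_center")
    )
    return out


def community_birth_change(rate_t0: float, rate_t1: float) -> float:
    """Percent change in the community-birth rate between two years:
    100 x (rate_t1 - rate_t0) / rate_t0."""
    if rate_t0 <= 0:
        raise VitalsError(f"percent change undefined for rate_t0={rate_t0}")
    return 100.0 * (rate_t1 - rate_t0) / rate_t0


# ---------------------------------------------------------------------------
# CSV dialect: one row per jurisdiction-year.
#
# Columns: jurisdiction, year, births_total, midwives_CNM_CM,
# midwives_CPM_other, births_<group>_<setting> (6 columns),
# pct_black_births, one column per OUTCOME_NAMES entry,
# community_birth_rate.

def _setting_col(group: str, setting: str) -> str:
    return f"births_{group}_{setting}"


def write_vitals_csv(
    records: Iterable[StateVitalRecord], path: str | Path
) -> None:
    rows = []
    for r in records:
        row = {
            "jurisdiction": r.jurisdiction,
            "year": r.year,
            "births_total": r.births_total,
        }
        for g in CREDENTIAL_GROUPS:
            row[f"midwives_{g}"] = r.midwife_counts.get(g, 0)
        for g in CREDENTIAL_GROUPS:
            for s in SETTINGS:
                row[_setting_col(g, s)] = r.births_by_attendant_setting.get(
                    (g, s), 0
                )
        row["pct_black_births"] = r.pct_black_births
        for name in OUTCOME_NAMES:
            row[name] = r.outcomes.get(name, float("nan"))
        row["community_birth_rate"] = r.community_birth_rate
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_vitals_csv(path: str | Path) -> list[StateVitalRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            StateVitalRecord(
                jurisdiction=str(row["jurisdiction"]),
                year=int(row["year"]),
                births_total=int(row["births_total"]),
                midwife_counts={
                    g: int(row[f"midwives_{g}"]) for g in CREDENTIAL_GROUPS
                },
                births_by_attendant_setting={
                    (g, s): int(row[_setting_col(g, s)])
                    for g in CREDENTIAL_GROUPS
                    for s in SETTINGS
                },
                pct_black_births=float(row["pct_black_births"]),
                outcomes={
                    name: float(row[name])
                    for name in OUTCOME_NAMES
                    if name in df.columns
                },
                community_birth_rate=float(row["community_birth_rate"]),
            )
        )
    bad = [v for r in records for v in r.validate()]
    if bad:
        raise VitalsError("; ".join(bad))
    return records
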