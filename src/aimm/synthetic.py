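"""Synthetic jurisdiction generator for end-to-end pipeline testing.

The real state response profiles behind the integration scores, and the
vital-statistics extracts they were correlated with, are not publicly
distributable. This module therefore generates complete synthetic inputs
— regulatory profiles, scores and jurisdiction-year vital records — from
a latent integration level θ_j ∈ [0, 1] per jurisdiction:

* item responses follow a latent-threshold (cumulative-link) rule whose
  probability of more favourable options rises monotonically in θ_j with
  configurable steepness, so the composite score tracks θ;
* midwife workforce counts are Poisson with mean proportional to θ_j and
  the birth cohort; midwife-attended and community-birth proportions rise
  linearly in θ_j;
* outcome rates follow the two-block generating equation
  ``outcome = intercept + beta_black · pct_black + beta_miss · (MISS/100) + ε``
  with Gaussian noise, clamped to the outcome's valid range (clamping
  logged) — mirroring the hierarchical regression the analysis fits.

Default parameters describe a 51-jurisdiction study with outcome levels
and dispersions in the range of US state-level statistics; effect sizes
default to a variance decomposition of roughly 40% ethnicity composition,
10% integration and 50% noise, the regime the ecological analysis probes.
Everything is deterministic given (seed, config), with separate
sub-streams for the profile and vitals blocks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .profiles import JURISDICTIONS, MissScore, StateProfile
from .rubric import Rubric
from .workforce import CREDENTIAL_GROUPS, OUTCOME_NAMES, StateVitalRecord

__all__ = [
    "OutcomeSpec",
    "SimConfig",
    "default_outcome_specs",
    "jurisdiction_codes",
    "draw_latent",
    "simulate_profiles",
    "simulate_vitals",
    "write_sim_sidecar",
]

log = logging.getLogger(__name__)

# sd of Beta(2, 10) x 100, the default % Black births distribution
_BLACK_SD = 100.0 * math.sqrt(2 * 10 / ((2 + 10) ** 2 * (2 + 10 + 1)))
# approximate sd of MISS/100 when theta ~ Beta(2, 2) and discrimination
# is moderate (the composite closely tracks theta)
_MISS_FRAC_SD = 0.21


@dataclass
class OutcomeSpec:
    """Generating-equation parameters for one outcome rate."""

    intercept: float
    beta_black: float   # change per percentage point of Black births
    beta_miss: float    # change per unit of MISS/100 (i.e. 0 -> 1)
    noise_sd: float
    lo: float = 0.0
    hi: float = 100.0


def _spec(
    intercept: float, sd_total: float, direction: int,
    lo: float = 0.0, hi: float = 100.0,
    share_black: float = 0.40, share_miss: float = 0.10,
) -> OutcomeSpec:
    share_noise = 1.0 - share_black - share_miss
    return OutcomeSpec(
        intercept=intercept,
        # adverse outcomes (direction -1) rise with % Black births and
        # fall with integration; favourable outcomes the converse
        beta_black=-direction * math.sqrt(share_black) * sd_total / _BLACK_SD,
        beta_miss=direction * math.sqrt(share_miss) * sd_total / _MISS_FRAC_SD,
        noise_sd=math.sqrt(share_noise) * sd_total,
        lo=lo, hi=hi,
    )


def default_outcome_specs() -> dict[str, OutcomeSpec]:
    """Outcome configurations at US state-level magnitudes.

    Intercepts and total SDs approximate 2014 state-level marginals;
    directions encode that integration is favourable (raises spontaneous
    vaginal birth, VBAC, breastfeeding; lowers intervention and adverse
    newborn outcomes) while a larger % of Black births associates with
    worse outcomes, mirroring documented disparities.
    """
    return {
        "svb":                   _spec(35.0, 4.0, +1),
        "vbac":                  _spec(11.0, 3.0, +1),
        "induction":             _spec(24.0, 4.0, -1),
        "preterm_birth":         _spec(9.5, 1.2, -1),
        "low_birth_weight":      _spec(8.0, 1.2, -1),
        "cesarean":              _spec(32.0, 3.5, -1),
        "neonatal_mortality":    _spec(4.0, 1.0, -1, hi=1000.0),
        "breastfeeding_at_birth": _spec(80.0, 8.0, +1),
        "breastfeeding_6mo":     _spec(50.0, 8.0, +1),
    }


@dataclass
class SimConfig:
    """Full configuration of the synthetic study."""

    n_jurisdictions: int = 51
    seed: int = 0
    #: latent integration distribution: ("beta", a, b) or ("fixed", value)
    latent_dist: tuple = ("beta", 2.0, 2.0)
    #: steepness of the ordered-categorical response rule
    item_discrimination: float = 6.0
    #: % Black births distribution: ("beta", a, b), scaled to [0, 100]
    black_dist: tuple = ("beta", 2.0, 10.0)
    #: expected midwives per 1000 births at theta = 1, per credential group
    workforce_rate: dict[str, float] = field(
        default_factory=lambda: {"CNM_CM": 3.0, "CPM_other": 1.0}
    )
    births_range: tuple[float, float] = (6000.0, 500000.0)
    #: proportion of births midwife-attended in hospital at theta = 1
    hospital_midwife_slope: float = 0.18
    #: proportion of community (home + birth-center) births at theta = 1
    community_slope: float = 0.035
    outcomes: dict[str, OutcomeSpec] = field(
        default_factory=default_outcome_specs
    )
    year: int = 2014
    target_total: float = 100.0
    #: optional separate seed for the vitals block (defaults to `seed`)
    vitals_seed: int | None = None

    def __post_init__(self):
        if self.n_jurisdictions < 4:
            raise ValueError("need at least 4 jurisdictions")
        for name, spec in self.outcomes.items():
            if spec.noise_sd < 0:
                raise ValueError(f"outcome {name}: negative noise_sd")


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def jurisdiction_codes(n: int) -> list[str]:
    """The 51 real jurisdiction codes, extended with synthetic S## codes
    when a larger simulated panel is requested."""
    codes = list(JURISDICTIONS[: min(n, len(JURISDICTIONS))])
    codes += [f"S{i:03d}" for i in range(len(codes), n)]
    return codes


def draw_latent(config: SimConfig) -> np.ndarray:
    """Latent integration levels θ (one per jurisdiction), on the profile
    sub-stream so profiles and vitals can be varied independently."""
    rng = _rng(config.seed, 0)
    kind, *params = config.latent_dist
    n = config.n_jurisdictions
    if kind == "beta":
        a, b = params
        return rng.beta(a, b, size=n)
    if kind == "fixed":
        return np.full(n, float(params[0]))
    raise ValueError(f"unknown latent_dist {config.latent_dist!r}")


def simulate_profiles(config: SimConfig, rubric: Rubric) -> list[StateProfile]:
    """Draw item responses from the latent-threshold rule.

    For an item with K options (ordered by favourability rank) the cut
    points are k/K for k = 1..K-1; jurisdiction j selects the option whose
    band contains u = θ_j + ε/a, with ε standard logistic and a the item
    discrimination. As a → ∞ the response becomes deterministic in θ_j;
    for any finite a the probability of more favourable options is
    strictly increasing in θ_j.
    """
    theta = draw_latent(config)
    rng = _rng(config.seed, 1)
    n = config.n_jurisdictions
    codes = jurisdiction_codes(n)
    a = config.item_discrimination
    if a <= 0:
        raise ValueError("item_discrimination must be > 0")
    responses: list[dict[str, str]] = [{} for _ in range(n)]
    for item in rubric.items:
        opts = sorted(item.options, key=lambda o: (o.raw_rank, o.points))
        k = len(opts)
        cuts = np.arange(1, k) / k
        u = theta + rng.logistic(0.0, 1.0, size=n) / a
        idx = (u[:, None] > cuts[None, :]).sum(axis=1)
        for j in range(n):
            responses[j][item.item_id] = opts[idx[j]].code
    return [
        StateProfile(jurisdiction=codes[j], responses=responses[j],
                     provenance={})
        for j in range(n)
    ]


def simulate_vitals(
    config: SimConfig, scores: Sequence[MissScore]
) -> list[StateVitalRecord]:
    """Generate jurisdiction-year vital records from composite scores.

    The integration level entering the workforce/access equations is the
    scaled composite θ̂ = total / target_total; outcomes follow the
    two-block generating equation with independent Gaussian noise.
    Values falling outside an outcome's valid range are clamped and the
    clamping is logged (a warning recommends re-parameterising when more
    than 10% of draws clamp).
    """
    seed = config.seed if config.vitals_seed is None else config.vitals_seed
    rng = _rng(seed, 2)
    n = len(scores)
    theta_hat = np.array([s.total / config.target_total for s in scores])
    lo, hi = config.births_range
    births = np.exp(
        rng.uniform(math.log(lo), math.log(hi), size=n)
    ).astype(int)
    a, b = config.black_dist[1:]
    black = rng.beta(a, b, size=n) * 100.0

    # workforce and access
    counts = {
        g: rng.poisson(config.workforce_rate[g] * theta_hat * births / 1000.0)
        for g in CREDENTIAL_GROUPS
    }
    p_hosp = np.clip(
        config.hospital_midwife_slope * theta_hat
        + rng.normal(0.0, 0.01, size=n),
        0.0, 0.6,
    )
    p_comm = np.clip(
        config.community_slope * theta_hat + rng.normal(0.0, 0.004, size=n),
        0.0, 0.2,
    )
    hosp = np.round(p_hosp * births).astype(int)
    home = np.round(p_comm * births * 2 / 3).astype(int)
    bc = np.round(p_comm * births * 1 / 3).astype(int)
    # hospital midwifery is predominantly CNM/CM; home births predominantly
    # CPM and other direct-entry midwives
    split = {"hospital": 0.9, "home": 0.25, "birth_center": 0.5}
    setting_counts = {"hospital": hosp, "home": home, "birth_center": bc}

    # outcomes
    out_draws: dict[str, np.ndarray] = {}
    for name, spec in config.outcomes.items():
        raw = (
            spec.intercept
            + spec.beta_black * black
            + spec.beta_miss * theta_hat
            + rng.normal(0.0, spec.noise_sd, size=n)
        )
        clamped = np.clip(raw, spec.lo, spec.hi)
        n_clamped = int((clamped != raw).sum())
        if n_clamped:
            log.warning(
                "outcome %s: clamped %d/%d draws to [%g, %g]",
                name, n_clamped, n, spec.lo, spec.hi,
            )
            if n_clamped > 0.1 * n:
                log.warning(
                    "outcome %s: more than 10%% of draws clamped; consider "
                    "re-parameterising intercept/noise", name,
                )
        out_draws[name] = clamped

    records = []
    for j, s in enumerate(scores):
        cells = {}
        for setting, tot in setting_counts.items():
            cnm = int(round(split[setting] * tot[j]))
            cells[("CNM_CM", setting)] = cnm
            cells[("CPM_other", setting)] = int(tot[j]) - cnm
        records.append(
            StateVitalRecord(
                jurisdiction=s.jurisdiction,
                year=config.year,
                births_total=int(births[j]),
                midwife_counts={g: int(counts[g][j]) for g in CREDENTIAL_GROUPS},
                births_by_attendant_setting=cells,
                pct_black_births=float(black[j]),
                outcomes={
                    name: float(out_draws[name][j]) for name in config.outcomes
                },
                community_birth_rate=float(
                    100.0 * (home[j] + bc[j]) / births[j]
                ),
            )
        )
    return records


def write_sim_sidecar(config: SimConfig, path: str | Path) -> None:
    """Record the full config and seed alongside emitted CSVs."""
    doc = dataclasses.asdict(config)
    doc["latent_dist"] = list(doc["latent_dist"])
    doc["black_dist"] = list(doc["black_dist"])
    doc["births_range"] = list(doc["births_range"])
    Path(path).write_text(
        json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8"
    )
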