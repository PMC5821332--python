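# Methods

## The instrument

The Midwifery Integration Scoring System (MISS) is a 50-item weighted
composite over seven regulatory domains (scope of practice, autonomy,
governance, referral & medications access, patient safety, quality,
access across birth settings). Each item presents ordered response
options describing progressively more favourable regulatory conditions;
the selected option contributes its point value, and the per-item maxima
sum to exactly 100, so a composite score is interpretable as "percent of
a fully integrated regulatory environment".

The published description of the instrument states that item-level
scores are weighted (on a 0–4 importance scale) and summed to an optimal
100, but not the weight-to-point mapping, and the full supplementary
item table is not publicly distributable. Two consequences for this
package:

1. **Point derivation.** `derive_points` fixes an explicit proportional
   convention, `points_ik = c · w_i · r_ik` with
   `c = target / Σ_i w_i · max_k r_ik`. This is the package's own
   choice; it is scale-invariant in the raw ranks and reproduces the
   sum-to-target invariant exactly. Rubric files may alternatively carry
   pre-computed point values (as a transcription of the published
   instrument would), in which case only the sum-to-target invariant is
   enforced — tolerance 1e-9 for derived rubrics, 0.5 for
   hand-transcribed ones (rounding), both configurable.
2. **The packaged rubric is partly synthetic.** Six items are
   transcribed verbatim (stems, option labels, printed point values)
   from the published sample-indicator table; the remaining 44 are
   plausible synthetic stand-ins whose maxima (16×1 + 20×2 + 8×3 = 80)
   complete the optimal total of 100. The file is named
   `miss_rubric_synthetic.yaml` to make this explicit. Structural
   claims (50 items, optimal 100) are exact; no claim is made that
   synthetic item content matches the unpublished supplement.

Items applying to several credentials (CNM/CM/CPM) are scored once;
`midwife_types` is metadata, because the study design reports a single
composite per jurisdiction.

## Scoring, ranking, quartiles

Missing responses are a hard error by default; an `impute_lowest` mode
scores unanswered items at their minimum-point option (the conservative
reading that an unverifiable condition is the most restrictive), logging
each imputation. Ranking is competition ranking ("1224") on descending
totals with alphabetical display order within ties — the engine must
define tie behaviour even though real score sets rarely tie.

Quartile categories use the percentile `p = 100 · #{strictly below}/n`
with bands very_low (p < 25), low (25–49), moderate (50–74), high
(p ≥ 75). The source material specifies the bands but not the percentile
estimator; the strictly-below convention yields four equal groups on any
distinct-valued set with n divisible by 4, and ties share a band.
Requires n ≥ 4.

## Workforce and access metrics

Density is `midwives / births × 1000`, separately for CNMs/CMs and for
CPMs plus other direct-entry midwives (the two bins available on US
birth certificates). Access is the proportion of all births attended by
each group in each of hospital, home and birth-center settings;
"community" means home + birth center. Community-birth change between
two years is percent change on rates, `100·(r₁ − r₀)/r₀`, undefined at
r₀ = 0.

## Inference

**Normality gate.** Shapiro–Wilk (delegated to `scipy.stats.shapiro`),
normal iff p > 0.05. In state-level maternity data, composite scores
tend to pass while outcome rates do not, which motivates rank
correlation for the exposure–outcome matrix.

**Spearman's ρ** is implemented directly as the Pearson correlation of
average ranks (ties get the mean of the ranks they span), with a
two-tailed p from `t = ρ√((n−2)/(1−ρ²))` on n−2 df and p = 0 at ρ = ±1.
Implementing it by hand (rather than calling `scipy.stats.spearmanr`,
which serves as an independent cross-check in the tests) pins down tie
handling and lets the test suite demand exact agreement with a
definition-based rational-arithmetic oracle. An exact permutation
p-value is available for n ≤ 8; beyond that the enumeration cost is
disproportionate for a convenience option (the t approximation is the
default at every n).

The correlation table crosses three exposures — composite score, % of
births midwife-attended in hospital, % midwife-led community births —
with the outcome list, joining scores and vital records on jurisdiction
with pairwise-complete deletion per cell (n recorded per cell; < 3
complete pairs is an error naming the cell). Stars at two-tailed 0.05
and 0.01. No multiple-testing correction is applied, matching the
analysis design this mirrors; regressions are unweighted across
jurisdictions, and all jurisdictions present in the join (including DC)
enter each analysis.

**Hierarchical regression.** Two nested OLS fits — block 1 (% Black
births), then block 1 + block 2 (integration score, entered raw, not as
quartiles) — with

    F_change = (ΔR²/q) / ((1 − R²_full)/(n − p_full − 1)),

q the number of block-2 columns, tested on F(q, n − p_full − 1).
Listwise deletion. OLS goes through a rank-checked least-squares solve:
rank-deficient designs raise rather than silently pseudo-inverting, with
one deliberate exception — when block 2 spans nothing beyond block 1
(e.g. a duplicated predictor) the nested models coincide and the
increment is defined as zero (F = 0, p = 1). A numerical guard clamps
R²_full to ≥ R²_block1 (float epsilon only; adding predictors cannot
reduce R²). Residual diagnostics report the Shapiro–Wilk p of
standardized residuals and the fitted–residual correlation (zero to
machine precision by OLS orthogonality when an intercept is present).

## Synthetic data generator

The generator emulates the study conditions: 51 jurisdictions (50 states
+ DC) by default, each with a latent integration level θ_j ~ Beta(2, 2)
on [0, 1].

* **Item responses** follow a latent-threshold (cumulative-link) rule:
  for an item with K options the cuts are k/K, and the selected option
  is the band containing `u = θ_j + ε/a` with ε standard logistic and
  `a` the item discrimination (default 6, "moderate": the composite then
  correlates with θ at ρ > 0.95). As a → ∞ responses become
  deterministic in θ; any finite a gives selection probabilities
  monotone in θ. The rule is the package's choice of a simple monotone
  ordered-categorical model and is swappable.
* **Vital records.** Births are log-uniform on [6 000, 500 000]
  (spanning Wyoming-to-California cohort sizes); % Black births ~
  Beta(2, 10)·100 (mean ≈ 17%, near the US marginal); midwife counts are
  Poisson with mean `rate_g · θ̂ · births/1000` (defaults 3.0 CNM/CM and
  1.0 CPM per 1000 at full integration, the order of magnitude of US
  workforce data); hospital-midwife and community-birth proportions rise
  linearly in θ̂ (18% and 3.5% at θ̂ = 1) with small Gaussian
  perturbation. θ̂ is the scaled composite `total/100` of the scored
  profiles, keeping `simulate_vitals` a function of scores alone.
* **Outcomes** follow the two-block generating equation
  `y = α + β_black·black + β_miss·(MISS/100) + ε`, ε ~ N(0, σ). Default
  intercepts and total SDs sit at US state-level magnitudes (e.g.
  cesarean 32 ± 3.5%, neonatal mortality 4 ± 1 per 1000), with the
  variance budget split roughly 40% ethnicity composition, 10%
  integration, 50% noise — the regime in which block-1 R² ≈ 0.4 and
  ΔR² ≈ 0.1, the scale of effect the ecological analysis is designed to
  resolve. Signs encode integration as favourable and % Black births as
  adverse (documented disparities). Draws outside an outcome's valid
  range are clamped and logged rather than drawn truncated, for
  transparency; clamping above 10% of draws triggers a warning to
  re-parameterise.

Determinism: all draws derive from `SeedSequence(seed, spawn_key)` with
separate sub-streams for the latent vector, item responses and vitals,
so setting `vitals_seed` redraws outcomes while leaving profiles
byte-identical. What passing tests on these panels shows is that the
*pipeline* (scoring, ranking, correlation, R²-change inference) behaves
correctly under a known generative model; it says nothing about real
spatial correlation between states, reporting artefacts in birth
certificates, or the content validity of the synthetic rubric items.

## Verification studies and problem sizes

The verification suite (and `scripts/acceptance.py`) uses:

* all 720 permutations of 6 distinct values plus 1000 random tied
  vectors (n = 12) for Spearman oracle equivalence — exact on the
  distinct set because ranks are small dyadic rationals, ≤ 1e-12 with
  ties;
* 100 random small designs (n = 10–40, 1–2 columns per block) for the
  sum-of-squares oracle at 1e-10;
* 2000 null replicates at n = 51 for type-I calibration: profiles are
  held fixed and only outcome noise redrawn (conditional on the design,
  p_change is uniform under the null), expected rejection 5% at
  α = 0.05, accepted band [3%, 7%];
* 100 seeds at n = 200 for recovery of a planted effect of one baseline
  outcome SD (β_miss = σ₀/0.21 with σ₀ the outcome SD absent the
  effect and 0.21 the predicted SD of MISS/100 under Beta(2, 2)); the
  observed median ΔR² is compared with the analytic variance share
  `β²V_m/(β_b²V_b + β²V_m + σ²)` computed from the realized predictor
  variances (expected ≈ 0.5, so power is effectively 1).

These sizes keep any single study within seconds on one CPU while
leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* The synthetic rubric's 44 stand-in items make jurisdiction-level
  totals on the packaged instrument illustrative, not comparable with
  published state scores (only the structural invariants are faithful).
* The latent model is unidimensional; real regulatory regimes may vary
  by domain in ways one θ cannot express.
* Generator states are independent; no spatial autocorrelation.
* The Spearman p-value uses the t approximation except on demand at
  n ≤ 8; at n = 51 the approximation error is negligible relative to
  the 0.05/0.01 star thresholds.
* Report-card outcome directions ship as an editable table
  (`OUTCOME_DIRECTIONS`); any outcome without an entry is rejected
  rather than guessed.
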