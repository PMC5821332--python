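# aimm

Scoring and ecological analysis of midwifery integration in US maternity
care.

How fully a US jurisdiction's laws integrate midwives into its health
system — licensure, scope of practice, prescriptive authority, Medicaid
reimbursement, access across birth settings — varies enormously between
states, and that regulatory environment is associated at the state level
with workforce density, access to midwife-led care, and perinatal
outcomes. `aimm` implements the instrument and analysis stack for this
kind of study:

* **MISS** — the Midwifery Integration Scoring System, a weighted 50-item
  composite. Each item offers ordered response options with point values;
  a jurisdiction answering every item at its most favourable option
  scores exactly 100. The package ships a 50-item instrument file (six
  items transcribed from the published sample indicators, the rest
  synthetic stand-ins for the unpublished supplement), plus a loader,
  validator and a point-derivation rule
  `points_ik = c · w_i · r_ik` with `c = T / Σ_i w_i max_k r_ik`,
  mapping Delphi importance weights `w_i ∈ {0..4}` and within-item
  favourability ranks `r_ik` onto points summing to the target `T = 100`.
* **Workforce & access metrics** — midwife density per 1000 births
  (separately for CNMs/CMs and CPMs/other direct-entry midwives), the
  proportion of births attended by each group in hospital, home and
  birth-center settings, and percent change in community-birth rates.
* **Ecological inference** — Shapiro–Wilk normality gate; Spearman's
  ρ (Pearson correlation of average ranks, two-tailed t-approximation
  p-values, significance stars at 0.05/0.01) between integration scores,
  access measures and outcome rates; and hierarchical (block-entry) OLS
  in which % non-Hispanic Black births enters in block 1 and the
  integration score in block 2, the increment tested with
  `F = (ΔR²/q) / ((1 − R²_full)/(n − p − 1))`.
* **Synthetic jurisdiction panels** — a latent integration level θ_j
  drives both item responses (cumulative-link rule) and outcome rates
  (two-block generating equation), so the whole pipeline runs and is
  testable at desk scale with no external data.
* **Report cards** — rank tables, quartile categories
  (very_low/low/moderate/high) and per-outcome flags marking
  jurisdictions in the extreme quartiles.

Analyses here are ecological: units are jurisdictions, and associations
need not hold at the individual level.

## Worked example

```sh
aimm simulate --seed 7 --n 51 --out-dir demo/
aimm score     --profiles demo/profiles.csv --out demo/scores.csv
aimm rank      --scores demo/scores.csv     --out demo/ranked.csv
aimm correlate --scores demo/ranked.csv --vitals demo/vitals.csv --out demo/corr.csv
aimm regress   --scores demo/ranked.csv --vitals demo/vitals.csv \
               --outcome neonatal_mortality --out demo/fit.csv
```

`demo/ranked.csv` starts:

```
jurisdiction,total,rank,quartile,...
UT,85.0,1,high,...
MD,82.0,2,high,...
MN,82.0,2,high,...
```

Totals are composite MISS points out of 100; tied jurisdictions share a
competition rank. `aimm correlate` first reports the normality gate
(`Shapiro–Wilk on composite scores: W=0.944 p=0.018`) and writes one
Spearman ρ per exposure × outcome cell, starred at the 0.05 (`*`) and
0.01 (`**`) two-tailed levels:

```
outcome,miss_total,pct_midwife_community,pct_midwife_hospital
cesarean,-0.505**,-0.423**,-0.405**
neonatal_mortality,-0.349*,-0.329*,-0.362**
svb,0.405**,0.331*,0.369**
...
```

On this synthetic panel higher integration correlates with fewer
cesareans and neonatal deaths and more spontaneous vaginal births —
the effect structure the generator plants. `demo/fit.csv` holds the
hierarchical model for neonatal mortality:

```
outcome,n,r2_block1,delta_r2,r2_total,f_change,p_change,sig
neonatal_mortality,51,0.474,0.047,0.521,4.708,0.035,p<0.05
```

i.e. % Black births alone explains R² = 0.474 of between-jurisdiction
variance in the simulated neonatal mortality rate, and the integration
score explains a further ΔR² = 0.047 (F-change p = 0.035).

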