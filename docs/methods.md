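# Methods

## The model

`bnpcea` implements a five-state Markov cohort model for outpatients with
heart failure with reduced ejection fraction (HFrEF), comparing monthly
B-type natriuretic peptide (BNP) guided care against standard clinical
assessment. The alive states index the number of previous heart-failure
rehospitalizations — NRH (none), RH1, RH2, RH3 (three or more) — plus an
absorbing death state. Rehospitalization count is used as a proxy for
disease progression: each monthly cycle a patient stays put, is readmitted
and moves one state up, or dies. State costs and utilities worsen with
rehospitalization count, so slowing progression both saves money and gains
quality-adjusted life-years (QALYs).

Per alive state *s* at age *a*, the monthly transition row is assembled
from three primitives:

- `p_death(s, a) = 1 − (1 − p_hf_death(s)) · (1 − p_bg(a))`, treating
  heart-failure death and age-banded background mortality as independent
  competing risks. Background mortality comes from an Iranian life table of
  annual probabilities by 5-year age band (45–49 … 85+), converted to
  monthly at constant hazard: `p_month = 1 − (1 − p_year)^(1/12)`.
- `p_hosp(s)`: the monthly rehospitalization probability, multiplied by the
  relative risk RR = 0.81 in the BNP arm only. This reflects the trial
  evidence that BNP-guided therapy reduces hospitalization but not
  mortality; the RR never touches the death entries. The product is capped
  at `1 − p_death` so the row stays feasible.
- `p_stay = 1 − p_hosp − p_death` (residual). RH3 has no upward transition.

The cohort starts fully in NRH at `start_age` (default 60 — the source
analysis never states the starting age, so this is a package default, not a
reported fact) and is propagated until age 100, a fixed horizon if
configured, or an alive fraction below 1e-8. Cycle *t* rewards are
`occupancy · cost` (USD) and `occupancy · utility / 12` (QALYs), discounted
by `(1 + r)^(−t/12)` with r = 5.8 %/yr for costs and 3 %/yr for effects.
Results are reported per patient; the nominal cohort size (1000) only
scales absolute outputs.

### Transition-label and cost-accrual semantics

The published input table labels the hospitalization rows as self-
transitions ("NRH to NRH"), which would make the printed values redundant
residuals. Because the accompanying text says patients "move to the next
state" on readmission and the source transition model parameterizes
admission events, the default reading (`transition_label_mode =
next-state`) interprets the printed values as the monthly probability of
the next rehospitalization (NRH→RH1, RH1→RH2, RH2→RH3). A `literal-stay`
mode — printed value is the stay probability, the residual moves — is kept
as a sensitivity flag.

State costs likewise come without accrual semantics. The default
(`cost_semantics = per-cycle`) charges the state cost every occupied cycle;
an `event` mode charges RH-state costs once on admission with only NRH
accruing per cycle. Half-cycle correction is off by default; a flag
averages start- and end-of-cycle occupancy when on.

With these defaults the deterministic lifetime run gives roughly 6 200 USD
/ 0.84 QALYs (BNP) versus 7 800 USD / 0.82 QALYs (standard) — BNP dominant,
matching the published direction, but the absolute totals do not match the
published 1 835/2.18 versus 2 376/2.07. No combination of the documented
semantic switches reconciles them: the published monthly death
probabilities (0.067–0.095) imply a life expectancy near one year, which is
arithmetically incompatible with 2+ discounted QALYs. The published
absolute totals are therefore treated as calibration references; the
package's claims are the incremental arithmetic (which reproduces every
printed increment exactly from the printed per-arm values) and the
qualitative conclusions.

### Engine validation

The cohort trace is validated against an independent individual-level
microsimulation (`microsim_oracle`) that draws state paths from the same
matrices and discounts identically: at 20 000 individuals the cohort totals
agree within three standard errors. Structural properties — occupancy
conservation to 1e-9, monotone death absorption, discount-zero equivalence,
bit-identical arms when RR = 1 with equal costs, and a closed-form
geometric-series check on a two-state reduction — are property-tested over
randomized feasible bundles.

## Uncertainty analysis

**Distributions.** Each input is fitted by the method of moments to its
published mean and SD with the published family: Beta for probabilities and
utilities, Gamma for costs, log-normal for the RR (with `mu = ln(mean) −
sigma²/2` so the arithmetic mean is preserved). The RR row prints a
dispersion of "5", unusable as a log-scale SD; the package defaults to
`rr_log_sd = 0.1`, exposes it in the config, and marks it as an assumption
in every run manifest.

**Beta feasibility repair.** Several printed SDs sit at or beyond the Beta
bound `sd² < m(1−m)` (e.g. mean 0.085 with SD 0.32). Fits with
`sd ≥ 0.95 × √(m(1−m))` are repaired by shrinking the SD to 95 % of the
bound and flagged; repaired fits are excluded from sampler-moment recovery
tests. The 0.95 trigger (rather than the bare bound) also catches fits a
hair inside the bound, which would otherwise degenerate into near-Bernoulli
two-point shapes.

**PSA.** Per draw, every input is sampled independently, a sampled
(hospitalization, death) row summing above 1 is rescaled by its sum (draw
flagged), the two-arm model is rerun, and (ΔC, ΔE) stored; 1000 draws by
default, fully determined by (seed, bundle, n). The cost-effectiveness
acceptability curve is the fraction of draws with positive net monetary
benefit `λ·ΔE − ΔC` over a willingness-to-pay grid; the threshold is
λ = 20 800 USD/QALY (three times per-capita GDP).

A caveat that matters: taken at face value, the printed transition and
utility SDs (0.23–0.37 on means of 0.067–0.85) are so large that even the
repaired Beta fits are U-shaped, and roughly half the draws invert the
state ordering of utilities or mortality or collapse hospitalization risk
toward 0/1. The resulting acceptability at 20 800 USD/QALY is ≈ 0.46, far
below the published 85 %. Re-running with small dispersions on those rows
(e.g. SD 0.03) yields ≈ 0.85–0.89, so the gap is attributable to the
printed dispersion column rather than to the model structure. The package
keeps the printed values as defaults — they are the stated inputs — and
reports the discrepancy rather than adjusting it away.

**Tornado.** Each of the 20 inputs is set to ±20 % of its base value
(clipped into validity, with clipping recorded), the deterministic model
rerun, and bars sorted by width. The default outcome is NMB at the
threshold because the ICER changes sign across the dominance boundary; an
ICER mode is provided.

**Bootstrap.** Percentile intervals (not BCa — the plainest reading of
"non-parametric bootstrapping") from 1000 resamples with replacement at the
original size, seeded. A simulation study in the test suite confirms
~95 % coverage of the true mean on n = 200 normal samples.

## Synthetic cohort

The study's patient-level data (200 interviews per arm) is not public. The
generator emulates its assumed structure:

- **Costs.** Ten itemized direct-cost categories (physician visits,
  medications, BNP test, diagnostics, hospitalization, nursing, special
  equipment, private service, accommodation, traveling) are gamma with
  shape 2 (right-skewed, CV ≈ 0.7), plus an indirect component realized as
  lost workdays × daily wage (human-capital approach, wage gamma with mean
  10 USD/day). Arm-level item means are calibrated so totals are 682 USD
  (BNP) and 649 USD (standard) in expectation, with the published dominant
  items fixed (medications 255/196, diagnostics 189/141) and the remainder
  allocated so that direct medical > indirect > direct non-medical, the
  reported component ordering. The full published item breakdown lives in a
  supplement that is not reproduced here, so the residual allocation is a
  package choice.
- **EQ-5D-3L.** Five dimensions at three levels, sampled per dimension from
  stratum-specific multinomials. Under the shipped synthetic value set
  (decrement 0.04 at level 2 and 0.12 at level 3 for every dimension, no
  N3 term) the level probabilities `p2 = 5D, p3 = 20D/3` with
  `D = (1 − target)/5` reproduce the target state utilities exactly in
  expectation. The value set is a documented stand-in, replaceable via CSV;
  no claim is made that it equals the Iranian tariff.
- **Strata.** Prior-hospitalization strata 0–3 with probabilities
  0.40/0.30/0.20/0.10; ages 45 + Gamma(4, 4) (mean 61), matching an
  over-45 outpatient population.

What passing tests show: the estimation pipeline (scoring, stratum means,
bootstrap CIs) recovers the generator's own targets at the study's sample
size. What they do not show: anything about the real cohort's dispersion,
item correlations (items are sampled independently here), or missingness —
the study reports none of these.

## Numerical choices and limitations

- Probability conversions assume constant hazard within a year;
  competing risks assume independence.
- Occupancy conservation is enforced to 1e-9; row feasibility to 1e-9
  (renormalized PSA rows can sit at 1 + 2e-16).
- ICER display truncates toward zero (matching the printed subgroup values
  466 = trunc(140/0.30) and 2954 = trunc(650/0.22)); full precision is kept
  in data output.
- Subgroup runs differ only through start age (50/60/70 for the published
  45–55/55–65/65–75 groups): the publication gives no subgroup-specific
  inputs, so the printed subgroup per-arm values are checked as pure
  arithmetic through the ICER operation instead.
- The published 45–55 subgroup QALYs (2.07 vs 1.24) are inconsistent in
  magnitude with the base case (2.18 vs 2.07); they are used as printed in
  the arithmetic checks, not rationalized.
- The 20-year scenario prints a cost difference of "542" with no sign; by
  analogy with every other scenario it is treated as a saving.
- No currency conversion or inflation adjustment (cost year 2019); no
  EVPI/EVPPI; no multi-comparator frontier; no tunnel states beyond RH3.

## Problem sizes

Default runs: lifetime horizon ≈ 190 monthly cycles (early-terminated at
alive fraction < 1e-8), 1000 PSA draws, 1000 bootstrap replicates, 20 000
microsimulated individuals for engine validation, 200 patients per arm for
the synthetic cohort — the sizes the study states, all computed in seconds
on one CPU.
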