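# Methods

## The synthetic cohort model

Each simulated person enters the study at time 0 with fixed categorical
covariates (gender, age band, optional extras) and is followed, dropout-free,
to an administrative censoring time (default 9.0 years, emulating roughly a
decade of claims linkage). Condition onsets arise from a continuous-time
multistate process over the ten tracked chronic conditions. Between onsets the
process is a race of competing exponential clocks: an unacquired condition
*c* fires at rate

    rate(c | history, covariates)
        = baseline_rate[c]
          * exp( sum of covariate log hazard ratios for c )
          * prod over acquired a of progression_multiplier[a][c]

Hazards are piecewise-constant between events, so the process is Markov in
(history, time-invariant covariates). A condition occurs at most once per
person, and simultaneous onsets have probability zero in continuous time.

The same process also runs on a pre-baseline lookback window (default 2.0
years, times in [-lookback, 0]); `screen_baseline_free` then removes every
person with any onset at or before time 0. This emulates the design of
excluding participants with any of the ten conditions at baseline. The real
study identified prevalent disease from self-report plus two years of claims;
the generator *emulates* that screen with its own onset process rather than
replicating it.

### Randomness and determinism

One top-level integer seed; each person's stream is
`numpy.random.default_rng([seed, person_id])`. Consequences: identical
(spec, hazards, seed) gives bit-identical tables across process invocations,
and enlarging `n_persons` leaves existing persons' histories unchanged.
No global mutable random state exists anywhere in the package.

### Default parameters (illustrative)

The cohort the analysis targets is observed only in restricted-access data,
and no incidence-rate inputs are public, so the defaults are the package's own
choice, made once and labelled illustrative:

| parameter | default | rationale |
|---|---|---|
| baseline rates (per person-year) | hypertension/dyslipidemia 0.016, osteoarthritis 0.009, CVD/mental 0.008, cancer/diabetes/asthma 0.006, hip replacement 0.002, neurodegenerative 0.001 | all-cause first-onset hazard ≈ 0.078/yr, so roughly half the cohort develops a primary condition over 9 years, with a CMD-heavy profile |
| follow-up | 9.0 years, uniform | administrative censoring; per-person variation adds nothing tested |
| lookback | 2.0 years | a screening window long enough to create a realistic prevalent fraction (~20%) |
| P(female) | 0.565; P(age 55–64) | 0.41 | plausible for a middle-aged volunteer cohort |
| covariate effects (in `default_hazard_spec`) | log(1.5) on all conditions for age 55–64; log(1.25) on the four CMDs for men | older age raises all onsets; male excess in cardiometabolic disease |
| progression multiplier (in `default_hazard_spec`) | uniform 2.0 off-diagonal | encodes the qualitative acceleration the design detects |

`null_hazard_spec()` keeps the rates but removes covariate effects and sets
all multipliers to 1 — the global-null configuration used for calibration
checks.

### What the generator does *not* emulate

No mortality or competing-death process, no time-varying covariates, no
claim-code emission, no seasonality or recording delays, no dependence of
censoring on health. Tests passing on this generator therefore demonstrate
that the analysis machinery recovers effects *of the kind the generator
produces*; they cannot certify behaviour under informative censoring,
misclassified onset dates, or unmodelled confounding in real claims data.

## Sequencing

Events are ranked per person by onset time; the gap at rank 1 is measured
from study entry (time 0), and at rank k ≥ 2 from the previous onset, so gaps
telescope to the final onset time. Ranks beyond 4 are computed and stored
(summaries label them "5+").

Exact ties cannot occur in simulated data but can in loaded same-day claims.
Two documented rules: `canonical` (default) orders tied events by the fixed
canonical condition ordering, keeps both, and flags them `tied` — note a kept
tie necessarily carries a zero gap, the one situation where the "gaps are
positive" invariant yields; `collapse` keeps only the canonically first event
of a tied run (flagged). Quartiles use linear interpolation between closest
ranks throughout.

## Patterns

Pattern keys are the conditions at ranks 1..k (k = 2, 3, 4) of each person
with ≥ k onsets, ordered (permutations) or canonically sorted (combinations),
at condition or group level. Group keys are **multisets**: hypertension →
dyslipidemia maps to (CMD, CMD), keeping "two concurrent cardiometabolic
disorders" representable — collapsing repeated groups would destroy the most
common pattern. Percentages are over the ≥ k subpopulation, so each table
sums to 100. Rows with fewer than `min_count` persons (default 5) are flagged
and withheld from public serializations, mirroring small-cell confidentiality
practice for claims data.

The contribution-by-rank table gives each condition's share of all onsets at
each rank; a chi-square test compares a condition's share between primary and
secondary onsets, and a Cochran–Armitage test (equally spaced integer scores
1..4; the score choice is a convention, not data-driven) assesses the trend
across ranks.

## Self-contained statistics

Every classical procedure the pipeline uses is implemented in
`mmtraj.stats` from its defining formulas, so each is verifiable against
brute-force oracles and an independent reference library in the tests
(lifelines, statsmodels, scipy are never called at runtime):

- **Wilcoxon rank-sum** — midranks; exact p by full enumeration of rank
  assignments when n ≤ 12 (or on request), otherwise a normal approximation
  with tie-corrected variance and 0.5 continuity correction. Two-sided exact
  p is the symmetric-tail probability P(|W − μ| ≥ |w − μ|).
- **Mann–Kendall** — S = Σ sign(xⱼ − xᵢ), tie-corrected variance,
  ±1 continuity correction, two-sided p. Note the test has limited resolution
  on very short sequences: a perfect monotone trend on 4 points cannot reach
  p < 0.05 two-sided, which is why rank-trend checks use five ranks.
- **Cox proportional hazards** — Breslow tie handling (chosen for its
  closed-form score and information), Newton–Raphson with step-halving.
  Convergence when the gradient max-norm < 1e-8 or the Newton step max-norm
  < 1e-8 (the gradient's floating-point noise floor grows with n, so the
  step criterion recognises convergence the gradient criterion cannot);
  maximum 100 iterations. Monotone likelihood (complete separation) is
  detected — a diverging or absurdly large coefficient (|β| > 15 at
  convergence) — and raised as an error rather than returned.
- **Poisson relative-risk model** — log-linear fit by IRLS (= Newton for the
  canonical link); sandwich covariance information⁻¹ (Σ scoreᵀscore)
  information⁻¹ (HC0, no small-sample correction). Frequency weights let the
  progression grid fit aggregated cell data with identical results to the
  expanded rows. Wald intervals and two-sided p-values throughout.
- **Benjamini–Hochberg** — step-up max-index rule; adjusted q-values by the
  monotone cumulative-minimum construction; ties share their adjusted value.

## The progression relative-risk design

For a contrast (exposure → outcome) with window *w* (default 5 years):

- **Reference arm**: all persons disease-free at baseline with ≥ *w* years of
  follow-up, minus the contrast's exposed persons (arms are kept disjoint —
  whether the original design excluded later-exposed persons from its
  reference is unknowable from the outside, and disjoint arms are the cleaner
  contract). Response: outcome occurred as the person's rank-1 condition
  within *w* years of entry. Persons with no onsets are included, response 0.
- **Exposed arm**: persons whose rank-1 condition (and rank-2 in order, for
  pair exposures) matches the exposure, every exposure onset within *w* years
  of entry, and ≥ *w* years of follow-up remaining after the last exposure
  onset (persons with less are excluded, not censored). Response: outcome is
  the *immediately next-ranked* condition, within *w* years of the last
  exposure onset.

The risk ratio is a 5-year cumulative-incidence ratio (binary response per
person over a fixed window), not a person-time rate ratio — which is exactly
what the Poisson-with-robust-variance model estimates on binary data. Two
switches expose the genuinely ambiguous choices: `anchor="entry"` measures
the outcome window from study entry instead of the last exposure onset
(onset-anchored is the default: the clock restarts at the existing
condition), and `allow_intervening=True` accepts the outcome at any later
rank within the window instead of requiring it next.

`ProgressionModel.fit` evaluates all 90 primary→secondary contrasts plus
every observed ordered pair with ≥ `min_exposed` (default 5) exposed persons
crossed with the 8 remaining outcomes, then applies Benjamini–Hochberg at
level q across the combined family of estimable contrasts (the family choice
is configurable by fitting secondary-only). Contrasts with an empty exposure
stratum or a zero case count in either arm are flagged inestimable and
excluded from the BH family rather than silently dropped. Strata with fewer
than `min_cell` (default 5) persons set a suppression flag; suppressed rows
keep their estimates in the raw view but have their counts withheld from
serialized output and are absent from the reported view.

### Numerical and calibration caveats

- With all multipliers at 1 the design's true ratio is not exactly 1:
  removing the exposure condition from the competing set slightly changes the
  race for the next onset (a structural ratio of ≈ 1.04 at the default rates
  for the hypertension→CVD contrast). This is far below sampling error at the
  cohort sizes used in the calibration checks.
- Sandwich Wald p-values are anti-conservative in strata with a handful of
  cases; under a global null, the handful of BH rejections that appear
  invariably come from contrasts with ~5–20 exposed persons and 1–2 cases.
  The grid-level reported fraction stays well below the nominal level, but
  individual tiny-cell rows in the raw view should be read with this in mind
  (the suppression threshold addresses confidentiality, not calibration).

## Problem sizes in the checks

Calibration and recovery checks use the sizes at which their Monte-Carlo
error bounds are meaningful: 50,000 persons for the closed-form
exponential-race comparisons (3 standard errors ≈ 0.0065), 20,000 for null
calibration of the grid (50 replicates for single-contrast CI coverage, 5 for
the full grid) and for the gap-time trend, and 6,000 × 50 replicates for
recovery of the injected multiplier of 4 (expected RR ≈ 3.9 given the
competing-risk structure). These sizes are the package's own choices,
recorded here so reruns are comparable.

## Known limitations

- The generator's defaults are illustrative, not calibrated to any real
  cohort; absolute incidences and pattern shares produced under them are
  demonstration values.
- Onsets are treated as exact dates (no interval censoring), conditions are
  unweighted counts, and the reference/exposed windows assume administrative
  censoring is non-informative — all inherited from the design being
  implemented.
- The Cox model here is a supporting tool (gender/age incidence contrasts);
  it implements Breslow ties and Wald inference only — no Efron ties, no
  frailty, no time-varying effects.
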