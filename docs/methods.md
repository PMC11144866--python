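# Methods

## Model structure

The model is a two-arm cohort state-transition model of perinatal
depression screening. A cohort of pregnant women enters in the first
trimester distributed over three living states defined by EPDS score —
normal (< 9), suspicious (9–12), high risk (≥ 13) — plus an absorbing
death state. Four cycles of 3 months (0.25 years) cover the first,
second and third trimesters and the postpartum period; the simulation
ends 3 months postpartum. The screened arm receives EPDS screening with
referral and treatment of screen-positives at every period; the
routine-care arm receives ordinary maternity care, with only high-risk
women assumed to seek specialist treatment.

Per cycle, utility accrues as the share-weighted state utility times the
cycle length and cost as the share-weighted per-state cycle cost; death
contributes neither. Totals are plain sums over the four cycles: the
horizon is about one year and recent, so there is **no within-horizon
discounting and no half-cycle correction**. These are deliberate
simplifications appropriate to a 1-year, 4-cycle model, not omissions.

### Anchored versus chained transitions

The packaged transition tables derive from longitudinal follow-up tables
that cross-tabulate each woman's state at the second trimester, third
trimester and postpartum *against her baseline state*. Such tables encode
P(state at period p | baseline state) — "anchored" semantics — not the
period-to-period conditionals P(state at p | state at p−1) of a textbook
Markov chain ("chained"). The engine supports both via a semantics flag:

* ANCHORED (default): πₚ = π₁ · Mₚ for each post-baseline period. This is
  the faithful reading of the estimation tables and is what reproduces the
  0.85 / 0.84 QALY totals.
* CHAINED: πₚ = πₚ₋₁ · Mₚ. Retained because the model is described as a
  Markov model and because chained tables are what a subject-level process
  actually follows.

The two coincide at the second trimester (one step from baseline) — an
invariant the tests assert for arbitrary inputs.

### Loss to follow-up

Anchored rows sum to less than 1 where women missed a period's screening
(e.g. the routine-care normal row in the second trimester sums to 0.958).
By default the engine propagates that deficit — occupancy mass simply
goes unattributed for the cycle, which is how the source tables were
evidently used — rather than renormalizing. A `renormalize` flag
redistributes each row proportionally for users who prefer a closed
cohort. Validation errors on row sums above 1.01 and warns below 0.95.

### Mortality

Depression-attributable death is modelled as a per-cycle probability
applied to the high-risk share (default 0, range 0–0.04 in the one-way
analysis, reflecting the 4% suicide rate reported for depression in the
general population used in place of an unavailable perinatal mortality
figure). The base case reproduces the published QALY totals without
mortality, so 0 is the default and the rate enters as an uncertainty
parameter only.

## Costs (yuan, payer perspective)

Per-state cycle costs are assembled from component fees:

| state | screened arm | routine care |
|---|---|---|
| normal | screening fee (19.0) | 0 |
| suspicious | screen + registration + first visit = 84.0 | 0 |
| high risk | 820.32 (see below) | specialist cost × PPV = 1405.9 × 0.59 = 829.48 |

The screened high-risk formula is screen + registration + first visit +
session cost × sessions × PPV + drug cost × medicated proportion; the PPV
(0.59 for the EPDS; 0.584 for the PHQ-9 alternative) deflates treatment
because only true positives are treated, and the drug term is deliberately
*not* PPV-deflated, following the documented formula verbatim. At the
default components (229 × 3 × 0.59 + 479.7 × 0.5 + 84) the formula gives
**729.18**, while the state cost actually used by the source evaluation
was **820.32**; no combination of its printed components reconciles the
two. The package keeps 820.32 as an explicit base-case override, exposes
the formula value separately, and logs the discrepancy. In sensitivity
analyses the override moves additively with the change the perturbed
components induce in the formula, so the base case stays pinned while
every component still has an effect.

The specialist-hospital cost (1,405.9) is a 2011 literature figure already
converted to the study year at 3%/yr over 9 years. The one-way
"discount rate" parameter (range 0–7%) re-converts it from the
back-derived raw value, so the 3% base reproduces 1,405.9 exactly.

Indirect, non-medical and societal costs are out of scope, as in the
source evaluation. Note the routine-care arm accrues no suspicious-state
cost; this under-shoots the source's per-capita routine cost (171.80),
whose attachment is not documented — see Reproducibility below.

## Utilities

State utility weights: normal 0.86, suspicious 0.80, high risk 0.63,
death 0 (international reports, ranges 0.77–0.95 / 0.72–0.83 /
0.30–0.73). QALYs per cycle are weight × 0.25 years.

## Decision rules

The comparison is routine care (comparator) minus screening (reference),
matching the source's table convention; the ICUR is ΔC/ΔE with dominance
quadrant labels because a signed ratio is ambiguous alone. The WTP rule:
a dominant comparator is always accepted, a dominated one never; in the
north-east quadrant accept iff ICUR ≤ λ, in the south-west iff ICUR ≥ λ
(savings per QALY forgone must exceed the threshold). Ties resolve to the
reference (no change without evidence). Net monetary benefit
NMB = λ·E − C gives the same choice — a property the tests verify over
randomized strategy pairs.

## Sensitivity analysis

**One-way:** each parameter is set to its low and high limit with all
others at base, the full two-arm model is rebuilt, and parameters are
ranked by outcome spread (tornado order, ties broken alphabetically so
the ranking is independent of listing order). Baseline-share parameters
rebalance the remaining shares proportionally to keep the baseline
summing to 1 — the source does not document its own handling, so this is
the package's choice. An evaluation failure at one limit is recorded on
that parameter and the sweep continues.

**Probabilistic:** the eight surveyed parameters — three utilities
(Beta) and five cost/frequency parameters (Gamma: screening fee 19 ± 21.83,
registration 22.5 ± 8.66, first visit 42.5 ± 10.85, session cost
229 ± 209.41, sessions 3.33 ± 0.84) — are fitted by method of moments
(Beta: k = m(1−m)/s² − 1, α = mk; Gamma: shape = m²/s², scale = s²/m) and
drawn independently, n = 1,000 by default, from a seeded NumPy generator
(`default_rng(seed)`; the seed is required input, never wall-clock).
Draws are not truncated or reordered, so a draw may invert the usual
utility ordering; this is logged, not rejected. Transition probabilities
are held fixed in the PSA (only deterministic ranges were reported for
them); the screening-fee SD exceeding its mean is accepted as surveyed
(the Gamma is well-defined with shape < 1). Per draw the decision rule is
the incremental-NMB sign, equivalent to "below the WTP line" on the
incremental plane; the CEAC evaluates the same fraction over a WTP grid.

## Estimation from longitudinal data

Seven visits (13/17/24/31/37 gestational weeks, postpartum days 3/42)
collapse to the four periods by averaging each pair; a half-missing pair
uses the available score (preserving sample size; logged), a fully
missing pair yields a missing period. Scores categorize with ≥ 9 positive
and ≥ 13 high risk; the overlapping printed bins "0–9"/"9–13" are
resolved as [0,9), [9,13), [13,∞) so that "≥ 9" is positive.

The anchored estimator divides, for each baseline group, the count in
each destination category at each period by the baseline group size;
women missing the period contribute to the denominator only, so row mass
equals retention. The chained estimator conditions on the previous
period over observed consecutive pairs. The persistent-positive share is
reported against both defensible denominators (all complete trajectories
and the ever-positive subgroup).

## Synthetic cohorts

The generator emulates the statistical structure of the longitudinal
cohort: a baseline state per subject, then sequential (chained) draws
from the row-normalized period matrices, optional independent per-period
missingness, and optional integer scores uniform within each state's band
(normal 0–8, suspicious 9–12, high risk 13–30), so scores always
re-categorize to the generating state. Generation must be chained —
anchored tables cannot produce coherent individual trajectories — so the
anchored estimator applied to synthetic data recovers the *compound*
baseline-to-period transitions, not the generating rows; the chained
estimator recovers the rows themselves. The tests document exactly this
asymmetry, which mirrors the real ambiguity in the source tables. The
generator does not emulate item-level EPDS responses, covariate-dependent
risk, or informative (state-dependent) dropout, so passing recovery tests
shows estimator correctness under ideal missingness, not robustness to
real-world attrition patterns.

Default study conditions used in tests: cohorts of 5,000–20,000 subjects
for recovery properties (every estimated cell within 3 binomial standard
errors of truth), 1,000 Monte Carlo draws for the PSA, chosen to match
the sampling scale of the source cohorts while keeping the suite fast.

## Numerical choices

* Probabilities are stored as fractions; CSV tables may declare
  `# units=percent|fraction`, and undeclared tables are inferred (values
  above 1.5 are treated as percentages), with the conversion logged.
* Reported tables round costs, QALYs and ratios to 2 decimals; internal
  arithmetic is double precision throughout.
* Mass-conservation and moment-fit round-trip tolerances are 1e-9;
  PSA-vs-deterministic equivalence is 1e-6.
* A zero-QALY arm makes the CUR undefined (error), and a zero QALY
  increment makes the ICUR undefined (labelled; decision falls back to
  cost minimization).

## Reproducibility and known limitations

Reproducible from packaged inputs: the 84 and 829.48 state costs, the
0.85/0.84 QALY totals (anchored roll-forward), retention 94.2%
(1,210/1,284), the ever-positive subgroup shares 30.7% (101/329) and
16.7% (55/329), the screened baseline positive rate 28.5%, and the
anchored transition cells (e.g. normal→normal 93.4% = 826/884).

Not reproducible at desk scale, by design: the source's per-capita costs
(129.54/171.80), CURs (152.17/205.05), ICUR (−3,126.77), Monte Carlo
means (112.95 / 0.83) and the 84.20% acceptability fraction. Its printed
state costs and occupancies imply different per-capita totals (the
engine computes 138.34/116.77 under anchored semantics), and its implied
unrounded ΔQALY (≈ 0.0135) lies outside what the printed tables generate;
the internal cost attachment and utility precision of the original
TreeAge implementation are not recoverable. The engine therefore reports
its own internally consistent totals, and cost attachment is fully
configurable so users can explore alternative wirings.
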