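# Methods

This note records the models, calibration defaults, numerical choices and
known limitations of `crcmolclass`, in the package's own words.

## Cohort model and interchange format

A cohort is one flat TSV row per tumour (schema in
[cohort_schema.md](cohort_schema.md)): ternary molecular calls
(1 = altered, 0 = wild-type, NA = missing) for CIN, MSI, KRAS, NRAS, BRAF,
PIK3CA, TP53, FBXW7 and 5q/17p/18q LOH; clinico-pathological covariates;
and a disease-free-survival (DFS) time/event pair.  No public per-tumour
format exists for this kind of study, so the schema is the package's own
invention, chosen flat so every stage is testable in isolation.  Age and
time serialize with 3 decimals, which bounds round-trip error; categorical
fields round-trip bit-exactly.  Grade is ordered (well < moderate < poor)
and enters regression models as the score 0/1/2.

## Synthetic cohort generator

The generator's defaults *are* the published study conditions; they are not
tuning knobs.

**Molecular joint model.**  A pairwise binary log-linear model over the
seven core variables; three-way and higher interactions are omitted because
only pairwise conditional dependencies are reported for the cohort being
emulated.  Interactions are the eight primary-association edges.  Defaults:

* marginal alteration probabilities from the published per-alteration
  counts (CIN 586/861, MSI 119/892, KRAS 304/898, NRAS 32/869, BRAF 91/903,
  PIK3CA 104/896, TP53 329/753);
* MSI–CIN interaction set to the log-odds-ratio of the published MSI×CIN
  cross-classification, log((23·179)/(96·563)) ≈ −2.575 — the only pair
  whose joint cells are published;
* every other edge |log-OR| = 1.1 with the published sign.  1.1 (OR ≈ 3)
  is a representative strong association for this literature; it is
  configurable per edge.

Calibration is by iterative proportional fitting of the one-variable
margins on the 2⁷-cell table.  Each IPF update multiplies cells by a
function of a single variable, so all pairwise interaction terms are
preserved *exactly*; convergence is to |achieved − target| ≤ 1e−10 per
marginal, typically a few dozen sweeps.  Exact model quantities (marginals,
double-negative/double-positive fractions, conditional log-ORs) are always
computed from the 128-cell table, never estimated, and sampling is i.i.d.
from that table; a fixed seed fixes the cohort byte for byte.

**Non-core alterations.**  FBXW7 and the three LOH calls are generated as
independent Bernoulli draws at their published frequencies: FBXW7 showed no
association with anything, and LOH dependence structure is deliberately not
emulated.

**Covariates.**  Drawn conditionally on molecular *group* (the grouping is
the generative truth, computed from the complete profiles before any
masking), because the published covariate effects are expressed as
group-vs-rest odds ratios.  Sex, site and stage follow logistic models with
a cohort baseline (female 36%, proximal 35%, stage III 51%) plus a
per-group log-OR shift; grade follows a proportional-odds shift over
baseline (8%, 82%, 10%); age is Normal(64.1, 10) truncated to (18, 95).
Default shifts take directions from the published narrative (group 1
proximal, poorly differentiated, female; group 2 distal, male; group 3
stage III; group 6 male) and magnitudes from the published table (2.06,
1/0.18, 2.08; 0.62, 1/3.09; 1.58; 0.24) — the table's printed OR coding
direction conflicts with the narrative for location and stage, and the
narrative wins.  Stage additionally receives a log(1.4) shift for
CIN-positive tumours (stage III tumours tend to be CIN⁺; no effect size is
published, 1.4 is the package's choice).  Note a design consequence: when
several groups carry shifts simultaneously, the empirical group-vs-rest OR
for one group differs from its configured shift, because "rest" is itself
shifted; the configured value is recovered exactly when it is the only
shift active (this is how the recovery tests are framed).

**Survival.**  Exponential proportional hazards:
hazard = λ₀ · HR₃^[group=3] · HR_stage^[stage=III] · HR_MSI^[MSI⁺], with λ₀
set so the reference stratum's 5-year DFS equals 0.70, and administrative
censoring at 5 years only.  This is the simplest form consistent with the
5-year proportional-hazards analyses being emulated.  Defaults plant
HR₃ = 1.59 and HR_stage = 1.99 with HR_MSI = 1; the MSI-adjusted scenario
(1.48, 1.98, 0.59) is used by the recovery analyses.

**Missingness.**  Missing-completely-at-random per marker, at rates implied
by the published typed denominators (e.g. TP53 typed in 753/906).  No
missingness mechanism is published; MCAR is the neutral choice.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: three-way interactions, LOH/FBXW7 dependence,
informative missingness, non-exponential baseline hazards, loss to
follow-up before 5 years, and covariate effects operating through
individual markers rather than through group.

## Association testing

Fisher's exact two-sided test is the default everywhere (the small cells in
these cohorts — e.g. a 23-tumour double-positive class — make exact testing
the safe choice); a continuity-corrected chi-square variant is available.
The odds ratio is the cross-product ratio with the Haldane–Anscombe 0.5
correction when any cell is zero, with a Woolf log-OR 95% interval on the
corrected table; a zero margin yields p = 1 and an undefined OR.  The two
published 2×2 tables reproduce their printed p-value roundings (0.003,
0.007) under Fisher's test, which is why it is the default.
Benjamini–Hochberg q-values control the FDR over each whole screen.
Reverse stepwise logistic regression starts from the full model and removes
the worst predictor with p > 0.05 one at a time; predictors that break the
fit (rank deficiency, separation detected by unbounded coefficients or a
condition-number guard) are dropped first with the reason recorded.
Meta-analysis pools per-study 2×2 tables with the Mantel–Haenszel
fixed-effect OR and the Robins–Breslow–Greenland variance.

Complete-case handling applies per analysis, mirroring the fully-typed
subset used by the multivariate analyses being reproduced.

## Network learning

Families are scored with BDeu (equivalent sample size 1.0 by default,
exposed in config; max 4 parents).  The search is exact: per-child best
parent sets are propagated over candidate subsets, then the optimal
ordering is found by DP over variable subsets — for 7 variables this is
cheap, and it is verified in the tests against exhaustive enumeration of
all 543 four-node DAGs.  Ties break toward lexicographically smaller
parent sets and sinks, so results are deterministic.  Arrow directions are
not interpreted; the reported object is the skeleton, signed by the
Mantel–Haenszel-pooled conditional log-OR of each pair across strata of the
union of the two variables' other parents (0.5 correction in empty cells).
Association loops are the chordless cycles of the skeleton, each with the
product of its edge signs.

A measured limitation: at n = 5,000 with the default calibration, the
MSI–NRAS edge (both markers rare) falls below BDeu's detection threshold in
roughly a quarter of draws, so exact recovery of all eight signed edges
happens in ~72% of runs, not more.  Edge strength and ess are configurable
if a user wants a sharper planted structure.

## Clustering

Binary dissimilarities: Hamming (mismatch fraction) or Jaccard
(1 − |intersection|/|union| of altered sets, 0 for two all-zero vectors by
convention).  Agglomerative clustering (average or complete linkage) runs
through scipy; rows are first sorted lexicographically so the tree depends
only on the data multiset and not on input order (distance ties are
endemic to binary data), with leaf ids mapped back to the caller's order.
Hamming is the default metric but is prevalence-dominated on rare markers;
the co-alteration block structure (CIN/TP53, MSI/BRAF, KRAS/PIK3CA, NRAS
apart) emerges under Jaccard.  Rows with any missing call are excluded, not
imputed.

## Classifier

Rules apply in the construction order of the grouping (1 ≻ 5 ≻ 3/4 ≻ 2 ≻
6 ≻ 7); that order is the only published ordering evidence and is what
keeps groups 2–5 free of MSI⁺/BRAF-mutant tumours.  Group 6 requires all
seven variables wild-type.  FBXW7 and LOH appear in no rule.  Missingness
is handled by three-valued (Kleene) logic: a rule is false if decidably
false whatever the missing calls are, and a tumour is `unclassifiable` only
when its earliest applicable rule is genuinely undecidable — so group 7
stays "atypical combination" rather than "unknown".  The seven rules
partition all 128 complete profiles (enumerated in the tests).

## Survival analysis

Administrative truncation at 5 years precedes every analysis (events later
than 5 years become censorings at 5).  Cox fits use the Efron tie
correction (standard for clinical data with tied times) via lifelines, with
Wald p-values; Kaplan–Meier uses the product-limit estimator with events
before censorings at tied times.  Group models are conditioned on the full
clinico-pathological set (sex, age, site, stage, grade, arm, chemo, radio),
retaining non-significant covariates; one-vs-rest mode fits groups 1–6 and
does not test the miscellaneous group 7, whose members remain in every
comparator.

## Problem sizes

The test-suite and reproduction scripts use: exact model arithmetic on the
128-cell table (no sampling) for the cross-classification checks; n =
20,000 draws for marginal recovery; n = 5,000 per simulation (pooled over
three seeds in tests) for hazard-ratio recovery; n = 50,000 for the KM
closed-form check; 50 seeds at n = 5,000 for structure recovery; and 200
simulations at n = 2,000 for Wald-CI coverage.  These sizes make
Monte-Carlo error small relative to the tolerances checked while keeping
the full suite fast on a single CPU.

## Known limitations

* The structure-learning score and prior used for the original cohort are
  not published; BDeu with exact search is a standard, documented
  substitute, and results are reported at Markov-equivalence level only.
* The classifier's treatment of partially-typed tumours
  (`unclassifiable` with the blocking marker named) is a package decision;
  how the original analysis assigned partially-typed tumours is not
  published.
* Group-vs-rest covariate ORs are not jointly calibrated (see above); only
  single-effect configurations reproduce their configured OR exactly.
* No competing risks, time-varying covariates or proportionality
  diagnostics; the meta-analysis module provides pooling machinery only,
  not the literature counts.
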