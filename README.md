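# crcmolclass

Multivariate molecular classification of colorectal cancer (CRC), packaged
as a reusable, tested pipeline.

Most molecular taxonomies of CRC rest on microsatellite instability (MSI),
chromosomal instability (CIN) and a handful of driver mutations considered
one at a time.  This package implements the multivariate route to a
finer-grained, seven-group classification of stage II/III tumours: it
identifies the *primary* pairwise associations among CIN, MSI and mutations
in *KRAS*, *NRAS*, *BRAF*, *PIK3CA* and *TP53* (separating them from
associations that are merely secondary), derives a rule-based grouping from
them, and evaluates the groups against clinico-pathological covariates and
disease-free survival (DFS).  Because no per-tumour data from the original
trial cohort are public, the package includes a first-class synthetic-cohort
generator calibrated to the published summary statistics, so every analysis
stage is testable end to end.

It is aimed at biostatisticians and cancer-genomics analysts who want
either the individual building blocks (exact Bayesian-network structure
learning on binary clinical variables, calibrated log-linear simulation,
contingency screening with FDR, rule-based subtyping, group-wise survival
models) or the one-command pipeline.

## The models

**Calibrated joint model.**  Molecular profiles x ∈ {0,1}⁷ follow a
pairwise binary log-linear model

    P(x) ∝ exp( Σᵢ αᵢ xᵢ + Σ_{i<j} λᵢⱼ xᵢ xⱼ )

whose non-zero interactions λᵢⱼ are exactly the eight published
primary-association edges (positive: CIN–TP53, MSI–BRAF, KRAS–PIK3CA;
negative: MSI–CIN, MSI–NRAS, KRAS–BRAF, KRAS–NRAS, KRAS–TP53).  Main
effects αᵢ are fitted by iterative proportional fitting so each alteration
frequency matches the published cohort profile; IPF rescales one-variable
margins only, so every λᵢⱼ is preserved exactly.  The MSI–CIN interaction
is calibrated to the published MSI×CIN cross-classification, whose four
cells (23, 96, 563, 179)/861 are forced by the printed totals.

**Structure learning.**  The network module scores families with the BDeu
marginal likelihood and finds the globally optimal DAG by dynamic
programming over variable subsets (exact, not heuristic).  The reported
object is the Markov-equivalence skeleton with a sign per edge (pooled
conditional log-odds-ratio) plus all chordless cycles — the "association
loops" that expose direct-versus-indirect relationships such as the direct
negative KRAS–TP53 edge against the indirect positive
TP53–CIN–MSI–BRAF–KRAS path.

**Classifier.**  Seven groups applied in strict precedence:
(1) MSI⁺ and/or BRAF-mutant; (5) NRAS-mutant; (3)/(4) KRAS- and/or
PIK3CA-mutant, TP53-wild-type, split CIN⁺/CIN⁻; (2) CIN⁺ and/or
TP53-mutant with wild-type KRAS and PIK3CA; (6) no alterations;
(7) atypical combinations.  Missing calls yield `unclassifiable` only when
the earliest applicable rule genuinely cannot be decided.

**Survival.**  Kaplan–Meier curves and Cox proportional-hazards fits
(Efron ties, via lifelines) of 5-year DFS, conditioned on the full
clinico-pathological covariate set, group-categorical or one-vs-rest.

## Worked example

```python
import crcmolclass as cm

model = cm.build_joint(cm.DEFAULT_MARGINALS, cm.DEFAULT_EDGES)
print(round(model.cell_probability({"msi": 0, "cin": 0}), 3))  # 0.212
print(round(model.cell_probability({"msi": 1, "cin": 1}), 3))  # 0.026

cohort = cm.simulate_cohort(cm.GeneratorConfig(n=906, seed=7))
classified, summary = cm.classify_cohort(cohort)
print(summary.counts["3"])                                     # 87
fits = cm.group_survival_analysis(cohort, mode="one_vs_rest")
fit = fits["group3"]
print(round(fit.hr("group3"), 2))                              # 1.7
```

The first two numbers are the exact model probabilities of the
double-negative (MSI⁻CIN⁻) and double-positive (MSI⁺CIN⁺) configurations —
21% and 3% of tumours.  The cohort draw yields 87 group-3 tumours
(KRAS/PIK3CA-mutant, CIN⁺, TP53-wild-type), and the one-vs-rest Cox fit
recovers a hazard ratio of 1.7 for group 3 (the generator plants 1.59),
with every other group indistinguishable from the rest.  The
`examples/` directory has one narrative script per capability, each
printing its numbers with a line on what they mean; `crcmolclass run
--seed 7 --out pipeline_out` runs every stage and renders an HTML report.

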