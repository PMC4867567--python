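# chmnat — natural history and genotype–phenotype analysis of choroideremia

Choroideremia (CHM) is an X-linked retinal dystrophy caused by mutations in
the *CHM* gene, whose product, Rab escort protein 1 (REP-1), is required for
Rab prenylation. Affected males develop nyctalopia in childhood, then
progressive constriction of their visual fields and, late in life, loss of
central acuity. Planning gene-therapy trials for CHM requires answering three
questions from cross-sectional clinic data: *when* does each visual metric
start to decline (the **critical age**), *how fast* does it decline
afterwards, and *whether* the mutation class predicts a milder course (it
does not appear to).

`chmnat` implements that analysis pipeline for cohorts of affected males —
one row per subject with the family's HGVS `c.` mutation, age, onset ages,
per-eye best-corrected acuity and per-eye horizontal visual-field width —
together with a synthetic-cohort generator so every stage can be exercised
and calibrated without patient-level data.

## What it computes

- **Normalization** — Snellen fractions and semiquantitative grades to
  logMAR (CF = 1.9, HM = 2.3, LP = 2.7, NLP = 3.0); better-eye selection
  (min logMAR, max field width); decade binning and stratified
  mean ± SD/median summaries with severity bands.
- **Critical age** — subjects are grouped by decade; a Kruskal–Wallis ANOVA
  with Dunn's pairwise z-tests runs over the groups, and the youngest groups
  are pooled iteratively until the pooled group differs significantly from
  the next-oldest decade. The age bounding the pooled group is the critical
  age *c*, and one OLS regression of the metric on age is fitted per phase:

  y(age) = β₀ + β₁·age (age ≤ c),  y(age) = γ₀ + γ₁·age (age > c)

  with t-based 95% CIs on the slopes.
- **Onset survival** — Kaplan–Meier curves of symptom-free fraction per
  genotype group (missense / REP-1-absent / other), log-rank (or
  Wilcoxon–Breslow) comparison, right-censoring at the assessment age.
- **Intereye agreement** — Spearman rank correlation between fellow eyes.
- **Mutation spectrum** — HGVS-dialect classification cascade
  (whole-gene/exon deletions and duplications, start-codon, nonsense,
  frameshift, splice, missense), family-level class counts, Pearson χ²
  goodness-of-fit against a genome-wide reference distribution.
- **Protein stability** — two-state unfolding propensity
  U = exp(ΔΔG/RT)/(1 + exp(ΔΔG/RT)) with effective RT = 0.6 kcal/mol, and an
  additivity check for double mutants.
- **Trial design** — years until a declining field width exits the
  test–retest variability band: t = f·baseline/rate (f = 0.17–0.22).

## Worked example

```python
from chmnat import CohortConfig, simulate_cohort, CriticalAgeModel

cohort = simulate_cohort(CohortConfig(seed=1))     # 128 affected males
print(CriticalAgeModel(cohort, metric="va").fit().summary())
```

```
Critical-age analysis: visual acuity (logMAR)
==========================================================
critical age: 40 years
  pooled    1–10 vs 11–20: z =  -0.77, adj. p = 0.4385
  pooled    1–20 vs 21–30: z =  -0.98, adj. p = 0.3266
  pooled    1–30 vs 31–40: z =   1.78, adj. p = 0.0755
  pooled    1–40 vs 41–50: z =  -2.58, adj. p = 0.0099  *
phase 1: slope -0.0011/yr (95% CI -0.0028 to 0.0006; P = 0.216; n = 74)
phase 2: slope +0.0428/yr (95% CI 0.0282 to 0.0573; P = 2.89e-07; n = 54)
```

Acuity is stable through age 40 (phase-1 slope indistinguishable from zero),
then worsens by ≈0.04 logMAR per year; the pooling trace shows each
pooled-vs-next comparison and the first significant one fixes the break.
The same cohort's trial-design arithmetic:

```python
from chmnat import trial_design_estimate
est = trial_design_estimate(age=20)
print(f"baseline {est.baseline_width}°, {est.years_to_detectable} years to detectable change")
# baseline 38.0°, 9.6 years to detectable change
```

i.e. a 20-year-old with a 38° field declining 0.868°/year needs 9.6 years of
follow-up before the loss exceeds 22% Goldmann test–retest variability.

The same analyses are available from the shell:

```bash
chmnat simulate --n 128 --seed 1 cohort.csv
chmnat critical-age cohort.csv --metric va
chmnat survival cohort.csv --symptom nyctalopia
chmnat trial-design --age 40
```

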