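# Methods

## The biphasic natural-history model

Cross-sectional visual metrics in choroideremia are modelled as two linear
phases of the better eye's value against age: a quiescent phase up to a
critical age *c* and a declining phase after it. The model is deliberately
nonparametric about *c*: rather than estimating a continuous breakpoint
(e.g. segmented least squares), *c* is restricted to decade boundaries and
found by an inclusion/exclusion procedure on decade groups:

1. Group subjects by decade of age at assessment (1–10, 11–20, …, 71–80);
   empty decades are skipped, not treated as zero-size groups.
2. Run a tie-corrected Kruskal–Wallis ANOVA over the current groups and
   Dunn's pairwise z-tests on the pooled mean ranks, with the variance term
   N(N+1)/12 − Σ(t³−t)/(12(N−1)).
3. Compare the youngest (pooled) group with the next-oldest decade. If not
   significant, merge them and repeat from 2; if significant, the upper age
   bound of the pooled group is the critical age.
4. Fit OLS of the metric on age separately for subjects at or below *c* and
   above *c*; 95% CIs and p-values for the slopes come from the t
   distribution with n − 2 df. If no comparison is ever significant a single
   whole-range regression is reported instead.

The procedure terminates in at most (number of non-empty decades − 1) steps
and the full pooling trace (pooled bins, z, adjusted p per step) is kept on
the results object as an audit trail.

**Multiplicity of the pooled-vs-next comparison.** Three readings of
"Dunn's correction" are implemented (`comparison=` on `CriticalAgeModel`):

* `selected` (default): the z statistic is computed on the ranks of all
  current groups, and the single comparison actually examined per step is
  tested at α uncorrected. This corresponds to re-running the omnibus test
  after each pooling and selecting one comparison per run.
* `all_pairs`: the same z, Bonferroni-corrected over all k(k−1)/2 current
  pairs.
* `two_group`: a fresh two-group rank test of pooled vs next only.

The default was chosen because, under the study conditions built into the
generator, it is the reading that recovers the published critical ages (40
years for acuity, 20 for fields) as the modal result; the all-pairs
correction systematically detects the break one decade late. Type-I
protection of the procedure as a whole is still testable via `all_pairs`
(the no-age-effect property test uses it).

Sign conventions: acuity slopes are in logMAR/year (positive = worsening);
field slopes are fitted in degrees/year and reported as a positive loss via
`CriticalAgeResults.decline_rate`.

## Onset survival and intereye agreement

Self-reported onset ages are analyzed with the Kaplan–Meier product-limit
estimator (via lifelines); a subject with no recorded onset is right-censored
at his age at assessment — the standard rule, adopted because a
retrospective chart review cannot distinguish "no symptom yet" from any
alternative. Genotype groups are compared with the log-rank (Mantel–Cox)
test by default; Wilcoxon–Breslow weighting is available since the original
test behind the published onset P-values is not named. Two median
conventions are carried: the step-function median (first time with S ≤ 0.5,
the lifelines convention) and an interpolated median that averages with the
next event time when S lands exactly on 0.5 (the classic even-n sample
median — this is the convention under which a median onset of 10.5 years can
arise from integer onset ages). Intereye agreement is Spearman's rho on
complete fellow-eye pairs (midranks; pairs with a missing eye are dropped).

## Variant classification

The HGVS `c.` dialect of CHM mutation tables is handled by a deterministic
cascade over the coding change and its free-text protein annotation, after
normalizing typographic dashes and an upper-case `C.` prefix:

1. "complete gene deletion" → whole-gene deletion (REP-1 absent);
2. exon-level rearrangements (breakpoint-uncertain `?` ranges or "deletion/
   duplication of exon(s)" annotations) → exon deletion/duplication; a
   deletion reaching the 5' UTR removes the start codon (REP-1 absent), and
   one additionally spanning into the 3' UTR is a whole-gene deletion;
3. a protein consequence containing `fs` → frameshift (this covers intronic
   changes whose annotated consequence is a frameshift);
4. `p.Xxx###*` → nonsense;
5. a substitution at coding positions 1–3 or a "start codon" annotation →
   start-codon loss (REP-1 absent);
6. an intronic ±offset position or a "splice" annotation → splice site;
7. `p.Xxx###Yyy` (or one-letter `p.X#Y`) → missense;
8. anything else → `other`, with a warning, never an exception.

Structural lesions outrank protein-level consequences (rules 1–2 before
3–4) because an exon deletion predicted to frameshift downstream is still a
deletion; with this ordering the bundled 106-family table reproduces the
published family accounting (22 gene/exon-deletion-or-start families, 21
frameshift, 2 duplication, 4 missense). Spectrum counts are per family: a
family with two variants counts once per class it contains but once in the
family total. Genotype groups for phenotype comparisons: `missense` if any
variant is missense; `rep1_absent` if every variant ablates expression at
the source (whole-gene deletion, start-codon loss, or a deletion removing
exon 1); `other` otherwise.

Known limitation: only the dialects occurring in such tables are parsed; no
genome coordinates, no validation against the reference transcript.

## Unfolding propensity and trial design

A mutation's stabilization free-energy change ΔΔG (kcal/mol, positive =
destabilizing) is mapped onto the probability of the unfolded state under a
two-state folded↔unfolded Boltzmann model, U = exp(ΔΔG/RT)/(1+exp(ΔΔG/RT)).
The effective RT is 0.6 kcal/mol. This constant is *inferred*, not printed
in any source: it is the single value that reproduces all six bundled
REP-1 mutant propensities to three decimals (0.467 → 0.685, 1.482 → 0.922,
and four saturated rows → 1.000), and physiological RT (0.59–0.62) does
not. The tests assert this one-parameter global fit. ΔΔG values are inputs;
no free-energy computation from structure is attempted.

The trial-design horizon treats one test–retest variability half-width as
the smallest detectable field change: t = f·w₀/rate, with f = 0.22 by
default (the upper bound of Goldmann variability reported for retinitis
pigmentosa; 0.17 available via the argument), w₀ the baseline width and the
rate defaulting to the fitted post-break decline of 0.868°/year anchored at
38° at age 20.

## The synthetic cohort generator

`simulate_cohort(CohortConfig(...))` emulates the structure of the study
cohort; defaults are the study conditions and all sampling is deterministic
given `seed`.

* **Ages**: drawn per decade with counts (10, 28, 17, 19, 24, 15, 12, 3)
  (sum 128), uniform integer ages within each decade; field measurements are
  assigned per decade with counts (5, 16, 7, 7, 15, 10, 4, 0) (sum 64).
  `CohortConfig.vf_study()` generates the field-assessed subcohort directly
  (n = 64, fields on every subject). Other cohort sizes scale both count
  vectors by largest remainder.
* **Acuity**: expected better-eye logMAR is flat near baseline 0.05
  (slope 0.001/yr) to the break at 40, then rises 0.048 logMAR/yr.
* **Fields**: a high-variance plateau at 73.5° (the n-weighted mean of the
  two pre-break decade means) up to the break at 20, then
  max(floor, 38 − 0.868·(age − 20)) with a 2° floor representing the
  residual central island of late disease.
* **Noise**: heteroskedastic, using each decade's published sample SD (VA:
  0.118 … 0.231; VF: 51 … 2). The noise family is a *floored lognormal*
  matched to the target mean and SD — VA values are a lognormal above the
  best recordable acuity (−0.1), VF above 0 — because the published decade
  medians sit far below the means (e.g. VA 0.5 median vs 0.818 mean at
  51–60), i.e. the data are right-skewed above a physical floor. A symmetric
  clipped-Gaussian alternative (`noise="gaussian"`) is kept for null
  calibration; under rank tests, clipping a wide symmetric distribution at
  the acuity floor places *old* subjects below young ones, which no real
  cohort does.
* **Fellow eyes**: a Gaussian copula with Pearson parameter
  r = 2·sin(πρ/6) targets the intereye Spearman ρ (VA 0.76, VF 0.95);
  because the lognormal transform is monotone, the copula's rank correlation
  passes through unchanged (up to clipping), and the generator recovers the
  configured ρ within ±0.05 at n = 64.
* **Onsets**: truncated normal at ≥ 1 year (nyctalopia mean 12.6, SD 8.4 —
  the SD recovered from the published SEM 1.0 at n = 71; other symptoms
  19.7, SD 11.0), kept only if ≤ the subject's age; an `onset_report_prob`
  of 0.58 emulates the observed reporting fraction (≈71/128). Unreported
  onsets are right-censored at the assessment age.
* **Genotypes**: families (≈106 per 128 subjects; the surplus subjects join
  existing families) draw a mutation class with probability proportional to
  the class's family count in the bundled spectrum, then a representative
  variant of that class.

What the generator does **not** emulate: within-subject correlation between
acuity and fields (independent given age), measurement quantization of
Snellen charts (unless `semiquant_recode=True`, which re-codes logMAR ≥ 1.9
to CF/HM/LP/NLP), instrument differences (Humphrey/MAIA widths pool with
Goldmann unscaled), longitudinal follow-up (the design is cross-sectional),
and any genotype–phenotype dependence (none was found in the data the
defaults describe). Passing recovery tests therefore show that the
*procedure* recovers the generating structure at the study's sample sizes
and noise levels — not that real cohorts satisfy the generating assumptions.

## Numerical and design notes

* Kruskal–Wallis is delegated to scipy (tie-corrected H, χ² reference);
  all-identical groups return H = 0, p = 1 by definition. Dunn's z-test is
  implemented directly (no post-hoc library dependency); OLS is statsmodels;
  KM/log-rank are lifelines; Spearman and the spectrum χ² are scipy.
* Degenerate phase regressions: < 3 points or zero age variance raise;
  a constant response returns slope 0 with p = 1.
* Decade bins are closed integer intervals; fractional ages are floored.
* Acuity severity bands are closed on the better-vision side
  ((−∞, 0.3], (0.3, 0.54], (0.54, 1.0], (1.0, ∞)).
* The cohort table's missing-value token is `NC` (case-insensitive);
  write∘read round-trips records exactly (floats serialized by `repr`).
* Simulation study sizes (100 seeds for modal critical ages, 200 replicates
  for slope recovery, 1,000 replicates for type-I calibration) were chosen
  so that sampling error in the reported rates is small relative to the
  effects examined.

## Known limitations

* The critical-age procedure inherits the decade grid: it cannot place a
  break at, say, 35, and its power at a true break depends on the adjacent
  decade's sample size. Under the built-in study conditions the exact-recovery
  rate is limited by the n = 7 decade adjacent to the field break; the modal
  recovered break is nevertheless the generating one for both metrics.
* The propensity model is two-state with an inferred effective temperature;
  it reproduces the catalogued values but should not be read as a
  thermodynamic measurement.
* Family-level spectrum counts depend on the annotation conventions of the
  input table; prose tallies that mix per-mutation and per-family accounting
  (as published abstracts sometimes do) will not reconcile exactly.
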