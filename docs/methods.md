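# Methods

## Model and assumptions

`sumroc` estimates the discrimination (ROC/AUROC) of a SNP risk panel from
summary statistics by *reconstruction*: it builds a synthetic case/control
population whose per-SNP allele counts are exactly those implied by the
published odds ratios and risk allele frequencies, then measures the
discrimination of a risk model fitted to that population.  The approach
rests on three assumptions:

1. **Allelic model.** The published OR is the allelic odds ratio (risk vs.
   non-risk allele) and the RAF is the risk allele frequency among control
   chromosomes.  Given those, the case-group allele counts follow from the
   2×2 allele-table identity; the ceiling function makes them integers.
2. **Independence of SNPs.** Panel SNPs are simulated with no linkage
   disequilibrium.  Reported panels are typically LD-pruned genome-wide
   hits, so this is usually benign, but discrimination will be
   overestimated for panels of correlated SNPs.
3. **No covariates or interactions.** The risk model is main-effects
   logistic regression on 0/1 carrier indicators; age, sex, population
   structure and epistasis are out of scope.

### Allele placement

The equations fix the *totals* Hs and Ds per group; how alleles combine
into individuals is not determined by the summary data.  We place the
alleles by a uniform random permutation over the group's 2N allele slots
and pair consecutive slots into individuals, so an individual's risk-allele
count is hypergeometric — the finite-population analogue of Hardy–Weinberg
genotype draws, with the allele totals conserved *exactly* for every seed.
Binarization follows the inheritance coding: dominant (≥ 1 risk allele,
the default), recessive (2), or the alternating per-SNP schemes
`odd_dominant` / `odd_recessive` (odd-indexed SNPs, counting from 1, take
the named coding and even-indexed SNPs the other), which cover the case
where the true inheritance model varies across a panel and is undisclosed.

### Risk model

* **Split.** Stratified 70/30 train/test (the source method says only
  "randomly split"; 70/30 is the package's choice, seed-controlled and
  recorded in every output).
* **Multicollinearity rule.** VIF_j = 1/(1 − R²_j) per SNP column, with
  1 − R² < 1e-10 reported as infinity.  Ridge replaces the standard fit
  only when ≥ 2 VIFs are infinite — i.e. under exact duplication of
  columns, which the 0/1 reconstruction can produce for SNPs with
  near-identical OR/RAF.  The cutoff's exact value is non-critical (finite
  alternatives move the AUROC by well under 0.01 in practice); single-SNP
  panels skip the screen.
* **Fitting.** Unpenalized maximum likelihood (scikit-learn lbfgs,
  tol 1e-10) for the standard model.  Ridge tunes λ on a 13-point
  log-spaced grid 1e-4…1e4 by nested CV: inner 2-fold AUROC selects λ
  within each outer fold; the outer 3-fold held-out AUROCs average into
  `cv_auroc`; the final model refits all training data with the modal
  (tie → smallest) λ.  Features are not standardized — 0/1 carriers are
  already on a common scale, so the penalty treats SNPs symmetrically.
* **Separation.** If the unpenalized fit diverges (|coefficient| > 30) or
  its linear predictor separates the training classes completely, the ML
  estimate does not exist; the fit falls back to ridge at the smallest
  grid penalty and the model record is flagged.
* **Headline AUROC** is the held-out test-set value (`cv_auroc` is kept
  as a diagnostic).  AUROC itself is the tie-corrected pair-counting
  (Mann–Whitney) statistic; the trapezoid area of the threshold-sweep
  polyline equals it to 1e-12 and is used as a cross-check in the tests.

### DeLong's test

Implemented from the structural components (midrank formulation).  The
default is the *unpaired* variant — variances add with zero covariance —
because the compared curves here come from disjoint cohorts (a real-data
curve vs. a reconstructed-population curve); a paired variant is available
for same-sample comparisons.  Zero pooled variance returns p = 1 when the
AUROCs are equal and p → 0 otherwise.

### Heritability

`var(g) = 2 Σ RAF_k (1 − RAF_k) (ln OR_k)²` (natural log), and
`h² = var(g)/(var(g) + π²/3)` on the logistic liability scale — no disease
prevalence needed.  The discrimination route uses `h² = (2·AUROC − 1)²`
with inverse `AUROC = (1 + √h²)/2`; both `h²_auroc` and Somers' D are
reported per study.  Report tables round half-up to 3 decimals.

## Synthetic truth generator

`gen_individual_study` emulates a raw genotype study: per SNP, control
allele frequency f and allelic OR give the case frequency
`f_case = OR·f/(1 − f + OR·f)`, and genotypes are two independent allele
draws per individual (Hardy–Weinberg within group), SNPs independent.
What it deliberately does **not** emulate: LD between SNPs, genotyping
error, population stratification, covariate effects, or ascertainment
bias.  Validation results therefore show that the reconstruction recovers
discrimination *when the summary statistics are faithful and SNPs are
independent* — they do not certify performance on panels violating those
assumptions.

The validation experiment generates studies of 2000 cases / 3000 controls
with 1–10 SNPs, allelic OR uniform on [1.1, 3.0] and control RAF uniform
on [0.05, 0.95], cycling the four inheritance codings across studies; the
"true" AUROC is fitted on the raw genotypes, the predicted AUROC comes
from the summary-level pipeline, and the curves are compared with the
unpaired DeLong test at the 0.05 level.  The default batch size of 20
studies gives a stable mean-absolute-error estimate in a few seconds;
observed mean errors are ≈ 0.01–0.015 AUROC with these settings.

## Numerical choices and degenerate inputs

* `Ds` is clamped to [0, 2·N_case] with a logged warning; the ceiling
  expression cannot exceed the bound analytically, so the clamp guards
  only floating-point pathology at extreme OR × RAF.
* The implied allelic OR of the integer counts deviates from the input OR
  by at most 1/Ds + 1/Dn (one ceiling, one allele); equivalently the case
  RAF matches `OR·Hs/(Hn + OR·Hs)` to within 1/(2·N_case).  At corners
  where the case group holds only tens of non-risk alleles (high RAF ×
  high OR at N ≈ 1000) this rounding can reach a few percent of the OR —
  an intrinsic property of integer allele counts, not an implementation
  tolerance.
* Summarizing synthetic raw data applies the Haldane–Anscombe +0.5
  correction to zero cells of the allele table; the association p-value
  (chi-square, no continuity correction) is carried as metadata only and
  never used in fitting.
* RAF = 0 or 1 produces constant feature columns; they carry no
  information, get a zero coefficient under ridge, and are reported with
  infinite VIF.
* Per-study seeds in batches derive from (master seed, CRC32 of study id)
  through a `SeedSequence`, making batch results independent of study
  order; all seeds stay below 2³¹.

## Problem sizes

Defaults follow the source studies' own scale: simulated populations equal
the study's reported case/control counts (an integer `scale` factor is
available for stability checks — the predicted AUROC moves by < 0.01 under
scaling because the reconstruction is frequency-exact).  The test suite
uses panels up to 10 SNPs and populations up to 20,000 individuals;
single-study runs at 50,000 individuals complete in seconds, and panels of
at least 200 SNPs are supported.

## Known limitations

* Discrimination is conditional on the published panel; it is not a
  genome-wide heritability estimate, and `h² = (2·AUROC − 1)²` inherits
  whatever bias the AUROC estimate has.
* The inheritance coding of published panels is usually unknown; results
  under the four codings can differ, and the dominant default is a
  convention, not an inference.
* For panels with strongly correlated SNPs the independence assumption
  overstates the effective information and hence the AUROC.
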