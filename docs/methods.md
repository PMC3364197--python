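# Methods

## Scope and data model

The package re-implements a 13-SNP genetic risk score (GRS) analysis for
late-stage age-related macular degeneration as a library.  Its inputs
are (a) a SNP panel file fixing identity, locus grouping and risk-allele
orientation of each variant, and (b) a subjects × SNPs risk-allele
dosage table (0/1/2, no missing values) with case/control status and
optional age, sex and AMD-subtype covariates.  Dosage always counts the
*risk* allele; the panel is the single source of orientation truth, and
no strand harmonisation or imputation is attempted.  An optional VCF
importer counts panel risk alleles from GT fields, rejecting
multi-allelic records and missing genotypes.

Because the original study's individual-level genotypes were never
deposited, the package also carries its published summary statistics
(per-SNP arm frequencies, single-SNP odds ratios, within-locus r²,
five-category composition, margins 986 cases / 796 controls) as
machine-readable constants, used for the published-result computations
and as the default parameterisation of the simulator.

## Synthetic cohorts

The generator draws subjects from a population logistic disease model:
genotypes `g_i` under Hardy-Weinberg equilibrium at specified
risk-allele frequencies, disease with probability
`sigmoid(α + Σ β_i g_i)`, and retrospective sampling by rejection until
exactly `n_cases` and `n_controls` are collected.  Defaults are the
study conditions: published control frequencies as population
frequencies, `β_i = log` of the published single-SNP odds ratios,
n = 986/796, and a target population prevalence of 15% (the assumed AMD
prevalence above age 85).  A single integer seed drives all randomness.

**Intercept calibration.** α solves
`E[sigmoid(α + Σ β_i g_i)] = prevalence` exactly: the burden
`Σ β_i g_i` has a finite distribution (3^13 ≈ 1.6M atoms for the full
panel) built by convolving per-block genotype distributions, and the
strictly increasing prevalence curve is inverted by Brent bracketing
(xtol 1e-12).  Exact enumeration was preferred over Monte Carlo even
for the full panel because it is fast (<1 s) and removes simulation
error from every downstream calibration; an independent 10⁶-draw Monte
Carlo oracle confirms it in the tests.  Calibrations are cached on the
disease-model parameters, so replicate simulations pay once.

**Linkage disequilibrium (optional).** Within a locus group, non-lead
SNPs can be coupled to the lead through two-locus haplotype frequencies
chosen to hit a target r² (positive risk-allele coupling, conditional
independence between followers given the lead allele); loci are
independent of each other, and subjects are two independent haplotypes.
Not every published r² is attainable this way: the APOE pair
(frequencies 0.079/0.881, target r² 0.783) is far outside the feasible
region — in reality those two risk alleles ride on *different*
haplotypes — and the CFH rs6677604 target (0.203, max 0.165) is
marginally outside.  Infeasible targets are clipped to the feasible
maximum with a warning.  The default configuration keeps all SNPs
independent, which also makes the simulating per-allele odds ratios
exactly the joint-model coefficients being recovered.

**What the simulator does not emulate.** Age, sex and smoking have no
effect on simulated disease (the risk model is purely genetic), real
within-CFH haplotype structure is reduced to pairwise coupling with the
lead SNP, and population stratification, genotyping error and
missingness are absent.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
model, not robustness to those real-data complications.  One visible
consequence: at 15% prevalence the disease is not rare, so simulated
*case* allele frequencies at strong loci sit systematically below the
published case frequencies (the published values reflect the real
cohort, not a 15%-prevalence logistic model); the test oracle for case
frequencies marginalises the disease probability over the other 12 SNPs
exactly rather than using the single-SNP rare-disease shortcut.

## Statistical conventions

- **Logistic fits** are maximum likelihood (Newton, log-likelihood
  tolerance 1e-8, ≤100 iterations) with Wald CIs and two-sided Wald
  p-values; a likelihood-ratio p is available by flag.  Models are
  unadjusted by default, with optional age/sex adjustment for
  sensitivity analysis.  Non-convergence, separation and rank
  deficiency raise errors naming the offending SNPs.
- **Hardy-Weinberg** uses the exact conditional test (sum of
  probabilities of heterozygote counts no more probable than observed,
  given allele counts), computed in log space; a violation is reported,
  never grounds for exclusion, mirroring the original panel's retention
  of its one HWE-violating variant.
- **AUC** is Mann-Whitney with midrank tie handling (ties credited
  0.5), identical to the trapezoidal area under the empirical ROC.  The
  enumerated single-SNP AUC from genotype distributions
  `Σ_ij c_i u_j ([i>j] + ½[i=j])` gives 0.67308 at the published CFH
  case/control frequencies (0.600/0.365).
- **GRS** is the fitted linear predictor including the intercept; no
  further centering or standardisation is applied.  On that scale the
  in-sample OR per GRS unit is e exactly (the joint fit's score
  equations force the refit slope to 1), which the package exploits as
  a self-calibration check.
- **Subgroup contrasts** use Welch's t by default (the pooled-variance
  test is a flag), with normal-approximation 95% CIs on group means and
  a Bonferroni threshold of 0.05/3 for the three planned subgroup
  comparisons (age, sex, subtype).
- **Categories** are equal-width over the pooled observed GRS range,
  right-closed (a score on a cut point falls in the lower category),
  five by default.  Category odds ratios versus the middle category use
  the conditional MLE with exact conditional 95% CIs; a Wald/Woolf
  interval was rejected because the top category can hold a single
  control, where exact conditional inference needs no continuity
  correction.  Screening sensitivity/specificity carry Clopper-Pearson
  exact CIs.
- **Projection** weights case counts by
  `w = (π/(1−π))·(N_controls/N_cases)`, the unique factor making the
  weighted case fraction equal the prevalence π.  The published
  category percentages are turned back into counts by
  `round(pct × margin)`; since the printed per-category sample sizes do
  not reconcile exactly with the percentage rows, the percentages are
  treated as authoritative and both integer and fractional
  reconstructions are exposed.  The reconstructed counts sum to 985
  cases (one short of the margin), so category tables may carry
  explicit arm margins — the weight uses the stated margins, and
  modeled population fractions are normalised over categories so they
  sum to one exactly.
- **Cross-validation** is simple random subsampling (2/3 train, 1/3
  test, 2000 repeats by default) refitting the joint model per repeat
  and scoring held-out subjects with training weights only; the CI on
  the mean is a normal approximation over repeats (percentile CI by
  flag); stratified splitting is optional.  Note that conditional on a
  single finite cohort the mean held-out AUC inherits that cohort's
  chance association, so null calibration is asserted across
  independent cohorts.
- **Parsimonious search** greedily drops whole locus groups ranked by
  single-locus AUC (weakest first), refitting at each step; an
  exhaustive leave-one-locus-out sweep is provided alongside so
  non-greedy choices are representable.  The smallest model within an
  AUC tolerance (default 0.001) of the full model is flagged.

## Problem sizes in tests

The default suite exercises study-scale cohorts (986/796) where the
check needs them — parameter-recovery coverage runs 500 such replicates
— and smaller cohorts (a few hundred subjects) and 15–200
cross-validation repeats where the property under test does not depend
on scale; those sizes keep the full suite under a minute on one core
while leaving every Monte-Carlo tolerance at 3 standard errors or
tighter.

## Known limitations

Absolute risks and predictive values are only as good as the assumed
prevalence schedule; the case-control design cannot estimate prevalence
itself.  The equal-width category scheme is fixed, not optimised, by
design.  Exact category ORs become one-sided (infinite bounds) when a
cell is empty.  The simulator's LD option cannot represent
negative-coupling or multi-haplotype loci (see above), and published
within-locus r² values measured on reference panels need not be
attainable at the study's risk-allele frequencies.
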