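# Methods

This note records the statistical model behind each module, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions made where the design was
genuinely open.

## Data model and harmonization

A summary-statistics table is one row per biallelic SNP: identifier,
chromosome/position, effect and other allele, effect-allele frequency
(EAF), per-allele effect (log-odds for binary traits), SE, two-sided p,
and sample size. Validation drops rows with non-positive SEs, non-ACGT or
identical alleles, EAF outside (0,1) or p outside (0,1]; indels and
multi-allelic records are rejected because the instruments this package
is built for are biallelic SNPs. Missing p-values are back-filled from
the two-sided normal approximation on beta/SE, the convention at GWAS
sample sizes. Duplicate identifiers keep the most significant row.

Harmonization expresses two traits' effects on a shared effect allele:
direct match, effect/other swap (negating the outcome beta, complementing
its EAF), strand complement, or complement-plus-swap. Palindromic SNPs
(A/T, C/G) cannot be resolved from allele letters; those with minor-allele
frequency above 0.42 in either trait are removed, and the remainder are
resolved by requiring both traits' EAFs to agree on which allele is minor
— if either EAF is missing the SNP is dropped (the conservative choice;
letters alone cannot decide). Finally every row is oriented so the
exposure effect is non-negative. Orientation negates both betas and
complements both EAFs, so each SNP's Wald ratio is unchanged exactly.

## Instrument selection

The cascade runs in this order: exposure significance filter (default
p < 5e-5 — the relaxed threshold used when genome-wide-significant
instruments are too few, as in microbial-abundance GWAS — with
MAF ≥ 0.01), greedy LD clumping (r² > 0.001 within 10,000 kb removes the
weaker SNP; ties on p break by chromosome, position, identifier),
harmonization with the outcome, exclusion of SNPs already associated with
the outcome (p < 5e-5), and Steiger directionality filtering. Instrument
strength is summarized by per-SNP F = (beta/SE)² and its mean; mean
F > 10 is the conventional bar. The F statistic characterizes the set by
default and only drops individual SNPs when an explicit `f_min` is set,
because silently removing SNPs on a strength criterion changes the
selection in ways a reader cannot audit; every removal is recorded in a
provenance list whose counts sum exactly to input minus output.

Steiger filtering recovers each trait's variance explained from
(p, n) by inverting the 1-df F test, r² = F/(F + n − 2), which needs no
variance model and therefore treats binary outcomes on the same footing;
for p below ~1e-16, where the F quantile overflows in double precision,
the 1-df chi-square quantile (its large-n limit) is used. A SNP is kept
iff r²_exposure > r²_outcome (strict); a z-test on the difference of
Fisher-transformed correlations marks SNPs "uncertain" at p > 0.05, which
are kept by default when the point inequality favours the exposure
(conservative dropping is a flag).

Clumping runs against a user-supplied LD panel (a symmetric r² matrix
plus positions) rather than external tooling, so the whole cascade is
testable offline; the clumped set satisfies, by construction and by
brute-force test, that no retained pair has r² above threshold within the
window.

## Estimators

All estimators consume harmonized per-SNP pairs (γ̂, σ_γ, Γ̂, σ_Γ) and
report beta, SE, normal-approximation 95% CI and two-sided p.

* **IVW** — weighted regression of Γ̂ on γ̂ through the origin, weights
  1/σ_Γ². The SE uses multiplicative random effects by default: the
  fixed-effects SE is inflated by √(Q/(n−1)) when Cochran's Q is
  overdispersed, and never deflated. Q and its χ²_{n−1} p-value ride in
  the extras.
* **Maximum likelihood** — profile of the joint normal likelihood over
  the causal effect and the true SNP-exposure effects; for fixed β the
  nuisance effects have a closed-form optimum, leaving
  Σ (Γ̂−βγ̂)²/(σ_Γ²+β²σ_γ²) to minimize numerically from the IVW start.
  SE from the profile curvature.
* **Weighted median** — interpolates the IVW-weighted percentile
  function of sorted Wald ratios at 50%; breakdown at half the weight.
  The SE is a parametric-bootstrap SD drawn from the *fitted* model
  (exposure effects about their estimates, outcome effects about the
  fitted ratio line). Centering outcome draws on the observations
  instead would count their noise twice, which for a median inflates the
  SE by ~10–15% and makes the null test anticonservative (type-I ~2–3%
  instead of 5%); the fitted-model bootstrap calibrates to nominal. The
  trade-off: the resampling assumes the valid-instrument model, so under
  heavy contamination the SE describes the valid-cluster fit rather than
  the contaminated mixture.
* **MR-Egger** — adds an intercept to the weighted regression; the
  intercept and its p-value test directional pleiotropy under InSIDE,
  with the same random-effects inflation (residual dispersion floored at
  1).
* **MR-PRESSO** — the observed residual sum of squares compares each
  SNP's outcome effect with its leave-one-out IVW prediction; the null
  distribution comes from 1000 parametric simulations under the
  no-pleiotropy model. Per-SNP outlier p-values are Bonferroni-corrected
  over SNPs (note: detecting any outlier at all therefore needs
  n_sim ≳ 20·n_snp). The corrected estimate is IVW without the flagged
  SNPs, and a distortion test compares the raw-vs-corrected shift with
  random removals of the same size.
* **dIVW** — subtracts the exposure-side sampling variance from the IVW
  denominator, Σ(γ̂²−σ_γ²)/σ_Γ², removing weak-instrument attenuation; SE
  by the estimating-equation sandwich. A non-positive denominator is
  raised as a weak-instrument signal, not silently patched.
* **Contamination mixture** — per SNP the larger of a valid-component
  likelihood N(β, se²) and an invalid-component likelihood N(0, se²+ψ²),
  profiled over a 2001-point grid spanning the ratio range ±3 max SE;
  ψ = 1.5 × SD of the ratio estimates by default. The CI is the grid
  region within χ²₁(0.95)/2 of the maximum and widens monotonically in ψ.
* **MR-RAPS** — solves the adjusted profile score with standardized
  residuals t_j = (Γ̂−βγ̂)/√(σ_Γ²+β²σ_γ²+τ²) under a Huber (default),
  Tukey or l2 loss, fitting the overdispersion τ² jointly (τ² is set to
  zero when the dispersion equation has no positive root). The variance
  is the expected-information form E[ψ(Z)²]/(E[ψ′(Z)]² · Σ(γ̂²−σ_γ²)/s²),
  with E[ψ′(Z)] = E[Zψ(Z)] by Stein's identity; a realized-residual
  sandwich was measurably anticonservative (coverage ~92% instead of
  ~95%) because the robust estimator's finite-sample tails are heavier
  than fitted residuals suggest. With the l2 loss, no overdispersion and
  σ_γ = 0 the estimator and SE reduce to maximum likelihood.
* **cML-MA** — for each candidate invalid count K, a constrained ML that
  lets exactly K SNPs carry a free pleiotropy offset (chosen each
  iteration by largest likelihood gain); per-K estimates are combined
  with BIC weights, and the variance adds the between-model spread. The
  deterministic no-data-perturbation variant is the default; K = 0
  reproduces the ML solution exactly. Per-K SEs come from the profile
  information restricted to the valid SNPs.

All two-sided p-values use the normal approximation on beta/SE.

## Sensitivity battery and evidence tiers

The report stores Cochran's Q (which equals the weighted residual sum of
squares of the IVW fit), the Egger intercept test, the PRESSO global and
outlier tests, leave-one-out IVW estimates, Steiger retention counts and
a reverse MR (outcome as exposure, full cascade rerun). Flags are pure
functions of the stored statistics at α = 0.05: heterogeneity when the Q
p-value is below α; pleiotropy when either the Egger-intercept p or the
PRESSO global p is; outliers when PRESSO flags SNPs *and* the corrected
estimate disagrees with the raw one in sign or significance; reverse
causation when the reverse IVW is significant or fewer than half the
instruments survive Steiger filtering; and a single-SNP-driver flag when
the full set is significant but some leave-one-out estimate is not. An
outcome with no selectable instruments makes reverse MR "not evaluable"
rather than an error.

Evidence tiers: **probable causality** needs IVW p < 0.05, support from
at least three of the four secondary methods (ML, weighted median,
Egger, PRESSO — "support" meaning p < 0.05 *with the IVW's sign*, since
an opposite-signed significant estimate contradicts rather than supports)
and all four sensitivity flags off; **causality** additionally needs
IVW p below 0.05 divided by the number of exposures screened (0.05/196
for the full named-taxa panel). Missing secondary estimates count as
unsupportive with a warning. The rule is monotone: improving a secondary
p-value never demotes the tier. Flags gate only the label, never the
numbers.

Note that the first-order Q statistic over-rejects when β²σ_γ² is
non-negligible next to σ_Γ² (its weights ignore exposure noise); at the
effect sizes and sample-size ratios of real microbiome–disease analyses
this term is ~3% and harmless, but it means the heterogeneity flag is
honest only where the first-order weighting itself is.

## Multivariable MR and mediation

`MvmrSet` holds per-SNP effects for k exposures harmonized to a common
effect allele; instruments are the union of each exposure's
significance-filtered SNPs (intersection by flag), re-clumped jointly
with the smallest cross-exposure p winning ties. MVMR-IVW regresses
outcome effects on all exposures' effects without intercept, weights
1/σ_out², random-effects inflation as in IVW; the solve uses the
pseudo-inverse so an identically-zero column reduces the fit to the
univariable one, while genuinely collinear non-zero columns raise a
collinearity error. MVMR-Egger adds an intercept with rows oriented on a
chosen exposure. Conditional F statistics are reported per exposure as a
purely informational weak-instrument diagnostic.

`mvmr_ivw(debias=True)` subtracts the exposure-side sampling covariance
from the weighted Gram matrix — the multivariable analogue of dIVW.
Without it, measurement error in a weakly-measured exposure not only
attenuates its own coefficient but inflates the coefficient of any
correlated co-exposure; at mean F ≈ 30 this inflates the mediator's
conditional effect by ~7% and is the difference between ~89% and ~96%
coverage of the mediation proportion's CI in the validation suite.

Mediation: indirect = β₁β₂ with SE √(β₂²σ₁² + β₁²σ₂²) (first-order
delta, independent two-sample estimates); proportion = indirect/total
with delta variance Var(IE)/TE² + IE²·Var(TE)/TE⁴, treating the two as
independent — the covariance between them (they share instruments) is
positive, so ignoring it errs wide; a Monte-Carlo CI is available by
option. A mediator is reported only if it passes three criteria: the
exposure influences it (UVMR p < 0.05), it affects the outcome after
adjustment (MVMR p < 0.05), and the indirect effect's sign matches the
total's. On the exposure→mediator leg the outcome-association exclusion
filter is suspended: a valid instrument is *expected* to associate with a
causally downstream mediator, so that filter would remove exactly the
valid instruments whenever β₁ is sizeable at the mediator GWAS's sample
size; Steiger filtering still guards the direction.

## Synthetic-data generator

The generator emulates the statistical shape of the target design: an
exposure GWAS at microbiome-consortium scale (n = 14,306), a mediator
GWAS at biobank risk-factor scale (n = 218,369), a disease outcome at UK
Biobank scale (n = 462,341), three non-overlapping samples. Per SNP:
MAF ~ U(0.05, 0.5); instrument effects γ ~ N(0, sd) with sd calibrated so
the realized mean F of the exposure's own instruments hits a target
(default 30, typical of relaxed-threshold microbial instruments) via
E[F] ≈ 1 + sd²·mean(1/σ_γ²); sampling noise SE = 1/√(2·MAF·(1−MAF)·n)
(standardized-trait approximation; binary traits are approximated by the
same model on the log-odds scale — a documented simplification). The
causal graph is linear: mediator effect γ·β_EM + ξ, outcome effect
γ·(β_direct + β_EM·β_MO) + ξ·β_MO + α, where ξ are the mediator's own
instrument effects (default 30% of SNPs; without them the true MVMR
design is collinear and β₂ is unidentifiable — exactly why real two-step
designs need the mediator GWAS's own loci) and α is a pleiotropy offset
on a configurable fraction of invalid SNPs, optionally correlated with γ
(ρ = 0.5) to violate InSIDE. Optional block-diagonal LD (equicorrelated
blocks) correlates both the true marginal effects and the estimation
noise within blocks and emits a matching r² panel; blocks are laid out
50 Mb apart so clumping windows never span blocks. An optional reverse
path gives a fraction of SNPs primary outcome effects δ with exposure
effect = reverse_coefficient·δ, giving directionality filters something
real to catch. Everything is reproducible from a single seed, and
`true_proportion = β_EM·β_MO/β_total` holds exactly by construction.

Default effect sizes (β_EM = 0.5, β_MO = 0.1, β_direct = 0.15; mediation
proportion 25%) describe a strong mediated pathway and are used by the
estimator-level validation. The end-to-end analysis scripts instead plant
a total effect of 0.04 — the magnitude actually reported for
microbiome–sleep-disorder links — because at biobank outcome sample
sizes a total effect of 0.2 makes every instrument genome-wide
significant for the outcome, and the cascade's own outcome-association
and reverse-direction screens then (correctly, per their definitions)
remove the instruments. Passing tests on this generator shows the
machinery is correct under its linear, normal, independent-sample
assumptions; it does not establish robustness to allele-frequency
mismatch between panels, sample overlap, winner's-curse selection of
instruments, or non-linear effects, none of which are modelled.

## Validation surface and problem sizes

`scripts/acceptance.py` (and `tests/test_acceptance.py`, which calls the
same routines) recomputes: weighted-least-squares oracle agreement of
IVW and MVMR-IVW (100 random instances, agreement to 1e-10 demanded,
~1e-15 achieved); the closed-form weighted-median (0.1667), Cochran-Q
(2.0) and exact-line Egger (slope 0.3, intercept 0.05) examples; type-I
error of IVW/ML/WM/Egger under the null generator at 1000 replicates
(50 SNPs, mean F 100); CI coverage of IVW/ML/dIVW/RAPS at a true effect
of 0.1 with 100 strong instruments over 500 replicates (matched
two-sample sizes of 200,000 — under a 14k-vs-462k design the first-order
IVW weighting itself under-covers through weak-instrument attenuation,
which is a property of the estimator, not of the code); MR-PRESSO
detection of a planted 10σ outlier over 100 seeds (n_sim = 1000);
mediation-proportion recovery over 500 replicates using the debiased
two-step; and the evidence-tier rule applied to the reported screen
summary bundled in `data/uvmr_screen_reported.tsv`. These problem sizes
keep the whole validation under a minute on one CPU while leaving the
Monte-Carlo error of every rate well inside its decision band.

## Known limitations

* Binary traits are treated on the log-odds scale with the
  standardized-trait noise model; no liability-scale conversion.
* The contamination-mixture CI is grid-based; its resolution is the grid
  step (configurable).
* cML-MA ships without data perturbation; the perturbation variant of
  the published method is out of scope.
* The proportion CI ignores the indirect–total covariance (errs wide)
  and the generator shares instruments between legs as real data would.
* No proxy-SNP lookup, no LD computation from genotypes, no remote data
  fetching: the package reads local files only.
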