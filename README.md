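# netmr — two-sample and network Mendelian randomization

`netmr` implements the full causal-inference workflow used to ask whether
gut-microbiota abundances causally influence sleep disorders — and, when
they do, *through what*: instrument selection from GWAS summary
statistics, a nine-estimator two-sample MR suite, a six-part sensitivity
battery, an evidence-tier classifier, multivariable MR, and two-step
(network) mediation analysis. It is written for epidemiologists and
statistical geneticists who work at the summary-statistic level: all
inputs are delimited text tables of per-SNP associations (identifier,
alleles, EAF, beta, SE, p, n), and every stage is runnable offline
against a bundled synthetic GWAS generator with known ground truth.

## The model

For SNP *j*, let γ̂*j* (SE σ*γj*) be its association with the exposure and
Γ̂*j* (SE σ*Γj*) its association with the outcome, estimated in
non-overlapping samples. Under the instrumental-variable assumptions each
Wald ratio Γ*j*/γ*j* estimates the causal effect β, and the
inverse-variance-weighted (IVW) estimate pools them as a weighted
regression through the origin:

    β̂_IVW = Σ γ̂ⱼ Γ̂ⱼ / σ²_Γⱼ  ÷  Σ γ̂ⱼ² / σ²_Γⱼ

The suite adds estimators that relax the assumptions: maximum likelihood
(exposure-side noise), the weighted median (up to 50% invalid weight),
MR-Egger (directional pleiotropy via the intercept, under InSIDE),
MR-PRESSO (simulation-based outlier detection and correction), dIVW
(many weak instruments), the contamination mixture (invalid-instrument
classification), MR-RAPS (robust adjusted profile score with
overdispersion), and cML-MA (constrained ML model-averaged over the
number of invalid instruments).

Mediation follows the two-step design: β₁ is the exposure→mediator effect
(univariable MR), β₂ the mediator→outcome effect adjusted for the
exposure (multivariable MR). The indirect effect is β₁β₂ with
delta-method SE √(β₂²σ₁² + β₁²σ₂²), and the mediation proportion is
β₁β₂ / β_total with a delta-method CI on the ratio.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study —
one causal taxon among nine nulls, a mediator carrying 25% of a total
log-odds effect of 0.04, biobank-scale outcome sampling noise:

```bash
python analysis/01_simulate_cohorts.py   # write cohorts under results/data/
python analysis/02_select_instruments.py
python analysis/03_uvmr_screen.py
python analysis/04_network_mediation.py
```

Instrument selection reports the cascade:

```
72 instruments selected from 200 candidate SNPs
mean F = 85.9 (no weak-instrument concern)
  significance/MAF         removed 119
  LD clumping              removed 0
  harmonization            removed 0
  outcome-associated       removed 9
  steiger                  removed 0
```

The screen finds exactly the planted taxon (Bonferroni bar
0.05/10 = 5e-3; a lucky null with IVW p = 0.027 is blocked by the
sensitivity gate):

```
taxon_causal     IVW beta=+0.0370 p=1.50e-61 nSNP= 72 support=4/4 tier=causality
taxon_null_00    IVW beta=-0.0089 p=3.41e-02 nSNP= 71 support=2/4 tier=none
...
```

and the mediation step recovers the planted pathway:

```
beta1 (taxon -> mediator)      = +0.4942 (SE 0.0053, p 0.00e+00)
beta2 (mediator -> outcome | taxon) = +0.0225 (SE 0.0031, p 2.00e-13)
total effect                   = +0.0370 (SE 0.0022)
indirect effect (beta1*beta2)  = +0.0111 (SE 0.0015)
mediation proportion = 30.1% (95% CI 21.3%, 38.9%); generating truth = 25.0%
```

The same operations are available as a CLI (`mr simulate | harmonize |
instruments | run | sensitivity | mvmr | mediate | screen`) for use on
real summary-statistic files.

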