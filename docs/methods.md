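# Methods

## The scientific problem

Epigenome-wide association studies find thousands of blood DNA-methylation
(DNAm) differences between smokers and non-smokers, but association alone
cannot say whether smoking alters methylation, whether methylation shifts
the propensity to smoke, or whether both are driven by shared genetic or
environmental causes.  This package implements a family of structural
models — MR-DoC models — that combine two complementary identification
strategies in a single likelihood:

* **Mendelian randomisation (MR)**: a polygenic score is used as an
  instrumental variable.  A smoking-initiation PRS instruments the smoking
  liability; a CpG-specific allelic score built from *cis*-mQTLs
  instruments DNAm.
* **Direction of causation (DoC) twin modelling**: monozygotic (MZ) and
  dizygotic (DZ) twin pairs differ in how cross-twin cross-trait
  covariances propagate, which carries information about the direction and
  magnitude of causal paths and about genetic confounding.

## Model

Per individual, with smoking modelled as a latent liability `x` and DNAm
as an observed continuous variable `y` (both on standardized scales):

```
x = b1·Z_prs + g2·y + a_x·A_x + e_x·E_x        (+ covariate mean shift)
y = b3·Z_mqtl + b2·Z_prs + g1·x + a_y·A_y + e_y·E_y
```

`g1` (liability → DNAm) and `g2` (DNAm → liability) are the causal paths;
`b2` is horizontal pleiotropy (instrument → outcome directly); `A`/`E` are
latent additive-genetic and unique-environmental factors with cross-trait
correlations `rA` and `rE` (the confounding); an AE decomposition is used
throughout (no shared-environment C component).  Across co-twins, A
factors correlate 1 (MZ) / 0.5 (DZ), E factors are independent, and
instrument scores correlate 1 (MZ) / `dz_iv_cross_corr` (DZ, default 0.5
under random mating, optionally estimated).  Simultaneity of `g1` and
`g2` is resolved exactly through the 2×2 reduced form, valid for
`|g1·g2| < 1`.

Three fitted variants:

| variant | causal paths | pleiotropy `b2` | `rE` | instruments |
|---|---|---|---|---|
| `doc1_pleiotropy` | one direction | free | fixed 0 | one |
| `doc1_re` | one direction | fixed 0 | free | one |
| `doc2` | both | fixed 0 | fixed 0 (optionally free) | both, covariance free |

Binary smoking status arises from the liability threshold model:
`S = 1{x + β_age·zage + β_sex·csex > τ}`.  Age and sex shift the liability
mean only (DNAm is residualized for them upstream); internally age is
z-scored and sex centred within the cohort, so `β_age` is per SD of age.
The liability scale is identified by constraining the structural variance
of `x` to 1; the residual E loading `e_x` is solved from the other
parameters (a quadratic with an explicit positive root), so the constraint
holds by construction during optimization.

## Likelihood

Estimation is full-information maximum likelihood over twin pairs.  For a
complete pair the likelihood factorizes into the Gaussian density of the
observed continuous block (DNAm and instrument scores of both twins) times
the rectangle probability of the observed smoking pattern under the
conditional bivariate normal of the two liabilities.  Rectangle
probabilities are computed from Owen's T function (absolute accuracy near
machine precision; validated to 1e-6 against direct 2-D Gauss–Legendre
quadrature of the latent-liability integral and to 1e-10 against the
normalization identity).  A missing smoking status marginalizes that
twin's orthant dimension; singletons contribute their one-twin marginal.
MZ co-twins carry identical instrument scores, so the MZ continuous block
includes each score once (the implied matrix would otherwise be singular).

The likelihood is evaluated on grouped, pre-extracted arrays (one group
per zygosity × missingness pattern), fully vectorized; one evaluation on
the default cohort costs well under a millisecond, which is what makes the
replicate-heavy calibration studies in the test suite feasible.

## Optimization and inference

Quasi-Newton (L-BFGS-B) in an unconstrained reparameterization: variances
and E loadings through `exp`, correlations through `tanh`, the instrument
covariance through `tanh` scaled by the geometric mean of the variances,
`e_x` eliminated by the identification constraint.  Data-driven starts:
τ from the probit of the observed smoking proportion, instrument paths
from single-variable probit/linear regressions, variance loadings from
Falconer-style cross-twin correlation arithmetic, causal paths at exactly
0.  Non-convergence triggers up to 3 seeded jittered restarts and is
flagged, never raised.  Standard errors come from the central-difference
Hessian (step 1e-4 on the unconstrained scale, insensitive to the step
over 1e-5…1e-3 in our checks) mapped to the natural scale by a numerical
delta method; Wald z and two-sided p follow.  Correlations with
`|r| > 0.999` are flagged as boundary estimates.

Fits are deterministic given data and options, and invariant to record
order (prepared data are canonically sorted).

## Synthetic cohorts

The generator mirrors the target study design and is the test bed for
every downstream stage.  Defaults: 706 MZ pairs, 412 DZ pairs, 341
singletons; current-smoking prevalence 528/2020 (threshold
τ = Φ⁻¹(1−0.2614) ≈ 0.639 when `tau=None`); PRS → liability path
√0.0507 (the PRS's 5.07% incremental liability-scale R²); mQTL score →
DNAm path √0.0904 (the mean 9.04% incremental R² of the allelic scores);
residual liability A share 0.44 (total genetic contribution ≈ 0.49,
consistent with twin estimates for smoking); DNAm A and E shares equal;
rA = 0.3 (moderate genetic confounding), rE = 0; ages uniform 18–79 with
co-twins sharing their age at blood draw; 67% female, MZ co-twins sharing
sex; β_age = −0.1, β_sex = −0.1 on the liability.  Covariate effects are
applied to z-scored age and centred sex so the structural liability
variance stays 1.

`simulate_cohort` emits exact model-scale variables so that Monte-Carlo
moments can be compared elementwise with the implied-covariance algebra
(they agree within 3 Monte-Carlo standard errors at 4·10⁵ pairs per
zygosity); standardization to the analysis convention is a separate step
(`standardize=True` or `TwinCohort.standardize()`).  `calibrated()`
rescales the A/E loadings so the implied liability and DNAm variances are
exactly 1 under non-zero causal paths, keeping stated effect sizes on the
standardized scale; the multi-CpG screen generator applies the analogous
per-CpG rescaling automatically.  Singletons are generated as pairs with
one member dropped, preserving the marginal distribution.  Reverse
causation is supported in the single-CpG generator; the multi-CpG
generator requires `g2 = 0` because a single shared liability cannot
receive simultaneous feedback from many methylation variables.

The generator deliberately does not emulate raw β-value scale, cell
composition, batch structure, or array artefacts: the pipeline consumes
residualized, standardized values, so passing tests validate the
statistical machinery, not upstream normalization.  A separate fixture
generator produces genotype dosages in equicorrelated LD blocks (with the
Gaussian-copula latent correlation inverted so the *dosage* correlation
matches the requested level), an empirical LD matrix, and marginal
summary statistics from a simulated phenotype, for exercising the
clumping/score machinery.

## Instruments

Greedy LD clumping with p-value thresholding (defaults p ≤ 5e-8,
r² < 0.1, *cis* window 1 Mb; ties on p broken by position then SNP id for
determinism), weighted sums of DNAm-increasing alleles (negative effects
flip allele and sign, so scores are invariant to re-orientation after
centering), the incremental-R² partial F statistic with the conventional
F > 10 relevance rule (denominator degrees of freedom count intercept,
covariates and score), and the ascertainment-adjusted threshold-model
transformation of observed-scale R² to the liability scale (reducing to
R²·K(1−K)/φ(t)² when the sample case fraction equals the population
prevalence K).

## Screen, FDR, inflation, triangulation

The screen fits, per CpG: both unidirectional MR-DoC1 variants for
Smoking → DNAm always, and the DNAm → Smoking MR-DoC1 variants plus the
bidirectional MR-DoC2 only where the CpG's mQTL allelic score has
F > 10 (one MR-DoC2 fit serves both directions).  Benjamini–Hochberg
q-values are computed per model, per direction, across CpGs, with
non-converged fits excluded (and counted in the log).  Genomic inflation
λ of the causal-test z-scores is computed by the median-χ² rule
(median(z²)/0.4549364) and by a normal-mixture decomposition: a dominant
null component flanked by two sign-constrained tail components, fitted by
deterministic EM with Dirichlet pseudo-counts, with the null-only
single-component fit preferred when BIC favours it (so data without
genuine tail effects are not over-decomposed); λ is the squared SD of the
null component and its mean is reported as bias.  λ is computed on the
z-scores of the causal estimates; z derived from p-values is the
selectable alternative.

Evidence is triangulated per CpG and direction: **robust** = FDR q < 0.05
in all three models with a consistent sign; **consistent_nominal** =
p < 0.05 in all three with a consistent sign; otherwise **inconsistent**;
any missing or non-converged fit gives **not_tested**.  Intersection
counts over the exact model subsets (plus at-least-two / all-three
rollups) reproduce the UpSet-style summary.

## Numerical choices and degenerate inputs

Optimizer tolerances `ftol=1e-11`, `gtol=1e-6`, max 1000 iterations;
inadmissible parameter regions (no positive `e_x` root, near-unstable
`|g1·g2|`, non-PD covariance) return a large penalty rather than raising
inside the optimizer, and raise descriptive errors at the API surface.
Probabilities are floored at 1e-300 before logs.  Cohorts that are all
smokers or all non-smokers are rejected at the starting-value stage;
cohorts missing a zygosity group fit with a warning (the A/E split is
then weakly identified).  Incomplete pairs are demoted to singletons.

## Power of the robustness criterion

At the study size, the weakest link for Smoking → DNAm is `doc1_re`,
whose causal information is essentially the MR channel of a PRS
explaining ~5% of liability variance: se(ĝ1) ≈ 0.094, so a standardized
effect of 0.3 has only ~60% power at an FDR-effective threshold, and
requiring all three models to pass (the "robust" category) is a
deliberately hard bar — consistent with the small robust fractions such
screens report.  The end-to-end screen demonstration therefore uses a
doubled design (1412/824/682), where that power is ~95% and recovering at
least 7 of 10 truly causal CpGs is the expected outcome; the type-I and
coverage studies use the study-size design (Wald type-I 0.037 at n=1118
pairs in 300 replicates; 95% CI coverage 0.93 over 100 MR-DoC2
replicates).

## Known limitations

* Binary exposure only (no ordinal smoking categories); linear causal
  effects only — no interactions or dose–response.
* No shared-environment (C) variance component.
* DNAm must be complete for modelled individuals; only the smoking status
  may be missing.
* The mixture inflation estimator is a deterministic EM/BIC approximation
  of the Bayesian Gibbs estimator it emulates; the two agree on the
  estimand (the null component's scale) but not in posterior uncertainty.
* The PRS is consumed as a precomputed column; training PRS weights is
  out of scope, as are genotype QC, imputation, and DNAm normalization.
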