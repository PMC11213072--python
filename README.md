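# mrdoc — twin Mendelian-randomisation models for smoking and blood DNA methylation

Blood DNA-methylation (DNAm) differences at thousands of CpG sites are
associated with cigarette smoking, but association cannot tell whether
smoking alters methylation, methylation influences smoking liability, or
shared genetic/environmental factors drive both.  `mrdoc` implements the
MR-DoC family of structural models, which combine Mendelian randomisation
(polygenic scores as instrumental variables) with the direction-of-
causation information in MZ/DZ twin covariance structure, and an
epigenome-style screening pipeline around them — exercised end-to-end on
synthetic twin cohorts that reproduce the statistical design of a
population twin register (706 MZ pairs, 412 DZ pairs, 341 singletons,
current-smoking prevalence 528/2020).

## The models

Per individual, with latent smoking liability `x` (binary status observed
through a threshold, `S = 1{x + β·covariates > τ}`) and continuous DNAm
`y`:

```
x = b1·Z_prs  + g2·y + a_x·A_x + e_x·E_x
y = b3·Z_mqtl + b2·Z_prs + g1·x + a_y·A_y + e_y·E_y
```

`g1` and `g2` are the causal paths (Smoking → DNAm and DNAm → Smoking);
`A`/`E` are additive-genetic and unique-environmental factors with
cross-trait correlations `rA`/`rE` (confounding); A factors correlate
1 (MZ) / 0.5 (DZ) across co-twins.  Three variants are fitted per CpG:
**MR-DoC1 with free horizontal pleiotropy** (`b2` free, `rE = 0`),
**MR-DoC1 with environmental confounding** (`b2 = 0`, `rE` free), and the
bidirectional **MR-DoC2** (both instruments, their covariance free).
Estimation is full-information maximum likelihood over twin pairs
(singletons and half-missing pairs contribute their marginals), with the
ordinal–continuous likelihood built on exact bivariate-normal rectangle
probabilities.  Evidence is triangulated across the three models per CpG:
`robust` (FDR < 0.05 in all three, consistent sign), `consistent_nominal`
(p < 0.05 in all three, consistent sign), else `inconsistent`.

Modules: `synthetic_data` (twin-cohort and genotype/LD/mQTL fixture
generators), `model_core` (implied moments, FIML likelihood, fitting,
Wald inference), `instruments` (LD clumping + thresholding, allelic
scores, partial-F instrument strength, liability-scale R²),
`phenotype_prep` (DNAm residualization, smoking-contrast encoding),
`screen` (per-CpG orchestration, BH-FDR, genomic-inflation λ,
triangulation, serialization), plus a `mrdoc` CLI.

## Worked example

```python
from mrdoc import (MRDoCSpec, SyntheticScenario, fit_mrdoc,
                   simulate_cohort, wald_statistics)

scenario = SyntheticScenario(g1=0.2, g2=0.1, b1=0.25, b3=0.25,
                             r_a=0.3, seed=11).calibrated()
cohort = simulate_cohort(scenario)          # 2577 individuals
fit = fit_mrdoc(cohort, MRDoCSpec(variant="doc2", direction="bidirectional"))
for name in ("g1", "g2", "r_a", "tau"):
    z, p = wald_statistics(fit, name)
    est, se = getattr(fit.estimates, name), fit.standard_errors[name]
    print(f"{name:4s} {est:+.3f} (se {se:.3f})  z={z:+.2f} p={p:.3g}")
```

prints (this exact run):

```
g1   +0.178 (se 0.064)  z=+2.77 p=0.00565
g2   +0.137 (se 0.074)  z=+1.85 p=0.0638
r_a  +0.411 (se 0.106)  z=+3.87 p=0.000107
tau  +0.632 (se 0.026)  z=+24.08 p=3.67e-128
```

The Smoking → DNAm path is recovered near its generative value 0.2 and
detected (p ≈ 0.006); the weaker reverse path (truth 0.1) lands within
one standard error of truth but short of significance at this sample
size — the power asymmetry the three-model triangulation is designed
around.  `tau ≈ 0.63` is the liability threshold implied by the ~26%
smoking prevalence, and `r_a` the genetic confounding (truth 0.3).

A multi-CpG screen, from the command line:

```bash
mrdoc simulate --config config.yaml --out cohort.tsv
mrdoc screen   --cohort cohort.tsv --config config.yaml --out results.tsv
mrdoc report   --results results.tsv
```

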