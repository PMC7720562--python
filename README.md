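# epilag

Vulnerable-window analysis of prenatal PM2.5 exposure and cord-blood DNA
methylation of imprinted growth genes.

Epidemiologists studying the fetal origins of disease ask *when* during
pregnancy an environmental exposure acts, not only whether it does.  This
package implements, as a tested and reusable pipeline, an analysis linking
weekly prenatal fine-particle (PM2.5) exposure histories to integrated
methylation measures of the IGF2/H19 imprinted cluster in cord blood:

1. **Preprocessing** — beta-values `β = M/(M + U + α)` (α = 100), per-locus
   outlier trimming on `[Q1 − 3·IQR, Q3 + 3·IQR]`, missingness filtering and
   complete-case reduction, contrast-coded covariates.
2. **Factor analysis** — each gene's correlated CpG loci are reduced to
   orthogonal common factors (KMO adequacy, parallel analysis, iterated
   principal-axis factoring, varimax, standardized regression scores, the
   |loading| > 0.45 assignment rule).
3. **Distributed-lag modelling** — a cross-basis `W = X·B` combines the
   linear exposure response with a natural-cubic-spline lag response
   (3 equally spaced inner knots over weeks 1–40, total DF 5), giving
   week-specific and cumulative (trimester) effects per 5 μg/m³ with
   delta-method CIs.
4. **Robust mixed models** — factor scores are regressed on the cross-basis
   and covariates with random intercepts for array batches (selected by the
   exact restricted LRT for zero variance components), fitted by REML/ML and
   by an M-estimation scheme with a smoothed Huber ψ and squared robustness
   weights at both the observation and the group level (k = 1.345 for 95%
   Gaussian efficiency; k = ∞ recovers REML exactly).
5. **Inference** — per-gene family-wise error control at 0.05 via Sidak
   individual levels `(1 − 0.05)^(1/m)`, sex-interaction likelihood-ratio
   tests, and a sensitivity suite (preterm exclusion, DF 5/7/9 plus the
   unconstrained DLM, k = 1.345/∞/1.69).
6. **Downstream** — growth regressions (birth weight, ponderal index),
   product-of-coefficients mediation with bootstrap CIs (exposure = mean
   PM2.5 of the last three gestational weeks), and transcript-correlation
   over-representation analysis (top-100 rule, hypergeometric p, BH q,
   p < 0.01 ∧ q < 0.05 ∧ ≥ 3 genes).

No cohort data ship with the package: a first-class synthetic-data module
generates seeded cohorts with the covariate marginals, autocorrelated
exposure series (zero-filled after preterm delivery), latent-factor
methylation structure with batch effects, and transcriptome the analysis
assumes — together with a ground-truth record for parameter-recovery tests.

## Worked example

```python
import pandas as pd
from epilag.pipeline import RunConfig, run_all

cfg = RunConfig.from_dict({
    "seed": 7,
    "outdir": "scratch/readme_run",
    # embed a true late-gestation lag response: a Gaussian bump peaking at
    # week 34 with 0.02 factor-score units per ug/m^3 at the peak
    "truth": {"lag_curve": {"type": "gaussian", "center": 34, "width": 3,
                            "scale": 0.02}},
})
manifest = run_all(cfg)

print(pd.read_csv("scratch/readme_run/lrt_IGF2.csv", index_col=0).round(3))
print(pd.read_csv("scratch/readme_run/effects_windows_IGF2_Factor3.csv",
                  index_col=0).round(2))
```

Output:

```
               stat  df      p  groups
factor
IGF2_Factor1  4.088   5  0.537     NaN
IGF2_Factor2  5.113   5  0.402     NaN
IGF2_Factor3  9.265   5  0.099     NaN

            estimate    se  lower  upper
window
overall         0.48  0.12   0.20   0.77
trimester1      0.01  0.08  -0.17   0.20
trimester2     -0.03  0.07  -0.19   0.13
trimester3      0.50  0.07   0.34   0.66
```

Reading it: no IGF2 factor shows significant sex modification (all
interaction LRT p > 0.05 on 5 df), so all-observation results are primary.
The factor that captured the injected exposure-sensitive loci (here
`IGF2_Factor3`) shows a cumulative change of +0.50 standardized score units
per 5 μg/m³ PM2.5 over trimester 3 — exactly where the simulated lag curve
peaks — with a Sidak-level CI (98.31% for the m = 3 factors extracted here)
excluding zero,
while trimesters 1–2 are null.  The same run writes per-week effect tables,
factor loadings/scores, the KMO/RMSR quality summary, the multiplicity
ledger and a manifest of artifact hashes under `scratch/readme_run/`.

The command-line interface mirrors the library:

```sh
epilag all --config config.yaml --seed 7 --outdir out/
epilag validate --cohort cohort.csv --exposure exposure.csv
```

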