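# Methods

`epilag` implements a pipeline for estimating *vulnerable gestational windows*:
the weeks of pregnancy during which maternal exposure to fine particulate
matter (PM2.5) is associated with DNA-methylation changes in imprinted growth
genes (the IGF2/H19 cluster) measured in cord blood.  Because the assayed CpG
loci within a region are strongly inter-correlated, the pipeline first
condenses each gene's loci into a handful of orthogonal factors and then
models each standardized factor score as the response of a distributed-lag
model embedded in a robust linear mixed model.

## 1. Methylation preprocessing

Beta-values are computed from methylated/unmethylated channel intensities as
`beta = M / (M + U + alpha)` with offset `alpha = 100`.  Each locus is trimmed
across samples: values outside `[Q1 - 3*IQR, Q3 + 3*IQR]` become missing.
Quartiles use linear interpolation (numpy default, "type 7"); the convention
is fixed so that the worked examples in the tests are stable.  Trimming is
idempotent because the surviving values can only widen the bounds relative to
their own range.  Loci missing in more than 20% of samples are dropped, the
remainder is reduced to complete cases (no imputation, which would distort
the correlation structure the factor analysis feeds on), and the survivors
are partitioned by gene.  Trimming happens before filtering, matching the
order in which the rules are stated.

Covariates (maternal age, pre-pregnancy BMI, education, smoking, parity,
pregnancy complications; newborn sex, gestational age, birth date, birth
season, ethnicity) are encoded with sum-to-zero contrasts for categoricals
and mean-centering for continuous variables; the birth date becomes days
since the earliest birth in the table.  The cross-basis coefficients of
interest are invariant to the contrast scheme, so the choice is cosmetic for
the headline estimates.

## 2. Factor analysis

Per gene: Kaiser-Meyer-Olkin sampling adequacy (ratio of squared
correlations to squared correlations plus squared anti-image partial
correlations; ~0.5 under independence), factor count by Horn-style parallel
analysis (95th percentile of eigenvalues from standard-normal data of the
same dimension, retained while the observed eigenvalue at the same rank
exceeds its threshold), then iterated principal-axis factoring: initial
communalities are squared multiple correlations; each sweep re-extracts the
leading eigenpairs of the reduced correlation matrix and updates the
communalities until the largest change falls below `tol = 1e-4`.  The
function default caps iteration at 100; the pipeline allows 5000 because
near-Heywood cases (a communality creeping towards its bound) converge
geometrically with a ratio close to 1 — each sweep is a single small `eigh`,
so the generous cap costs milliseconds.  Rotation is raw varimax; factors
are ordered by explained variance with sign fixed so column sums are
non-negative.  Scores use the regression (Thurstone) method from the rotated
loadings and are re-standardized to mean 0 / SD 1.  Model fit is summarised
by RMSR (root mean square off-diagonal residual correlation) and per-factor
explained variance; the quality rules from the literature (total variance >
60% acceptable, RMSR < 0.042 by Kelly's criterion) are reported, not
enforced.  Loci are assigned to every factor where |loading| strictly
exceeds 0.45, keeping the sign.

## 3. Distributed-lag cross-basis

The exposure history is the vector of 40 weekly mean PM2.5 values, week 1 at
conception, weeks after delivery identically zero for preterm pairs.  The
exposure-response relation is linear; the lag-response relation is a natural
cubic spline over weeks 1..40 with 3 internal knots equally spaced in value
(10.75, 20.5, 30.25), boundary knots at 1 and 40, and the intercept *inside*
the lag basis, so the cross-basis `W = X B` spans exactly 5 columns (total
DF 5).  The spline uses the truncated-power construction with linearity
constraints beyond the boundaries (C^2 everywhere, linear outside); any
basis of the same space gives identical predictions, so the convention is
unit-tested rather than matched to any particular software.  Week-specific
effects per a 5 ug/m^3 increment are `delta * B[l,:] theta` with delta-method
normal CIs; window effects (overall 1-40, trimesters 1-13 / 14-26 / 27-40)
use summed basis rows, making cumulative = sum-of-weekly an exact identity.
Sensitivity settings re-fit with DF 7 and 9 (5 and 7 internal knots) and the
unconstrained 40-parameter distributed lag model.

## 4. Robust linear mixed models

Each factor score is modelled with fixed effects (cross-basis block,
covariates, optionally sex x cross-basis) and independent random intercepts
for array-batch groupings (plate, sentrix row, sentrix column).  Gaussian
fits profile the REML/ML objective over the variance ratios with a Woodbury
identity (cost O(n q^2) per evaluation); the implementation is cross-checked
against statsmodels MixedLM in the tests.

Which groupings enter is decided per factor by the exact restricted
likelihood ratio test for a zero variance component.  The null law of that
statistic is a boundary mixture, not chi-square; it is simulated.  For one
component the REML profile reduces to a spectral form in the eigenvalues of
`Z'KZ` (K the fixed-effects residual projector), so each simulated statistic
costs one projection plus a cheap scalar optimisation.  Under the null the
law depends only on the design and the grouping — not on the fixed effects
or the residual scale — so a simulated null distribution can be shared
across responses with the same design.

The headline fits are robust: observation-level standardized conditional
residuals and group-level standardized predicted intercepts are mapped
through a smoothed Huber psi (classical Huber with a C^1 cubic blend over
[0.9k, 1.1k]) to robustness weights `psi(r)/r` in (0, 1], and the squared
weights re-enter a weighted REML fit (variances scaled by 1/w^2), iterating
to a fixed point (weight tolerance 1e-5, which sits just above the numerical
jitter floor of the inner optimiser).  Consistency under clean Gaussian data
is kept by dividing the reweighted variance estimates by
`kappa(k) = E[psi_k(Z)^2]`, and the reported fixed-effect covariance carries
the first-order M-estimation correction `E[(psi(Z)/Z)^2] / (E[psi'(Z)])^2`
— without it the robust confidence intervals are anti-conservative (the
global-null calibration study measured a familywise rate of ~0.12 instead of
0.05).  At `k = infinity` every weight is 1, all corrections equal 1, and
the fit coincides with REML to numerical precision; this identity, together
with the contamination contract (under 5% gross outliers the robust weekly
curve carries less than half of REML's bias), is the correctness contract of
the robust scheme — no coefficient-level equality with any external
implementation is claimed.  The tuning constant defaults to `k = 1.345` for
both levels (95% asymptotic efficiency under the Gaussian model, from the
closed-form normal integrals in `huber_efficiency`); the sensitivity suite
compares k = 1.345, k = infinity and k = 1.69.

## 5. Inference and multiplicity

Each gene contributes m independent hypotheses — one per factor — and the
per-gene familywise error rate is held at 0.05 by building every interval at
the Sidak level `(1 - 0.05)^(1/m)` (99.36%/99.15% for m = 8/6; 99.68%/99.57%
when sex stratification doubles m).  The designated per-factor hypothesis is
the overall (week 1-40) cumulative association; with that definition the
per-gene familywise rate is exactly the FWER by construction, which the
end-to-end null calibration verifies.  The week-specific and trimester
intervals are reported at the same individual level but are *exploratory*:
40 correlated pointwise looks through a 5-DF spline exceed the nominal
any-week error rate (~0.067 measured at the m = 8 level under the null), so
they localise a finding rather than establish one.

Sex modification is tested per factor by an ML likelihood-ratio test on the
sex x cross-basis block (df = 5 at defaults); sex-specific curves come from
the interaction model by linear contrasts of the +1/-1 sex code.  The
unconstrained-DLM comparison uses an ML LRT with df = 40 - 5 = 35, and DF
selection is reported with both AIC and BIC on ML fits.

## 6. Downstream analyses

Growth associations are ordinary least squares of birth weight or ponderal
index (PI = 100 w / l^3, g/cm^3) on one standardized factor score plus the
covariates.  Mediation takes the mean PM2.5 of the last three gestational
weeks (weeks g-2..g per pair) as exposure, the factor score as mediator and
PI as outcome: the indirect effect is the product of coefficients from two
nested linear models (total = direct + indirect holds exactly), with a
percentile bootstrap CI over pair resamples (default 1000; resamples that
lose design rank are redrawn and counted).  Mediation is computed even when
the total exposure-outcome association is weak, which the product-of-
coefficients framework tolerates.  Transcript follow-up: Pearson correlation
of a factor score with each transcript, selection of the first 100 by
ascending raw p among those with p < 0.05, then hypergeometric
over-representation within gene sets with Benjamini-Hochberg q-values; a set
is called significant only when p < 0.01, q < 0.05 and at least 3 genes
overlap.

## 7. Synthetic cohorts

The generator draws mother-newborn pairs with the study marginals (48.1%
girls, 89.9% European, 7.4% preterm, maternal age 29.3 +/- 4.3 y, BMI 24.2
+/- 4.2 kg/m^2, birth weight 3.40 +/- 0.48 kg coupled to gestational age and
sex, PI 2.69 +/- 0.22 g/cm^3, the published education/smoking/parity/season
frequencies) and a shuffled 2 x 6 chip layout for plate/row/column batch
labels.  Weekly exposure is log-scale AR(1) around a shared seasonal
sinusoid; the lognormal parameters are solved from the target marginals
(12.97 +/- 8.25 ug/m^3) with Bessel-function corrections for the seasonal
term, exact when conception dates are uniform over the year — the seasonal
birth-frequency pattern leaves a residual bias of about 1% in the mean at
the default amplitude 0.25 (log scale), and zero when the amplitude is 0.
The AR coefficient defaults to 0.7, reproducing the positive adjacent-week
correlation of real exposure series.  Post-delivery weeks are zero-filled
exactly.

Methylation: true factor scores = (configurable lag curve applied to the
exposure history, on a designated factor) + batch random intercepts + noise;
probe latents = loadings x standardized scores + uniqueness noise; betas by
inverse-logit around bimodal baselines (hypo/hypermethylated by region
annotation); channel intensities scaled back out of the betas so the
beta formula round-trips.  Outlier and missing cells are *probe-
concentrated* (a fraction of probes carries them), mirroring arrays where
most loci are clean and complete-case filtering removes a minority — iid
cell-level missingness would annihilate every probe at realistic rates.
The generator does not emulate probe-type chemistry differences, spatial
chip artefacts, cell-type composition or genotype effects, so passing tests
demonstrate correctness of the statistical machinery under the assumed
model, not robustness to those real-data features.

## 8. Problem sizes in the test suite

The simulation studies run at sizes chosen to give decisive checks on one
CPU in minutes: lag-curve recovery uses 200 cohorts of n = 2000 (mean
absolute weekly bias < 0.01 per ug/m^3, pointwise coverage 93-97%);
robustness contracts use n = 1000 with 5% outliers at +10 residual SDs;
factor recovery uses n = 5000; the interaction-LRT and exact-RLRT
calibrations use 500 null datasets each (the RLRT study shares one simulated
null distribution across datasets, valid by the design-invariance noted
above); the end-to-end global-null study runs the full pipeline 100 times at
n = 189 with a reduced probe count (12 + 8).  The mediation coverage study
uses 300 cohorts of n = 189 with 500 bootstrap resamples.

## 9. Known limitations

* The robust variance-component estimating equations are a squared-weight
  approximation, not a reproduction of any reference implementation's exact
  scheme; the k = infinity identity and the contamination contract are what
  is guaranteed.
* Weekly CIs are pointwise (see section 5); joint bands across weeks are not
  implemented.
* The exact RLRT screens one variance component at a time; correlated batch
  structures could in principle mask one another.
* The exposure generator's seasonal phase is tied to calendar conception
  dates with a single shared phase parameter; pair-specific seasonal
  heterogeneity is not modelled.
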