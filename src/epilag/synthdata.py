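"""Seeded synthetic cohorts with the structure the analysis assumes.

The generator emulates a birth cohort of mother-newborn pairs with:

* covariate marginals matching the study population defaults (about 48%
  girls, 90% European ethnicity, 7.4% preterm births, maternal age
  29.3 +/- 4.3 years, pre-pregnancy BMI 24.2 +/- 4.2 kg/m^2);
* a weekly prenatal PM2.5 exposure matrix (N x 40, ug/m^3): per-pair
  log-scale AR(1) series around a shared seasonal sinusoid, calibrated so the
  long-run marginal mean/SD hit their targets (12.97 +/- 8.25 by default),
  with weeks after delivery zero-filled for preterm pairs;
* a latent-factor methylation model: factor scores receive a configurable
  true lag-response applied to the exposure history, plus batch random
  intercepts (plate / sentrix row / sentrix column) and noise; probe-level
  latent values are loadings x scores plus uniqueness noise, mapped to
  beta-values through an inverse-logit, and methylated/unmethylated channel
  intensities are scaled back out of the betas;
* optionally a transcript expression matrix with a configurable number of
  transcripts truly correlated with a designated factor score, plus gene
  sets for enrichment testing.

Every function takes an integer seed and is bitwise reproducible.  The
:class:`TruthSpec` records the ground truth (lag curve, loadings, batch SDs,
mediation path coefficients) so parameter-recovery tests can compare
estimates against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, i0

from .downstream import last3_mean_exposure

__all__ = [
    "TruthSpec", "default_truth", "lag_curve_gaussian", "lag_curve_null",
    "generate_cohort", "generate_exposure", "generate_methylation",
    "generate_transcriptome", "generate_growth_outcome", "make_gene_sets",
    "DEFAULT_COHORT_PARAMS",
]

N_WEEKS = 40
WEEK_COLUMNS = [f"week_{w}" for w in range(1, N_WEEKS + 1)]


def lag_curve_gaussian(center: float = 34.0, width: float = 3.0,
                       scale: float = 0.02) -> np.ndarray:
    """A smooth bump lag-response: ``scale`` score units per ug/m^3 at the peak."""
    weeks = np.arange(1, N_WEEKS + 1)
    return scale * np.exp(-0.5 * ((weeks - center) / width) ** 2)


def lag_curve_null() -> np.ndarray:
    return np.zeros(N_WEEKS)


@dataclass
class TruthSpec:
    """Ground truth embedded in a synthetic cohort."""

    lag_curve: np.ndarray  # week 1..40 effect on the affected factor per ug/m^3
    factor_loadings: pd.DataFrame  # probes x factors, entries in [-1, 1]
    batch_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)  # plate, row, col
    noise_sd: float = 1.0
    mediation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # a, b, c'
    affected_factor: int = 0
    sex_effect: float = 0.0  # added to the affected factor for boys

    def __post_init__(self):
        self.lag_curve = np.asarray(self.lag_curve, dtype=float)
        if self.lag_curve.shape != (N_WEEKS,):
            raise ValueError(f"lag_curve must cover all {N_WEEKS} weeks")
        L = self.factor_loadings.to_numpy()
        if np.any(np.abs(L) > 1):
            raise ValueError("loadings must lie in [-1, 1]")
        if not np.all((np.abs(L) >= 0.45).any(axis=0)):
            raise ValueError("every factor needs at least one |loading| >= 0.45")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(s < 0 for s in self.batch_sd):
            raise ValueError("batch SDs must be non-negative")

    @property
    def n_probes(self) -> int:
        return self.factor_loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.factor_loadings.shape[1]


def default_truth(
    n_probes: dict[str, int] | None = None,
    n_factors: dict[str, int] | None = None,
    loading: float = 0.7,
    lag_curve: np.ndarray | None = None,
    batch_sd: tuple[float, float, float] = (0.3, 0.2, 0.2),
    noise_sd: float = 1.0,
    mediation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    affected_factor: int = 0,
    sex_effect: float = 0.0,
) -> tuple[TruthSpec, pd.DataFrame]:
    """Block loading matrix plus probe annotation for a two-gene design.

    Each gene's factors load ``loading`` on disjoint probe groups (block
    structure); the probe annotation carries gene, gene-region and CpG-island
    labels compatible with the preprocessing stage.
    """
    n_probes = n_probes or {"IGF2": 24, "H19": 16}
    n_factors = n_factors or {"IGF2": 3, "H19": 2}
    regions = ["TSS200", "TSS1500", "Body", "5'UTR"]
    islands = ["Island", "N_Shore", "S_Shore", "OpenSea"]

    rows, ann_rows, blocks = [], [], []
    total_k = sum(n_factors.values())
    col_off = 0
    probe_idx = 0
    for gene, p in n_probes.items():
        k = n_factors[gene]
        group = np.array_split(np.arange(p), k)
        for j in range(p):
            lam = np.zeros(total_k)
            for f, idx in enumerate(group):
                if j in idx:
                    lam[col_off + f] = loading
            rows.append(lam)
            ann_rows.append({
                "probe_id": f"cg{probe_idx:08d}",
                "gene": gene,
                "region": regions[j % len(regions)],
                "island": islands[j % len(islands)],
                "excluded": False,
            })
            probe_idx += 1
        col_off += k
    loadings = pd.DataFrame(
        np.vstack(rows),
        index=[r["probe_id"] for r in ann_rows],
        columns=[f"{g}_F{f + 1}" for g, k in n_factors.items() for f in range(k)],
    )
    annotation = pd.DataFrame(ann_rows)
    truth = TruthSpec(
        lag_curve=lag_curve if lag_curve is not None else lag_curve_null(),
        factor_loadings=loadings, batch_sd=batch_sd, noise_sd=noise_sd,
        mediation=mediation, affected_factor=affected_factor,
        sex_effect=sex_effect,
    )
    return truth, annotation


# ---------------------------------------------------------------------------
# Cohort covariates
# ---------------------------------------------------------------------------

DEFAULT_COHORT_PARAMS: dict = {
    "p_female": 0.481,
    "p_european": 0.899,
    "preterm_prob": 0.074,
    # term gestational ages conditional on not preterm (weeks 37..41)
    "term_ga_probs": {37: 0.032, 38: 0.138, 39: 0.243, 40: 0.381, 41: 0.132},
    "preterm_ga_weights": {ga: w for ga, w in zip(
        range(24, 37), [1, 1, 1, 1, 2, 2, 3, 4, 6, 8, 12, 16, 20])},
    "maternal_age_mean": 29.3, "maternal_age_sd": 4.3,
    "bmi_mean": 24.2, "bmi_sd": 4.2,
    "education_probs": {"low": 0.143, "middle": 0.344, "high": 0.513},
    "smoking_probs": {"never": 0.646, "former": 0.217, "smoker": 0.137},
    "parity_probs": {"primi": 0.550, "secundi": 0.312, "multi": 0.138},
    "complications_prob": 0.212,
    "season_probs": {"winter": 0.222, "spring": 0.434, "summer": 0.138,
                     "autumn": 0.206},
    "birth_weight_mean": 3400.0, "birth_weight_sd": 480.0,
    "weight_ga_slope": 140.0,  # g per gestational week
    "weight_sex_diff": 114.0,  # boys minus girls, g
    "pi_mean": 2.69, "pi_sd": 0.22,
    "year_start": "2010-01-01",
    "chip_rows": 6, "chip_cols": 2, "chips_per_plate": 4,
}

_SEASON_DOY = {  # meteorological seasons, day-of-year ranges (non-leap)
    "winter": [(335, 365), (1, 59)],
    "spring": [(60, 151)],
    "summer": [(152, 243)],
    "autumn": [(244, 334)],
}


def _season_of_doy(doy: np.ndarray) -> np.ndarray:
    out = np.empty(doy.shape, dtype=object)
    for season, ranges in _SEASON_DOY.items():
        for lo, hi in ranges:
            out[(doy >= lo) & (doy <= hi)] = season
    return out


def _categorical(rng, levels_probs: dict, n: int) -> np.ndarray:
    levels = list(levels_probs)
    p = np.array([levels_probs[l] for l in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def generate_cohort(n: int, seed: int, params: dict | None = None) -> pd.DataFrame:
    """Draw ``n`` mother-newborn pairs with the default study marginals.

    Gestational age is an integer in 24..42 weeks; birth weight depends on
    gestational age and sex; birth length is backed out of a drawn ponderal
    index so the PI marginal matches its target; array batch labels (plate,
    sentrix row/column) come from a shuffled chip layout of 2 x 6 samples.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n < 20:
        raise ValueError("need at least 20 pairs for a meaningful cohort")
    pr = dict(DEFAULT_COHORT_PARAMS)
    pr.update(params or {})
    rng = np.random.default_rng(seed)
    ids = [f"S{i + 1:04d}" for i in range(n)]

    sex = np.where(rng.random(n) < pr["p_female"], "female", "male")
    ethnicity = np.where(rng.random(n) < pr["p_european"], "European", "non-European")

    preterm = rng.random(n) < pr["preterm_prob"]
    term_levels = np.array(list(pr["term_ga_probs"]))
    term_p = np.array(list(pr["term_ga_probs"].values()), dtype=float)
    term_p /= term_p.sum()
    pre_levels = np.array(list(pr["preterm_ga_weights"]))
    pre_p = np.array(list(pr["preterm_ga_weights"].values()), dtype=float)
    pre_p /= pre_p.sum()
    ga = np.where(preterm,
                  rng.choice(pre_levels, size=n, p=pre_p),
                  rng.choice(term_levels, size=n, p=term_p)).astype(int)

    season = _categorical(rng, pr["season_probs"], n)
    doy = np.empty(n, dtype=int)
    for s, ranges in _SEASON_DOY.items():
        idx = np.where(season == s)[0]
        days = np.concatenate([np.arange(lo, hi + 1) for lo, hi in ranges])
        doy[idx] = rng.choice(days, size=len(idx))
    year0 = pd.Timestamp(pr["year_start"])
    birth_date = year0 + pd.to_timedelta(doy - 1, unit="D")

    ga_mean = float(ga.mean())
    ga_var = float(ga.var())
    sex_shift = (sex == "male") * pr["weight_sex_diff"] - pr["weight_sex_diff"] * (1 - pr["p_female"])
    resid_var = max(pr["birth_weight_sd"] ** 2
                    - pr["weight_ga_slope"] ** 2 * ga_var
                    - np.var(sex_shift), 100.0**2)
    weight = (pr["birth_weight_mean"]
              + pr["weight_ga_slope"] * (ga - ga_mean)
              + sex_shift
              + rng.normal(0.0, np.sqrt(resid_var), n))
    weight = np.clip(weight, 500.0, None)
    pi = np.clip(rng.normal(pr["pi_mean"], pr["pi_sd"], n), 1.5, None)
    length = np.cbrt(100.0 * weight / pi)

    age = np.clip(rng.normal(pr["maternal_age_mean"], pr["maternal_age_sd"], n), 16, 45)
    bmi = np.clip(rng.normal(pr["bmi_mean"], pr["bmi_sd"], n), 15, 45)

    # chip layout: shuffled assignment to 2 x 6 chips, several chips per plate
    perm = rng.permutation(n)
    pos = np.empty(n, dtype=int)
    pos[perm] = np.arange(n)
    per_chip = pr["chip_rows"] * pr["chip_cols"]
    row = pos % pr["chip_rows"]
    col = (pos // pr["chip_rows"]) % pr["chip_cols"]
    chip = pos // per_chip
    plate = chip // pr["chips_per_plate"]

    return pd.DataFrame({
        "sex": sex,
        "ethnicity": ethnicity,
        "birth_season": season,
        "birth_weight": weight,
        "birth_length": length,
        "gestational_age": ga,
        "birth_date": birth_date,
        "maternal_age": age,
        "pre_pregnancy_bmi": bmi,
        "education": _categorical(rng, pr["education_probs"], n),
        "smoking": _categorical(rng, pr["smoking_probs"], n),
        "parity": _categorical(rng, pr["parity_probs"], n),
        "complications": np.where(rng.random(n) < pr["complications_prob"], "yes", "no"),
        "plate": [f"P{i + 1}" for i in plate],
        "sentrix_row": [f"R{i + 1}" for i in row],
        "sentrix_col": [f"C{i + 1}" for i in col],
    }, index=pd.Index(ids, name="sample_id"))


# ---------------------------------------------------------------------------
# Weekly exposure
# ---------------------------------------------------------------------------

def generate_exposure(cohort: pd.DataFrame, seed: int, mean: float = 12.97,
                      sd: float = 8.25, ar_coef: float = 0.7,
                      seasonal_amplitude: float = 0.25,
                      seasonal_phase: float = 0.0) -> pd.DataFrame:
    """Weekly mean PM2.5 series per pair, zero-filled after delivery.

    Log-scale model: log X_iw = mu + A*cos(2*pi*doy_iw/365.25 - phase) + eta_iw
    with eta a stationary AR(1) (coefficient ``ar_coef``).  mu and the AR
    stationary variance are solved from the target marginal mean/SD using the
    lognormal moments averaged over a uniform seasonal phase (Bessel-I0
    corrections), so the non-zero cells approach the targets in the long run.
    Weeks g+1..40 are exactly zero for a pair delivered at week g.
    """
    if not (0 <= ar_coef < 1):
        raise ValueError("ar_coef must be in [0, 1)")
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    A = float(seasonal_amplitude)
    if A < 0:
        raise ValueError("seasonal amplitude must be non-negative")
    m2 = (mean**2 + sd**2) / mean**2
    var_eta = np.log(m2 * i0(A) ** 2 / i0(2 * A))
    if var_eta <= 0:
        raise ValueError("seasonal amplitude too large for the target SD")
    mu = np.log(mean) - np.log(i0(A)) - var_eta / 2.0

    rng = np.random.default_rng(seed)
    n = len(cohort)
    sd_eta = np.sqrt(var_eta)
    eta = np.empty((n, N_WEEKS))
    eta[:, 0] = rng.normal(0.0, sd_eta, n)
    innov_sd = sd_eta * np.sqrt(1.0 - ar_coef**2)
    for w in range(1, N_WEEKS):
        eta[:, w] = ar_coef * eta[:, w - 1] + rng.normal(0.0, innov_sd, n)

    ga = cohort["gestational_age"].to_numpy(int)
    conception = pd.to_datetime(cohort["birth_date"]) - pd.to_timedelta(7 * ga, unit="D")
    doy0 = conception.dt.dayofyear.to_numpy(float)
    weeks = np.arange(N_WEEKS)
    doy = doy0[:, None] + 7.0 * weeks[None, :] + 3.5
    seasonal = A * np.cos(2 * np.pi * doy / 365.25 - seasonal_phase)

    X = np.exp(mu + seasonal + eta)
    mask = weeks[None, :] + 1 > ga[:, None]
    X[mask] = 0.0
    return pd.DataFrame(X, index=cohort.index, columns=WEEK_COLUMNS)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def _true_scores(cohort, exposure, truth, rng) -> pd.DataFrame:
    n = len(cohort)
    k = truth.n_factors
    F = rng.normal(0.0, truth.noise_sd, size=(n, k))
    Xe = exposure[WEEK_COLUMNS].to_numpy(float)
    F[:, truth.affected_factor] += Xe @ truth.lag_curve
    a = truth.mediation[0]
    if a != 0.0:
        F[:, truth.affected_factor] += a * last3_mean_exposure(exposure, cohort).to_numpy()
    if truth.sex_effect != 0.0:
        F[:, truth.affected_factor] += truth.sex_effect * (cohort["sex"] == "male").to_numpy(float)
    for sd_b, col in zip(truth.batch_sd, ("plate", "sentrix_row", "sentrix_col")):
        if sd_b > 0:
            codes = pd.Categorical(cohort[col]).codes
            eff = rng.normal(0.0, sd_b, size=(codes.max() + 1, k))
            F += eff[codes]
    return pd.DataFrame(F, index=cohort.index, columns=truth.factor_loadings.columns)


def generate_methylation(
    cohort: pd.DataFrame,
    exposure: pd.DataFrame,
    truth: TruthSpec,
    annotation: pd.DataFrame,
    seed: int,
    frac_probes_outlier: float = 0.0,
    cell_outlier_rate: float = 0.02,
    frac_probes_missing: float = 0.0,
    cell_missing_rate: float = 0.15,
    total_intensity: float = 10000.0,
    alpha: float = 100.0,
    beta_scale: float = 0.5,
):
    """Latent-factor methylation data with channel intensities.

    Factor scores (standardized within cohort) mix through the truth loadings
    into per-probe latent values with uniqueness noise; an inverse-logit of a
    probe baseline plus ``beta_scale`` times the latent value gives the
    beta-value.  Channel intensities are scaled back out of the betas so that
    beta = M/(M+U+alpha) round-trips (up to rounding).

    Data problems are probe-concentrated, as on real arrays: a fraction
    ``frac_probes_outlier`` of probes receives outlier cells (beta flipped to
    the opposite methylation mode) at rate ``cell_outlier_rate``, and a
    disjoint fraction ``frac_probes_missing`` receives missing cells at rate
    ``cell_missing_rate``, exercising the trimming, missingness and
    complete-case filters.

    Returns (M, U, beta, scores): DataFrames with probes x samples for the
    first three and samples x factors for the ground-truth scores.
    """
    if len(annotation) != truth.n_probes:
        raise ValueError("annotation rows must match truth loadings rows")
    rng = np.random.default_rng(seed)
    scores_raw = _true_scores(cohort, exposure, truth, rng)
    Fz = (scores_raw - scores_raw.mean()) / scores_raw.std(ddof=1)

    L = truth.factor_loadings.to_numpy()  # p x k
    h2 = np.sum(L**2, axis=1)
    if np.any(h2 > 1):
        raise ValueError("probe communalities exceed 1")
    uniq = np.sqrt(1.0 - h2)
    n, p = len(cohort), truth.n_probes
    latent = Fz.to_numpy() @ L.T + rng.standard_normal((n, p)) * uniq  # n x p

    hyper = np.isin(annotation["region"].to_numpy(), ["Body", "5'UTR"])
    baseline = np.where(hyper, 1.5, -1.5)
    beta = expit(baseline[None, :] + beta_scale * latent)  # n x p

    perm = rng.permutation(p)
    n_out = int(round(frac_probes_outlier * p))
    n_mis = int(round(frac_probes_missing * p))
    out_probes, mis_probes = perm[:n_out], perm[n_out:n_out + n_mis]
    if n_out:
        out_mask = np.zeros((n, p), dtype=bool)
        out_mask[:, out_probes] = rng.random((n, n_out)) < cell_outlier_rate
        beta = np.where(out_mask, 1.0 - beta, beta)

    S = total_intensity
    M = np.round(beta * (S + alpha))
    U = np.round(np.clip((1.0 - beta) * (S + alpha) - alpha, 0.0, None))

    if n_mis:
        miss = np.zeros((n, p), dtype=bool)
        miss[:, mis_probes] = rng.random((n, n_mis)) < cell_missing_rate
        beta = np.where(miss, np.nan, beta)
        M = np.where(miss, np.nan, M)
        U = np.where(miss, np.nan, U)

    probe_ids = truth.factor_loadings.index
    to_df = lambda a: pd.DataFrame(a.T, index=probe_ids, columns=cohort.index)
    return to_df(M), to_df(U), to_df(beta), scores_raw


def generate_growth_outcome(cohort: pd.DataFrame, exposure: pd.DataFrame,
                            scores: pd.DataFrame, truth: TruthSpec, seed: int,
                            noise_sd: float = 0.2) -> pd.Series:
    """Ponderal-index outcome with the truth's b and c' paths embedded.

    PI = baseline + b * standardized mediator score + c' * (mean PM2.5 of the
    last three gestational weeks) + noise.
    """
    rng = np.random.default_rng(seed)
    _, b, cprime = truth.mediation
    med = scores.iloc[:, truth.affected_factor]
    med = (med - med.mean()) / med.std(ddof=1)
    last3 = last3_mean_exposure(exposure, cohort)
    pi = 2.69 + b * med + cprime * last3.to_numpy() + rng.normal(0, noise_sd, len(cohort))
    return pd.Series(pi, index=cohort.index, name="ponderal_index")


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def generate_transcriptome(cohort: pd.DataFrame, scores: pd.DataFrame, seed: int,
                           n_transcripts: int = 2000, linked: int = 100,
                           r: float = 0.5, target_factor: int = 0):
    """Expression matrix with ``linked`` transcripts correlated to one factor.

    Linked transcripts are r * standardized score + sqrt(1 - r^2) * noise;
    the rest are independent standard normal.  Returns (expression DataFrame,
    transcripts x samples, with gene-symbol index; list of linked genes).
    """
    if linked > n_transcripts:
        raise ValueError("linked cannot exceed n_transcripts")
    if not -1 < r < 1:
        raise ValueError("r must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    s = scores.iloc[:, target_factor].to_numpy(float)
    s = (s - s.mean()) / s.std(ddof=1)
    E = rng.standard_normal((n_transcripts, n))
    E[:linked] = r * s[None, :] + np.sqrt(1 - r**2) * E[:linked]
    genes = [f"GENE{i + 1:05d}" for i in range(n_transcripts)]
    expr = pd.DataFrame(E, index=pd.Index(genes, name="gene"), columns=cohort.index)
    return expr, genes[:linked]


def make_gene_sets(universe: list[str], enriched_in: list[str], seed: int,
                   n_sets: int = 20, set_size: int = 40,
                   n_enriched_sets: int = 3, enriched_overlap: int = 15) -> dict[str, list[str]]:
    """Gene sets for enrichment tests: a few truly enriched, the rest random."""
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    pool = np.asarray(universe)
    enr = np.asarray(enriched_in)
    for i in range(n_sets):
        name = f"SET{i + 1:03d}"
        if i < n_enriched_sets and len(enr):
            take = min(enriched_overlap, len(enr))
            members = list(rng.choice(enr, size=take, replace=False))
            rest = rng.choice(pool, size=set_size - take, replace=False)
            members += [g for g in rest if g not in members]
        else:
            members = list(rng.choice(pool, size=set_size, replace=False))
        sets[name] = members
    return sets
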