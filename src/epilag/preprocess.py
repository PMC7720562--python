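"""Methylation and covariate preprocessing.

Turns raw methylated/unmethylated signal intensities (or beta-values) plus the
cohort covariate table into the analysis-ready objects: per-gene complete-case
beta matrices and a contrast-coded, mean-centered design matrix.

Conventions fixed here and relied on downstream:

* beta = M / (M + U + alpha) with alpha = 100 by default, the usual offset that
  stabilises the ratio when both channel intensities are small.
* Per-locus outlier trimming uses the range [Q1 - 3*IQR, Q3 + 3*IQR] with
  quartiles computed by linear interpolation (numpy's default, "type 7");
  values strictly outside the range are set to missing.
* Probes with missing values in more than ``max_missing`` of the samples are
  dropped, and the remainder is reduced to complete cases (no imputation).
* Categorical covariates are sum-to-zero contrast coded; continuous covariates
  except the birth date are centered at their sample mean; the birth date is
  coded as days since the earliest birth date in the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "beta_from_signals",
    "trim_outliers",
    "filter_probes",
    "ponderal_index",
    "encode_covariates",
    "EncodedDesign",
    "ProbeFilterReport",
]

#: categorical covariates and their admissible levels, in reference order
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "sex": ["male", "female"],
    "ethnicity": ["European", "non-European"],
    "birth_season": ["winter", "spring", "summer", "autumn"],
    "education": ["low", "middle", "high"],
    "smoking": ["never", "former", "smoker"],
    "parity": ["primi", "secundi", "multi"],
    "complications": ["no", "yes"],
}

#: continuous covariates centered at the mean (birth_date handled separately)
CONTINUOUS_COVARIATES = ["maternal_age", "pre_pregnancy_bmi", "gestational_age"]


def beta_from_signals(M, U, alpha: float = 100.0):
    """Methylation beta-value from channel intensities.

    beta = M / (M + U + alpha).  Vectorised over arrays of any shape;
    returns an ndarray (or scalar for scalar input).
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if np.any(M < 0) or np.any(U < 0):
        raise ValueError("signal intensities must be non-negative")
    with np.errstate(invalid="ignore"):
        beta = M / (M + U + alpha)
    if beta.ndim == 0:
        return float(beta)
    return beta


def trim_outliers(values) -> tuple[np.ndarray, int]:
    """Set extreme values of one probe's beta vector to missing.

    Values strictly outside [Q1 - 3*IQR, Q3 + 3*IQR] become NaN.  Quartiles
    use linear interpolation on the non-missing values.  Returns the trimmed
    vector and the number of values trimmed.  Idempotent: a second pass trims
    nothing, because the bounds computed from the surviving values can only
    widen relative to the surviving range.
    """
    v = np.asarray(values, dtype=float).copy()
    obs = v[~np.isnan(v)]
    if obs.size == 0:
        raise ValueError("all values missing")
    if obs.size < 4:
        raise ValueError("need at least 4 non-missing values to trim")
    q1, q3 = np.percentile(obs, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    mask = (v < lo) | (v > hi)
    mask &= ~np.isnan(v)
    v[mask] = np.nan
    return v, int(mask.sum())


@dataclass
class ProbeFilterReport:
    """Accounting of what happened to every input probe."""

    reasons: pd.Series  # index: probe id, value: reason label
    counts: dict[str, int] = field(default_factory=dict)

    REASONS = ("annotation_excluded", "missing_gt_20pct", "incomplete_record", "retained")

    def __post_init__(self):
        self.counts = {r: int((self.reasons == r).sum()) for r in self.REASONS}

    @property
    def n_total(self) -> int:
        return int(len(self.reasons))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"probe_id": self.reasons.index, "reason": self.reasons.values})


def filter_probes(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    max_missing: float = 0.20,
    genes: list[str] | None = None,
) -> tuple[dict[str, pd.DataFrame], ProbeFilterReport]:
    """Apply the missingness filters and split the probes by gene.

    Parameters
    ----------
    beta : DataFrame, probes x samples, NaN marks missing values.
    annotation : DataFrame with columns ``probe_id``, ``gene`` and optionally
        ``excluded`` (a pre-computed array-QC exclusion flag).
    max_missing : probes missing in strictly more than this fraction of the
        samples are dropped; the survivors are then reduced to complete cases.
    genes : gene labels to return; defaults to every gene in the annotation.

    Returns per-gene complete-case beta matrices and a
    :class:`ProbeFilterReport` that partitions the input probes.
    """
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    missing_ann = beta.index.difference(ann.index)
    if len(missing_ann):
        raise ValueError(f"annotation does not cover probes: {list(missing_ann)[:5]}")
    if genes is None:
        genes = list(pd.unique(ann.loc[beta.index, "gene"]))
    else:
        known = set(ann["gene"])
        for g in genes:
            if g not in known:
                raise ValueError(f"gene label {g!r} absent from annotation")

    reasons = pd.Series("retained", index=beta.index, dtype=object)
    if "excluded" in ann.columns:
        flagged = ann.loc[beta.index, "excluded"].astype(bool)
        reasons[flagged.values] = "annotation_excluded"
    live = reasons == "retained"

    frac_missing = beta.isna().mean(axis=1)
    too_missing = live & (frac_missing > max_missing)
    reasons[too_missing] = "missing_gt_20pct"
    live &= ~too_missing

    any_missing = live & beta.isna().any(axis=1)
    reasons[any_missing] = "incomplete_record"
    live &= ~any_missing

    report = ProbeFilterReport(reasons=reasons)
    out: dict[str, pd.DataFrame] = {}
    kept = beta.loc[live]
    gene_of = ann.loc[kept.index, "gene"]
    for g in genes:
        out[g] = kept.loc[gene_of[gene_of == g].index]
    return out, report


def ponderal_index(weight_g, length_cm):
    """Rohrer's ponderal index, 100 * weight(g) / length(cm)^3, in g/cm^3."""
    w = np.asarray(weight_g, dtype=float)
    l = np.asarray(length_cm, dtype=float)
    if np.any(w <= 0) or np.any(l <= 0):
        raise ValueError("weight and length must be positive")
    pi = 100.0 * w / l**3
    return float(pi) if pi.ndim == 0 else pi


@dataclass
class EncodedDesign:
    """Contrast-coded covariate matrix plus the metadata to re-apply it."""

    matrix: pd.DataFrame  # samples x encoded columns
    centers: dict[str, float]
    level_order: dict[str, list[str]]
    reference_birth_date: pd.Timestamp | None
    sex_code: pd.Series | None = None  # +1 male / -1 female, for interactions

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)


def _sum_contrast(series: pd.Series, name: str, levels: list[str]) -> pd.DataFrame:
    """Sum-to-zero contrasts: one column per non-last level, last level = -1."""
    unknown = set(series.unique()) - set(levels)
    if unknown:
        raise ValueError(f"unknown level(s) {sorted(unknown)} in covariate {name!r}")
    cols = {}
    for lev in levels[:-1]:
        col = (series == lev).astype(float) - (series == levels[-1]).astype(float)
        cols[f"{name}[{lev}]"] = col
    return pd.DataFrame(cols, index=series.index)


def encode_covariates(cohort: pd.DataFrame, include_sex: bool = True) -> EncodedDesign:
    """Encode the covariate table into model-ready columns.

    Categorical covariates get sum-to-zero contrasts; continuous covariates
    except the birth date are centered; the birth date becomes days since the
    earliest birth date.  Missing covariate values are rejected (pairs with
    incomplete covariates are expected to be dropped upstream).
    """
    needed = list(CATEGORICAL_LEVELS) + CONTINUOUS_COVARIATES + ["birth_date"]
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks covariates: {missing_cols}")
    if cohort[needed].isna().any().any():
        bad = cohort[needed].isna().any()
        raise ValueError(f"missing covariate values in: {list(bad[bad].index)}")

    parts = []
    level_order = {}
    for name, levels in CATEGORICAL_LEVELS.items():
        if name == "sex" and not include_sex:
            continue
        parts.append(_sum_contrast(cohort[name].astype(str), name, levels))
        level_order[name] = list(levels)

    centers = {}
    cont = {}
    for name in CONTINUOUS_COVARIATES:
        mu = float(cohort[name].mean())
        centers[name] = mu
        cont[name] = cohort[name].astype(float) - mu
    bd = pd.to_datetime(cohort["birth_date"])
    ref = bd.min()
    cont["birth_date_days"] = (bd - ref).dt.days.astype(float)
    parts.append(pd.DataFrame(cont, index=cohort.index))

    matrix = pd.concat(parts, axis=1)
    sex_code = None
    if include_sex:
        sex_code = matrix["sex[male]"].rename("sex_code")
    return EncodedDesign(
        matrix=matrix,
        centers=centers,
        level_order=level_order,
        reference_birth_date=ref,
        sex_code=sex_code,
    )
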