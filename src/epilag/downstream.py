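"""Functional follow-up of the methylation factors.

Three analyses probe what an exposure-associated methylation factor means
biologically:

* growth regressions — ordinary least squares of birth weight or ponderal
  index on a standardized factor score, adjusted for the full covariate set;
* mediation — does the factor score carry part of the exposure effect on
  fetal growth?  The exposure variable is the mean PM2.5 of the last three
  gestational weeks (weeks g-2..g for a pair delivered at week g); the
  indirect effect is the product of coefficients from two nested linear
  models, with a nonparametric pair-resampling percentile bootstrap CI;
* transcript correlation + ORA — Pearson correlation of the factor score
  with each transcript, selection of the first 100 transcripts by ascending
  p among those with p < 0.05, and hypergeometric over-representation of the
  selection within gene sets, significant when p < 0.01, BH q < 0.05 and at
  least 3 genes overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "last3_mean_exposure", "growth_regression", "mediate", "MediationResult",
    "correlate_transcripts", "ora", "read_gmt", "write_gmt",
]


def last3_mean_exposure(exposure: pd.DataFrame, cohort: pd.DataFrame) -> pd.Series:
    """Mean PM2.5 over each pair's last three gestational weeks (g-2..g)."""
    X = exposure.to_numpy(float)
    ga = cohort["gestational_age"].to_numpy(int)
    out = np.empty(len(cohort))
    for i, g in enumerate(ga):
        out[i] = X[i, max(g - 3, 0):g].mean()
    return pd.Series(out, index=cohort.index, name="pm25_last3")


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with coefficient covariance; raises on rank deficiency."""
    n, p = X.shape
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, cov, n - p


def growth_regression(outcome: pd.Series, score: pd.Series,
                      covariates: pd.DataFrame) -> tuple[float, float, float]:
    """OLS of a growth outcome on one factor score, covariate-adjusted.

    Returns (coefficient per SD of the score, standard error, two-sided p).
    """
    y = outcome.to_numpy(float)
    X = np.column_stack([
        np.ones(len(y)),
        score.to_numpy(float),
        covariates.to_numpy(float),
    ])
    beta, cov, dof = _ols(y, X)
    se = float(np.sqrt(cov[1, 1]))
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), dof)
    return float(beta[1]), se, float(p)


@dataclass
class MediationResult:
    a: float  # exposure -> mediator
    b: float  # mediator -> outcome | exposure
    c_prime: float  # direct effect
    indirect: float  # a * b
    total: float  # from the outcome ~ exposure model
    ci_lower: float
    ci_upper: float
    conf_level: float
    n_boot: int
    seed: int | None
    n_degenerate_resamples: int = 0


def mediate(exposure: pd.Series, mediator: pd.Series, outcome: pd.Series,
            covariates: pd.DataFrame, n_boot: int = 1000, seed: int | None = None,
            conf_level: float = 0.95) -> MediationResult:
    """Product-of-coefficients mediation with a percentile bootstrap CI.

    Two linear models share the covariates: mediator ~ exposure + C gives a;
    outcome ~ mediator + exposure + C gives b and the direct effect c'.  The
    indirect effect is a*b; for nested linear fits total = c' + a*b exactly.
    Resampling is of whole pairs; a resample whose design loses rank is drawn
    again (counted in the result).
    """
    if n_boot < 500:
        raise ValueError("n_boot must be at least 500")
    e = exposure.to_numpy(float)
    m = mediator.to_numpy(float)
    y = outcome.to_numpy(float)
    C = covariates.to_numpy(float)
    n = len(e)
    ones = np.ones(n)

    def paths(idx):
        Xm = np.column_stack([ones[idx], e[idx], C[idx]])
        a = np.linalg.lstsq(Xm, m[idx], rcond=None)[0][1]
        Xy = np.column_stack([ones[idx], m[idx], e[idx], C[idx]])
        coef = np.linalg.lstsq(Xy, y[idx], rcond=None)[0]
        return a, coef[1], coef[2]

    idx0 = np.arange(n)
    a, b, c_prime = paths(idx0)
    Xt = np.column_stack([ones, e, C])
    total = float(np.linalg.lstsq(Xt, y, rcond=None)[0][1])

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n_degenerate = 0
    p_full = 3 + C.shape[1]
    for bb in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, n)
            Xy = np.column_stack([ones[idx], m[idx], e[idx], C[idx]])
            if np.linalg.matrix_rank(Xy) == p_full:
                break
            n_degenerate += 1
        else:
            raise np.linalg.LinAlgError(
                "bootstrap resamples persistently rank-deficient; "
                "mediator/exposure/covariates may be collinear")
        ab, bbta, _ = paths(idx)
        boots[bb] = ab * bbta
    lo, hi = np.percentile(boots, [100 * (1 - conf_level) / 2,
                                   100 * (1 + conf_level) / 2])
    return MediationResult(
        a=float(a), b=float(b), c_prime=float(c_prime), indirect=float(a * b),
        total=total, ci_lower=float(lo), ci_upper=float(hi),
        conf_level=conf_level, n_boot=n_boot, seed=seed,
        n_degenerate_resamples=n_degenerate,
    )


def correlate_transcripts(score: pd.Series, expression: pd.DataFrame,
                          p_cutoff: float = 0.05, top: int = 100) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of one factor score with every transcript.

    ``expression`` is transcripts x samples; sample alignment is by id.
    Returns the full ranked table (r, p, ascending p) and the selected gene
    list: transcripts with p < ``p_cutoff``, first ``top`` by ascending p.
    Constant transcripts get p = 1 with a warning.
    """
    common = expression.columns.intersection(score.index)
    if len(common) != expression.shape[1] or len(common) != len(score):
        raise ValueError("sample ids of score and expression do not align")
    E = expression[score.index].to_numpy(float)
    s = score.to_numpy(float)
    n = len(s)
    sz = (s - s.mean()) / s.std(ddof=0)
    Em = E - E.mean(axis=1, keepdims=True)
    sd = E.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant transcript(s); p set to 1")
    sd_safe = np.where(const, 1.0, sd)
    r = (Em / sd_safe[:, None]) @ sz / n
    r = np.clip(np.where(const, 0.0, r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(const, 1.0, p)
    table = pd.DataFrame({"r": r, "p": p}, index=expression.index).sort_values("p", kind="mergesort")
    hits = table[table["p"] < p_cutoff]
    selected = list(hits.index[:top])
    return table, selected


def ora(selected_genes: list[str], gene_sets: dict[str, list[str]],
        universe: list[str], p_rule: float = 0.01, q_rule: float = 0.05,
        min_overlap: int = 3) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list within gene sets.

    For each set (intersected with the universe) the upper-tail hypergeometric
    p of the observed overlap is computed; q-values are Benjamini-Hochberg
    across sets; a set is significant when p < 0.01, q < 0.05 and the overlap
    has at least 3 genes.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sel = set(selected_genes)
    if not sel <= uni:
        raise ValueError("selected genes must be a subset of the universe")
    N, n_sel = len(uni), len(sel)
    rows = []
    for name, members in gene_sets.items():
        mem = set(members) & uni
        K = len(mem)
        k = len(mem & sel)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_sel)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "universe_size": N, "selected_size": n_sel, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = []
    out["significant"] = (out["p"] < p_rule) & (out["q"] < q_rule) & (out["overlap"] >= min_overlap)
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "synthetic"):
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description] + list(genes)) + "\n")
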