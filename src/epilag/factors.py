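"""Exploratory factor analysis of per-gene CpG beta matrices.

Each gene's correlated CpG loci are reduced to a small number of orthogonal
common factors; the standardized factor scores are the integrated methylation
measures that downstream models take as responses.

Pipeline: sampling adequacy (KMO), factor count by parallel analysis,
iterated principal-axis factoring of the correlation matrix, varimax
rotation, regression (Thurstone) factor scores re-standardized to mean 0 /
SD 1, and probe-to-factor assignment at the |loading| > 0.45 cutoff.

Numerical conventions: initial communalities are squared multiple
correlations; the communality iteration converges when the largest absolute
change falls below ``tol`` (default 1e-4); varimax operates on the raw (not
Kaiser-normalized) loadings; factors are ordered by explained variance with
signs flipped so each column's loading sum is non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FactorSolution", "kmo", "parallel_analysis", "fit_factors",
           "assign_cpgs", "varimax", "tucker_congruence", "FactorConvergenceError"]


class FactorConvergenceError(RuntimeError):
    """Raised when the communality iteration fails; carries the last iterate."""

    def __init__(self, msg, last_loadings=None, last_communalities=None):
        super().__init__(msg)
        self.last_loadings = last_loadings
        self.last_communalities = last_communalities


def _corr_from_samples(data: np.ndarray) -> np.ndarray:
    R = np.corrcoef(data, rowvar=False)
    return np.atleast_2d(R)


def _safe_inverse_corr(R: np.ndarray, ridge: float = 1e-8):
    """Inverse of a correlation matrix with a documented ridge fallback."""
    p = R.shape[0]
    try:
        return np.linalg.inv(R)
    except np.linalg.LinAlgError:
        pass
    for eps in (1e-8, 1e-6, 1e-4):
        try:
            Ri = np.linalg.inv(R + eps * np.eye(p))
            warnings.warn(f"correlation matrix singular; ridge {eps} applied")
            return Ri
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("correlation matrix singular even after ridge")


def kmo(data) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    MSA = sum r^2 / (sum r^2 + sum q^2) over off-diagonal elements, where the
    q are the anti-image partial correlations obtained from the inverse
    correlation matrix.  Near 0.5 for independent variables, approaching 1
    with strong common variance.  ``data`` is samples x variables (or a
    correlation matrix, detected by its square shape with unit diagonal).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("need a 2-d array")
    if X.shape[0] == X.shape[1] and np.allclose(np.diag(X), 1.0):
        R = X.copy()
    else:
        R = _corr_from_samples(X)
    Ri = _safe_inverse_corr(R)
    d = np.sqrt(np.diag(Ri))
    Q = -Ri / np.outer(d, d)  # anti-image partial correlations
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def parallel_analysis(data, n_sims: int = 200, quantile: float = 0.95,
                      seed: int | None = None) -> int:
    """Number of factors to retain by Horn-style parallel analysis.

    Eigenvalues of the observed correlation matrix are compared rank-by-rank
    against the chosen quantile of eigenvalues from ``n_sims`` standard-normal
    datasets of the same dimension; components are retained while the observed
    eigenvalue exceeds its simulated threshold, stopping at the first failure.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    obs = np.sort(np.linalg.eigvalsh(_corr_from_samples(X)))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sims, p))
    for s in range(n_sims):
        Z = rng.standard_normal((n, p))
        sims[s] = np.sort(np.linalg.eigvalsh(_corr_from_samples(Z)))[::-1]
    thresh = np.quantile(sims, quantile, axis=0)
    k = 0
    while k < p and obs[k] > thresh[k]:
        k += 1
    return k


def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (raw, no Kaiser normalization).

    Maximizes the summed variance of squared loadings over orthogonal
    rotations.  Returns (rotated loadings, rotation matrix).
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    T = np.eye(k)
    if k < 2:
        return L.copy(), T
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ T
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / p)
        )
        T = u @ vt
        var_new = float(np.sum(s))
        if var_new - var_old < tol:
            break
        var_old = var_new
    return L @ T, T


@dataclass
class FactorSolution:
    """Loadings, communalities, fit summaries, and standardized scores."""

    loadings: pd.DataFrame  # probes x factors
    communalities: pd.Series
    rotation: str
    explained_variance: pd.Series  # fraction of total variance per factor
    total_explained: float
    rmsr: float
    scores: pd.DataFrame  # samples x factors, mean 0 / SD 1
    n_iter: int

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]


def fit_factors(beta: pd.DataFrame, n_factors: int, max_iter: int = 100,
                tol: float = 1e-4, rotate: bool = True) -> FactorSolution:
    """Iterated principal-axis factoring with varimax rotation.

    ``beta`` is samples x probes (a transposed per-gene beta matrix is
    accepted via DataFrame orientation: rows are observations).  Initial
    communalities are squared multiple correlations; each iteration replaces
    the correlation-matrix diagonal with the current communalities, extracts
    the leading ``n_factors`` eigenpairs (eigenvalues clipped at zero), and
    updates the communalities from the loading rows until the largest change
    is below ``tol``.
    """
    if not isinstance(beta, pd.DataFrame):
        beta = pd.DataFrame(np.asarray(beta, dtype=float))
    X = beta.values.astype(float)
    n, p = X.shape
    if not (1 <= n_factors < p):
        raise ValueError("n_factors must be >= 1 and < number of probes")
    R = _corr_from_samples(X)
    Ri = _safe_inverse_corr(R)
    h = 1.0 - 1.0 / np.diag(Ri)  # SMC start
    h = np.clip(h, 0.0, 0.999)

    # near-Heywood cases creep towards a boundary communality very slowly, so
    # the iteration cap must be generous; each step is one small eigh
    L = None
    for it in range(1, max_iter + 1):
        Rh = R.copy()
        np.fill_diagonal(Rh, h)
        vals, vecs = np.linalg.eigh(Rh)
        order = np.argsort(vals)[::-1][:n_factors]
        lam = np.clip(vals[order], 0.0, None)
        L = vecs[:, order] * np.sqrt(lam)
        h_new = np.clip(np.sum(L**2, axis=1), 0.0, 0.999)
        delta = float(np.max(np.abs(h_new - h)))
        h = h_new
        if delta < tol:
            break
    else:
        raise FactorConvergenceError(
            f"communalities not converged after {max_iter} iterations",
            last_loadings=L, last_communalities=h,
        )

    rotation = "none"
    if rotate and n_factors > 1:
        L, _ = varimax(L)
        rotation = "varimax"
    # order by explained variance, make column sums non-negative
    ssq = np.sum(L**2, axis=0)
    order = np.argsort(ssq)[::-1]
    L = L[:, order]
    sign = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    L = L * sign

    factor_names = [f"Factor{j + 1}" for j in range(n_factors)]
    loadings = pd.DataFrame(L, index=beta.columns, columns=factor_names)
    communalities = pd.Series(np.sum(L**2, axis=1), index=beta.columns)

    resid = R - L @ L.T
    off = ~np.eye(p, dtype=bool)
    rmsr = float(np.sqrt(np.mean(resid[off] ** 2)))
    explained = pd.Series(np.sum(L**2, axis=0) / p, index=factor_names)

    # regression (Thurstone) scores from rotated loadings, re-standardized
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    S = Z @ (Ri @ L)
    S = (S - S.mean(axis=0)) / S.std(axis=0, ddof=1)
    scores = pd.DataFrame(S, index=beta.index, columns=factor_names)

    return FactorSolution(
        loadings=loadings, communalities=communalities, rotation=rotation,
        explained_variance=explained, total_explained=float(explained.sum()),
        rmsr=rmsr, scores=scores, n_iter=it,
    )


def assign_cpgs(solution: FactorSolution, cutoff: float = 0.45) -> dict[str, pd.Series]:
    """Group probes to every factor where |loading| strictly exceeds ``cutoff``.

    The signed loading is retained, so inverse contributions (negative
    loadings) stay distinguishable.
    """
    out: dict[str, pd.Series] = {}
    for f in solution.loadings.columns:
        col = solution.loadings[f]
        out[f] = col[col.abs() > cutoff]
    return out


def tucker_congruence(A, B) -> float:
    """Mean Tucker congruence between two loading matrices.

    Columns of ``B`` are greedily matched to columns of ``A`` by absolute
    congruence; the unsigned coefficients are averaged.  Used for
    parameter-recovery checks against a known loading matrix.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    ka, kb = A.shape[1], B.shape[1]
    C = np.zeros((ka, kb))
    for i in range(ka):
        for j in range(kb):
            denom = np.linalg.norm(A[:, i]) * np.linalg.norm(B[:, j])
            C[i, j] = np.abs(A[:, i] @ B[:, j]) / denom if denom > 0 else 0.0
    used = set()
    vals = []
    for i in np.argsort(-C.max(axis=1)):
        j_order = np.argsort(-C[i])
        for j in j_order:
            if j not in used:
                used.add(j)
                vals.append(C[i, j])
                break
    return float(np.mean(vals))
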