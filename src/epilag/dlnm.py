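"""Distributed-lag model machinery: lag basis, cross-basis, effect prediction.

The exposure history of each pregnancy is the vector of 40 weekly mean PM2.5
concentrations (week 1 at estimated conception).  The exposure-response
relation is taken linear; the lag-response relation is a natural cubic spline
over the lag (week) axis.  Crossing the two bases gives the cross-basis block
W = X B, where X is the N x 40 exposure matrix and B the 40 x d lag basis.
A fitted coefficient vector on the cross-basis columns then translates into
week-specific and window-cumulative changes in the response per a fixed
exposure increment (5 ug/m^3 by default).

The default lag basis is a natural cubic spline with 3 internal knots equally
spaced in value over [1, 40] (at 10.75, 20.5, 30.25), boundary knots at 1 and
40, with the intercept column part of the basis, giving total dimension 5.
An identity basis (one column per week) yields the unconstrained distributed
lag model used as a sensitivity check.

The natural spline uses the truncated-power construction with linearity
constraints beyond the boundary knots; the resulting functions are piecewise
cubic, twice continuously differentiable and linear outside the boundaries.
Any basis of the same spline space would give identical predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LagBasis", "CrossBasis", "LagEffectEstimate", "lag_basis", "cross_basis",
           "predict_effects", "natural_spline_matrix", "WINDOWS"]

#: gestational exposure windows (1-based, inclusive)
WINDOWS: dict[str, tuple[int, int]] = {
    "overall": (1, 40),
    "trimester1": (1, 13),
    "trimester2": (14, 26),
    "trimester3": (27, 40),
}


def natural_spline_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (no intercept) evaluated at ``x``.

    ``knots`` is the full increasing knot sequence including the two boundary
    knots.  Returns len(x) x (len(knots) - 1) columns: the linear term plus
    one truncated-power difference function per non-boundary-pair knot,
    following the standard construction

        N_1(x) = x,   N_{k+1}(x) = d_k(x) - d_{M-1}(x),  k = 1..M-2,
        d_k(x) = [ (x - xi_k)_+^3 - (x - xi_M)_+^3 ] / (xi_M - xi_k),

    which is linear beyond the boundary knots and C^2 everywhere.
    """
    x = np.asarray(x, dtype=float)
    xi = np.asarray(knots, dtype=float)
    if np.any(np.diff(xi) <= 0):
        raise ValueError("knots must be strictly increasing")
    M = len(xi)

    def d(k):
        return ((np.clip(x - xi[k], 0, None)) ** 3 - (np.clip(x - xi[M - 1], 0, None)) ** 3) / (
            xi[M - 1] - xi[k]
        )

    cols = [x]
    d_last = d(M - 2)
    for k in range(M - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


@dataclass
class LagBasis:
    """Basis over the lag (gestational week) axis, rows at weeks 1..n_lags."""

    matrix: np.ndarray  # n_lags x d
    kind: str  # "ns" or "identity"
    knots: np.ndarray | None
    boundary: tuple[float, float] | None
    intercept: bool
    weeks: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.weeks is None:
            self.weeks = np.arange(1, self.matrix.shape[0] + 1)

    @property
    def n_lags(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


def lag_basis(n_lags: int = 40, n_knots: int = 3, intercept: bool = True,
              kind: str = "ns") -> LagBasis:
    """Construct the lag basis evaluated at integer weeks 1..n_lags.

    For ``kind="ns"``: natural cubic spline with ``n_knots`` internal knots
    equally spaced in value over [1, n_lags], boundary knots at 1 and n_lags,
    and an intercept column prepended when ``intercept``; the dimension is
    n_knots + 1 + intercept.  For ``kind="identity"``: the n_lags x n_lags
    identity (unconstrained distributed lag model).
    """
    weeks = np.arange(1, n_lags + 1, dtype=float)
    if kind == "identity":
        return LagBasis(matrix=np.eye(n_lags), kind="identity", knots=None,
                        boundary=None, intercept=False, weeks=weeks)
    if kind != "ns":
        raise ValueError(f"unknown lag basis kind {kind!r}")
    if n_knots < 1:
        raise ValueError("need at least one internal knot")
    internal = 1.0 + (np.arange(1, n_knots + 1)) * (n_lags - 1.0) / (n_knots + 1)
    if internal.min() <= 1.0 or internal.max() >= n_lags:
        raise ValueError("internal knots must lie strictly inside [1, n_lags]")
    knots = np.concatenate([[1.0], internal, [float(n_lags)]])
    B = natural_spline_matrix(weeks, knots)
    if intercept:
        B = np.column_stack([np.ones(n_lags), B])
    return LagBasis(matrix=B, kind="ns", knots=internal, boundary=(1.0, float(n_lags)),
                    intercept=intercept, weeks=weeks)


@dataclass
class CrossBasis:
    """Cross-basis block: N x d design columns from linear exposure x lag basis."""

    matrix: np.ndarray  # N x d
    basis: LagBasis
    column_names: list[str] = None

    def __post_init__(self):
        if self.column_names is None:
            self.column_names = [f"cb{j}" for j in range(self.matrix.shape[1])]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_names, index=index)


def cross_basis(exposure, basis: LagBasis) -> CrossBasis:
    """W = X B with X the N x n_lags exposure matrix (linear exposure basis)."""
    X = exposure.values if isinstance(exposure, pd.DataFrame) else np.asarray(exposure, float)
    if X.ndim != 2 or X.shape[1] != basis.n_lags:
        raise ValueError(f"exposure must have {basis.n_lags} columns, got {X.shape}")
    if np.isnan(X).any():
        raise ValueError("exposure contains missing cells; zero-fill happens upstream")
    return CrossBasis(matrix=X @ basis.matrix, basis=basis)


@dataclass
class LagEffectEstimate:
    """Week-specific and window-cumulative effects per ``delta`` ug/m^3."""

    weekly: pd.DataFrame  # index week, columns estimate/se/lower/upper
    windows: pd.DataFrame  # index window name, same columns
    delta: float
    conf_level: float


def predict_effects(coef: np.ndarray, vcov: np.ndarray, basis: LagBasis,
                    delta: float = 5.0, conf_level: float = 0.95) -> LagEffectEstimate:
    """Translate cross-basis coefficients into lag effects with normal CIs.

    Week-l effect = delta * B[l, :] @ coef; a window's cumulative effect uses
    the summed basis rows, so cumulative = sum of weekly holds exactly.
    """
    coef = np.asarray(coef, dtype=float).ravel()
    vcov = np.asarray(vcov, dtype=float)
    if coef.shape[0] != basis.d or vcov.shape != (basis.d, basis.d):
        raise ValueError("coef/vcov dimensions do not match the lag basis")
    if not np.allclose(vcov, vcov.T, atol=1e-8):
        raise ValueError("vcov must be symmetric")
    z = stats.norm.ppf(0.5 + conf_level / 2.0)

    def row_effects(rows: np.ndarray) -> pd.DataFrame:
        est = delta * rows @ coef
        var = delta**2 * np.einsum("ij,jk,ik->i", rows, vcov, rows)
        se = np.sqrt(np.clip(var, 0.0, None))
        return pd.DataFrame({
            "estimate": est, "se": se,
            "lower": est - z * se, "upper": est + z * se,
        })

    weekly = row_effects(basis.matrix)
    weekly.index = pd.Index(basis.weeks.astype(int), name="week")

    wrows = np.vstack([
        basis.matrix[(basis.weeks >= lo) & (basis.weeks <= hi)].sum(axis=0)
        for lo, hi in WINDOWS.values()
    ])
    windows = row_effects(wrows)
    windows.index = pd.Index(list(WINDOWS), name="window")
    return LagEffectEstimate(weekly=weekly, windows=windows, delta=delta,
                             conf_level=conf_level)
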