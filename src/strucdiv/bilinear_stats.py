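"""Bilinear regression machinery for sequence -> structure divergence.

The central model regresses a structural divergence response y (RMSD or
structure-alignment Z-score) on one substitution variable x1 and one indel
variable x2:

    y = b0 + b1*x1 + b2*x2 + u

The absolute coefficients |b1| and |b2| are the structural substitution
sensitivity (SSS) and structural indel sensitivity (SIDS): the structural
change per unit of substitution or per standard-length indel. Around the
fit this module provides:

* the multiple correlation R (non-negative root of R²), adjusted R²
  ``1 - (1-R²)(n-1)/(n-k-1)``, and the overall F-test of R = 0;
* adequacy, the ratio of the bilinear adjusted R² to that of a
  one-predictor linear fit — how much the two-variable model improves on
  substitutions or indels alone;
* first-order partial correlations of each predictor with the response
  (t-tested on n-3 degrees of freedom) and the two-predictor variance
  inflation factor ``VIF = 1/(1 - r12²)``;
* the product-measure contribution decomposition ``C_i = beta_i * r_i``
  (standardized coefficient times zero-order correlation), whose two terms
  sum exactly to R² — apportioning the explained variance between
  substitutions and indels.

Fits are ordinary least squares via statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDataError

_EPS = 1e-12


@dataclass
class BilinearFit:
    """Full results of one bilinear (two-predictor) OLS fit."""

    b0: float
    b1: float
    b2: float
    sss: float  # |b1|
    sids: float  # |b2|
    r: float
    r2: float
    adj_r2: float
    f_stat: float
    p_value: float
    beta1: float  # standardized coefficients
    beta2: float
    ry1: float  # zero-order predictor-response correlations
    ry2: float
    c_sub: float  # product-measure contributions; c_sub + c_indel = r2
    c_indel: float
    partial1: float
    partial2: float
    partial_p1: float
    partial_p2: float
    vif: float
    n: int
    se_b0: float = float("nan")
    se_b1: float = float("nan")
    se_b2: float = float("nan")


@dataclass
class LinearFit:
    """Simple one-predictor OLS fit (the adequacy comparator)."""

    b0: float
    b1: float
    r2: float
    adj_r2: float
    n: int
    se_b1: float = float("nan")


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size == 0:
        raise DegenerateDataError(f"{name} is empty")
    if not np.all(np.isfinite(v)):
        raise DegenerateDataError(f"{name} contains non-finite values")
    if np.std(v) == 0:
        raise DegenerateDataError(f"{name} has zero variance")
    return v


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Adjusted coefficient of determination ``1 - (1-R²)(n-1)/(n-k-1)``."""
    if n <= k + 1:
        raise DegenerateDataError(
            f"adjusted R² needs n > k + 1; got n = {n}, k = {k}"
        )
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def fit_bilinear(x1, x2, y) -> BilinearFit:
    """OLS fit of ``y = b0 + b1*x1 + b2*x2 + u`` with all diagnostics.

    Raises :class:`DegenerateDataError` if any variable has zero variance,
    if the predictors are perfectly collinear, or if n < 4.
    """
    x1 = _as_vector(x1, "x1")
    x2 = _as_vector(x2, "x2")
    yv = _as_vector(y, "y")
    n = yv.size
    if not (x1.size == x2.size == n):
        raise DegenerateDataError("x1, x2 and y must have equal lengths")
    if n < 4:
        raise DegenerateDataError(f"bilinear fit needs n >= 4, got {n}")
    r12 = _pearson(x1, x2)
    if abs(r12) >= 1.0 - _EPS:
        raise DegenerateDataError("x1 and x2 are perfectly collinear")

    X = sm.add_constant(np.column_stack([x1, x2]))
    res = sm.OLS(yv, X).fit()
    b0, b1, b2 = (float(c) for c in res.params)
    r2 = float(res.rsquared)
    ry1 = _pearson(yv, x1)
    ry2 = _pearson(yv, x2)
    sd_y = float(np.std(yv, ddof=1))
    beta1 = b1 * float(np.std(x1, ddof=1)) / sd_y
    beta2 = b2 * float(np.std(x2, ddof=1)) / sd_y
    try:
        partial1, p1, partial2, p2 = partial_correlations(x1, x2, y)
    except DegenerateDataError:
        # e.g. y exactly collinear with one predictor: the OLS fit itself is
        # fine, only the partials are undefined
        partial1 = p1 = partial2 = p2 = float("nan")
    return BilinearFit(
        b0=b0,
        b1=b1,
        b2=b2,
        sss=abs(b1),
        sids=abs(b2),
        r=float(np.sqrt(max(r2, 0.0))),
        r2=r2,
        adj_r2=adjusted_r2(r2, n, 2),
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        beta1=beta1,
        beta2=beta2,
        ry1=ry1,
        ry2=ry2,
        c_sub=beta1 * ry1,
        c_indel=beta2 * ry2,
        partial1=partial1,
        partial2=partial2,
        partial_p1=p1,
        partial_p2=p2,
        vif=vif(x1, x2),
        n=n,
        se_b0=float(res.bse[0]),
        se_b1=float(res.bse[1]),
        se_b2=float(res.bse[2]),
    )


def fit_linear(x, y) -> LinearFit:
    """Simple OLS fit ``y = b0 + b1*x``; R² is the squared correlation."""
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size != yv.size:
        raise DegenerateDataError("x and y must have equal lengths")
    if xv.size < 3:
        raise DegenerateDataError(f"linear fit needs n >= 3, got {xv.size}")
    res = sm.OLS(yv, sm.add_constant(xv)).fit()
    r2 = float(res.rsquared)
    return LinearFit(
        b0=float(res.params[0]),
        b1=float(res.params[1]),
        r2=r2,
        adj_r2=adjusted_r2(r2, xv.size, 1),
        n=xv.size,
        se_b1=float(res.bse[1]),
    )


def adequacy(bilinear: BilinearFit, linear: LinearFit) -> float:
    """Adjusted-R² ratio of the bilinear fit over a one-predictor fit.

    Values above 1 quantify the improvement from modelling substitutions
    and indels jointly.
    """
    if linear.adj_r2 <= 0:
        raise DegenerateDataError(
            f"adequacy undefined: linear adjusted R² = {linear.adj_r2:.4g} <= 0"
        )
    return bilinear.adj_r2 / linear.adj_r2


def partial_correlations(x1, x2, y) -> tuple[float, float, float, float]:
    """First-order partial correlations of each predictor with the response.

    Returns ``(partial1, p1, partial2, p2)`` where ``partial1`` is
    r(y, x1 | x2) = (r_y1 - r_y2*r_12) / sqrt((1-r_y2²)(1-r_12²)) and the
    p-values come from the two-sided t-test
    t = r_p * sqrt((n-3)/(1-r_p²)) on n-3 degrees of freedom.
    """
    x1 = _as_vector(x1, "x1")
    x2 = _as_vector(x2, "x2")
    yv = _as_vector(y, "y")
    n = yv.size
    if n < 4:
        raise DegenerateDataError(f"partial correlation needs n >= 4, got {n}")
    ry1 = _pearson(yv, x1)
    ry2 = _pearson(yv, x2)
    r12 = _pearson(x1, x2)
    for name, r in (("r_y1", ry1), ("r_y2", ry2), ("r_12", r12)):
        if abs(r) >= 1.0 - _EPS:
            raise DegenerateDataError(f"degenerate correlation |{name}| = 1")

    def _partial(ra, rb):
        return (ra - rb * r12) / np.sqrt((1 - rb**2) * (1 - r12**2))

    def _pvalue(rp):
        rp = min(max(rp, -1.0 + _EPS), 1.0 - _EPS)
        t = rp * np.sqrt((n - 3) / (1 - rp**2))
        return float(2 * stats.t.sf(abs(t), df=n - 3))

    p1v = float(_partial(ry1, ry2))
    p2v = float(_partial(ry2, ry1))
    return p1v, _pvalue(p1v), p2v, _pvalue(p2v)


def vif(x1, x2) -> float:
    """Two-predictor variance inflation factor ``1/(1 - r12²)``."""
    x1 = _as_vector(x1, "x1")
    x2 = _as_vector(x2, "x2")
    r12 = _pearson(x1, x2)
    if abs(r12) >= 1.0 - _EPS:
        raise DegenerateDataError("infinite VIF: predictors perfectly collinear")
    return float(1.0 / (1.0 - r12**2))


def contributions(fit: BilinearFit) -> tuple[float, float]:
    """Product-measure contributions ``(C_sub, C_indel)``; they sum to R²."""
    return fit.c_sub, fit.c_indel
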