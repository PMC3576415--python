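"""Inferential primitives shared by every pipeline stage.

Covariate-adjusted ordinary least squares, accurate Gaussian tail
probabilities, Storey q-values, exact binomial upper tails and dosage
LD r-squared.  All functions are pure (no I/O) and operate on plain
numpy arrays / floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import special
from scipy import stats as sps
from scipy.interpolate import UnivariateSpline

__all__ = [
    "LinearFit",
    "QvalueResult",
    "DegenerateFitError",
    "InsufficientDataError",
    "ols_fit",
    "gaussian_upper_tail",
    "storey_qvalues",
    "binomial_upper_tail",
    "ld_r2",
]


class DegenerateFitError(ValueError):
    """The design is singular (e.g. a constant predictor)."""


class InsufficientDataError(ValueError):
    """Too few complete observations to fit the requested model."""


@dataclass(frozen=True)
class LinearFit:
    """One covariate-adjusted OLS slope.

    Attributes
    ----------
    beta : effect of the predictor per unit change.
    se : standard error of ``beta``.
    tstat : ``beta / se``.
    df : residual degrees of freedom, ``n - n_columns`` (intercept included).
    p : two-sided Student-t tail probability.
    n : number of samples used after listwise deletion.
    """

    beta: float
    se: float
    tstat: float
    df: int
    p: float
    n: int


@dataclass(frozen=True)
class QvalueResult:
    """Storey q-values aligned to the input p-values plus the pi0 estimate."""

    qvalues: np.ndarray
    pi0: float


def ols_fit(response, predictor, covariates=None) -> LinearFit:
    """Fit ``response ~ intercept + predictor + covariates`` by OLS.

    Rows with any missing value are dropped (listwise deletion); the
    reported ``n`` is the number of rows actually used.  The p-value is
    the two-sided Student-t tail with ``df = n - k`` where ``k`` counts
    every design column including the intercept.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if covariates is None:
        covs = np.empty((y.shape[0], 0))
    else:
        covs = np.asarray(covariates, dtype=float)
        if covs.ndim == 1:
            covs = covs[:, None]
    if not (y.shape[0] == x.shape[0] == covs.shape[0]):
        raise ValueError("response, predictor and covariates differ in length")

    keep = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(covs), axis=1)
    y, x, covs = y[keep], x[keep], covs[keep]
    n = y.shape[0]
    k = 2 + covs.shape[1]  # intercept + predictor + covariates
    if n <= k:
        raise InsufficientDataError(
            f"need more than {k} complete observations, got {n}"
        )
    if np.ptp(x) == 0:
        raise DegenerateFitError("predictor is constant after listwise deletion")

    X = np.column_stack([np.ones(n), x, covs])
    beta_hat, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateFitError("design matrix is rank deficient")
    resid = y - X @ beta_hat
    df = n - k
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(sigma2 * xtx_inv[1, 1])
    if se == 0.0:
        # perfect fit: report the machine floor rather than dividing by zero
        tstat = math.copysign(np.inf, beta_hat[1]) if beta_hat[1] != 0 else 0.0
        p = 0.0 if beta_hat[1] != 0 else 1.0
        return LinearFit(float(beta_hat[1]), 0.0, tstat, df, max(p, 5e-324), n)
    tstat = float(beta_hat[1]) / se
    p = float(2.0 * sps.t.sf(abs(tstat), df))
    return LinearFit(float(beta_hat[1]), se, tstat, df, max(p, 5e-324), n)


def gaussian_upper_tail(z: float) -> float:
    """P(Z > z) for standard normal Z, accurate deep into the tail.

    Uses the complementary error function, avoiding the catastrophic
    cancellation of ``1 - cdf(z)`` for large ``z``.
    """
    z = float(z)
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    return 0.5 * float(special.erfc(z / math.sqrt(2.0)))


_LAMBDA_GRID = np.arange(0.05, 0.9001, 0.05)


def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray = _LAMBDA_GRID) -> float:
    """Estimate the null proportion pi0 by cubic-smoother extrapolation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is smoothed with a
    cubic spline over the lambda grid and evaluated at lambda -> 1,
    then clipped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    spline = UnivariateSpline(lambdas, pi0_lambda, k=3)
    pi0 = float(spline(1.0))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(
    pvalues,
    pi0: float | None = None,
    small_m_fallback: int = 100,
) -> QvalueResult:
    """Storey q-values for a vector of p-values.

    ``pi0`` is estimated by the smoother unless given explicitly.  For
    fewer than ``small_m_fallback`` tests the smoother is unreliable and
    pi0 = 1 is used (a BH-style conservative fallback).  q-values are
    ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j`` over the sorted order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d array")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = 1.0 if m < small_m_fallback else estimate_pi0(p)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return QvalueResult(qvalues=q, pi0=float(pi0))


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p0).

    Summed in exact rational arithmetic for moderate ``n`` so that tiny
    tails keep full precision; for large ``n`` the regularised
    incomplete beta function is used.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, {n}], got {k}")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    if k == 0:
        return 1.0
    if n <= 1000:
        p = Fraction(p0)
        q = 1 - p
        total = Fraction(0)
        for i in range(k, n + 1):
            total += math.comb(n, i) * p**i * q ** (n - i)
        return float(total)
    # P(X >= k) = I_{p0}(k, n - k + 1)
    return float(special.betainc(k, n - k + 1, p0))


def ld_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation between two dosage vectors.

    This is the composite-LD convention appropriate for (possibly
    imputed) allele dosages in [0, 2].
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("dosage vectors must be equal-length 1-d with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateFitError("LD undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
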