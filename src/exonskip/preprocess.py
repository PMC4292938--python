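"""Probe-level normalization stack for expression microarrays.

The stack mirrors the classical robust multiarray (RMA) pipeline:

1. *Norm-exp background correction.*  Each observed probe intensity is
   modelled as ``X = B + S`` where the background ``B ~ Normal(mu, sigma^2)``
   is probe-sequence independent and the true signal ``S ~ Exponential``
   with mean ``alpha``.  The corrected value is the posterior mean
   ``E[S | X = x]``, which is strictly positive and monotone in ``x``.
2. *Quantile normalization.*  A target distribution is formed by averaging
   the order statistics over all arrays; every array is then mapped onto
   that target, preserving within-array ranks.
3. *log2 transform.*
4. *Median-polish summarization* of the probes in a probeset to one value
   per sample (Tukey's additive row + column fit by alternating median
   sweeps).

The index computation downstream consumes the *probe-level* log2 values
(step 3); summarization is exposed for probeset-level analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "EstimationError",
    "NormExpParams",
    "normexp_fit",
    "normexp_correct",
    "background_correct",
    "quantile_normalize",
    "MedianPolishFit",
    "median_polish",
    "median_polish_summarize",
    "rma_preprocess",
]

# strictly positive floor for corrected intensities (log2 must be defined)
_CORRECTED_FLOOR = 1e-10


class EstimationError(RuntimeError):
    """A model fit could not be computed from the data given."""


@dataclass(frozen=True)
class NormExpParams:
    """Parameters of the normal-background + exponential-signal convolution.

    Attributes
    ----------
    mu : float
        Background mean, in raw intensity units.
    sigma : float
        Background standard deviation (>= 0).
    alpha : float
        Mean of the exponential signal distribution (> 0).
    """

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.mu, self.sigma, self.alpha])):
            raise ValueError("norm-exp parameters must be finite")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


def _normexp_logpdf(x: np.ndarray, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """Log density of X = B + S at x (vectorized, numerically stable)."""
    if sigma == 0:
        out = np.full_like(x, -np.inf, dtype=float)
        pos = x > mu
        out[pos] = -np.log(alpha) - (x[pos] - mu) / alpha
        return out
    z = (x - mu - sigma**2 / alpha) / sigma
    return -np.log(alpha) + sigma**2 / (2 * alpha**2) - (x - mu) / alpha + special.log_ndtr(z)


def normexp_fit(column, *, min_n: int = 10) -> NormExpParams:
    """Maximum-likelihood fit of the norm-exp convolution to one array.

    Uses moment-based starting values (the third central moment of the
    convolution is ``2 * alpha**3``) followed by quasi-Newton optimization of
    the log-likelihood in ``(mu, log sigma, log alpha)``.  Falls back to the
    method-of-moments estimate if the optimizer fails.

    Parameters
    ----------
    column : array-like
        Raw intensities of a single array; needs >= ``min_n`` finite values.

    Raises
    ------
    EstimationError
        For fewer than ``min_n`` finite values or an (almost) constant column,
        where the three parameters are not identifiable.
    """
    x = np.asarray(column, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise EstimationError(
            f"norm-exp fit needs at least {min_n} finite values, got {x.size}"
        )
    sd = float(np.std(x))
    if sd < 1e-12 * max(1.0, abs(float(np.mean(x)))):
        raise EstimationError(
            "norm-exp fit on a constant column: background and signal are not identifiable"
        )

    m = float(np.mean(x))
    v = float(np.var(x))
    m3 = float(np.mean((x - m) ** 3))
    alpha0 = (m3 / 2.0) ** (1.0 / 3.0) if m3 > 0 else sd / 2.0
    alpha0 = max(alpha0, 1e-3 * sd)
    sigma0 = float(np.sqrt(max(v - alpha0**2, (0.1 * sd) ** 2)))
    mu0 = m - alpha0
    moments = NormExpParams(mu=mu0, sigma=sigma0, alpha=float(alpha0))

    def nll(theta: np.ndarray) -> float:
        mu, sigma, alpha = theta[0], float(np.exp(theta[1])), float(np.exp(theta[2]))
        if sigma < 1e-8 * sd or alpha < 1e-8 * sd or not np.isfinite([mu, sigma, alpha]).all():
            return 1e30
        with np.errstate(over="ignore", invalid="ignore"):
            ll = _normexp_logpdf(x, mu, sigma, alpha)
        if not np.all(np.isfinite(ll)):
            return 1e30
        return -float(np.sum(ll))

    theta0 = np.array([mu0, np.log(sigma0), np.log(alpha0)])
    span = float(np.max(x) - np.min(x))
    bounds = [
        (float(np.min(x)) - 5 * sd, float(np.max(x))),
        (np.log(1e-6 * sd), np.log(10 * span)),
        (np.log(1e-6 * sd), np.log(100 * span)),
    ]
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
    if res.success and np.isfinite(res.fun) and res.fun < 1e29:
        return NormExpParams(
            mu=float(res.x[0]), sigma=float(np.exp(res.x[1])), alpha=float(np.exp(res.x[2]))
        )
    warnings.warn(
        "norm-exp MLE did not converge; falling back to method-of-moments estimate",
        RuntimeWarning,
        stacklevel=2,
    )
    return moments


def normexp_correct(column, params: NormExpParams) -> np.ndarray:
    """Posterior-mean background correction.

    Returns ``E[S | X = x]`` for each observed intensity ``x`` under the
    fitted convolution model.  Output is strictly positive and monotone
    increasing in ``x``.
    """
    x = np.asarray(column, dtype=float)
    if params.sigma == 0:
        return np.maximum(x - params.mu, _CORRECTED_FLOOR)
    mu_sf = x - params.mu - params.sigma**2 / params.alpha
    z = mu_sf / params.sigma
    # E[S|X=x] = mu_sf + sigma * phi(z) / Phi(z), computed in log space
    out = mu_sf + params.sigma * np.exp(stats.norm.logpdf(z) - special.log_ndtr(z))
    return np.maximum(out, _CORRECTED_FLOOR)


def background_correct(matrix):
    """Fit and apply norm-exp correction per array (column).

    Parameters
    ----------
    matrix : DataFrame or ndarray, probes x samples

    Returns
    -------
    corrected : same type as input
    params : list of NormExpParams, one per column
    """
    is_df = isinstance(matrix, pd.DataFrame)
    vals = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    out = np.empty_like(vals)
    fitted = []
    for j in range(vals.shape[1]):
        p = normexp_fit(vals[:, j])
        fitted.append(p)
        out[:, j] = normexp_correct(vals[:, j], p)
    if is_df:
        out = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out, fitted


def quantile_normalize(matrix):
    """Map every array onto the across-array average order-statistic target.

    After normalization each column's multiset of values equals the target
    distribution (row means of the column-sorted matrix); within-column rank
    order is preserved and ties receive the average of the target values over
    their rank span.  A single-column input is returned unchanged.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    vals = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if vals.ndim != 2:
        raise ValueError("quantile_normalize expects a 2-D matrix")
    if np.isnan(vals).any():
        raise ValueError("missing values must be resolved before quantile normalization")
    n, k = vals.shape
    if k == 1:
        return matrix.copy()
    target = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(k):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = target
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < n:  # average the target over tied rank spans
            sums = np.bincount(inv, weights=assigned)
            counts = np.bincount(inv)
            assigned = (sums / counts)[inv]
        out[:, j] = assigned
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


@dataclass
class MedianPolishFit:
    """Result of a Tukey median-polish fit ``x ~ overall + row + col``."""

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int

    @property
    def col_summaries(self) -> np.ndarray:
        """Per-column summary ``overall + col_effect`` (the RMA probeset value)."""
        return self.overall + self.col_effects


def median_polish(matrix, max_iter: int = 50, tol: float = 1e-10) -> MedianPolishFit:
    """Iterative median sweeps for the additive row + column model.

    Convergence when the change in the sum of absolute residuals falls below
    ``tol * matrix.size``.  Non-convergence returns the last iterate with
    ``converged=False`` and a warning.
    """
    z = np.array(matrix, dtype=float, copy=True)
    if z.ndim == 1:
        z = z[None, :]
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    oldsum = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rdelta = np.nanmedian(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = float(np.nanmedian(col))
        col -= delta
        overall += delta
        cdelta = np.nanmedian(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = float(np.nanmedian(row))
        row -= delta
        overall += delta
        newsum = float(np.nansum(np.abs(z)))
        if newsum == 0 or abs(newsum - oldsum) < tol * z.size:
            converged = True
            break
        oldsum = newsum
    if not converged:
        warnings.warn(
            f"median polish did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return MedianPolishFit(
        overall=overall,
        row_effects=row,
        col_effects=col,
        residuals=z,
        converged=converged,
        n_iter=it,
    )


def median_polish_summarize(probe_matrix) -> np.ndarray:
    """Summarize one probeset (probes x samples, log2 scale) to one value per sample."""
    fit = median_polish(probe_matrix)
    return fit.col_summaries


def rma_preprocess(
    intensities: pd.DataFrame,
    probeset_ids=None,
    *,
    background: bool = True,
    quantile: bool = True,
    log2: bool = True,
):
    """Run the full normalization stack on a probes x samples matrix.

    Parameters
    ----------
    intensities : DataFrame
        Raw probe intensities, probes as rows, samples as columns.
    probeset_ids : Series or array, optional
        Per-probe probeset membership (aligned with ``intensities.index``).
        When given, a probeset x samples summary matrix is also returned.

    Returns
    -------
    dict with keys
        ``probe_level`` : normalized probe-level DataFrame,
        ``params`` : per-array NormExpParams (or None),
        ``probeset_level`` : summarized DataFrame (only when probeset_ids given).
    """
    mat = intensities
    params = None
    if background:
        mat, params = background_correct(mat)
    if quantile:
        mat = quantile_normalize(mat)
    if log2:
        vals = mat.to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError("log2 stage requires strictly positive inputs")
        mat = pd.DataFrame(np.log2(vals), index=mat.index, columns=mat.columns)
    out = {"probe_level": mat, "params": params}
    if probeset_ids is not None:
        ps = pd.Series(np.asarray(probeset_ids), index=intensities.index)
        rows = []
        names = []
        for probeset, sub in mat.groupby(ps, sort=False):
            rows.append(median_polish_summarize(sub.to_numpy()))
            names.append(probeset)
        out["probeset_level"] = pd.DataFrame(
            np.vstack(rows), index=names, columns=mat.columns
        )
    return out
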