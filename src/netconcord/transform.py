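"""Calibration of heterogeneous gene weights.

GWAS gene scores (-log10 p) and pseudo-bulk expression scores
(mean log(CPM+1)) are both right-skewed, on different scales, and must be
made distributionally compatible before they can be summed in a module
score.  The calibration has three steps:

1. Box-Cox transform each vector toward normality, with the power lambda
   chosen from a fixed grid by maximizing a Shapiro-Wilk normality
   statistic; the transformed vector is re-shifted so its median equals
   the median of the input.
2. Generate a rank-based inverse normal (INT) reference vector of the
   same length (Blom offset 3/8).
3. Quantile-normalize the N x 3 matrix [INT reference, GWAS, expression]
   and keep the last two columns as the calibrated weights (v_g, v_s).

Quantile normalization forces the two weight systems onto a single common
distribution anchored by the normal reference while preserving the rank
order within each system, so the two weights can be added meaningfully.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

#: Candidate Box-Cox exponents: -2.00, -1.95, ..., 2.00.
BOXCOX_LAMBDA_GRID = np.round(np.arange(-40, 41) * 0.05, 2)

#: Largest sample handed to the Shapiro-Wilk statistic during the lambda
#: search; larger vectors are thinned by a deterministic stride.
_SW_MAX_N = 5000


def boxcox_transform(values: np.ndarray, lam: float) -> np.ndarray:
    """Apply the Box-Cox power transform at a fixed lambda (no shift)."""
    values = np.asarray(values, dtype=float)
    if lam == 0.0:
        return np.log(values)
    return (values ** lam - 1.0) / lam


def _normality_stat(x: np.ndarray) -> float:
    """Shapiro-Wilk W on a deterministic subsample of at most 5000 points."""
    if x.size > _SW_MAX_N:
        stride = int(np.ceil(x.size / _SW_MAX_N))
        x = x[::stride]
    if np.ptp(x) == 0.0:
        return -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).statistic)


def boxcox_fit_transform(values: np.ndarray) -> tuple[float, np.ndarray]:
    """Box-Cox transform with grid-searched lambda and median re-centering.

    The exponent is chosen from :data:`BOXCOX_LAMBDA_GRID` to maximize the
    Shapiro-Wilk W of the transformed values; if the argmax is exactly 0
    the second-best lambda is used instead, so the returned exponent is
    always a genuine power.  The transformed vector is shifted so that its
    median equals the median of the input (the transform re-shapes the
    distribution but keeps its center).

    Parameters
    ----------
    values
        Strictly positive reals.

    Returns
    -------
    (lambda, transformed)

    Raises
    ------
    ValueError
        If any value is non-positive.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot Box-Cox transform an empty vector")
    if np.any(values <= 0):
        raise ValueError("Box-Cox transform requires strictly positive values")
    if values.size < 20:
        warnings.warn(
            f"only {values.size} values: the Box-Cox lambda estimate is unstable",
            stacklevel=2,
        )
    scores = np.array(
        [_normality_stat(boxcox_transform(values, lam)) for lam in BOXCOX_LAMBDA_GRID]
    )
    order = np.argsort(scores, kind="stable")[::-1]
    best = BOXCOX_LAMBDA_GRID[order[0]]
    if best == 0.0:
        best = BOXCOX_LAMBDA_GRID[order[1]]
    transformed = boxcox_transform(values, best)
    transformed = transformed - np.median(transformed) + np.median(values)
    return float(best), transformed


def inverse_normal_reference(n: int) -> np.ndarray:
    """Rank-based inverse normal scores for n ordered observations.

    Returns Phi^-1((i - c) / (n - 2c + 1)) for i = 1..n with the Blom
    offset c = 3/8: a strictly increasing vector, symmetric about 0.
    """
    if n < 2:
        raise ValueError("need at least 2 observations for an INT reference")
    c = 0.375
    i = np.arange(1, n + 1)
    return stats.norm.ppf((i - c) / (n - 2 * c + 1))


def _map_to_sorted(values: np.ndarray, target_sorted: np.ndarray) -> np.ndarray:
    """Replace each value by the target value at its (average) rank.

    Ties receive the mean of the target values spanned by their average
    rank, so tied inputs map to identical outputs and the result does not
    depend on input order.
    """
    ranks = stats.rankdata(values, method="average")  # 1-based, possibly x.5
    idx = ranks - 1.0
    lo = np.floor(idx).astype(int)
    hi = np.ceil(idx).astype(int)
    return 0.5 * (target_sorted[lo] + target_sorted[hi])


def quantile_calibrate_pair(
    gwas: np.ndarray, expr: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-normalize the weight pair against an INT anchor.

    Builds the N x 3 matrix [INT reference, gwas, expr], replaces each
    column's values by the across-column mean of the order statistics at
    each rank, and returns the calibrated gwas and expr columns.  After
    calibration both vectors have identical sorted values and each keeps
    its original rank order.
    """
    gwas = np.asarray(gwas, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if gwas.shape != expr.shape or gwas.ndim != 1:
        raise ValueError("gwas and expr must be 1-D vectors of equal length")
    n = gwas.size
    ref = inverse_normal_reference(n)
    mean_sorted = (ref + np.sort(gwas) + np.sort(expr)) / 3.0
    return _map_to_sorted(gwas, mean_sorted), _map_to_sorted(expr, mean_sorted)


def calibrate_weight_pair(
    gwas_raw: np.ndarray, expr_raw: np.ndarray, epsilon: float = 1e-6
) -> dict:
    """Full calibration pipeline for a (GWAS, expression) weight pair.

    Both vectors are offset by ``epsilon`` (exact zeros arise from p = 1
    genes and from silent genes and would leave the Box-Cox domain),
    Box-Cox transformed with independent grid-searched lambdas, median
    re-centered, and finally quantile-normalized against a shared INT
    reference.

    Returns a dict with keys ``v_g``, ``v_s``, ``lambda_g``, ``lambda_s``,
    ``boxcox_g``, ``boxcox_s``.
    """
    gwas_raw = np.asarray(gwas_raw, dtype=float)
    expr_raw = np.asarray(expr_raw, dtype=float)
    if gwas_raw.shape != expr_raw.shape:
        raise ValueError("weight vectors must cover the same gene universe")
    lam_g, bc_g = boxcox_fit_transform(gwas_raw + epsilon)
    lam_s, bc_s = boxcox_fit_transform(expr_raw + epsilon)
    v_g, v_s = quantile_calibrate_pair(bc_g, bc_s)
    return {
        "v_g": v_g,
        "v_s": v_s,
        "lambda_g": lam_g,
        "lambda_s": lam_s,
        "boxcox_g": bc_g,
        "boxcox_s": bc_s,
    }
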