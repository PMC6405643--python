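"""Slow, transparent reference estimator of F_q(n) for validation.

Everything here recomputes the fluctuation function by definition: each
block's detrending polynomial is obtained by generic least squares on the
block's own samples (gathered directly, never through prefix differences)
and the residual variance is an explicit mean of squared residuals.  The
implementation shares nothing with the fast prefix-sum path beyond the
series normalization, so agreement between the two is a genuine check of
the moment algebra and its precision safeguards.

Intended for tests and validation at desk scale; the per-scale cost is
O(M * n) instead of O(N).
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np

from .core import (FluctuationSurface, NormalizedSeries, block_scheme,
                   cumulative_profile, default_q_grid, normalize_series,
                   _resolve_overlap)

__all__ = ["reference_variances", "reference_fq", "relative_error"]

_LENGTH_GUARD = 10 ** 6
_CHUNK_ELEMENTS = 4_000_000


def reference_variances(y: np.ndarray, starts: np.ndarray, n: int,
                        order: int) -> np.ndarray:
    """Residual variances by direct per-block least squares.

    The design matrix uses a centered local index (an affine
    reparameterization that leaves residuals unchanged but keeps the
    normal equations well conditioned); the fit is the Moore-Penrose
    solution applied to each block's samples, and the variance an explicit
    mean of squared residuals with numpy's pairwise-compensated summation.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    j = np.arange(n, dtype=float) - (n - 1) / 2.0
    X = np.vander(j, order + 1, increasing=True)
    pinvT = np.linalg.pinv(X).T          # (n, order+1)
    out = np.empty(starts.size)
    chunk = max(1, _CHUNK_ELEMENTS // n)
    for lo in range(0, starts.size, chunk):
        st = starts[lo:lo + chunk]
        blk = y[(st - 1)[:, None] + np.arange(n)]
        fitted = (blk @ pinvT) @ X.T
        res = blk - fitted
        out[lo:lo + chunk] = np.mean(res * res, axis=1)
    return out


def _fq_direct(variances: np.ndarray, q: float, eps: float
               ) -> tuple[float, int]:
    """Plain-formula evaluation of the q-order fluctuation function."""
    v = np.asarray(variances, dtype=float).ravel()
    keep = v >= eps
    if q <= 0:
        keep &= v > 0.0
    v = v[keep]
    if v.size == 0:
        return float("nan"), 0
    if q == 0:
        return float(np.exp(np.mean(np.log(v)) / 2.0)), v.size
    return float(np.mean(v ** (q / 2.0)) ** (1.0 / q)), v.size


def reference_fq(raw, q_grid=None, n_grid=None, overlap="max",
                 order: int = 1, eps: float = 0.0) -> FluctuationSurface:
    """Reference F_q(n) surface for one detrending order.

    Mathematically identical in definition to the fast estimator, computed
    by per-block direct summation.  Warns above 10^6 samples (quadratic
    cost in the block size).
    """
    series = raw if isinstance(raw, NormalizedSeries) else normalize_series(raw)
    N = series.N
    if N > _LENGTH_GUARD:
        warnings.warn(
            f"reference estimator on N={N} > {_LENGTH_GUARD}: expect a "
            "long run time", RuntimeWarning, stacklevel=2)
    q_grid = default_q_grid() if q_grid is None else \
        np.asarray(q_grid, dtype=float).ravel()
    if n_grid is None:
        raise ValueError("reference_fq requires an explicit scale grid")
    n_grid = np.unique(np.asarray(n_grid, dtype=np.int64).ravel())
    y = cumulative_profile(series).y
    F = np.full((q_grid.size, n_grid.size), np.nan)
    retained = np.zeros(F.shape, dtype=np.int64)
    for jn, n in enumerate(n_grid):
        n = int(n)
        if n < order + 2:
            continue
        scheme = block_scheme(N, n, _resolve_overlap(overlap, n))
        var = reference_variances(y, scheme.starts, n, order)
        for jq, q in enumerate(q_grid):
            F[jq, jn], retained[jq, jn] = _fq_direct(var, float(q), eps)
    return FluctuationSurface(order=order, q_grid=q_grid, n_grid=n_grid,
                              F=F, retained=retained, sigma=series.sigma)


def relative_error(F_fast, F_ref) -> tuple[np.ndarray, float]:
    """Per-cell relative deviation |F_fast - F_ref| / F_ref and its max.

    Accepts :class:`FluctuationSurface` pairs (grids must match) or plain
    arrays.  Cells where the reference is zero or non-finite are excluded
    (NaN) with a warning when zeros occur; the scalar is the max over the
    remaining cells (NaN if none).
    """
    if isinstance(F_fast, FluctuationSurface):
        if not (np.array_equal(F_fast.n_grid, F_ref.n_grid)
                and np.allclose(F_fast.q_grid, F_ref.q_grid)):
            raise ValueError("surfaces are on different grids")
        a, b = F_fast.F, F_ref.F
    else:
        a = np.asarray(F_fast, dtype=float)
        b = np.asarray(F_ref, dtype=float)
        if a.shape != b.shape:
            raise ValueError("arrays have different shapes")
    zero = b == 0.0
    if np.any(zero & np.isfinite(a)):
        warnings.warn("reference cells equal to 0 excluded from the "
                      "relative error", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.abs(a - b) / b
    err = np.where(zero | ~np.isfinite(b) | ~np.isfinite(a), np.nan, err)
    finite = np.isfinite(err)
    worst = float(err[finite].max()) if finite.any() else float("nan")
    return err, worst
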