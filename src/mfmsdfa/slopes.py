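"""Local scaling exponents alpha(q, n) from fluctuation surfaces.

The scaling exponent surface is the first derivative of log F_q(n) with
respect to log n.  Because the computed scale grid is only approximately
log-uniform (integer block sizes), log F_q is first interpolated by a
natural cubic spline in log-log coordinates and resampled on an exactly
log-equispaced grid n_h; the derivative is then taken with a five-point
central finite-difference stencil in the interior and three-point one-sided
stencils at the edges.  All stencils are exact for straight lines, so a
pure power law F = c * n^alpha returns alpha at every point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .core import FluctuationSurface

__all__ = [
    "AlphaSurface",
    "log_scale_grid",
    "resample_log_spline",
    "local_slopes",
    "alpha_surface",
]

DEFAULT_H_PER_DECADE = 25
_MIN_SPLINE_POINTS = 4
_MIN_H = 5


@dataclass
class AlphaSurface:
    """Local scaling exponents alpha(q, n_h) on a log-equispaced scale grid.

    ``order`` is 1, 2, or ``"weighted"`` for the DFA1/DFA2 combination.
    ``logF`` keeps the resampled log10 F_q(n_h) the slopes were taken from.
    Cells without sufficient support (EPS-emptied fluctuation cells, or
    scales outside a q-row's finite range) are NaN.
    """

    order: int | str
    q_grid: np.ndarray
    n_h: np.ndarray
    alpha: np.ndarray  # shape (len(q_grid), len(n_h))
    logF: np.ndarray | None = None

    @property
    def H(self) -> int:
        return self.n_h.size

    def to_frame(self, tau: np.ndarray | None = None):
        """Long-format table {order, q, n, tau, alpha}."""
        import pandas as pd

        qq, nn = np.meshgrid(self.q_grid, self.n_h, indexing="ij")
        tt = np.broadcast_to(
            self.n_h if tau is None else np.asarray(tau, dtype=float),
            nn.shape)
        return pd.DataFrame({
            "order": str(self.order),
            "q": qq.ravel(),
            "n": nn.ravel(),
            "tau": tt.ravel().astype(float),
            "alpha": self.alpha.ravel(),
        })


def log_scale_grid(n_min: float, n_max: float,
                   h_per_decade: int = DEFAULT_H_PER_DECADE) -> np.ndarray:
    """Exactly log-equispaced real scales covering [n_min, n_max]."""
    if not 0 < n_min < n_max:
        raise ValueError(f"need 0 < n_min < n_max, got [{n_min}, {n_max}]")
    decades = np.log10(n_max / n_min)
    H = max(_MIN_H, int(round(decades * h_per_decade)) + 1)
    return np.logspace(np.log10(n_min), np.log10(n_max), H)


def resample_log_spline(n: np.ndarray, F: np.ndarray,
                        H: int) -> tuple[np.ndarray, np.ndarray]:
    """Resample one F(n) curve onto H log-equispaced scales by spline.

    Fits a natural interpolating cubic spline to log10 F vs log10 n over
    the finite samples and evaluates it at H points equispaced in log10 n
    spanning [min n, max n] of the finite support.  Returns ``(n_h, F_h)``.

    Raises
    ------
    ValueError
        If fewer than 4 finite, positive samples are available.
    """
    n = np.asarray(n, dtype=float).ravel()
    F = np.asarray(F, dtype=float).ravel()
    good = np.isfinite(F) & (F > 0) & np.isfinite(n) & (n > 0)
    if good.sum() < _MIN_SPLINE_POINTS:
        raise ValueError(
            f"only {int(good.sum())} usable points; spline needs "
            f">= {_MIN_SPLINE_POINTS}")
    logn = np.log10(n[good])
    logF = np.log10(F[good])
    order = np.argsort(logn)
    spline = CubicSpline(logn[order], logF[order], bc_type="natural")
    log_nh = np.linspace(logn.min(), logn.max(), H)
    return 10.0 ** log_nh, 10.0 ** spline(log_nh)


def local_slopes(logF: np.ndarray, log_n: np.ndarray) -> np.ndarray:
    """First derivative of logF with respect to log_n on an equispaced grid.

    Interior points (2 < h < H-1, 1-based) use the five-point stencil
    (-f[h+2] + 8 f[h+1] - 8 f[h-1] + f[h-2]) / (12 d); the first and last
    points use the one-sided three-point stencil and their neighbours the
    central two-point difference.  NaNs in logF propagate to the slopes
    that reference them.
    """
    logF = np.asarray(logF, dtype=float).ravel()
    log_n = np.asarray(log_n, dtype=float).ravel()
    H = logF.size
    if H < _MIN_H:
        raise ValueError(f"need at least {_MIN_H} points, got {H}")
    if log_n.size != H:
        raise ValueError("logF and log_n must have equal length")
    steps = np.diff(log_n)
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
        raise ValueError("log_n must be equispaced")
    alpha = np.full(H, np.nan)
    alpha[2:-2] = (8.0 * (logF[3:-1] - logF[1:-3])
                   - (logF[4:] - logF[:-4])) \
        / (3.0 * (log_n[4:] - log_n[:-4]))
    alpha[0] = (-logF[2] + 4.0 * logF[1] - 3.0 * logF[0]) \
        / (log_n[2] - log_n[0])
    alpha[1] = (logF[2] - logF[0]) / (log_n[2] - log_n[0])
    alpha[-2] = (logF[-1] - logF[-3]) / (log_n[-1] - log_n[-3])
    alpha[-1] = (logF[-3] - 4.0 * logF[-2] + 3.0 * logF[-1]) \
        / (log_n[-1] - log_n[-3])
    return alpha


def alpha_surface(surface: FluctuationSurface,
                  h_per_decade: int = DEFAULT_H_PER_DECADE,
                  n_h: np.ndarray | None = None) -> AlphaSurface:
    """Local-slope surface alpha(q, n_h) of one fluctuation surface.

    Every q-row is spline-resampled over its own finite support onto the
    common log-equispaced grid ``n_h`` (default: spanning the full scale
    grid at ``h_per_decade`` points per decade); scales outside a row's
    support stay NaN, as do rows with fewer than 4 finite cells.
    """
    if n_h is None:
        n_h = log_scale_grid(float(surface.n_grid[0]),
                             float(surface.n_grid[-1]), h_per_decade)
    else:
        n_h = np.asarray(n_h, dtype=float).ravel()
    log_nh = np.log10(n_h)
    logn = np.log10(surface.n_grid.astype(float))
    H = n_h.size
    nq = surface.q_grid.size
    logF_h = np.full((nq, H), np.nan)
    alpha = np.full((nq, H), np.nan)
    for jq in range(nq):
        row = surface.F[jq]
        good = np.isfinite(row) & (row > 0)
        if good.sum() < _MIN_SPLINE_POINTS:
            continue
        spline = CubicSpline(logn[good], np.log10(row[good]),
                             bc_type="natural", extrapolate=False)
        logF_h[jq] = spline(log_nh)
        alpha[jq] = local_slopes(logF_h[jq], log_nh)
    return AlphaSurface(order=surface.order, q_grid=surface.q_grid.copy(),
                        n_h=n_h, alpha=alpha, logF=logF_h)
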