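"""Weighted combination of DFA1 and DFA2 scaling-exponent surfaces.

For series in the fractional-Gaussian-noise / fractional-Brownian-motion
family, first-order detrending is less biased at short scales (second-order
polynomials overfit the smallest blocks) while at large scales the better
order depends on the sign of the moment q: DFA2 is more stable for q < 0,
DFA1 for q > 0, and at q = 0 their average improves on either.  The
combined estimate is a pointwise weighted mean

    alpha_w(q, n) = (1 - w2(q, n)) * alpha1(q, n) + w2(q, n) * alpha2(q, n)

whose DFA2 weight w2 is zero below scale 12, ramps linearly in n between
scales 12 and 24, and varies linearly in q so that at large scales w2 = 1
at q = -5, 1/2 at q = 0 and 0 at q = +5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .slopes import AlphaSurface

__all__ = ["combination_weight", "combine_surfaces"]

_N_LOW = 12.0
_N_HIGH = 24.0
_Q_MIN, _Q_MAX = -5.0, 5.0


def combination_weight(q, n):
    """DFA2 weight w2(q, n) in [0, 1]; the DFA1 weight is 1 - w2.

    Accepts scalars or arrays (broadcast).  q outside the calibrated range
    [-5, 5] is clamped with a warning.
    """
    q = np.asarray(q, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(q < _Q_MIN) or np.any(q > _Q_MAX):
        warnings.warn(
            "q outside the calibrated range [-5, 5]; weight clamped",
            RuntimeWarning, stacklevel=2)
        q = np.clip(q, _Q_MIN, _Q_MAX)
    qfac = (_Q_MAX - q) / (_Q_MAX - _Q_MIN)  # 1 at q=-5 ... 0 at q=+5
    ramp = np.clip((n - _N_LOW) / (_N_HIGH - _N_LOW), 0.0, 1.0)
    w2 = ramp * qfac
    return float(w2) if w2.ndim == 0 else w2


def combine_surfaces(alpha1: AlphaSurface,
                     alpha2: AlphaSurface) -> AlphaSurface:
    """Pointwise weighted average of DFA1 and DFA2 alpha surfaces.

    Both surfaces must share identical (q, n_h) grids; the grid is
    preserved in the result, whose ``order`` is ``"weighted"``.
    """
    if alpha1.q_grid.shape != alpha2.q_grid.shape or \
            not np.allclose(alpha1.q_grid, alpha2.q_grid):
        raise ValueError("q grids differ between the two surfaces")
    if alpha1.n_h.shape != alpha2.n_h.shape or \
            not np.allclose(alpha1.n_h, alpha2.n_h):
        raise ValueError("scale grids differ between the two surfaces")
    w2 = combination_weight(alpha1.q_grid[:, None], alpha1.n_h[None, :])
    # a zero-weight surface must not poison the average with its NaNs
    with np.errstate(invalid="ignore"):
        blend = (1.0 - w2) * alpha1.alpha + w2 * alpha2.alpha
    combined = np.where(w2 == 0.0, alpha1.alpha,
                        np.where(w2 == 1.0, alpha2.alpha, blend))
    return AlphaSurface(order="weighted", q_grid=alpha1.q_grid.copy(),
                        n_h=alpha1.n_h.copy(), alpha=combined)
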