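"""Fourier-phase-shuffled surrogates and nonlinearity significance maps.

A phase-shuffled surrogate shares the original series' discrete-Fourier
amplitude spectrum (hence its full linear autocorrelation structure) but
has independent uniformly random phases: any multifractal structure that
survives in the surrogates is attributable to the linear spectrum alone.
Comparing the original alpha(q, n) surface against an ensemble of surrogate
surfaces cell by cell yields a two-sided empirical-percentile significance
map; cells with p below a display threshold (0.01 by convention) mark
scales and moment orders where the observed scaling cannot be explained by
a linear Gaussian process with the same spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core, slopes, combination
from .slopes import AlphaSurface

__all__ = [
    "phase_shuffle",
    "surrogate_seeds",
    "significance_map",
    "surrogate_test",
    "SurrogateTest",
]

DEFAULT_N_SURROGATES = 100
MIN_SURROGATES = 20
DISPLAY_P = 0.01


def phase_shuffle(series, seed=None, rng: np.random.Generator | None = None
                  ) -> np.ndarray:
    """One Fourier-phase-shuffled surrogate of ``series``.

    The rFFT amplitudes are kept exactly; the phases of all strictly
    positive frequencies are drawn i.i.d. uniform on [0, 2*pi).  The DC
    component, and the Nyquist component for even length, are left
    untouched (they must stay real), so the surrogate is real-valued with
    the original mean and periodogram.
    """
    x = np.asarray(series, dtype=float).ravel()
    N = x.size
    if N < core.MIN_SERIES_LENGTH:
        raise ValueError(f"series too short: N={N}")
    if rng is None:
        rng = np.random.default_rng(seed)
    X = np.fft.rfft(x)
    K = X.size
    phases = rng.uniform(0.0, 2.0 * np.pi, K)
    amp = np.abs(X)
    Xs = amp * np.exp(1j * phases)
    Xs[0] = X[0]
    if N % 2 == 0:
        Xs[-1] = X[-1]
    return np.fft.irfft(Xs, n=N)


def surrogate_seeds(master_seed, count: int) -> list[np.random.Generator]:
    """Independent per-surrogate generators spawned from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [np.random.default_rng(child) for child in ss.spawn(count)]


def significance_map(alpha_orig, alpha_surr) -> np.ndarray:
    """Two-sided empirical percentile p of the original among surrogates.

    Per (q, n) cell the mid-rank of the original value within the Ns
    surrogate values gives r = (count_below + 0.5*count_equal + 0.5) /
    (Ns + 1) and p = 2*min(r, 1-r); ties take mid-ranks, and the +0.5 /
    (Ns+1) convention keeps p strictly positive (smallest attainable p is
    about 1/(Ns+1)).  Cells that are NaN in the original or in any
    surrogate are NaN.
    """
    if isinstance(alpha_orig, AlphaSurface):
        _check_grids(alpha_orig, alpha_surr)
        orig = alpha_orig.alpha
        stack = np.stack([s.alpha for s in alpha_surr])
    else:
        orig = np.asarray(alpha_orig, dtype=float)
        stack = np.asarray(alpha_surr, dtype=float)
        if stack.shape[1:] != orig.shape:
            raise ValueError("surrogate stack does not match original grid")
    ns = stack.shape[0]
    if ns < MIN_SURROGATES:
        raise ValueError(f"need >= {MIN_SURROGATES} surrogates, got {ns}")
    below = np.sum(stack < orig, axis=0)
    equal = np.sum(stack == orig, axis=0)
    r = (below + 0.5 * equal + 0.5) / (ns + 1.0)
    p = 2.0 * np.minimum(r, 1.0 - r)
    bad = ~np.isfinite(orig) | np.any(~np.isfinite(stack), axis=0)
    p = np.where(bad, np.nan, p)
    return p


def _check_grids(a: AlphaSurface, ensemble) -> None:
    for s in ensemble:
        if s.alpha.shape != a.alpha.shape or \
                not np.allclose(s.q_grid, a.q_grid) or \
                not np.allclose(s.n_h, a.n_h):
            raise ValueError("surrogate alpha grids do not match original")


@dataclass
class SurrogateTest:
    """Result of a surrogate-data nonlinearity test on alpha(q, n)."""

    p: np.ndarray                     # (q, H) two-sided percentile p-values
    alpha_orig: AlphaSurface
    alpha_surrogate_mean: AlphaSurface
    n_surrogates: int
    threshold: float = DISPLAY_P

    def significant_fraction(self, threshold: float | None = None) -> float:
        """Fraction of testable cells with p below the threshold."""
        th = self.threshold if threshold is None else threshold
        finite = np.isfinite(self.p)
        if not finite.any():
            return float("nan")
        return float(np.mean(self.p[finite] < th))


def surrogate_test(series, n_surrogates: int = DEFAULT_N_SURROGATES,
                   seed=None, order="weighted",
                   q_grid=None, n_grid=None, overlap="max",
                   thresholds=None, eps=None,
                   h_per_decade=slopes.DEFAULT_H_PER_DECADE) -> SurrogateTest:
    """Full nonlinearity test: surrogates analyzed with the same pipeline.

    Every surrogate is passed through exactly the same settings (grids,
    overlap, thresholds, EPS, slope resolution) as the original series.
    ``order`` selects which alpha surface is compared: 1, 2 or
    ``"weighted"`` (DFA1/DFA2 combination).
    """
    x = np.asarray(series, dtype=float).ravel()

    def pipeline(data) -> AlphaSurface:
        orders = (1, 2) if order == "weighted" else (int(order),)
        surf = core.fq_surface(data, q_grid=q_grid, n_grid=n_grid,
                               overlap=overlap, orders=orders,
                               thresholds=thresholds, eps=eps)
        if order == "weighted":
            a1 = slopes.alpha_surface(surf[1], h_per_decade=h_per_decade)
            a2 = slopes.alpha_surface(surf[2], n_h=a1.n_h)
            return combination.combine_surfaces(a1, a2)
        return slopes.alpha_surface(surf[int(order)],
                                    h_per_decade=h_per_decade)

    alpha_orig = pipeline(x)
    ensemble = []
    for rng in surrogate_seeds(seed, n_surrogates):
        surr = pipeline(phase_shuffle(x, rng=rng))
        if surr.alpha.shape != alpha_orig.alpha.shape or \
                not np.allclose(surr.n_h, alpha_orig.n_h):
            raise RuntimeError("surrogate produced a mismatching alpha grid")
        ensemble.append(surr.alpha)
    stack = np.stack(ensemble)
    p = significance_map(alpha_orig.alpha, stack)
    with np.errstate(invalid="ignore"):
        mean_alpha = np.nanmean(stack, axis=0)
    mean_surface = AlphaSurface(order=alpha_orig.order,
                                q_grid=alpha_orig.q_grid.copy(),
                                n_h=alpha_orig.n_h.copy(), alpha=mean_alpha)
    return SurrogateTest(p=p, alpha_orig=alpha_orig,
                         alpha_surrogate_mean=mean_surface,
                         n_surrogates=n_surrogates)
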