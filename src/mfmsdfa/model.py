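"""Model/results interface to the fast multifractal multiscale DFA.

:class:`MultifractalDFA` bundles a series with the analysis settings
(moment grid, scale grid, overlap, detrending orders, precision
thresholds); :meth:`MultifractalDFA.fit` runs the single-pass fluctuation
computation plus the slope pipeline and returns a
:class:`MultifractalDFAResults` carrying the F_q(n) surfaces, the
alpha(q, n) surfaces (per order and weighted), global exponent summaries
and the surrogate nonlinearity test.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from . import combination, core, io, slopes, surrogates
from .core import FluctuationSurface, Thresholds
from .slopes import AlphaSurface

__all__ = ["MultifractalDFA", "MultifractalDFAResults"]


class MultifractalDFA:
    """Multifractal multiscale DFA of one univariate time series.

    Parameters
    ----------
    endog : array-like
        The raw series (e.g. beat-by-beat R-R intervals, EEG samples).
        Normalization to zero mean / unit SD is internal; fluctuation
        values can be rescaled to original units via the stored SD.
    q : array-like, optional
        Moment orders; default integers -5..+5.
    scales : array-like of int, optional
        Block sizes; default exponentially spaced, 8 per decade, from 8 to
        N/4.
    order : {1, 2, "both"}
        Detrending polynomial order(s); "both" (default) computes DFA1 and
        DFA2 in a single pass and enables the weighted combination.
    overlap : {"max", "none", int}
        Block overlap L; "max" (default) uses L = n-1.
    thresholds : Thresholds, optional
        Precision thresholds; default length-dependent values.
    eps : float
        Variance floor below which blocks are discarded from F_q.
    """

    def __init__(self, endog, q=None, scales=None, order="both",
                 overlap="max", thresholds: Thresholds | None = None,
                 eps: float = 0.0,
                 segment_width: int = core.DEFAULT_SEGMENT_WIDTH):
        self.series = np.asarray(endog, dtype=float).ravel()
        self.nobs = self.series.size
        self.q_grid = core.default_q_grid() if q is None else \
            np.asarray(q, dtype=float).ravel()
        self.n_grid = core.default_scale_grid(self.nobs) if scales is None \
            else np.unique(np.asarray(scales, dtype=np.int64).ravel())
        if order == "both":
            self.orders: tuple[int, ...] = (1, 2)
        elif order in (1, 2):
            self.orders = (int(order),)
        else:
            raise ValueError(f"order must be 1, 2 or 'both', got {order!r}")
        self.overlap = overlap
        self.thresholds = thresholds if thresholds is not None else \
            core.default_thresholds(self.nobs, eps=eps)
        if thresholds is not None and eps:
            from dataclasses import replace
            self.thresholds = replace(self.thresholds, eps=float(eps))
        self.segment_width = segment_width

    @classmethod
    def from_file(cls, path, format=None, column=None, **kwargs
                  ) -> "MultifractalDFA":
        """Build a model from a one-column text file or a CSV column."""
        return cls(io.read_series(path, format=format, column=column),
                   **kwargs)

    @classmethod
    def simulate(cls, model: str, N: int, seed=None, **params) -> np.ndarray:
        """Generate a synthetic validation series (see ``synthetic``)."""
        from . import synthetic
        return synthetic.gen_series(model, N, seed=seed, **params)

    def fit(self, h_per_decade: int = slopes.DEFAULT_H_PER_DECADE
            ) -> "MultifractalDFAResults":
        """Compute the fluctuation and local-slope surfaces."""
        surfaces = core.fq_surface(
            self.series, q_grid=self.q_grid, n_grid=self.n_grid,
            overlap=self.overlap, orders=self.orders,
            thresholds=self.thresholds,
            segment_width=self.segment_width)
        alphas: dict = {}
        n_h = None
        for o in self.orders:
            alphas[o] = slopes.alpha_surface(
                surfaces[o], h_per_decade=h_per_decade, n_h=n_h)
            n_h = alphas[o].n_h
        if set(self.orders) == {1, 2}:
            alphas["weighted"] = combination.combine_surfaces(
                alphas[1], alphas[2])
        return MultifractalDFAResults(self, surfaces, alphas, h_per_decade)


class MultifractalDFAResults:
    """Fitted multifractal multiscale DFA surfaces and diagnostics."""

    def __init__(self, model: MultifractalDFA,
                 fluctuations: dict[int, FluctuationSurface],
                 alphas: dict, h_per_decade: int):
        self.model = model
        self.fluctuations = fluctuations
        self._alphas = alphas
        self.h_per_decade = h_per_decade

    # -- access -----------------------------------------------------------
    def fluctuation(self, order: int) -> FluctuationSurface:
        return self.fluctuations[int(order)]

    def alpha(self, order: int | str = "weighted") -> AlphaSurface:
        """Alpha surface for one order, or the DFA1/DFA2 combination."""
        key = order if order == "weighted" else int(order)
        if key not in self._alphas:
            raise KeyError(
                f"alpha surface {order!r} not available; fitted orders: "
                f"{sorted(self._alphas, key=str)}")
        return self._alphas[key]

    # -- diagnostics ------------------------------------------------------
    def global_exponent(self, q: float = 2.0, order: int | None = None,
                        n_range: tuple[float, float] | None = None) -> float:
        """Single scaling exponent: LS slope of log F_q vs log n.

        This is the classical one-number DFA summary, fitted over
        ``n_range`` (default: the full scale grid) at moment order ``q``.
        """
        order = order if order is not None else self.model.orders[0]
        surf = self.fluctuations[int(order)]
        jq = int(np.argmin(np.abs(surf.q_grid - q)))
        F = surf.F[jq]
        n = surf.n_grid.astype(float)
        good = np.isfinite(F) & (F > 0)
        if n_range is not None:
            good &= (n >= n_range[0]) & (n <= n_range[1])
        if good.sum() < 2:
            return float("nan")
        coef = np.polyfit(np.log10(n[good]), np.log10(F[good]), 1)
        return float(coef[0])

    def mean_alpha(self, q: float = 0.0, order: int | str = "weighted",
                   n_range: tuple[float, float] | None = None) -> float:
        """Mean local slope alpha(q, n) over a scale range."""
        a = self.alpha(order)
        jq = int(np.argmin(np.abs(a.q_grid - q)))
        row = a.alpha[jq]
        keep = np.isfinite(row)
        if n_range is not None:
            keep &= (a.n_h >= n_range[0]) & (a.n_h <= n_range[1])
        if not keep.any():
            return float("nan")
        return float(row[keep].mean())

    def surrogate_test(self, n_surrogates: int = 100, seed=None,
                       order: int | str = "weighted"
                       ) -> surrogates.SurrogateTest:
        """Phase-shuffled surrogate nonlinearity test with this model's
        settings applied identically to every surrogate."""
        m = self.model
        return surrogates.surrogate_test(
            m.series, n_surrogates=n_surrogates, seed=seed, order=order,
            q_grid=m.q_grid, n_grid=m.n_grid, overlap=m.overlap,
            thresholds=m.thresholds, h_per_decade=self.h_per_decade)

    # -- presentation -----------------------------------------------------
    def to_frame(self):
        """All fluctuation surfaces as one long-format DataFrame."""
        import pandas as pd
        return pd.concat([s.to_frame() for s in self.fluctuations.values()],
                         ignore_index=True)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Multifractal multiscale DFA",
            "=" * 46,
            f"Observations:        {m.nobs}",
            f"Detrending orders:   {', '.join(map(str, m.orders))}",
            f"Overlap:             {m.overlap}",
            f"q grid:              {m.q_grid[0]:g} .. {m.q_grid[-1]:g} "
            f"({m.q_grid.size} values)",
            f"Scales:              {m.n_grid[0]} .. {m.n_grid[-1]} "
            f"({m.n_grid.size} block sizes)",
            f"Thresholds:          Th1={m.thresholds.th1:g}  "
            f"Th2={m.thresholds.th2:g}  EPS={m.thresholds.eps:g}",
            "-" * 46,
            "Global scaling exponents (log-log LS slope):",
        ]
        for o in m.orders:
            for q in (-5.0, 0.0, 2.0, 5.0):
                if np.any(np.isclose(m.q_grid, q)):
                    lines.append(
                        f"  DFA{o}  q={q:+.0f}:  "
                        f"alpha = {self.global_exponent(q, order=o):.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_alpha(self, order: int | str = "weighted", ax=None, **kwargs):
        """Contour plot of the alpha(q, n) surface (requires matplotlib)."""
        import matplotlib.pyplot as plt

        a = self.alpha(order)
        if ax is None:
            _, ax = plt.subplots()
        mesh = ax.pcolormesh(a.n_h, a.q_grid, a.alpha, shading="nearest",
                             **kwargs)
        ax.set_xscale("log")
        ax.set_xlabel("scale n")
        ax.set_ylabel("moment order q")
        ax.figure.colorbar(mesh, ax=ax, label=r"$\alpha(q,n)$")
        return ax
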