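"""Fast q-order fluctuation functions for detrended fluctuation analysis.

Computes the multifractal fluctuation function F_q(n) of a univariate time
series for first- and second-order detrending polynomials (DFA1 / DFA2)
simultaneously, at any block overlap including maximal overlap (consecutive
blocks share n-1 samples).  The per-scale cost is O(N) rather than the
O(N*n) of per-block summation: block moments of the cumulative profile are
read off segmented prefix-sum arrays in O(1), the least-squares detrending
coefficients and residual variances follow from closed-form normal
equations, and the sums of integer powers in the design matrix come from
exact Faulhaber polynomials.

Two numerical safeguards control floating-point cancellation:

* prefix sums are accumulated in short segments (default 128 samples) and
  recombined from per-segment totals, so small terms are never added to a
  huge running sum;
* a residual variance falling below a length-dependent threshold (where
  cancellation error could dominate) is recomputed directly over the block's
  n samples.

All quantities are computed on the series normalized to zero mean and unit
standard deviation; multiply F_q(n) by the stored ``sigma`` to recover
original units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NormalizedSeries",
    "Profile",
    "BlockScheme",
    "Thresholds",
    "BlockMoments",
    "FluctuationSurface",
    "MomentPrefixStore",
    "normalize_series",
    "cumulative_profile",
    "block_scheme",
    "power_sum",
    "range_power_sum",
    "build_prefix_store",
    "block_moment",
    "local_block_moments",
    "fit_block_poly",
    "residual_variance_fast",
    "default_thresholds",
    "fluctuation_function",
    "default_scale_grid",
    "default_q_grid",
    "fq_surface",
]

logger = logging.getLogger(__name__)

MIN_SERIES_LENGTH = 16
DEFAULT_SEGMENT_WIDTH = 128
#: (V, W) exponent pairs of the profile moments sum(i^V * y_i^W) needed by
#: the order-1/order-2 normal equations and residual-variance identities.
MOMENT_PAIRS = ((0, 1), (1, 1), (2, 1), (0, 2))
# Direct per-block recompute is chunked to bound temporary memory.
_CHUNK_ELEMENTS = 4_000_000


# ---------------------------------------------------------------------------
# normalization and profile

@dataclass(frozen=True)
class NormalizedSeries:
    """Zero-mean, unit-SD series with the original mean/SD retained."""

    values: np.ndarray
    mu: float
    sigma: float

    @property
    def N(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class Profile:
    """Cumulative sum of a normalized series (the object being detrended)."""

    y: np.ndarray

    @property
    def N(self) -> int:
        return self.y.size


def normalize_series(raw: Sequence[float] | np.ndarray) -> NormalizedSeries:
    """Remove the mean and scale to unit (population) standard deviation.

    Raises
    ------
    ValueError
        If the series is shorter than 16 samples, contains non-finite
        values, or is constant (zero standard deviation).
    """
    x = np.asarray(raw, dtype=float).ravel()
    if x.size < MIN_SERIES_LENGTH:
        raise ValueError(
            f"series too short: N={x.size} < {MIN_SERIES_LENGTH}"
        )
    if not np.all(np.isfinite(x)):
        bad = int(np.count_nonzero(~np.isfinite(x)))
        raise ValueError(f"series contains {bad} non-finite samples")
    mu = float(x.mean())
    sigma = float(x.std())  # population SD: threshold scale is reproducible
    if sigma <= 0.0 or np.ptp(x) == 0.0:
        raise ValueError("constant series: standard deviation is zero")
    return NormalizedSeries((x - mu) / sigma, mu, sigma)


def cumulative_profile(series: NormalizedSeries) -> Profile:
    """Cumulative sum y_i = sum_{j<=i} s_j of the normalized series."""
    return Profile(np.cumsum(series.values))


# ---------------------------------------------------------------------------
# block scheme

@dataclass(frozen=True)
class BlockScheme:
    """Partition of N samples into M blocks of size n overlapping by L.

    ``starts`` holds the 1-based first index of each block,
    I_k = (n-L)(k-1)+1.  When N-n is not a multiple of n-L, the trailing
    ``excluded_tail`` samples take part in no block.  Maximal overlap
    (L = n-1) gives M = N-n+1 and an empty tail.
    """

    N: int
    n: int
    L: int
    M: int
    starts: np.ndarray  # int64, 1-based
    excluded_tail: int


def block_scheme(N: int, n: int, L: int) -> BlockScheme:
    if not 4 <= n <= N:
        raise ValueError(f"block size n={n} must satisfy 4 <= n <= N={N}")
    if not 0 <= L < n:
        raise ValueError(f"overlap L={L} must satisfy 0 <= L < n={n}")
    step = n - L
    M = (N - n) // step + 1
    starts = 1 + step * np.arange(M, dtype=np.int64)
    tail = N - (M - 1) * step - n
    return BlockScheme(N=N, n=n, L=L, M=M, starts=starts, excluded_tail=tail)


# ---------------------------------------------------------------------------
# exact power sums (Faulhaber closed forms)

def power_sum(V: int, n: int) -> int:
    """Exact sum_{i=1..n} i^V for V in 1..4, in integer arithmetic.

    The closed forms are the Faulhaber polynomials; every product below is
    divisible exactly, so the result is an exact Python integer for any n.
    """
    if V not in (1, 2, 3, 4):
        raise ValueError(f"power V={V} outside supported range 1..4")
    if n < 1:
        raise ValueError(f"n={n} must be >= 1")
    n = int(n)
    if V == 1:
        return n * (n + 1) // 2
    if V == 2:
        return n * (n + 1) * (2 * n + 1) // 6
    if V == 3:
        return (n * (n + 1) // 2) ** 2
    return n * (n + 1) * (2 * n + 1) * (3 * n * n + 3 * n - 1) // 30


def range_power_sum(V: int, start: int, n: int) -> int:
    """Exact sum_{i=start..start+n-1} i^V via differences of power sums."""
    if start < 1:
        raise ValueError(f"start={start} must be >= 1")
    hi = power_sum(V, start + n - 1)
    lo = power_sum(V, start - 1) if start > 1 else 0
    return hi - lo


# ---------------------------------------------------------------------------
# segmented prefix sums of profile moments

class MomentPrefixStore:
    """Segmented prefix sums of i^V * y_i^W enabling O(1) block moments.

    For each exponent pair (V, W) the running sum A_{V,W}(i) is not kept as
    one long accumulation; the terms are cut into segments of
    ``segment_width`` samples (conceptually a matrix of segment-position
    rows by Q = floor((N-1)/width)+1 segment columns).  A_{V,W}(i) is then
    the within-segment running sum at i plus the sum of the closing totals
    of all earlier segments, so no small term is ever added to a long-run
    accumulation.
    """

    def __init__(self, profile: Profile,
                 segment_width: int = DEFAULT_SEGMENT_WIDTH):
        if segment_width < 1:
            raise ValueError("segment_width must be >= 1")
        y = profile.y
        N = y.size
        self.N = N
        self.segment_width = int(segment_width)
        self.Q = (N - 1) // self.segment_width + 1
        self._segcum: dict[tuple[int, int], np.ndarray] = {}
        self._coltot: dict[tuple[int, int], np.ndarray] = {}
        i = np.arange(1, N + 1, dtype=float)
        w = self.segment_width
        padded_len = self.Q * w
        for V, W in MOMENT_PAIRS:
            terms = y if (V, W) == (0, 1) else (i ** V if V else 1.0) * (y ** W)
            t = np.zeros(padded_len)
            t[:N] = terms
            t = t.reshape(self.Q, w)
            seg = np.cumsum(t, axis=1)
            totals = seg[:, -1]
            # coltot[c] = sum of closing totals of segments 0..c-1,
            # accumulated in extended precision so that differences of
            # column totals between two block endpoints do not carry the
            # rounding of the full-series running sum
            coltot = np.concatenate(
                ([0.0], np.cumsum(totals, dtype=np.longdouble)))
            self._segcum[(V, W)] = seg.reshape(-1)[:N]
            self._coltot[(V, W)] = coltot

    def prefix(self, V: int, W: int,
               idx: int | np.ndarray) -> float | np.ndarray:
        """Reconstructed running sum A_{V,W}(idx), with A(0) = 0."""
        if (V, W) not in self._segcum:
            raise KeyError(f"moment pair (V={V}, W={W}) not stored")
        idx = np.asarray(idx, dtype=np.int64)
        if np.any(idx < 0) or np.any(idx > self.N):
            raise IndexError("prefix index outside 0..N")
        seg = self._segcum[(V, W)]
        col = self._coltot[(V, W)]
        safe = np.maximum(idx, 1)
        out = seg[safe - 1] + np.asarray(
            col[(safe - 1) // self.segment_width], dtype=float)
        out = np.where(idx == 0, 0.0, out)
        return float(out) if out.ndim == 0 else out

    def block_sum(self, V: int, W: int, start: int | np.ndarray,
                  n: int) -> float | np.ndarray:
        """sum_{i=start..start+n-1} i^V y_i^W via prefix differences.

        The difference A(hi) - A(lo) is regrouped as (within-segment
        difference) + (difference of accumulated column totals): segments
        common to both endpoints then cancel exactly, so the error scales
        with the segment-local magnitudes rather than with the ulp of the
        full-series running sum.
        """
        start = np.asarray(start, dtype=np.int64)
        scalar = start.ndim == 0
        start = np.atleast_1d(start)
        hi = start + n - 1
        if np.any(start < 1) or np.any(hi > self.N):
            raise IndexError("block outside series range")
        seg = self._segcum[(V, W)]
        col = self._coltot[(V, W)]
        w = self.segment_width
        lo = start - 1
        lo_safe = np.maximum(lo, 1)
        seg_lo = np.where(lo == 0, 0.0, seg[lo_safe - 1])
        cl = np.where(lo == 0, 0, (lo_safe - 1) // w)
        ch = (hi - 1) // w
        between = np.asarray(col[ch] - col[cl], dtype=float)
        out = (seg[hi - 1] - seg_lo) + between
        return float(out[0]) if scalar else out


def build_prefix_store(profile: Profile,
                       segment_width: int = DEFAULT_SEGMENT_WIDTH,
                       ) -> MomentPrefixStore:
    return MomentPrefixStore(profile, segment_width=segment_width)


def block_moment(store: MomentPrefixStore, V: int, W: int,
                 start: int, n: int) -> float:
    """Moment sum of one block; thin validated wrapper over the store."""
    if (V, W) not in MOMENT_PAIRS:
        raise KeyError(f"moment pair (V={V}, W={W}) not stored")
    return float(store.block_sum(V, W, int(start), int(n)))


# ---------------------------------------------------------------------------
# thresholds

@dataclass(frozen=True)
class Thresholds:
    """Precision thresholds triggering direct recomputation, plus EPS.

    ``th1``/``th2`` are compared against the analytic residual variance of
    order-1/order-2 fits: below them, cancellation error may be of the same
    order as the value, and the variance is recomputed directly from the
    block samples.  ``eps`` discards near-zero variances from F_q (guard
    against overfitted small blocks or quantization floors); default 0.
    """

    th1: float
    th2: float
    eps: float = 0.0

    def for_order(self, order: int) -> float:
        return self.th1 if order == 1 else self.th2


def default_thresholds(N: int, eps: float = 0.0) -> Thresholds:
    """Length-dependent defaults for the precision thresholds."""
    if N < MIN_SERIES_LENGTH:
        raise ValueError(f"N={N} < {MIN_SERIES_LENGTH}")
    th1 = 1e-3 if N <= 10 ** 5 else N / 10 ** 8
    th2 = 1e-2 if N <= 10 ** 2 else N / 10 ** 4
    return Thresholds(th1=th1, th2=th2, eps=eps)


# ---------------------------------------------------------------------------
# block moments in local index, detrending fits, residual variances

@dataclass
class BlockMoments:
    """Per-block data moments in the local index j = 1..n.

    s0 = sum y, s1 = sum j*y, s2 = sum j^2*y, sy2 = sum y^2, one entry per
    block.  Local moments come from the global prefix sums through the
    exact shift identities
        sum j*y   = sum i*y   - (I_k-1) sum y
        sum j^2*y = sum i^2*y - 2(I_k-1) sum i*y + (I_k-1)^2 sum y
    which avoid forming huge powers of the global index inside the normal
    equations.
    """

    n: int
    starts: np.ndarray
    s0: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    sy2: np.ndarray


def local_block_moments(store: MomentPrefixStore,
                        scheme: BlockScheme) -> BlockMoments:
    I = scheme.starts
    n = scheme.n
    shift = (I - 1).astype(float)
    s0 = store.block_sum(0, 1, I, n)
    g1 = store.block_sum(1, 1, I, n)
    g2 = store.block_sum(2, 1, I, n)
    sy2 = store.block_sum(0, 2, I, n)
    s1 = g1 - shift * s0
    s2 = g2 - 2.0 * shift * g1 + shift ** 2 * s0
    return BlockMoments(n=n, starts=I, s0=np.atleast_1d(s0),
                        s1=np.atleast_1d(s1), s2=np.atleast_1d(s2),
                        sy2=np.atleast_1d(sy2))


def _design_constants(n: int) -> dict[str, float]:
    """Scale-only parts of the normal equations (exact power sums of 1..n)."""
    p1 = float(power_sum(1, n))
    p2 = float(power_sum(2, n))
    p3 = float(power_sum(3, n))
    p4 = float(power_sum(4, n))
    ibar = p1 / n
    i2bar = p2 / n
    return {
        "p1": p1, "p2": p2, "p3": p3, "p4": p4,
        "ibar": ibar, "i2bar": i2bar,
        "sii": p2 / n - ibar * ibar,
        "sii2": p3 / n - ibar * i2bar,
        "si2i2": p4 / n - i2bar * i2bar,
    }


def _coeffs_from_moments(order: int, n: int, s0, s1, s2):
    """Closed-form least-squares coefficients from local block moments."""
    d = _design_constants(n)
    ybar = s0 / n
    siy = s1 / n - d["ibar"] * ybar
    if order == 1:
        b1 = siy / d["sii"]
        a1 = ybar - b1 * d["ibar"]
        return (a1, b1)
    si2y = s2 / n - d["i2bar"] * ybar
    den = d["sii"] * d["si2i2"] - d["sii2"] ** 2
    c2 = (si2y * d["sii"] - siy * d["sii2"]) / den
    b2 = (siy * d["si2i2"] - si2y * d["sii2"]) / den
    a2 = ybar - b2 * d["ibar"] - c2 * d["i2bar"]
    return (a2, b2, c2)


def fit_block_poly(moments: BlockMoments, order: int):
    """Least-squares detrending coefficients for every block at once.

    Returns ``(a1, b1)`` arrays for order 1 (fit y = b1*j + a1) or
    ``(a2, b2, c2)`` for order 2 (fit y = c2*j^2 + b2*j + a2), in the local
    block index j = 1..n.
    """
    if order not in (1, 2):
        raise ValueError(f"detrending order must be 1 or 2, got {order}")
    if moments.n < order + 2:
        raise ValueError(
            f"block size n={moments.n} too small for order-{order} fit"
        )
    return _coeffs_from_moments(order, moments.n,
                                moments.s0, moments.s1, moments.s2)


def _direct_block_variances(y: np.ndarray, starts: np.ndarray, n: int,
                            order: int) -> np.ndarray:
    """Residual variances by direct per-block summation (chunked).

    Refits the detrending polynomial from directly summed local moments and
    averages the squared residuals over the block; used when the analytic
    fast value falls below the precision threshold.
    """
    j = np.arange(1, n + 1, dtype=float)
    j2 = j * j
    out = np.empty(starts.size)
    chunk = max(1, _CHUNK_ELEMENTS // n)
    for lo in range(0, starts.size, chunk):
        st = starts[lo:lo + chunk]
        idx = (st - 1)[:, None] + np.arange(n)
        blk = y[idx]
        s0 = blk.sum(axis=1)
        s1 = blk @ j
        if order == 1:
            a, b = _coeffs_from_moments(1, n, s0, s1, None)
            res = blk - (a[:, None] + b[:, None] * j)
        else:
            s2 = blk @ j2
            a, b, c = _coeffs_from_moments(2, n, s0, s1, s2)
            res = blk - (a[:, None] + b[:, None] * j + c[:, None] * j2)
        out[lo:lo + chunk] = np.mean(res * res, axis=1)
    return out


def residual_variance_fast(coeffs, moments: BlockMoments, order: int,
                           thresholds: Thresholds,
                           profile: Profile) -> np.ndarray:
    """Residual variances sigma^2_n(k) of all blocks, with safeguards.

    The analytic value expands the squared residual into moment sums (no
    second pass over the samples).  Values below the order's precision
    threshold are recomputed directly from the block samples; residual
    negative values beyond -1e-9 are flagged, and all negatives clipped
    to zero.
    """
    n = moments.n
    d = _design_constants(n)
    # The squared-residual expansion is assembled from centered moments:
    # sigma^2 = S_yy - b*S_iy (- c*S_i2y), algebraically identical to
    # expanding around the raw coefficients but without the a^2-sized
    # cancellation, which for large-magnitude profiles (e.g. integrated
    # Brownian motion) would otherwise swamp small variances with rounding
    # noise bigger than the recompute threshold.
    ybar = moments.s0 / n
    syy = moments.sy2 / n - ybar * ybar
    siy = moments.s1 / n - d["ibar"] * ybar
    if order == 1:
        _, b1 = coeffs
        var = syy - b1 * siy
    else:
        _, b2, c2 = coeffs
        si2y = moments.s2 / n - d["i2bar"] * ybar
        var = syy - b2 * siy - c2 * si2y
    var = np.atleast_1d(np.asarray(var, dtype=float))
    th = thresholds.for_order(order)
    flagged = var < th
    if np.any(flagged):
        var = var.copy()
        var[flagged] = _direct_block_variances(
            profile.y, moments.starts[flagged], n, order)
    worst = float(var.min()) if var.size else 0.0
    if worst < -1e-9:
        warnings.warn(
            f"negative residual variance {worst:.3e} after direct "
            f"recompute (order {order}, n={n}); clipped to 0",
            RuntimeWarning, stacklevel=2)
    np.maximum(var, 0.0, out=var)
    return var


# ---------------------------------------------------------------------------
# fluctuation function and surface

def fluctuation_function(variances: np.ndarray, q: float,
                         eps: float = 0.0) -> tuple[float, int]:
    """q-order fluctuation F from the block residual variances at one scale.

    q != 0 gives the generalized power mean (mean of sigma^(q) raised to
    1/q, i.e. (mean (sigma^2)^(q/2))^(1/q)); q = 0 the log-mean limit
    exp(mean(ln sigma^2)/2).  Variances below ``eps`` are discarded, as are
    zero variances whenever q <= 0 (the formula is undefined there); the
    mean is over the retained count, returned alongside F.  With no block
    retained, F is NaN.
    """
    v = np.asarray(variances, dtype=float).ravel()
    keep = v >= eps
    if q <= 0:
        keep &= v > 0.0
    v = v[keep]
    m = v.size
    if m == 0:
        return float("nan"), 0
    if q == 0:
        return float(np.exp(0.5 * np.mean(np.log(v)))), m
    if q > 0:
        return float(np.mean(v ** (q / 2.0)) ** (1.0 / q)), m
    # negative q: evaluate in the log domain to dodge overflow from tiny
    # variances raised to large negative powers
    logterms = (q / 2.0) * np.log(v)
    peak = logterms.max()
    logmean = peak + np.log(np.mean(np.exp(logterms - peak)))
    return float(np.exp(logmean / q)), m


@dataclass
class FluctuationSurface:
    """F_q(n) on a q-grid x scale-grid for one detrending order.

    ``F`` is in normalized-series units; multiply by ``sigma`` for the
    original units.  ``retained`` counts the blocks surviving the EPS /
    zero-variance exclusion per cell; cells with no retained block hold
    NaN.
    """

    order: int
    q_grid: np.ndarray
    n_grid: np.ndarray
    F: np.ndarray          # shape (len(q_grid), len(n_grid))
    retained: np.ndarray   # same shape, int
    sigma: float = 1.0

    def to_frame(self, tau: np.ndarray | None = None):
        """Long-format table {order, q, n, tau, F_normalized,
        F_original_units, retained_blocks}."""
        import pandas as pd

        qq, nn = np.meshgrid(self.q_grid, self.n_grid, indexing="ij")
        tt = np.broadcast_to(
            self.n_grid if tau is None else np.asarray(tau, dtype=float),
            nn.shape)
        return pd.DataFrame({
            "order": self.order,
            "q": qq.ravel(),
            "n": nn.ravel(),
            "tau": tt.ravel().astype(float),
            "F_normalized": self.F.ravel(),
            "F_original_units": self.F.ravel() * self.sigma,
            "retained_blocks": self.retained.ravel(),
        })


def default_q_grid() -> np.ndarray:
    """Integer moment orders -5..+5."""
    return np.arange(-5.0, 6.0)


def default_scale_grid(N: int, n_min: int = 8, n_max: int | None = None,
                       per_decade: int = 8) -> np.ndarray:
    """Exponentially spaced integer block sizes, ``per_decade`` per decade."""
    if n_max is None:
        n_max = max(N // 4, n_min)
    n_max = min(n_max, N)
    if n_min < 4:
        raise ValueError("n_min must be >= 4")
    if n_max < n_min:
        raise ValueError(f"n_max={n_max} < n_min={n_min}")
    decades = np.log10(n_max / n_min)
    count = max(2, int(round(decades * per_decade)) + 1)
    grid = np.unique(np.round(
        np.logspace(np.log10(n_min), np.log10(n_max), count)).astype(np.int64))
    return grid


def _resolve_overlap(overlap, n: int) -> int:
    if overlap == "max":
        return n - 1
    if overlap in ("none", 0):
        return 0
    L = int(overlap)
    if L < 0:
        raise ValueError(f"overlap must be >= 0, got {L}")
    return min(L, n - 1)  # a fixed overlap cannot exceed n-1 at small scales


def fq_surface(raw, q_grid=None, n_grid=None, overlap="max",
               orders: Iterable[int] = (1, 2),
               thresholds: Thresholds | None = None,
               eps: float | None = None,
               segment_width: int = DEFAULT_SEGMENT_WIDTH,
               ) -> dict[int, FluctuationSurface]:
    """F_q(n) surfaces for DFA1 and/or DFA2 in a single pass.

    One prefix store is built once and shared by both detrending orders and
    every scale.  ``overlap`` is ``"max"`` (L = n-1), ``"none"`` (L = 0) or
    a fixed integer L (clipped to n-1 at scales where L >= n).  ``eps``
    overrides the EPS carried by ``thresholds``.  Deterministic given its
    inputs.

    Returns a dict mapping detrending order to its
    :class:`FluctuationSurface`.
    """
    series = raw if isinstance(raw, NormalizedSeries) else normalize_series(raw)
    N = series.N
    q_grid = default_q_grid() if q_grid is None else \
        np.asarray(q_grid, dtype=float).ravel()
    n_grid = default_scale_grid(N) if n_grid is None else \
        np.unique(np.asarray(n_grid, dtype=np.int64).ravel())
    if n_grid.size == 0:
        raise ValueError("empty scale grid")
    if n_grid[0] < 4 or n_grid[-1] > N:
        raise ValueError(f"scales must lie in [4, N={N}]")
    orders = tuple(sorted(set(int(o) for o in orders)))
    if not orders or any(o not in (1, 2) for o in orders):
        raise ValueError(f"orders must be a subset of {{1, 2}}, got {orders}")
    th = thresholds if thresholds is not None else default_thresholds(N)
    if eps is not None:
        th = replace(th, eps=float(eps))

    profile = cumulative_profile(series)
    store = build_prefix_store(profile, segment_width=segment_width)

    shape = (q_grid.size, n_grid.size)
    F = {o: np.full(shape, np.nan) for o in orders}
    retained = {o: np.zeros(shape, dtype=np.int64) for o in orders}

    for jn, n in enumerate(n_grid):
        n = int(n)
        scheme = block_scheme(N, n, _resolve_overlap(overlap, n))
        moments = local_block_moments(store, scheme)
        for o in orders:
            if n < o + 2:
                logger.debug("scale n=%d too small for order %d; skipped",
                             n, o)
                continue
            coeffs = fit_block_poly(moments, o)
            var = residual_variance_fast(coeffs, moments, o, th, profile)
            for jq, q in enumerate(q_grid):
                f, m = fluctuation_function(var, float(q), th.eps)
                F[o][jq, jn] = f
                retained[o][jq, jn] = m
                if m == 0:
                    logger.debug("no blocks retained at order=%d q=%g n=%d",
                                 o, q, n)

    return {
        o: FluctuationSurface(order=o, q_grid=q_grid.copy(),
                              n_grid=n_grid.copy(), F=F[o],
                              retained=retained[o], sigma=series.sigma)
        for o in orders
    }
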