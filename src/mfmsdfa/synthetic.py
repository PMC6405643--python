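"""Seeded generators for the validation time series.

Every generator is deterministic given (parameters, N, seed) and emulates
one of the stochastic processes used to validate the fast fluctuation
estimator:

* white Gaussian noise (scaling exponent alpha = 0.5);
* Brownian motion, the cumulative sum of a zero-mean white noise
  (alpha = 1.5);
* their superposition ``wb``: unit-variance white noise plus a Brownian
  motion with increment variance 0.01986918, which places the spectral
  white/brown crossover at f = 10^-2.5, i.e. a crossover scale of about
  316 samples;
* a first-order autoregressive process x_i = a x_{i-1} + wn_i with
  a = 0.9391014 (low-pass cut-off 0.01, crossover scale about 100;
  alpha tends to 0.5 at large scales);
* heavy-tailed Cauchy noise (location 0, scale 3);
* a binomial multiplicative cascade embedded in noise: a canonical
  multifractal built by recursively splitting a mass-1 segment and
  multiplying random halves by 0.25 / 0.75 for 14 steps, flooring values
  below 1e-6 with uniform noise on [0, 0.01], and subtracting the reversed
  duplicate to symmetrize the distribution; several independent cascades
  can be concatenated.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "white_noise",
    "brownian_motion",
    "noise_plus_brownian",
    "ar1",
    "cauchy_noise",
    "binomial_cascade",
    "gen_series",
    "WB_INCREMENT_VARIANCE",
    "AR1_COEFFICIENT",
]

#: Brownian increment variance of the superposition series; puts the
#: white/brown spectral crossover at f = 10^-2.5 (scale ~316 samples).
WB_INCREMENT_VARIANCE = 0.01986918
#: AR(1) coefficient, a low-pass filter with cut-off frequency 0.01.
AR1_COEFFICIENT = 0.9391014

CASCADE_WEIGHT = 0.25
CASCADE_STEPS = 14
CASCADE_FLOOR = 1e-6
CASCADE_NOISE_HIGH = 0.01


def _rng(seed, rng):
    return rng if rng is not None else np.random.default_rng(seed)


def white_noise(N: int, sigma2: float = 1.0, seed=None, rng=None
                ) -> np.ndarray:
    """Zero-mean Gaussian noise with variance ``sigma2``."""
    return _rng(seed, rng).normal(0.0, np.sqrt(sigma2), N)


def brownian_motion(N: int, increment_var: float = 1.0, seed=None, rng=None
                    ) -> np.ndarray:
    """Cumulative sum of zero-mean white noise with the given variance."""
    return np.cumsum(white_noise(N, increment_var, seed=seed, rng=rng))


def noise_plus_brownian(N: int,
                        increment_var: float = WB_INCREMENT_VARIANCE,
                        seed=None, rng=None) -> np.ndarray:
    """Superposition wb_i = wn_i + Bm_i of unit white noise and a Brownian
    motion with the given increment variance (independent draws)."""
    rng = _rng(seed, rng)
    return white_noise(N, 1.0, rng=rng) + \
        brownian_motion(N, increment_var, rng=rng)


def ar1(N: int, a: float = AR1_COEFFICIENT, seed=None, rng=None
        ) -> np.ndarray:
    """First-order autoregression x_i = a x_{i-1} + wn_i, x_0 = 0."""
    wn = white_noise(N, 1.0, seed=seed, rng=rng)
    return lfilter([1.0], [1.0, -a], wn)


def cauchy_noise(N: int, loc: float = 0.0, scale: float = 3.0,
                 seed=None, rng=None) -> np.ndarray:
    """I.i.d. Cauchy samples (heavy-tailed multifractal test case)."""
    return loc + scale * _rng(seed, rng).standard_cauchy(N)


def binomial_cascade(steps: int = CASCADE_STEPS,
                     weight: float = CASCADE_WEIGHT,
                     floor: float = CASCADE_FLOOR,
                     noise_high: float = CASCADE_NOISE_HIGH,
                     n_cascades: int = 1, seed=None, rng=None,
                     return_raw: bool = False):
    """Binomial multiplicative cascade(s) embedded in noise.

    Each cascade starts from 2**steps unit samples; at every of the
    ``steps`` splitting levels each segment is halved and one random half
    is multiplied by ``weight``, the other by ``1 - weight``.  The raw
    cascade conserves total mass 1 exactly.  Values below ``floor`` are
    then replaced by uniform noise on [0, noise_high], and the reversed
    duplicate is subtracted, making the sample distribution symmetric
    (mean exactly 0).  ``n_cascades`` independent cascades are
    concatenated; ``return_raw`` additionally returns the pre-floor,
    pre-subtraction cascade(s).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not 0.0 < weight < 1.0:
        raise ValueError(f"weight must lie in (0, 1), got {weight}")
    if n_cascades < 1:
        raise ValueError("n_cascades must be >= 1")
    rng = _rng(seed, rng)
    pieces, raws = [], []
    n = 2 ** steps
    for _ in range(n_cascades):
        x = np.ones(n)
        seg = n
        for _level in range(steps):
            seg //= 2
            pairs = n // (2 * seg)
            first_gets_w = rng.integers(0, 2, size=pairs).astype(bool)
            mult = np.where(first_gets_w[:, None],
                            [weight, 1.0 - weight],
                            [1.0 - weight, weight])
            x *= np.repeat(mult.ravel(), seg)
        raws.append(x.copy())
        low = x < floor
        x[low] = rng.uniform(0.0, noise_high, int(low.sum()))
        pieces.append(x - x[::-1])
    out = np.concatenate(pieces)
    if return_raw:
        return out, np.concatenate(raws)
    return out


_MODELS = {
    "white": white_noise,
    "brownian": brownian_motion,
    "wb": noise_plus_brownian,
    "ar1": ar1,
    "cauchy": cauchy_noise,
    "cascade": None,  # handled specially: length is 2**steps * n_cascades
}


def gen_series(model: str, N: int, seed=None, rng=None, **params
               ) -> np.ndarray:
    """Generate one validation series by model name.

    Models: ``white``, ``brownian``, ``wb``, ``ar1``, ``cauchy``,
    ``cascade``.  For the cascade, N must equal ``n_cascades * 2**steps``
    (steps defaults to 14, n_cascades to 1); other models accept any N.
    Deterministic given (model, params, N, seed).
    """
    if model not in _MODELS:
        raise ValueError(
            f"unknown model {model!r}; choose from {sorted(_MODELS)}")
    if model == "cascade":
        n_casc = int(params.pop("n_cascades", 1))
        steps = params.pop("steps", None)
        if steps is None:
            if N % n_casc or (N // n_casc) & (N // n_casc - 1):
                raise ValueError(
                    f"cascade length N={N} must be n_cascades * (a power "
                    f"of 2)")
            steps = int(np.log2(N // n_casc))
        if n_casc * 2 ** int(steps) != N:
            raise ValueError(
                f"N={N} != n_cascades={n_casc} * 2**steps={2 ** int(steps)}")
        return binomial_cascade(steps=int(steps), n_cascades=n_casc,
                                seed=seed, rng=rng, **params)
    return _MODELS[model](N, seed=seed, rng=rng, **params)
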