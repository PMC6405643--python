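# Methods

## Model and procedure

The analysis operates on a univariate series S_j, j = 1..N, normalized to
zero mean and unit standard deviation, s_j = (S_j − μ)/σ. Normalization is
not required by DFA itself (the scaling exponents are invariant under
affine maps of the series); it fixes the scale on which the numerical
thresholds below are defined, and the fluctuation function of the original
series is recovered as F_q(n)·σ. The population SD (divide by N) is used,
so the threshold scale is exactly reproducible from the data.

The object being detrended is the profile y_i = Σ_{j≤i} s_j. At block size
n and overlap L (0 ≤ L < n) the profile is split into
M = ⌊(N−n)/(n−L)⌋ + 1 blocks starting at I_k = (n−L)(k−1)+1; any trailing
samples that do not complete a block are excluded. Maximal overlap, L = n−1,
gives M = N−n+1 blocks and uses every sample; it is the default because it
minimizes the variance of the F_q estimate, which is what makes
derivative-based local slopes workable. No second pass over the reversed
series is performed.

Each block is detrended by a least-squares polynomial of order 1 or 2;
σ²_n(k) is the mean squared residual. The q-order fluctuation function is
the generalized power mean of the block variances,
F_q(n) = (mean_k (σ²_n(k))^{q/2})^{1/q}, with the geometric-mean limit
exp(mean ln σ²/2) at q = 0. For fixed n, F_q(n) is non-decreasing in q
whenever the same block set enters every q (power-mean inequality).

## Fast evaluation

The per-scale cost is O(N) regardless of overlap:

- **Design sums.** All sums of i^V (V = 1..4) over a block reduce to
  differences of Faulhaber polynomials, evaluated in exact integer
  arithmetic.
- **Data moments.** The sums Σ i^V y_i^W needed by the normal equations,
  for (V,W) ∈ {(0,1),(1,1),(2,1),(0,2)}, come from prefix-sum arrays: one
  subtraction per block.
- **Local index shift.** Block moments are shifted to the local index
  j = 1..n through the exact identities
  Σ j·y = Σ i·y − (I_k−1) Σ y and
  Σ j²·y = Σ i²·y − 2(I_k−1) Σ i·y + (I_k−1)² Σ y,
  so the normal equations never see powers of the global index.
- **Closed-form fits.** Order-1 and order-2 coefficients follow from the
  centered normal equations (covariances S_iy, S_i²y against S_ii, S_ii²,
  S_i²i²), identical to a generic least-squares solve but in O(1) per
  block once the moments are known.
- **Residual variance.** Assembled from the same moments as
  σ² = S_yy − b·S_iy (order 1) or σ² = S_yy − b·S_iy − c·S_i²y (order 2).
  This centered form is algebraically identical to expanding the squared
  residual around the raw coefficients, but avoids a cancellation of size
  ȳ² that would otherwise dominate small variances when the profile is
  large (e.g. integrated Brownian motion).

Both detrending orders share one prefix store and one pass over the scale
grid.

## Numerical safeguards

Three mechanisms control floating-point error; all are user-overridable.

**Segmented prefix sums.** Prefix arrays are accumulated in segments of
128 samples (a 129-row layout: within-segment running sums plus per-segment
closing totals). A block moment is regrouped as (within-segment
difference) + (difference of accumulated segment totals): segments common
to both endpoints cancel exactly, so the error of a block moment scales
with segment-local magnitudes, not with the ulp of the full-series running
sum. The totals are themselves accumulated in extended precision
(longdouble), which matters for profiles reaching ~10⁴–10⁵ in magnitude.
The segment width (default 128) is exposed as an advanced option.

**Recompute thresholds.** An analytic residual variance below Th₁ (order
1) or Th₂ (order 2) may be dominated by cancellation error, and is
recomputed directly over the block's n samples (moments summed directly,
residuals squared explicitly). Defaults depend only on N because of the
unit-variance normalization:
Th₁ = 10⁻³ for N ≤ 10⁵, N/10⁸ above; Th₂ = 10⁻² for N ≤ 10², N/10⁴ above.
Variances still negative beyond −10⁻⁹ after recomputation trigger a
warning; all negatives are clipped to zero.

**EPS floor.** Blocks with σ² < EPS are discarded from F_q and the mean
taken over the retained count (reported per cell). This guards against
overfitted small blocks and measurement-quantization floors. Default
EPS = 0; a typical non-zero choice for filtered signals is 10⁻⁴ of the
normalized dynamics. Zero variances are additionally excluded whenever
q ≤ 0, where the power mean is undefined; at q > 0 they legitimately
contribute zero. Consequently the retained set — and hence the
monotonicity-in-q guarantee — is identical across q only when all
variances are positive or EPS > 0. A (q, n) cell with no retained blocks
is reported missing (NaN), never as 0.

## Local slopes

α(q, n) is the first derivative of log₁₀ F_q versus log₁₀ n. Because the
integer scale grid is only approximately geometric, log F is first
interpolated by a natural cubic spline in log-log coordinates and resampled
at H points exactly equispaced in log n (default 25 per decade, finer than
the F grid; the F grid itself defaults to 8 integer scales per decade from
n = 8 to N/4). The natural spline has no smoothing parameter — noise
control is delegated to maximal overlapping. Derivatives use the five-point
centered stencil (−f₂+8f₁−8f₋₁+f₋₂)/(12d) in the interior (exact for
polynomials of degree ≤ 4 on an equispaced grid) and three-point one-sided
or central stencils at the two points on each edge (second-order accurate).
All stencils are exact on straight lines, so pure power laws return their
exponent everywhere. Rows with fewer than four finite F cells, and
resampled scales outside a row's finite support, yield missing slopes.

## Combining DFA₁ and DFA₂

For series in the fractional-Gaussian-noise / fractional-Brownian-motion
family, order-1 detrending is less biased at short scales (order-2
polynomials overfit small blocks), while at large scales order 2 is more
stable for q < 0, order 1 for q > 0, and their average is best at q = 0.
The combined surface is α_w = (1−w₂)α¹ + w₂α² with

    w₂(q, n) = clip((n−12)/12, 0, 1) · (5−q)/10 .

This single expression reproduces the three anchor cases — pure DFA₁ below
scale 12 at all q; at large scales pure DFA₂ at q = −5, the plain average
at q = 0, pure DFA₁ at q = +5 — and interpolates linearly in q between
them and linearly in n across the 12–24 ramp; it is the natural closed
form of those anchors and is documented here as a reconstruction. Outside
the calibrated range |q| ≤ 5 the weight is clamped with a warning. The
weighted surface is the default presentation when both orders are fitted,
but either single order remains available, since domain knowledge (e.g.
comparability with clinical DFA₁ indices, or suspected long-term trends
favoring DFA₂) may make one order preferable.

## Surrogate nonlinearity test

Surrogates preserve the rFFT amplitudes exactly and draw all positive-
frequency phases i.i.d. uniform (DC, and Nyquist for even N, stay
untouched), destroying nonlinear structure while keeping the full linear
autocorrelation. Every surrogate is analyzed with exactly the original
pipeline settings. Per (q, n) cell the original α is located within the
Ns surrogate values by mid-rank, r = (below + 0.5·ties + 0.5)/(Ns+1), and
the two-sided significance is p = 2·min(r, 1−r). The +0.5/(Ns+1)
convention avoids p = 0; the smallest attainable p is ≈ 1/(Ns+1), so
detecting at the conventional p < 0.01 display threshold requires
Ns ≥ 100 (the default). Per-surrogate RNG streams are spawned from one
master seed, making the whole test reproducible.

## Synthetic validation series

The generators produce the study conditions under which the estimator is
validated, all seeded: white Gaussian noise (α = 0.5); Brownian motion as
the cumulative sum of zero-mean white noise (α = 1.5); their superposition
"wb" with Brownian increment variance 0.01986918, placing the spectral
white/brown crossover at f = 10^−2.5 (scale ≈ 316); AR(1) with
a = 0.9391014, a low-pass with cut-off 0.01 whose α returns to 0.5 beyond
the ≈100-sample crossover; Cauchy noise (location 0, scale 3); and a
binomial multiplicative cascade: 14 splitting steps with weight 0.25
assigned to a random half at each split (mass 1 conserved exactly before
post-processing), values below 10⁻⁶ replaced by uniform noise on
[0, 0.01], the reversed duplicate subtracted to symmetrize, and optionally
several independent cascades concatenated.

These series probe specific failure modes — large profile magnitudes
(Brownian), crossovers (wb, AR1), heavy tails (Cauchy), genuine
multifractality with near-zero quiet segments (cascade) — but they are
i.i.d.-innovation constructions: passing tests demonstrates numerical
correctness and calibration of the estimator, not robustness to artifacts
of real recordings (ectopic beats, missing data, nonstationary variance),
which must be handled upstream.

## Reference estimator

The oracle recomputes F_q(n) by definition: per-block generic least
squares via the pseudo-inverse of a centered local design matrix (an
affine reparameterization that leaves residuals unchanged), explicit mean
squared residuals with numpy's pairwise-compensated summation, and the
plain power-mean formula. It shares nothing with the fast path beyond
normalization, and is used in the tests as the independent standard; the
per-cell relative deviation |F_fast − F_ref|/F_ref (reference-zero cells
excluded) summarizes the agreement.

## Problem sizes and design choices

The validation suite runs the fast-versus-reference comparison on three
series families at N = 10⁵ with scales 10–10⁴ (observed worst error
~4·10⁻⁶, i.e. ~4·10⁻⁴ %), monofractal recovery on ensembles of ten
N = 200,000 series (mean q = 0 slope over scales 100–10,000), the AR(1)
large-scale asymptote at N = 16,384 averaged over ten seeds, and the
surrogate test on one 2¹⁴-sample cascade with 100 surrogates. These sizes
exercise every code path — including the threshold-triggered recomputes,
which fire frequently for Brownian-family series at small scales — while
keeping a full validation run to a few minutes on one CPU.

Choices made where the design was genuinely open: natural (rather than
smoothing) spline for resampling; log-domain evaluation of the power mean
at q < 0 to avoid overflow from tiny variances; a fixed integer overlap
is clipped to n−1 at scales where it would reach the block size; q = 0 is
dispatched exactly (not as a small-q limit); the scale grid rounds a
geometric progression to unique integers.

## Known limitations

- Detrending orders above 2 are not implemented (rare in biomedical
  practice; the moment algebra extends but requires new thresholds).
- The local-slope estimate at the largest scales rests on few effective
  blocks and remains noisy even with maximal overlap; ensemble averages
  of large-scale slopes (as in the AR(1) validation) carry visible
  seed-to-seed spread.
- The combination weights are calibrated for fGn/fBm-like dynamics and
  |q| ≤ 5; outside that family the weighted surface is a heuristic.
- Inputs must be fully numeric; artifact editing and R-peak/ectopy
  handling are out of scope.
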