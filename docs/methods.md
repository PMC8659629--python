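# Methods

## Scope and data model

The package analyses cumulative drug-release curves from thin hydrogel
films. A curve is a strictly increasing time grid (minutes) with
non-negative cumulative released amounts (mg/mL) or release fractions;
amounts are normalised by a reference `M_inf`. By default `M_inf` is the
last observed cumulative value (with a logged notice); when per-film
loading is trusted, the loaded mass can be used instead
(`normalization: loaded_mass`). The default is deliberate: loaded masses
and released amounts in typical source tables are reported in mixed units
(mg vs mg/mL), so the last observed value is the only normalisation that
is always internally consistent. Fractions slightly above 1 (up to +0.05)
are tolerated to absorb that unit slack and measurement noise.

## Burst-phase fit (Higuchi)

The burst fit regresses fraction on sqrt(t) **through the origin** over a
window, default `0 < t <= 30` min (the burst phase of these films):

    k_H = sum(f_i sqrt(t_i)) / sum(t_i)

There is no intercept because the law is `f = k_H t^(1/2)` exactly, with
f(0) = 0. The reported "correlation" is the Pearson correlation between
observed and fitted fractions on the window — one of several quantities
the literature loosely calls a correlation factor; it is reported,
documented, and never used as a fitting criterion. Degenerate inputs
(all-zero fractions) return a flagged result with `k_H = 0` rather than
raising, so batch runs over mixed panels complete; fewer than two usable
window points is a hard error.

## Thickness relation and units

`k_H = 2 sqrt(sigma)/d` converts the Higuchi constant of a film of
thickness `d` (mm) into a diffusion coefficient. Internally `sigma` is
kept in mm²/min (consistent with `k_H` in min^(-1/2)); mm²/s is derived by
dividing by 60. The conversion and its inverse round-trip to 1e-12
relative, and the pipeline asserts that invariant on every result row.

Applied to the seven-film study panel shipped as a fixture
(`higuchi_table.csv`: printed k_H, d, and reported D per film), the
relation reproduces the reported D values at their printed precision.
Two caveats, both traceable to print rounding of the inputs:

* **F4**: recomputed D = 0.18054e-6 mm²/s vs reported 0.181e-6 (0.25%
  apart). The printed k_H (3.18e-3, three significant figures) cannot
  constrain D better than ~0.3%, and the recomputed value rounds exactly
  to the reported one, so the check is at printed precision.
* **F3**: recomputed 3.4095e-6 vs reported 3.421e-6 (~0.34%), outside
  what rounding of the reported value alone explains; the row is treated
  as internally inconsistent and excluded from exact reproduction.

## Long-time model (truncated erfc series)

    f(t) = 2 sqrt(sigma t / d^2) [ pi^(-1/2)
           + sum_{n=1..N} (-1)^n erfc( n d / (2 sqrt(sigma t)) ) ]

with default truncation N = 2, which is sufficient out to
`sigma t / d^2` ≈ 0.25 (the erfc terms beyond n = 2 are below 1e-10
there). `f(0) = 0` by continuity, avoiding the 0/0 in the erfc argument.
erfc underflows to zero for large arguments, so small times are exact and
overflow-free at any N. The fit optimises log10(sigma) by
Levenberg–Marquardt least squares over all points with t > 0; sigma spans
two orders of magnitude across films, and the log parameterisation both
enforces positivity and conditions the problem. The starting value
defaults to the burst-fit sigma through the thickness relation.
Correlation is again Pearson between observed and predicted.

### The π inconsistency between the two laws

The N = 0 limit of the series is `f = (2/sqrt(pi)) sqrt(sigma t)/d`,
while the Higuchi form used for the burst fit is `f = 2 sqrt(sigma t)/d`
— the `pi^(-1/2)` prefactor is genuinely absent from the latter as the
model is stated, and the reported panel D values are consistent with the
prefactor-free thickness relation. Both forms are therefore implemented
exactly as stated, and the consequence is pinned by tests: fitting the
Higuchi law to noise-free N = 0 series data and converting through the
thickness relation recovers `sigma/pi`, to 1e-6 relative (and within 1%
in the end-to-end synthetic check). Which small-time law was intended as
canonical is not decidable from the model statement; the package exposes
the bias rather than silently "fixing" either form.

## Pattern dynamics

Stationary density: `rho(x) = 2 Re(z0 e^{i(kx+phi)})`, a real solution of
`rho'' + k^2 rho = 0`; `k²` is treated as a single lumped parameter. The
SL(2,R) synchronisation acts by Möbius maps `z -> (az+b)/(cz+d)`
(`ad − bc ≠ 0`, normalisable to 1); composition equals the matrix product,
asserted to 1e-10 on seeded random draws.

Non-stationary amplitude: the harmonic-map solution

    z(chi, alpha) = i (cosh chi − e^{−i alpha} sinh chi)
                    / (cosh chi + e^{−i alpha} sinh chi)

becomes, after dividing by sinh chi and writing r = coth chi,

    z = [−2 r sin(alpha) + i (r² − 1)] / (1 + r² + 2 r cos(alpha)).

The package's `z_pattern(r, omega, t)` uses the sign convention
`Re z = +2 r sin(2ωt)/Δ`, `Im z = (1 − r²)/Δ`, i.e.
`z_pattern(coth chi, omega, t) = −z_harmonic(chi, 2ωt)`; the phase mapping
`alpha = 2ωt` is forced by the algebra above (a description of the
transition to non-stationary states as `alpha = ωt` would put `2ωt` and
`ωt` in conflict; the algebraic mapping is used). The equivalence is a
test invariant at 1e-10. A purely-imaginary variant — both components
summed on one axis, modulus `|Re z + Im z|` — is exposed as
`signed_amplitude`; see below.

Numerical conventions: the denominator `Δ = 1 + r² + 2 r cos(2ωt)`
vanishes on the ring r = 1, 2ωt = π (mod 2π); evaluations with
`|Δ| < 1e-9` are masked as NaN and propagate as missing in maps, never
clipped. `r = coth chi > 1` for real chi, but the default map grids use
r ∈ [0, 0.99] (400 points) × t over 4 periods (800 points) at fixed ω,
staying clear of the singular ring; both r < 1 and r > 1 are accepted
everywhere. |z| is exactly periodic in t with period π/ω.

### Period-doubling diagnostic

Under the complex reading, `|z|²` simplifies to
`(1 + r² − 2 r cos 2ωt)/(1 + r² + 2 r cos 2ωt)`, which has exactly **one**
maximum per period for every r — it cannot show period doubling. The
single-axis amplitude `|Re z + Im z| = |2 r sin(2ωt) + 1 − r²|/Δ`,
however, develops a rectification cusp as soon as its numerator changes
sign within a period, i.e. for `r > sqrt(2) − 1 ≈ 0.414`, and then has
**two** local maxima per period. The package therefore reports both
traces (`abs_z` and `signed_abs_z`) from `time_traces`, and the
period-doubling indicator (peak count at r = 0.9 exceeding r = 0.1,
counted wrap-aware on a 10⁴-point one-period grid) is defined on the
signed amplitude. Regime labels attached to ω values (burst / period
doubling / modulated / damped) are qualitative metadata; no figure-level
quantity is asserted beyond these structural diagnostics, since grid
extents and colour scales of rendered maps are conventions, not model
content. No Lyapunov or formal chaos statistics are computed.

Delay embedding uses point k = (s[k], s[k+lag], …, s[k+(dim−1)lag]); the
default heuristic is dim = 3 with lag = quarter period in samples, both
exposed as flags. A sine embedded at quarter-period lag in 2-D lies on the
unit circle to 1e-6, the calibration test of the embedding.

## Synthetic data generator

The generator emulates the study's sampling design: one sample per minute
over the burst (1–30 min) then 60, 120, 240, 480, 960, 1440, 2160,
2800 min. The forward model is either the Higuchi law (k_H derived from
the ground-truth sigma through the thickness relation) or the erfc series
(N = 2 by default). Noise is additive i.i.d. Gaussian on the fraction
scale, clipped at zero, default sd = 0.01 fractions — a stand-in chosen as
a plausible scale for triplicate-averaged UV–VIS assays, since no error
model is reported for the source data; real residuals are likely
heteroscedastic and autocorrelated, so passing recovery tests demonstrate
estimator correctness under the stated noise model, not performance on
real assays. A cumulative-max "monotone" option reproduces the
monotonicity of real cumulative assays but is off by default because it
biases noise upward near the plateau. Panels draw thickness uniformly on
[2.07, 9.14] mm and sigma log-uniformly on [0.181e-6, 11.58e-6] mm²/s —
the spans of the study panel. All randomness flows from a single integer
seed through `numpy.random.default_rng`; identical spec + seed is
bit-for-bit reproducible.

Recovery scoring reports per-film signed relative errors of sigma and the
median/max absolute relative error. Problem sizes used by the test suite
(7 films, 38-point grids, 1% noise) keep the full suite under a few
seconds while matching the study's panel size; "matched generator/fitter"
recovery fits over the full sampled range, since the generated square-root
law holds on all of it. At 1% noise the burst window alone carries too
little signal for the smallest-sigma films (fractions < 0.01 at 30 min),
which is a property of the study conditions, not of the estimator.

## Pipeline

`run_panel_analysis` reads a film panel (CSV) and per-film curve files (or
in-memory objects), fits the burst window, converts to D, fits the N = 2
series model, and summarises D versus release efficiency across films
with a **Spearman rank** correlation — the across-panel claim is about
ordering, not linearity, so rank correlation is the appropriate summary.
Films with missing thickness or insufficient data are skipped with logged
warnings; degenerate curves are flagged rows, and the run exits
successfully. Results files are written with 17-significant-digit floats
(`%.17g`) and re-read with round-trip float parsing, so write→read is
lossless and identical configurations produce byte-identical outputs.

## Known limitations

* Only the two stated release laws are implemented; no multi-mechanism
  model selection (e.g. Korsmeyer–Peppas exponents).
* The erfc-series fit assumes a single homogeneous slab per film and a
  time-independent sigma.
* The pattern-dynamics layer is a qualitative exploration tool; its
  outputs are structurally analogous to, not reproductions of, rendered
  figures of any particular study.
* The synthetic noise model is i.i.d. Gaussian on fractions; it does not
  emulate replicate averaging, baseline drift, or calibration error.
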