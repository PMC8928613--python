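# Methods

## Band decomposition

A daily series of length *n* is decomposed with the real FFT. Fourier index
*j* (0 … ⌊n/2⌋) corresponds to frequency f_j = j · days_per_year / n cycles
per year; each index is assigned to the unique half-open band [low, high)
containing f_j, with boundary ties going to the upper band. Band components
are inverse transforms of the spectrum masked to each band's indices; because
masking acts on the half-spectrum, conjugate symmetry is preserved and
components are exactly real and sum back to the input at floating-point
accuracy. Components at disjoint Fourier frequencies are exactly orthogonal
on the full grid, so band variances add to the series variance.

Two deliberate conventions close gaps the band definitions leave open:

* **Sub-band frequencies.** The first band starts at 1 cycle/year, but the
  decomposition must be complete for the reconstruction identity to hold.
  Frequencies below the first band — including the mean at j = 0 — are
  assigned to band 1 by default; a flag on `BandSpec` turns this into an
  error instead for users who want strict band semantics.
* **days_per_year = 365.** On the default 3-year grid (n = 1095) this makes
  integer cycles-per-year frequencies sit exactly on Fourier indices
  (j = 3f), so band-limited signals are band-limited exactly, not
  approximately. It is configurable for real data spanning leap years; the
  default acute band's upper bound (183) covers the Nyquist frequency for
  any daily grid (f_max ≤ 182.5).

## Performance metrics

For a reference (observed) series and a prediction, overall and per band:
Pearson correlation; RMSE (1/n inside the root, as conventionally printed)
divided by the sample SD of the reference; and LVR, the log ratio of sample
variances. All sample statistics use the n−1 denominator. A zero-variance
reference makes scaled RMSE and LVR meaningless and raises for the overall
call; in per-band calls a component whose SD is below 1e−9 of the parent
series SD is treated as numerically constant and yields a typed `UNDEFINED`
marker for that band (never a silent NaN, never a failure of the whole
call). This threshold matters in practice: a band that carries no signal
still contains ~1e−14-relative FFT roundoff, and metrics computed on that
junk would be arbitrary.

## Exposure simulation

The log-scale signal is x(t) = Σ_k x_k(t) / SD(Σ_k x_k(t)), k ∈ {1, 2, 6}
by default (seasonal, monthly, acute). Each x_k is a sum of cosines at
**every integer cycles-per-year frequency inside band k** (band 1: 1–5,
band 2: 6–11, band 6: 104–182), equal amplitudes, independent uniform random
phases redrawn per series, standardized to its target sample variance
(default 1 per active band). This is the natural maximal-support reading of
"band-limited cosine components with varying wavelengths"; the exact
amplitude/frequency table used in the original study is not published, which
is the main source of quantitative (not qualitative) wiggle in downstream
summary numbers. The observed concentration is z = exp(x·σₓ + μₓ) with
μₓ = 1.9 and σₓ = 0.6 log μg/m³ — log-normal, strictly positive,
right-skewed, median exp(1.9) ≈ 6.7 μg/m³, the scale of urban PM2.5.

Predictions add classical error on the log scale: w_k is the band-k
component of n iid standard normals, standardized to unit sample variance,
and x* = x + w_k·σ_c with σ_c ∈ {0.2, 0.4, 0.6, 0.8} across conditions;
z* = exp(x*·σₓ + μₓ). Error confinement is exact on the log scale. On the
concentration scale exponentiation leaks error across bands — a slow
multiplicative factor exp(σₓσ_c·w₁) modulates the acute component too. This
leakage is a genuine property of multiplicative error, not an artifact: it
degrades z-scale metrics in non-error bands mildly and induces attenuation
bias in health estimates even for slow-band error (≈ −25% at σ_c = 0.8 in
any band; ≈ −70% when the error is acute).

The seasonal-variance sensitivity analysis sets Var(x₁) ∈ {1, 1.5², 2²}
with the total re-standardized to 1: overall metrics are untouched (the
error magnitude is unchanged relative to total variance) while acute-band
metrics degrade, because the acute component's share of variance shrinks.

**Seeding.** A master seed plus a spawn key (replicate, purpose) feeds
`numpy.random.SeedSequence`: purpose 0 = base signal, 1 = counts, 2 + c =
error draw for condition c. Streams are independent, reproducible, and
bitwise-stable across runs.

## Health counts and exposure split

Counts are Poisson with mean
μ(t) = exp(β₀ + β₁·z_resid(t) + 0.03·z_fit(t)), where (z_fit, z_resid) come
from OLS of z on a natural cubic spline of the day index with 24 total
degrees of freedom — about 8/year on the 3-year default, capturing seasonal
and monthly trends, leaving sub-monthly (acute) variation in the residual.
β₁ = log(1.1)/10 (relative rate 1.1 per 10 μg/m³), β₀ = 5, and the 0.03
coefficient on the smooth part together yield ≈190–200 counts/day. The 24 df
are read as a total over the series (the per-year convention is used, and
stated, only for the analysis model); knots sit at equally spaced quantiles
of the day index, which on a gap-free grid coincides with calendar time.

## Health association model

A quasi-likelihood Poisson regression (log link) of counts on the predicted
exposure z* in μg/m³ (matching β₁'s calibration), an intercept, and a
natural spline of the day index with 280 df/year (840 total on n = 1095,
design width 842). The rich spline is the point: it spans fluctuations up to
roughly 140 cycles/year, so exposure error at bands 1–5 is projected out of
the estimate, while acute-band error survives and attenuates β̂₁.

Numerics: the spline block, including the intercept direction, is QR-
orthonormalized once per (n, df) and cached; coefficients come from Fisher
scoring (IRLS) with Cholesky-solved normal equations, converging when the
relative deviance change falls below 1e−8 (max 25 iterations; a
non-converged fit is returned flagged and dropped from aggregation with a
logged warning, never imputed). The quasi part only rescales the standard
error by the Pearson χ²/(n−p) dispersion; coefficient paths are identical to
plain Poisson IRLS, which is what the test suite verifies against
statsmodels GLM to 1e−8. A hand-rolled IRLS is used because a fit of this
width must run ~600 times per study; with the cached orthonormal basis one
fit takes well under a second.

The natural-spline basis itself (cubic B-splines with second derivatives
vanishing at the boundary knots, interior knots at quantiles) is built from
`scipy.interpolate.BSpline` plus a null-space projection of the boundary
constraints; its span is verified against R's `splines::ns` in the tests.

## Study design and aggregation

Default desk-scale study: 25 replicate observed series × 24 conditions
(4 σ_c × 6 error bands); 100 replicates — the original scale — behind a
flag (`--replicates 100`, ~5 min on one CPU). Counts are drawn once per
replicate (they depend only on the observed series); each condition gets a
fresh error realization. Per condition: arithmetic means of each metric
across replicates (z-scale, as a practitioner would compute them), percent
relative mean bias 100·mean(β̂₁ − β₁)/β₁, and health RMSE
√(mean (β̂₁ − β₁)²). The final table regresses each health measure on each
condition-mean metric (overall and acute-band scope) across the 24 condition
points and reports the squared correlation — condition means, matching how
the scatter summaries are constructed, with replicate-level points
available by computing on the raw fits.

## What the generator does and does not emulate

It reproduces the marginal distribution (log-normal, μₓ = 1.9, σₓ = 0.6),
the timescale composition (seasonal/monthly/acute), and classical
band-limited error. It does not include meteorological confounding, missing
data, Berkson or mixed error structures, spatial variation, or
autocorrelated counts — so passing tests demonstrate the method's behavior
under clean classical error at known timescales, not performance on any
particular real monitoring network. Real-data preprocessing (gap
interpolation strictly below 10 consecutive days, linear between flanking
values, boundary gaps untouched; longest complete run of at least a year)
lives in the I/O layer and is exercised on constructed series.

## Known limitations

* Input must be gap-free daily data after preprocessing; no irregular-
  sampling spectral methods.
* The acute band's default upper bound (183 cycles/year) is tied to daily
  sampling; other cadences need a custom `BandSpec`.
* Concentration-scale band metrics inherit the exponentiation leakage
  described above; log-scale metrics are available by transforming inputs.
* R² summary values at 25 replicates carry Monte-Carlo noise of a few
  hundredths; the band-6 vs overall contrast is far larger and stable.
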