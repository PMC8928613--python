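# freqband

Timescale-specific ("frequency band") evaluation of air-pollution exposure
prediction models, for time-series epidemiology.

## The problem

Modern air-quality models predict daily pollutant concentrations (PM2.5,
ozone, NO2) at places without monitors. Before using those predictions in a
health study, they are usually validated against monitor data with *overall*
metrics — Pearson correlation *r*, RMSE, or the log variance ratio
LVR = log(Var(ẑ)/Var(z)). Overall metrics mix errors at every timescale. An
acute (short-term) health study, however, estimates associations from
*day-to-day* variation: a model that tracks seasonal cycles beautifully but
scrambles daily fluctuations can look excellent overall while being nearly
useless — and biasing the health estimate — at the timescale that matters.

`freqband` evaluates predictions band by band. Both series are decomposed
with a discrete Fourier transform into components confined to non-overlapping
frequency bands (in cycles per year),

    z(t) = Σₖ z_k(t),   k = 1 … K,

and the same metrics are computed per band:
r₍ₖ₎ = Cor(ẑ_k, z_k), RMSE₍ₖ₎ = √(1/n Σ (ẑ_k − z_k)²) scaled by SD(z_k),
and LVR₍ₖ₎ = log(Var(ẑ_k)/Var(z_k)). The default partition has K = 6 bands:
[1,6), [6,12), [12,26), [26,52), [52,104), [104,183) cycles/year, from
seasonal (band 1) to acute (band 6, fluctuations of ≲3.5 days).

The package also contains the full simulation machinery that justifies the
approach: log-normal PM2.5-like series (z = exp(x·σₓ + μₓ), μₓ = 1.9,
σₓ = 0.6), predictions carrying classical measurement error confined to one
band (x* = x + w_k·σ_c, σ_c ∈ {0.2, …, 0.8}), Poisson daily health counts
(~200/day, true acute log relative rate β₁ = log(1.1)/10 per μg/m³), and a
quasi-Poisson health regression with a 280 df/year time spline. Crossing
4 error magnitudes × 6 error bands shows that acute-band metrics track bias
and RMSE of the estimated health association far better than overall metrics.

## Worked example

```python
import numpy as np
from freqband import (ExposureSimConfig, ErrorConfig, simulate_observed,
                      make_prediction, overall_metrics, band_metrics)

# three years of simulated daily PM2.5 and a prediction with acute-band error
pair = make_prediction(
    simulate_observed(ExposureSimConfig(seed=3)),
    ErrorConfig(sigma_c=0.8, error_band=6, seed=9),
)
m = overall_metrics(pair.observed, pair.predicted)
b6 = band_metrics(pair.observed, pair.predicted)[5]
print(f"overall: r={m.correlation:.3f} rmse/sd={m.rmse_scaled:.3f} lvr={m.lvr:.3f}")
print(f"band 6 : r={b6.correlation:.3f} rmse/sd={b6.rmse_scaled:.3f} lvr={b6.lvr:.3f}")
```

prints

```
overall: r=0.749 rmse/sd=1.032 lvr=0.836
band 6 : r=0.614 rmse/sd=1.445 lvr=1.204
```

The overall correlation (0.75) would pass casual inspection, but the acute
band reveals the damage where it matters for a short-term health study:
band-6 correlation drops to 0.61 and the band-scaled RMSE exceeds 1.4 —
the prediction's day-to-day component is mostly error. Had the same error
been placed in the seasonal band instead, band-6 metrics would stay
near-perfect while overall metrics degraded just as much.

The same comparison for real data, from (date, value) CSVs:

```bash
freqband evaluate observed.csv predicted.csv --output metrics.csv
```

which interpolates short gaps (<10 days), takes the longest complete run of
each series (≥1 year), aligns the common date range, and reports overall plus
per-band metrics. `freqband reproduce-study --outdir out/` runs the full
simulation study (default 25 replicate series; `--replicates 100` for the
full scale) and writes the condition summaries and the R² table linking each
performance metric to health estimation capacity.

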