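"""Frequency band decomposition and model-performance metrics.

A daily pollutant series (observations ``z(t)`` or predictions ``z*(t)``)
is decomposed with the discrete Fourier transform into components confined
to non-overlapping frequency bands expressed in cycles per year.  Model
performance — Pearson correlation, RMSE scaled by the reference standard
deviation, and the log variance ratio (LVR) — can then be computed either
on the whole series ("overall") or band by band, so that a prediction
model can be judged at the timescale that matters for a given
epidemiologic design (e.g. the acute, day-to-day band for short-term
health studies).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "UNDEFINED",
    "DailySeries",
    "BandSpec",
    "BandDecomposition",
    "MetricSet",
    "assign_frequencies",
    "decompose",
    "overall_metrics",
    "band_metrics",
]


class _Undefined:
    """Typed marker for metrics that are mathematically undefined
    (e.g. correlation against a constant component)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


#: Singleton returned in place of an undefined metric value.
UNDEFINED = _Undefined()


@dataclass(frozen=True)
class DailySeries:
    """A gap-free, regularly sampled daily time series.

    Parameters
    ----------
    values
        One value per day (concentration in ug/m3, log-concentration, or
        counts).  Must be finite, length >= 2.
    start_date
        Calendar date of the first sample.
    days_per_year
        Conversion constant between Fourier index and cycles per year.
        365 by default, so that integer cycles-per-year frequencies sit
        exactly on the Fourier grid of an n = 1095 (3 x 365) series.
    """

    values: np.ndarray
    start_date: datetime.date = datetime.date(2000, 1, 1)
    days_per_year: float = 365.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("DailySeries needs a 1-d array of length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("DailySeries values must be finite (no gaps)")
        if self.days_per_year <= 0:
            raise ValueError("days_per_year must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    def dates(self) -> np.ndarray:
        """Calendar dates of the samples as a numpy datetime64[D] array."""
        start = np.datetime64(self.start_date, "D")
        return start + np.arange(self.n)

    def with_values(self, values: np.ndarray) -> "DailySeries":
        """New series with the same calendar anchoring but other values."""
        return DailySeries(values, self.start_date, self.days_per_year)


# The default partition used for acute-health applications: six half-open
# bands in cycles per year, from seasonal (band 1) to acute (band 6,
# fluctuations of roughly 3.5 days or less).
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (1.0, 6.0),
    (6.0, 12.0),
    (12.0, 26.0),
    (26.0, 52.0),
    (52.0, 104.0),
    (104.0, 183.0),
)


@dataclass(frozen=True)
class BandSpec:
    """An ordered, contiguous partition of frequencies into K half-open
    bands ``[low_k, high_k)`` in cycles per year.

    Frequencies below the first band's lower bound (including the series
    mean at frequency zero) are assigned to band 1 when
    ``include_sub_band_frequencies_in_first`` is set (the default), so
    that the band components always sum back to the input series.
    """

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    include_sub_band_frequencies_in_first: bool = True

    def __post_init__(self) -> None:
        bands = tuple((float(lo), float(hi)) for lo, hi in self.bands)
        object.__setattr__(self, "bands", bands)
        if len(bands) < 1:
            raise ValueError("BandSpec needs at least one band")
        for lo, hi in bands:
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
                raise ValueError(f"invalid band [{lo}, {hi})")
        for (_, hi), (lo2, _) in zip(bands[:-1], bands[1:]):
            if hi != lo2:
                raise ValueError(
                    "bands must be contiguous and strictly increasing: "
                    f"gap or overlap between {hi} and {lo2}"
                )

    @property
    def k(self) -> int:
        """Number of bands K."""
        return len(self.bands)

    def labels(self) -> list[str]:
        return [str(i + 1) for i in range(self.k)]

    def to_pairs(self) -> list[list[float]]:
        """Plain list-of-pairs form, for config-file serialization."""
        return [[lo, hi] for lo, hi in self.bands]

    @classmethod
    def from_pairs(cls, pairs: Sequence[Sequence[float]], **kwargs) -> "BandSpec":
        return cls(tuple((float(lo), float(hi)) for lo, hi in pairs), **kwargs)


@dataclass(frozen=True)
class BandDecomposition:
    """K real component series that sum exactly to the source series."""

    components: tuple[DailySeries, ...]
    source: DailySeries
    spec: BandSpec

    def component(self, band: int) -> DailySeries:
        """Component for 1-based band index ``band``."""
        return self.components[band - 1]

    def reconstruction(self) -> np.ndarray:
        return np.sum([c.values for c in self.components], axis=0)


@dataclass(frozen=True)
class MetricSet:
    """Model-performance metrics for one comparison (overall or one band).

    ``correlation`` is Pearson r in [-1, 1], or :data:`UNDEFINED` when a
    component is constant.  ``rmse_scaled`` is RMSE divided by the sample
    SD of the reference (observed) series.  ``lvr`` is
    log(Var(pred)/Var(obs)); 0 means matched variability.
    """

    correlation: float | _Undefined
    rmse_scaled: float | _Undefined
    lvr: float | _Undefined
    band_label: str = "overall"


def assign_frequencies(n: int, days_per_year: float, spec: BandSpec) -> np.ndarray:
    """Map each Fourier index ``j`` in 0..floor(n/2) to a 1-based band index.

    The frequency of index ``j`` is ``f_j = j * days_per_year / n`` cycles
    per year.  Indices with ``f_j`` below the first band (including j = 0,
    the mean) go to band 1 by default; the half-open band intervals send
    boundary ties upward.

    Raises
    ------
    ValueError
        If the top frequency (Nyquist for even n) is not covered by the
        last band, or sub-band frequencies exist while
        ``include_sub_band_frequencies_in_first`` is unset.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    j = np.arange(n // 2 + 1)
    f = j * days_per_year / n
    lows = np.array([lo for lo, _ in spec.bands])
    highs = np.array([hi for _, hi in spec.bands])
    # np.searchsorted on the band lower bounds; half-open [lo, hi) means a
    # frequency equal to a boundary belongs to the upper band.
    band = np.searchsorted(lows, f, side="right")  # 0 => below first band
    fmax = f[-1]
    if fmax >= highs[-1]:
        raise ValueError(
            f"frequency {fmax:g} cycles/year (index {n // 2}) exceeds the "
            f"last band's upper bound {highs[-1]:g}; extend the band spec"
        )
    if np.any(band == 0):
        if not spec.include_sub_band_frequencies_in_first:
            raise ValueError(
                "frequencies below the first band exist (e.g. the mean at "
                "0 cycles/year) and include_sub_band_frequencies_in_first "
                "is False"
            )
        band[band == 0] = 1
    return band


def decompose(ts: DailySeries, spec: BandSpec | None = None) -> BandDecomposition:
    """Split a daily series into real band-limited components.

    Each component is the inverse real FFT of the spectrum masked to that
    band's Fourier indices.  Because masking acts on the half-spectrum of
    a real FFT, conjugate symmetry is preserved and components are exactly
    real; they sum back to the input to floating-point accuracy.
    """
    spec = spec if spec is not None else BandSpec()
    assignment = assign_frequencies(ts.n, ts.days_per_year, spec)
    spectrum = np.fft.rfft(ts.values)
    components = []
    for band in range(1, spec.k + 1):
        masked = np.where(assignment == band, spectrum, 0.0)
        comp = np.fft.irfft(masked, n=ts.n)
        components.append(ts.with_values(comp))
    return BandDecomposition(tuple(components), ts, spec)


def _metrics(obs: np.ndarray, pred: np.ndarray, band_label: str,
             strict: bool = True, var_floor: float = 0.0) -> MetricSet:
    diff = pred - obs
    rmse = float(np.sqrt(np.mean(diff * diff)))
    var_obs = float(np.var(obs, ddof=1))
    var_pred = float(np.var(pred, ddof=1))
    if var_obs <= var_floor:
        if strict:
            raise ValueError(
                "reference series has zero variance: scaled RMSE and LVR "
                "are undefined"
            )
        return MetricSet(UNDEFINED, UNDEFINED, UNDEFINED, band_label)
    rmse_scaled = rmse / np.sqrt(var_obs)
    if var_pred <= var_floor:
        correlation: float | _Undefined = UNDEFINED
        lvr: float | _Undefined = -np.inf
    else:
        correlation = float(np.corrcoef(obs, pred)[0, 1])
        correlation = float(np.clip(correlation, -1.0, 1.0))
        lvr = float(np.log(var_pred / var_obs))
    return MetricSet(correlation, float(rmse_scaled), lvr, band_label)


def overall_metrics(obs: DailySeries, pred: DailySeries) -> MetricSet:
    """Whole-series performance: Pearson r, SD-scaled RMSE and LVR.

    Sample statistics (correlation, variances, the SD used for RMSE
    scaling) use the n-1 denominator; the RMSE itself averages squared
    differences with 1/n.
    """
    if obs.n != pred.n:
        raise ValueError("observed and predicted series differ in length")
    if obs.n < 3:
        raise ValueError("need at least 3 points for stable metrics")
    return _metrics(obs.values, pred.values, "overall")


def band_metrics(obs: DailySeries, pred: DailySeries,
                 spec: BandSpec | None = None) -> list[MetricSet]:
    """Per-band performance: metric set k compares band-k components of
    the two series, with the observed component as the reference.

    A band whose observed component is (numerically) constant yields
    :data:`UNDEFINED` markers for that band rather than failing the call.
    """
    spec = spec if spec is not None else BandSpec()
    if obs.n != pred.n:
        raise ValueError("observed and predicted series differ in length")
    dec_obs = decompose(obs, spec)
    dec_pred = decompose(pred, spec)
    # a band whose component variance is at floating-point roundoff level
    # relative to the parent series is numerically constant -> UNDEFINED
    scale = max(float(np.std(obs.values)), float(np.std(pred.values)))
    var_floor = (1e-9 * scale) ** 2
    out = []
    for band in range(1, spec.k + 1):
        out.append(
            _metrics(
                dec_obs.component(band).values,
                dec_pred.component(band).values,
                str(band),
                strict=False,
                var_floor=var_floor,
            )
        )
    return out
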