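"""CSV series I/O and real-data preprocessing.

Monitor data arrive as daily (date, value) CSVs with gaps: missing dates
or empty value cells.  The preprocessing pipeline mirrors standard
practice for building gap-free daily series from monitor records:
linearly interpolate short gaps (strictly fewer than 10 consecutive
missing days, by default) and keep the longest contiguous complete
stretch, requiring at least a year of data.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .core import BandSpec, DailySeries

__all__ = [
    "RawSeries",
    "read_series",
    "write_series",
    "interpolate_short_gaps",
    "longest_complete_run",
    "read_band_spec",
    "write_band_spec",
    "generate_fixtures",
]


@dataclass(frozen=True)
class RawSeries:
    """A daily record with possible gaps, on a complete calendar grid.

    ``values`` holds NaN on missing days; dates run consecutively from
    ``start_date``.
    """

    values: np.ndarray
    start_date: datetime.date
    site_id: str = ""

    @property
    def n(self) -> int:
        return self.values.size

    def dates(self) -> np.ndarray:
        return np.datetime64(self.start_date, "D") + np.arange(self.n)


def read_series(path, date_col: str = "date",
                value_col: str = "value", site_id: str = "") -> RawSeries:
    """Read a (date, value) CSV into a gap-preserving RawSeries.

    Empty value cells and dates absent from the file both become gaps.
    Duplicate dates, unparseable dates and non-numeric values raise with
    the offending row or date named.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in (date_col, value_col):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    try:
        dates = pd.to_datetime(frame[date_col], format="ISO8601")
    except (ValueError, TypeError):
        bad = pd.to_datetime(frame[date_col], errors="coerce", format="mixed")
        rows = frame.index[bad.isna() & frame[date_col].notna()].tolist()
        raise ValueError(f"{path}: unparseable dates at rows {rows[:5]}")
    values = pd.to_numeric(frame[value_col], errors="coerce")
    bad_rows = frame.index[
        values.isna() & frame[value_col].notna()
        & (frame[value_col].astype(str).str.strip() != "")
    ].tolist()
    if bad_rows:
        raise ValueError(f"{path}: non-numeric values at rows {bad_rows[:5]}")
    dup = dates[dates.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated date {dup.iloc[0].date()}")
    order = np.argsort(dates.values)
    dates = dates.iloc[order]
    values = values.iloc[order]
    full = pd.date_range(dates.iloc[0], dates.iloc[-1], freq="D")
    series = pd.Series(values.values, index=dates.values).reindex(full)
    return RawSeries(series.to_numpy(dtype=float),
                     full[0].date(), site_id=site_id)


def write_series(series: DailySeries, path, value_col: str = "value") -> None:
    """Write (date, value) CSV at full floating-point precision."""
    frame = pd.DataFrame({
        "date": pd.to_datetime(series.dates()).strftime("%Y-%m-%d"),
        value_col: [repr(float(v)) for v in series.values],
    })
    frame.to_csv(path, index=False)


def interpolate_short_gaps(raw: RawSeries, max_gap: int = 10) -> RawSeries:
    """Linearly fill runs of missing days strictly shorter than max_gap.

    Gaps of max_gap days or more, and gaps touching the series
    boundaries (no flanking observation on one side), are left missing.
    """
    values = raw.values.copy()
    isnan = np.isnan(values)
    if not isnan.any():
        return raw
    # run-length encode the NaN mask
    boundaries = np.flatnonzero(np.diff(isnan.astype(int)))
    starts = np.r_[0, boundaries + 1]
    ends = np.r_[boundaries, raw.n - 1]
    for s, e in zip(starts, ends):
        if not isnan[s]:
            continue
        length = e - s + 1
        if length >= max_gap or s == 0 or e == raw.n - 1:
            continue
        left, right = values[s - 1], values[e + 1]
        frac = np.arange(1, length + 1) / (length + 1)
        values[s:e + 1] = left + frac * (right - left)
    return RawSeries(values, raw.start_date, raw.site_id)


def longest_complete_run(raw: RawSeries, min_days: int = 365,
                         days_per_year: float = 365.0) -> DailySeries:
    """Longest contiguous gap-free stretch, ties broken toward the
    earliest run; raises if the longest run is shorter than min_days."""
    ok = ~np.isnan(raw.values)
    best_start, best_len = 0, 0
    run_start = None
    for i, good in enumerate(np.r_[ok, False]):
        if good and run_start is None:
            run_start = i
        elif not good and run_start is not None:
            length = i - run_start
            if length > best_len:
                best_start, best_len = run_start, length
            run_start = None
    if best_len < min_days:
        raise ValueError(
            f"longest complete run is {best_len} days, below the "
            f"required {min_days}"
        )
    start = raw.start_date + datetime.timedelta(days=int(best_start))
    return DailySeries(raw.values[best_start:best_start + best_len],
                       start_date=start, days_per_year=days_per_year)


def read_band_spec(path) -> BandSpec:
    """Band spec from a YAML file: a list of [low, high) pairs in
    cycles/year under key ``bands`` (or a bare list)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        pairs = data["bands"]
        include = data.get("include_sub_band_frequencies_in_first", True)
    else:
        pairs, include = data, True
    return BandSpec.from_pairs(
        pairs, include_sub_band_frequencies_in_first=include)


def write_band_spec(spec: BandSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({
            "bands": spec.to_pairs(),
            "include_sub_band_frequencies_in_first":
                spec.include_sub_band_frequencies_in_first,
        }, fh)


def generate_fixtures(seed: int, outdir) -> dict[str, tuple[str, str]]:
    """Write small deterministic observed/predicted CSV pairs (n = 365).

    Three scenarios: no error, seasonal (band 1) error at sigma_c = 0.8,
    and acute (band 6) error at sigma_c = 0.8.  Returns a mapping from
    scenario name to the (observed, predicted) file paths.  Identical
    seeds produce byte-identical files.
    """
    import os

    from .exposure import (ErrorConfig, ExposureSimConfig, make_prediction,
                           simulate_observed)

    os.makedirs(outdir, exist_ok=True)
    scenarios = {
        "noerror": ErrorConfig(0.0, 6),
        "band1_sigma08": ErrorConfig(0.8, 1),
        "band6_sigma08": ErrorConfig(0.8, 6),
    }
    out = {}
    for i, (name, err) in enumerate(scenarios.items()):
        cfg = ExposureSimConfig(n=365)
        ss = np.random.SeedSequence(seed, spawn_key=(i, 0))
        pair0 = simulate_observed(cfg, np.random.default_rng(ss))
        ss_err = np.random.SeedSequence(seed, spawn_key=(i, 1))
        pair = make_prediction(pair0, err, np.random.default_rng(ss_err))
        obs_path = os.path.join(outdir, f"{name}_observed.csv")
        pred_path = os.path.join(outdir, f"{name}_predicted.csv")
        write_series(pair.observed, obs_path)
        write_series(pair.predicted, pred_path)
        out[name] = (obs_path, pred_path)
    return out
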