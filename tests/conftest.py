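"""Shared fixtures and independent oracles.

The brute-force DFT oracle below recomputes band components from
explicit sums of sines and cosines per Fourier index, independent of the
FFT-based implementation, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def oracle_band_index(j: int, n: int, days_per_year: float,
                      bands: list[tuple[float, float]]) -> int:
    """1-based band for Fourier index j; sub-band frequencies -> band 1."""
    f = j * days_per_year / n
    for k, (lo, hi) in enumerate(bands, start=1):
        if lo <= f < hi:
            return k
    if f < bands[0][0]:
        return 1
    raise AssertionError(f"frequency {f} not covered")


def oracle_band_components(values: np.ndarray, days_per_year: float,
                           bands: list[tuple[float, float]]) -> np.ndarray:
    """(K, n) band components via explicit O(n^2) trigonometric sums."""
    values = np.asarray(values, dtype=float)
    n = values.size
    t = np.arange(n)
    comps = np.zeros((len(bands), n))
    for j in range(n // 2 + 1):
        cosj = np.cos(2 * np.pi * j * t / n)
        sinj = np.sin(2 * np.pi * j * t / n)
        a = float(np.sum(values * cosj))
        b = float(np.sum(values * sinj))
        if j == 0:
            contrib = np.full(n, a / n)
        elif n % 2 == 0 and j == n // 2:
            contrib = (a / n) * cosj
        else:
            contrib = (2.0 / n) * (a * cosj + b * sinj)
        comps[oracle_band_index(j, n, days_per_year, bands) - 1] += contrib
    return comps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220317)
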