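"""Band decomposition and performance metrics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from freqband import (
    UNDEFINED,
    BandSpec,
    DailySeries,
    assign_frequencies,
    band_metrics,
    decompose,
    overall_metrics,
)
from freqband.core import DEFAULT_BANDS

from .conftest import oracle_band_components


class TestBandSpec:
    def test_default_is_six_band_partition(self):
        spec = BandSpec()
        assert spec.k == 6
        assert spec.bands[0] == (1.0, 6.0)
        assert spec.bands[-1] == (104.0, 183.0)

    def test_rejects_gaps_and_overlaps(self):
        with pytest.raises(ValueError, match="contiguous"):
            BandSpec(((1.0, 6.0), (7.0, 12.0)))
        with pytest.raises(ValueError, match="invalid band"):
            BandSpec(((6.0, 1.0),))

    def test_pairs_round_trip(self):
        spec = BandSpec()
        assert BandSpec.from_pairs(spec.to_pairs()) == spec


class TestAssignFrequencies:
    @pytest.mark.parametrize("j,band", [
        (3, 1),     # 1.0 cycles/yr -> seasonal band
        (0, 1),     # the mean goes to the lowest band
        (547, 6),   # 182.33 cycles/yr -> acute band
        (17, 1),    # 5.67 cycles/yr, below the band-2 boundary
        (18, 2),    # exactly 6 cycles/yr: half-open tie goes upward
    ])
    def test_index_assignment_n1095(self, j, band):
        assignment = assign_frequencies(1095, 365.0, BandSpec())
        assert assignment[j] == band

    def test_partition_is_complete(self):
        assignment = assign_frequencies(1095, 365.0, BandSpec())
        assert assignment.size == 548
        assert np.all((assignment >= 1) & (assignment <= 6))

    def test_uncovered_nyquist_raises(self):
        spec = BandSpec(((1.0, 50.0),))
        with pytest.raises(ValueError, match="exceeds"):
            assign_frequencies(1095, 365.0, spec)

    def test_sub_band_exclusion_flag(self):
        spec = BandSpec(include_sub_band_frequencies_in_first=False)
        with pytest.raises(ValueError, match="below the first band"):
            assign_frequencies(1095, 365.0, spec)


class TestDecompose:
    def test_pure_cosine_lands_in_one_band(self):
        t = np.arange(1095)
        ts = DailySeries(np.cos(2 * np.pi * 3 * t / 365))
        dec = decompose(ts)
        np.testing.assert_allclose(dec.component(1).values, ts.values,
                                   atol=1e-8)
        for band in range(2, 7):
            np.testing.assert_allclose(dec.component(band).values, 0.0,
                                       atol=1e-8)

    def test_constant_series_is_all_band_one(self):
        ts = DailySeries(np.full(730, 7.5))
        dec = decompose(ts)
        np.testing.assert_allclose(dec.component(1).values, 7.5, atol=1e-10)
        for band in range(2, 7):
            np.testing.assert_allclose(dec.component(band).values, 0.0,
                                       atol=1e-10)

    def test_matches_bruteforce_oracle_on_random_series(self, rng):
        values = rng.normal(size=30)
        dec = decompose(DailySeries(values))
        expected = oracle_band_components(values, 365.0, list(DEFAULT_BANDS))
        got = np.array([c.values for c in dec.components])
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_components_are_spectrally_confined(self, rng):
        ts = DailySeries(rng.normal(size=400))
        dec = decompose(ts)
        assignment = np.array([
            1 if f < 1.0 else next(k for k, (lo, hi) in
                                   enumerate(DEFAULT_BANDS, 1) if lo <= f < hi)
            for f in np.arange(201) * 365.0 / 400
        ])
        for band in range(1, 7):
            spec_amp = np.abs(np.fft.rfft(dec.component(band).values)) ** 2
            total = spec_amp.sum()
            if total == 0:
                continue
            outside = spec_amp[assignment != band].sum()
            assert outside < 1e-10 * total

    @given(arrays(np.float64, st.integers(8, 64),
                  elements=st.floats(-100, 100, allow_nan=False)))
    def test_reconstruction_property(self, values):
        if np.ptp(values) == 0:
            values = values + np.arange(values.size) * 1e-3
        ts = DailySeries(values)
        dec = decompose(ts)
        scale = max(np.max(np.abs(values)), 1.0)
        np.testing.assert_allclose(dec.reconstruction(), values,
                                   atol=1e-8 * scale)

    @given(arrays(np.float64, st.integers(8, 64),
                  elements=st.floats(-50, 50, allow_nan=False)))
    def test_variance_additivity_property(self, values):
        """Components at disjoint Fourier frequencies are empirically
        uncorrelated on the full grid, so variances add."""
        ts = DailySeries(values + np.arange(values.size) * 1e-6)
        dec = decompose(ts)
        total = np.var(ts.values, ddof=1)
        parts = sum(np.var(c.values, ddof=1) for c in dec.components)
        np.testing.assert_allclose(parts, total, rtol=1e-8, atol=1e-10)


class TestOverallMetrics:
    def test_identity_prediction(self, rng):
        obs = DailySeries(rng.normal(size=100))
        m = overall_metrics(obs, obs)
        assert m.correlation == pytest.approx(1.0)
        assert m.rmse_scaled == 0.0
        assert m.lvr == pytest.approx(0.0)

    def test_variance_inflation_gives_log4_lvr(self, rng):
        obs = DailySeries(rng.normal(size=100))
        pred = obs.with_values(
            obs.values.mean() + 2.0 * (obs.values - obs.values.mean()))
        m = overall_metrics(obs, pred)
        assert m.correlation == pytest.approx(1.0)
        assert m.lvr == pytest.approx(math.log(4.0), abs=1e-10)

    def test_hand_computed_four_point_example(self):
        # obs=(1,2,3,4), pred=(1,2,3,8): explicit sums give
        # cov = 11/3, var_obs = 5/3, var_pred = 29/3,
        # r = 11/sqrt(145), RMSE = sqrt(16/4) = 2,
        # rmse_scaled = 2/sqrt(5/3), lvr = log(29/5).
        obs = DailySeries([1.0, 2.0, 3.0, 4.0])
        pred = DailySeries([1.0, 2.0, 3.0, 8.0])
        m = overall_metrics(obs, pred)
        assert m.correlation == pytest.approx(11.0 / math.sqrt(145.0), abs=1e-12)
        assert m.rmse_scaled == pytest.approx(2.0 / math.sqrt(5.0 / 3.0), abs=1e-12)
        assert m.lvr == pytest.approx(math.log(29.0 / 5.0), abs=1e-12)

    def test_zero_variance_reference_raises(self):
        obs = DailySeries(np.ones(10))
        pred = DailySeries(np.arange(10.0))
        with pytest.raises(ValueError, match="zero variance"):
            overall_metrics(obs, pred)

    def test_zero_variance_prediction_is_undefined(self, rng):
        obs = DailySeries(rng.normal(size=10))
        pred = DailySeries(np.ones(10))
        m = overall_metrics(obs, pred)
        assert m.correlation is UNDEFINED
        assert m.lvr == -np.inf

    def test_lvr_antisymmetry(self, rng):
        obs = DailySeries(rng.normal(size=60))
        pred = DailySeries(rng.normal(size=60) * 2.0)
        assert (overall_metrics(obs, pred).lvr
                == pytest.approx(-overall_metrics(pred, obs).lvr))


class TestBandMetrics:
    def test_identity_in_every_band(self, rng):
        obs = DailySeries(rng.normal(size=365))
        for m in band_metrics(obs, obs):
            assert m.rmse_scaled == pytest.approx(0.0, abs=1e-12)
            assert m.lvr == pytest.approx(0.0, abs=1e-9)

    def test_band_limited_noise_degrades_only_its_band(self, rng):
        """Error confined to the acute band leaves bands 1-5 at identity."""
        t = np.arange(1095)
        base = sum(np.cos(2 * np.pi * f * t / 365 + f) for f in (2, 8, 120))
        obs = DailySeries(base)
        noise = decompose(DailySeries(rng.normal(size=1095))).component(6)
        pred = obs.with_values(obs.values + noise.values)
        sets = band_metrics(obs, pred)
        for m in sets[:5]:
            if m.rmse_scaled is UNDEFINED:
                continue  # band carries no signal at all
            assert m.correlation == pytest.approx(1.0, abs=1e-6)
            assert m.rmse_scaled == pytest.approx(0.0, abs=1e-6)
        assert sets[5].rmse_scaled > 0.1

    def test_constant_component_yields_undefined_not_failure(self):
        t = np.arange(730)
        obs = DailySeries(np.cos(2 * np.pi * 2 * t / 365))  # band 1 only
        pred = obs.with_values(obs.values + 0.1 * np.cos(2 * np.pi * 8 * t / 365))
        sets = band_metrics(obs, pred)
        assert sets[0].correlation == pytest.approx(1.0)
        assert sets[1].rmse_scaled is UNDEFINED  # obs band-2 part is zero
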