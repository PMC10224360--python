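import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import electrome as e
from electrome import BandDefinition, Recording
from electrome.errors import (
    EmptyBandError,
    ShortRecordingError,
    UndefinedCentroidError,
)
from electrome.spectral import PSDEstimate, mean_frequency_series, mean_ddp_series

from oracles import direct_dft_onesided, rectangle_band_power

FS = 62.5


def _rec(samples, fs=FS, **kw):
    return Recording(samples=np.asarray(samples, dtype=float), fs=fs, **kw)


class TestSegmentation:
    def test_two_hours_gives_120_windows_of_3750(self):
        rec = _rec(np.ones(450_000))
        windows = e.segment_minutes(rec)
        assert len(windows) == 120
        assert all(w.size == 3750 for w in windows)

    def test_exactly_one_window(self):
        assert len(e.segment_minutes(_rec(np.ones(3750)))) == 1

    def test_one_sample_short_is_an_error(self):
        with pytest.raises(ShortRecordingError):
            e.segment_minutes(_rec(np.ones(3749)))

    def test_trailing_partial_window_dropped(self):
        windows = e.segment_minutes(_rec(np.ones(2 * 3750 + 100)))
        assert len(windows) == 2


class TestMeanFrequency:
    def test_pure_tone_centroid_hits_the_line(self):
        t = np.arange(3750) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        assert e.mean_frequency(x, FS) == pytest.approx(5.0, abs=1 / 60)

    def test_equal_power_tones_average_symmetrically(self):
        t = np.arange(3750) / FS
        x = np.sin(2 * np.pi * 2.0 * t) + np.sin(2 * np.pi * 8.0 * t)
        assert e.mean_frequency(x, FS) == pytest.approx(5.0, abs=1 / 60)

    def test_white_noise_centroid_near_quarter_fs(self, rng):
        x = rng.standard_normal(60_000)
        assert e.mean_frequency(x, FS) == pytest.approx(FS / 4, rel=0.05)

    def test_zero_window_has_no_centroid(self):
        with pytest.raises(UndefinedCentroidError):
            e.mean_frequency(np.zeros(1000), FS)

    def test_magnitude_mean_mode_differs_from_centroid_on_skewed_spectra(self, rng):
        t = np.arange(3750) / FS
        x = 10 * np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 10.0 * t)
        c = e.mean_frequency(x, FS, mode="centroid")
        m = e.mean_frequency(x, FS, mode="magnitude_mean")
        assert m > c  # magnitude weighting boosts the weak high line

    def test_rfft_matches_direct_dft_oracle(self, rng):
        """The transform underlying the centroid agrees with a brute-force
        O(n^2) DFT to 1e-9 relative error."""
        for _ in range(10):
            n = int(rng.integers(16, 1025))
            x = rng.standard_normal(n)
            ours = np.fft.rfft(x - x.mean())
            oracle = direct_dft_onesided(x - x.mean())
            err = np.abs(ours - oracle).max() / np.abs(oracle).max()
            assert err <= 1e-9


class TestMeanDDP:
    @pytest.mark.parametrize(
        "window,expected",
        [([1.0, 2.0, 3.0], 2.0), (np.full(100, 17.0), 17.0)],
    )
    def test_mean_of_raw_samples(self, window, expected):
        assert e.mean_ddp(window) == pytest.approx(expected)

    def test_zero_mean_sinusoid(self):
        t = np.arange(3750) / FS
        assert e.mean_ddp(np.sin(2 * np.pi * 1.0 * t)) == pytest.approx(0.0, abs=1e-3)


class TestWelchPSD:
    def test_grid_matches_four_second_windows(self, rng):
        psd = e.welch_psd(rng.standard_normal(10_000), FS)
        assert psd.freqs_hz[0] == 0.0
        assert psd.nyquist_hz == 31.25
        assert psd.df == pytest.approx(0.25)
        assert len(psd.freqs_hz) == 126  # 250-sample segments, one-sided

    def test_zero_signal_gives_zero_density(self):
        psd = e.welch_psd(np.zeros(1000), FS)
        assert np.all(psd.density == 0.0)

    def test_unit_variance_white_noise_integrates_to_one(self, rng):
        x = rng.standard_normal(500_000)
        x = (x - x.mean()) / x.std()
        psd = e.welch_psd(x, FS)
        assert psd.total_power() == pytest.approx(1.0, rel=0.05)

    def test_too_short_input_rejected(self):
        with pytest.raises(ShortRecordingError):
            e.welch_psd(np.zeros(200), FS)  # < 250-sample segment


class TestBandPower:
    def test_closed_form_on_linear_density(self):
        """density = f integrates to (hi^2 - lo^2)/2; Simpson is exact."""
        freqs = np.arange(0, 31.25 + 0.25, 0.25)
        psd = PSDEstimate(freqs, freqs.copy(), 4.0, 0.5, "hann")
        band = BandDefinition("delta", 0.5, 4.0)
        expected = (4.0**2 - 0.5**2) / 2
        assert e.band_power(psd, band) == pytest.approx(expected, rel=1e-6)

    def test_tone_power_is_conserved_across_the_full_grid(self, tone_recording):
        """Parseval: the binned PSD of a 10 uV tone carries A^2/2 = 50 uV^2."""
        psd = e.welch_psd(tone_recording.samples, FS)
        total = rectangle_band_power(psd.freqs_hz, psd.density, 0.0, 31.25)
        assert total == pytest.approx(50.0, rel=0.02)

    def test_simpson_on_a_spectral_line_carries_known_bias(self, tone_recording):
        """Composite Simpson under-integrates a 3-bin Hann line by up to 1/9;
        the delta-band figure stays within 15% of the true 50 uV^2."""
        psd = e.welch_psd(tone_recording.samples, FS)
        abp = e.band_power(psd, BandDefinition("delta", 0.5, 4.0))
        assert abp == pytest.approx(50.0, rel=0.15)

    def test_out_of_band_leakage_below_half_percent(self, tone_recording):
        psd = e.welch_psd(tone_recording.samples, FS)
        theta = e.band_power(psd, BandDefinition("theta", 4.0, 8.0))
        assert theta <= 0.5

    def test_band_above_nyquist_is_an_error(self):
        freqs = np.arange(0, 31.25 + 0.25, 0.25)
        psd = PSDEstimate(freqs, np.ones_like(freqs), 4.0, 0.5, "hann")
        with pytest.raises(EmptyBandError):
            e.band_power(psd, BandDefinition("ultra", 40.0, 90.0))

    def test_gamma_band_clipped_at_nyquist(self, caplog):
        freqs = np.arange(0, 31.25 + 0.25, 0.25)
        psd = PSDEstimate(freqs, np.ones_like(freqs), 4.0, 0.5, "hann")
        with caplog.at_level("WARNING", logger="electrome.spectral"):
            abp = e.band_power(psd, BandDefinition("gamma", 20.0, 100.0))
        # unit density: integral over the clipped interval [20, 31.25]
        assert abp == pytest.approx(11.25, rel=1e-9)
        assert any("clipped" in m for m in caplog.messages)

    def test_narrow_band_falls_back_to_trapezoid(self, caplog):
        freqs = np.arange(0, 31.25 + 0.25, 0.25)
        psd = PSDEstimate(freqs, np.ones_like(freqs), 4.0, 0.5, "hann")
        with caplog.at_level("WARNING", logger="electrome.spectral"):
            abp = e.band_power(psd, BandDefinition("sliver", 10.0, 10.3))
        assert abp == pytest.approx(0.25)  # two unit-density points, df apart
        assert any("trapezoidal" in m for m in caplog.messages)

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_quadratic_scaling_in_amplitude(self, scale):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(2000)
        band = BandDefinition("delta", 0.5, 4.0)
        base = e.band_power(e.welch_psd(x, FS), band)
        scaled = e.band_power(e.welch_psd(scale * x, FS), band)
        assert scaled == pytest.approx(scale**2 * base, rel=1e-9)


class TestParsevalPartition:
    PARTITION = [(0.0, 0.5), (0.5, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 31.25)]

    def _partition_sum(self, psd):
        return sum(
            e.band_power(psd, BandDefinition(f"part{i}", lo, hi))
            for i, (lo, hi) in enumerate(self.PARTITION)
        )

    def test_partition_sum_matches_integral_and_variance(self, rng):
        """For zero-mean windows whose content the 4 s Welch segments can
        resolve, the partition band-power sum equals the full PSD integral
        (within 2%) and the window variance (within 5%)."""
        for _ in range(5):
            bg = float(rng.uniform(5.0, 20.0))
            cfg = e.GeneratorConfig(
                duration_s=240.0,
                n_replicates=1,
                background_exponent=0.0,
                background_rms=bg,
                components=(
                    e.OscillatoryComponent(
                        center_hz=float(rng.uniform(6.0, 12.0)),
                        bandwidth_hz=6.0,
                        rms_uv=bg * float(rng.uniform(0.3, 0.7)),
                    ),
                ),
                base_seed=int(rng.integers(0, 2**31 - 1)),
            )
            x = e.generate_recording(cfg, 0, "before").samples
            x = x - x.mean()
            psd = e.welch_psd(x, FS)
            total = self._partition_sum(psd)
            assert total == pytest.approx(psd.total_power(), rel=0.02)
            assert total == pytest.approx(x.var(), rel=0.05)


class TestFeatureSeries:
    def test_abp_series_has_one_value_per_minute_per_band(self, small_config):
        rec = e.generate_recording(small_config, 0, "before")
        series = e.abp_series(rec, e.default_bands())
        assert set(series) == {b.name for b in e.DEFAULT_BANDS}
        for s in series.values():
            assert len(s) == 5  # 300 s / 60 s
            assert s.units == "uV^2"

    def test_stationary_abp_has_bounded_minute_to_minute_variability(self):
        """~29 averaged Welch segments per minute keep the coefficient of
        variation of a stationary signal's band power below 30%."""
        cfg = e.GeneratorConfig(
            duration_s=1200,
            n_replicates=1,
            background_rms=10.0,
            background_exponent=0.0,
            components=(
                e.OscillatoryComponent(center_hz=2.0, bandwidth_hz=1.0, rms_uv=10.0),
            ),
            base_seed=77,
        )
        rec = e.generate_recording(cfg, 0, "before")
        values = e.abp_series(rec, [BandDefinition("delta", 0.5, 4.0)])["delta"].values
        assert values.std() / values.mean() < 0.30

    def test_circular_shift_leaves_band_power_distribution_unchanged(self, rng):
        """Band powers of a stationary signal are invariant in distribution
        under circular shift: medians over 100 shifts agree within 5%."""
        x = rng.standard_normal(3750)
        band = BandDefinition("delta", 0.5, 4.0)
        shifts = rng.integers(0, 3750, size=100)
        powers = np.array(
            [e.band_power(e.welch_psd(np.roll(x, s), FS), band) for s in shifts]
        )
        ref = e.band_power(e.welch_psd(x, FS), band)
        assert np.median(powers) == pytest.approx(ref, rel=0.05)

    def test_compute_features_bundles_all_series(self, small_config):
        rec = e.generate_recording(small_config, 0, "before")
        series = e.compute_features(rec, e.default_bands())
        names = [s.feature_name for s in series]
        assert names[:2] == ["mean_frequency", "mean_ddp"]
        assert names[2:] == [f"abp:{b.name}" for b in e.DEFAULT_BANDS]

    def test_mean_series_metadata_propagates(self, small_config):
        rec = e.generate_recording(small_config, 2, "after")
        mf = mean_frequency_series(rec)
        dd = mean_ddp_series(rec)
        assert mf.plant_id == dd.plant_id == "plant02"
        assert mf.phase == "after"
        assert mf.units == "Hz" and dd.units == "uV"
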