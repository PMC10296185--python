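import numpy as np
import pytest

from nirsgraph import (
    ConfigError,
    DataError,
    PreprocessConfig,
    SimulationConfig,
    bandpass,
    beer_lambert,
    optical_density,
    preprocess_pipeline,
    short_channel_regress,
    simulate_raw,
    wavelet_despike,
    zscore,
)
from nirsgraph.preprocess import DEFAULT_EXTINCTION

FS = 7.81


class TestOpticalDensity:
    def test_constant_intensity_zero_od(self):
        np.testing.assert_array_equal(optical_density(np.full(20, 3.5)), np.zeros(20))

    def test_log10_decade(self):
        # mean kept at exactly 1 so the dip to 0.1 is one decade below it
        intensities = np.ones(10)
        intensities[3] = 0.1
        intensities[7] = 1.9
        od = optical_density(intensities)
        assert od[3] == pytest.approx(1.0, abs=1e-12)

    def test_matches_log_ratio_oracle(self, rng):
        intensities = rng.uniform(0.5, 2.0, size=40)
        od = optical_density(intensities)
        mean = intensities.sum() / 40
        for t in range(40):
            assert od[t] == pytest.approx(-np.log10(intensities[t] / mean), abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(DataError):
            optical_density(np.array([1.0, 0.0, 2.0]))


class TestBeerLambert:
    def test_zero_od_zero_concentration(self):
        out = beer_lambert(np.zeros((10, 2)), separation_cm=3.0)
        np.testing.assert_array_equal(out, np.zeros((10, 2)))

    def test_forward_inverse_roundtrip(self, rng):
        conc = rng.standard_normal((50, 2)) * 1e-3
        sep, dpf = 3.0, (6.0, 6.2)
        forward = DEFAULT_EXTINCTION * sep * np.asarray(dpf)[:, None]
        od = conc @ forward.T
        recovered = beer_lambert(od, sep, dpf)
        np.testing.assert_allclose(recovered, conc, atol=1e-10)

    def test_identity_configuration_passthrough(self, rng):
        od = rng.standard_normal((30, 2))
        out = beer_lambert(od, separation_cm=1.0, dpf=1.0, extinction=np.eye(2))
        np.testing.assert_allclose(out, od, atol=1e-12)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ConfigError):
            beer_lambert(np.zeros((5, 2)), 3.0, 6.0, np.ones((2, 2)))


class TestZscore:
    def test_hand_example(self):
        np.testing.assert_allclose(zscore(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    def test_defining_property(self, rng):
        out = zscore(rng.standard_normal(100) * 5 + 3)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.var(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(DataError):
            zscore(np.full(10, 2.0))


class TestWaveletDespike:
    def sinusoid(self, t_len=1024):
        t = np.arange(t_len) / FS
        return np.sin(2 * np.pi * 0.04 * t)

    def test_zero_input_zero_output(self):
        np.testing.assert_array_equal(wavelet_despike(np.zeros(64)), np.zeros(64))

    def test_smooth_signal_nearly_untouched(self):
        x = self.sinusoid()
        out = wavelet_despike(x)
        rms_dev = np.sqrt(np.mean((out - x) ** 2))
        assert rms_dev < 0.05 * np.sqrt(np.mean(x**2))

    def test_spike_suppressed_signal_kept(self):
        x = self.sinusoid()
        spiked = x.copy()
        spiked[500] += 10.0 * x.std()
        out = wavelet_despike(spiked)
        spike_before = spiked[500] - x[500]
        spike_after = out[500] - x[500]
        assert abs(spike_after) <= 0.5 * abs(spike_before)
        mask = np.ones(len(x), dtype=bool)
        mask[494:507] = False
        off_change = np.sqrt(np.mean((out - spiked)[mask] ** 2))
        assert off_change < 0.10 * np.sqrt(np.mean(x**2))

    def test_length_preserved_odd_sizes(self, rng):
        for t_len in (8, 100, 601, 2100):
            assert wavelet_despike(rng.standard_normal(t_len)).shape == (t_len,)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            wavelet_despike(np.zeros(7))

    def test_lambda_validation(self):
        with pytest.raises(ValueError):
            wavelet_despike(np.zeros(64), lam=0.0)


class TestBandpass:
    def test_dc_rejection(self):
        out = bandpass(np.full(2000, 5.0), fs=FS)
        assert np.abs(out[100:-100]).max() < 1e-8

    def test_passband_gain(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 0.04 * t)
        out = bandpass(x, fs=FS)
        mid = slice(1000, 3000)
        gain = out[mid].std() / x[mid].std()
        assert 0.9 <= gain <= 1.1

    def test_cardiac_band_attenuation(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        out = bandpass(x, fs=FS)
        assert np.abs(out[1000:3000]).max() < 0.1

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), band=(0.08, 0.01), fs=FS)
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), band=(0.01, 5.0), fs=FS)


class TestShortChannelRegress:
    def test_perfect_fit_zero_residual(self, rng):
        s = rng.standard_normal(200)
        res = short_channel_regress(s, s)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_orthogonal_long_passthrough(self):
        t = np.arange(256)
        shorts = np.column_stack([np.sin(2 * np.pi * t / 256), np.cos(2 * np.pi * t / 256)])
        long = np.sin(2 * np.pi * 5 * t / 256) + 2.0  # orthogonal + offset
        res = short_channel_regress(long, shorts)
        np.testing.assert_allclose(res, long - long.mean(), atol=1e-10)

    def test_residual_orthogonality(self, rng):
        shorts = rng.standard_normal((300, 3))
        long = 2.0 * shorts[:, 0] + rng.standard_normal(300)
        res = short_channel_regress(long, shorts)
        for j in range(3):
            num = abs(np.dot(res, shorts[:, j] - shorts[:, j].mean()))
            denom = np.linalg.norm(res) * np.linalg.norm(shorts[:, j])
            assert num / denom < 1e-8

    def test_rank_deficient_warns(self, rng):
        s = rng.standard_normal(100)
        shorts = np.column_stack([s, s])  # duplicated regressor
        with pytest.warns(RuntimeWarning):
            short_channel_regress(rng.standard_normal(100), shorts)

    def test_too_few_frames(self, rng):
        with pytest.raises(DataError):
            short_channel_regress(np.zeros(3), rng.standard_normal((3, 2)))


def recovery_config(seed, superficial=0.0, t_frames=3000):
    onsets = tuple(np.arange(10.0, t_frames / FS - 30.0, 35.0))
    return SimulationConfig(
        n_participants=4,
        n_long_channels=3,
        n_short_channels=2,
        n_frames=t_frames,
        fs=FS,
        ar_coefficient=0.3,
        event_onsets=onsets,
        event_duration=15.0,
        responsive_channels=(0, 1, 2),
        effect_size=10.0,
        gain_jitter=0.0,
        superficial_amplitude=superficial,
        seed=seed,
    )


def recovery_correlations(group, truth, fs):
    ref = bandpass(truth.clean_signals[:, 0], fs=fs)
    return np.array(
        [
            np.corrcoef(group.data[p][:, c], ref)[0, 1]
            for p in range(group.n_participants)
            for c in range(group.n_channels)
        ]
    )


class TestPipeline:
    def test_output_unit_variance(self):
        recordings, _ = simulate_raw(recovery_config(0, t_frames=800))
        group = preprocess_pipeline(recordings)
        for p in range(group.n_participants):
            np.testing.assert_allclose(
                group.data[p].var(axis=0, ddof=1), 1.0, atol=1e-8
            )

    def test_confound_free_recovery(self):
        config = recovery_config(1)
        recordings, truth = simulate_raw(config)
        group = preprocess_pipeline(recordings)
        corrs = recovery_correlations(group, truth, config.fs)
        assert corrs.mean() > 0.95
        assert corrs.min() > 0.9

    def test_short_regression_beats_no_regression_under_confound(self):
        config = recovery_config(2, superficial=5.0)
        recordings, truth = simulate_raw(config)
        with_reg = preprocess_pipeline(recordings, PreprocessConfig(short_regression=True))
        without = preprocess_pipeline(recordings, PreprocessConfig(short_regression=False))
        assert recovery_correlations(with_reg, truth, config.fs).mean() > (
            recovery_correlations(without, truth, config.fs).mean()
        )

    def test_unequal_lengths_truncated(self):
        recordings, _ = simulate_raw(recovery_config(3, t_frames=512))
        short_rec = recordings[1]
        short_rec.intensities = short_rec.intensities[:500]
        group = preprocess_pipeline(recordings)
        assert group.n_frames == 500

    def test_geometry_mismatch_rejected(self):
        recordings, _ = simulate_raw(recovery_config(4, t_frames=256))
        recordings[1].channels[0].channel_id = "rogue"
        with pytest.raises(DataError, match="geometry"):
            preprocess_pipeline(recordings)

    def test_stage_errors_name_participant(self):
        recordings, _ = simulate_raw(recovery_config(5, t_frames=256))
        with pytest.raises(DataError):
            bad = recordings[0].intensities.copy()
            bad[5, 0] = -1.0
            recordings[0].intensities = bad
            preprocess_pipeline(recordings)


class TestPreprocessConfig:
    def test_band_validation(self):
        with pytest.raises(ConfigError):
            PreprocessConfig(band=(0.08, 0.01))

    def test_extinction_validation(self):
        with pytest.raises(ConfigError):
            PreprocessConfig(extinction=np.ones((2, 2)))

    def test_chromophore_validation(self):
        with pytest.raises(ConfigError):
            PreprocessConfig(chromophore="melanin")
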