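import numpy as np
import pytest

from scorploc import (
    ChannelMismatch,
    MultichannelRecording,
    SceneConfigError,
    SineWaveform,
    SourceTrajectory,
    default_benchmark_scene,
    make_geometry,
    propagation_delay,
    render_scene,
)
from scorploc.waveforms import BurstWaveform, SampledWaveform


def _static(bearing, duration=0.25):
    return SourceTrajectory(kind="static", start_bearing_deg=bearing, duration_s=duration)


class TestTrajectory:
    def test_rotating_ground_truth(self):
        traj = SourceTrajectory(kind="rotating", start_bearing_deg=0.0, angular_speed_dps=18.0)
        assert traj.bearing_at(10.0) == pytest.approx(180.0)
        assert traj.bearing_at(0.0) == pytest.approx(0.0)

    def test_stepwise_dwells(self):
        traj = SourceTrajectory(kind="stepwise", duration_s=20.0)
        np.testing.assert_allclose(traj.bearing_at([2.0, 7.0, 12.0, 17.0]), [0, 90, 180, 270])

    def test_inconsistent_dwells_rejected(self):
        with pytest.raises(SceneConfigError):
            SourceTrajectory(kind="stepwise", dwell_times_s=(5.0, 5.0), duration_s=20.0)


class TestRenderScene:
    def test_mirror_symmetric_channels(self, geometry8):
        rec = render_scene(
            geometry8, _static(0.0), SineWaveform(), ChannelMismatch.ideal(8), seed=0
        )
        np.testing.assert_array_equal(rec.channels[1], rec.channels[7])
        np.testing.assert_array_equal(rec.channels[2], rec.channels[6])

    def test_pure_noise_has_requested_std(self, geometry8):
        wav = SineWaveform(amplitude=0.0)
        mis = ChannelMismatch((1.0,) * 8, (0.0,) * 8, (0.3,) * 8)
        rec = render_scene(geometry8, _static(0.0), wav, mis, seed=1)
        np.testing.assert_allclose(rec.channels.std(axis=1), 0.3, rtol=0.05)
        # channels are mutually independent streams, not copies
        corr = np.corrcoef(rec.channels)
        assert np.max(np.abs(corr - np.eye(8))) < 0.05

    def test_same_seed_bit_identical(self, geometry8):
        mis = ChannelMismatch((1.0,) * 8, (0.0,) * 8, (0.1,) * 8)
        a = render_scene(geometry8, _static(10.0), SineWaveform(), mis, seed=7)
        b = render_scene(geometry8, _static(10.0), SineWaveform(), mis, seed=7)
        np.testing.assert_array_equal(a.channels, b.channels)

    def test_mismatch_length_checked(self, geometry8):
        bad = ChannelMismatch((1.0,) * 7, (0.0,) * 7, (0.0,) * 7)
        with pytest.raises(SceneConfigError):
            render_scene(geometry8, _static(0.0), SineWaveform(), bad, seed=0)

    def test_phase_realizes_geometric_delays(self, geometry8):
        """Measured inter-channel phase at the carrier matches tau_j exactly."""
        f = 1000.0
        rec = render_scene(
            geometry8, _static(30.0, 0.5), SineWaveform(frequency=f),
            ChannelMismatch.ideal(8), seed=0,
        )
        t = rec.times()
        probe = np.exp(-2j * np.pi * f * t)
        phases = np.angle(rec.channels @ probe)
        tau = propagation_delay(geometry8, 30.0, 1.0)
        for j in range(1, 8):
            measured = (phases[0] - phases[j]) / (2 * np.pi * f)
            expected = tau[j] - tau[0]
            # wrap to one carrier period
            diff = (measured - expected + 0.5 / f) % (1.0 / f) - 0.5 / f
            assert abs(diff) < 1e-9  # far below one 48 kHz sample (20.8 us)

    def test_rotational_equivariance(self, geometry8):
        """Source +45 deg and a one-step channel roll give the same scene."""
        base = render_scene(
            geometry8, _static(0.0), SineWaveform(), ChannelMismatch.ideal(8), seed=0
        )
        rot = render_scene(
            geometry8, _static(45.0), SineWaveform(), ChannelMismatch.ideal(8), seed=0
        )
        np.testing.assert_allclose(rot.channels, np.roll(base.channels, 1, axis=0), atol=1e-12)

    def test_equal_rms_at_constant_distance(self, geometry8):
        rec = render_scene(
            geometry8,
            SourceTrajectory(kind="rotating", duration_s=1.0),
            SineWaveform(),
            ChannelMismatch.ideal(8),
            seed=0,
        )
        rms = np.sqrt(np.mean(rec.channels**2, axis=1))
        np.testing.assert_allclose(rms, rms[0], rtol=1e-3)


class TestDefaultScene:
    def test_shape_and_truth_span(self):
        rec = default_benchmark_scene(seed=0, noise=False)
        assert rec.channels.shape == (8, 960000)
        assert rec.fs == 48000.0
        truth = rec.trajectory.bearing_at(rec.times()[:: 4800])
        assert truth.min() >= 0.0 and truth.max() < 360.0
        assert truth.max() > 350.0  # the sweep covers the full circle

    def test_noise_free_is_seed_independent(self):
        a = default_benchmark_scene(seed=1, noise=False)
        b = default_benchmark_scene(seed=2, noise=False)
        np.testing.assert_array_equal(a.channels, b.channels)


class TestIO:
    def test_wav_roundtrip(self, tmp_path, geometry8):
        rec = render_scene(
            geometry8, _static(0.0, 0.1), SineWaveform(), ChannelMismatch.ideal(8), seed=0
        )
        rec.to_wav(tmp_path / "scene.wav")
        back = MultichannelRecording.from_wav(tmp_path / "scene.wav")
        assert back.fs == rec.fs
        assert back.channels.shape == rec.channels.shape
        np.testing.assert_allclose(back.channels, rec.channels, atol=1e-6)

    def test_truth_csv(self, tmp_path, geometry8):
        rec = render_scene(
            geometry8,
            SourceTrajectory(kind="rotating", duration_s=1.0),
            SineWaveform(),
            ChannelMismatch.ideal(8),
            seed=0,
        )
        rec.write_truth_csv(tmp_path / "truth.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "truth.csv")
        assert list(df.columns) == ["time_s", "bearing_deg", "distance_m"]
        assert df["bearing_deg"].iloc[0] == pytest.approx(0.0)


class TestWaveforms:
    def test_burst_silent_intervals(self):
        wav = BurstWaveform(on_intervals=((0.0, 16.0), (17.0, 20.0)))
        assert wav.silent_intervals(20.0) == [(16.0, 17.0)]
        t = np.array([8.0, 16.5])
        out = wav.evaluate(t)
        assert out[1] == 0.0 and abs(out[0]) >= 0.0

    def test_sampled_waveform_reconstructs_sine(self):
        fs = 48000.0
        n = np.arange(4096)
        samples = np.sin(2 * np.pi * 1000.0 * n / fs)
        wav = SampledWaveform(samples, fs=fs)
        # evaluate at quarter-sample offsets well inside the support
        t = (n[64:-64] + 0.25) / fs
        expected = np.sin(2 * np.pi * 1000.0 * t)
        assert np.max(np.abs(wav.evaluate(t) - expected)) < 1e-4

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            SineWaveform(frequency=30000.0, fs=48000.0)
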