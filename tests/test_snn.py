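import numpy as np
import pytest

from scorploc import (
    ChannelMismatch,
    ModelConfig,
    MultichannelRecording,
    SimulationConfigError,
    SineWaveform,
    SourceTrajectory,
    TopologyError,
    build_network,
    make_geometry,
    max_interleg_delay,
    normalize_channels,
    render_scene,
    simulate,
    triad,
)
from scorploc.snn import resolve_config


@pytest.fixture(scope="module")
def clean_norm(geometry8):
    """Normalized clean static scene from bearing 0 (1 s)."""
    traj = SourceTrajectory(kind="static", start_bearing_deg=0.0, duration_s=1.0)
    rec = render_scene(
        geometry8, traj, SineWaveform(frequency=1000.0), ChannelMismatch.ideal(8), seed=0
    )
    norm, _ = normalize_channels(rec)
    return norm


class TestTriad:
    def test_opposite_triads(self):
        # with legs ordered R1..R4,L4..L1, leg 3 = R3 opposes L3,L2,L1
        assert triad(3) == {6, 7, 8}
        assert triad(7) == {2, 3, 4}
        assert triad(1) == {4, 5, 6}

    def test_symmetric_relation(self):
        for k in range(1, 9):
            for j in range(1, 9):
                assert (j in triad(k)) == (k in triad(j))

    @pytest.mark.parametrize("n", [4, 6, 16])
    def test_non_eight_leg_layouts_rejected(self, n):
        with pytest.raises(TopologyError):
            triad(1, n_legs=n)


class TestBuildNetwork:
    def test_edge_counts(self, geometry8):
        net = build_network(geometry8)
        assert len(net.exc_edges) == 8
        assert len(net.inh_edges) == 24
        # every command receives exactly 3 inhibitory edges
        per_cmd = np.bincount([c for _, c in net.inh_edges], minlength=8)
        assert (per_cmd == 3).all()

    def test_circulant_topology(self, geometry8):
        net = build_network(geometry8)
        rotated = {((l + 1) % 8, (c + 1) % 8) for l, c in net.inh_edges}
        assert rotated == set(net.inh_edges)

    def test_resolved_constants(self, geometry8):
        rcfg = resolve_config(ModelConfig(), geometry8, fs=48000.0)
        aperture = max_interleg_delay(geometry8)
        assert rcfg.inh_delay == pytest.approx(0.7 * aperture)
        assert rcfg.inh_delay == pytest.approx(183.7e-6, rel=1e-3)
        assert rcfg.refractory == pytest.approx(aperture)
        assert rcfg.dt == pytest.approx(1.0 / 48000.0)

    def test_refractory_fraction_mode(self, geometry8):
        rcfg = resolve_config(
            ModelConfig(refractory_fraction=0.15), geometry8, fs=48000.0, window_length=0.5
        )
        assert rcfg.refractory == pytest.approx(0.075)


class TestSimulate:
    def test_zero_input_is_silent(self, geometry8, deterministic_model):
        rec = MultichannelRecording(
            fs=48000.0, channels=np.zeros((8, 24000)), geometry=geometry8
        )
        net = build_network(geometry8, deterministic_model)
        spikes = simulate(net, rec, seed=0)
        assert spikes.counts().sum() == 0

    def test_nearest_command_neuron_dominates(self, geometry8, clean_norm, deterministic_model):
        """Core mechanism: source at sensor 1's bearing -> command 1 fires most,
        and the opposite triad is almost silent."""
        net = build_network(geometry8, deterministic_model)
        counts = simulate(net, clean_norm, seed=0).counts()
        assert counts[0] == counts.max()
        assert counts[[3, 4, 5]].max() < 0.05 * counts[0]

    def test_rotational_equivariance(self, geometry8, clean_norm, deterministic_model):
        net = build_network(geometry8, deterministic_model)
        base = simulate(net, clean_norm, seed=0)
        for m in (1, 3):
            shifted = MultichannelRecording(
                fs=clean_norm.fs,
                channels=np.roll(clean_norm.channels, m, axis=0),
                geometry=geometry8,
            )
            out = simulate(net, shifted, seed=0)
            for j in range(8):
                np.testing.assert_array_equal(out.trains[(j + m) % 8], base.trains[j])

    @pytest.mark.parametrize("model_kwargs", [{}, {"refractory_fraction": 0.05}])
    def test_refractory_contract(self, geometry8, clean_norm, model_kwargs):
        cfg = ModelConfig(**model_kwargs)
        net = build_network(geometry8, cfg)
        spikes = simulate(net, clean_norm, seed=3)
        refractory = spikes.config.refractory
        for train in spikes.trains:
            if len(train) > 1:
                assert np.diff(train).min() >= refractory - 1e-12
                assert (np.diff(train) > 0).all()

    def test_inhibition_only_suppresses(self, geometry8, clean_norm, deterministic_model):
        """Removing inhibition never lowers any command count; the opposite
        triad fires strictly less with inhibition on."""
        with_inh = simulate(build_network(geometry8, deterministic_model), clean_norm, seed=0)
        no_inh_cfg = ModelConfig(sensory_noise_sigma=0.0, w_inh=0.0)
        without = simulate(build_network(geometry8, no_inh_cfg), clean_norm, seed=0)
        assert (without.counts() >= with_inh.counts()).all()
        assert (with_inh.counts()[[3, 4, 5]] < without.counts()[[3, 4, 5]]).all()

    def test_determinism(self, geometry8, clean_norm):
        net = build_network(geometry8, ModelConfig())
        a = simulate(net, clean_norm, seed=11)
        b = simulate(net, clean_norm, seed=11)
        for x, y in zip(a.trains, b.trains):
            np.testing.assert_array_equal(x, y)

    def test_unresolvable_delay_rejected(self, geometry8, clean_norm):
        cfg = ModelConfig(dt=1e-3)  # coarser than the 183.7 us inhibitory delay
        net = build_network(geometry8, cfg)
        with pytest.raises(SimulationConfigError):
            simulate(net, clean_norm, seed=0)

    def test_channel_count_checked(self, geometry8):
        rec = MultichannelRecording(
            fs=48000.0, channels=np.zeros((7, 100)), geometry=geometry8
        )
        net = build_network(geometry8)
        with pytest.raises(SimulationConfigError):
            simulate(net, rec, seed=0)

    def test_spike_csv_export(self, tmp_path, geometry8, clean_norm, deterministic_model):
        spikes = simulate(build_network(geometry8, deterministic_model), clean_norm, seed=0)
        spikes.to_csv(tmp_path / "spikes.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "spikes.csv")
        assert list(df.columns) == ["neuron_id", "spike_time_s"]
        assert len(df) == spikes.counts().sum()
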