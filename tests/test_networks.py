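"""Architecture builders, dense/spiking executors, activation quantizer."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from spikedenoise.networks import (
    LayerSpec,
    build_cae,
    build_dncnn,
    build_dnsnn,
    count_parameters,
    load_network,
    run_ann_inference,
    run_snn_inference,
    save_network,
    uniform_quantize_activation,
)
from spikedenoise.neurons import NeuronParams


def _identity_snn(v_th=1.0, T=4):
    """conv(identity) -> ATIF -> conv(identity) readout."""
    net = build_dnsnn(depth=2, filters=1, neuron_params=NeuronParams(v_th=v_th),
                      T=T, seed=0)
    for layer in net.layers:
        layer.W[:] = 0.0
        layer.W[0, 0, 1, 1] = 1.0
        layer.b[:] = 0.0
    return net


class TestBuilders:
    def test_dncnn_parameter_count(self):
        # 640 + 15 * 36,928 + 577
        assert count_parameters(build_dncnn(17, 64)) == 555_137

    def test_dnsnn_adds_one_threshold_per_spiking_layer(self):
        assert count_parameters(build_dnsnn(17, 64)) == 555_137 + 16

    def test_minimal_depth_and_validation(self):
        net = build_dncnn(2, 1)
        assert len(net.layers) == 2
        assert sum(l.activation == "relu" for l in net.layers) == 1
        with pytest.raises(ValueError):
            build_dncnn(1, 1)

    def test_output_preserves_shape(self, rng):
        net = build_dncnn(3, 4, seed=1)
        for size in ((11, 13), (8, 8)):
            assert run_ann_inference(net, rng.uniform(0, 1, size)).shape == size

    def test_cae_bottleneck_and_divisibility(self, rng):
        net = build_cae(spiking=False, filters=4, seed=0)
        kinds = [l.kind for l in net.layers]
        assert kinds == ["conv"] + ["conv_down"] * 3 + ["conv_up"] * 3 + ["conv"]
        y = rng.uniform(0, 1, (64, 64))
        assert run_ann_inference(net, y).shape == (64, 64)
        with pytest.raises(ValueError):
            run_ann_inference(net, rng.uniform(0, 1, (44, 44)))

    def test_layer_spec_invariants(self):
        with pytest.raises(ValueError):
            LayerSpec("conv", 1, 4, kernel=4)
        with pytest.raises(ValueError):
            LayerSpec("conv", 1, 4, stride=2)
        with pytest.raises(ValueError):
            LayerSpec("conv_down", 1, 4, stride=1)


class TestAnnInference:
    def test_zero_weight_net_outputs_zero_residual(self, small_image):
        net = build_dncnn(3, 2, seed=0)
        for layer in net.layers:
            layer.W[:] = 0.0
            layer.b[:] = 0.0
        assert np.allclose(run_ann_inference(net, small_image), 0.0)

    def test_rejects_spiking_network(self, small_image):
        with pytest.raises(ValueError):
            run_ann_inference(build_dnsnn(3, 2), small_image)

    def test_matches_direct_convolution_oracle(self, rng):
        """Single layer against scipy's correlate2d on a 5x5 image."""
        net = build_dncnn(2, 3, seed=5)
        y = rng.uniform(0, 1, (5, 5))
        out = run_ann_inference(net, y)
        hidden = np.stack([
            np.maximum(correlate2d(y, net.layers[0].W[c, 0], mode="same")
                       + net.layers[0].b[c], 0.0)
            for c in range(3)
        ])
        ref = sum(correlate2d(hidden[c], net.layers[1].W[0, c], mode="same")
                  for c in range(3)) + net.layers[1].b[0]
        assert np.allclose(out, ref, atol=1e-12)


class TestSnnInference:
    def test_identity_toy_decodes_exactly(self):
        """Constant 0.5 image through one unit-threshold ATIF layer at T=4
        decodes to 0.5 exactly (2 spikes / 4 steps, unit gain)."""
        net = _identity_snn(v_th=1.0, T=4)
        residual, stats = run_snn_inference(net, np.full((5, 5), 0.5))
        assert np.allclose(residual, 0.5)
        assert stats[0]["theta"] == 2.0
        assert stats[0]["theta_over_T"] == 0.5

    def test_zero_image_silent_network(self):
        net = _identity_snn()
        residual, stats = run_snn_inference(net, np.zeros((4, 4)))
        assert np.allclose(residual, 0.0)
        assert stats[0]["spike_total"] == 0.0

    def test_deterministic(self, small_image):
        net = build_dnsnn(3, 4, T=5, seed=3)
        r1, s1 = run_snn_inference(net, small_image, record_rasters=True)
        r2, s2 = run_snn_inference(net, small_image, record_rasters=True)
        assert np.array_equal(r1, r2)
        for a, b in zip(s1, s2):
            assert np.array_equal(a["raster"], b["raster"])

    def test_theta_bounded_by_T(self, small_image):
        net = build_dnsnn(4, 4, T=6, seed=2)
        _, stats = run_snn_inference(net, small_image)
        for s in stats:
            assert 0.0 <= s["theta"] <= 6.0
            assert 0.0 <= s["theta_over_T"] <= 1.0

    def test_residual_converges_as_latency_grows(self, small_image):
        """With frozen weights the residual approaches a fixed limit."""
        net = build_dnsnn(3, 4, T=1, seed=4)
        limit, _ = run_snn_inference(net, small_image, T=256)
        errs = [
            np.max(np.abs(run_snn_inference(net, small_image, T=T)[0] - limit))
            for T in (8, 32, 128)
        ]
        assert errs[2] < errs[0]
        assert errs[2] < 0.05

    def test_rejects_formal_net_and_bad_T(self, small_image):
        with pytest.raises(ValueError):
            run_snn_inference(build_dncnn(3, 2), small_image)
        with pytest.raises(ValueError):
            run_snn_inference(build_dnsnn(3, 2), small_image, T=0)


class TestUniformQuantizer:
    def test_level_count(self):
        x = np.linspace(-0.5, 2.0, 4001)
        out = uniform_quantize_activation(x, 4, 1 / 15)
        assert len(np.unique(out)) == 16

    def test_relu_floor_and_fixed_points(self):
        assert np.all(uniform_quantize_activation(
            np.array([-1.0, -0.01, 0.0]), 4, 0.1) == 0.0)
        grid = np.arange(10) * 0.1
        assert np.allclose(
            uniform_quantize_activation(grid, 4, 0.1), grid, atol=1e-12)

    def test_snn_equivalence_floor_mode(self):
        """One ATIF layer at latency T equals a floor quantizer with
        bitwidth log2(T+1) and step v_th/T on constant inputs in [0, v_th]."""
        v_th = 1.0
        for T, bits in ((1, 1), (7, 3), (15, 4)):
            net = _identity_snn(v_th=v_th, T=T)
            xs = np.linspace(0, v_th, 2 * T + 3)
            snn_out = np.array([
                run_snn_inference(net, np.full((3, 3), x))[0][0, 0] for x in xs
            ])
            q_out = uniform_quantize_activation(xs, bits, v_th / T,
                                                rounding="floor")
            assert np.allclose(snn_out, q_out, atol=1e-12)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            uniform_quantize_activation(np.zeros(2), 0, 0.1)
        with pytest.raises(ValueError):
            uniform_quantize_activation(np.zeros(2), 2, 0.0)


def test_round_trip_serialization(tmp_path, small_image):
    net = build_dnsnn(3, 4, T=6, seed=8)
    path = tmp_path / "net.npz"
    save_network(net, str(path))
    loaded = load_network(str(path))
    r1, _ = run_snn_inference(net, small_image)
    r2, _ = run_snn_inference(loaded, small_image)
    assert np.array_equal(r1, r2)
    assert [l.v_th for l in loaded.layers] == [l.v_th for l in net.layers]
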