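"""Event counting and energy estimation for dense and spiking networks."""

import numpy as np
import pytest

from spikedenoise.energy import (
    EnergyTable,
    count_ann,
    count_snn,
    estimate_energy,
)
from spikedenoise.networks import build_dncnn, build_dnsnn
from spikedenoise.neurons import NeuronParams


def _snn_spikes(net, theta_over_T, T, side):
    """Spike totals for every ATIF layer at a given firing fraction."""
    return [theta_over_T * T * l.filters * side * side
            for l in net.layers if l.activation == "atif"]


class TestCounts:
    def test_single_layer_mac_count(self):
        net = build_dncnn(2, 1, seed=0)
        counts = count_ann(net, (4, 4))
        # first layer: 16 output px * 9-tap fan-in = 144 MACs
        assert counts[0]["synaptic_ops"] == 144
        assert counts[0]["mem_reads"] == 2 * 144
        assert counts[0]["mem_writes"] == 16
        assert counts[0]["addr_events"] == 144

    def test_counts_scale_with_pixels(self):
        net = build_dncnn(3, 4, seed=0)
        c8 = count_ann(net, (8, 8))
        c16 = count_ann(net, (16, 16))
        for a, b in zip(c8, c16):
            assert b["synaptic_ops"] == 4 * a["synaptic_ops"]

    def test_snn_hand_counted_toy(self):
        """Hidden layer emits 3 spikes; the next conv has fan-out
        2 filters x 1x1 kernel = 2, so 6 ACCs and 6 weight reads."""
        from spikedenoise.networks import LayerSpec, NetworkSpec

        rng = np.random.default_rng(0)
        layers = [
            LayerSpec("conv", 1, 1, 1, 1, "atif",
                      rng.normal(size=(1, 1, 1, 1)), np.zeros(1)),
            LayerSpec("conv", 1, 2, 1, 1, "none",
                      rng.normal(size=(2, 1, 1, 1)), np.zeros(2)),
        ]
        net = NetworkSpec(layers=layers, T=3, mode="spiking")
        counts = count_snn(net, [3.0], 3, (2, 2))
        out = counts[1]
        assert out["op_kind"] == "acc"
        assert out["synaptic_ops"] == 6
        assert out["mem_reads"] == 2 * 6 + (2 * 2 * 2) * 3  # + threshold checks
        assert out["addr_events"] == 6

    def test_snn_ops_linear_in_spikes(self):
        net = build_dnsnn(4, 8, NeuronParams(), T=4, seed=0)
        s1 = _snn_spikes(net, 0.2, 4, 16)
        s2 = [2 * s for s in s1]
        c1 = count_snn(net, s1, 4, (16, 16))
        c2 = count_snn(net, s2, 4, (16, 16))
        for a, b in zip(c1[1:], c2[1:]):  # conv1 is dense, excluded
            assert b["synaptic_ops"] == 2 * a["synaptic_ops"]

    def test_snn_requires_spike_stats(self):
        net = build_dnsnn(3, 4, NeuronParams(), T=2, seed=0)
        with pytest.raises(ValueError):
            count_snn(net, None, 2, (8, 8))
        with pytest.raises(ValueError):
            count_snn(net, [1.0], 2, (8, 8))


class TestEstimate:
    def test_zero_counts_zero_energy(self):
        report = estimate_energy([], EnergyTable())
        assert report.totals["e_total"] == 0.0

    def test_unit_table_sums_counts(self):
        counts = [{"layer": 0, "op_kind": "mac", "synaptic_ops": 10,
                   "mem_reads": 20, "mem_writes": 5, "addr_events": 10}]
        table = EnergyTable(e_mac=1.0, e_acc=1.0, e_mem_read=1.0,
                            e_mem_write=1.0, e_addr=1.0)
        report = estimate_energy(counts, table)
        assert report.totals["e_total"] == pytest.approx(45 / 1e3)

    def test_energy_linear_in_table(self):
        net = build_dncnn(3, 4, seed=0)
        counts = count_ann(net, (8, 8))
        e1 = estimate_energy(counts, EnergyTable()).totals["e_total"]
        doubled = EnergyTable(9.2, 1.8, 10.0, 10.0, 1.8)
        e2 = estimate_energy(counts, doubled).totals["e_total"]
        assert e2 == pytest.approx(2 * e1)

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            EnergyTable(e_mac=1.0, e_acc=2.0)
        with pytest.raises(ValueError):
            EnergyTable(e_mem_read=-1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_energy([{"layer": 0, "op_kind": "mac",
                              "synaptic_ops": -1, "mem_reads": 0,
                              "mem_writes": 0, "addr_events": 0}])


class TestTrends:
    def test_ann_energy_is_latency_invariant(self):
        net = build_dncnn(4, 8, seed=0)
        counts = count_ann(net, (32, 32))
        e = estimate_energy(counts).totals["e_total"]
        assert e == estimate_energy(count_ann(net, (32, 32))).totals["e_total"]
        assert "T" not in {k for c in counts for k in c}  # counts carry no T

    def test_snn_energy_increases_with_latency_at_fixed_rate(self):
        side, theta_over_T = 32, 0.3
        energies = []
        for T in (1, 2, 4, 8):
            net = build_dnsnn(4, 8, NeuronParams(), T=T, seed=0)
            spikes = _snn_spikes(net, theta_over_T, T, side)
            counts = count_snn(net, spikes, T, (side, side))
            energies.append(
                estimate_energy(counts, mode="snn", T=T).totals["e_total"])
        assert all(a < b for a, b in zip(energies, energies[1:]))

    def test_acc_energy_beats_mac_energy_on_matched_network(self):
        """Sparse event-driven synaptic energy undercuts the dense MAC
        energy whenever theta * e_acc < K * e_mac (theta/T ~ 0.3)."""
        side, T = 32, 2
        table = EnergyTable()
        ann = build_dncnn(4, 8, seed=0)
        snn = build_dnsnn(4, 8, NeuronParams(), T=T, seed=0)
        spikes = _snn_spikes(snn, 0.3, T, side)
        e_ann = estimate_energy(count_ann(ann, (side, side)), table)
        e_snn = estimate_energy(count_snn(snn, spikes, T, (side, side)), table)
        # compare the spike-driven layers only (conv1 is dense in both)
        ops_ann = sum(c["e_ops"] for c in e_ann.per_layer[1:])
        ops_snn = sum(c["e_ops"] for c in e_snn.per_layer[1:])
        assert ops_snn < ops_ann

    def test_memory_dominates_total_energy(self):
        T = 2
        net = build_dnsnn(6, 16, NeuronParams(), T=T, seed=0)
        spikes = _snn_spikes(net, 0.3, T, 32)
        report = estimate_energy(count_snn(net, spikes, T, (32, 32)),
                                 mode="snn", T=T)
        assert report.totals["e_mem"] > report.totals["e_ops"]
        assert report.totals["e_mem"] > report.totals["e_addr"]

    def test_snn_ann_ratio_decreases_with_network_width(self):
        """With the measured firing fractions of wider networks (which
        decrease with width), the SNN/ANN total-energy ratio falls."""
        theta_over_T = {64: 0.422, 96: 0.407, 128: 0.366, 160: 0.342}
        side, T = 16, 2
        ratios = []
        for filters, rate in theta_over_T.items():
            ann = build_dncnn(4, filters, seed=0)
            snn = build_dnsnn(4, filters, NeuronParams(), T=T, seed=0)
            spikes = _snn_spikes(snn, rate, T, side)
            e_ann = estimate_energy(count_ann(ann, (side, side)))
            e_snn = estimate_energy(count_snn(snn, spikes, T, (side, side)))
            ratios.append(e_snn.totals["e_total"] / e_ann.totals["e_total"])
        assert all(a > b for a, b in zip(ratios, ratios[1:]))
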