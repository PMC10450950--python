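"""Hardware-independent energy estimation for formal and spiking networks.

The estimate counts three event classes per layer -- synaptic operations,
memory accesses, and element addressing -- and multiplies each count by a
configurable per-event energy.  Dense (formal) layers perform one
multiply-accumulate (MAC) per synapse per inference; event-driven spiking
layers perform one accumulate (ACC) per received spike per outgoing
synapse, so their operation count scales with the network activity rather
than with the architecture alone.

Counting contract
-----------------
Every layer owns a local (non-shared) SRAM holding its parameters, its
activation buffer and, for spiking layers, the membrane potentials
(32-bit words for both).

Formal layer with N output elements and fan-in K (= in_channels * k^2):
  synaptic ops  : N*K MACs
  memory reads  : N*K weight reads + N*K input-activation reads
  memory writes : N (output buffer)
  addressing    : N*K (one per synaptic op)

Spiking layer receiving S input spike events, each fanning out to
F = out_channels * k^2 synapses, run for T timesteps over N neurons:
  synaptic ops  : S*F ACCs
  memory reads  : S*F weight reads + S*F membrane reads
                  + N*T membrane reads (threshold checks)
  memory writes : S*F membrane writes + (spikes emitted) writes
  addressing    : S*F (one per synaptic op)
The first convolution sees the analog image, so it is charged as a formal
layer once per timestep.

The default energy table uses the standard 45 nm per-operation estimates
(FP32 multiply-add 4.6 pJ, add 0.9 pJ, local SRAM word access 5 pJ,
addressing 0.9 pJ); all entries are configurable, and only relative trends
are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import NetworkSpec, _out_size

__all__ = [
    "EnergyTable",
    "EnergyReport",
    "count_ann",
    "count_snn",
    "estimate_energy",
]


@dataclass
class EnergyTable:
    """Per-event energies in pJ.  ``e_acc <= e_mac`` is the premise of the
    accumulate-vs-MAC saving of event-driven hardware."""

    e_mac: float = 4.6
    e_acc: float = 0.9
    e_mem_read: float = 5.0
    e_mem_write: float = 5.0
    e_addr: float = 0.9

    def __post_init__(self) -> None:
        for name in ("e_mac", "e_acc", "e_mem_read", "e_mem_write", "e_addr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.e_acc > self.e_mac:
            raise ValueError("e_acc must not exceed e_mac")


@dataclass
class EnergyReport:
    """Counts and energies (nJ) per layer and in total."""

    mode: str
    T: int
    per_layer: list = field(default_factory=list)
    totals: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"mode": self.mode, "T": self.T,
                "per_layer": self.per_layer, "totals": self.totals}

    def table(self) -> str:
        hdr = (f"{'layer':>5} {'kind':>8} {'syn_ops':>14} {'mem_reads':>14} "
               f"{'mem_writes':>14} {'addr':>14} {'e_total[nJ]':>14}")
        rows = [hdr]
        for e in self.per_layer:
            rows.append(
                f"{e['layer']:>5} {e['op_kind']:>8} {e['synaptic_ops']:>14.0f} "
                f"{e['mem_reads']:>14.0f} {e['mem_writes']:>14.0f} "
                f"{e['addr_events']:>14.0f} {e.get('e_total', 0.0):>14.3f}"
            )
        t = self.totals
        rows.append(
            f"{'total':>5} {'':>8} {t['synaptic_ops']:>14.0f} "
            f"{t['mem_reads']:>14.0f} {t['mem_writes']:>14.0f} "
            f"{t['addr_events']:>14.0f} {t.get('e_total', 0.0):>14.3f}"
        )
        return "\n".join(rows)


def _layer_geometry(net: NetworkSpec, input_size) -> list:
    """Spatial output size, N (output elements) and K (fan-in) per layer."""
    h, w = input_size
    geo = []
    for layer in net.layers:
        if layer.kind == "conv_up":
            oh, ow = h * layer.stride, w * layer.stride
        else:
            oh, ow = _out_size(h, layer.kernel, layer.stride), \
                _out_size(w, layer.kernel, layer.stride)
        geo.append({
            "layer": len(geo),
            "out_hw": (oh, ow),
            "N": layer.filters * oh * ow,
            "K": layer.in_channels * layer.kernel**2,
            "fan_out": layer.filters * layer.kernel**2,
        })
        h, w = oh, ow
    return geo


def count_ann(net: NetworkSpec, input_size) -> list:
    """Dense per-layer event counts for a formal network (T-independent)."""
    if net.mode != "formal":
        raise ValueError("count_ann requires a formal-mode network")
    counts = []
    for g in _layer_geometry(net, input_size):
        nk = g["N"] * g["K"]
        counts.append({
            "layer": g["layer"], "op_kind": "mac",
            "synaptic_ops": nk,
            "mem_reads": 2 * nk,
            "mem_writes": g["N"],
            "addr_events": nk,
        })
    return counts


def count_snn(net: NetworkSpec, per_layer_spike_totals, T: int,
              input_size) -> list:
    """Event-driven per-layer counts for a spiking network.

    ``per_layer_spike_totals`` are the spike totals of each ATIF layer as
    reported by ``run_snn_inference`` (one entry per spiking layer, in
    order).  Layer l >= 2 receives the spikes of the previous spiking
    layer; the first convolution is charged densely once per timestep.
    """
    if net.mode != "spiking":
        raise ValueError("count_snn requires a spiking-mode network")
    spiking_idx = [i for i, l in enumerate(net.layers)
                   if l.activation == "atif"]
    if per_layer_spike_totals is None or \
            len(per_layer_spike_totals) != len(spiking_idx):
        raise ValueError(
            f"need one spike total per spiking layer "
            f"({len(spiking_idx)}), got {per_layer_spike_totals!r}"
        )
    spikes_of = dict(zip(spiking_idx, [float(s) for s in per_layer_spike_totals]))

    geo = _layer_geometry(net, input_size)
    counts = []
    prev_spiking = None
    for i, layer in enumerate(net.layers):
        g = geo[i]
        if prev_spiking is None:
            # analog input: dense MACs, repeated every timestep
            nk = g["N"] * g["K"] * T
            entry = {
                "layer": i, "op_kind": "mac",
                "synaptic_ops": nk,
                "mem_reads": 2 * nk,
                "mem_writes": g["N"] * T,
                "addr_events": nk,
            }
        else:
            s_in = spikes_of[prev_spiking]
            ops = s_in * g["fan_out"]
            entry = {
                "layer": i, "op_kind": "acc",
                "synaptic_ops": ops,
                # weight read + membrane read per ACC, plus threshold checks
                "mem_reads": 2 * ops + g["N"] * T,
                "mem_writes": ops + spikes_of.get(i, 0.0),
                "addr_events": ops,
            }
        if layer.activation == "atif":
            # spike-emission writes for this layer's own neurons
            entry["mem_writes"] += spikes_of[i]
            prev_spiking = i
        counts.append(entry)
    return counts


def estimate_energy(counts, table: EnergyTable = None,
                    mode: str = None, T: int = 1) -> EnergyReport:
    """Multiply event counts by per-event energies; totals in nJ."""
    table = table or EnergyTable()
    per_layer = []
    totals = {k: 0.0 for k in ("synaptic_ops", "mem_reads", "mem_writes",
                               "addr_events", "e_ops", "e_mem", "e_addr",
                               "e_total")}
    for c in counts:
        for key in ("synaptic_ops", "mem_reads", "mem_writes", "addr_events"):
            if c[key] < 0:
                raise ValueError(f"negative count {key} in layer {c['layer']}")
        e_op = table.e_mac if c["op_kind"] == "mac" else table.e_acc
        e_ops = c["synaptic_ops"] * e_op / 1e3
        e_mem = (c["mem_reads"] * table.e_mem_read
                 + c["mem_writes"] * table.e_mem_write) / 1e3
        e_addr = c["addr_events"] * table.e_addr / 1e3
        entry = dict(c)
        entry.update(e_ops=e_ops, e_mem=e_mem, e_addr=e_addr,
                     e_total=e_ops + e_mem + e_addr)
        per_layer.append(entry)
        for key in ("synaptic_ops", "mem_reads", "mem_writes", "addr_events"):
            totals[key] += c[key]
        totals["e_ops"] += e_ops
        totals["e_mem"] += e_mem
        totals["e_addr"] += e_addr
        totals["e_total"] += entry["e_total"]
    return EnergyReport(mode=mode or "ann", T=T, per_layer=per_layer,
                        totals=totals)
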