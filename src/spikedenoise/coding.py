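"""Image <-> spike conversion and the minimal threshold-compensation network.

Covers the constant-current (direct) encoder used by the spiking denoiser,
the stochastic Poisson rate encoder, the integrate-without-fire readout,
and a three-neuron reference network demonstrating threshold scaling with
gain compensation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .neurons import MembraneState, NeuronParams, if_step

__all__ = [
    "SpikeRaster",
    "MinimalNetwork",
    "encode_constant",
    "encode_poisson",
    "readout_accumulate",
    "scale_thresholds_and_compensate",
    "run_minimal_network",
    "conversion_error",
]


@dataclass
class SpikeRaster:
    """Binary spike events indexed ``[timestep, neuron...]``."""

    events: np.ndarray
    T: int

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events)
        if self.events.shape[0] != self.T:
            raise ValueError(
                f"raster has {self.events.shape[0]} timesteps, expected T={self.T}"
            )
        if not np.all((self.events == 0) | (self.events == 1)):
            raise ValueError("spike raster entries must be 0 or 1")

    def counts(self) -> np.ndarray:
        """Per-neuron spike totals over the inference."""
        return self.events.sum(axis=0)


@dataclass
class MinimalNetwork:
    """Two-layer, three-neuron network with a rate decoder.

    Hidden neurons 1 and 2 receive constant inputs ``x1``/``x2``; the output
    neuron receives the weighted hidden spikes; the decoder reads
    ``(count_3 / T) * w3 * v_th3``.
    """

    x1: float = 1.5
    x2: float = 1.2
    w1: float = 2.0
    w2: float = 3.0
    w3: float = 1.0
    bias: float = 0.0
    v_th1: float = 1.0
    v_th2: float = 1.0
    v_th3: float = 1.0
    T: int = 8

    def __post_init__(self) -> None:
        if min(self.v_th1, self.v_th2, self.v_th3) <= 0:
            raise ValueError("thresholds must be positive")
        if self.T < 1:
            raise ValueError("T must be >= 1")


def encode_constant(image, T: int) -> np.ndarray:
    """Repeat the image as the input current of each of ``T`` timesteps.

    Direct encoding: the analog image is presented unchanged at every step
    and the first convolutional layer's neurons perform the spike
    conversion.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    img = np.asarray(image, dtype=float)
    return np.broadcast_to(img, (int(T),) + img.shape).copy()


def encode_poisson(image, T: int, seed: int) -> SpikeRaster:
    """Poisson (Bernoulli-per-step) rate encoding of an image in [0, 1].

    Each pixel with intensity ``x_i`` spikes independently at each timestep
    with probability ``x_i``, an independent realization of a discrete-time
    Poisson process with rate ``x_i``.
    """
    img = np.asarray(image, dtype=float)
    if np.any(img < 0) or np.any(img > 1):
        raise ValueError("pixel values must lie in [0, 1] for Poisson encoding")
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    rng = np.random.default_rng(seed)
    events = (rng.random((int(T),) + img.shape) < img).astype(np.uint8)
    return SpikeRaster(events=events, T=int(T))


def readout_accumulate(currents) -> np.ndarray:
    """Integrate-without-fire readout: elementwise sum over timesteps.

    The readout neurons accumulate their input at every step and never
    spike; the membrane potential after the last step is the output.
    """
    seq = [np.asarray(c, dtype=float) for c in currents]
    if len(seq) == 0:
        raise ValueError("empty current sequence")
    shape = seq[0].shape
    for c in seq[1:]:
        if c.shape != shape:
            raise ValueError(f"shape mismatch: {c.shape} vs {shape}")
    return np.sum(seq, axis=0)


def scale_thresholds_and_compensate(
    net: MinimalNetwork, mode: str = "compensated"
) -> MinimalNetwork:
    """Set the firing thresholds to match the input ranges.

    ``compensated`` sets each hidden threshold to the layer's maximum input
    value and the output threshold to the ceiling of the formal output
    range, so that every quantization interval falls inside the operating
    range.  The gain each raised threshold introduces is compensated
    downstream: the output neuron's per-step current weights each hidden
    spike by ``w_i * v_th_i`` and the decoder applies the final gain
    ``w3 * v_th3`` (see :func:`run_minimal_network`).

    ``mismatched`` resets all thresholds to 1.
    """
    if mode == "mismatched":
        return replace(net, v_th1=1.0, v_th2=1.0, v_th3=1.0)
    if mode != "compensated":
        raise ValueError(f"unknown mode {mode!r}")
    hidden_max = max(net.x1 + net.bias, net.x2 + net.bias)
    if hidden_max <= 1.0:
        # inputs already inside the unit quantization range: nothing to fix
        return net
    formal_max = net.x1 * net.w1 + net.x2 * net.w2 + net.bias
    return replace(
        net,
        v_th1=hidden_max,
        v_th2=hidden_max,
        v_th3=float(math.ceil(formal_max)),
    )


def run_minimal_network(net: MinimalNetwork) -> dict:
    """Time-stepped simulation of the three-neuron network.

    Hidden neurons integrate their constant inputs; at each step the output
    neuron receives ``w1 * v_th1 * z1(t) + w2 * v_th2 * z2(t)`` (with unit
    thresholds this reduces to the plain weighted spikes).  The decoded
    output is ``(count_3 / T) * w3 * v_th3``.

    Returns a dict with per-neuron ``spike_counts``, the ``decoded`` value,
    ``total_spikes``, the ``formal`` (non-spiking) output and the absolute
    conversion error ``delta``.
    """
    T = net.T
    p1 = NeuronParams(v_th=net.v_th1)
    p2 = NeuronParams(v_th=net.v_th2)
    p3 = NeuronParams(v_th=net.v_th3)
    s1 = MembraneState.zeros(())
    s2 = MembraneState.zeros(())
    s3 = MembraneState.zeros(())
    z1 = z2 = z3 = 0
    raster = np.zeros((T, 3), dtype=np.uint8)
    for t in range(T):
        r1 = if_step(s1, np.asarray(net.x1 + net.bias), p1)
        r2 = if_step(s2, np.asarray(net.x2 + net.bias), p2)
        s1, s2 = r1.state, r2.state
        spike1, spike2 = float(r1.spikes), float(r2.spikes)
        current3 = (
            net.w1 * net.v_th1 * spike1 + net.w2 * net.v_th2 * spike2 + net.bias
        )
        r3 = if_step(s3, np.asarray(current3), p3)
        s3 = r3.state
        spike3 = float(r3.spikes)
        raster[t] = (spike1, spike2, spike3)
        z1 += int(spike1)
        z2 += int(spike2)
        z3 += int(spike3)

    decoded = (z3 / T) * net.w3 * net.v_th3
    formal = (net.x1 * net.w1 + net.x2 * net.w2 + net.bias) * net.w3
    return {
        "spike_counts": (z1, z2, z3),
        "decoded": decoded,
        "total_spikes": z1 + z2 + z3,
        "formal": formal,
        "delta": conversion_error(formal, decoded),
        "raster": SpikeRaster(events=raster, T=T),
    }


def conversion_error(formal: float, decoded: float) -> float:
    """Absolute difference between the formal and spike-decoded outputs."""
    return abs(formal - decoded)
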