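"""Quantization and denoising quality metrics.

SQNR of an encode/decode pass, spike sparsity theta, PSNR, and the
latency <-> bitwidth correspondence between spiking and quantized-ReLU
activations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .coding import SpikeRaster

__all__ = [
    "QuantReport",
    "sqnr",
    "sparsity_theta",
    "psnr",
    "bitwidth_for_latency",
    "delta_psnr",
]

#: Explicit sentinel for a zero-error comparison (infinite ratio in dB).
INF_DB = math.inf


@dataclass
class QuantReport:
    """SQNR and sparsity of a single encode/decode pass.

    ``theta`` counts spikes per neuron over the whole inference;
    ``theta_normalized`` = theta / T is the per-timestep firing fraction.
    """

    sqnr_db: float
    theta: float
    theta_normalized: float
    T: int
    v_th: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "sqnr_db": self.sqnr_db,
                "theta": self.theta,
                "theta_over_T": self.theta_normalized,
                "T": self.T,
                "v_th": self.v_th,
            }
        )


def sqnr(x, x_hat) -> float:
    """Signal-to-quantization-noise ratio in dB.

    ``10 log10(E[x^2] / E[(x - x_hat)^2])``.  Returns the ``inf`` sentinel
    when the reconstruction is exact; raises if the signal is identically
    zero (undefined signal power).
    """
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    p_sig = float(np.mean(x**2))
    if p_sig == 0.0:
        raise ValueError("signal is identically zero; SQNR undefined")
    p_err = float(np.mean((x - x_hat) ** 2))
    if p_err == 0.0:
        return INF_DB
    return 10.0 * math.log10(p_sig / p_err)


def sparsity_theta(raster: SpikeRaster, n: int, m: int) -> float:
    """Average spikes per neuron over one inference (theta).

    Total spike events across all timesteps divided by the ``n * m``
    neurons of the population.
    """
    events = np.asarray(raster.events)
    if events[0].size != n * m:
        raise ValueError(
            f"raster covers {events[0].size} neurons, expected {n}x{m}={n * m}"
        )
    return float(events.sum()) / (n * m)


def psnr(reference, test, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB between two images.

    ``10 log10(peak^2 / MSE)``; peak defaults to 1 for [0, 1]-normalized
    images.  Returns the ``inf`` sentinel on zero error.
    """
    ref = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return INF_DB
    return 10.0 * math.log10(peak**2 / mse)


def bitwidth_for_latency(T: int) -> float:
    """Equivalent activation bitwidth of a latency-``T`` spiking layer.

    A soft-reset IF neuron run for ``T`` steps provides ``T + 1``
    quantization levels, matching a ``log2(T + 1)``-bit uniform quantizer.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    return math.log2(T + 1)


def delta_psnr(a: float, b: float) -> float:
    """Absolute PSNR gap |a - b| in dB."""
    return abs(a - b)
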