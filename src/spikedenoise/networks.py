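"""Denoising network construction and execution.

Architectures
-------------
* ``build_dncnn`` -- the plain deep convolutional denoiser: ``depth``
  3x3 convolutional layers, ``filters`` channels, ReLU activations,
  residual output (the network predicts the noise).
* ``build_dnsnn`` -- the same topology with every ReLU replaced by a
  soft-reset ATIF spiking layer and an integrate-without-fire readout
  accumulating the last convolution over ``T`` timesteps.
* ``build_cae`` -- a multi-resolution convolutional autoencoder: three
  stride-2 down-sampling layers, three fractionally-strided up-sampling
  layers, dimension-preserving first and last layers.

Execution is numpy-only.  Convolutions use an im2col/col2im formulation
whose input/parameter gradients are exposed for the BPTT trainer in
:mod:`spikedenoise.training`; fractionally-strided convolution is the exact
adjoint of the stride-2 convolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .neurons import NeuronParams

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "build_dncnn",
    "build_dnsnn",
    "build_cae",
    "run_ann_inference",
    "run_snn_inference",
    "uniform_quantize_activation",
    "count_parameters",
    "save_network",
    "load_network",
]


# ---------------------------------------------------------------------------
# convolution primitives (batched, NCHW, "same" padding)
# ---------------------------------------------------------------------------

def _out_size(n: int, k: int, s: int) -> int:
    p = k // 2
    return (n + 2 * p - k) // s + 1


def _im2col(x: np.ndarray, k: int, s: int) -> np.ndarray:
    """(B, C, H, W) -> (C*k*k, B*oh*ow) column matrix, zero 'same' padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    B, C, oh, ow = win.shape[:4]
    return win.transpose(1, 4, 5, 0, 2, 3).reshape(C * k * k, B * oh * ow), (oh, ow)


def conv2d(x: np.ndarray, W: np.ndarray, b: Optional[np.ndarray] = None,
           stride: int = 1) -> np.ndarray:
    """Cross-correlation with zero 'same' padding; x (B,C,H,W), W (O,C,k,k)."""
    O, C, k, _ = W.shape
    cols, (oh, ow) = _im2col(x, k, stride)
    out = (W.reshape(O, -1) @ cols).reshape(O, x.shape[0], oh, ow)
    out = out.transpose(1, 0, 2, 3)
    if b is not None:
        out = out + b[None, :, None, None]
    return out


def conv2d_input_grad(dout: np.ndarray, W: np.ndarray, in_hw: tuple,
                      stride: int = 1) -> np.ndarray:
    """Adjoint of :func:`conv2d` with respect to its input (col2im scatter)."""
    O, C, k, _ = W.shape
    B = dout.shape[0]
    oh, ow = dout.shape[2], dout.shape[3]
    H, W_in = in_hw
    p = k // 2
    dflat = dout.transpose(1, 0, 2, 3).reshape(O, -1)
    dcols = (W.reshape(O, -1).T @ dflat).reshape(C, k, k, B, oh, ow)
    dxp = np.zeros((B, C, H + 2 * p, W_in + 2 * p), dtype=dout.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                dcols[:, i, j].transpose(1, 0, 2, 3)
    return dxp[:, :, p:p + H, p:p + W_in]


def conv2d_param_grad(dout: np.ndarray, x: np.ndarray, k: int,
                      stride: int = 1) -> tuple:
    """Gradients (dW, db) of :func:`conv2d` given upstream dout."""
    O = dout.shape[1]
    cols, _ = _im2col(x, k, stride)
    dflat = dout.transpose(1, 0, 2, 3).reshape(O, -1)
    dW = (dflat @ cols.T).reshape(O, x.shape[1], k, k)
    db = dout.sum(axis=(0, 2, 3))
    return dW, db


def conv2d_transpose(x: np.ndarray, W: np.ndarray, b: Optional[np.ndarray] = None,
                     stride: int = 2) -> np.ndarray:
    """Fractionally-strided convolution: exact adjoint of the stride-``s``
    'same' convolution, mapping (B, C, H, W) -> (B, O, s*H, s*W).

    ``W`` has shape (O, C, k, k) in the layer's own output-first convention.
    """
    O, C, k, _ = W.shape
    B, _, H, Wd = x.shape
    out = conv2d_input_grad(x, W.transpose(1, 0, 2, 3).copy(),
                            (stride * H, stride * Wd), stride)
    if b is not None:
        out = out + b[None, :, None, None]
    return out


# ---------------------------------------------------------------------------
# layer / network specifications
# ---------------------------------------------------------------------------

_KINDS = ("conv", "conv_down", "conv_up")
_ACTIVATIONS = ("atif", "relu", "quantized_relu", "none")


@dataclass
class LayerSpec:
    """One convolutional layer: geometry, activation kind, parameters."""

    kind: str
    in_channels: int
    filters: int
    kernel: int = 3
    stride: int = 1
    activation: str = "relu"
    W: np.ndarray = None
    b: np.ndarray = None
    v_th: float = 1.0            # ATIF firing threshold (per-layer scalar)
    bitwidth: int = 4            # quantized_relu parameters
    step: float = 1.0 / 15

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        if self.filters <= 0:
            raise ValueError("filters must be positive")
        if self.stride == 2 and self.kind == "conv":
            raise ValueError("stride 2 requires conv_down or conv_up")
        if self.kind in ("conv_down", "conv_up") and self.stride != 2:
            raise ValueError(f"{self.kind} requires stride 2")

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "conv_up":
            return conv2d_transpose(x, self.W, self.b, self.stride)
        return conv2d(x, self.W, self.b, self.stride)

    def input_grad(self, dout: np.ndarray, in_hw: tuple) -> np.ndarray:
        if self.kind == "conv_up":
            return conv2d(dout, self.W.transpose(1, 0, 2, 3).copy(),
                          None, self.stride)
        return conv2d_input_grad(dout, self.W, in_hw, self.stride)

    def param_grad(self, dout: np.ndarray, x: np.ndarray) -> tuple:
        if self.kind == "conv_up":
            dWt, _ = conv2d_param_grad(x, dout, self.kernel, self.stride)
            return dWt.transpose(1, 0, 2, 3), dout.sum(axis=(0, 2, 3))
        return conv2d_param_grad(dout, x, self.kernel, self.stride)

    def n_params(self) -> int:
        extra = 1 if self.activation == "atif" else 0
        return self.W.size + self.b.size + extra


@dataclass
class NetworkSpec:
    """Ordered layer list plus the execution mode and spiking latency."""

    layers: list
    T: int = 8
    mode: str = "formal"
    surrogate_slope: float = 4.0

    def __post_init__(self) -> None:
        if self.mode not in ("formal", "spiking"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.layers and self.layers[-1].activation != "none":
            raise ValueError("last layer must have activation 'none' (readout input)")

    @property
    def spiking_layers(self) -> list:
        return [l for l in self.layers if l.activation == "atif"]


def _he_init(rng: np.random.Generator, out_c: int, in_c: int, k: int,
             scale: float = 1.0):
    """He-normal weight init; the final layer uses a small ``scale`` so an
    untrained residual net starts near the identity denoiser."""
    W = scale * rng.normal(0.0, np.sqrt(2.0 / (in_c * k * k)),
                           size=(out_c, in_c, k, k))
    return W, np.zeros(out_c)


def build_dncnn(depth: int = 17, filters: int = 64, seed: int = 0,
                activation: str = "relu") -> NetworkSpec:
    """Plain convolutional residual denoiser: ``depth`` layers of
    ``filters`` 3x3 filters, single-channel input/output, 'same' padding.

    The default 17/64 configuration has 555,137 trainable parameters.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    rng = np.random.default_rng(seed)
    layers = []
    chans = [1] + [filters] * (depth - 1) + [1]
    for i in range(depth):
        in_c, out_c = chans[i], chans[i + 1]
        act = activation if i < depth - 1 else "none"
        W, b = _he_init(rng, out_c, in_c, 3,
                        scale=0.05 if i == depth - 1 else 1.0)
        layers.append(LayerSpec("conv", in_c, out_c, 3, 1, act, W, b))
    return NetworkSpec(layers=layers, mode="formal")


def build_dnsnn(depth: int = 17, filters: int = 64,
                neuron_params: Optional[NeuronParams] = None,
                T: int = 8, seed: int = 0) -> NetworkSpec:
    """Spiking counterpart of :func:`build_dncnn`: every ReLU becomes an
    ATIF layer (one learnable threshold per layer) and the last convolution
    feeds an integrate-without-fire readout."""
    params = neuron_params or NeuronParams()
    net = build_dncnn(depth, filters, seed, activation="atif")
    for layer in net.layers:
        if layer.activation == "atif":
            layer.v_th = params.v_th
    net.mode = "spiking"
    net.T = int(T)
    net.surrogate_slope = params.surrogate_slope
    return net


def build_cae(spiking: bool = False, filters: int = 64, seed: int = 0,
              T: int = 8,
              neuron_params: Optional[NeuronParams] = None) -> NetworkSpec:
    """Multi-resolution convolutional autoencoder (8 layers).

    Layers 1 and 8 preserve dimensions; layers 2-4 halve the spatial size
    with stride-2 convolutions; layers 5-7 double it back with
    fractionally-strided convolutions.  Input sides must be divisible by 8.
    """
    act = "atif" if spiking else "relu"
    params = neuron_params or NeuronParams()
    rng = np.random.default_rng(seed)
    kinds = ["conv", "conv_down", "conv_down", "conv_down",
             "conv_up", "conv_up", "conv_up", "conv"]
    chans = [1] + [filters] * 7 + [1]
    layers = []
    for i, kind in enumerate(kinds):
        in_c, out_c = chans[i], chans[i + 1]
        stride = 2 if kind != "conv" else 1
        a = act if i < 7 else "none"
        W, b = _he_init(rng, out_c, in_c, 3, scale=0.05 if i == 7 else 1.0)
        layers.append(LayerSpec(kind, in_c, out_c, 3, stride, a, W, b,
                                v_th=params.v_th))
    return NetworkSpec(layers=layers, T=int(T),
                       mode="spiking" if spiking else "formal",
                       surrogate_slope=params.surrogate_slope)


def count_parameters(net: NetworkSpec) -> int:
    """Trainable parameter count (weights, biases, learnable thresholds)."""
    return sum(l.n_params() for l in net.layers)


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def uniform_quantize_activation(x, bitwidth: int, step: float,
                                rounding: str = "nearest") -> np.ndarray:
    """Quantized ReLU: clip(round(max(x, 0) / step), 0, 2**b - 1) * step.

    ``rounding='floor'`` selects the floor binning realized by a soft-reset
    IF neuron (same level grid, bins offset by half a step).
    """
    if bitwidth < 1:
        raise ValueError("bitwidth must be >= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    x = np.maximum(np.asarray(x, dtype=float), 0.0) / step
    if rounding == "nearest":
        q = np.round(x)
    elif rounding == "floor":
        q = np.floor(x)
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    return np.clip(q, 0, 2**bitwidth - 1) * step


def _check_image(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {y.shape}")
    return y


def _check_cae_size(net: NetworkSpec, y: np.ndarray) -> None:
    n_down = sum(1 for l in net.layers if l.kind == "conv_down")
    div = 2 ** n_down
    if n_down and (y.shape[0] % div or y.shape[1] % div):
        raise ValueError(
            f"input sides {y.shape} must be divisible by {div} for this network"
        )


def run_ann_inference(net: NetworkSpec, y) -> np.ndarray:
    """Dense single-pass forward of a formal network; returns the residual
    image R(y) (the denoised image is ``y - R(y)``)."""
    if net.mode != "formal":
        raise ValueError("run_ann_inference requires a formal-mode network")
    y = _check_image(y)
    _check_cae_size(net, y)
    x = y[None, None]
    for layer in net.layers:
        x = layer.forward(x)
        if layer.activation == "relu":
            x = np.maximum(x, 0.0)
        elif layer.activation == "quantized_relu":
            x = uniform_quantize_activation(x, layer.bitwidth, layer.step)
    return x[0, 0]


def run_snn_inference(net: NetworkSpec, y, T: Optional[int] = None,
                      record_rasters: bool = False) -> tuple:
    """T-step event-driven forward pass of a spiking network.

    The analog image is presented at every timestep; each ATIF layer
    integrates its convolution input, emits binary spikes with soft reset,
    and the final convolution is accumulated by the readout.  All membrane
    potentials start from zero (hard reset between samples) and the run is
    deterministic.

    Returns
    -------
    residual : ndarray
        Readout membrane at the last timestep, normalized by T (the
        integrate-without-fire readout carries a fixed 1/T synaptic gain,
        mirroring rate decoding; this keeps the output scale — and hence
        the residual — convergent as T grows).
    stats : list of dict
        Per spiking layer: spike_total, neurons, theta, theta_over_T (and
        the full raster when ``record_rasters``).
    """
    if net.mode != "spiking":
        raise ValueError("run_snn_inference requires a spiking-mode network")
    T = int(net.T if T is None else T)
    if T < 1:
        raise ValueError("T must be >= 1")
    y = _check_image(y)
    _check_cae_size(net, y)
    x0 = y[None, None]

    membranes = {}   # layer index -> membrane array, lazily shaped
    acc = None
    spike_totals = {}
    rasters = {i: [] for i, l in enumerate(net.layers) if l.activation == "atif"}

    for _ in range(T):
        x = x0
        for i, layer in enumerate(net.layers):
            x = layer.forward(x)
            if layer.activation == "atif":
                q = membranes.get(i)
                if q is None:
                    q = np.zeros_like(x)
                q = q + x
                z = (q >= layer.v_th).astype(float)
                membranes[i] = q - layer.v_th * z
                spike_totals[i] = spike_totals.get(i, 0.0) + float(z.sum())
                if record_rasters:
                    rasters[i].append(z[0].astype(np.uint8))
                x = z
        acc = x if acc is None else acc + x

    stats = []
    for i, layer in enumerate(net.layers):
        if layer.activation != "atif":
            continue
        n = spike_totals.get(i, 0.0)
        neurons = membranes[i].size
        entry = {
            "layer": i,
            "spike_total": n,
            "neurons": neurons,
            "theta": n / neurons,
            "theta_over_T": n / neurons / T,
        }
        if record_rasters:
            entry["raster"] = np.stack(rasters[i])
        stats.append(entry)
    return acc[0, 0] / T, stats


# ---------------------------------------------------------------------------
# serialization (spec JSON + named weight arrays in one .npz archive)
# ---------------------------------------------------------------------------

def save_network(net: NetworkSpec, path: str) -> None:
    meta = {
        "T": net.T,
        "mode": net.mode,
        "surrogate_slope": net.surrogate_slope,
        "layers": [
            {
                "kind": l.kind, "in_channels": l.in_channels,
                "filters": l.filters, "kernel": l.kernel, "stride": l.stride,
                "activation": l.activation, "v_th": float(l.v_th),
                "bitwidth": l.bitwidth, "step": l.step,
            }
            for l in net.layers
        ],
    }
    arrays = {"meta": np.array(json.dumps(meta))}
    for i, l in enumerate(net.layers):
        arrays[f"layer{i}_W"] = l.W
        arrays[f"layer{i}_b"] = l.b
    np.savez(path, **arrays)


def load_network(path: str) -> NetworkSpec:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        layers = []
        for i, ld in enumerate(meta["layers"]):
            layers.append(LayerSpec(
                ld["kind"], ld["in_channels"], ld["filters"], ld["kernel"],
                ld["stride"], ld["activation"], data[f"layer{i}_W"],
                data[f"layer{i}_b"], ld["v_th"], ld["bitwidth"], ld["step"],
            ))
    return NetworkSpec(layers=layers, T=meta["T"], mode=meta["mode"],
                       surrogate_slope=meta["surrogate_slope"])
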