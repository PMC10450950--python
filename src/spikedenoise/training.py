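"""Surrogate-gradient BPTT training of spiking denoisers.

The spiking network is unrolled over its ``T`` timesteps and trained with
backpropagation through time.  The forward pass uses the hard Heaviside
spike; during the backward pass its derivative is replaced by the
derivative of a logistic sigmoid evaluated at the membrane potential
measured from the threshold (``q - V_th``), which simultaneously yields
the gradient of the loss with respect to each layer's learnable firing
threshold (``dL/dV_th = -dL/dz * sigma'(q - V_th)``, plus the soft-reset
bookkeeping).  The gradient of the soft-reset subtraction is detached from
the spike (the standard convention); a fully differentiable "soft" mode
with a sigmoid forward exists so the entire pipeline can be checked
against finite differences.

Thresholds are kept positive by optimizing ``log V_th``.  Formal (ReLU)
networks are trained with ordinary single-pass backpropagation through the
same convolution primitives.  The optimizer is Adam with step-decayed
learning rate, matching the denoiser training protocol (lr 1e-3, decay
0.1 every 10 epochs, 30 epochs, 40x40 patches).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .data_synth import NoiseSpec, add_noise, extract_patches
from .metrics import psnr
from .networks import NetworkSpec, run_ann_inference, run_snn_inference

__all__ = [
    "TrainConfig",
    "residual_loss",
    "train",
    "evaluate",
    "snn_loss_and_grads",
    "ann_loss_and_grads",
]

#: abort threshold for exploding gradients
_LOSS_ABORT = 1e6


@dataclass
class TrainConfig:
    """Training protocol parameters.

    Defaults follow the reference denoiser recipe; ``max_steps`` caps the
    total number of optimizer updates for scaled-down runs, and
    ``threshold_lr_multiplier`` scales the learning rate applied to the
    (log-) thresholds relative to the weights.
    """

    learning_rate: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 10
    epochs: int = 30
    patch_size: int = 40
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    T: int = 8
    seed: int = 0
    batch_size: int = 16
    max_steps: int = None
    threshold_lr_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def residual_loss(predicted_residual, true_noise) -> float:
    """Mean squared error between the predicted residual R(y) and the
    noise v it should reproduce."""
    p = np.asarray(predicted_residual, dtype=float)
    v = np.asarray(true_noise, dtype=float)
    if p.shape != v.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {v.shape}")
    return float(np.mean((p - v) ** 2))


# ---------------------------------------------------------------------------
# loss + gradients
# ---------------------------------------------------------------------------

from scipy.special import expit as _sigmoid


def snn_loss_and_grads(net: NetworkSpec, y, v, soft: bool = False,
                       detach_reset: bool = True) -> tuple:
    """Unrolled T-step forward pass and BPTT backward pass.

    Parameters
    ----------
    y, v : ndarray (B, 1, H, W)
        Noisy input batch and the noise it contains (the residual target).
    soft : bool
        Replace the Heaviside by a sigmoid in the *forward* pass as well,
        making the computation differentiable end to end (used only for
        finite-difference verification).
    detach_reset : bool
        Stop the gradient of the soft-reset subtraction at the spike.

    Returns
    -------
    loss : float
    grads : dict mapping ("W", i) / ("b", i) / ("v_th", i) to arrays.
    """
    if net.mode != "spiking":
        raise ValueError("snn_loss_and_grads requires a spiking network")
    T = net.T
    k = net.surrogate_slope
    L = len(net.layers)
    y = np.asarray(y)
    v = np.asarray(v)

    membranes = {}
    inputs = [[None] * L for _ in range(T)]      # input to each conv
    pre_u = [dict() for _ in range(T)]           # membrane before reset
    spikes = [dict() for _ in range(T)]
    acc = None
    cur0 = net.layers[0].forward(y)  # analog input is constant across steps

    for t in range(T):
        x = y
        for i, layer in enumerate(net.layers):
            inputs[t][i] = x
            cur = cur0 if i == 0 else layer.forward(x)
            if layer.activation == "atif":
                q = membranes.get(i, 0.0)
                u = q + cur
                if soft:
                    z = _sigmoid(k * (u - layer.v_th))
                else:
                    z = (u >= layer.v_th).astype(u.dtype)
                membranes[i] = u - layer.v_th * z
                pre_u[t][i] = u
                spikes[t][i] = z
                x = z
            elif layer.activation == "relu":
                raise ValueError("spiking networks must not contain ReLU layers")
            else:
                x = cur
        acc = x if acc is None else acc + x

    # readout carries a fixed 1/T gain (see networks.run_snn_inference)
    out = acc / T
    loss = float(np.mean((out - v) ** 2))
    d_acc = 2.0 * (out - v) / (out.size * T)

    grads = {}
    for i, layer in enumerate(net.layers):
        grads[("W", i)] = np.zeros_like(layer.W)
        grads[("b", i)] = np.zeros_like(layer.b)
        if layer.activation == "atif":
            grads[("v_th", i)] = 0.0

    dq = {}  # carried membrane gradient per spiking layer
    d_cur0_sum = None  # layer 0 sees the same input every step
    for t in range(T - 1, -1, -1):
        dout = d_acc
        for i in range(L - 1, -1, -1):
            layer = net.layers[i]
            if layer.activation == "atif":
                dz = dout
                u = pre_u[t][i]
                z = spikes[t][i]
                if soft:
                    s = z
                    g = k * s * (1.0 - s)
                else:
                    s = _sigmoid(k * (u - layer.v_th))
                    g = k * s * (1.0 - s)
                dq_i = dq.get(i, 0.0)
                if detach_reset:
                    du = dz * g + dq_i
                    grads[("v_th", i)] += float(
                        np.sum(-dz * g) + np.sum(-dq_i * z)
                    )
                else:
                    du = dz * g + dq_i * (1.0 - layer.v_th * g)
                    grads[("v_th", i)] += float(
                        np.sum(-dz * g) + np.sum(dq_i * (-z + layer.v_th * g))
                    )
                dq[i] = du
                d_cur = du
            else:
                d_cur = dout
            if i == 0:
                d_cur0_sum = d_cur if d_cur0_sum is None else d_cur0_sum + d_cur
            else:
                x_in = inputs[t][i]
                dW, db = layer.param_grad(d_cur, x_in)
                grads[("W", i)] += dW
                grads[("b", i)] += db
                dout = layer.input_grad(d_cur, x_in.shape[2:])
    dW0, db0 = net.layers[0].param_grad(d_cur0_sum, y)
    grads[("W", 0)] += dW0
    grads[("b", 0)] += db0
    return loss, grads


def ann_loss_and_grads(net: NetworkSpec, y, v) -> tuple:
    """Single-pass loss and gradients for a formal (ReLU) network."""
    if net.mode != "formal":
        raise ValueError("ann_loss_and_grads requires a formal network")
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    xs, pre = [], []
    x = y
    for layer in net.layers:
        xs.append(x)
        cur = layer.forward(x)
        pre.append(cur)
        x = np.maximum(cur, 0.0) if layer.activation == "relu" else cur
    loss = float(np.mean((x - v) ** 2))
    dout = 2.0 * (x - v) / x.size
    grads = {}
    for i in range(len(net.layers) - 1, -1, -1):
        layer = net.layers[i]
        d_cur = dout * (pre[i] > 0) if layer.activation == "relu" else dout
        dW, db = layer.param_grad(d_cur, xs[i])
        grads[("W", i)] = dW
        grads[("b", i)] = db
        if i > 0:
            dout = layer.input_grad(d_cur, xs[i].shape[2:])
    return loss, grads


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, params: dict, grads: dict, lr_of) -> None:
        self.t += 1
        for key, g in grads.items():
            m = self.m.get(key, 0.0)
            vv = self.v.get(key, 0.0)
            m = self.beta1 * m + (1 - self.beta1) * g
            vv = self.beta2 * vv + (1 - self.beta2) * np.square(g)
            self.m[key], self.v[key] = m, vv
            mh = m / (1 - self.beta1**self.t)
            vh = vv / (1 - self.beta2**self.t)
            params[key] = params[key] - lr_of(key) * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(net: NetworkSpec, train_images, config: TrainConfig) -> tuple:
    """Train a (copy of a) denoising network on noisy synthetic patches.

    Each epoch iterates over all 40x40 patches in shuffled mini-batches;
    noise is re-sampled per patch per batch, so the network sees fresh
    degradations of the same clean content.  Returns ``(trained_net,
    history)`` where history holds one record per epoch: mean loss,
    learning rate and the per-layer thresholds.
    """
    net = copy.deepcopy(net)
    spiking = net.mode == "spiking"
    net.T = int(config.T) if spiking else net.T
    # single precision is ample for SGD and roughly halves the matmul cost
    for layer in net.layers:
        layer.W = layer.W.astype(np.float32)
        layer.b = layer.b.astype(np.float32)
    patches = extract_patches(train_images, config.patch_size)
    if not patches:
        raise ValueError("no training patches")
    patches = np.asarray(patches, dtype=np.float32)
    rng = np.random.default_rng(config.seed)
    opt = _Adam()
    n_steps = 0
    history = []

    # positive thresholds via log-reparameterization
    def params_view():
        p = {}
        for i, layer in enumerate(net.layers):
            p[("W", i)] = layer.W
            p[("b", i)] = layer.b
            if layer.activation == "atif":
                p[("log_v_th", i)] = np.array(math.log(layer.v_th))
        return p

    steps_per_epoch = max(1, len(patches) // config.batch_size)
    for epoch in range(config.epochs):
        lr = config.learning_rate * (
            config.lr_decay_factor ** (epoch // config.lr_decay_every)
        )
        epoch_losses = []
        order = rng.permutation(len(patches))
        for s in range(steps_per_epoch):
            idx = order[s * config.batch_size:(s + 1) * config.batch_size]
            if idx.size == 0:
                idx = order[:config.batch_size]
            clean = patches[idx][:, None]  # (B,1,H,W)
            noise_seed = int(rng.integers(2**31 - 1))
            spec = NoiseSpec(config.noise.model, config.noise.sigma, noise_seed)
            noisy = add_noise(clean, spec).astype(np.float32)
            v = noisy - clean
            if spiking:
                loss, grads = snn_loss_and_grads(net, noisy, v)
            else:
                loss, grads = ann_loss_and_grads(net, noisy, v)
            if not np.isfinite(loss) or loss > _LOSS_ABORT:
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, step {s}: loss={loss}"
                )
            # chain rule through v_th = exp(log_v_th)
            up_grads = {}
            for key, g in grads.items():
                if key[0] == "v_th":
                    up_grads[("log_v_th", key[1])] = \
                        g * net.layers[key[1]].v_th
                else:
                    up_grads[key] = g
            p = params_view()
            opt.step(
                p, up_grads,
                lr_of=lambda key: lr * (config.threshold_lr_multiplier
                                        if key[0] == "log_v_th" else 1.0),
            )
            for i, layer in enumerate(net.layers):
                layer.W = p[("W", i)]
                layer.b = p[("b", i)]
                if ("log_v_th", i) in p:
                    layer.v_th = float(np.exp(p[("log_v_th", i)]))
            epoch_losses.append(loss)
            n_steps += 1
            if config.max_steps is not None and n_steps >= config.max_steps:
                break
        history.append({
            "epoch": epoch,
            "loss": float(np.mean(epoch_losses)),
            "lr": lr,
            "v_th": [l.v_th for l in net.layers if l.activation == "atif"],
        })
        if config.max_steps is not None and n_steps >= config.max_steps:
            break
    return net, history


def evaluate(net: NetworkSpec, test_images, noise: NoiseSpec) -> float:
    """Mean PSNR of the denoised test images under a fixed degradation.

    Each image is degraded with a per-image seed derived from the noise
    spec, denoised as ``y - R(y)``, and scored against the clean image.
    """
    scores = []
    for i, x in enumerate(test_images):
        spec = NoiseSpec(noise.model, noise.sigma, noise.seed + i)
        y = add_noise(x, spec)
        if net.mode == "spiking":
            residual, _ = run_snn_inference(net, y)
        else:
            residual = run_ann_inference(net, y)
        scores.append(psnr(np.asarray(x, dtype=float), y - residual))
    return float(np.mean(scores))
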