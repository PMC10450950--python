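"""Integrate-and-Fire neuron dynamics and their quantizer closed forms.

The soft-reset IF neuron accumulates an input current into a membrane
potential ``q`` and emits a binary spike whenever ``q >= V_th``, after which
``V_th`` is subtracted (soft reset).  Driven by a constant current for ``T``
timesteps and decoded by rate coding, this neuron acts as a uniform
quantizer with ``T + 1`` levels over ``[0, V_th]``.

The ATIF variant makes ``V_th`` a learnable parameter: during the backward
pass the Heaviside step is replaced by the derivative of a logistic sigmoid
(surrogate gradient), which also yields a gradient with respect to the
threshold itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "NeuronParams",
    "MembraneState",
    "StepResult",
    "if_step",
    "if_spike_count_closed_form",
    "rate_decode",
    "surrogate_sigmoid_grad",
    "atif_threshold_grad",
]


@dataclass
class NeuronParams:
    """Parameters of a (population of) IF/ATIF neurons.

    Parameters
    ----------
    v_th : float
        Firing threshold, same units as the input current.  Must be > 0.
    surrogate_slope : float
        Slope ``k`` of the logistic surrogate ``sigma(k x)``.  The default
        4.0 gives a unit surrogate derivative at the threshold.
    learnable_threshold : bool
        Whether ``v_th`` is updated during training (the ATIF neuron).
    """

    v_th: float = 1.0
    surrogate_slope: float = 4.0
    learnable_threshold: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.v_th) or self.v_th <= 0:
            raise ValueError(f"v_th must be a finite positive number, got {self.v_th}")
        if not np.isfinite(self.surrogate_slope) or self.surrogate_slope <= 0:
            raise ValueError(
                f"surrogate_slope must be positive, got {self.surrogate_slope}"
            )


@dataclass
class MembraneState:
    """Per-neuron membrane potential ``q``.

    Reset to zero between samples (hard reset); within a sample the soft
    reset of :func:`if_step` applies.
    """

    q: np.ndarray = field(default_factory=lambda: np.zeros(()))

    @classmethod
    def zeros(cls, shape) -> "MembraneState":
        return cls(q=np.zeros(shape, dtype=float))


@dataclass
class StepResult:
    """Outcome of one IF timestep: binary spikes and the post-reset state."""

    spikes: np.ndarray
    state: MembraneState


def if_step(
    state: MembraneState, input_current, params: NeuronParams
) -> StepResult:
    """Advance a soft-reset IF population by one timestep.

    The membrane integrates the current, ``q' = q + I``; wherever
    ``q' >= v_th`` a single spike is emitted and ``v_th`` is subtracted
    exactly once (at most one spike per neuron per step, even if
    ``q' >= 2 v_th``).  Sub-threshold and negative potentials persist
    unclamped.

    Returns
    -------
    StepResult
        Binary spike array (same shape as the input) and the new state.
    """
    current = np.asarray(input_current, dtype=float)
    q = np.asarray(state.q, dtype=float)
    if q.shape != current.shape:
        raise ValueError(
            f"state shape {q.shape} does not match input shape {current.shape}"
        )
    if not np.all(np.isfinite(current)):
        raise ValueError("input current contains non-finite values")
    q_new = q + current
    spikes = (q_new >= params.v_th).astype(float)
    q_new = q_new - params.v_th * spikes
    return StepResult(spikes=spikes, state=MembraneState(q=q_new))


def if_spike_count_closed_form(x: float, b: float, v_th: float, T: int) -> int:
    """Total spikes of a soft-reset IF neuron under constant drive.

    For constant input current ``x + b`` over ``T`` timesteps starting from
    ``q = 0`` the spike count is ``clamp(floor((x + b) T / v_th), 0, T)``:
    the neuron cannot spike more than once per step, and negative drive
    emits nothing.
    """
    T = int(T)
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if v_th <= 0:
        raise ValueError(f"v_th must be positive, got {v_th}")
    count = int(np.floor((x + b) * T / v_th))
    return int(np.clip(count, 0, T))


def rate_decode(count: int, T: int, gain: float) -> float:
    """Rate-decode a spike count: ``(count / T) * gain``.

    With ``gain = v_th`` this inverts the encoder's scale, recovering a
    quantized version of the input on the ``T + 1``-level grid.
    """
    T = int(T)
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not 0 <= count <= T:
        raise ValueError(f"count {count} outside [0, {T}]")
    return (count / T) * gain


def surrogate_sigmoid_grad(q, slope: float = 4.0):
    """Derivative of the logistic surrogate ``sigma(slope * q)``.

    Returns ``slope * s * (1 - s)`` with ``s = sigma(slope * q)``: strictly
    positive, symmetric about 0, peak ``slope / 4`` at ``q = 0``, and unit
    integral over the real line.  Accepts scalars or arrays.
    """
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    q = np.asarray(q, dtype=float)
    s = expit(slope * q)
    out = slope * s * (1.0 - s)
    return out if out.ndim else float(out)


def atif_threshold_grad(upstream_grad, q, slope: float = 4.0):
    """Gradient of the loss with respect to the firing threshold.

    The spike ``z = Theta(q - v_th)`` depends on ``v_th`` with opposite sign
    to ``q``, so under the sigmoid surrogate
    ``dL/dv_th = -dL/dz * sigma'(q)`` where ``q`` is the surrogate argument
    supplied by the caller (membrane potential measured from the threshold).
    """
    g = np.asarray(upstream_grad, dtype=float)
    out = -g * surrogate_sigmoid_grad(q, slope)
    return out if np.ndim(out) else float(out)
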