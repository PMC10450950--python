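# Methods

## Spiking neurons as quantizers

The core neuron is the Integrate-and-Fire neuron with *soft reset*: the
membrane potential integrates the input current, `q ← q + I`; whenever
`q ≥ V_th` the neuron emits one binary spike and `V_th` is subtracted
(never more than one spike per timestep, and the membrane is not clamped
for negative drive).  Between input samples all membranes are hard-reset
to zero.  For a constant current `x + b` held for `T` steps the spike
count is exactly `clamp(floor((x+b)·T/V_th), 0, T)`, so encode + rate
decode realizes a uniform quantizer with `T + 1` levels over `[0, V_th]`
and a worst-case round-trip error of `V_th / T`.  Two conventions matter
and are fixed here:

* the spike condition is `q ≥ V_th` (not `>`), which the saturating cases
  of the worked example require;
* the quantizer is a *floor* quantizer.  A rounding (mid-tread) quantizer
  shares the same level grid but shifts every bin by half a step, so the
  quantized-ReLU baseline exposes a `rounding` mode; the
  latency↔bitwidth equivalence (`b = log2(T+1)`, pairing T = 1/7/15 with
  1/3/4 bits at step `V_th/T`) is exact in floor mode.

Quantization quality is summarized by the SQNR,
`10·log10(E[x²]/E[(x−x̂)²])`, and activity by the sparsity θ (spikes per
neuron per inference; θ/T is the per-step firing fraction).  The SQNR
landscape over the input range `x_max` peaks where the range matches
`V_th`: below it, part of the available levels is unused; above it, the
saturated tail dominates the error.  One caveat worth stating: with a
floor decoder the peak-at-`V_th` property depends on the image histogram.
For a *uniform* histogram at very low latency (T = 4) the extra signal
power of a slightly over-range encoding outweighs the half-step floor
bias, and the SQNR peaks just above `V_th`.  Histograms with substantial
mass near both extremes — typical of natural photographs, and of the
`checker` synthetic source used in the sweep tests — restore the peak at
`V_th` for every latency.

## Threshold scaling and gain compensation

Raising a neuron's threshold to its input maximum removes saturation but
introduces a gain of `1/V_th`.  The package compensates it the way the
worked three-neuron network does: each downstream synaptic current weights
presynaptic spikes by `w_i · V_th,i`, and the decoder applies the output
gain `w3 · V_th,3`.  For the output neuron neither the per-step current
maximum (7.5) nor the formal maximum (6.6) equals the documented
threshold 7; the builder uses the ceiling of the formal maximum, which
reproduces the reference configuration `(1.5, 1.5, 7)`.  All numbers of
the example — spike counts (8, 8, 8) vs (8, 6, 7), decoded 1.0 vs 6.125,
errors 5.6 vs 0.475, totals 24 vs 21 — come from the time-stepped
simulator, not from the closed forms.

## The ATIF neuron and surrogate-gradient BPTT

The ATIF neuron makes `V_th` a learnable per-layer scalar.  Training
unrolls the spiking dynamics over the `T` timesteps and backpropagates
through the unrolled graph.  The forward pass uses the hard Heaviside
spike; the backward pass substitutes the derivative of a logistic sigmoid
`σ(k·(q − V_th))` for the Heaviside's, with slope `k = 4` by default so
the surrogate derivative is 1 at the threshold.  The same factor yields
the threshold gradient `dL/dV_th = −dL/dz·σ′(q − V_th)` (plus the reset
bookkeeping).  Numerical choices:

* **Detached reset.**  The gradient of the soft-reset subtraction
  `q ← u − V_th·z` treats `z` as a constant (the standard convention;
  attaching it adds a `−V_th·σ′` term that destabilizes deep unrolls).
  A fully differentiable mode (sigmoid forward, attached reset) exists
  solely so the entire pipeline can be validated against central finite
  differences, which the test suite does to ~1e−7.
* **Positive thresholds.**  `V_th` is optimized as `log V_th`, so gradient
  descent cannot drive it non-positive.
* **Spike scale.**  Hidden spikes are passed downstream as plain binary
  values; any threshold-induced scale is absorbed into the learned
  weights.  The explicit `w·V_th` compensation appears only in the
  post-training threshold-scaling mode above.
* **Readout.**  The output layer is integrate-without-fire: it accumulates
  the final convolution at every step and its membrane at step `T` is the
  prediction, with a fixed `1/T` synaptic gain (a time average).  The
  average, rather than the raw sum, keeps the output — and hence the
  residual — convergent as `T` grows with frozen weights, mirrors rate
  decoding, and makes the output scale independent of `T`, so one
  optimizer setting works across latencies.
* **Divergence guard.**  Training aborts with a diagnostic if the loss is
  non-finite or exceeds 1e6; gradient clipping is off by default.

Networks: the residual denoiser stacks `depth` 3×3 'same' convolutions
(`filters` channels, single-channel input/output; 555,137 parameters at
the default 17 × 64, plus one threshold per spiking layer); there is no
batch normalization.  The network predicts the noise, `R(y) ≈ v`, the
denoised image is `y − R(y)`, and the loss is the MSE of the residual.
The autoencoder variant has 8 layers whose middle six halve and then
restore the spatial size (stride-2 convolutions and their exact adjoint,
fractionally-strided convolutions), requiring input sides divisible by 8.
The final layer of every builder is initialized at 1/20 of the usual He
scale so the untrained residual network starts near the identity
denoiser.  Convolutions, their input/parameter gradients, and Adam are
implemented in numpy (im2col/col2im); the forward pass is checked against
scipy's direct correlation and all gradients against finite differences.
The first convolution sees the analog image, which is constant across
timesteps, so it is computed once per sample and its parameter gradient
accumulated over the unroll.

Optimizer protocol (defaults): Adam, learning rate 1e−3 decayed by 0.1
every 10 epochs, 30 epochs, 40×40 training patches, batch size 16, noise
re-sampled per patch per step, no data augmentation.  Thresholds share the
weights' optimizer and learning rate (a multiplier is exposed).

## Degradation models and synthetic data

Gaussian: `y = x + v`, `v ~ N(0, (σ/255)²)` per pixel; speckle:
`y = x + x·v`, so the error variance scales with `x²`.  σ is quoted on
the 0–255 scale while images live in [0, 1]; noisy images are *not*
clipped by default, which makes the expected PSNR of a degraded image
exactly `20·log10(255/σ)` — 20.17 dB at σ = 25 and 14.15 dB at σ = 50 —
and those anchors are asserted to ±0.05 dB at 256×256.  A clipping flag
exists for display.

The synthetic generator (gradients, softened checkerboards, blob scenes,
band-limited textures; deterministic under seed, values in [0.1, 0.9])
replaces natural-image corpora.  It reproduces piecewise-smooth content
and edges but not the heavy-tailed gradient statistics, fine texture, or
resolution of photographs, so passing desk-scale tests demonstrates the
mechanics and trends of the method, not photographic denoising quality.

## Desk-scale experimental protocol

The latency/performance study trains 4-layer / 8-filter networks on
40×40 patches from sixteen 80×80 mixed synthetic images (Gaussian noise,
σ = 25), 25 epochs with decay every 10, batch 8, three seeds, latencies
T ∈ {1, 3, 7, 15}, evaluated as mean PSNR over four held-out images.
Representative seed-averaged results produced by this protocol: spiking
20.5 / 23.6 / 26.1 / 26.9 dB for T = 1 / 3 / 7 / 15 against 27.7 dB for
the formal baseline — monotone in latency and approaching the dense
network from below, with firing fractions θ/T strictly inside (0, 1).
These problem sizes were chosen as the smallest at which the trend is
stable across seeds.

## Energy model

The estimator counts, per layer: synaptic operations (dense MACs for
formal layers; one ACC per received spike per outgoing synapse for
spiking layers), memory accesses (weight and activation reads, membrane
reads/writes, per-step threshold checks), and one addressing event per
synaptic operation; the first spiking-network convolution is charged
densely once per timestep.  Each layer owns a local 32-bit-word SRAM for
parameters, activations and membranes.  Counts are multiplied by a
configurable per-event energy table; the shipped defaults are the
standard 45 nm estimates (FP32 MAC 4.6 pJ, add 0.9 pJ, SRAM word access
5 pJ, addressing 0.9 pJ).  Absolute figures depend entirely on that
table and on unmodeled micro-architecture, so only relative statements
are meaningful, and only trends are asserted: formal-network energy is
latency-invariant while spiking energy grows with `T` at fixed per-step
sparsity; event-driven synaptic energy undercuts dense MAC energy at
realistic firing fractions; totals are dominated by memory traffic for
these architectures; and, using the decreasing firing fractions measured
on wider networks, the spiking/formal energy ratio falls as the layer
width grows.

## Known limitations

Single-channel images only; known-σ (non-blind) denoising; per-layer
(not per-channel) thresholds; no leaky neuron variant; no weight/membrane
quantization; the Poisson encoder is provided and characterized but the
main denoiser uses direct (constant-current) encoding; training at full
photographic scale (hundreds of natural images, 17-layer networks) is out
of desk-scale reach and is not attempted.
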