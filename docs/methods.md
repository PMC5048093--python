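# Methods

This note records the modelling choices, default parameters, and the
limits of what the packaged synthetic experiments demonstrate.

## Model

Each channel of a C × F₂ input owns a private stack of convolution
units; a unit is a valid 1D convolution (no padding) followed by
non-overlapping max-pooling, so the per-map length after a unit is
(L − kernel + 1) / pool, which must be a positive integer. This shape
algebra is enforced at construction: the two reference architectures
resolve exactly to 1700 → 240 → 38 → 5 (kernels 21/13/9, pools 7/6/6)
and 1900 → 269 → 43 → 6 (kernels 18/12/8, pools 7/6/6), with feature
map counts 6/7/5, giving fully connected fan-ins of 8·5·5 = 200 and
8·6·5 = 240.

Choices the architecture description leaves open, fixed here:

- **No cross-channel weight sharing** (each channel's stack is its
  own); a `share_channels` flag exists for ablations.
- **Full map connectivity** between consecutive units within a channel.
- **Hidden activation tanh**, output a single logistic unit, loss
  binary cross-entropy. Pooling is applied to pre-activations and the
  activation to the pooled value; for monotone activations this is
  identical to activating before pooling and halves the activation
  work.
- **Initialization** Glorot-uniform, biases zero, deterministic per
  seed; a zero-init debug mode makes the forward output exactly 0.5.
- Parameters are float32 by default; gradient-check tests run float64.

The forward/backward pass is pure numpy. Gradients are analytic and are
validated against central finite differences (relative error < 1e-4
asserted; measured ≲ 1e-7 on float64 test configurations).

## Training

Both procedures share one presentation loop: each epoch reshuffles the
training set; each presented sample receives a freshly drawn uniform
random crop offset and, with probability 0.8, additive i.i.d. uniform
noise bounded by ±0.15. Gradients are averaged over a cycle of `p_max`
presentations and applied in one momentum update (v ← μv − ηg,
w ← w + v). A `per_sample` mode (update every presentation, validate
every cycle) is available since the prose description admits either
reading; `per_cycle` is the default because it makes `p_max` both the
batch size and the validation cadence. A trailing partial cycle at an
epoch boundary is flushed as a short cycle.

The step schedule is multiplicative: η(1) = 0.02 and
η(e) = η(e−1)·(1 − d(e)) with d = 0.0505 in epochs 2 and 3 and 0.01
otherwise. A subtractive reading of the same constants would zero the
step by epoch 3, inconsistent with training budgets of hundreds of
epochs, so the multiplicative reading is the only self-consistent one.
The momentum coefficient is not specified anywhere authoritative;
μ = 0.9 is the default and is configurable.

Checkpointing is strict-improvement only (ties keep the earliest best
model). Explicit training scores a held-out validation set after every
update on fixed-offset (offset 1), undistorted crops; implicit training
scores each cycle's own training samples the same way, pools the
correct counts over the epoch, and checkpoints only at epoch ends.
Both return the best checkpoint, not the final model, and identical
(dataset, config, seed) triples reproduce identical histories and
parameters bit for bit.

## Prediction and fusion

Subview prediction averages the model output over a list of fixed
1-based offsets (reference list 1, 26, …, 201 for 1700-of-1900 crops);
test-time distortion is off by default. Simple-Average fusion takes the
equal-weight per-class mean over k members (the reference setting is
k = 2, one member per filtering view and training regime). The binary
decision rule is p ≥ 0.5 → abnormal; an exact tie classifies abnormal,
the conservative direction for a screening application. Because all
members share the offset grid, fusing subview means equals flat
averaging over the member × offset grid; a test asserts this identity.

## Filtering views

The low-pass view is a zero-phase (forward-backward) Butterworth,
cutoff 40 Hz, order 4. The band-pass view is zero-phase Butterworth
0.5–40 Hz, **order 5**: with the order doubled by the forward-backward
pass, order 5 attenuates 50 Hz mains interference to ≈ 8% (≥ 90%
suppression), while order 4 leaves ≈ 13%, too little for the generator's
powerline-rejection property. Filtering uses even-reflection padding:
odd reflection lets a kink at the record edge excite the very slow
0.5 Hz high-pass transient and smear it across a short window (measured
as ~27% residual RMS on a 4 s stop-band sinusoid, versus ~8% with even
padding). Downsampling is polyphase resampling with line padding;
output length is ⌊F·target/rate⌋.

## Synthetic generator

Each record is a latent beat train — Gaussian bumps for P/Q/R/S/T-like
deflections, normalized so the dominant deflection is 1, RR intervals
jittered around a per-record heart rate — rendered into C channels
through a fixed cosine-tapered lead-gain pattern with ±10% per-record
jitter and small integer delays, plus baseline wander (0.33 Hz
sinusoid, amplitude 0.2 by default), powerline interference (50 Hz,
amplitude 0.05) and white noise (SD 0.05). The abnormal class differs
by one of: beat-amplitude scaling (default, ×(1+m)), extra RR jitter,
or T-wave inversion. Lead gains are modelled as a stable per-channel
pattern rather than fully random per record because lead projections
are anatomy-determined; a fully random gain would confound the
amplitude class effect and make the labels near-unidentifiable at any
training budget.

Default dimensions (8 channels, 500 Hz, 9.5 s → 4750 samples, i.e.
1900 per channel after downsampling to 200 Hz) mirror the reference
preprocessing endpoint. The packaged **easy benchmark** is deliberately
small so the full double-training experiment runs in seconds: 2
channels at 100 Hz, 200 samples per record, amplitude effect m = 0.5,
low noise, split 200/60/200; the paired tiny network is single-stage
(kernel 11, pool 10, 4 maps, FC 16, 2049 parameters) on 160-sample
crops, and its training config keeps the reference step schedule with
`p_max` = 10, preserving roughly the reference ratio of updates per
epoch (22 updates over 12 320 samples ≈ 20 updates over 200).

What passing on this benchmark shows: the whole pipeline — generation,
filtering, crop/distortion augmentation, both training loops,
checkpoint selection, subview averaging, fusion, metrics — is wired
correctly and can extract a genuine class signal. What it does not
show: performance on real ECG, whose inter-patient variability,
artifact structure and label noise the generator does not attempt to
model.

## Metrics and statistics

Counts follow the screening convention (abnormal = positive;
prob ≥ threshold → abnormal). The ROC curve is built over all distinct
score thresholds plus the (0,0)/(1,1) endpoints with TPR = Sp and
FPR = 1−Se; its trapezoidal area equals the conventional AUC (the curve
is the standard one reflected through both axes), and tests verify it
against a brute-force pairwise rank count and scikit-learn. The
NPV-constrained operating point maximizes Sp among thresholds with
NPV ≥ target (default 0.95); "equal to" a target NPV is operationalized
as ≥ because exact equality is measure-zero on finite data, and the
sentinel (0, 0) marks an unattainable constraint.

The exact Wilcoxon signed-ranks test drops zero differences, midranks
tied |d|, takes W = min(W⁺, W⁻), and computes the two-sided p as
P(W⁺ ≤ W) + P(W⁺ ≥ total − W) over all 2ⁿ sign assignments of the
realized (mid)ranks, evaluated by convolution DP on doubled (integer)
ranks; n ≤ 20 is enforced. On the shipped nine-dataset reference
columns this reproduces the published p-values 0.0039 (= 2/512, all
nine differences positive) and 0.0078 (= 4/512, one smallest-magnitude
negative difference). One published comparison (p = 0.1641) is known to
be reproducible only under integer tie-broken ranks rather than
midranks; midranks are kept and that value is not asserted. Summaries
are the arithmetic mean and the sample SD (n − 1).

## Known limitations

- The original low-pass preprocessing of the prior ECG pipeline is not
  published in detail; the order-4 Butterworth default is a documented
  substitute, configurable.
- Whether training distortion was channel-correlated is unknown;
  independence is assumed.
- The implicit trainer's per-epoch pooled accuracy makes its checkpoint
  cadence much coarser than the explicit trainer's per-cycle cadence;
  on very short runs it may return an early-epoch model.
- Binary classification is the tested path; the fusion rule accepts
  M-class probability vectors but no multi-class trainer is provided.
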