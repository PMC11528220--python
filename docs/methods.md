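# Methods

## Overview

`lfpdyn` implements a decoding strategy for intracortical brain–computer
interfaces (iBCIs) that replaces high-bandwidth spike acquisition with local
field potential (LFP) band power while retaining spike-level decoding
performance. The core is a sequential variational autoencoder over latent
neural dynamics whose *input* is LFP band power p(t) (or spike counts s(t))
and whose *objective* is always Poisson reconstruction of the spike counts.
A model trained on simultaneously recorded LFP and spikes can afterwards be
run from the LFP alone, so the implant's analog front end only needs the
low-bandwidth signal. The package also provides the preprocessing chain,
behavioral event detection, Wiener-filter kinematic decoding and its
metrics, a closed-form front-end power model, and a synthetic-session
generator that makes the whole pipeline testable end to end without any
recorded data.

## Front-end power model

Per-channel amplifier power follows the noise-efficiency-factor relation

    P_amp = V_source (NEF / V_RMS)^2 · (π · U_T · 4kT · BW) / 2

with V_source = 3.3 V, NEF = 4.0, V_RMS = 2 µV, U_T = 26.7 mV, T = 310 K and
BW the amplifier signal bandwidth; ADC power follows the Schreier figure of
merit P_ADC = BW / 10^((FoM_s − SNDR)/10) with FoM_s = 185 dB, SNDR = 96 dB
and BW the sampling bandwidth (half the sampling rate). Scenario
conventions: the amplifier bandwidth of a band [lo, hi) is hi − lo; the ADC
samples at the Nyquist rate of the band's upper edge, except that signals
acquired at 2 kHz (raw LFP 0–1000 Hz, spike-band power 300–1000 Hz) use a
1000 Hz sampling bandwidth and the 0–25 Hz band is sampled at 50 Hz (the
slowest rate compatible with 20 ms feature bins). The high-bandwidth spike
band is 5–10000 Hz, so its amplifier bandwidth is 9995 Hz. Both formulas are
linear in bandwidth. Feature-extraction power is treated as zero — it is
orders of magnitude below the analog front end — and transmitter power is
matched across scenarios through the transmission rate
(channels × bits/sample ÷ bin width), so scenario comparisons isolate the
analog front end. Display values are rounded to 2 significant figures; full
precision is kept internally.

## Preprocessing

**LFP extraction.** Two pipelines produce a 2 kHz LFP from broadband
voltage: a causal 1st-order 0.3–500 Hz band-pass followed by resampling and
60 Hz-harmonic notches (2nd-order IIR, Q = 35), or a 5th-order 1000 Hz
Butterworth low-pass followed by downsampling and the same notches.
Resampling is polyphase FIR with a Kaiser-windowed filter cut at 0.9× the
new Nyquist rate; tones in the top tenth of a band therefore fall inside
the anti-alias transition.

**Band power.** A short-time Fourier transform with a rectangular window of
1/Δf seconds (Δf = 5 Hz, or 2 Hz for the 0–8 Hz band) hops by 10% (4%) of
the window so that each hop equals one 20 ms bin; power is the sum of
squared magnitudes of the one-sided coefficients whose center frequency f
satisfies lo ≤ f < hi. The rectangular window is what makes "frequency
resolution" equal 1/T exactly; no doubling of the one-sided spectrum is
applied since absolute scale cancels in the log + z-score.

**Channel quality control.** Per-channel mean band power below 50% of the
median of per-channel means flags a channel disconnected; at or above twice
the 99th quantile flags it overly active. The rule is applied per analyzed
band, on un-normalized power.

**Normalization.** Power is log-transformed (clamped at ε = 1e-8) and
causally z-scored: the mean and standard deviation at bin t are computed
over the trailing 3 min window (t − w, t], never the future. Before 10 bins
of history exist the output is 0; the same ε guards the zero-variance
denominator.

**Quantization.** To emulate compressed wireless transmission, each channel
is min-max scaled over the session to [0, 2^b) and floored to integers
(clamped at 2^b − 1; constant channels map to 0).

**Spike cleaning.** On the 1 ms raster, any time step on which strictly
more than 30% of channels spiked is zeroed across channels (coincident
artifacts). Channels are then removed greedily — the channel participating
in the most pairwise Pearson correlations above 0.2 is dropped, ties to the
lower index, and correlations recomputed — until no pair exceeds the
threshold; greedy removal keeps more channels than removing both members of
every offending pair, and at least one channel always survives. Surviving
counts are summed into half-open 20 ms bins.

**Smoothing.** Gaussian smoothing (SD 30 ms for monkey-style data, 50 ms
for human speech data) uses a ±4 SD truncated kernel renormalized at the
edges, so constants are preserved exactly; a causal (past-only) variant is
available but not the default.

## Behavioral events

Movement onset per trial is the first upward crossing of 70% of the trial's
peak speed, searched from 250 ms after trial start; a crossing is a bin at
or above threshold whose predecessor is below, so a trial already above
threshold at the search start has no defined crossing and is rejected.
Trials whose first (forward) and last (backward) crossings disagree —
multiple speed peaks — are rejected. Analysis windows span 250 ms before to
500 ms after the alignment bin (37 bins at 20 ms, alignment bin included).

The speech path computes a microphone envelope (mean-center, causal
4th-order 65 Hz high-pass, rectify, 10 Hz low-pass, downsample to 50 Hz)
and takes speech onset as the first local maximum of the envelope
derivative with magnitude ≥ 3.5, and offset as the last such maximum of the
negated derivative, within the go-cue-to-stop window; peaks are separated
by at least 60 ms. The 3.5 threshold applies to the raw derivative
(envelope units per second) and is configurable.

## Dynamics model

The model is a sequential variational autoencoder in the LFADS lineage,
built from gated recurrent units:

* a bidirectional encoder reads the whole input window and parameterizes a
  diagonal-Gaussian posterior over the generator initial condition
  (prior N(0, I));
* a controller, fed the encoder's per-step bidirectional features and the
  previous factors, parameterizes a per-step Gaussian posterior over an
  inferred input u(t) (prior N(0, I), no autoregression); co_dim = 0
  removes the controller entirely, yielding an autonomous model;
* the generator evolves from the initial condition driven by u(t); factors
  are a linear readout of its state, and per-channel rates (spikes/bin) are
  the exponential of a linear readout of the factors;
* the loss is the Poisson negative log likelihood of the spike counts plus
  KL terms for the initial condition and inferred inputs (weights 1e-3 and
  3e-3 per normalized element, linear warm-up over 100 steps) plus L2 on
  the recurrent weights.

Continuous sessions are cut into 1000 ms windows with 200 ms overlap
(350 ms for less structured tasks; steps are quantized to whole 20 ms
bins, so the nominal 650 ms step is 640 ms). Training uses Adam
(lr 1e-2, ×0.996/epoch, gradient norm clipped at 10), batch 64, input
dropout 0.05, and for spike-input models a jitter augmentation that
independently displaces each input spike by up to ±2 bins (clipped at the
window edges, so counts are conserved) freshly each step. 20% of segments
(seeded shuffle) form a validation split; the parameters with the best
validation Poisson NLL at posterior means are restored after training.
Training aborts with a diagnostic on non-finite loss. All randomness flows
from one seed, so identical configurations reproduce identical loss curves.

Desk-scale default dimensions are encoder 64, generator 64, controller 64,
initial-condition 32, inferred-input 8, factors 12. The inferred-input and
factor sizes are deliberately larger than the minimal latent dimensionality
of the synthetic task: the generator must be *driven* (the latents are
excited at movement onset), and a too-narrow controller path visibly
underfits. Larger, supplement-scale dimensions can be passed through the
configuration.

**Inference.** Causal inference slides a trailing window over the stream:
for each new bin the model runs on the window ending at that bin using
posterior means (no sampling) and only the final bin's rates and factors
are emitted, so outputs at bin t depend only on bins ≤ t; nothing is
emitted before one full window of history exists. Acausal inference runs
full windows and merges overlaps by keeping, for every session bin, the
value from the window in which that bin is deepest (most left-context; ties
to the earlier window) — a centered-merge variant was measured and performs
indistinguishably. With n_samples > 1, rates are averaged over posterior
samples; n_samples = 1 is exactly the posterior-mean pass.

**Implementation.** The model runs on a small reverse-mode automatic
differentiation tape over numpy arrays written for this package; gradients
are verified against central finite differences in the test suite, and a
tape-free numpy forward path used for inference is verified against the
tape path bit-for-bit.

## Decoding and metrics

The Wiener filter solves (XᵀX + P) W = Xᵀy where row t of X concatenates
feature bins t … t−4 plus a bias column, and P is diagonal with the
regularization constant λ everywhere except 0 at the bias. The swept
constant is read as the penalty itself (P = λI); the literal "RᵀR with λ on
R's diagonal" reading (penalty λ²) is available via a flag — the
conventional sweep ranges (100–1000) indicate the former. λ is chosen from
20 log-spaced values by 10-fold cross-validation on contiguous time blocks
(shuffled bins would leak through overlapping history; rows whose history
spans a fold boundary are dropped), and the reported R² comes from a final
held-out block (the last 20% of rows) never touched during the sweep.
Held-out R² may be negative and is reported as-is.

Variance-weighted R² is the pooled ratio
1 − Σ_d Σ_i (ŷ−y)² / Σ_d Σ_i (y−ȳ_d)² — a single quotient over output
dimensions, not a per-dimension average, so high-variance dimensions weigh
more. PSTH R² smooths the reference spikes (30 ms Gaussian), extracts
aligned windows, averages within condition, concatenates condition averages
along time, computes each channel's coefficient of determination on the
concatenation (no per-channel recentering), and averages uniformly over
channels. Phoneme error rate is Levenshtein distance (unit-cost
substitution/insertion/deletion, computed by edlib) divided by the true
sequence length.

## Synthetic sessions

The generator emulates an eight-target center-out reaching session. Its
defaults are the package's study conditions: 40 spike channels plus one
exact duplicate, 16 LFP-power channels, 4 latent dimensions, 300 trials
(about a 10 min session, matching typical recording-session lengths), 20 ms
bins, 10 Hz mean firing rate, latent-to-noise power ratio 4, and 20%
multiplicative drift with a 6 min period.

**Latents.** Two 2-D rotation planes (400 and 150 ms periods) are excited
at each trial's movement onset by a condition-dependent state on a circle
of target angles (the second plane at twice the angle), gated by a smooth
unit-peak rise (120 ms) and exponential decay (320 ms), with small white
state noise. A Lorenz system is available for nonlinearity stress tests.

**Spikes.** Rates are r = exp(W_r z + b) with unit-norm tuning rows scaled
to depth 1.5 — log-rate swings of ±1.5 at unit latent amplitude, i.e.
several-fold modulation around baseline as in motor-cortical reach data —
and each channel's mean rate is normalized to the target. Spikes are
Poisson draws on a 1 ms raster; a small fraction (0.2%) of raster steps
receives a coincident artifact on about half the channels, and one
duplicated channel is appended, so the downstream cleaning rules always
have real work to do.

**LFP power.** Channels read softplus(W_p(G z + η) + b) with offsets near
zero (band power is rectified energy and sits at its floor during
quiescence), times the slow drift, times channel-level lognormal
measurement noise that is 50% shared across the array. Two structural
features matter:

* G expresses the second latent plane at gain 0.35 — the LFP is an
  aggregate signal and carries only part of the population state, while
  spiking expresses all of it;
* η is latent-level AR(1) noise (correlation time 150 ms) with a common
  amplitude floor referenced to the dominant plane, taking 80% of the
  1/coupling_snr noise budget (the rest is the channel-level lognormal).

These choices are what make the central model-vs-raw-power comparison
meaningful. Purely channel-level noise — however large — is averaged or
projected out by a 16-channel linear decoder, which then decodes nearly
perfectly and no model consuming the same features could beat it.
Correlated latent-level noise that does not drive spiking is exactly the
component a spike-anchored dynamics model can reject but a linear filter
cannot, mirroring the common-mode artifacts and volume-conducted
fluctuations of real recordings.

**Behavior.** Velocity is a linear readout of the latents (both planes,
the second at gain 0.6, peak speed 10 cm/s) plus small white noise; speed
profiles are bell-shaped by construction of the latent envelope. The
ground truth returned with each session carries the latents, noiseless
rates, the 70%-of-peak crossing times of the clean speed (the alignment
algorithm's target), the duplicated-channel index, and the noiseless LFP
readout.

**What the generator does not emulate.** Real broadband extracellular
voltage (band power is generated directly at the 20 ms feature level; a
separate sinusoid-plus-noise fixture exercises the STFT and filtering
paths), spike waveforms and sorting artifacts, non-stationarities beyond
the smooth multiplicative drift, behavioral variability beyond onset
jitter, and any speech-like audio beyond piecewise envelope fixtures.
Passing tests therefore demonstrate that the algorithms are implemented
correctly and that the method's qualitative claims hold under the stated
statistical structure — not that the numeric performance would transfer to
any particular recording.

## Numerical and testing choices

Zero-variance and log guards use ε = 1e-8. The STFT path is tested against
a direct per-window DFT sum to 1e-9 relative; the Wiener solver against an
augmented-rows least-squares oracle to 1e-8; the Poisson NLL against
term-by-term evaluation; PSTH R² against a brute-force recomputation from
the aligned tensors. Causality of the rolling z-score and of sliding-window
inference is tested by mutating future bins and requiring bit-identical
prefixes. Training-dependent checks (ground-truth PSTH recovery ≥ 0.6,
LFP-model/spikes-model parity within 0.15, decoding uplift of model rates
over smoothed raw power across three seeds, quantization robustness within
0.05) run at the default study conditions with the default model
configuration; each model trains in roughly two minutes on one CPU at the
desk-scale dimensions above.

## Known limitations

Training at desk scale uses a few hundred optimizer steps, far short of
full-scale practice, and the margin of the decoding-uplift comparison is a
few hundredths of R²; population-based hyperparameter search, multi-session
stitching, re-referencing of human broadband, and the recurrent CTC phoneme
decoder are out of scope. The causal z-score emits zeros during its warm-up
rather than backfilling. The CLI covers the reach pipeline end to end;
speech-specific stages are exposed as library functions only.
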