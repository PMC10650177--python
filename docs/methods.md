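# Methods

This note documents the models, parameter choices and numerical decisions
behind `periemg`, and what the synthetic benchmarks do and do not show.

## Generative model of a session

**Sources.** Eight muscle sources stand in for the main perifacial muscle
groups (left/right frontalis, corrugator, left/right orbicularis oculi,
orbicularis oris, left/right zygomaticus). During an action window a source
emits band-limited Gaussian noise — white noise shaped by a 4th-order
Butterworth bandpass, 20–350 Hz, the dominant sEMG energy band — multiplied
by a raised-cosine (Hann) burst envelope and normalized to unit carrier
RMS. Outside its windows a source is exactly zero. This
"amplitude-modulated Gaussian" form is the standard stochastic model of
surface EMG interference patterns; it is super-Gaussian (sparse) over a
session, which is what makes ICA separation well posed.

**Recruitment.** Each of the five actions (raise eyebrows, frown, close
eyes, purse lips, lift mouth corners) drives a fixed subset of sources with
fixed weights (`ACTION_SOURCE_WEIGHTS`), e.g. raising the eyebrows drives
both frontalis sources at weight 1 and the corrugator weakly at 0.2.
Co-recruited sources share burst *timing* (one physical contraction) but
draw **independent** noise carriers — motor-unit activity of distinct
muscles is independent even when co-activated.

**Amplitudes.** Per-action drive scales (a.u.): raise eyebrows 1.0, purse
lips 1.0, lift mouth corners 0.8, frown 0.25, close eyes 0.2. Forceful
intensity doubles the drive; a log-normal trial-to-trial jitter
(sd 0.2 in log-space) models natural variation in effort. The weak scales
for frowning and eye closure are deliberate: at normal intensity these
actions land near the sensor noise floor, reproducing the real-world
finding that distal electrodes can barely capture small movements (such
epochs often cannot even be labeled from human recordings).

**Mixing.** Sixteen electrodes sit on an ellipse around the face, eight
sources inside it (2-D sketch, arbitrary "face units"); mixing coefficient
`A[i, j] = 1 / d(i, j)^p` with exponent `p = 1` by default. Volume
conduction in tissue is only qualitatively an inverse-distance decay, so
the exponent and even the law are configurable; any non-negative,
distance-monotone callable is accepted.

**Interference.** A mains sinusoid (50 Hz, common phase across channels,
amplitude 0.2 a.u.), a per-channel DC offset (0.5 a.u.) and white sensor
noise (sd 0.05 a.u.) are added. All randomness flows through
`numpy.random.SeedSequence`, so a session is bit-reproducible from its
seed.

**Protocol.** Defaults: 5 actions × 2 intensities × 5 repetitions per
block × 3 blocks; each trial is cue 2 s → action 2 s → rest 3 s, with 30 s
between blocks (the cue and action phases are treated as strictly
sequential). That yields 150 labeled epochs in an 1110 s session at 1 kHz.

**What the simulator does not model.** Motor-unit action potentials and
firing statistics, nonstationary fatigue effects, electrode-skin impedance
drift, movement artifacts, inter-subject anatomy, and any facial geometry
beyond the 2-D sketch. Tests passing on this generator therefore validate
the *pipeline's* correctness and internal consistency, not expected
accuracy on human recordings — the near-perfect classification accuracies
on default synthetic sessions reflect clean, well-separated simulated
conditions.

## Device model

The ADC is modeled after 24-bit ΔΣ biopotential front-ends: code-to-voltage
scale `volts = code · vref / (gain · (2^23 − 1))` with defaults gain 24 and
vref 4.5 V (typical internal reference for this chip family; the datasheet
convention makes full-scale = vref/gain). Valid sample rates are
250–16 000 SPS. Throughput is `D = N · fs · R` bits/s; each 24-bit
conversion is sign-extended to a 32-bit word for transport, so 16 channels
at 1 kHz produce 512 kbit/s.

The binary frame layout is this package's own documented dialect (the
device protocol fixes only "header, packet number, check digit"): 2-byte
header `0xA5 0x5A`, 4-byte little-endian packet counter, one little-endian
int32 per channel, 1-byte XOR checksum. XOR detects every single-bit flip;
stream decoding resynchronizes on the next valid header after corruption,
and counter gaps expose dropped packets. Text recordings are
whitespace-separated volts (rows = sample instants, columns = channels)
with `#`-prefixed metadata lines (rate, channel labels, ADC settings).

## Conditioning chain

Stage order: 50 Hz notch (quality 30) → 4th-order Butterworth bandpass
20–350 Hz → DC removal → full-wave rectification → 2nd-order Butterworth
low-pass at 10 Hz (linear envelope). The notch frequency, quality and
envelope cutoff are conventional values for 50 Hz-mains regions; all are
configurable. DC removal is kept after the bandpass even though the
bandpass already suppresses DC, so each stage can be audited independently.

Filtering is zero-phase (forward–backward) by default so epoch onsets stay
aligned to the cue schedule; this squares the magnitude response, putting
corners at −6 dB instead of the single-pass −3 dB (tests measure
accordingly, and `zero_phase=False` gives single-pass behavior). Envelope
output may dip slightly below zero from low-pass ripple; strictly
non-negative consumers should clip. ICA consumes the full chain output by
default; `preprocess_chain(..., return_stages=True)` exposes every
intermediate for pipelines that prefer to unmix the band-passed signal
instead.

## ICA

Whitening is PCA-based (SVD of the centered data, singular-value cutoff
1e−10 relative), reducing 16 channels to 8 unit-variance directions; the
affine transform is stored for reuse and inversion. The rotation is then
estimated by fixed-point iteration with the log-cosh contrast and symmetric
decorrelation — tolerance 1e−4 on the diagonal of `W_new W^T`, max 200
iterations, random orthonormal start from the seed. Non-convergence is
reported on the result object rather than raised: the final iterate is
usually still usable, and Gaussian-dominated data may legitimately never
settle (Gaussian sources are unidentifiable in principle).

ICA's inherent sign/scale/permutation ambiguity is canonicalized: unit
component variance, sign fixed so the largest-magnitude sample is positive,
components ordered by explained input variance. Recovery against ground
truth is scored with greedy absolute-correlation matching and the Amari
index (permutation/scale-invariant, 0 = perfect).

On clean equal-strength independent burst mixtures
(`simulate.independent_burst_sources`, 60 s at 1 kHz), all 8 sources are
recovered essentially perfectly (worst correlation ≥ 0.95, Amari ≤ 0.1,
median over 20 seeds). On full sessions recovery is intrinsically partial:
bilateral muscle pairs share burst timing, so they are uncorrelated but
energy-co-modulated (not independent), and the midline corrugator's mixing
column is nearly a linear combination of the frontalis columns. This is a
property of co-active facial muscles, not an implementation artifact; the
session-level guarantee is that sources well above the noise floor
(epoch RMS ≥ 0.15 a.u.) match at median |corr| ≥ 0.7, with at least three
of them ≥ 0.9.

## Features

Per component and epoch (whole 2 s window, no sub-windowing): IEMG, VAR
(population 1/N form, as conventionally printed for EMG), MAV, SSI, RMS;
and from an amplitude spectrum, FC (spectral centroid), MF and FRMS.
Identities `IEMG = N·MAV` and `SSI = N·RMS²` hold exactly, and
`FRMS ≥ FC` by Cauchy–Schwarz.

The spectrum estimator is the magnitude of a single discrete Fourier
transform of the mean-removed epoch, normalized by N (a Welch option
exists). **Note:** MF here is the *mean spectrum amplitude*
(`Σ S(n) / N_bins`, N taken as the bin count — the only consistent
reading), not the median frequency that "MF" often denotes in the EMG
literature. Consequently MF scales linearly with signal amplitude while FC
and FRMS are scale-invariant. An all-zero spectrum leaves FC/FRMS
undefined: `frequency_domain_features` raises `ZeroSpectrumError`, and the
matrix builder substitutes 0.0 for both so feature matrices never contain
NaNs. Columns are `c{k}_{feature}` in fixed order; 8 components × 8
features = 64 per epoch.

## Agreement statistics

Spearman (average ranks for ties), energy ratio, LCC and CCC. The energy
of a sampled signal is `Σ x² · dt`; the *ratio* convention is
`min(E_x, E_y) / max(E_x, E_y)`, chosen to be symmetric and to lie in
[0, 1]. CCC at lag 0 is the raw-sum Pearson formula and equals LCC
algebraically — both are reported because device-comparison tables
conventionally list them side by side; an optional `max_lag` mode sweeps
Pearson over lags and reports the best lag for imperfectly aligned pairs.
Constant inputs and all-zero energy pairs raise explicit errors instead of
returning NaN. Signals are compared after identical preprocessing and
epoch-onset alignment; no time warping.

## Classifiers

**SVM.** One-vs-rest with a Gaussian kernel. Dual problems are solved by
libsvm, but prediction runs through this package's own kernel expansion
`f_m(x) = Σ_i α_i^m y_i exp(−γ‖x − x_i‖²) + b_m` over the extracted
support vectors, and `kkt_audit` verifies dual feasibility
(0 ≤ α ≤ C, |Σ α y| ≤ 1e−6) after training. Defaults C = 1 and
γ = 1/(n_features · var) on internally standardized features (the
standardizer is fit on training data only and stored on the model).

**Random forest.** 200 trees; prediction is an explicit majority vote over
the trees with even votes broken deterministically toward the lowest class
index.

**BPNN.** One hidden layer of 32 tanh units by default, softmax output,
cross-entropy loss, full-batch gradient descent with momentum 0.9 and
learning rate 0.05 for 200 epochs, Glorot-uniform initialization from the
seed. `epochs=0` yields the untrained network; the per-epoch loss history
is recorded; a non-finite loss raises `DivergenceError`.

**Tasks and evaluation.** `five_class` uses forceful epochs only (labels
CE, PL, RE, LCM, FR); `ten_class` uses action × intensity. Splits are
random 80/20, stratified by default, seeded. Recall and F1 are
macro-averaged and every report tags the scheme; confusion matrices use
true classes as rows.

## Pipeline reproducibility

`PipelineConfig` (pydantic, `extra="forbid"`) validates all stage
parameters and cross-stage constraints (e.g. ICA components ≤ channels)
before any stage runs. The global seed fans out as
`SeedSequence([seed, stage_index]) mod 2^31`, so each stage is
independently reproducible. The manifest records per-stage seeds, timings
and SHA-256 hashes of every artifact; re-running the same config
reproduces all hashes byte-identically.

## Problem sizes

Benchmarks and the acceptance script use: one full default session
(150 epochs, 1110 s × 16 channels at 1 kHz) for the end-to-end
classification figures; 20 seeds of 60 s clean 8×16 mixtures for ICA
recovery; 20-sine-second tones for filter attenuation; and a compressed
protocol (1 block × 3 reps, 1 s actions) for the two-device agreement
simulation. These sizes give stable medians while keeping a full run
around a minute.
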