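# Methods

This note records the models, estimators and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the decisions taken where the design was genuinely open.

## Study design being emulated

A session is five blocks in the fixed presentation order
resting → scenario 4 → scenario 3 → scenario 1 → scenario 2. The scenarios
map onto an induced-workload axis by task load (baseline traffic <
high nominal < high off-nominal < overload), giving the workload ranks

    resting = 0 < scenario1 = 1 < scenario2 = 2 < scenario4 = 3 < scenario3 = 4.

Four labelings of the five conditions are supported: A resting/working;
B 0 / medium-low {scn1, scn2} / high {scn3, scn4}; C 0 / low {scn1} /
medium-high {scn2, scn3, scn4}; D 0 / low / medium / high ({scn3, scn4}
merged as high).

## Synthetic EEG generator

**Model.** Each channel of each block is stationary coloured Gaussian
noise. The base power spectrum is `S(f) ∝ 1/max(f, 1 Hz) + 0.04` over
0.5–110 Hz — a 1/f slope with a flat broadband floor about −14 dB below
the 1 Hz power, mimicking the flattening of scalp spectra above ~30 Hz.
On the configured informative channels, the spectrum inside each
canonical band is multiplied by a per-condition band gain. Shaping a
single white spectrum is distributionally identical to summing
independent band-limited processes, because disjoint frequency bins of a
Gaussian process are independent; it gives exact control of every band's
expected power, which is the property the downstream analysis consumes.
The overall scale is calibrated so a unit-gain channel has 20 µV RMS.

**Default workload effect.** Band gains move geometrically with workload
rank r: θ ×1.3^r, β ×1.7^r, γ ×2.8^r, α ×0.9^r, δ flat. Two points about
this profile:

- Direction matches the physiology the analysis assumes (θ, β, γ rise
  with load; α is suppressed; δ is load-neutral).
- The steep γ step is deliberate. Band-power estimates from short epochs
  are chi-square distributed with roughly `2 × bandwidth × duration`
  degrees of freedom, so multiplicative effects in narrow low bands
  saturate (gain and estimator noise scale together), while the 70 Hz-wide
  γ band supports precise per-epoch readout. Placing most of the
  discriminative signal in γ puts the generator in the near-separable
  regime that high-accuracy (≈0.98–1.0) workload detection presumes, and
  mirrors the analysis' own conclusion that gamma-containing features
  dominate. Since γ rides on the small broadband floor, absolute µV
  excursions stay modest.

**Inter-subject variability.** Per subject and band, a level factor
`exp(σz)` (applied to every condition) and an effect exponent `1 + σz'`
on the gains, with σ = 0.03 by default. Subjects draw from substreams
hashed from (seed, subject_id, purpose), so enlarging the cohort never
changes existing subjects.

**Artifacts.** blink: Gaussian bumps (σ = 0.08 s by default, configurable
width) at Poisson times on frontal channels — energy mostly <4 Hz with a
θ tail; emg: 0.5 s Tukey-windowed 20–100 Hz bursts on temporal channels;
ecg: a shared quasi-periodic QRS-like spike train (ripple ~1.1 Hz, 3% RR
jitter) mixed into all targeted channels with random low-amplitude
weights — the one artifact class that is global by construction;
channel_noise: continuous white noise on exactly one channel. Untargeted
channels are returned bit-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no volume-conducted correlation structure
between neighbouring electrodes (channels are independent), no
within-block nonstationarity (fatigue, drifts), no event-related
dynamics, no realistic artifact morphology beyond the four stylized
classes, and inter-subject variation limited to smooth gain scaling.
Planted-truth recovery here demonstrates the pipeline's correctness, not
field performance.

## Preprocessing

Fixed order: drop channels → re-reference → bandpass → (ICA) → epoch.

- Re-reference: common average by default (standard for dense montages
  and reference-free downstream power ratios); single-electrode reference
  supported.
- Filter: 4th-order Butterworth 0.5–100 Hz, applied forward-backward
  (`sosfiltfilt`) so wavelet timing is unaffected; DC removed first.
  Refiltering is a no-op (≤1% RMS) only for passband content: spectral
  content at the band edges is re-attenuated on every pass, and 1/f EEG
  holds real power near 0.5 Hz, so a broadband refilter moves ~6% RMS.
- Epoching: non-overlapping 2 s windows by default, tiled per annotation
  with partial tails dropped. Two seconds is marginal for the 0.5 Hz
  filter edge and short for the δ band (a documented limitation) but
  gives 30 epochs per 60 s block, which the mutual-information stage
  needs. The segment length the emulated study used is unknown; it is a
  config field.

### ICA artifact removal

Algorithm: PCA reduction to 20 components (configurable), whitening, then
deflation FastICA with a tanh contrast and seeded initialisation
(max_iter 200, tol 1e-4). Deflation with per-component convergence
tracking matters here: on directions whose sources are near-Gaussian the
FastICA fixed point is degenerate (`E[x g(wᵀx)] − E[g']w ≈ 0`), so those
components cannot settle and are retained as non-artifact residual
sources; `strict=True` converts any such component into an
`ICAConvergenceError` with iteration diagnostics.

Component flagging is deterministic, from topography, spectrum, waveform
and time structure:

- blink: >0.6 of squared loading on frontal electrodes, >50% of power
  below 4 Hz, and intermittent;
- emg: >0.5 loading on temporal electrodes, >40% of power above 30 Hz,
  and intermittent;
- channel_noise: a single channel holds >0.9 of the loading norm, a
  high-frequency-heavy (>65% above 30 Hz) spectrum, non-intermittent,
  and stationary across blocks;
- ecg: kurtosis >8 with a regular 0.4–2 s inter-peak interval
  (CV < 0.25) in the source waveform.

"Intermittent" is the within-block burstiness — the standard deviation of
log RMS over 1 s frames inside each annotation (> 0.35). This gate is
what separates artifacts from genuine workload signal: both are
non-Gaussian over a session, but artifacts switch on and off within a
block while band-power workload structure is stationary within a block
and only shifts between blocks. Without it, strong single-channel
informative components are occasionally removed as "noise", corrupting
the ICA audit. Flagged sources are zeroed and the mixture re-assembled;
channel and sample counts never change.

## Spectral features

The time-frequency transform is a complex Morlet CWT with 7 cycles
(σ_t = 7/(2πf)) on a 60-point logarithmic grid over 1–100 Hz (≥2 rows per
band guaranteed), L²-normalized kernels, realized as FFT
cross-correlation. Band power is the **mean** of |W|² over a band's rows
and the epoch's samples — mean rather than sum so the statistic does not
depend on grid density; ratios are unaffected either way. The γ band is
closed at 100 Hz (the filter's upper edge); content in [0.5, 1) Hz passes
the filter but no feature reads it.

For whole datasets, band powers are evaluated in the frequency domain via
Parseval: the full-convolution time sum of |W|² equals
`Σ_f |x̂(f)|² |ψ̂_a(f)|² / nfft`, so a band power is one weighted
projection of the epoch's periodogram. This is mathematically the
unbiased stationary estimate; the per-sample map path (`cwt_power`),
cropped to the epoch, undercounts edge energy by ≈ wavelet-width/epoch
(visible in δ for short epochs). The two paths share one kernel
construction and are cross-checked in tests, with MNE's Morlet TFR and an
analytic closed-form response as independent oracles.

The 26-feature bank is evaluated exactly as written (features 1–13
classical, 14–26 gamma-augmented); a zero denominator yields NaN — a
logged sentinel, never a silent zero — and NaN epochs are dropped
per-feature downstream.

## Feature ranking

Per feature, the predictor is that feature's values across all channels.
RBF-SVM with one-vs-one multiclass voting (ties resolve to the lowest
class index via argmax), z-scored inside each training fold, grid over
C ∈ {0.1, 1, 10, 100} × γ ∈ 10^{−3..1} (log-spaced) by default.
Cross-validation is stratified 5-fold **grouped by subject**, so no
subject's epochs straddle folds — epoch-level CV would leak subject
identity and inflate every accuracy. The best feature overall is the
highest mean accuracy across the four schemes, ties to the lower id.
Which feature wins depends on the planted gain profile: under the default
profile, ratio features such as α/β (which move strongly when α falls and
β rises) compete with the gamma sums; under a gamma-only effect the
gamma-containing features win by construction.

## Channel selection

Mutual information is a plugin estimate in bits on discretized values:
equal-frequency binning with 8 bins for continuous inputs (robust to the
heavy right tails of power features), label encoding for already-discrete
inputs. The estimator is exact on contingency tables (tested to 1e-12
against direct summation). mRMR is the standard greedy incremental form:
first channel maximizes I(x; c); step m adds the channel maximizing
`I(x_i; c) − (1/|S|) Σ_{j∈S} I(x_i; x_j)`, ties to the lowest channel
index, per-step relevance/redundancy/φ logged. k = 10 per subject by
default; the consensus rule selects channels present in strictly more
than 80% of subjects' lists.

## Workload model

CART decision tree, depth capped at 10, grid over depth {3,5,7,10} ×
min-leaf {1,5,20} × criterion {gini, entropy}, class-weighted because one
resting block faces four working blocks. Evaluation is
leave-one-subject-out: the grid search (3-fold stratified) runs inside
each training fold; the held-out subject contributes accuracy, macro
precision/recall/F1 and macro one-vs-rest ROC-AUC plus a stored confusion
matrix. Subset sweeps reuse identical folds and seeds for paired
comparison. The ICA audit trains single-channel models on
otherwise-identical feature tables from the ICA and no-ICA variants; a
channel is "stable" when its mean LOSO accuracy moves by at most 0.05
(default tolerance — the audit has no canonical numeric criterion).

## Problem sizes and tolerances

Test and acceptance runs use desk-scale versions of the design:
60 s blocks (not half-hour sessions), 4–10 subjects per experiment, and
reduced hyperparameter grids in the multi-seed repetitions (grid size
affects runtime, not which feature or channel wins). The consensus
recovery check runs 20 seeded replicates of a 10-subject dataset; ranking
and audit checks use 10 replicates at 6 and 4 subjects. The acceptance
script reports the same quantities at slightly smaller replicate counts.
Numerical tolerances: MI and feature identities to 1e-12/1e-10 (pure
algebra); spectral localization at the 80%-of-total level; accuracy-based
checks at the band the corresponding experiment defines (±0.02 model
parity, ±0.05 audit stability).

## Known limitations

- The generator's channels are spatially independent; spatial filters
  (common average, ICA) therefore behave more cleanly than on real EEG.
- FastICA separation quality at 30–60 s of data is modest; the audit
  depends on the blink source being strong and frontal.
- δ-band estimates from 2 s epochs are heavily smoothed by the 7-cycle
  wavelet and edge-dominated; no default feature decision rests on δ
  alone.
- EDF output is plain 16-bit EDF with a JSON sidecar for annotations, not
  EDF+; quantization error is bounded by one step of the per-channel
  physical range.
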