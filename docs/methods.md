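# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the `turnintent` pipeline.

## The behavioral generator

Gap acceptance is modeled as a logistic rule. At an intersection, gaps are
drawn uniformly on [1, 6] s and presented in ascending order (small gaps
first, probing the minimal acceptable gap, as in staircase-like protocols).
A gap *g* offered after *w* cars have passed is accepted with probability

    P(accept) = sigmoid(k · (g − (g_c − r·w)))

with critical gap g_c = 3.5 s, steepness k = 3 s⁻¹ and urgency rate
r = 0.15 s per car. The urgency term implements the well-documented
finding that drivers grow more aggressive the longer they wait. With
probability 0.08 per rejected gap the driver takes it anyway; these
"atypical" accepts are flagged in the ground truth and drive amplified
(2×) neural activation. If no gap in a sequence is accepted the sequence
is re-drawn, mirroring a protocol in which essentially every turn happened
within the presented cars; degenerate parameter settings (k ≈ 0 with no
atypical channel) raise after a bounded number of re-draws rather than
looping. Event timing: the first car crosses 2 s after arrival, the press
follows the lead car of the accepted gap by 0.5 s, and 15–20 s separate a
press from the next arrival so that windows and hemodynamic tails never
collide.

Both analysis windows need context features. The turn window carries the
accepted gap and cars waited; the no-turn window carries the gap on offer
and cars passed at its center (4.5 s before the press). Without
phase-specific context the context-only classifier would be at chance by
construction, which contradicts both intuition and the behavior this
package emulates.

Gap metres use a per-second rounding convention: distance = round(v/3.6)·g,
so 50 km/h → 14 m/s and the printed 1–6 s ↔ 14–84 m bracket is exact.

## The optical forward model

Ground-truth HbR per active channel is −A·(boxcar ⊛ h)(t), peak-normalized,
with A = 1 µmol/l (2 µmol/l on atypical turns), a 4-s boxcar starting 2 s
before the press, and h the canonical double-gamma impulse response (peak
≈ 5.5 s, undershoot ratio 6). The onset precedes the press because the
decision precedes the movement; the hemodynamic delay then places the
response inside the turn window. HbO mirrors the activation at −2× the HbR
amplitude. Ten of 107 channels are active by default, with channel gains
in [0.6, 1].

Noise has five components (amplitudes in mmol/l):

| component   | default | structure |
|-------------|---------|-----------|
| cardiac     | 2e-4    | global sinusoid ~1.0–1.2 Hz (aliased at 2 Hz sampling), per-channel gain 0.5–1.5 |
| respiratory | 1.5e-4  | global sinusoid ~0.3 Hz, same coupling |
| Mayer       | 1.5e-4  | global sinusoid ~0.08–0.12 Hz — inside the analysis band |
| spatial     | 4e-5    | 15 latent smooth time courses × random channel patterns |
| drift/white | 3e-4 / 1e-4 | independent per channel |

Two structural choices matter. First, the oscillatory physiology is
*global* (one waveform per subject, random channel gains): systemic
pulsation and blood-pressure waves are body-wide, and this is what makes
the first principal component a physiology catcher — the reason the
pipeline discards it. With independent per-channel phases the first PC
would instead capture the task activation and dropping it would destroy
the fNIRS signal. Second, the latent spatially-correlated noise gives the
channel covariance the fat eigenvalue spectrum of real multichannel
recordings; its amplitude was set so that the number of components passing
the 0.7 eigenvalue cutoff (~17) is of the order reported for real
recordings (~13), and so that the fNIRS-only classifier performs clearly
above chance yet below the context model, the qualitative regime of
interest. These defaults are the study conditions of every test and are
not adjusted per experiment.

The forward Beer–Lambert step maps concentrations to intensities via
ΔOD(λ) = (ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR)·L·DPF(λ), I = I₀·10^(−ΔOD), with
extinction coefficients (1/(mmol/l)/cm) 1.4866/3.8437 at 760 nm and
2.5264/1.7986 at 850 nm from the standard compiled tables,
L = 3 cm source–detector separation and DPF = 6 at both wavelengths. The
same constants drive the inverse step in preprocessing, so conversion is a
round trip by construction; the recovered series differ from the injected
ones only through the I₀ convention (channel temporal mean, removed by the
band-pass together with the small Jensen offset of the log) and filter
edge effects. The noise-free round-trip correlation in-band exceeds 0.999.

## Preprocessing

Channel rejection is automated (reproducibility requires no human in the
loop): a channel is rejected when the maximum MAD-scaled robust z of its
intensity deviations — or of their successive differences — exceeds 8.
Amplitude deviations are included because at 2 Hz sampling the cardiac
component aliases close to Nyquist, making successive differences
signal-sized and blind to spikes. On clean synthetic recordings the scores
stay below ~4; injected ±10 SD spikes score well above the threshold.

The band-pass is a 3rd-order Butterworth, 0.01–0.1 Hz, applied forward and
backward (zero phase, so event-locked windows are not shifted). It is
applied to the concentration series rather than to the raw intensities:
filtering intensities removes their DC and makes −log(I/I₀) ill-defined,
while the linearity of both the filter and the (small-signal) Beer–Lambert
relation makes the two orders numerically equivalent. The filtered output
is explicitly demeaned, so the mean-zero contract holds exactly on finite
records. Measured response: a 0.05 Hz tone passes within 0.2%, a 0.3 Hz
(respiratory) tone is attenuated by >99.9%.

Only HbR is analyzed downstream; HbO is computed and stored but never used
as a model input, reflecting HbR's lower susceptibility to systemic
physiology.

## Windows, PCA and features

Turn = [press−2 s, press+2 s), no-turn = [press−6.5 s, press−2.5 s),
half-open at sample resolution with the press snapped to the nearest
sample; at 2 Hz each window holds 8 samples and each intersection yields
exactly 2 epochs. Windows out of bounds are skipped with a warning, and
pairing in the effect maps is pairwise-complete.

Each window is standardized per channel (mean 0, SD 1 over its 8 samples;
flat windows map to zero). PCA treats every window time sample as an
observation and channels as variables, so eigenvectors are channel-space
loadings that can be mapped back onto the montage. Because of the window
standardization, per-channel variance is ~1 and the eigenvalue cutoff 0.7
behaves like a correlation-matrix Kaiser/Jolliffe rule. The first
component is dropped; components 2–8 (inclusive — 7 features, so that
7 + 2 context = 9 combined features) feed the classifiers regardless of
how many further components pass the cutoff. One instance is one window
time sample; context features repeat across a window's 8 samples. This
reading is forced by the instance arithmetic: 100 × 2 × 8 = 1,600
instances per subject and 1,280 training instances in an 80/20 fold.

Cross-validation is grouped by intersection by default (all 16 instances
of an intersection on the same side of the split) to prevent within-event
leakage; ungrouped splitting is available. PCA eigenvectors and the
feature standardization (mean/SD of the continuous features from the
training split; the discrete cars-waited count passes through unscaled)
are refitted inside every fold and frozen for the test projection.

## Classifiers

All variants use the same network: input → 25 ReLU → 25 ReLU → sigmoid,
10% inverted dropout on the hidden layers during training only, binary
cross-entropy, Adam (lr 1e-3, β = 0.9/0.999), 500 epochs, full-batch by
default (batch size is configurable; on 1,280 × ≤9 inputs full-batch Adam
converges comfortably within 500 epochs and keeps training deterministic
and fast). Weights are seeded uniform fan-in; identical seeds give
bit-identical predictions. The implementation is a compact numpy network:
it keeps dropout (absent from off-the-shelf MLP classifiers in the
dependency set), full determinism and a trivially batchable forward pass
for the attribution step. Thresholds: 0.5 for confusion matrices; ROC is
swept over all score thresholds and AUC integrated by trapezoid. Headline
accuracy is the median over folds (and subjects at cohort level); pooled
accuracy over concatenated test folds is also reported.

## Shapley attribution

`shap_mc` is the permutation estimator: per feature j, M draws of a random
feature permutation and a random background row; x₊ⱼ takes the instance's
values on j and on features preceding j in the permutation and background
values elsewhere; x₋ⱼ additionally replaces j. φ̂_j is the mean prediction
difference, with a per-feature Monte-Carlo standard error available
(`shap_mc_se`). The background is empirical — by default the training
split ("random feature values" = marginal imputation). Default M = 2,000,
at which the SE is a few percent of the largest |φ| on the synthetic
fixture. `shap_exact` enumerates all 2^p coalitions (p ≤ 12) with the same
background-imputation value function and satisfies efficiency, symmetry,
dummy and linearity to machine precision; it is the oracle for the
estimator in the tests. Global importance is the mean absolute φ per
feature; beeswarm exports carry min–max normalized feature values for
color-coding.

## Effect maps

Per channel, each intersection contributes the pair (mean HbR in the turn
window, mean HbR in the no-turn window); the reduction to window means is
the default (a peak option exists). The paired t and d = mean/SD of the
differences use the sign convention diff = no-turn − turn, so positive d
means a stronger HbR decrease (more activation) while deciding to turn.
d = t/√n holds identically. An exactly null difference gives d = 0; a
constant nonzero difference with zero spread has no defined d and is
flagged NaN. Group maps average subject t values channel-wise over the
common channel frame and convert via d = t̄/√n̄; averaging attenuates
idiosyncratic effects roughly by 1/√S, which is why group maps span ~±0.2
where single subjects reach |d| ≈ 1. No multiple-testing correction is
applied — the maps are descriptive effect sizes.

## Problem sizes and determinism

The default protocol (100 intersections, 107 channels, 2 Hz) runs one full
subject — simulation through three cross-validated models — in under ten
seconds; the test suite and the acceptance script use full-protocol
subjects for the design arithmetic, the 12-subject cohorts for the
ordering and null analyses, and reduced channel counts (24–40) where the
quantity under test does not depend on the montage size. Cohort subject
seeds derive from a master seed through a counter scheme
(SeedSequence(master, spawn_key=(i,))), so cohorts are reproducible as a
whole and per subject. All randomness flows from explicit generators; no
global state.

## What the synthetic data does and does not show

The generator reproduces the design's structure: the instance bookkeeping,
the class balance, the context/brain information split, a global
physiological subspace for the first PC, a fat channel covariance
spectrum, and atypical decisions whose information lives only in the
brain channel. It does not emulate motion artifacts beyond what the spike
criterion needs, optode-scalp coupling variation, anatomy (no MNI/Brodmann
mapping — channel indices are the sensor space), inter-subject variability
in HRF shape, or temporal autocorrelation structure beyond the modeled
oscillations. Passing tests therefore demonstrate the correctness and the
qualitative behavior of the pipeline under controlled conditions — e.g.
that combining context with brain features halves the missed-turn rate
when atypical turns carry amplified activation — not that real recordings
reach any particular accuracy. Absolute accuracies on synthetic subjects
(e.g. fNIRS-only ~0.70) depend on the chosen noise regime and are reported
as computed, not tuned to match any external figure.
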