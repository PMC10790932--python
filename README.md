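# turnintent

Recognition of a driver's intent to turn left through oncoming traffic at an
unsignalized intersection, from functional near-infrared spectroscopy (fNIRS)
brain activation combined with situational context (the gap in traffic and
the waiting time). The package is a complete, synthetic-data-driven
re-implementation of that analysis: because no human recordings are
distributed, a forward model generates behaviorally and physiologically
realistic sessions with known ground truth, and every downstream stage —
preprocessing, feature extraction, classification, attribution, effect
mapping — is validated against that ground truth.

## What it computes

**Behavior.** A subject faces 100 intersections in 10 blocks. Oncoming cars
(~8–10 per intersection, ~50 km/h) present gaps of 1–6 s (14–84 m). A gap of
size *g* after *w* cars is accepted with probability
σ(k·(g − (g_c − r·w))): a logistic gap-acceptance rule whose effective
critical gap g_c shrinks as the driver waits (urgency). With small
probability the driver takes an "atypical" sub-threshold gap; those
decisions carry amplified neural activation.

**Signal.** Each of 107 channels records two-wavelength (760/850 nm) light
attenuation at 2 Hz. Active channels carry a negative-going
deoxyhemoglobin (HbR) response — a double-gamma hemodynamic response
convolved with a 4-s boxcar starting 2 s before the accelerator press —
inside global cardiac / respiratory / Mayer-wave physiology, spatially
correlated slow noise, drift and white noise. Preprocessing inverts the
modified Beer–Lambert law (ΔOD = −log₁₀(I/I₀), 2×2 extinction solve, path
length × DPF) and band-passes 0.01–0.1 Hz, zero phase.

**Features.** Per intersection, a "turn" window [press−2 s, press+2 s) and a
"no-turn" window of 4 s ending 0.5 s earlier; 8 samples each at 2 Hz, so
100 × 2 × 8 = 1,600 instances per subject. Windows are standardized per
channel, PCA is fitted on training folds only (channels as variables),
components with eigenvalues < 0.7 are discarded, the first component
(systemic physiology / movement) is dropped, and components 2–8 are the 7
fNIRS features. Context features are the gap on offer and cars waited at
each window.

**Models.** Three multilayer perceptrons — context-only (2 features),
fNIRS-only (7), combined (9) — each 2 hidden layers × 25 ReLU units, 10%
dropout, sigmoid output, binary cross-entropy, Adam, 500 epochs, five-fold
cross-validation grouped by intersection. Accuracy is
(TP+TN)/(TP+TN+FP+FN) with "turn" positive, so a false negative is a missed
turn — the safety-critical cell.

**Attribution.** Permutation-sampling Monte-Carlo Shapley values
φ̂_j = (1/M) Σ_m (f̂(x₊ⱼ) − f̂(x₋ⱼ)) with the training split as background,
global importance I_j = (1/n) Σ_i |φ_j(i)|, and an exact 2^p enumeration
oracle used in tests.

**Effect maps.** Channel-wise paired t over intersections between turn and
no-turn window means, Cohen's d = t/√n, and group maps from channel-wise
averaged t statistics.

## Worked example

```bash
python analysis/01_simulate_subject.py --seed 1
python analysis/04_train_models.py --seed 1
python analysis/07_cohort.py --seed 1
```

The single-subject run (seed 1) prints:

```
context   median accuracy 0.825, AUC 0.914 +/- 0.021, missed-turn rate 0.230
fnirs     median accuracy 0.688, AUC 0.784 +/- 0.048, missed-turn rate 0.324
combined  median accuracy 0.869, AUC 0.945 +/- 0.026, missed-turn rate 0.125
```

and the 12-subject cohort:

```
  context   median accuracy 82.5%, AUC 0.91 +/- 0.02, missed turns 23.4%
  fnirs     median accuracy 69.8%, AUC 0.75 +/- 0.05, missed turns 36.8%
  combined  median accuracy 84.7%, AUC 0.93 +/- 0.02, missed turns 16.1%
combined model lowers the missed-turn rate for 11/12 subjects (sign test p = 0.0032)
```

Read: context alone recognizes typical turns well but misses almost a
quarter of actual turns — precisely the atypical small-gap decisions a
gap/waiting-time model cannot see. Adding the brain features roughly halves
the missed-turn rate, and the advantage is consistent across subjects. The
attribution analysis (`analysis/05_shapley.py`) shows gap size as the most
important single feature and, on the turns the context model misses but the
combined model rescues, the brain features carrying most of the attribution
mass. `analysis/06_effect_maps.py` recovers the injected activation
channels from the top Cohen's-d ranks (recall 1.0 at seed 1) and shows the
group-level attenuation of d.

The numbered scripts under `analysis/` are thin narrative drivers over the
library in `src/turnintent/`; each writes its tables under
`results/analysis/`. The same stages are scriptable via the `turnintent`
CLI (`simulate`, `preprocess`, `run`, `cohort`).

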