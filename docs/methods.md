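# Methods

This note documents the models, statistical procedures, and synthetic
data underlying `eegfuse`, together with the numerical choices that are
not visible from the API.

## Problem setting

Subject-independent emotion recognition from 62-channel EEG (10–20
montage): a classifier trained on one set of subjects must predict the
emotion class {negative, neutral, positive} of trials from an unseen
subject. EEG feature distributions shift strongly between individuals
(the domain-shift problem), and part of that shift is structured by
demographics — age, sex, and cultural background. The package evaluates
whether fusing demographic covariates into the classifier improves
generalization to unseen subjects, and interprets how much each
covariate contributes.

## Feature extraction

1. **Band-pass filtering.** Each trial is filtered to 1–75 Hz with a
   4th-order Butterworth filter applied forward–backward
   (`sosfiltfilt`), i.e. zero phase and effectively 8th-order
   attenuation. The order and phase handling are our choice (standard
   practice); only the pass band is prescribed. Trials are filtered in
   full before windowing — per-window filtering would differ at window
   edges and is not supported.
2. **Windowing.** Non-overlapping 4-s windows from time zero; a
   trailing remainder is discarded. An overlap option exists but
   defaults to zero.
3. **Differential entropy (DE).** Per window, channel and canonical
   band (δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–50 Hz, half-open
   intervals so bands never share a DFT bin), the band power σ²_ch,b is
   the mean one-sided periodogram over the band's bins, with the
   periodogram normalized so its total equals the window's mean square
   value (Parseval-consistent; rectangular taper). DE is then
   ½·ln(π·e·σ²) under a Gaussian signal model. Note this convention
   omits the factor 2 of the standard Gaussian differential entropy
   ½·ln(2π·e·σ²); the offset is a constant −½·ln 2 per dimension and
   vanishes after standardization. `convention="standard"` restores the
   textbook value. Since any consistent DFT normalization shifts DE
   only additively per band, consistency — not the particular
   normalization — is the contract.
4. **Standardization.** DE features are z-scored per subject per
   session (sample SD, ddof = 1). This uses no labels, so applying it
   with the held-out subject's own session statistics leaks nothing.
   Constant dimensions map to zero with a warning; single-sample groups
   are rejected.
5. **Demographics.** (age, sex, nationality) encode as a 4-vector
   (age, sex bit, nat₁, nat₂) with nationality dummy-coded
   Chinese (0,0) / French (1,0) / German (0,1), then z-scored with
   statistics of the *training* subjects of the current fold.

The 62 × 5 window features flatten channel-major to the 310-vector the
EEG branch consumes.

## Models

Four backbones of comparable capacity (all ending in a linear layer to
3 logits, cross-entropy loss, fixed epochs, batch size 32):

| model | structure | defaults |
|---|---|---|
| `cnn` | 2 × [Conv 3×3 (32, then 64 filters) → ReLU → max-pool (2,1) → dropout 0.2] → FC | 30 epochs, SGD, lr 1e-3 |
| `gnn` | graph conv 5→8 over the montage graph → ReLU → dropout 0.2 → FC | 50 epochs, SGD, lr 1e-2 |
| `gnn_lstm` | graph layer per window → BiLSTM (32 hidden/direction) → dropout → FC | 80 epochs, AdamW, lr 1e-3, wd 0.1 |
| `gnn_transformer` | graph layer (SiLU, dropout, layer-norm) per window → 496-d tokens + learnable positions → 1 encoder layer (4 heads, FF 992, dropout 0.3) → mean pool → FC | 80 epochs, AdamW, lr 1e-3, wd 0.1 |

The montage graph connects electrodes within 60 mm on a realistic adult
head (standard 10-05 coordinates; the cerebellar leads CB1/CB2 map to
I1/I2, the nearest labelled positions) and is symmetrically
degree-normalized with self-loops, D^{-1/2}(A+I)D^{-1/2} — first-order
(Kipf-style) aggregation, chosen because the graph-convolution variant
was otherwise open. 60 mm is the smallest round threshold at which
immediate 10–20 neighbours (e.g. FP1–FP2, ~59 mm apart) are connected.

Sequence models classify runs of `W` consecutive windows of a trial
(default `W` = 10, i.e. 40 s; trailing windows drop; shorter trials are
excluded with a warning). `cnn`/`gnn` classify single windows.
Per-trial labels, where wanted, come from majority vote over the
trial's sequences.

All neural components run on a compact NumPy reverse-mode autodiff
engine (`eegfuse._autograd`, `eegfuse.nn`) written for this package;
training is deterministic given the seed (dropout and shuffling draw
from a per-model generator), so every experiment is exactly
reproducible.

## Attention fusion (extended model)

The transformer's pooled 496-d embedding projects to 16 units (O₁);
the encoded 4-d demographic vector projects, without bias, to 16 units
(O₂ = X₂·L). A learnable 16-vector A gates the two modalities per
dimension:

    ω₁ⱼ = exp(Aⱼ O₁ⱼ) / (exp(Aⱼ O₁ⱼ) + exp(Aⱼ O₂ⱼ)),   ω₂ = 1 − ω₁
    O_fusion = ω₁ ⊙ O₁ + ω₂ ⊙ O₂

computed in the numerically stable sigmoid form
ω₁ = σ(A ⊙ (O₁ − O₂)); ω₂ is stored as the exact complement 1 − ω₁.
The per-dimension (vector-ω) reading is used rather than a scalar dot
product: it is the only reading consistent with a 16-entry ω and with
indexing its j-th component in the importance analysis; the scalar
variant is one configuration switch away. The demographic projection
carries no bias so O₂ = X₂·L holds exactly as the importance analysis
assumes. A concatenation head (O₁ ⧺ O₂ → linear) exists as the internal
fusion baseline. Fusion weights are recorded on test folds only.

## Evaluation

**LOSOCV.** One fold per subject; the held-out subject contributes
nothing to model fitting or demographic scaling statistics. Per-fold
seeds derive deterministically from the master seed and fold index.
Each fold records SHA-256 hashes of its train/test sample identifiers
and its training-subject list; `verify_no_leakage` recomputes and
asserts them.

**Metrics.** Accuracy, per-class recall/precision/F1 (per-class
accuracy = class recall), macro F1, macro one-vs-rest ROC-AUC, and the
3×3 confusion matrix, via scikit-learn (hand-enumeration oracles in the
tests).

**Grid search.** lr ∈ {1e-5, 1e-4, 1e-3, 1e-2} × wd ∈ {0, 1e-4, 1e-3,
1e-2, 1e-1}, scored on a fixed subject-grouped 80/20 split of the
training cohort. Scoring on the training data itself would reward
memorization, so the grouped split is a deliberate deviation from
scoring "performance on the training data"; ties break to the lower
learning rate, then lower weight decay. No early stopping anywhere —
fixed epochs keep the training budget identical across folds.

**Ablation.** Each demographic variable is removed in turn (age: 1
column, sex: 1, nationality: 2; the demographic projection resizes),
the extended LOSOCV re-runs, and pooled per-class and overall
ROC-AUC are reported next to accuracy.

## Statistics

* **Paired Wilcoxon signed-rank**, two-sided. Zero differences are
  discarded (classic convention); |d| ranked with average ranks for
  ties. For n ≤ 12 the exact null is enumerated over all 2ⁿ sign
  assignments; beyond that, the normal approximation with tie
  correction (no continuity correction). p = min(1, 2·min(tails)).
* **Bonferroni**: p → min(1, m·p), with the family = all group ×
  outcome cells actually tested within one grouping (nationality, sex,
  or the age dichotomy ≤23 vs >23). Cells with fewer than two subjects
  are flagged and not tested. Evidence tiers: p < 0.01 strong,
  < 0.05 moderate, < 0.1 weak.
* **Confidence intervals** for mean differences: Student-t
  (mean ± t_{n−1,(1+level)/2}·SD/√n); a percentile bootstrap is
  available behind a flag.
* **Importance.** Per subject and emotion category (conditioned on
  true labels by default, predicted optionally): the subject's mean ω₂
  over that category's samples forms |ω̄₂ⱼ·L_ij|, averaged over the 16
  fused columns to a per-variable vector, normalized to sum to one,
  then averaged across subjects. Cells with zero ω₂ mass are excluded
  with a warning.

## Synthetic cohorts

The generator emulates the structure of the three-site
emotion-recognition corpora recorded with 62-channel caps: by default
15/8/8 subjects of Chinese/French/German nationality, 45/63/54
recordings per subject over 3 sessions, class-balanced labels, ages
19–29, site-specific male ratios (7/15, 5/8, 7/8). Sampling rate
defaults to 200 Hz (not fixed by the corpora descriptions;
configurable); trial length defaults to 60 s.

Signals are sums over the five bands of band-limited Gaussian noise,
band-limited with the same Butterworth design the preprocessing uses.
The expected in-band power of band b factorizes as

    baseline_b × emotion(label, b) × Π_g demographic(g, b)
               × Π_g interaction(g, label, b) × subject_b × trial_b

over the subject's groups g (nationality, sex, age ≤23 vs >23), with
log-normal subject effects (SD `subject_sd`, default 0.1) and mean-one
log-normal per-trial fluctuations (`trial_sd`, default 0.2) shared
across channels. The trial-level fluctuation models the trial-to-trial
band-power variability of real recordings; without it, 62 channels of
independent noise would make any band effect nearly perfectly decodable
and every comparison would saturate.

Two numerical points:

* **Leakage compensation.** Butterworth skirts plus the rectangular
  window's periodogram sidelobes move several percent of each
  component's power into neighbouring bands — enough to push the
  realized window power of θ/β/γ ~5–9 % above target at the default
  1/f-like power profile. The generator therefore measures a 5×5
  band-to-band leakage matrix M once (500 windows of noise, fixed
  internal seed, cached) and scales components to M⁻¹·targets, so the
  *composite* signal meets the per-band window-power contract to
  within ~1–2 %. If a target profile is so contrasted that
  compensation would need a negative component, it falls back to
  uncompensated targets with a warning.
* **Interactions, not main effects.** A multiplicative demographic
  main effect on band power is an additive per-subject constant on DE
  and is removed exactly by per-session z-scoring; only
  emotion-by-group interactions can make demographics informative.
  The `interaction_effects` table exists for precisely this reason and
  is empty by default.

What the generator does **not** emulate: eye-blink/EMG artifacts,
volume conduction (channels are conditionally independent given the
trial's band powers), within-trial nonstationarity, and realistic
spatial topographies (channel gains default to 1). Passing tests on
these cohorts therefore demonstrate the pipeline's statistical
machinery — not performance on real EEG.

## The demographic-fusion study (`eegfuse.study`)

A scaled-down end-to-end experiment sized for a single CPU: 12
subjects (4 per nationality), 18 trials per subject over 3 sessions,
20-s trials, sequences of W = 5 windows, 20 training epochs, three
replicate cohorts plus a zero-effect control, with the nationality
ablation and the fusion-weight/importance interpretation on top.

The study cohort's demographic structure is a nationality-dependent
**emotion-to-pattern permutation**: all sites express the same three
β/γ band-power patterns (negative/neutral/positive responses), but
French subjects swap the neutral and positive responses and German
subjects the negative and neutral ones. Because every subject expresses
the same set of patterns, per-session standardization leaves the three
feature-space clusters in identical positions for every site — only the
cluster-to-label assignment varies. A group-blind decoder therefore
faces mixed labels on every cluster (best-case accuracy 5/9 by majority
vote), while a nationality-aware decoder can in principle decode
everyone. This is the sharpest construction we found: designs that
merely shift one band per group either stay decodable group-blind
(any unique (group, class) feature signature identifies the label) or
collapse within-group separability. Age and sex carry no effect, which
pins down the expected ablation ordering (nationality ≫ age, sex) and
the expected importance mass.

Study hyperparameters: lr 1e-2, weight decay 0, selected from the
standard search grid at this problem size — the full-scale recipe
(lr 1e-3, wd 0.1, 80 epochs) over-regularizes the fusion gate in a
20-epoch budget. Both approaches share the configuration, mirroring the
equal-tuning comparison philosophy.

## Known limitations

* The NumPy training stack is single-threaded and sized for the study
  scale; full-scale cohorts (31 subjects × 60-s trials, 80 epochs) are
  supported but slow.
* The permutation construction is an extreme form of cultural response
  difference; real demographic effects are surely milder, so the
  study's effect sizes say nothing about the magnitude of real-data
  gains.
* EDF export is not implemented (the HDF5 container is the native
  format); EDF reading requires `mne`.
* The exact-Wilcoxon enumeration is O(2ⁿ) and switches to the normal
  approximation above n = 12.
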