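# eegfuse

Subject-independent EEG emotion recognition with attention-based fusion
of differential-entropy features and demographic covariates.

EEG responses to emotional stimuli differ so much between individuals
that a classifier trained on one group of subjects often transfers
poorly to a new person — the domain-shift problem of subject-independent
affective computing. Part of that shift is structured: age, sex, and
cultural background modulate how emotions register in band power. This
package implements and evaluates a deep model that *fuses* the EEG
representation with those demographic covariates, for researchers who
want to quantify whether, where, and for whom demographic awareness
helps.

## The method

**Features.** Each 62-channel recording (10–20 montage) is band-pass
filtered to 1–75 Hz (zero-phase Butterworth), cut into 4-s windows, and
summarized per channel and canonical band (δ, θ, α, β, γ) by the
differential entropy of a Gaussian process with the window's band power
σ²:

    DE_ch,b = ½ ln(π e σ²_ch,b),    σ²_ch,b = (1/N_b) Σ_k |X[k]|²-normalized

giving a 62 × 5 matrix per window (310 features), z-scored per subject
per session. Demographics encode as (age, sex, nat₁, nat₂) with
nationality dummy-coded Chinese (0,0) / French (1,0) / German (0,1),
standardized with training-fold statistics.

**Models.** Four backbones — CNN, GNN over the electrode-proximity
graph, GNN+BiLSTM, and GNN+Transformer (62×8 = 496-d tokens, 4 heads,
mean pooling) — share a 3-class head and training protocol. The
*extended* model projects the transformer embedding to O₁ ∈ ℝ¹⁶ and the
demographic vector to O₂ = X₂L ∈ ℝ¹⁶, then gates them per dimension
with a learnable vector A:

    ω₁ = σ(A ⊙ (O₁ − O₂)),  ω₂ = 1 − ω₁,  O_fusion = ω₁⊙O₁ + ω₂⊙O₂

**Evaluation.** Leave-one-subject-out cross-validation (train on all
other subjects, test on the held-out one), accuracy / macro-F1 /
macro-AUC per fold, paired Wilcoxon signed-rank tests (exact null for
n ≤ 12) with Bonferroni correction across demographic groups, a
demographic ablation, and an interpretation of the learned fusion
weights ω and of per-variable importance |ω̄₂ ⊙ L| rows.

A synthetic-cohort generator (`eegfuse.synth`) emulates the three-site
structure of the benchmark emotion corpora — subject counts, sessions,
class balance, age range, sex ratios — with band-limited Gaussian EEG
whose band powers respond to emotion class, demographic group, and
subject/trial random effects, so the entire pipeline is testable
without access to any licensed recordings. See `docs/methods.md` for
the full model and design documentation.

## Worked example

```python
import numpy as np
from eegfuse import (CohortSpec, generate_cohort, prepare_features,
                     attention_fuse, paired_wilcoxon, difference_ci)

spec = CohortSpec(
    n_subjects_per_nationality={"Chinese": 2, "French": 2, "German": 2},
    trials_per_subject=6, sessions=2, trial_seconds=12.0,
    emotion_effects={("positive", "gamma"): 1.5, ("negative", "gamma"): 0.7},
    seed=42)
cohort = generate_cohort(spec)
dataset = prepare_features(cohort, sequence_length=3)

gamma = dataset.X_win[:, :, 4].mean(axis=1)
for cls, name in enumerate(("negative", "neutral", "positive")):
    print(f"mean z-scored gamma DE, {name}: "
          f"{gamma[dataset.y_win == cls].mean():+.3f}")
```

prints

```
mean z-scored gamma DE, negative: -1.057
mean z-scored gamma DE, neutral: +0.058
mean z-scored gamma DE, positive: +0.999
```

— the generator's multiplicative gamma-power effects (×0.7 negative,
×1.5 positive) surface as ordered differential-entropy shifts after
standardization, exactly the structure the classifiers consume. The
fusion gate and the group statistics are equally direct:

```python
fused, w1, w2 = attention_fuse(np.array([2.0, -1.0, 0.5]),
                               np.array([0.0, 1.0, 0.5]),
                               np.array([1.0, 1.0, 0.0]))
print("omega1 =", np.round(w1, 4), " fused =", np.round(fused, 4))

gains = [0.02, 0.05, -0.01, 0.04, 0.03, 0.06, 0.00, 0.02]
res = paired_wilcoxon(gains)
lo, hi = difference_ci(gains)
print(f"Wilcoxon p = {res.p_value:.4f} ({res.method}); "
      f"95% CI [{lo:+.4f}, {hi:+.4f}]")
```

```
omega1 = [0.8808 0.1192 0.5   ]  fused = [1.7616 0.7616 0.5   ]
Wilcoxon p = 0.0312 (exact); 95% CI [+0.0063, +0.0462]
```

Where A = 0 the gate is a plain average (ω₁ = 0.5); where the EEG
coordinate dominates its logit, ω₁ → 1. The per-subject accuracy gains
of a demographically extended model over its baseline feed the same
`paired_wilcoxon` / `difference_ci` machinery.

Classifiers follow scikit-learn conventions:

```python
from eegfuse import EmotionBackboneClassifier, losocv
clf = EmotionBackboneClassifier(architecture="gnn_transformer", seed=0)
clf.fit(dataset.X_seq, dataset.y_seq)          # sequences of DE windows
folds = losocv(dataset, approach="extended")   # leave-one-subject-out
```

A CLI covers simulation and evaluation:
`eegfuse simulate --config cohort.yaml --out DIR --seed 3` and
`eegfuse losocv --config run.yaml --approach extended --out DIR`.

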