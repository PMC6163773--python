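# ahar — activity recognition from sound with transfer-learning augmentation

Everyday activities — running a shower, brewing coffee, washing dishes —
produce characteristic sound. Recognizing them from a microphone signal is
useful for ambient monitoring and digital-health applications, but real
activity corpora are strongly imbalanced: some classes come with hundreds of
clips, others with a handful. `ahar` implements a full recognition chain
for this setting, built around a statistical data-augmentation idea: find
the class that is *statistically closest* to each data-poor class, learn a
feature-space transformation from the rich class to the poor one, and train
the poor class's model on real plus transformed data.

The chain:

1. **Features** — per 30 ms frame: 13 MFCCs + 13 velocities (26 dims),
   MPEG-7 spectrum centroid/spread/flatness descriptors (30 dims), and
   perceptual wavelet-packet features over Bark critical bands (22 dims);
   normalized with training-set statistics.
2. **Proximity** — per-class diagonal GMMs `G_i`; class distance is the
   symmetrized Kullback–Leibler divergence estimated by Monte Carlo,
   `KL(M‖N) ≈ (1/ω) Σ_i log[p_M(x_i)/p_N(x_i)]`, `x_i ~ M`, ω = 2000;
   the donor `C_d` of a limited class `C_l` is the arg-min over candidates.
3. **Transfer** — an echo-state network `x(k) = tanh(W_in u(k−1) +
   W_res x(k−1))` with ridge-regression readout
   `W_out = (XᵀX + εI)⁻¹XᵀD` learns the donor→limited MIMO map
   `F_l′ = f_RN(F_d)`; donor clips pushed through `f_RN` become synthetic
   limited-class clips.
4. **Recognition** — per-class left–right HMMs with GMM emissions
   (Baum–Welch), or a universal ergodic HMM adapted to each class by
   MAP (relevance-factor) updates; maximum per-frame forward likelihood
   decides.
5. **Evaluation** — repeated stratified 3-fold cross-validation of the four
   variants (cHMM, cHMM-TL, uHMM, uHMM-TL) with row-normalized confusion
   matrices and a programmatic no-leakage audit on every fold.

A deterministic synthetic-corpus generator (band-limited noise + harmonic
stacks with per-clip device-like variability, classes in linked pairs with
known ground-truth transformations) makes the whole chain testable without
any external data. See `docs/methods.md` for models, parameters and
limitations.

## Worked example

```python
import numpy as np
from ahar import (ExperimentConfig, default_test_corpus, extract_features,
                  fit_normalizer, fit_gmm, closest_class, run_experiment)

# 199 clips, 8 classes, counts 60 down to 4 — a strongly imbalanced corpus
clips, manifest = default_test_corpus(seed=1)

# which data-rich class is statistically closest to the 4-clip class?
feats = [extract_features(c, "mfcc") for c in clips]
norm = fit_normalizer(feats)
by_class = {}
for f in (norm.apply(f) for f in feats):
    by_class.setdefault(f.label, []).append(f)
models = {c: fit_gmm(np.vstack([f.values for f in fs])[:4000], 16, seed=0,
                     label=c) for c, fs in by_class.items()}
pairing = closest_class("no_activity", models, draws=2000, seed=0)
print(pairing.donor_class, round(pairing.divergence, 1))
# hand_washing 37.5

# the full four-system comparison (scaled-down grids, 10 repetitions)
report = run_experiment(ExperimentConfig.scaled_down(repetitions=10, seed=1),
                        clips)
for system, rate in report.average_rate.items():
    print(f"{system}: {rate:.1f}%")
```

The pairing step reports that the 4-clip *no activity* class is closest to
*hand washing* (its designed donor) with symmetrized divergence ≈ 38, far
below the next candidate. The experiment prints the average recognition
rate (mean per-class recall) of each variant; on this corpus the
transfer-augmented class-specific system scores about two points above its
plain counterpart, with the gain concentrated in the data-limited classes.
`report.confusion[...]` holds the row-normalized confusion matrices and
`report.per_class_recall[...]` the per-class diagonal.

The same chain is scriptable from the shell:

```bash
ahar synth   --out corpus --seed 3 --duration 2.5
ahar extract --manifest corpus/manifest.csv --features mfcc --out feats
ahar pair    --features feats --limited no_activity --limited use_microwave \
             --out pairing.json
ahar run     --scaled --seed 1 --out results/
```

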