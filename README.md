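# emfspeech

Classification of children with developmental disorders (DD: autism
disorder, PDD-NOS, or specific language impairment) versus typically
developing (TD) children from utterance-level acoustic speech features —
using each child's **emotional modulation function (EMF)** rather than the
acoustic features themselves.

## The idea

Acoustic features of a single utterance are a poor direct marker of a
developmental disorder: utterance-level classifiers hover near chance.
What does differ between children is *how* their voice features co-vary with
the emotional valence of what they are saying.  `emfspeech` models this
per-child modulation and uses it as the subject-level signature:

1. **Valence-correlated selection.** For subject *i* and feature *j*, the
   Pearson correlation ρ<sub>j,i</sub> between the feature column and the
   valence sequence e(k) ∈ {−1, 0, +1} is computed; features with
   |ρ<sub>j,i</sub>| > 0.7 for some subject form the shared set
   S = ∪<sub>i</sub> S<sub>i</sub> of N_opt features (with optional
   mutual-correlation redundancy pruning).
2. **Per-valence moments.** The subject's utterances are grouped by valence
   class; each class and feature is summarized by skewness, mean and
   kurtosis, giving a 3 × 3·N_opt moment matrix **M**<sub>i</sub> with rows
   for valence −1, 0, +1.
3. **The EMF.** The subject's signature is the minimum-norm least-squares
   solution **B**<sub>i</sub> of
   **M**<sub>i</sub>**B**<sub>i</sub> = (−1, 0, +1)ᵀ (Moore–Penrose
   pseudoinverse; the system is underdetermined for N_opt ≥ 2).
4. **Dynamic feature selection + linear SVM.** Signatures are stacked into a
   matrix **D** (one row per child, binary label TD/DD).  Under
   leave-one-subject-out cross-validation, a three-gate cascade re-selects
   EMF coefficients *for each held-out child*: a Fisher-discriminant-score
   gate (training only), a Mahalanobis-ratio gate and a Gaussian
   class-probability gate (both conditioned on the test vector).  A linear
   SVM (C = 1, training-fold standardization) makes the final call.

The companion generator (`emfspeech.simulate`) produces cohorts with the
statistical structure this analysis assumes — 68 TD and 34 DD children in
three subgroups, 15/6/5 negative/neutral/positive utterances per child,
valence-modulated signal features with group-dependent slopes plus nuisance
features — so the whole pipeline is testable without the access-restricted
clinical corpus it was designed for.

## Worked example

```bash
python examples/03_loso_classification.py
```

prints, for the default strong-effect synthetic cohort (seed 0):

```
EMF dataset: 102 subjects x 30 coefficients

confusion (TD neg / DD pos): TN=67 FP=1 FN=1 TP=33
sensitivity 97.1%   specificity 98.5%
balanced accuracy 97.8%   AUC 0.999
  PDD-NOS: 9/10 recognized (90%)
  SLI: 13/13 recognized (100%)
  AD: 11/11 recognized (100%)
```

102 children, 10 selected features → 30 EMF coefficients each.  Balanced
accuracy (mean of the two class recalls) is immune to the 2:1 TD:DD
imbalance; the subgroup lines show how many children of each DD subgroup
were recognized as DD.  `examples/04_standard_vs_emf.py` runs the central
contrast: on a cohort where the groups differ *only* in modulation slopes
(matched per-utterance feature distributions), utterance-level baselines
score ~50% while the EMF pipeline scores ~100%.

Other entry points: `examples/01_simulate_cohort.py` (the generative
model), `examples/02_emf_signature.py` (moment matrix and EMF for one
child), and a thin CLI (`emfspeech simulate|select|classify|baseline|report`)
over the same library calls.

## Layout

- `src/emfspeech/data.py` — feature-table and manifest I/O, cohort validation
- `src/emfspeech/simulate.py` — synthetic cohort generator with ground truth
- `src/emfspeech/selection.py` — valence correlation, union, redundancy pruning
- `src/emfspeech/emf.py` — moment matrices, EMF estimation, dataset assembly
- `src/emfspeech/dfs.py` — the three-gate dynamic feature-selection cascade
- `src/emfspeech/evaluate.py` — LOSO evaluation, metrics, selection frequency
- `src/emfspeech/baselines.py` — FS1/FS2 utterance-level baselines, valence LDA
- `src/emfspeech/pipeline.py`, `cli.py` — orchestration, configs, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
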