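# Methods

## Model and procedure

`emfspeech` treats diagnosis classification as a two-stage problem.  Stage
one is personalised: for each child, the relation between acoustic features
and utterance valence is summarised by a single coefficient vector, the
emotional modulation function (EMF).  Stage two is population-level: those
vectors become the rows of a dataset on which a standard supervised
classifier is trained and evaluated subject-wise.

**Assumptions.**  Valence labels {−1, 0, +1} are treated as a numeric scale,
both in the Pearson selection step and as the regression target.  The
per-valence feature distributions of one child are assumed exchangeable
across utterances (no time/order structure is modelled) and are summarised
by three moments per feature: mean, skewness (m₃/m₂^{3/2}) and non-excess
kurtosis (m₄/m₂²), all from population central moments (divide by N).  These
normalised forms are used instead of raw central-moment sums so that the
descriptors are scale-free; a zero-variance class yields skewness 0 and
kurtosis 0 with a degeneracy flag rather than an error.

**EMF estimation.**  The per-subject system M·B = (−1, 0, +1)ᵀ has 3
equations and 3·N_opt unknowns, so its normal-equation form is singular
whenever N_opt ≥ 2.  B is therefore the minimum-norm least-squares solution
(Moore–Penrose pseudoinverse, `numpy.linalg.lstsq`), which coincides with
the normal-equation solution whenever that inverse exists, interpolates the
targets exactly whenever rank(M) = 3 (the generic case, verified in tests),
and is unique.  No intercept column is added and moment descriptors are not
standardised before the fit; standardisation happens only inside the
classifier, fitted on training folds.

**Dynamic feature selection.**  For each held-out subject the cascade
evaluates, per EMF coefficient:

- C1 — Fisher discriminant score FDS = SB/SW, with SB the squared scatter of
  the two class means about the global mean and SW the sum of per-class mean
  squared deviations (population form).  Kept iff FDS strictly exceeds the
  threshold.  SW = 0 with SB > 0 gives FDS = +∞ (always kept); SB = SW = 0
  gives 0.
- C2 — Mahalanobis ratio MR = M_near²/M_far, where M_near ≤ M_far are the
  scalar squared Mahalanobis distances (unbiased class variances) of the
  test element from the two class distributions.  Kept iff MR is strictly
  below the threshold.  The ratio is anchored at the class *nearer* the test
  element: an element typical of either class scores low, an outlier to both
  classes scores ≈ z², and an element midway between two well-separated
  classes scores ≈ (separation/2)² — the two situations the gate is meant to
  remove.  Anchoring the ratio at a fixed class instead would delete every
  class-2-informative feature exactly when the test subject belongs to
  class 2, collapsing sensitivity; the two forms agree whenever the test
  element is nearer class 1.
- C3 — maximum Gaussian class probability: the larger of the two fitted
  normal densities at the test element.  The default threshold is expressed
  in z-units (keep iff the nearer class mean is within 2.5 class SDs), which
  is invariant to per-feature rescaling; an absolute-density mode implements
  the literal density threshold.

Gates run in cascade (C2/C3 only on C1 survivors) and are stateless across
test subjects.  If the final mask is empty the C1 mask is used, then all
features, with the fallback recorded — a cross-validation run can never be
left featureless.  Degenerate statistics (zero class variance) propagate as
0/∞ by documented conventions rather than raising.

**Classifier and evaluation.**  A linear-kernel SVM with box constraint
C = 1 and per-feature z-standardisation fitted on the training fold only
("feature weighted standardization"); the held-out subject never contributes
to scaling statistics.  Leave-one-subject-out cross-validation keeps all of
a child's data on one side of the split.  Reports carry the confusion counts
(TD negative / DD positive), sensitivity, specificity, unbalanced and
balanced accuracy, PPV, NPV and a rank-based AUC (Mann–Whitney, ties ½)
over the signed SVM decision scores.  One published report labels the
quantity TN/(TN+FN) "FOR" although it is numerically the negative predictive
value; this package emits it as `npv` and documents the naming so both
readings are recoverable from the counts.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| selection threshold | 0.7 | per-subject \|ρ\| cut (strict >), dimensionless |
| redundancy threshold | 0.95 | greedy mutual-correlation prune cut; 1.0 removes only exact duplicates |
| min_per_valence | 3 | utterances per valence class needed for finite skew/kurtosis; subjects below are excluded, reported |
| th_FDS | p50 | C1 cut, resolved as a percentile of the training FDS distribution (scale-free) |
| th_MR | 1.0 | C2 cut on the nearer-anchored Mahalanobis ratio |
| th_P | 2.5 | C3 radius in z-units (density mode available) |
| SVM C | 1.0 | margin penalty |
| leakage mode | as-paper | selected-feature set from all subjects' valence annotations ("strict" recomputes per training fold) |

The cascade thresholds are deliberately scale-free (percentile, ratio,
z-units) so they behave comparably across feature magnitudes; all are
exposed in the run configuration.  The "as-paper" leakage default reflects
that selection uses valence annotations only, never diagnosis; the strict
mode exists because the held-out subject's valence structure can still
influence the shared feature set.

## The synthetic cohort

The generator emulates the statistical skeleton the analysis assumes, not
realistic acoustics.  Cohort shape: 68 TD, 10 PDD-NOS, 13 SLI, 11 AD
children; 15 negative, 6 neutral and 5 positive utterances per child,
mirroring the emotional composition of the picture book used for
elicitation.  Signal feature j of child i at utterance k is
a_ij·e(k) + b_ij + ε, ε ~ N(0, σ_ε²); slopes a_ij are drawn around
group-specific means with within-group SD; offsets b_ij ~ N(0, 1) model
subject baselines; nuisance features are standard-normal noise.

Default effect geometry: TD mean slope 1 on every signal feature; each DD
subgroup's mean slope is shifted by the effect size δ with a
subgroup-specific ±1 pattern.  The patterns share +1 on even-indexed
features and differ on odd-indexed ones: the shared component keeps the
pooled DD class on one side of a hyperplane (a precondition for the fixed
linear-margin classifier), while the differing components keep the three
subgroups mutually distinct for subgroup-level analyses.

Default scale: δ = 0.9 with within-group SD 0.3 (δ = 3 within-group SDs) and
σ_ε = 0.1.  The shift is set comparable to the base modulation itself —
i.e. DD children modulate some features almost not at all or twice as much,
the flattened/atypical-prosody picture the model encodes — because the EMF
transform has a δ-independent noise floor: skewness and kurtosis of a small
same-valence sample are scale-free statistics, so they contribute O(1)
sampling noise to the moment matrix however small σ_ε is, and the subject
offsets b rotate the minimum-norm solution.  A slope contrast well below the
base modulation is genuinely not recoverable through this transform at
n = 102.

A second geometry, `sign_flip`, gives TD mean slope +δ/2 and all DD
subgroups −δ/2.  With an equal number of negative and positive utterances
the per-utterance marginal distribution of every feature is then identical
across groups, so utterance-level classifiers are structurally blind while
the modulation difference remains maximal — the cohort used for the
paradigm-contrast experiment.

**What passing tests do and do not show.**  The generator's features are
conditionally Gaussian, exactly linear in valence, exchangeable within
class, and its nuisance features are independent noise.  Real acoustic
features are heavy-tailed, cross-correlated, nonlinearly valence-dependent
and confounded with age, sex and recording conditions.  Success on these
cohorts demonstrates that the implementation recovers planted modulation
structure under the model's own assumptions; it is not evidence about
clinical performance.

## Numerical choices and degenerate inputs

- Pearson correlations of zero-variance columns are flagged undefined and
  treated as 0, so constant nuisance features cannot crash a run or be
  selected.
- Redundancy pruning visits candidates in descending order of their
  strongest per-subject valence correlation, ties toward the lower column
  index; fully deterministic.
- Welch (unequal-variance) t is used for the FS1 ranking; a feature with
  zero variance in both groups and equal means ranks last (|t| = 0), with
  distinct means first (|t| = ∞); ties break by column order.
- The valence-recognition comparator uses a three-class linear discriminant
  with leave-one-utterance-out evaluation; a singular within-class scatter
  falls back to a shrinkage discriminant.
- All randomness (generator, classifier, fold order) is seed-pinned; reruns
  of a pipeline configuration produce byte-identical reports.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
default cohort size (102 subjects, ~2 650 utterances, 30 features); the
acceptance script averages the stochastic quantities over 3–5 generated
cohorts, which is where their Monte-Carlo error becomes small relative to
the effects being measured.

## Known limitations

- Real corpora enter through one CSV layout (one row per utterance); no
  audio processing or acoustic feature extraction is included.
- The DFS cascade is defined for the two-class problem only.
- The 4-class (subgroup) problem is reported descriptively (per-subgroup
  recall, selection frequencies) but no 4-class classifier is built.
- With "as-paper" leakage the selected-feature set is computed once from all
  subjects; cross-validated accuracy can be slightly optimistic relative to
  the strict mode.
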