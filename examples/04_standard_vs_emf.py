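"""The central contrast: utterance-level classification vs EMF signatures.

This cohort is built so the diagnosis groups differ ONLY in modulation
slopes (TD +, DD -) with a symmetric valence design, which makes the
per-utterance feature distributions of the two groups identical.  A
classifier fed raw utterance features (the standard paradigm, FS1/FS2) then
has nothing to learn from, while the EMF signature - which measures how
features co-vary with valence within each child - separates the groups.
"""

from emfspeech import (
    BaselineConfig,
    SyntheticConfig,
    baseline_evaluate,
    build_emf_dataset,
    generate_cohort,
    loso_evaluate,
    select_features,
)

cfg = SyntheticConfig(seed=0, slope_mode="sign_flip", utterances_per_valence=(8, 8, 8))
table, manifest, _ = generate_cohort(cfg)

selected = select_features(table, 0.7, 0.95)
dataset = build_emf_dataset(table, manifest, selected)
emf_report, _, _ = loso_evaluate(dataset, manifest=manifest)

fs1 = baseline_evaluate(table, manifest, BaselineConfig(mode="FS1", seed=0))
fs2 = baseline_evaluate(table, manifest, BaselineConfig(mode="FS2", seed=0))

print("balanced accuracy (TD vs DD):")
print(f"  EMF signature pipeline : {emf_report.balanced_accuracy:.1%}")
print(f"  FS1 (t-test + SVM)     : {fs1.balanced_accuracy:.1%}")
print(f"  FS2 (valence-corr + SVM): {fs2.balanced_accuracy:.1%}")
print("\nThe baselines hover at chance (50%) because the groups' utterance")
print("marginals are matched by construction; only the modulation structure")
print("differs, and only the EMF representation exposes it.")
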