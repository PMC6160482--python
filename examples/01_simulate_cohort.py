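"""Generate a synthetic story-telling cohort and inspect its structure.

The generator plants subject-specific modulation slopes: each signal feature
follows a*e + b + noise, where e is the utterance's valence (-1/0/+1).
TD children share one mean slope; the three DD subgroups (PDD-NOS, SLI, AD)
have shifted mean slopes, which is the diagnostic signal the EMF pipeline is
meant to recover.
"""

from collections import Counter

from emfspeech import SyntheticConfig, generate_cohort

config = SyntheticConfig(seed=0)
table, manifest, truth = generate_cohort(config)

print(f"subjects: {len(manifest)}  ->  {dict(Counter(manifest.diagnoses.values()))}")
print(f"utterances: {len(table.df)} rows, {table.n_features} features "
      f"({config.n_signal} valence-modulated, {config.n_nuisance} nuisance)")

sid = table.subjects[0]
print(f"\nper-valence utterance counts for {sid}: {table.valence_counts(sid)}")
print(f"planted slopes for {sid} (first 4): {truth.slopes[sid][:4].round(3)}")
print(f"TD group mean slope:      {truth.group_mean_slopes['TD'][:4].round(2)}")
print(f"AD group mean slope:      {truth.group_mean_slopes['AD'][:4].round(2)}")
print("\nThe AD-vs-TD slope gap (effect size 0.9, three within-group SDs) is")
print("invisible in any single utterance but defines how features co-vary")
print("with valence - exactly what the EMF signature captures.")
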