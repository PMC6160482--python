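"""From utterances to a subject's EMF signature.

Pipeline for one subject: select features correlated with valence
(|rho| > 0.7, union over subjects), aggregate each valence class into
skewness/mean/kurtosis descriptors (a 3 x 3*N_opt moment matrix), and fit
the minimum-norm regression of that matrix onto the valence targets
(-1, 0, +1).  The coefficient vector is the subject's emotional modulation
function (EMF).
"""

import numpy as np

from emfspeech import (
    SyntheticConfig,
    estimate_emf,
    generate_cohort,
    per_valence_moments,
    select_features,
)

table, manifest, truth = generate_cohort(SyntheticConfig(seed=0))

selected = select_features(table, threshold=0.7, redundancy_threshold=0.95)
print(f"selected {selected.n_opt} features: {selected.names}")
print("(the generator's signal features are", truth.signal_features, ")")

sid = table.subjects[0]
mm = per_valence_moments(table, sid, selected)
print(f"\nmoment matrix for {sid}: {mm.matrix.shape[0]} valence rows x "
      f"{mm.matrix.shape[1]} descriptors (skew | mean | kurt blocks)")
print("mean block (rows = valence -1, 0, +1):")
print(mm.block("mean").round(2))

emf = estimate_emf(mm)
print(f"\nEMF coefficients (length {len(emf.coefficients)}), "
      f"rank {emf.rank}, residual {emf.residual_norm:.2e}")
print("fitted valences:", (mm.matrix @ emf.coefficients).round(6))
print("\nResidual ~0 means the signature interpolates the three valence")
print("targets exactly; the coefficients, not the fit quality, carry the")
print("subject-specific modulation style used for diagnosis downstream.")
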