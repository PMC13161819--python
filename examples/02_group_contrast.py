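"""Detect injected case-control differences in regional MIND.

Ten of 60 regions get a standardized feature-mean shift of 0.8 in patients.
The shifted distributions become less similar to every other region, so
patients' weighted node degree drops there; the region-wise GLM (age, sex,
TIV and their pairwise interactions as covariates) recovers the affected
regions after Bonferroni correction.
"""

import numpy as np
import pandas as pd

from mindnet import (
    CohortSpec,
    compute_mind_matrix,
    fit_region_glm,
    generate_cohort,
    generate_parcellation,
    regional_and_global_mind,
    zscore_vertex_features,
)

geometry = generate_parcellation(60, 50, seed=0)
affected = np.arange(0, 60, 6)[:10]
delta = np.zeros(60)
delta[affected] = 0.8

subjects, pheno = generate_cohort(
    geometry,
    CohortSpec(n_patients=50, n_controls=50, effect_map=delta, seed=2),
)

profiles = pd.DataFrame(
    {
        fs.subject_id: regional_and_global_mind(
            compute_mind_matrix(zscore_vertex_features(fs))
        ).regional_mind
        for fs in subjects
    },
    index=geometry.region_ids,
)

contrast = fit_region_glm(profiles, pheno)
sig = set(contrast.significant(0.05))
truth = set(geometry.region_ids[affected])

print(f"regions significant after Bonferroni: {len(sig)}")
print(f"affected regions recovered: {len(sig & truth)}/10")
print(f"t-statistics in affected regions: "
      f"{np.round(contrast.t[affected], 1)}")
print("Negative t means patients < controls: the injected shift makes "
      "affected regions less similar to the rest of the cortex.")
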