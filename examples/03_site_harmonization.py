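"""Remove scanner-site batch effects with empirical-Bayes ComBat.

Two sites differ by region-varying additive offsets around one standard
deviation.  ComBat removes the site location/scale differences while
preserving the group effect supplied as a biological covariate.
"""

import numpy as np
import pandas as pd

from mindnet import combat_harmonize, standardized_mean_difference

rng = np.random.default_rng(0)
n_reg, n_per = 60, 200
cols = [f"s{i}" for i in range(2 * n_per)]
site = pd.Series(["siteA"] * n_per + ["siteB"] * n_per, index=cols)
group = np.tile([1, 0], n_per)

values = rng.normal(0, 1, (n_reg, 2 * n_per)) + 0.6 * group[None, :]
values[:, n_per:] += rng.normal(1.0, 0.3, n_reg)[:, None]  # site B offset
data = pd.DataFrame(values, columns=cols)
covariates = pd.DataFrame({"group": group}, index=cols)

harmonized, model = combat_harmonize(
    data, site, covariates, mode="parametric"
)

site01 = (site == "siteB").astype(float).to_numpy()
smd_before = np.mean(
    [standardized_mean_difference(data.iloc[r], site01)
     for r in range(n_reg)]
)
smd_after = np.mean(
    [standardized_mean_difference(harmonized.iloc[r], site01)
     for r in range(n_reg)]
)
print(f"mean between-site SMD before: {smd_before:.3f}")
print(f"mean between-site SMD after:  {smd_after:.3f}")
print(f"estimated site location shifts (mean |gamma*|): "
      f"{np.abs(model.gamma_star).mean():.3f}")
print("SMD near zero after harmonization means the sites are no longer "
      "distinguishable region by region; the group effect is untouched "
      "because it was preserved as a covariate.")
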