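"""Wrapper feature selection with binary GWO, against the GA baseline.

Plants 10 informative columns (3-sigma class separation) among 90 noise
columns, then minimizes Gamma = 0.99 * holdout-kNN-error + 0.01 * q_s/q_t
with both optimizers at the same evaluation budget.
"""

import numpy as np

from hemopipe import GAConfig, GWOConfig, PlantedFeatureSpec, ga_select, gwo_select, make_feature_dataset

features, truth = make_feature_dataset(PlantedFeatureSpec(
    classes=2, per_class=60, dims=100, informative=10, effect=3.0, seed=0))

gwo_mask, gwo_hist = gwo_select(features, GWOConfig(n_pop=20, t_max=50), seed=0)
ga_mask, ga_hist = ga_select(features, GAConfig(n_pop=20, t_max=50), seed=0)

noise = np.setdiff1d(np.arange(features.n_features), truth)
for name, mask, hist in (("GWO", gwo_mask, gwo_hist), ("GA ", ga_mask, ga_hist)):
    print(f"{name}: Gamma {hist.f_alpha[0]:.4f} -> {hist.f_alpha[-1]:.4f}, "
          f"selected {int(mask.sum())}/{mask.size} features, "
          f"informative hit rate {mask[truth].mean():.2f}, "
          f"noise hit rate {mask[noise].mean():.2f}")
# Gamma near 0.01 * q_s/q_t means the holdout error is zero and only the
# parsimony term remains.  At 3-sigma separation a handful of informative
# columns already zeroes the error, so both optimizers prune freely; the GA's
# bit-flip mutation sheds redundant columns faster than the GWO update, whose
# OR-with-leader step cannot clear a bit once all three leaders carry it.
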