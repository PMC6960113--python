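"""Predict age with GPR and RVR on a linear-kernel similarity matrix.

Vectorizes each subject's network image, forms the subjects x subjects Gram
matrix of dot products, fits both kernel regressors on a balanced training
split and evaluates them on the held-out subjects.  Expect held-out MAEs
around 9-11 years for a network calibrated at r = -0.8 on a cohort of this
size (the mean-age baseline sits near 18 years).
"""

import numpy as np

from netage import (
    CohortSpec,
    GprOptions,
    fit_gpr,
    fit_rvr,
    linear_similarity,
    make_cohort,
    make_masks,
    predict_gpr,
    predict_rvr,
    split_cohort,
    trace_normalize,
)

GRID = (16, 16, 16)
masks = make_masks(GRID, 1, seed=3)
spec = CohortSpec(n_subjects=250, grid_dims=GRID, n_networks=1,
                  target_r=(-0.8,), seed=11)
subjects, table = make_cohort(spec, masks)
ages = table["age"].to_numpy()

split = split_cohort(table, test_count=50, seed=0)
row = {sid: i for i, sid in enumerate(table["subject_id"])}
tr = np.array([row[s] for s in split.train_ids])
te = np.array([row[s] for s in split.test_ids])
print(f"split: {len(tr)} train / {len(te)} test "
      f"(age balance p={split.p_age:.2f}, sex balance p={split.p_sex:.2f})")

support = masks[0].values.astype(bool)
feats = np.stack([s.gm.values[support] for s in subjects]).astype(float)
k = trace_normalize(linear_similarity(feats))
k_train, k_cross = k[np.ix_(tr, tr)], k[np.ix_(te, tr)]

baseline = np.abs(ages[te] - ages[tr].mean()).mean()
print(f"mean-age baseline MAE: {baseline:.2f} yr")

gpr = fit_gpr(k_train, ages[tr], GprOptions(center_kernel=True))
mae_gpr = np.abs(predict_gpr(gpr, k_cross) - ages[te]).mean()
print(f"GPR:  held-out MAE {mae_gpr:.2f} yr "
      f"(theta2={gpr.theta2:.3g}, sigma2={gpr.sigma2:.3g})")

rvr = fit_rvr(k_train, ages[tr])
mae_rvr = np.abs(predict_rvr(rvr, k_cross) - ages[te]).mean()
print(f"RVR:  held-out MAE {mae_rvr:.2f} yr "
      f"({rvr.n_relevance_vectors} relevance vectors of {len(tr)} bases)")
print(
    "\nBoth kernel models recover most of the age signal; the residual"
    "\nerror reflects the network-coherent noise the generator injects."
)
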