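"""Generate a synthetic aging cohort and check its GMV-age calibration.

Builds seven disjoint network parcels on a small grid, simulates 400
subjects whose network gray-matter volumes decline linearly with age at the
seven published correlation strengths, and prints the empirical Pearson r
per network next to its target.  The printed values should agree to within
sampling noise (a few hundredths at this cohort size).
"""

import numpy as np

from netage import (
    CohortSpec,
    DEFAULT_TARGET_R,
    apply_mask,
    gmv_age_correlation,
    make_cohort,
    make_masks,
    network_gmv,
)

GRID = (24, 24, 24)

masks = make_masks(GRID, n_networks=7, seed=1)
spec = CohortSpec(n_subjects=400, grid_dims=GRID, seed=42)
subjects, table = make_cohort(spec, masks)
ages = table["age"].to_numpy()

print(f"cohort: n={len(subjects)}, ages {ages.min():.0f}-{ages.max():.0f} yr")
print(f"{'network':>8} {'voxels':>7} {'target r':>9} {'empirical r':>12}")
for target, mask in zip(DEFAULT_TARGET_R, masks):
    v = np.array([network_gmv(apply_mask(s.gm, mask)) for s in subjects])
    r = gmv_age_correlation(v, ages, label=mask.label)
    print(f"{mask.label:>8} {mask.n_voxels:>7} {target:>9.2f} {r.r:>12.3f}")
print(
    "\nEach network's summed gray-matter volume declines with age; the"
    "\nempirical correlations match the calibration targets."
)
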