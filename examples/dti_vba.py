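"""Multi-template voxel-based analysis of a two-group FA cohort.

Plants a fractional-anisotropy decrease (-0.10) in one group of a
10 vs 10 synthetic cohort, maps voxelwise group differences with the
exact Mann-Whitney U test, and keeps only voxels significant with the
same sign across five reference templates.
"""

import numpy as np

from hypoperf import vba
from hypoperf.phantoms import (
    EffectSpec, default_dti_template, ellipsoid_mask, generate_dti_cohort,
)

shape = (20, 20, 10)
template = default_dti_template(shape=shape)
centre = np.array(shape) * np.array(template.spacing) / 2
mask = ellipsoid_mask(shape, template.spacing, centre,
                      np.array(shape) * np.array(template.spacing) / 5)

effect = EffectSpec(region_mask=mask, index="FA", effect=-0.10,
                    subject_sd=0.03, n_per_group=10, seed=6)
sham, occluded, info = generate_dti_cohort(template, effect)

result = vba.run_multi_template_vba(sham, occluded, templates=range(5),
                                    alpha=0.05, fraction=1.0)
cons = result.consensus
regions = vba.summarize_regions(cons, {"FA": sham + occluded},
                                ["sham"] * 10 + ["occluded"] * 10)

# smoothing spreads a planted effect one voxel beyond its mask, so false
# positives are judged outside the kernel-dilated region
from scipy.ndimage import binary_dilation

halo = binary_dilation(mask, structure=np.ones((3, 3, 3), bool))
print(f"planted region      : {int(mask.sum())} voxels, FA effect -0.10")
print(f"consensus voxels    : {int((cons != 0).sum())} "
      f"(+1 means sham > occluded: {int((cons > 0).sum())})")
print(f"sensitivity inside  : {(cons[mask] != 0).mean():.2f}")
print(f"flagged beyond halo : {(cons[~halo] != 0).mean():.4f}")
print(regions[["cluster", "n_voxels", "sign",
               "FA_sham_mean", "FA_occluded_mean"]].to_string(index=False))
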