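"""Two-group DTI index cohorts with a planted regional effect.

Each subject map = template + white Gaussian subject field; the effect
(additive shift inside a known region mask) is applied to group 2 only.
FA maps are clipped back to [0, 1] and the clip count reported, since
fractional anisotropy is bounded by definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..image import ImageVolume

__all__ = ["EffectSpec", "generate_dti_cohort", "default_dti_template"]

_INDEX_RANGES = {
    # plausible additive-effect magnitude ceilings per index
    "FA": 1.0,
    "MD": 3e-3,
    "AD": 5e-3,
    "RD": 3e-3,
}


@dataclass
class EffectSpec:
    """Planted group difference for a DTI index cohort."""

    region_mask: np.ndarray
    index: str = "FA"
    effect: float = -0.10
    subject_sd: float = 0.03
    n_per_group: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.index not in _INDEX_RANGES:
            raise ValueError(f"unknown DTI index {self.index!r}")
        if abs(self.effect) > _INDEX_RANGES[self.index]:
            raise ValueError(f"|effect| {self.effect} implausible for {self.index}")
        if self.n_per_group < 3:
            raise ValueError("need n >= 3 per group for a voxelwise test")
        self.region_mask = np.asarray(self.region_mask, dtype=bool)


def default_dti_template(shape=(24, 24, 12), spacing=(0.309, 0.309, 0.309),
                         index: str = "FA", seed: int = 7) -> ImageVolume:
    """Smooth synthetic template for one DTI index (not a real rat atlas)."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    base = {"FA": 0.40, "MD": 0.7e-3, "AD": 1.1e-3, "RD": 0.5e-3}[index]
    rel = gaussian_filter(rng.normal(0.0, 1.0, size=shape), sigma=3.0)
    rel = rel / (6.0 * max(np.abs(rel).max(), 1e-12))  # +-~17% structure
    data = base * (1.0 + rel)
    if index == "FA":
        data = np.clip(data, 0.0, 1.0)
    return ImageVolume(data=data, spacing=spacing)


def generate_dti_cohort(template: ImageVolume, effect: EffectSpec):
    """Two groups of subject index maps in template (common) space.

    Returns (group1, group2, info): lists of ImageVolume and a dict with
    the seeds used and the number of clipped FA voxels.
    """
    if effect.region_mask.shape != template.shape:
        raise ValueError("region mask shape differs from template")
    tdata = np.asarray(template.data, float)
    if effect.index == "FA" and (tdata.min() < 0 or tdata.max() > 1):
        raise ValueError("FA template outside [0, 1]")
    if effect.index != "FA" and (tdata <= 0).any():
        raise ValueError("diffusivity template must be > 0")
    ss = np.random.SeedSequence(effect.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * effect.n_per_group)]
    n_clipped = 0
    groups = ([], [])
    for i in range(2 * effect.n_per_group):
        g = i // effect.n_per_group
        rng = np.random.default_rng(seeds[i])
        data = tdata + rng.normal(0.0, effect.subject_sd, size=tdata.shape)
        if g == 1:
            data = data + np.where(effect.region_mask, effect.effect, 0.0)
        if effect.index == "FA":
            bad = (data < 0) | (data > 1)
            n_clipped += int(bad.sum())
            data = np.clip(data, 0.0, 1.0)
        groups[g].append(ImageVolume(data=data, spacing=template.spacing))
    if n_clipped:
        warnings.warn(f"{n_clipped} FA voxels clipped to [0, 1]", stacklevel=2)
    return groups[0], groups[1], {"seeds": seeds, "n_clipped": n_clipped}
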