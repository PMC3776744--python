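"""Multi-template voxel-based analysis of DTI index maps.

Group differences are mapped voxelwise with a Mann-Whitney U test
(exact null distribution for small samples, tie-corrected normal
approximation otherwise), signed by the direction of the group-median
difference: +1 where group A > group B, -1 where A < B.  Because the
choice of reference template biases any single analysis, the procedure
is repeated with several subjects as template and only voxels that are
significant with the same sign in a sufficient fraction of templates
(default: all of them) are retained in the consensus map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .angio import register_affine
from .image import ImageVolume
from .stats import _u_counts

__all__ = [
    "VBAResult",
    "register_cohort",
    "smooth_cohort",
    "voxelwise_mann_whitney",
    "consensus_across_templates",
    "summarize_regions",
    "truncated_gaussian_kernel",
    "run_multi_template_vba",
]

log = logging.getLogger(__name__)


@dataclass
class VBAResult:
    """Signed per-template significance maps plus their consensus."""

    per_template: list                 # list of int8 arrays in {-1, 0, +1}
    consensus: np.ndarray
    alpha: float
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------- registration

def register_cohort(cohort, template_index: int, elastic=None):
    """Register every subject of a cohort to one subject taken as template.

    The affine stage maximises mutual information (driven by the index
    volume, FA in the original design); ``elastic`` is a pluggable
    nonlinear refinement ``f(moving, fixed) -> ImageVolume`` applied
    after the affine stage (None skips it).  Subjects whose registration
    fails are excluded with a log entry.
    """
    if len(cohort) < 2:
        raise ValueError("need >= 2 subjects to register a cohort")
    fixed = cohort[template_index]
    out, excluded = [], []
    for i, vol in enumerate(cohort):
        if i == template_index:
            out.append(vol)
            continue
        try:
            _, resampled = register_affine(vol, fixed)
            if elastic is not None:
                resampled = elastic(resampled, fixed)
            out.append(resampled)
        except RuntimeError as exc:
            log.warning("subject %d excluded: %s", i, exc)
            excluded.append(i)
    if excluded:
        log.warning("registration excluded %d subjects", len(excluded))
    return out, excluded


def demons_refine(moving: ImageVolume, fixed: ImageVolume,
                  iterations: int = 30, field_sigma_vox: float = 1.5) -> ImageVolume:
    """Multi-resolution demons-style displacement refinement (SimpleITK),
    regularised by Gaussian smoothing of the displacement field."""
    import SimpleITK as sitk

    from .angio import _to_sitk

    f = sitk.Cast(_to_sitk(fixed), sitk.sitkFloat32)
    m = sitk.Cast(_to_sitk(moving), sitk.sitkFloat32)
    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(iterations)
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(field_sigma_vox)
    disp = demons.Execute(f, m)
    warped = sitk.Resample(m, f, sitk.DisplacementFieldTransform(disp),
                           sitk.sitkLinear, 0.0)
    arr = np.transpose(sitk.GetArrayFromImage(warped), (2, 1, 0))
    return fixed.copy(data=arr)


# ------------------------------------------------------------- smoothing

def truncated_gaussian_kernel(size: int = 3, sigma_vox: float = 1.0) -> np.ndarray:
    """Separable Gaussian kernel truncated to size^3 and renormalised to 1."""
    r = size // 2
    ax = np.exp(-np.arange(-r, r + 1) ** 2 / (2.0 * sigma_vox**2))
    k = ax[:, None, None] * ax[None, :, None] * ax[None, None, :]
    return k / k.sum()


def smooth_cohort(cohort, size: int = 3, sigma_vox: float = 1.0):
    """Gaussian smoothing (3x3x3 kernel, sd 1 voxel) of each volume."""
    k = truncated_gaussian_kernel(size, sigma_vox)
    out = []
    for vol in cohort:
        data = ndimage.convolve(np.asarray(vol.data, float), k, mode="nearest")
        out.append(vol.copy(data=data))
    return out


# ---------------------------------------------------------- voxelwise MW

def voxelwise_mann_whitney(group_a, group_b, alpha: float = 0.05,
                           fdr: bool = False):
    """Signed voxelwise Mann-Whitney map: +1 A>B, -1 A<B, 0 n.s.

    Exact U null distribution for nA+nB <= 20 (tie-free voxels);
    tie-corrected normal approximation otherwise.  No multiplicity
    correction by default; ``fdr=True`` applies Benjamini-Hochberg.

    Returns (signed int8 map, p-value map).
    """
    a = np.stack([np.asarray(v.data, float) for v in group_a], axis=-1)
    b = np.stack([np.asarray(v.data, float) for v in group_b], axis=-1)
    na, nb = a.shape[-1], b.shape[-1]
    if na < 3 or nb < 3:
        raise ValueError("need >= 3 subjects per group")
    if a.shape[:-1] != b.shape[:-1]:
        raise ValueError("groups are not in a common space")
    shape = a.shape[:-1]
    pooled = np.concatenate([a, b], axis=-1).reshape(-1, na + nb)
    ranks = sps.rankdata(pooled, axis=1)
    u_a = ranks[:, :na].sum(axis=1) - na * (na + 1) / 2.0

    has_ties = np.array([len(np.unique(row)) < na + nb for row in pooled])
    p = np.ones(pooled.shape[0])
    if na + nb <= 20:
        counts = np.asarray(_u_counts(na, nb))
        total = counts.sum()
        cdf = np.cumsum(counts) / total
        sf = np.cumsum(counts[::-1])[::-1] / total
        ui = np.clip(np.round(u_a).astype(int), 0, na * nb)
        exact_p = np.minimum(1.0, 2.0 * np.minimum(cdf[ui], sf[ui]))
        p[~has_ties] = exact_p[~has_ties]
        approx_idx = has_ties
    else:
        approx_idx = np.ones(pooled.shape[0], bool)
    if approx_idx.any():
        N = na + nb
        mu = na * nb / 2.0
        rows = pooled[approx_idx]
        tie_term = np.array([
            (np.unique(r, return_counts=True)[1] ** 3
             - np.unique(r, return_counts=True)[1]).sum()
            for r in rows
        ]) / (N * (N - 1))
        sigma2 = na * nb / 12.0 * ((N + 1) - tie_term)
        sigma = np.sqrt(np.maximum(sigma2, 1e-300))
        z = (np.abs(u_a[approx_idx] - mu) - 0.5) / sigma
        p_ap = 2 * sps.norm.sf(np.maximum(z, 0.0))
        p_ap = np.where(sigma2 <= 0, 1.0, np.minimum(p_ap, 1.0))
        p[approx_idx] = p_ap
    all_tied = np.array([len(np.unique(row)) == 1 for row in pooled])
    p[all_tied] = 1.0

    med_a = np.median(pooled[:, :na], axis=1)
    med_b = np.median(pooled[:, na:], axis=1)
    sign = np.sign(med_a - med_b).astype(np.int8)
    # break median ties by rank-sum direction
    zero_med = sign == 0
    sign[zero_med] = np.sign(u_a[zero_med] - na * nb / 2.0).astype(np.int8)

    thresh = p < alpha
    if fdr:
        order = np.argsort(p)
        m = len(p)
        crit = (np.arange(1, m + 1) / m) * alpha
        passed = p[order] <= crit
        k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
        thresh = np.zeros(m, bool)
        thresh[order[:k]] = True
    signed = np.where(thresh, sign, 0).astype(np.int8)
    return signed.reshape(shape), p.reshape(shape)


# -------------------------------------------------------------- consensus

_CONN26 = np.ones((3, 3, 3), bool)


def consensus_across_templates(maps, fraction: float = 1.0,
                               min_cluster_voxels: int = 10) -> np.ndarray:
    """Voxels significant with the same sign in >= `fraction` of templates.

    Voxels whose significant sign conflicts across templates are dropped
    (and logged).  Retained voxels are grouped into 26-connected
    clusters; clusters below ``min_cluster_voxels`` are removed.
    """
    if not maps:
        raise ValueError("no per-template maps")
    stack = np.stack([np.asarray(m, np.int8) for m in maps])
    n = stack.shape[0]
    pos = (stack > 0).sum(axis=0)
    neg = (stack < 0).sum(axis=0)
    need = int(np.ceil(fraction * n))
    cons = np.zeros(stack.shape[1:], np.int8)
    cons[pos >= need] = 1
    cons[neg >= need] = -1
    conflict = (pos >= need) & (neg >= need)
    if conflict.any():
        log.warning("%d voxels dropped for sign conflict", int(conflict.sum()))
        cons[conflict] = 0
    # also drop voxels significant in both directions across templates
    mixed = (pos > 0) & (neg > 0) & (cons != 0)
    if mixed.any():
        log.info("%d consensus voxels had dissenting signs elsewhere", int(mixed.sum()))
    if min_cluster_voxels > 1 and cons.any():
        for s in (1, -1):
            part = cons == s
            labels, k = ndimage.label(part, structure=_CONN26)
            if k:
                sizes = np.bincount(labels.ravel(), minlength=k + 1)
                small_ids = [i for i in range(1, k + 1) if sizes[i] < min_cluster_voxels]
                if small_ids:
                    cons[part & np.isin(labels, small_ids)] = 0
    return cons


def summarize_regions(consensus: np.ndarray, cohorts: dict,
                      group_labels) -> pd.DataFrame:
    """Per-cluster group mean +- SD for each DTI index.

    ``cohorts`` maps index name -> list of subject ImageVolumes (common
    space, any group order matching ``group_labels``).  For each
    26-connected consensus cluster and each index: the mean over
    subjects of the subject-wise cluster mean, and the SD across
    subjects, per group.
    """
    cons = np.asarray(consensus)
    labels, k = ndimage.label(cons != 0, structure=_CONN26)
    rows = []
    group_labels = np.asarray(group_labels)
    for cl in range(1, k + 1):
        region = labels == cl
        sign = int(np.sign(cons[region].sum()))
        base = {"cluster": cl, "n_voxels": int(region.sum()), "sign": sign}
        for index, vols in cohorts.items():
            subj_means = np.array([np.asarray(v.data, float)[region].mean() for v in vols])
            for g in pd.unique(group_labels):
                vals = subj_means[group_labels == g]
                base[f"{index}_{g}_mean"] = float(vals.mean())
                base[f"{index}_{g}_sd"] = float(vals.std(ddof=1))
        rows.append(base)
    return pd.DataFrame(rows)


# ------------------------------------------------------------ end-to-end

def run_multi_template_vba(
    group_a,
    group_b,
    templates=None,
    alpha: float = 0.05,
    fraction: float = 1.0,
    min_cluster_voxels: int = 10,
    register: bool = False,
    smooth: bool = True,
) -> VBAResult:
    """Repeat the voxelwise analysis with several subjects as template
    and keep only consistent voxels.

    ``templates``: indices into the pooled cohort (A then B) used as
    reference; default: the first 5 subjects (or all if fewer).  With
    ``register=False`` the cohort is assumed already in a common space
    (the usual phantom setting) and the template choice only anchors the
    repeated analysis.
    """
    pooled = list(group_a) + list(group_b)
    na = len(group_a)
    if templates is None:
        templates = list(range(min(5, len(pooled))))
    per_template = []
    for t in templates:
        cohort = pooled
        if register:
            cohort, excluded = register_cohort(pooled, t)
            if excluded:
                raise RuntimeError(f"registration excluded subjects {excluded}")
        if smooth:
            cohort = smooth_cohort(cohort)
        signed, _ = voxelwise_mann_whitney(cohort[:na], cohort[na:], alpha=alpha)
        per_template.append(signed)
    cons = consensus_across_templates(per_template, fraction=fraction,
                                      min_cluster_voxels=min_cluster_voxels)
    return VBAResult(
        per_template=per_template,
        consensus=cons,
        alpha=alpha,
        params={"fraction": fraction, "min_cluster_voxels": min_cluster_voxels,
                "templates": list(templates), "registered": register,
                "smoothed": smooth},
    )
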