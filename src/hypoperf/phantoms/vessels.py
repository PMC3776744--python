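"""Tubular bright-vessel phantoms emulating 3-D TOF angiograms.

A vessel volume is a set of bright tubes around parametric centrelines on
a dark (optionally noisy) background.  Ground truth (arc length by
adaptive quadrature, chord length) travels with the volume as a sidecar
table so that skeleton metrics can be validated without re-deriving truth
from the image itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..image import ImageVolume
from .curves import CurveSpec, curve_arc_length, curve_chord_length, curve_points

__all__ = [
    "GridSpec",
    "generate_vessel_volume",
    "helix_for_metrics",
    "simulate_longitudinal_metrics",
    "generate_longitudinal_cohort",
]


@dataclass
class GridSpec:
    """Voxel lattice geometry: counts per axis, mm per axis, s per frame."""

    shape: tuple
    spacing: tuple
    frame_interval: float | None = None

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape must be >= 1 per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be > 0 per axis")

    @property
    def extent(self) -> np.ndarray:
        """World-coordinate extent (mm) spanned by voxel centres."""
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)


def _check_inside(spec: CurveSpec, grid: GridSpec, pts: np.ndarray) -> None:
    lo = pts.min(axis=0) - spec.radius
    hi = pts.max(axis=0) + spec.radius
    ext = grid.extent
    if (lo < 0).any() or (hi > ext).any():
        raise ValueError(
            f"curve (with tube radius {spec.radius} mm) exits the grid: "
            f"occupies [{lo.round(2)}, {hi.round(2)}] mm, grid extent {ext.round(2)} mm"
        )


def generate_vessel_volume(
    curves,
    grid: GridSpec,
    background_sd: float = 0.0,
    seed: int = 0,
    vessel_intensity: float = 1000.0,
    supersample: int = 3,
):
    """Rasterise tube phantoms and return (volume, ground-truth table).

    A voxel belongs to a vessel when its centre lies within the tube
    radius of the supersampled centreline polyline.  Ground truth per
    curve: arc length (adaptive quadrature of |dgamma/dt|) and chord
    length (Euclidean endpoint distance), both in mm.
    """
    if isinstance(curves, CurveSpec):
        curves = [curves]
    if not curves:
        raise ValueError("no curves given")
    rng = np.random.default_rng(seed)
    data = np.zeros(grid.shape, dtype=float)
    axes = [np.arange(n) * s for n, s in zip(grid.shape, grid.spacing)]
    records = []
    for ci, spec in enumerate(curves):
        # supersampled polyline: step = min spacing / supersample
        length_guess = curve_arc_length(spec)
        step = min(grid.spacing) / supersample
        n_samp = max(int(np.ceil(length_guess / step)) + 1, 2)
        pts = curve_points(spec, np.linspace(0.0, 1.0, n_samp))
        _check_inside(spec, grid, pts)
        # restrict to the curve's bounding box, then distance query
        lo_idx = [
            max(int(np.floor((pts[:, d].min() - spec.radius) / grid.spacing[d])), 0)
            for d in range(3)
        ]
        hi_idx = [
            min(int(np.ceil((pts[:, d].max() + spec.radius) / grid.spacing[d])) + 1, grid.shape[d])
            for d in range(3)
        ]
        sub_axes = [axes[d][lo_idx[d] : hi_idx[d]] for d in range(3)]
        xx, yy, zz = np.meshgrid(*sub_axes, indexing="ij")
        centres = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        tree = cKDTree(pts)
        dist, _ = tree.query(centres, k=1)
        inside = (dist <= spec.radius).reshape(xx.shape)
        data[lo_idx[0] : hi_idx[0], lo_idx[1] : hi_idx[1], lo_idx[2] : hi_idx[2]][
            inside
        ] = vessel_intensity
        records.append(
            {
                "curve": ci,
                "family": spec.family,
                "arc_length_mm": curve_arc_length(spec),
                "chord_length_mm": curve_chord_length(spec),
                "radius_mm": spec.radius,
            }
        )
    if background_sd > 0:
        data = data + rng.normal(0.0, background_sd, size=data.shape)
    vol = ImageVolume(data=data, spacing=grid.spacing)
    truth = pd.DataFrame.from_records(records)
    truth["tortuosity_true"] = truth["arc_length_mm"] / truth["chord_length_mm"]
    return vol, truth


def helix_for_metrics(
    length_mm: float,
    tortuosity: float,
    turns: float = 2.0,
    axis: str = "z",
    center=(0.0, 0.0, 0.0),
    radius_mm: float = 0.3,
) -> CurveSpec:
    """Helix whose arc length and arc/chord tortuosity hit given targets.

    For an integer-turn helix the chord equals the axial extent, so
    tortuosity tau = sqrt(1 + (2 pi r / pitch)^2); solving gives
    pitch = length / (turns * tau) and r = pitch * sqrt(tau^2 - 1) / (2 pi).
    tau = 1 degenerates to a straight line along the axis.
    """
    if tortuosity < 1.0:
        raise ValueError("tortuosity must be >= 1")
    pitch = length_mm / (turns * tortuosity)
    if tortuosity == 1.0:
        u, v, w = np.eye(3)[{"x": 0, "y": 1, "z": 2}[axis]], None, None
        start = np.asarray(center, float)
        return CurveSpec(
            "line", {"start": start, "end": start + u * length_mm}, radius=radius_mm
        )
    r = pitch * np.sqrt(tortuosity**2 - 1.0) / (2.0 * np.pi)
    return CurveSpec(
        "helix",
        {"center": tuple(center), "radius": r, "pitch": pitch, "turns": turns, "axis": axis},
        radius=radius_mm,
    )


# ------------------------------------------------------------- longitudinal

DEFAULT_TIMEPOINTS = ("pre", "2h", "24h", "10d", "3w", "7w", "12w")


def simulate_longitudinal_metrics(
    base_length_mm: float = 15.0,
    base_tortuosity: float = 1.15,
    length_multipliers: dict | None = None,
    tortuosity_multipliers: dict | None = None,
    timepoints=DEFAULT_TIMEPOINTS,
    n_per_group: dict | None = None,
    subject_sd_frac: float = 0.05,
    residual_sd_frac: float = 0.03,
    seed: int = 0,
):
    """Ground-truth + measured longitudinal metric tables for two groups.

    Models the study design: an occluded group whose vessel length and
    tortuosity grow over follow-up while the sham group stays flat.
    Per-subject lognormal scale (between-subject sd, fraction of the
    base value) plus multiplicative residual measurement noise.

    Returns (measured, truth): long-format DataFrames with columns
    subject, group, timepoint, length_mm, tortuosity.
    """
    timepoints = list(timepoints)
    T = len(timepoints)
    if n_per_group is None:
        n_per_group = {"occluded": 6, "sham": 4}
    ones = {tp: 1.0 for tp in timepoints}
    if length_multipliers is None:
        # occluded length ramps to +20% by the final follow-up
        ramp = np.concatenate([[1.0, 1.0, 1.0], np.linspace(1.05, 1.20, T - 3)])
        length_multipliers = {"occluded": dict(zip(timepoints, ramp)), "sham": ones}
    if tortuosity_multipliers is None:
        ramp = np.concatenate([[1.0, 1.0, 1.0], np.linspace(1.05, 1.25, T - 3)])
        tortuosity_multipliers = {"occluded": dict(zip(timepoints, ramp)), "sham": ones}
    for g, mult in length_multipliers.items():
        vals = np.array([mult[tp] for tp in timepoints])
        if g != "sham" and (vals < 1.0 - 1e-12).any():
            raise ValueError("occluded-group multipliers must be >= 1")
    rng = np.random.default_rng(seed)
    rows_truth, rows_meas = [], []
    for group, n in n_per_group.items():
        for s in range(n):
            subj = f"{group}{s:02d}"
            subj_scale = float(np.exp(rng.normal(0.0, subject_sd_frac)))
            for tp in timepoints:
                lt = base_length_mm * length_multipliers[group][tp] * subj_scale
                tt = base_tortuosity * tortuosity_multipliers[group][tp]
                rows_truth.append(
                    {"subject": subj, "group": group, "timepoint": tp,
                     "length_mm": lt, "tortuosity": tt}
                )
                rows_meas.append(
                    {"subject": subj, "group": group, "timepoint": tp,
                     "length_mm": lt * float(np.exp(rng.normal(0.0, residual_sd_frac))),
                     "tortuosity": tt * float(np.exp(rng.normal(0.0, residual_sd_frac)))}
                )
    return pd.DataFrame(rows_meas), pd.DataFrame(rows_truth)


def generate_longitudinal_cohort(
    grid: GridSpec,
    seed: int = 0,
    render: bool = True,
    background_sd: float = 20.0,
    vessel_radius_mm: float = 0.35,
    helix_turns: float = 1.0,
    **metric_kwargs,
):
    """Per-subject, per-timepoint vessel volumes with a ground-truth table.

    The noiseless per-subject metric trajectories from
    :func:`simulate_longitudinal_metrics` are realised as helix phantoms
    (exact length and tortuosity by construction).  With ``render=False``
    only the tables are produced.

    Returns (volumes, truth) where volumes maps (subject, timepoint) ->
    ImageVolume (empty dict when not rendering).
    """
    measured, truth = simulate_longitudinal_metrics(seed=seed, **metric_kwargs)
    volumes = {}
    if render:
        ext = grid.extent
        center = (ext[0] / 2.0, ext[1] / 2.0, 0.05 * ext[2])
        ss = np.random.SeedSequence([seed, 0x5E55])
        child = iter(ss.spawn(len(truth)))
        for axis in ("x0", "y0", "z0", "x1", "y1", "z1"):
            truth[axis] = np.nan
        for idx, row in truth.iterrows():
            spec = helix_for_metrics(
                row["length_mm"], row["tortuosity"], turns=helix_turns,
                center=center, radius_mm=vessel_radius_mm,
            )
            vol, _ = generate_vessel_volume(
                spec, grid, background_sd=background_sd,
                seed=int(next(child).generate_state(1)[0] % (2**31)),
            )
            ends = curve_points(spec, np.array([0.0, 1.0]))
            truth.loc[idx, ["x0", "y0", "z0"]] = ends[0]
            truth.loc[idx, ["x1", "y1", "z1"]] = ends[1]
            volumes[(row["subject"], row["timepoint"])] = vol
    return volumes, truth
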