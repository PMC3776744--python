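"""Parametric 3-D centreline curves for vessel phantoms.

Each curve family exposes points, derivatives and an adaptive-quadrature
arc length, so that rasterised tube phantoms carry analytic ground truth
for skeleton length and tortuosity, independent of the analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = ["CurveSpec", "curve_points", "curve_arc_length", "curve_chord_length"]

_FAMILIES = ("line", "arc", "helix", "polyline")


@dataclass
class CurveSpec:
    """A named parametric curve plus a tube radius (mm).

    families
    --------
    line     : params start (mm), end (mm)
    arc      : params center, radius, basis_u, basis_v (orthonormal, in-plane),
               theta0, theta1 (radians); gamma(t) = c + r(cos th u + sin th v)
    helix    : params center, radius, pitch (mm per turn), turns, axis in
               {'x','y','z'}; integer turns give chord = pitch * turns
    polyline : params points (k x 3 mm)
    """

    family: str
    params: dict
    radius: float = 0.3

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown curve family {self.family!r}")
        if self.radius <= 0:
            raise ValueError("tube radius must be > 0")


def _helix_frame(axis: str):
    frames = {
        "z": (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0])),
        "x": (np.array([0, 1.0, 0]), np.array([0, 0, 1.0]), np.array([1.0, 0, 0])),
        "y": (np.array([0, 0, 1.0]), np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),
    }
    return frames[axis]


def curve_points(spec: CurveSpec, t: np.ndarray) -> np.ndarray:
    """Evaluate gamma(t) for t in [0, 1]; returns (len(t), 3) mm."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = spec.params
    if spec.family == "line":
        a = np.asarray(p["start"], float)
        b = np.asarray(p["end"], float)
        return a[None, :] + t[:, None] * (b - a)[None, :]
    if spec.family == "arc":
        c = np.asarray(p["center"], float)
        r = float(p["radius"])
        u = np.asarray(p["basis_u"], float)
        v = np.asarray(p["basis_v"], float)
        th = p["theta0"] + t * (p["theta1"] - p["theta0"])
        return c[None, :] + r * (np.cos(th)[:, None] * u + np.sin(th)[:, None] * v)
    if spec.family == "helix":
        c = np.asarray(p["center"], float)
        r = float(p["radius"])
        pitch = float(p["pitch"])
        turns = float(p["turns"])
        u, v, w = _helix_frame(p.get("axis", "z"))
        th = 2.0 * np.pi * turns * t
        z = pitch * turns * t
        return (
            c[None, :]
            + r * (np.cos(th)[:, None] * u + np.sin(th)[:, None] * v)
            + z[:, None] * w
        )
    # polyline: piecewise-linear interpolation with arc-length parameter
    pts = np.asarray(p["points"], float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] == 0:
        raise ValueError("degenerate polyline")
    s = t * cum[-1]
    out = np.empty((len(t), 3))
    for d in range(3):
        out[:, d] = np.interp(s, cum, pts[:, d])
    return out


def _speed(spec: CurveSpec, t: float) -> float:
    """|dgamma/dt| by central finite difference (analytic for line/helix)."""
    p = spec.params
    if spec.family == "line":
        a = np.asarray(p["start"], float)
        b = np.asarray(p["end"], float)
        return float(np.linalg.norm(b - a))
    if spec.family == "arc":
        return float(p["radius"]) * abs(p["theta1"] - p["theta0"])
    if spec.family == "helix":
        r = float(p["radius"])
        pitch = float(p["pitch"])
        turns = float(p["turns"])
        return turns * np.hypot(2.0 * np.pi * r, pitch)
    h = 1e-6
    t0 = min(max(t, h), 1 - h)
    d = (curve_points(spec, np.array([t0 + h]))[0] - curve_points(spec, np.array([t0 - h]))[0]) / (
        2 * h
    )
    return float(np.linalg.norm(d))


def curve_arc_length(spec: CurveSpec) -> float:
    """Arc length (mm) by adaptive quadrature of the speed |dgamma/dt|."""
    if spec.family == "polyline":
        pts = np.asarray(spec.params["points"], float)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    val, _ = quad(lambda t: _speed(spec, t), 0.0, 1.0, limit=200)
    return float(val)


def curve_chord_length(spec: CurveSpec) -> float:
    """Euclidean distance (mm) between the curve endpoints."""
    ends = curve_points(spec, np.array([0.0, 1.0]))
    return float(np.linalg.norm(ends[1] - ends[0]))
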