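"""Dynamic susceptibility contrast (DSC) bolus phantoms.

The tissue passage of a gadolinium bolus on a T2*-weighted series is
modelled as a baseline signal minus a gamma-variate dip,

    S(t) = baseline - A * g((t - t0) / beta; alpha),
    g(x; alpha) = (x / alpha)^alpha * exp(alpha - x),  x > 0,

normalised so the dip reaches depth A exactly at t = t0 + alpha*beta.
Ground-truth TTP / FWHM / AUC are computed on the noiseless continuous
curve by root finding and adaptive quadrature — never from the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from ..image import ImageVolume
from .vessels import GridSpec

__all__ = ["BolusSpec", "gamma_variate", "bolus_ground_truth", "generate_bolus_series",
           "DEFAULT_PHASES"]

#: baseline / injection / post-injection lengths in frames (at 0.16 s/frame
#: this is 2 min baseline, 20 s injection, 3 min 36 s recovery: 2100 frames).
DEFAULT_PHASES = (750, 125, 1350)


@dataclass
class BolusSpec:
    """Gamma-variate bolus parameters for one ROI."""

    baseline: float = 1000.0
    amplitude: float = 300.0
    t0: float = 125.0          # arrival time, s from series start
    alpha: float = 3.0         # shape
    beta: float = 1.5          # scale, s
    noise_sd: float = 0.0
    phases: tuple = DEFAULT_PHASES

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.amplitude > self.baseline:
            raise ValueError("bolus amplitude exceeds baseline signal (would clip at 0)")


def gamma_variate(t, t0: float, alpha: float, beta: float) -> np.ndarray:
    """Unit-peak gamma-variate: 1.0 at t = t0 + alpha*beta, 0 for t <= t0."""
    t = np.asarray(t, dtype=float)
    x = (t - t0) / beta
    out = np.zeros_like(t)
    pos = x > 0
    out[pos] = (x[pos] / alpha) ** alpha * np.exp(alpha - x[pos])
    return out


def bolus_ground_truth(spec: BolusSpec, t_end: float) -> dict:
    """Continuous-curve oracle for TTP, FWHM (s) and AUC (signal*s).

    TTP is relative to the arrival time t0; FWHM solves g = 1/2 on both
    flanks by Brent root finding; AUC integrates the dip depth over
    [t0, t_end] by adaptive quadrature.
    """
    if spec.amplitude == 0:
        return {"ttp_s": np.nan, "fwhm_s": np.nan, "auc": 0.0, "no_bolus": True}
    a, b, t0 = spec.alpha, spec.beta, spec.t0
    t_peak = t0 + a * b

    def g(t):
        return float(gamma_variate(np.array([t]), t0, a, b)[0])

    left = brentq(lambda t: g(t) - 0.5, t0 + 1e-12, t_peak)
    # bracket the right crossing by expanding past the peak
    hi = t_peak + b
    while g(hi) > 0.5:
        hi += b
    right = brentq(lambda t: g(t) - 0.5, t_peak, hi)
    auc, _ = quad(lambda t: spec.amplitude * g(t), t0, t_end, limit=500)
    return {
        "ttp_s": t_peak - t0,
        "fwhm_s": right - left,
        "auc": float(auc),
        "max_enhancement": spec.amplitude,
        "no_bolus": False,
    }


def generate_bolus_series(
    layout: ImageVolume,
    specs: dict,
    grid: GridSpec,
    seed: int = 0,
):
    """4-D DSC series from an ROI label volume and per-ROI bolus specs.

    ``layout`` holds integer ROI labels (0 = background); ``specs`` maps
    label -> BolusSpec.  Returns (series, truth table) where the series
    signal is baseline minus the gamma-variate dip plus Gaussian noise.
    """
    if grid.frame_interval is None or grid.frame_interval <= 0:
        raise ValueError("grid.frame_interval must be > 0 for a dynamic series")
    labels = np.asarray(layout.data).astype(int)
    n_frames = sum(specs[next(iter(specs))].phases) if specs else 0
    if not specs:
        raise ValueError("no ROI specs given")
    t = np.arange(n_frames) * grid.frame_interval
    rng = np.random.default_rng(seed)
    series = np.zeros(labels.shape + (n_frames,), dtype=float)
    records = []
    for label, spec in specs.items():
        if sum(spec.phases) != n_frames:
            raise ValueError("all ROI specs must share the same total series length")
        curve = spec.baseline - spec.amplitude * gamma_variate(t, spec.t0, spec.alpha, spec.beta)
        where = labels == label
        if not where.any():
            raise ValueError(f"label {label} absent from layout")
        series[where, :] = curve[None, :]
        if spec.noise_sd > 0:
            series[where, :] += rng.normal(0.0, spec.noise_sd, size=(int(where.sum()), n_frames))
        truth = bolus_ground_truth(spec, t_end=t[-1])
        truth.update({"roi": label, "baseline": spec.baseline})
        records.append(truth)
    vol = ImageVolume(data=series, spacing=grid.spacing, frame_interval=grid.frame_interval)
    return vol, pd.DataFrame.from_records(records)
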