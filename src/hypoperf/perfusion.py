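"""Relative perfusion parameters from DSC bolus-tracking series.

On a T2*-weighted series the gadolinium bolus causes a transient signal
*drop*; the module therefore analyses the enhancement curve
E(t) = S_baseline_mean - S(t), so that "maximum" means peak contrast
concentration.  Reported per ROI:

    max_enhancement  peak of E (signal units)
    ttp              time to peak, from bolus arrival (s)
    auc              trapezoidal integral of E over the passage (relCBV)
    fwhm             full width of E at half maximum (s; transit-time proxy)
    relcbf           auc / fwhm, exactly

Arrival is the first frame after injection start where E exceeds the
baseline mean + k*sd (default k = 3) for at least 3 consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import ImageVolume

__all__ = ["BolusCurve", "PerfusionParams", "segment_bolus_phases", "roi_curve",
           "bolus_parameters"]


@dataclass
class BolusCurve:
    """ROI-averaged signal time course with phase boundaries (frames)."""

    time_s: np.ndarray
    signal: np.ndarray
    phases: tuple              # (baseline, injection, post) lengths, frames
    frame_interval: float      # s

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, float)
        self.signal = np.asarray(self.signal, float)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if sum(self.phases) != len(self.signal):
            raise ValueError("phases do not cover the series")

    @property
    def boundaries(self):
        b, i, p = self.phases
        return (0, b), (b, b + i), (b + i, b + i + p)


@dataclass
class PerfusionParams:
    max_enhancement: float
    ttp_s: float
    auc: float                 # signal * s (relCBV estimate)
    fwhm_s: float              # mean-transit-time estimate
    relcbf: float              # = auc / fwhm
    arrival_s: float
    raw_signal_max: float      # literal maximum of the raw signal curve
    truncated: bool = False


def segment_bolus_phases(series_length: int, phases=(750, 125, 1350)) -> tuple:
    """Validate and return (baseline, injection, post) frame counts."""
    phases = tuple(int(p) for p in phases)
    if any(p < 0 for p in phases) or sum(phases) != series_length:
        raise ValueError(
            f"phases {phases} do not sum to series length {series_length}"
        )
    return phases


def roi_curve(series: ImageVolume, roi_mask: np.ndarray,
              phases=(750, 125, 1350), paired_mask: np.ndarray | None = None) -> BolusCurve:
    """Per-frame mean over ROI voxels (bilateral ROIs averaged when paired)."""
    data = np.asarray(series.data, float)
    if data.ndim != 4:
        raise ValueError("need a 4-D dynamic series")
    if series.frame_interval is None:
        raise ValueError("series has no frame timing")
    roi = np.asarray(roi_mask, bool)
    if roi.shape != data.shape[:-1]:
        raise ValueError("ROI shape differs from the spatial grid")
    if not roi.any():
        raise ValueError("empty ROI")
    curve = data[roi].mean(axis=0)
    if paired_mask is not None:
        pm = np.asarray(paired_mask, bool)
        if not pm.any():
            raise ValueError("empty paired ROI")
        curve = 0.5 * (curve + data[pm].mean(axis=0))
    phases = segment_bolus_phases(data.shape[-1], phases)
    t = np.arange(data.shape[-1]) * series.frame_interval
    return BolusCurve(time_s=t, signal=curve, phases=phases,
                      frame_interval=series.frame_interval)


def _interp_crossing(t, e, i0, i1, level):
    """Linear interpolation of the time where e crosses `level` in [i0, i1]."""
    t0, t1 = t[i0], t[i1]
    e0, e1 = e[i0], e[i1]
    if e1 == e0:
        return t0
    return t0 + (level - e0) * (t1 - t0) / (e1 - e0)


def bolus_parameters(
    curve: BolusCurve,
    k_sd: float = 3.0,
    sustained_frames: int = 3,
    auc_tail_fraction: float = 0.10,
    analyze_raw_signal: bool = False,
    subframe_refinement: bool = True,
    smooth_frames: int = 9,
) -> PerfusionParams:
    """Model-free bolus metrics from an ROI time course.

    With ``analyze_raw_signal=True`` the raw signal maximum replaces the
    enhancement maximum for TTP/max (literal signal-curve reading); the
    default analyses the inverted (signal-drop) curve.

    ``subframe_refinement`` (default) interpolates the arrival time
    (linear crossing of the detection threshold) and the peak time
    (3-point parabola) below the frame interval; without it both are
    quantised to whole frames.  ``smooth_frames`` applies a centred
    moving average (reflect-padded) used *only* to localise the peak,
    suppressing frame-to-frame noise at the fast sampling; arrival,
    max, AUC and FWHM are measured on the raw curve.  Set 0/1 to
    disable.
    """
    (b0, b1), (i0, i1), (p0, p1) = curve.boundaries
    if b1 - b0 < 30:
        raise ValueError("need >= 30 baseline frames")
    s = curve.signal
    t = curve.time_s
    base = s[b0:b1]
    e = base.mean() - s
    if analyze_raw_signal:
        e = s - base.mean()
    e_smooth = e
    if smooth_frames and smooth_frames > 1:
        w = int(smooth_frames) | 1
        pad = np.pad(e, w // 2, mode="reflect")
        e_smooth = np.convolve(pad, np.ones(w) / w, mode="valid")
    e_base = e[b0:b1]
    thresh = e_base.mean() + k_sd * e_base.std(ddof=1)

    above = e > thresh
    arrival_idx = None
    for i in range(i0, len(e) - sustained_frames + 1):
        if above[i : i + sustained_frames].all():
            arrival_idx = i
            break
    if arrival_idx is None:
        raise ValueError("no bolus arrival detected")

    peak_idx = int(np.argmax(e_smooth[arrival_idx:])) + arrival_idx
    truncated = peak_idx == len(e) - 1
    max_e = float(e[np.argmax(e[arrival_idx:]) + arrival_idx])

    t_arrival = t[arrival_idx]
    t_peak = t[peak_idx]
    if subframe_refinement:
        if arrival_idx > 0 and e[arrival_idx] > thresh >= e[arrival_idx - 1]:
            t_arrival = _interp_crossing(t, e, arrival_idx - 1, arrival_idx, thresh)
        if 0 < peak_idx < len(e) - 1:
            y0, y1, y2 = e_smooth[peak_idx - 1 : peak_idx + 2]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                t_peak = t[peak_idx] + 0.5 * (y0 - y2) / denom * curve.frame_interval
    ttp = float(t_peak - t_arrival)

    # passage window: one frame before arrival (to capture the rising
    # edge) until the first return below the tail fraction of the max
    end_idx = len(e) - 1
    for i in range(peak_idx, len(e)):
        if e[i] < auc_tail_fraction * max_e:
            end_idx = i
            break
    start_idx = max(arrival_idx - 1, 0)
    auc = float(np.trapezoid(e[start_idx : end_idx + 1], t[start_idx : end_idx + 1]))

    # FWHM with linear interpolation on both flanks
    half = max_e / 2.0
    li = peak_idx
    while li > 0 and e[li] >= half:
        li -= 1
    if e[li] >= half:
        raise ValueError("left half-maximum flank not reached")
    t_left = _interp_crossing(t, e, li, li + 1, half)
    ri = peak_idx
    while ri < len(e) - 1 and e[ri] >= half:
        ri += 1
    if e[ri] >= half:
        t_right = t[ri]   # truncated right flank
        truncated = True
    else:
        t_right = _interp_crossing(t, e, ri - 1, ri, half)
    fwhm = float(t_right - t_left)
    if fwhm <= 0:
        raise ValueError("degenerate FWHM")

    return PerfusionParams(
        max_enhancement=max_e,
        ttp_s=ttp,
        auc=auc,
        fwhm_s=fwhm,
        relcbf=auc / fwhm,
        arrival_s=float(t[arrival_idx]),
        raw_signal_max=float(s.max()),
        truncated=truncated,
    )
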