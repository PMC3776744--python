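"""Multi-echo spin-echo phantoms for T2 relaxometry.

Signal model: S(TE) = S0 * exp(-TE / T2), voxelwise, with optional
Gaussian or Rician noise.  Rician noise is the magnitude of the complex
signal with iid Gaussian noise on both channels, the appropriate model
for magnitude MR images.
"""

from __future__ import annotations

import numpy as np

from ..image import ImageVolume

__all__ = ["default_echo_times", "generate_multiecho_series", "ellipsoid_mask",
           "noise_sd_for_snr", "RAYLEIGH_SD_FACTOR"]

#: sd of the background (A = 0) magnitude relative to the per-channel sd
RAYLEIGH_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))


def noise_sd_for_snr(s0: float, snr: float) -> float:
    """Per-channel noise sd for a target magnitude-image SNR.

    SNR here follows the air-ROI convention used when characterising
    magnitude MR images: peak signal divided by the standard deviation
    of the background (Rayleigh-distributed) magnitude noise, so
    sigma = sqrt(2 - pi/2) * S0 / SNR.
    """
    return RAYLEIGH_SD_FACTOR * s0 / snr


def default_echo_times(n: int = 16, first_ms: float = 11.0, last_ms: float = 176.0) -> np.ndarray:
    """Echo-time ladder: n echoes evenly spanning [first, last] ms."""
    return np.linspace(first_ms, last_ms, n)


def generate_multiecho_series(
    t2_map: ImageVolume,
    s0_map: ImageVolume,
    echo_times,
    noise: str = "none",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ImageVolume:
    """4-D multi-echo series from T2 (ms) and S0 maps.

    ``noise`` is one of ``none | gaussian | rician``; ``noise_sd`` is the
    per-channel standard deviation in signal units.
    """
    te = np.asarray(echo_times, dtype=float)
    if te.ndim != 1 or len(te) < 2:
        raise ValueError("need >= 2 echo times")
    if not np.all(np.diff(te) > 0):
        raise ValueError("echo_times must be strictly increasing")
    t2 = np.asarray(t2_map.data, float)
    s0 = np.asarray(s0_map.data, float)
    if t2.shape != s0.shape:
        raise ValueError("t2_map and s0_map shapes differ")
    if np.any((s0 > 0) & (t2 <= 0)):
        raise ValueError("t2_map must be > 0 wherever s0_map > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(-te[None, :] / np.where(t2 > 0, t2, np.inf).reshape(-1, 1))
    signal = (s0.reshape(-1, 1) * decay).reshape(t2.shape + (len(te),))
    rng = np.random.default_rng(seed)
    if noise == "none" or noise_sd == 0:
        pass
    elif noise == "gaussian":
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    elif noise == "rician":
        re = signal + rng.normal(0.0, noise_sd, size=signal.shape)
        im = rng.normal(0.0, noise_sd, size=signal.shape)
        signal = np.hypot(re, im)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return ImageVolume(data=signal, spacing=t2_map.spacing, frame_interval=None)


def ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    """Boolean ellipsoid in voxel space (world-mm centre and semi-axes)."""
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    grids = np.meshgrid(*axes, indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_mm, radii_mm))
    return q <= 1.0
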