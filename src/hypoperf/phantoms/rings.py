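"""Vessel-ring micrograph phantoms for wall morphometry.

An annular media band between an inner (internal elastic lamina) and an
outer (external elastic lamina) contour, with optional nuclei rendered
as disjoint bright blobs inside the media.  Ground truth lamina lengths
come from 2*pi*r for circles and from adaptive quadrature of the
elliptic perimeter integrand for ellipses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from ..image import ImageVolume

__all__ = ["RingImage", "ellipse_perimeter", "generate_ring_image"]


@dataclass
class RingImage:
    """2-D ring micrograph plus machine-readable ground truth."""

    image: ImageVolume        # pixel size in um stored in spacing
    truth: dict               # l_i/l_e (um), areas (um^2), nucleus count + centres


def ellipse_perimeter(a: float, b: float) -> float:
    """Perimeter of an ellipse with semi-axes a, b by adaptive quadrature."""
    val, _ = quad(
        lambda t: np.hypot(a * np.sin(t), b * np.cos(t)), 0.0, 2.0 * np.pi, limit=200
    )
    return float(val)


def generate_ring_image(
    inner_radius_um: float,
    outer_radius_um: float,
    pixel_size_um: float = 0.5,
    media_intensity: float = 200.0,
    background_intensity: float = 20.0,
    n_nuclei: int = 0,
    nucleus_radius_um: float | None = None,
    nucleus_intensity: float = 255.0,
    axis_ratio: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RingImage:
    """Annulus phantom with circular (or elliptic, axis_ratio != 1) laminae.

    The media band occupies inner_radius <= rho <= outer_radius where rho
    is the elliptic radius; ground-truth lamina lengths l = 2*pi*r for
    circles, otherwise the elliptic-perimeter quadrature value, and areas
    pi*a*b.
    """
    if not (outer_radius_um > inner_radius_um > 0):
        raise ValueError("need outer_radius > inner_radius > 0")
    margin = 4 * pixel_size_um + outer_radius_um * max(1.0, axis_ratio) * 0.1
    half = outer_radius_um * max(1.0, axis_ratio) + margin
    n = int(np.ceil(2 * half / pixel_size_um))
    c = (n - 1) / 2.0 * pixel_size_um
    yy, xx = np.meshgrid(np.arange(n) * pixel_size_um, np.arange(n) * pixel_size_um,
                         indexing="ij")
    # elliptic radius: semi-axes (r * axis_ratio, r) for nominal radius r
    rho = np.hypot((xx - c) / axis_ratio, yy - c)
    media = (rho >= inner_radius_um) & (rho <= outer_radius_um)
    img = np.full((n, n), background_intensity, dtype=float)
    img[media] = media_intensity

    rng = np.random.default_rng(seed)
    if nucleus_radius_um is None:
        nucleus_radius_um = max(0.12 * (outer_radius_um - inner_radius_um), 2 * pixel_size_um)
    centres = []
    if n_nuclei > 0:
        band = outer_radius_um - inner_radius_um
        if nucleus_radius_um * 2 >= band:
            raise ValueError("nuclei larger than the media band")
        # feasibility: rough packing bound on the media area
        media_area = np.pi * axis_ratio * (outer_radius_um**2 - inner_radius_um**2)
        if n_nuclei * (2 * nucleus_radius_um) ** 2 * 2.0 > media_area:
            raise ValueError("nuclei do not fit inside the media area")
        tries = 0
        while len(centres) < n_nuclei:
            tries += 1
            if tries > 20000:
                raise ValueError("nuclei do not fit inside the media area")
            theta = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(inner_radius_um + nucleus_radius_um,
                            outer_radius_um - nucleus_radius_um)
            px = c + r * np.cos(theta) * axis_ratio
            py = c + r * np.sin(theta)
            if all(np.hypot(px - qx, py - qy) > 2.4 * nucleus_radius_um
                   for qx, qy in centres):
                centres.append((px, py))
        for px, py in centres:
            blob = np.hypot(xx - px, yy - py) <= nucleus_radius_um
            img[blob] = nucleus_intensity
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)

    if axis_ratio == 1.0:
        l_i = 2 * np.pi * inner_radius_um
        l_e = 2 * np.pi * outer_radius_um
    else:
        l_i = ellipse_perimeter(inner_radius_um * axis_ratio, inner_radius_um)
        l_e = ellipse_perimeter(outer_radius_um * axis_ratio, outer_radius_um)
    truth = {
        "l_i_um": l_i,
        "l_e_um": l_e,
        "area_i_um2": np.pi * axis_ratio * inner_radius_um**2,
        "area_e_um2": np.pi * axis_ratio * outer_radius_um**2,
        "n_nuclei": len(centres),
        "nucleus_centres_um": centres,
    }
    vol = ImageVolume(data=img, spacing=(pixel_size_um, pixel_size_um))
    return RingImage(image=vol, truth=truth)
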