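"""RGB <-> HSI conversion.

The enhancement stage operates on the intensity (I) channel of the HSI
representation only, leaving hue and saturation untouched, so the
round-trip fidelity of these two functions bounds the colour error of
the whole enhancement step.

Conventions: channels are floats in [0, 1]; hue is in degrees [0, 360);
achromatic pixels (S = 0 or I = 0) carry H = 0 and S = 0 by convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rgb_to_hsi", "hsi_to_rgb"]

_EPS = 1e-12


def rgb_to_hsi(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an RGB image to hue, saturation, intensity channels.

    Parameters
    ----------
    rgb
        Array of shape ``(..., 3)`` with values in ``[0, 1]``.

    Returns
    -------
    (H, S, I)
        Hue in degrees ``[0, 360)``, saturation in ``[0, 1]``, and
        intensity ``I = (R + G + B) / 3``.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim < 1 or rgb.shape[-1] != 3:
        raise ValueError(f"expected a trailing axis of 3 channels, got shape {rgb.shape}")
    if rgb.min() < -_EPS or rgb.max() > 1 + _EPS:
        raise ValueError("RGB values must lie in [0, 1]")

    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    intensity = (r + g + b) / 3.0

    minimum = np.minimum(np.minimum(r, g), b)
    saturation = np.where(intensity > _EPS, 1.0 - minimum / np.maximum(intensity, _EPS), 0.0)

    # theta = arccos( 0.5*((R-G)+(R-B)) / sqrt((R-G)^2 + (R-B)(G-B)) )
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(invalid="ignore"):
        theta = np.degrees(np.arccos(np.clip(num / np.maximum(den, _EPS), -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where((saturation <= _EPS) | (den <= _EPS), 0.0, hue)
    hue = np.mod(hue, 360.0)
    return hue, np.clip(saturation, 0.0, 1.0), intensity


def hsi_to_rgb(hue: np.ndarray, sat: np.ndarray, inten: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_hsi` on the valid gamut.

    Uses the standard sector decomposition of the hue circle: in each
    120-degree sector one channel is pinned at ``I(1-S)``, a second is
    ``I(1 + S cos(h)/cos(60-h))`` and the third closes the sum ``R+G+B = 3I``.
    The result is clipped to ``[0, 1]`` (out-of-gamut combinations exist for
    extreme S at high I).
    """
    hue = np.asarray(hue, dtype=float)
    sat = np.asarray(sat, dtype=float)
    inten = np.asarray(inten, dtype=float)
    if np.any((hue < 0) | (hue >= 360.0)):
        raise ValueError("hue must lie in [0, 360)")
    if np.any((sat < -_EPS) | (sat > 1 + _EPS)):
        raise ValueError("saturation must lie in [0, 1]")
    if np.any((inten < -_EPS) | (inten > 1 + _EPS)):
        raise ValueError("intensity must lie in [0, 1]")

    hue, sat, inten = np.broadcast_arrays(hue, sat, inten)
    h = np.mod(hue, 360.0)
    sector = (h // 120.0).astype(int)  # 0: RG, 1: GB, 2: BR
    h_local = np.radians(h - 120.0 * sector)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.cos(h_local) / np.cos(np.radians(60.0) - h_local)
    low = inten * (1.0 - sat)
    mid = inten * (1.0 + sat * ratio)
    high = 3.0 * inten - (low + mid)

    rgb = np.empty(h.shape + (3,), dtype=float)
    for s, order in enumerate(((2, 0, 1), (0, 1, 2), (1, 2, 0))):
        # order = (index of low, index of mid, index of high) per sector
        m = sector == s
        rgb[..., order[0]][m] = low[m]
        rgb[..., order[1]][m] = mid[m]
        rgb[..., order[2]][m] = high[m]
    return np.clip(rgb, 0.0, 1.0)
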