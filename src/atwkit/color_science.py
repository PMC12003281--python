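"""sRGB → CIELAB conversion and the CIEDE2000 color difference.

These two primitives underpin the Average Temperature Weight metric: every
heat-map pixel is converted to CIELAB and compared against the four
reference anchor colors with ΔE00.

Conventions (fixed, exposed as module constants for auditability):

* sRGB transfer function per IEC 61966-2-1 (linear segment below 0.04045,
  gamma 2.4 above).
* D65 reference white, 2° standard observer.  The white point is derived
  from the sRGB → XYZ matrix itself so that (255, 255, 255) maps to
  L* = 100 exactly up to floating-point rounding.
* CIEDE2000 follows the standard published formulation, including the
  G chroma rescaling, hue rotation term R_T and the well-known mean-hue
  branch rules.  Parametric factors default to kL = kC = kH = 1.

All functions are vectorised: they accept a single triple or any
``(..., 3)`` array and broadcast.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SRGB_TO_XYZ", "D65_WHITE", "srgb_to_lab", "ciede2000"]

#: Linear sRGB → XYZ (D65) matrix, IEC 61966-2-1 primaries.
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: D65 white point (X_n, Y_n, Z_n) implied by the matrix: image of RGB (1,1,1).
D65_WHITE = SRGB_TO_XYZ.sum(axis=1)

# CIELAB companding threshold: (6/29)^3 and the linear-segment slope terms.
_DELTA = 6.0 / 29.0


def srgb_to_lab(rgb) -> np.ndarray:
    """Convert 8-bit sRGB to CIELAB (D65, 2° observer).

    Parameters
    ----------
    rgb
        Triple or ``(..., 3)`` array of channel values in [0, 255].
        Values may be int or float; fractional values are accepted.

    Returns
    -------
    ndarray
        Same leading shape, last axis = (L*, a*, b*).  L* is in [0, 100]
        for any valid sRGB input; a*, b* are unbounded.

    Raises
    ------
    ValueError
        If any channel is outside [0, 255] or non-finite.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected last axis of size 3, got shape {rgb.shape}")
    if not np.all(np.isfinite(rgb)):
        raise ValueError("non-finite RGB channel value")
    if np.any(rgb < 0.0) or np.any(rgb > 255.0):
        raise ValueError("RGB channel outside [0, 255]")

    c = rgb / 255.0
    linear = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    xyz = linear @ SRGB_TO_XYZ.T
    t = xyz / D65_WHITE
    f = np.where(t > _DELTA**3, np.cbrt(t), t / (3.0 * _DELTA**2) + 4.0 / 29.0)

    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def ciede2000(lab1, lab2, kL: float = 1.0, kC: float = 1.0, kH: float = 1.0):
    """CIEDE2000 color difference ΔE00 between two CIELAB colors.

    Symmetric, non-negative, and zero iff the inputs are identical.
    Broadcasts over leading axes; returns a scalar for two plain triples.

    Raises
    ------
    ValueError
        On non-finite input.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    if lab1.shape[-1] != 3 or lab2.shape[-1] != 3:
        raise ValueError("Lab inputs must have last axis of size 3")
    if not (np.all(np.isfinite(lab1)) and np.all(np.isfinite(lab2))):
        raise ValueError("non-finite Lab input")

    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    c7 = Cbar**7
    G = 0.5 * (1.0 - np.sqrt(c7 / (c7 + 25.0**7)))

    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where(C1p == 0.0, 0.0, h1p)
    h2p = np.where(C2p == 0.0, 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p

    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0.0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        habs <= 180.0,
        0.5 * hsum,
        np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
    )
    hbp = np.where(C1p * C2p == 0.0, hsum, hbp)

    rad = np.radians
    T = (
        1.0
        - 0.17 * np.cos(rad(hbp - 30.0))
        + 0.24 * np.cos(rad(2.0 * hbp))
        + 0.32 * np.cos(rad(3.0 * hbp + 6.0))
        - 0.20 * np.cos(rad(4.0 * hbp - 63.0))
    )

    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    cbp7 = Cbp**7
    RC = 2.0 * np.sqrt(cbp7 / (cbp7 + 25.0**7))
    RT = -np.sin(rad(2.0 * dtheta)) * RC

    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T

    tL = dLp / (kL * SL)
    tC = dCp / (kC * SC)
    tH = dHp / (kH * SH)
    dE = np.sqrt(tL**2 + tC**2 + tH**2 + RT * tC * tH)
    if dE.ndim == 0:
        return float(dE)
    return dE
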