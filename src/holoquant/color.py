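"""Device-independent colour conversions and colour-difference metrics.

All conversions follow the CIE 1976 L*a*b* definitions with tristimulus
values on the Y=100 scale and the D65 / 2-degree observer white point, and
the geometric (Gonzalez & Woods) hue-saturation-intensity model.  Every
function is vectorised: a "triple" argument may be a length-3 vector or an
(..., 3) array of triples.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "D65_WHITE",
    "xyz_to_lab",
    "lab_to_xyz",
    "rgb_to_hsi",
    "xyz_to_xy",
    "delta_e_ab",
    "srgb_matrix",
    "linear_rgb_to_xyz",
]

#: CIE D65 white point, 2-degree 1931 observer, Y normalised to 100.
D65_WHITE = np.array([95.047, 100.0, 108.883])

# sRGB linear RGB -> XYZ (D65), Y of white = 1 before the x100 scaling.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

_EPS = (6.0 / 29.0) ** 3  # Lab linear-branch threshold
_KAPPA = (29.0 / 6.0) ** 2 / 3.0  # slope of the linear branch


def srgb_matrix() -> np.ndarray:
    """3x3 matrix taking linear sRGB primaries to XYZ (white Y = 1)."""
    return _SRGB_TO_XYZ.copy()


def linear_rgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """Map linear-light RGB in [0, 1] to XYZ on the Y=100 scale."""
    rgb = np.asarray(rgb, dtype=float)
    return 100.0 * rgb @ _SRGB_TO_XYZ.T


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _EPS, np.cbrt(t), _KAPPA * t + 4.0 / 29.0)


def _lab_f_inv(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    return np.where(f > 6.0 / 29.0, f**3, (f - 4.0 / 29.0) / _KAPPA)


def xyz_to_lab(xyz: np.ndarray, white: np.ndarray = D65_WHITE) -> np.ndarray:
    """Convert XYZ tristimulus values to CIE 1976 L*a*b*.

    Parameters
    ----------
    xyz : (..., 3) array
        Tristimulus values, Y on the 0-100 scale.
    white : length-3 array
        Reference white tristimulus; must be strictly positive.

    Returns
    -------
    (..., 3) array of (L*, a*, b*); the white point maps to (100, 0, 0).
    """
    white = np.asarray(white, dtype=float)
    if white.shape != (3,) or np.any(white <= 0) or not np.all(np.isfinite(white)):
        raise ValueError("reference white must be three strictly positive finite values")
    xyz = np.asarray(xyz, dtype=float)
    f = _lab_f(xyz / white)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def lab_to_xyz(lab: np.ndarray, white: np.ndarray = D65_WHITE) -> np.ndarray:
    """Inverse of :func:`xyz_to_lab` (exact on the Lab gamut)."""
    white = np.asarray(white, dtype=float)
    if white.shape != (3,) or np.any(white <= 0):
        raise ValueError("reference white must be three strictly positive values")
    lab = np.asarray(lab, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    f = np.stack([fx, fy, fz], axis=-1)
    return _lab_f_inv(f) * white


def rgb_to_hsi(rgb: np.ndarray) -> np.ndarray:
    """Convert RGB in [0, 1] to hue (degrees), saturation and intensity.

    Uses the geometric model: I = (R+G+B)/3, S = 1 - min/I (0 when I = 0),
    and H from the arccos of the normalised opponent projection.  Achromatic
    inputs (S = 0) report H = 0 by convention.
    """
    rgb = np.asarray(rgb, dtype=float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    intensity = (r + g + b) / 3.0
    minimum = np.minimum(np.minimum(r, g), b)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(intensity > 0, 1.0 - minimum / np.where(intensity > 0, intensity, 1.0), 0.0)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.degrees(np.arccos(np.clip(np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0), -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where((sat <= 0) | (den == 0), 0.0, hue)
    hue = np.mod(hue, 360.0)
    return np.stack([hue, sat, intensity], axis=-1)


def xyz_to_xy(xyz: np.ndarray) -> np.ndarray:
    """Project XYZ onto the CIE 1931 (x, y) chromaticity plane."""
    xyz = np.asarray(xyz, dtype=float)
    total = xyz.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("chromaticity undefined: X+Y+Z must be positive")
    return np.stack([xyz[..., 0] / total, xyz[..., 1] / total], axis=-1)


def delta_e_ab(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray:
    """CIE76 colour difference: Euclidean distance in L*a*b* space."""
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    return np.sqrt(np.sum((lab1 - lab2) ** 2, axis=-1))


def circular_mean_deg(angles_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Mean of angles in degrees computed on the unit circle."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    s = float(np.sum(w * np.sin(a)))
    c = float(np.sum(w * np.cos(a)))
    if s == 0.0 and c == 0.0:
        return 0.0
    angle = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return 0.0 if angle >= 360.0 else angle  # -eps % 360 rounds up to 360
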