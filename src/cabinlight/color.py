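"""Forward color transforms: display sRGB -> XYZ -> LMS -> IPT correlates.

All transforms are vectorized over leading axes: inputs are arrays whose
last axis has length 3 (one triple per pixel/block/stimulus).

Conventions
-----------
* sRGB values are gamma-encoded display codes normalized to [0, 1]
  (8-bit codes divide by 255); linearization follows the IEC 61966-2-1
  EOTF.
* XYZ is D65-referred on the relative scale Y(white) = 1.
* LMS is the IPT working scale: the Hunt-Pointer-Estevez-type matrix of
  the IPT model, normalized so that D65 white maps to L = M = S = 1.
* IPT applies a sign-preserving 0.43 power to LMS, then the opponent
  matrix; D65 white maps to (I, P, T) = (1, 0, 0).
* Perceptual correlates J (lightness), c (chroma) and h (hue angle,
  degrees in [0, 360)) are scaled so that J and c share the 0-100 range
  used by CAM16, easing dimension-by-dimension comparison of the two
  spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SRGB_TO_XYZ",
    "XYZ_TO_LMS_IPT",
    "LMS_TO_IPT",
    "D65_WHITE_XYZ",
    "IPT_EXPONENT",
    "Correlates",
    "srgb_to_linear",
    "linear_to_srgb",
    "srgb8_to_linear",
    "linear_rgb_to_xyz",
    "xyz_to_linear_rgb",
    "xyz_to_lms_ipt",
    "lms_to_ipt",
    "ipt_correlates",
    "srgb_to_xyz",
    "xyz_to_ipt",
]

# IEC 61966-2-1 sRGB primaries, D65 white (rows: X, Y, Z).
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
XYZ_TO_SRGB = np.linalg.inv(SRGB_TO_XYZ)

#: D65 white point on the relative scale Y = 1 (row sums of SRGB_TO_XYZ).
D65_WHITE_XYZ = SRGB_TO_XYZ.sum(axis=1)

# Hunt-Pointer-Estevez-type cone matrix of the IPT model.  The published
# 4-digit coefficients are normalized to a slightly rounded D65; each row
# is rescaled here so that the sRGB-derived D65 white maps to exactly
# L = M = S = 1 (the model's normalization, carried to full precision).
_LMS_BASE = np.array(
    [
        [0.4002, 0.7075, -0.0807],
        [-0.2280, 1.1500, 0.0612],
        [0.0000, 0.0000, 0.9184],
    ]
)
XYZ_TO_LMS_IPT = _LMS_BASE / (_LMS_BASE @ SRGB_TO_XYZ.sum(axis=1))[:, None]

# Opponent matrix of the IPT model; the I row weights sum to 1.
LMS_TO_IPT_M = np.array(
    [
        [0.4000, 0.4000, 0.2000],
        [4.4550, -4.8510, 0.3960],
        [0.8056, 0.3572, -1.1628],
    ]
)

#: Compressive nonlinearity exponent of the IPT model.
IPT_EXPONENT = 0.43

#: Chroma below which hue is reported as undefined (achromatic).
ACHROMATIC_TOL = 1e-9


@dataclass
class Correlates:
    """Perceptual correlates of one or more stimuli in one appearance space.

    ``J`` is lightness on 0-100, ``c`` chroma (>= 0, shared 0-100 scale),
    ``h`` hue angle in degrees in [0, 360).  ``achromatic`` flags stimuli
    whose chroma is below tolerance; their hue is reported as 0 by
    convention and should be skipped in hue statistics.  CAM16 results
    additionally carry colorfulness ``M``, saturation ``s``, brightness
    ``Q`` and hue composition ``H``.
    """

    space: str
    J: np.ndarray
    c: np.ndarray
    h: np.ndarray
    achromatic: np.ndarray = field(default=None)  # type: ignore[assignment]
    M: np.ndarray | None = None
    s: np.ndarray | None = None
    Q: np.ndarray | None = None
    H: np.ndarray | None = None

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.achromatic is None:
            self.achromatic = self.c < ACHROMATIC_TOL
        self.achromatic = np.asarray(self.achromatic, dtype=bool)

    def __len__(self) -> int:
        return int(np.atleast_1d(self.J).shape[0])


def _validate_triples(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError(f"{name} must have last axis of length 3, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def srgb_to_linear(c, *, tol: float = 1e-9) -> np.ndarray:
    """Decode gamma-encoded sRGB in [0, 1] to linear light in [0, 1].

    Applies the IEC 61966-2-1 EOTF per channel: a linear segment below
    code 0.04045, the offset 2.4-power branch above.
    """
    c = _validate_triples(c, "sRGB") if np.ndim(c) and np.shape(c)[-1] == 3 else np.asarray(c, dtype=float)
    if np.any(c < -tol) or np.any(c > 1 + tol):
        raise ValueError("gamma-encoded sRGB values must lie in [0, 1]")
    c = np.clip(c, 0.0, 1.0)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(c, *, tol: float = 1e-9) -> np.ndarray:
    """Encode linear light in [0, 1] to gamma-encoded sRGB (inverse EOTF)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < -tol) or np.any(c > 1 + tol):
        raise ValueError("linear sRGB values must lie in [0, 1]")
    c = np.clip(c, 0.0, 1.0)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1 / 2.4) - 0.055)


def srgb8_to_linear(codes) -> np.ndarray:
    """Decode 8-bit sRGB codes (0-255) to linear light in [0, 1]."""
    codes = np.asarray(codes, dtype=float)
    if np.any(codes < 0) or np.any(codes > 255):
        raise ValueError("8-bit sRGB codes must lie in [0, 255]")
    return srgb_to_linear(codes / 255.0)


def linear_rgb_to_xyz(rgb) -> np.ndarray:
    """Linear sRGB (D65 primaries) to CIE XYZ, Y(white) = 1."""
    rgb = _validate_triples(rgb, "linear RGB")
    return rgb @ SRGB_TO_XYZ.T


def xyz_to_linear_rgb(xyz) -> np.ndarray:
    """CIE XYZ (D65-referred, Y(white) = 1) to linear sRGB; may leave gamut."""
    xyz = _validate_triples(xyz, "XYZ")
    return xyz @ XYZ_TO_SRGB.T


def xyz_to_lms_ipt(xyz) -> np.ndarray:
    """D65-referred XYZ to cone responses on the IPT working scale."""
    xyz = _validate_triples(xyz, "XYZ")
    return xyz @ XYZ_TO_LMS_IPT.T


def _signed_power(v: np.ndarray, p: float) -> np.ndarray:
    return np.sign(v) * np.abs(v) ** p


def lms_to_ipt(lms) -> np.ndarray:
    """Cone responses to IPT: sign-preserving 0.43 power, then opponent matrix.

    Negative cone values (possible for out-of-gamut XYZ) pass through the
    odd-symmetric extension of the power function.
    """
    lms = _validate_triples(lms, "LMS")
    return _signed_power(lms, IPT_EXPONENT) @ LMS_TO_IPT_M.T


def ipt_correlates(ipt) -> Correlates:
    """Lightness, chroma, hue from IPT: J = 100 I, c = 100 sqrt(P^2+T^2),
    h = atan2(T, P) mapped to [0, 360)."""
    ipt = _validate_triples(ipt, "IPT")
    i, p, t = ipt[..., 0], ipt[..., 1], ipt[..., 2]
    c = 100.0 * np.hypot(p, t)
    achromatic = c < ACHROMATIC_TOL
    h = np.degrees(np.arctan2(t, p)) % 360.0
    h = np.where(achromatic, 0.0, h)
    return Correlates(space="IPT", J=100.0 * i, c=c, h=h, achromatic=achromatic)


def srgb_to_xyz(c) -> np.ndarray:
    """Gamma-encoded sRGB in [0, 1] straight to D65-referred XYZ."""
    return linear_rgb_to_xyz(srgb_to_linear(c))


def xyz_to_ipt(xyz) -> np.ndarray:
    """D65-referred XYZ straight to IPT."""
    return lms_to_ipt(xyz_to_lms_ipt(xyz))


# Alias matching the opponent-matrix export name used in docs/tests.
LMS_TO_IPT = LMS_TO_IPT_M
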