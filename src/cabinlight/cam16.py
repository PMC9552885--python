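"""CAM16 color appearance model: viewing conditions and forward pass.

Implements the published CAM16 formulation (CAT16 chromatic adaptation,
luminance-level adaptation factor F_L, post-adaptation cone compression,
opponent dimensions, and the appearance correlates J, Q, C, M, s, h, H).
Only the forward direction is provided; the inverse model and the
CAM16-UCS uniform space are out of scope here.

The stimulus and the white point must be supplied on the same XYZ scale;
the conventional scale with Y(white) = 100 is used throughout.  Inputs
on the Y(white) = 1 scale can be multiplied by 100 (see
:func:`cam16_from_xyz_rel`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .color import Correlates, D65_WHITE_XYZ, _validate_triples

__all__ = [
    "Surround",
    "SURROUNDS",
    "ViewingConditions",
    "cam16_viewing_conditions",
    "cam16_forward",
    "cam16_from_xyz_rel",
    "DEFAULT_VIEWING_CONDITIONS",
]

# CAT16 matrix (Li et al.): XYZ -> sharpened cone-like RGB.
M16 = np.array(
    [
        [0.401288, 0.650173, -0.051461],
        [-0.250268, 1.204414, 0.045854],
        [-0.002079, 0.048952, 0.953127],
    ]
)

# Unique-hue data for the hue-quadrature correlate H.
_UNIQUE_H = np.array([20.14, 90.00, 164.25, 237.53, 380.14])
_UNIQUE_E = np.array([0.8, 0.7, 1.0, 1.2, 0.8])
_UNIQUE_HQ = np.array([0.0, 100.0, 200.0, 300.0, 400.0])


@dataclass(frozen=True)
class Surround:
    """Surround parameters: F (adaptation), c (impact of surround), N_c."""

    F: float
    c: float
    N_c: float


SURROUNDS = {
    "average": Surround(1.0, 0.69, 1.0),
    "dim": Surround(0.9, 0.59, 0.9),
    "dark": Surround(0.8, 0.525, 0.8),
}


@dataclass(frozen=True)
class ViewingConditions:
    """CAM16 viewing conditions with all derived adaptation quantities.

    Users supply the adapting white point (XYZ, Y-scale declared by
    ``white``), the adapting luminance L_A in cd/m^2, the background
    relative luminance Y_b (same scale as the white's Y), and the
    surround class.  Everything else (degree of adaptation D, luminance
    adaptation factor F_L, n, z, N_bb, N_cb, the per-channel adaptation
    gains and the adapted white's achromatic response A_w) is derived
    here and never user-supplied.
    """

    white: np.ndarray
    L_A: float
    Y_b: float
    surround_name: str = "average"
    surround: Surround = field(init=False)
    D: float = field(init=False)
    F_L: float = field(init=False)
    n: float = field(init=False)
    z: float = field(init=False)
    N_bb: float = field(init=False)
    N_cb: float = field(init=False)
    D_rgb: np.ndarray = field(init=False)
    A_w: float = field(init=False)
    rgb_aw: np.ndarray = field(init=False)

    def __post_init__(self):
        white = np.asarray(self.white, dtype=float)
        if white.shape != (3,) or not np.all(np.isfinite(white)) or white[1] <= 0:
            raise ValueError("white point must be a finite XYZ triple with Y > 0")
        if not np.isfinite(self.L_A) or self.L_A <= 0:
            raise ValueError("adapting luminance L_A must be positive")
        if self.surround_name not in SURROUNDS:
            raise ValueError(f"unknown surround class {self.surround_name!r}")
        object.__setattr__(self, "white", white)
        sr = SURROUNDS[self.surround_name]
        object.__setattr__(self, "surround", sr)

        Y_w = white[1]
        rgb_w = M16 @ white

        D = sr.F * (1.0 - (1.0 / 3.6) * np.exp((-self.L_A - 42.0) / 92.0))
        D = float(np.clip(D, 0.0, 1.0))
        object.__setattr__(self, "D", D)

        k = 1.0 / (5.0 * self.L_A + 1.0)
        F_L = 0.2 * k**4 * (5.0 * self.L_A) + 0.1 * (1.0 - k**4) ** 2 * (
            5.0 * self.L_A
        ) ** (1.0 / 3.0)
        object.__setattr__(self, "F_L", float(F_L))

        n = self.Y_b / Y_w
        if not 0 < n:
            raise ValueError("background luminance Y_b must be positive")
        object.__setattr__(self, "n", float(n))
        object.__setattr__(self, "z", float(1.48 + np.sqrt(n)))
        N_bb = 0.725 * (1.0 / n) ** 0.2
        object.__setattr__(self, "N_bb", float(N_bb))
        object.__setattr__(self, "N_cb", float(N_bb))

        D_rgb = D * Y_w / rgb_w + 1.0 - D
        object.__setattr__(self, "D_rgb", D_rgb)

        rgb_wc = D_rgb * rgb_w
        rgb_aw = _adapt(rgb_wc, F_L)
        object.__setattr__(self, "rgb_aw", rgb_aw)
        A_w = (2.0 * rgb_aw[0] + rgb_aw[1] + 0.05 * rgb_aw[2] - 0.305) * N_bb
        object.__setattr__(self, "A_w", float(A_w))


def _adapt(rgb: np.ndarray, F_L: float) -> np.ndarray:
    """Post-adaptation cone response compression (sign-preserving)."""
    x = (F_L * np.abs(rgb) / 100.0) ** 0.42
    return np.sign(rgb) * 400.0 * x / (x + 27.13) + 0.1


def cam16_viewing_conditions(
    white=None,
    L_A: float = 20.0,
    Y_b: float = 20.0,
    surround: str = "average",
) -> ViewingConditions:
    """Build :class:`ViewingConditions`.

    Defaults describe the package's nominal display model: D65 white
    scaled to Y = 100, adapting luminance 20 cd/m^2 (20% of a nominal
    100 cd/m^2 peak white), background relative luminance 20, average
    surround.  The display peak is a configuration knob, not a measured
    quantity.
    """
    if white is None:
        white = D65_WHITE_XYZ * 100.0
    return ViewingConditions(white=np.asarray(white, dtype=float), L_A=L_A, Y_b=Y_b, surround_name=surround)


DEFAULT_VIEWING_CONDITIONS = cam16_viewing_conditions()


def _hue_quadrature(h: np.ndarray) -> np.ndarray:
    hp = np.where(h < _UNIQUE_H[0], h + 360.0, h)
    i = np.searchsorted(_UNIQUE_H, hp, side="right") - 1
    i = np.clip(i, 0, 3)
    h_i, h_i1 = _UNIQUE_H[i], _UNIQUE_H[i + 1]
    e_i, e_i1 = _UNIQUE_E[i], _UNIQUE_E[i + 1]
    num = 100.0 * (hp - h_i) / e_i
    den = (hp - h_i) / e_i + (h_i1 - hp) / e_i1
    with np.errstate(invalid="ignore"):
        H = _UNIQUE_HQ[i] + np.where(den > 0, num / den, 0.0)
    return H


def cam16_forward(xyz, vc: ViewingConditions | None = None) -> Correlates:
    """Full CAM16 forward pass for stimuli ``xyz`` (same scale as vc.white).

    Returns lightness J, chroma C (as ``c``), hue angle h plus
    colorfulness M, saturation s, brightness Q and hue composition H.
    An all-zero stimulus maps to J = 0, C = 0 (achromatic).
    """
    if vc is None:
        vc = DEFAULT_VIEWING_CONDITIONS
    xyz = _validate_triples(xyz, "XYZ")

    rgb = xyz @ M16.T
    rgb_c = vc.D_rgb * rgb
    rgb_a = _adapt(rgb_c, vc.F_L)

    R, G, B = rgb_a[..., 0], rgb_a[..., 1], rgb_a[..., 2]
    a = R - 12.0 * G / 11.0 + B / 11.0
    b = (R + G - 2.0 * B) / 9.0

    h = np.degrees(np.arctan2(b, a)) % 360.0

    A = (2.0 * R + G + 0.05 * B - 0.305) * vc.N_bb
    A = np.maximum(A, 0.0)
    sr = vc.surround
    J = 100.0 * (A / vc.A_w) ** (sr.c * vc.z)
    Q = (4.0 / sr.c) * np.sqrt(J / 100.0) * (vc.A_w + 4.0) * vc.F_L**0.25

    e_t = 0.25 * (np.cos(np.radians(h) + 2.0) + 3.8)
    denom = R + G + 21.0 * B / 20.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (
            (50000.0 / 13.0)
            * sr.N_c
            * vc.N_cb
            * e_t
            * np.hypot(a, b)
            / denom
        )
    t = np.where(np.isfinite(t) & (t > 0), t, 0.0)

    C = t**0.9 * np.sqrt(J / 100.0) * (1.64 - 0.29**vc.n) ** 0.73
    M = C * vc.F_L**0.25
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(Q > 0, 100.0 * np.sqrt(np.where(Q > 0, M / np.where(Q > 0, Q, 1.0), 0.0)), 0.0)

    achromatic = C < 1e-9
    h = np.where(achromatic, 0.0, h)
    H = _hue_quadrature(h)

    return Correlates(
        space="CAM16", J=J, c=C, h=h, achromatic=achromatic, M=M, s=s, Q=Q, H=H
    )


def cam16_from_xyz_rel(xyz_rel, vc: ViewingConditions | None = None) -> Correlates:
    """CAM16 correlates for XYZ on the relative Y(white) = 1 scale.

    Scales the stimulus by 100 to match the conventional Y(white) = 100
    scale of the default viewing conditions.
    """
    return cam16_forward(np.asarray(xyz_rel, dtype=float) * 100.0, vc)
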