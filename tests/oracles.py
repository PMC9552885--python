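"""Independent oracle implementations used only by the test suite.

These are second, deliberately separate transcriptions of the published
transforms and statistics: scalar, loop-based, transcribed from the
primary sources independently of the package's vectorized code paths.
They exist to catch transcription and broadcasting errors in the main
implementation and must never import from it.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import rankdata

# --------------------------------------------------------------------------
# sRGB / IPT oracle (scalar, published 4-digit matrices, no renormalization)

_SRGB2XYZ = (
    (0.4124564, 0.3575761, 0.1804375),
    (0.2126729, 0.7151522, 0.0721750),
    (0.0193339, 0.1191920, 0.9503041),
)
_XYZ2LMS_RAW = (
    (0.4002, 0.7075, -0.0807),
    (-0.2280, 1.1500, 0.0612),
    (0.0, 0.0, 0.9184),
)
# The cone matrix is declared normalized so that D65 white (here derived
# from the sRGB matrix's row sums) maps to L = M = S = 1 exactly.
_D65 = tuple(sum(row) for row in _SRGB2XYZ)
_XYZ2LMS = tuple(
    tuple(m / sum(row[j] * _D65[j] for j in range(3)) for m in row)
    for row in _XYZ2LMS_RAW
)
_LMS2IPT = (
    (0.4000, 0.4000, 0.2000),
    (4.4550, -4.8510, 0.3960),
    (0.8056, 0.3572, -1.1628),
)


def srgb_eotf_oracle(code: float) -> float:
    """IEC 61966-2-1 decoding of one normalized gamma-encoded channel."""
    if code <= 0.04045:
        return code / 12.92
    return ((code + 0.055) / 1.055) ** 2.4


def _matvec(m, v):
    return [sum(m[i][j] * v[j] for j in range(3)) for i in range(3)]


def ipt_oracle(xyz) -> tuple[float, float, float]:
    """XYZ (D65, Y=1 scale) -> IPT via the published matrices."""
    lms = _matvec(_XYZ2LMS, list(xyz))
    lmsp = [math.copysign(abs(v) ** 0.43, v) for v in lms]
    return tuple(_matvec(_LMS2IPT, lmsp))


def srgb_to_xyz_oracle(rgb8) -> tuple[float, float, float]:
    lin = [srgb_eotf_oracle(c / 255.0) for c in rgb8]
    return tuple(_matvec(_SRGB2XYZ, lin))


# --------------------------------------------------------------------------
# CAM16 oracle (scalar step-by-step transcription)

_M16 = (
    (0.401288, 0.650173, -0.051461),
    (-0.250268, 1.204414, 0.045854),
    (-0.002079, 0.048952, 0.953127),
)
_SURROUND = {
    "average": (1.0, 0.69, 1.0),
    "dim": (0.9, 0.59, 0.9),
    "dark": (0.8, 0.525, 0.8),
}


def cam16_oracle(xyz, white, L_A, Y_b, surround="average") -> dict:
    """Full CAM16 forward pass for a single stimulus (Y_w = 100 scale)."""
    F, c, N_c = _SURROUND[surround]
    Y_w = white[1]

    rgb_w = _matvec(_M16, list(white))
    D = F * (1.0 - (1.0 / 3.6) * math.exp((-L_A - 42.0) / 92.0))
    D = min(1.0, max(0.0, D))
    D_rgb = [D * Y_w / rgb_w[i] + 1.0 - D for i in range(3)]

    k = 1.0 / (5.0 * L_A + 1.0)
    F_L = 0.2 * k**4 * 5.0 * L_A + 0.1 * (1.0 - k**4) ** 2 * (5.0 * L_A) ** (1.0 / 3.0)

    n = Y_b / Y_w
    z = 1.48 + math.sqrt(n)
    N_bb = 0.725 * (1.0 / n) ** 0.2
    N_cb = N_bb

    def adapt(v):
        x = (F_L * abs(v) / 100.0) ** 0.42
        return math.copysign(400.0 * x / (x + 27.13), v) + 0.1

    rgb_aw = [adapt(D_rgb[i] * rgb_w[i]) for i in range(3)]
    A_w = (2.0 * rgb_aw[0] + rgb_aw[1] + 0.05 * rgb_aw[2] - 0.305) * N_bb

    rgb = _matvec(_M16, list(xyz))
    rgb_a = [adapt(D_rgb[i] * rgb[i]) for i in range(3)]
    Ra, Ga, Ba = rgb_a
    a = Ra - 12.0 * Ga / 11.0 + Ba / 11.0
    b = (Ra + Ga - 2.0 * Ba) / 9.0
    h = math.degrees(math.atan2(b, a)) % 360.0

    A = max(0.0, (2.0 * Ra + Ga + 0.05 * Ba - 0.305) * N_bb)
    J = 100.0 * (A / A_w) ** (c * z)
    Q = (4.0 / c) * math.sqrt(J / 100.0) * (A_w + 4.0) * F_L**0.25

    e_t = 0.25 * (math.cos(math.radians(h) + 2.0) + 3.8)
    denom = Ra + Ga + 21.0 * Ba / 20.0
    t = 0.0
    if denom != 0.0:
        t = (50000.0 / 13.0) * N_c * N_cb * e_t * math.hypot(a, b) / denom
        t = max(0.0, t)
    C = t**0.9 * math.sqrt(J / 100.0) * (1.64 - 0.29**n) ** 0.73
    M = C * F_L**0.25
    s = 100.0 * math.sqrt(M / Q) if Q > 0 else 0.0
    return {
        "J": J, "C": C, "h": h, "M": M, "s": s, "Q": Q,
        "D": D, "F_L": F_L, "n": n, "z": z, "N_bb": N_bb, "A_w": A_w,
    }


# --------------------------------------------------------------------------
# Wilcoxon exact-enumeration oracle (distinct from the package's path)

def wilcoxon_exact_oracle(a, b) -> float:
    """Two-sided exact signed-rank p by itertools enumeration."""
    d = [x - y for x, y in zip(a, b) if x != y]
    ranks = rankdata([abs(v) for v in d])
    mu = ranks.sum() / 2.0
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    count = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2 ** len(d)


# --------------------------------------------------------------------------
# Regression oracle via the normal equations

def ols_oracle(x, y) -> tuple[float, float]:
    """(slope, intercept) from the closed-form normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    slope = float(((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum())
    return slope, float(ybar - slope * xbar)
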