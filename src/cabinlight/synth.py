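"""Synthetic study data with known ground truth.

The survey renders and rating tables behind the original study are not
public, so every analysis stage is exercised on synthetic data that
emulates the study conditions:

* equirectangular cabin scenes (1024 x 512 by default) with a
  parametric exterior archetype seen through a window band covering 25%
  of blocks, and interior lighting defined by a CCT in {3000, 4500,
  6000 K}, a spot or spatial (or mixed) distribution, and one of five
  intensity levels (spot: 5, 11, 25, 50, 100%; spatial: 10, 20, 30, 70,
  100%);
* the eight luminaire settings L1-L8 (L8 = no in-vehicle light);
* paired-comparison rating matrices generated from a known
  low-dimensional latent configuration plus clipped, discretized
  Gaussian ordinal noise;
* preference tables with known linear contrast-preference slopes for
  trend-recovery tests.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .color import linear_to_srgb, xyz_to_linear_rgb
from .scene import EquirectImage, SceneMask, default_scene_mask

__all__ = [
    "SyntheticSceneSpec",
    "LatentRatingSpec",
    "ARCHETYPES",
    "LIGHT_SETTINGS",
    "SPOT_LEVELS",
    "SPATIAL_LEVELS",
    "cct_to_srgb",
    "cct_to_xy",
    "gen_scene",
    "gen_paired_ratings",
    "gen_preference_data",
]

#: Relative intensity (%) of the five user-selectable brightness levels.
SPOT_LEVELS = (5.0, 11.0, 25.0, 50.0, 100.0)
SPATIAL_LEVELS = (10.0, 20.0, 30.0, 70.0, 100.0)

#: The eight luminaire settings: (spot CCT, spatial CCT); None = off.
LIGHT_SETTINGS = {
    "L1": {"spot": 3000.0, "spatial": None},
    "L2": {"spot": 4500.0, "spatial": None},
    "L3": {"spot": 6000.0, "spatial": None},
    "L4": {"spot": None, "spatial": 6000.0},
    "L5": {"spot": None, "spatial": 3000.0},
    "L6": {"spot": 6000.0, "spatial": 3000.0},
    "L7": {"spot": 3000.0, "spatial": 6000.0},
    "L8": {"spot": None, "spatial": None},
}

# Exterior archetypes: target mean linear luminance of the window region,
# base chromatic palette (linear RGB), and texture contrast.  Chosen so
# that mean region lightness orders sun_city ~ countryside > forest >
# night while night keeps high local chroma (city lights) and forest
# stays desaturated.
ARCHETYPES = {
    "sun_city": {
        "luminance": 0.75,
        "palette": [[1.0, 0.95, 0.85], [0.9, 0.9, 1.0], [1.0, 0.85, 0.7]],
        "texture": 0.25,
    },
    "countryside": {
        "luminance": 0.70,
        "palette": [[0.55, 0.75, 1.0], [0.45, 0.85, 0.35], [0.95, 0.95, 0.8]],
        "texture": 0.25,
    },
    "forest": {
        "luminance": 0.06,
        "palette": [[0.28, 0.33, 0.26], [0.30, 0.34, 0.28], [0.26, 0.30, 0.24]],
        "texture": 0.15,
    },
    "night": {
        "luminance": 0.015,
        "palette": [[0.9, 0.2, 0.1], [0.1, 0.4, 1.0], [1.0, 0.8, 0.1]],
        "texture": 0.9,
    },
}


@dataclass
class SyntheticSceneSpec:
    """Parameters of one synthetic cabin scene."""

    archetype: str = "sun_city"
    setting: str = "L7"
    level: int = 5  # 1..5 brightness level index
    seed: int = 0
    height: int = 512  # width = 2 * height
    block: int = 32
    spot_cct: float | None = field(default=None)
    spatial_cct: float | None = field(default=None)

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown exterior archetype {self.archetype!r}")
        if not 1 <= self.level <= 5:
            raise ValueError("intensity level index must lie in 1..5")
        if self.setting is not None:
            if self.setting not in LIGHT_SETTINGS:
                raise ValueError(f"unknown luminaire setting {self.setting!r}")
            cfg = LIGHT_SETTINGS[self.setting]
            if self.spot_cct is None:
                self.spot_cct = cfg["spot"]
            if self.spatial_cct is None:
                self.spatial_cct = cfg["spatial"]
        for cct in (self.spot_cct, self.spatial_cct):
            if cct is not None and not 1000.0 <= cct <= 20000.0:
                raise ValueError("CCT must lie in [1000, 20000] K")
        if self.height % self.block or (2 * self.height) % self.block:
            raise ValueError("scene height must be divisible by the block size")


@dataclass
class LatentRatingSpec:
    """Parameters of a synthetic paired-comparison rating experiment."""

    n_items: int = 8
    k_true: int = 3
    n_subjects: int = 148
    noise: float = 1.0  # SD of the ordinal noise in rating-scale units
    seed: int = 0
    scale_max: int = 10

    def __post_init__(self):
        if self.k_true >= self.n_items:
            raise ValueError("latent dimension must be below the item count")
        if self.noise < 0:
            raise ValueError("noise level must be nonnegative")


def cct_to_xy(cct: float) -> tuple[float, float]:
    """CIE 1931 chromaticity of a white source at the given CCT.

    Uses the CIE daylight-locus polynomial above 4000 K (so 6504 K
    lands on D65) and the Kim et al. cubic-spline Planckian-locus
    approximation below; valid for 1667-25000 K.
    """
    T = float(cct)
    if not 1667.0 <= T <= 25000.0:
        raise ValueError("CCT outside the validity range [1667, 25000] K")
    if T >= 4000.0:
        # CIE daylight locus.
        if T <= 7000.0:
            x = 0.244063 + 0.09911e3 / T + 2.9678e6 / T**2 - 4.6070e9 / T**3
        else:
            x = 0.237040 + 0.24748e3 / T + 1.9018e6 / T**2 - 2.0064e9 / T**3
        y = -3.000 * x**2 + 2.870 * x - 0.275
    else:
        # Kim et al. Planckian approximation.
        x = (
            -0.2661239e9 / T**3
            - 0.2343589e6 / T**2
            + 0.8776956e3 / T
            + 0.179910
        )
        if T <= 2222.0:
            y = (
                -1.1063814 * x**3
                - 1.34811020 * x**2
                + 2.18555832 * x
                - 0.20219683
            )
        else:
            y = (
                -0.9549476 * x**3
                - 1.37418593 * x**2
                + 2.09137015 * x
                - 0.16748867
            )
    return x, y


def cct_to_srgb(cct: float, level: float = 1.0):
    """Gamma-encoded sRGB of a white source at ``cct``, scaled by ``level``.

    ``level`` is the relative luminance in [0, 1] of the brightest
    channel.  Returns (srgb, clipped): linear RGB outside [0, 1] is
    clipped and flagged.
    """
    if level < 0:
        raise ValueError("level must be nonnegative")
    if level == 0:
        return np.zeros(3), False
    x, y = cct_to_xy(cct)
    xyz = np.array([x / y, 1.0, (1.0 - x - y) / y])
    rgb = xyz_to_linear_rgb(xyz)
    clipped = bool(np.any(rgb < 0))
    rgb = np.clip(rgb, 0.0, None)
    rgb = rgb / rgb.max() * level
    over = bool(np.any(rgb > 1.0))
    rgb = np.clip(rgb, 0.0, 1.0)
    return linear_to_srgb(rgb), clipped or over


def _exterior_texture(rng, shape, arche: dict) -> np.ndarray:
    """Linear-RGB exterior texture with the archetype's palette and level."""
    h, w = shape
    pal = np.asarray(arche["palette"], dtype=float)
    # Low-frequency patchwork of palette entries plus multiplicative noise.
    cells = rng.integers(0, len(pal), size=(max(2, h // 8), max(2, w // 8)))
    cells = np.kron(cells, np.ones((8, 8), dtype=int))[:h, :w]
    base = pal[cells]
    gain = 1.0 + arche["texture"] * (rng.random((h, w, 1)) - 0.5) * 2.0
    img = base * gain
    if arche["texture"] > 0.5:
        # Sparse bright lights on a dark ground (night archetype).
        lights = rng.random((h, w, 1)) < 0.02
        ground = 0.08 * (1.0 + 0.3 * (rng.random((h, w, 1)) - 0.5))
        img = np.where(lights, img * 8.0, ground * np.ones(3))
    # Scale to the archetype's target mean luminance (Y of linear RGB).
    Y = img @ np.array([0.2126729, 0.7151522, 0.0721750])
    img = img * (arche["luminance"] / max(Y.mean(), 1e-9))
    return np.clip(img, 0.0, 1.0)


def _interior_light(rng, shape, spec: SyntheticSceneSpec) -> np.ndarray:
    """Linear-RGB interior illumination field for the spec's luminaires."""
    h, w = shape
    out = np.zeros((h, w, 3))
    yy, xx = np.mgrid[0:h, 0:w]
    if spec.spot_cct is not None:
        frac = SPOT_LEVELS[spec.level - 1] / 100.0
        srgb, _ = cct_to_srgb(spec.spot_cct, 1.0)
        color = np.clip(
            np.where(srgb <= 0.04045, srgb / 12.92, ((srgb + 0.055) / 1.055) ** 2.4),
            0,
            1,
        )
        # Concentrated patch with Gaussian falloff in the lower cabin.
        cy, cx = int(h * 0.78), int(w * 0.5)
        sigma = h * 0.12
        fall = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
        out += frac * color * fall[..., None]
    if spec.spatial_cct is not None:
        frac = SPATIAL_LEVELS[spec.level - 1] / 100.0
        srgb, _ = cct_to_srgb(spec.spatial_cct, 1.0)
        color = np.clip(
            np.where(srgb <= 0.04045, srgb / 12.92, ((srgb + 0.055) / 1.055) ** 2.4),
            0,
            1,
        )
        out += frac * 0.55 * color * np.ones((h, w, 1))
    return out


def gen_scene(spec: SyntheticSceneSpec):
    """Generate one synthetic cabin scene and its block scene mask.

    Returns (EquirectImage, SceneMask).  The exterior archetype fills the
    window band (25% of blocks); the interior receives the luminaire
    field plus a faint constant ambient floor.  Deterministic under
    ``spec.seed``; raising the intensity level strictly raises the
    interior region's mean luminance.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, 2 * spec.height
    mask = default_scene_mask(h // spec.block, w // spec.block)
    ext_pix = np.kron(mask.external, np.ones((spec.block, spec.block), dtype=bool))

    arche = ARCHETYPES[spec.archetype]
    exterior = _exterior_texture(rng, (h, w), arche)
    interior = _interior_light(rng, (h, w), spec)
    interior += 0.004  # ambient floor: roof-frame orientation light
    # Cabin surfaces reflect the luminaire field with mild texture.
    albedo = 0.75 + 0.1 * (rng.random((h, w, 1)) - 0.5)
    interior = np.clip(interior * albedo, 0.0, 1.0)

    linear = np.where(ext_pix[..., None], exterior, interior)
    pixels = np.clip(np.rint(linear_to_srgb(np.clip(linear, 0, 1)) * 255), 0, 255)
    return EquirectImage(pixels.astype(np.uint8)), mask


def gen_paired_ratings(spec: LatentRatingSpec):
    """Paired-comparison difference ratings from a latent configuration.

    Item dissimilarities are Euclidean distances between latent
    coordinates in ``k_true`` dimensions, scaled monotonically to the
    0..scale_max rating range; each subject's rating of a pair is that
    value plus clipped, discretized Gaussian noise.

    Returns (ratings, true_dissim, latent): a subjects x pairs DataFrame
    whose columns are (item_i, item_j) tuples, the true n x n
    dissimilarity matrix, and the latent coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    latent = rng.normal(size=(spec.n_items, spec.k_true))
    items = [f"L{i + 1}" for i in range(spec.n_items)]
    diff = latent[:, None, :] - latent[None, :, :]
    true_d = np.sqrt((diff**2).sum(-1))
    scale = spec.scale_max / true_d.max()
    pairs = list(combinations(range(spec.n_items), 2))
    cols = [(items[i], items[j]) for i, j in pairs]
    clean = np.array([true_d[i, j] * scale for i, j in pairs])
    noisy = clean[None, :] + rng.normal(0, spec.noise, size=(spec.n_subjects, len(pairs)))
    ratings = np.clip(np.rint(noisy), 0, spec.scale_max).astype(int)
    df = pd.DataFrame(ratings, columns=pd.Index(cols))
    return df, true_d * scale, latent


def gen_preference_data(
    slopes: dict[str, float],
    noise: float = 5.0,
    n: int = 20,
    seed: int = 0,
    x_range: tuple[float, float] = (0.0, 3.0),
    intercepts: dict[str, float] | None = None,
):
    """Contrast/preference table with known linear trends.

    For each contrast dimension in ``slopes`` (keys among dJ, dc, dh),
    samples predictor values x over ``x_range`` (the ordered
    bright-to-dark scene axis) and sets y = intercept + slope * x +
    Gaussian noise (contrast percent units).  A 7-point preference
    rating is derived from the dJ column by a fixed monotone map and
    discretized.  Returns (DataFrame, ground_truth dict).
    """
    if n < 4:
        raise ValueError("need at least 4 points")
    rng = np.random.default_rng(seed)
    x = rng.uniform(*x_range, size=n)
    intercepts = intercepts or {}
    data = {"x": x}
    truth = {}
    for dim, slope in slopes.items():
        b0 = intercepts.get(dim, 0.0)
        data[dim] = b0 + slope * x + rng.normal(0, noise, size=n)
        truth[dim] = {"slope": slope, "intercept": b0}
    df = pd.DataFrame(data)
    if "dJ" in df:
        # Preference peaks where internal and external lightness match.
        pref = 7.0 - np.abs(df["dJ"]) / 25.0 + rng.normal(0, 0.3, size=n)
        df["rating"] = np.clip(np.rint(pref), 1, 7).astype(int)
    return df, truth
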