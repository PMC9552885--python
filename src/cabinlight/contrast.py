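"""External/internal perceptual contrast statistics and trend analysis.

The central statistic is the normalized percentage contrast between the
external scenery (sc) and the in-vehicle interior (il) for each
perceptual dimension v in {J, c, h}:

    Contrast_v = 100 * (|v_sc| - |v_il|) / (|v_sc| + |v_il|)   [%]

computed once per scene from region-aggregated correlates (region first,
then contrast: the statistic is written with a single sc and il value
per scene).  A per-block variant is available for sensitivity analysis.

Working areas collect the contrast triples attainable across luminaire
settings ("possible") and the subset whose mean preference rating clears
a threshold ("preferred").  Trend fits regress a contrast dimension on
an ordered scene index; space correlations regress CAM16 correlates on
IPT correlates dimension by dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.spatial import ConvexHull, QhullError

from .cam16 import ViewingConditions, cam16_from_xyz_rel
from .color import Correlates, ipt_correlates, xyz_to_ipt
from .scene import RegionBlocks

__all__ = [
    "ContrastTriple",
    "WorkingArea",
    "TrendFit",
    "region_correlates",
    "scene_contrast",
    "per_block_contrast",
    "working_area",
    "fit_contrast_trend",
    "correlate_spaces",
]


@dataclass
class ContrastTriple:
    """Percentage contrasts between external and internal regions.

    Each of dJ, dc, dh lies in [-100, 100]; dh is NaN when either
    region is entirely achromatic (hue undefined).
    """

    dJ: float
    dc: float
    dh: float
    space: str
    scene: str = ""
    setting: str = ""
    level: int | None = None

    def as_dict(self) -> dict:
        return {
            "scene": self.scene,
            "setting": self.setting,
            "level": self.level,
            "space": self.space,
            "dJ": self.dJ,
            "dc": self.dc,
            "dh": self.dh,
        }


@dataclass
class WorkingArea:
    """Possible vs preferred contrast region for one scene.

    ``possible`` holds all setting contrasts, ``preferred`` those whose
    mean rating reached the threshold.  Bounding boxes span each
    dimension; the optional hull is the 2-D convex hull in (dJ, dc).
    """

    scene: str
    possible: list[ContrastTriple]
    preferred: list[ContrastTriple]
    threshold: float
    possible_box: dict = field(init=False)
    preferred_box: dict = field(init=False)
    possible_hull: np.ndarray | None = field(init=False)
    preferred_hull: np.ndarray | None = field(init=False)
    empty_preferred: bool = field(init=False)

    def __post_init__(self):
        self.possible_box = _bounding_box(self.possible)
        self.preferred_box = _bounding_box(self.preferred)
        self.possible_hull = _hull_2d(self.possible)
        self.preferred_hull = _hull_2d(self.preferred)
        self.empty_preferred = len(self.preferred) == 0

    def as_dict(self) -> dict:
        return {
            "scene": self.scene,
            "threshold": self.threshold,
            "n_possible": len(self.possible),
            "n_preferred": len(self.preferred),
            "empty_preferred": self.empty_preferred,
            "possible_box": self.possible_box,
            "preferred_box": self.preferred_box,
            "possible": [c.as_dict() for c in self.possible],
            "preferred": [c.as_dict() for c in self.preferred],
        }


@dataclass
class TrendFit:
    """Polynomial trend of a contrast dimension over an ordered predictor."""

    predictor: str
    response: str
    degree: int
    coefficients: np.ndarray  # increasing powers: [intercept, slope, ...]
    slope: float
    slope_se: float
    t_statistic: float
    p_value: float
    r2_adj: float
    n: int

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "response": self.response,
            "degree": self.degree,
            "coefficients": list(map(float, self.coefficients)),
            "slope": self.slope,
            "slope_se": self.slope_se,
            "t": self.t_statistic,
            "p": self.p_value,
            "r2_adj": self.r2_adj,
            "n": self.n,
        }


def _bounding_box(points: list[ContrastTriple]) -> dict:
    if not points:
        return {}
    box = {}
    for dim in ("dJ", "dc", "dh"):
        vals = np.array([getattr(p, dim) for p in points], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            box[dim] = [float(vals.min()), float(vals.max())]
    return box


def _hull_2d(points: list[ContrastTriple]) -> np.ndarray | None:
    if not points:
        return None
    pts = np.array([[p.dJ, p.dc] for p in points], dtype=float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if len(pts) < 3:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None  # degenerate (collinear) point set
    return pts[hull.vertices]


def region_correlates(
    blocks: RegionBlocks | np.ndarray,
    space: str = "IPT",
    vc: ViewingConditions | None = None,
) -> Correlates:
    """Aggregate per-block correlates of one scene region.

    Region J and c are block means.  Region hue is the angle of the mean
    opponent vector (mean of c*cos h, c*sin h), respecting circularity;
    a region whose mean opponent vector vanishes is achromatic.
    """
    xyz = blocks.xyz if isinstance(blocks, RegionBlocks) else np.asarray(blocks, dtype=float)
    if xyz.ndim == 1:
        xyz = xyz[None, :]
    if len(xyz) == 0:
        raise ValueError("region is empty: correlates are undefined")
    if space.upper() == "IPT":
        per_block = ipt_correlates(xyz_to_ipt(xyz))
    elif space.upper() == "CAM16":
        per_block = cam16_from_xyz_rel(xyz, vc)
    else:
        raise ValueError(f"unknown appearance space {space!r}")
    J = float(np.mean(per_block.J))
    c = float(np.mean(per_block.c))
    # Mean opponent vector on the chroma/hue plane.
    a = np.mean(per_block.c * np.cos(np.radians(per_block.h)))
    b = np.mean(per_block.c * np.sin(np.radians(per_block.h)))
    if np.hypot(a, b) < 1e-9:
        h, achromatic = 0.0, True
    else:
        h, achromatic = float(np.degrees(np.arctan2(b, a)) % 360.0), False
    return Correlates(
        space=space.upper(),
        J=np.asarray(J),
        c=np.asarray(c),
        h=np.asarray(h),
        achromatic=np.asarray(achromatic),
    )


def _contrast_value(v_sc: float, v_il: float) -> float:
    num = abs(v_sc) - abs(v_il)
    den = abs(v_sc) + abs(v_il)
    if den == 0.0:
        warnings.warn(
            "contrast undefined: both regions are zero in this dimension",
            RuntimeWarning,
            stacklevel=3,
        )
        return float("nan")
    # Mathematically in [-100, 100]; clip floating-point spill at the ends.
    return float(np.clip(100.0 * num / den, -100.0, 100.0))


def scene_contrast(
    sc: Correlates,
    il: Correlates,
    scene: str = "",
    setting: str = "",
    level: int | None = None,
) -> ContrastTriple:
    """Percentage contrast triple between external (sc) and internal (il).

    Antisymmetric under swapping the regions; each value lies in
    [-100, 100].  The hue contrast is NaN if either region is
    achromatic (hue undefined there).
    """
    if sc.space != il.space:
        raise ValueError(
            f"appearance spaces differ: {sc.space!r} vs {il.space!r}"
        )
    dJ = _contrast_value(float(sc.J), float(il.J))
    dc = _contrast_value(float(sc.c), float(il.c))
    if bool(np.any(sc.achromatic)) or bool(np.any(il.achromatic)):
        dh = float("nan")
    else:
        dh = _contrast_value(float(sc.h), float(il.h))
    return ContrastTriple(
        dJ=dJ, dc=dc, dh=dh, space=sc.space, scene=scene, setting=setting, level=level
    )


def per_block_contrast(
    sc_blocks: Correlates, il_blocks: Correlates
) -> np.ndarray:
    """Sensitivity variant: contrasts of every external/internal block pair.

    Returns an (n_sc * n_il, 3) array of (dJ, dc, dh) for all pairs of
    per-block correlates; intended for exploring how much the
    region-then-contrast aggregation hides.
    """
    if sc_blocks.space != il_blocks.space:
        raise ValueError("appearance spaces differ")
    out = []
    sc_J, sc_c, sc_h = map(np.atleast_1d, (sc_blocks.J, sc_blocks.c, sc_blocks.h))
    il_J, il_c, il_h = map(np.atleast_1d, (il_blocks.J, il_blocks.c, il_blocks.h))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(len(sc_J)):
            for j in range(len(il_J)):
                out.append(
                    [
                        _contrast_value(sc_J[i], il_J[j]),
                        _contrast_value(sc_c[i], il_c[j]),
                        _contrast_value(sc_h[i], il_h[j]),
                    ]
                )
    return np.asarray(out)


def working_area(
    contrasts: list[ContrastTriple],
    ratings: dict[str, float],
    threshold: float = 5.0,
    scene: str = "",
) -> WorkingArea:
    """Possible and preferred contrast areas for one scene.

    ``ratings`` maps setting labels to mean preference ratings on the
    7-point scale (7 = excellent ... 1 = very bad); the default
    threshold 5 corresponds to the scale point labeled "good".  An empty
    preferred set is flagged, not an error.
    """
    if not contrasts:
        raise ValueError("working area needs at least one contrast point")
    missing = [c.setting for c in contrasts if c.setting not in ratings]
    if missing:
        raise KeyError(f"no rating for settings: {sorted(set(missing))}")
    preferred = [c for c in contrasts if ratings[c.setting] >= threshold]
    return WorkingArea(
        scene=scene or contrasts[0].scene,
        possible=list(contrasts),
        preferred=preferred,
        threshold=threshold,
    )


def fit_contrast_trend(
    x, y, degree: int = 1, predictor: str = "scene_order", response: str = "contrast"
) -> TrendFit:
    """Least-squares polynomial trend with a slope t-test.

    Fits y on [1, x, ..., x^degree]; reports the linear coefficient, its
    standard error, the two-sided t-test of slope = 0, and adjusted R^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree < 1:
        raise ValueError("polynomial degree must be >= 1")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < degree + 2:
        raise ValueError(
            f"need at least degree + 2 = {degree + 2} points, got {len(x)}"
        )
    X = np.vander(x, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < degree + 1:
        raise ValueError("rank-deficient design: predictor values do not span the polynomial")
    fit = sm.OLS(y, X).fit()
    return TrendFit(
        predictor=predictor,
        response=response,
        degree=degree,
        coefficients=np.asarray(fit.params),
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        t_statistic=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        r2_adj=float(fit.rsquared_adj),
        n=int(len(x)),
    )


def correlate_spaces(a, b, circular: bool = False):
    """OLS of CAM16 correlates (b) on IPT correlates (a), one dimension.

    With ``circular=True`` (hue), pairs straddling the 0/360 wrap
    (|a - b| > 180) are excluded and counted.  Returns a dict with
    slope, intercept, r2_adj, p, n and n_excluded.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n_excluded = 0
    if circular:
        straddle = np.abs(a - b) > 180.0
        n_excluded = int(straddle.sum())
        a, b = a[~straddle], b[~straddle]
    if len(a) < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(a) == 0:
        raise ValueError("zero variance in predictor")
    X = sm.add_constant(a)
    fit = sm.OLS(b, X).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r2_adj": float(fit.rsquared_adj),
        "p": float(fit.pvalues[1]),
        "n": int(len(a)),
        "n_excluded": n_excluded,
    }
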