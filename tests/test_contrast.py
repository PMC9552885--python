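"""Contrast statistic, working areas, trend fits, space correlation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cabinlight import (
    ContrastTriple,
    Correlates,
    correlate_spaces,
    decompose_blocks,
    fit_contrast_trend,
    per_block_contrast,
    region_correlates,
    scene_contrast,
    working_area,
)
from cabinlight.color import srgb8_to_linear, linear_rgb_to_xyz
from cabinlight.scene import RegionBlocks
from cabinlight.color import xyz_to_lms_ipt

from oracles import ols_oracle


def _corr(J, c, h, space="IPT"):
    return Correlates(space=space, J=np.asarray(float(J)), c=np.asarray(float(c)),
                      h=np.asarray(float(h)))


def _region(xyz_rows):
    xyz = np.atleast_2d(np.asarray(xyz_rows, dtype=float))
    return RegionBlocks(lms=xyz_to_lms_ipt(xyz), xyz=xyz, label="test")


class TestRegionCorrelates:
    def test_single_block_is_its_own_correlates(self):
        from cabinlight import ipt_correlates, xyz_to_ipt

        xyz = np.array([0.3, 0.35, 0.2])
        reg = region_correlates(_region([xyz]), "IPT")
        ref = ipt_correlates(xyz_to_ipt(xyz))
        assert np.isclose(float(reg.J), float(ref.J))
        assert np.isclose(float(reg.c), float(ref.c))
        assert np.isclose(float(reg.h), float(ref.h))

    def test_circular_hue_mean_symmetry(self, monkeypatch):
        # Two blocks with equal chroma at 10 and 350 degrees -> region hue 0.
        import cabinlight.contrast as mod

        fake = Correlates(space="IPT", J=np.array([50.0, 50.0]),
                          c=np.array([20.0, 20.0]), h=np.array([10.0, 350.0]))
        monkeypatch.setattr(mod, "ipt_correlates", lambda ipt: fake)
        reg = region_correlates(_region([[0.3, 0.3, 0.3], [0.4, 0.4, 0.4]]), "IPT")
        circ_dist = min(float(reg.h), 360.0 - float(reg.h))
        assert circ_dist < 1e-9

    def test_matches_pixel_level_recomputation(self, rng):
        # Aggregated region correlates equal a brute-force recomputation
        # from the raw pixels of the union of blocks.
        pix = rng.integers(0, 256, (32, 64, 3), dtype=np.uint8)
        grid = decompose_blocks(pix, 16)
        region = RegionBlocks(
            lms=grid.lms.reshape(-1, 3), xyz=grid.xyz.reshape(-1, 3), label="all"
        )
        reg = region_correlates(region, "IPT")

        from cabinlight import ipt_correlates, xyz_to_ipt

        Js, cs, hs = [], [], []
        for r in range(2):
            for c_ in range(4):
                block = pix[r * 16 : (r + 1) * 16, c_ * 16 : (c_ + 1) * 16]
                mean_xyz = linear_rgb_to_xyz(srgb8_to_linear(block).mean(axis=(0, 1)))
                cr = ipt_correlates(xyz_to_ipt(mean_xyz))
                Js.append(float(cr.J)), cs.append(float(cr.c)), hs.append(float(cr.h))
        assert np.isclose(float(reg.J), np.mean(Js), atol=1e-9)
        assert np.isclose(float(reg.c), np.mean(cs), atol=1e-9)
        a = np.mean(np.array(cs) * np.cos(np.radians(hs)))
        b = np.mean(np.array(cs) * np.sin(np.radians(hs)))
        assert np.isclose(float(reg.h), np.degrees(np.arctan2(b, a)) % 360, atol=1e-9)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            region_correlates(np.empty((0, 3)), "IPT")


class TestSceneContrast:
    def test_equal_regions_zero(self):
        tri = scene_contrast(_corr(50, 20, 90), _corr(50, 20, 90))
        assert tri.dJ == tri.dc == tri.dh == 0.0

    def test_one_sided_limit(self):
        tri = scene_contrast(_corr(50, 20, 90), _corr(0, 0, 0))
        assert tri.dJ == 100.0 and tri.dc == 100.0

    def test_direct_arithmetic(self):
        tri = scene_contrast(_corr(10, 1, 1), _corr(30, 1, 1))
        assert np.isclose(tri.dJ, -50.0)

    def test_space_mismatch_rejected(self):
        with pytest.raises(ValueError, match="space"):
            scene_contrast(_corr(1, 1, 1, "IPT"), _corr(1, 1, 1, "CAM16"))

    def test_achromatic_region_gives_nan_hue(self):
        tri = scene_contrast(_corr(50, 0, 0), _corr(40, 10, 30))
        assert np.isnan(tri.dh) and np.isfinite(tri.dJ)

    def test_zero_over_zero_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            tri = scene_contrast(_corr(0, 10, 20), _corr(0, 10, 20))
        assert np.isnan(tri.dJ)

    @given(
        a=st.floats(0.0, 100.0), b=st.floats(0.0, 100.0),
        c=st.floats(0.1, 100.0), d=st.floats(0.1, 100.0),
    )
    def test_antisymmetry_and_bounds(self, a, b, c, d):
        x, y = _corr(a, c, 10), _corr(b, d, 20)
        f, r = scene_contrast(x, y), scene_contrast(y, x)
        for dim in ("dJ", "dc", "dh"):
            vf, vr = getattr(f, dim), getattr(r, dim)
            if np.isnan(vf):
                assert np.isnan(vr)
                continue
            assert np.isclose(vf, -vr, atol=1e-9)
            assert -100.0 <= vf <= 100.0

    def test_dj_strictly_decreasing_in_internal_lightness(self):
        sc = _corr(60, 10, 0)
        vals = [scene_contrast(sc, _corr(j, 10, 0)).dJ for j in np.linspace(5, 95, 10)]
        assert np.all(np.diff(vals) < 0)

    def test_per_block_variant_shape(self):
        sc = Correlates(space="IPT", J=np.array([10.0, 20.0]), c=np.array([1.0, 2.0]),
                        h=np.array([5.0, 10.0]))
        il = Correlates(space="IPT", J=np.array([30.0, 40.0, 50.0]),
                        c=np.array([3.0, 4.0, 5.0]), h=np.array([15.0, 20.0, 25.0]))
        out = per_block_contrast(sc, il)
        assert out.shape == (6, 3)
        assert np.all(out >= -100 - 1e-9) and np.all(out <= 100 + 1e-9)


def _triples(vals, setting_prefix="S"):
    return [
        ContrastTriple(dJ=v[0], dc=v[1], dh=v[2], space="IPT",
                       setting=f"{setting_prefix}{i}")
        for i, v in enumerate(vals)
    ]


class TestWorkingArea:
    def test_single_point_degenerate_box(self):
        tris = _triples([(10.0, -5.0, 2.0)])
        wa = working_area(tris, {"S0": 6.0}, threshold=5.0)
        assert wa.possible_box["dJ"] == [10.0, 10.0]
        assert len(wa.preferred) == 1

    def test_threshold_filters_preferred(self):
        tris = _triples([(10, 0, 0), (-20, 5, 1)])
        wa = working_area(tris, {"S0": 6.0, "S1": 3.0}, threshold=5.0)
        assert len(wa.possible) == 2 and len(wa.preferred) == 1
        assert wa.preferred[0].setting == "S0"

    def test_empty_preferred_flagged_not_raised(self):
        tris = _triples([(10, 0, 0), (-20, 5, 1)])
        wa = working_area(tris, {"S0": 2.0, "S1": 3.0})
        assert wa.empty_preferred and wa.preferred_box == {}

    def test_preferred_hull_inside_possible_hull(self, rng):
        vals = rng.uniform(-80, 80, size=(30, 3))
        tris = _triples(vals.tolist())
        ratings = {t.setting: float(rng.uniform(1, 7)) for t in tris}
        wa = working_area(tris, ratings, threshold=4.0)
        # Preferred points are a subset, so their box nests inside.
        for dim in wa.preferred_box:
            lo, hi = wa.preferred_box[dim]
            assert wa.possible_box[dim][0] <= lo and hi <= wa.possible_box[dim][1]
        if wa.possible_hull is not None and wa.preferred_hull is not None:
            from scipy.spatial import ConvexHull

            area = lambda pts: ConvexHull(pts).volume if len(pts) >= 3 else 0.0
            assert area(wa.possible_hull) >= area(wa.preferred_hull) - 1e-9

    def test_missing_rating_rejected(self):
        with pytest.raises(KeyError):
            working_area(_triples([(1, 1, 1)]), {})


class TestTrendFit:
    def test_exact_line_recovered(self):
        x = np.arange(6, dtype=float)
        fit = fit_contrast_trend(x, 2.0 * x + 1.0)
        assert np.isclose(fit.slope, 2.0) and np.isclose(fit.coefficients[0], 1.0)
        assert fit.r2_adj > 0.999999

    def test_null_slope_rejection_rate_near_alpha(self, rng):
        hits = 0
        for _ in range(200):
            x = rng.uniform(0, 3, size=50)
            y = 5.0 + rng.normal(0, 1, size=50)  # true slope 0
            if fit_contrast_trend(x, y).p_value < 0.05:
                hits += 1
        assert 0.01 <= hits / 200 <= 0.10

    def test_quick_ci_coverage(self, rng):
        # A fuller 500-replicate calibration runs in the acceptance suite.
        from scipy.stats import t as tdist

        true = -26.5
        cover = 0
        for _ in range(60):
            x = rng.uniform(0, 3, size=20)
            y = 5.0 + true * x + rng.normal(0, 5, size=20)
            fit = fit_contrast_trend(x, y)
            half = tdist.ppf(0.975, fit.n - 2) * fit.slope_se
            cover += fit.slope - half <= true <= fit.slope + half
        assert cover / 60 >= 0.85

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            fit_contrast_trend([0.0, 1.0], [1.0, 2.0], degree=1)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_contrast_trend([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])


class TestCorrelateSpaces:
    def test_identity_and_scaling(self):
        a = np.array([10.0, 20.0, 30.0, 40.0])
        res = correlate_spaces(a, a)
        assert np.isclose(res["slope"], 1.0) and np.isclose(res["r2_adj"], 1.0)
        res = correlate_spaces(a, 0.9 * a)
        assert np.isclose(res["slope"], 0.90) and np.isclose(res["r2_adj"], 1.0)

    def test_matches_normal_equations_oracle(self, rng):
        a = rng.uniform(0, 100, size=40)
        b = 0.8 * a + rng.normal(0, 5, size=40)
        res = correlate_spaces(a, b)
        slope, intercept = ols_oracle(a, b)
        assert np.isclose(res["slope"], slope, atol=1e-10)
        assert np.isclose(res["intercept"], intercept, atol=1e-10)

    def test_hue_wrap_pairs_excluded_and_counted(self):
        a = np.array([350.0, 355.0, 10.0, 20.0, 30.0, 40.0])
        b = np.array([5.0, 8.0, 12.0, 22.0, 28.0, 41.0])  # first two straddle
        res = correlate_spaces(a, b, circular=True)
        assert res["n_excluded"] == 2 and res["n"] == 4

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_spaces(np.ones(5), np.arange(5.0))
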