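"""Rank statistics: Wilcoxon, Cohen's r, Bray-Curtis, nMDS, PCoA scree."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from cabinlight import (
    DissimilarityMatrix,
    bray_curtis,
    cohens_r,
    effect_label,
    exact_signed_rank_p,
    kruskal_stress,
    mean_difference_matrix,
    nmds,
    pcoa_scree,
    rating_profiles,
    wilcoxon_signed_rank,
)

from oracles import wilcoxon_exact_oracle


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank(a, a)

    def test_six_unit_shifts_exact_p(self):
        a = np.arange(6.0)
        res = wilcoxon_signed_rank(a, a + 1.0, method="exact")
        assert np.isclose(res.p, 2 / 64)
        assert res.method == "exact" and res.n_used == 6

    def test_small_n_falls_back_to_exact(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = wilcoxon_signed_rank(a, a + np.array([1.0, 2.0, 1.0, 3.0]))
        assert res.method == "exact"
        assert np.isclose(res.p, wilcoxon_exact_oracle(a, a + np.array([1.0, 2.0, 1.0, 3.0])))

    def test_zero_differences_dropped(self):
        a = np.array([3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        b = a.copy()
        b[:5] += np.array([1.0, 2.0, 1.5, 0.5, 3.0])
        res = wilcoxon_signed_rank(a, b)
        assert res.n_total == 7 and res.n_used == 5

    def test_asymptotic_close_to_enumeration(self, rng):
        # The normal approximation tracks the exact conditional test at
        # n = 8-12 with deviations of a few percent (tied ordinal data);
        # a fuller 200-dataset calibration runs in the acceptance suite.
        devs = []
        while len(devs) < 30:
            n = int(rng.integers(8, 13))
            a = rng.integers(0, 11, n).astype(float)
            b = rng.integers(0, 11, n).astype(float)
            if np.count_nonzero(a - b) < 8:
                continue
            res = wilcoxon_signed_rank(a, b, method="approx")
            devs.append(abs(res.p - wilcoxon_exact_oracle(a, b)))
        assert float(np.median(devs)) < 0.04
        assert max(devs) < 0.12

    def test_rank_statistic_scale_free(self, rng):
        a = rng.integers(0, 11, 20).astype(float)
        b = rng.integers(0, 11, 20).astype(float)
        r1 = wilcoxon_signed_rank(a, b)
        r2 = wilcoxon_signed_rank(3.0 * a, 3.0 * b)
        assert np.isclose(r1.z, r2.z) and np.isclose(r1.r, r2.r)

    def test_exact_helper_rejects_degenerate(self):
        with pytest.raises(ValueError):
            exact_signed_rank_p([0.0, 0.0])


class TestCohensR:
    def test_zero_effect(self):
        r, label = cohens_r(0.0, 10)
        assert r == 0.0 and label == "below-weak"

    @pytest.mark.parametrize(
        "z, n, r3, label",
        [(3.497, 148, 0.287, "medium"), (8.352, 148, 0.687, "strong")],
    )
    def test_printed_effect_sizes(self, z, n, r3, label):
        r, lab = cohens_r(z, n)
        assert round(r, 3) == r3 and lab == label

    def test_label_thresholds_inclusive(self):
        assert effect_label(0.10) == "weak"
        assert effect_label(0.25) == "medium"
        assert effect_label(0.40) == "strong"
        assert effect_label(0.0999) == "below-weak"

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            cohens_r(1.0, 0)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis([[1, 2, 3], [1, 2, 3]])
        assert d.values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis([[1, 0, 2], [0, 3, 0]])
        assert np.isclose(d.values[0, 1], 1.0)

    def test_formula_example(self):
        d = bray_curtis([[1, 2, 3], [2, 2, 4]])
        assert np.isclose(d.values[0, 1], 2 / 14)

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="nonnegative"):
            bray_curtis([[1, -1], [1, 1]])
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis([[0, 0], [1, 1]])

    def test_properties_on_random_profiles(self, rng):
        for _ in range(20):
            prof = rng.uniform(0.1, 10, size=(6, 9))
            d = bray_curtis(prof).values
            assert np.allclose(d, d.T)
            assert np.all(np.diag(d) == 0)
            assert np.all((d >= 0) & (d <= 1))

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(np.array([[0.0, 1.0], [0.5, 0.0]]), ["a", "b"], "x")

    def test_profile_constructions(self):
        import pandas as pd

        items = ["L1", "L2", "L3"]
        means = pd.Series({("L1", "L2"): 4.0, ("L1", "L3"): 6.0, ("L2", "L3"): 2.0})
        prof = rating_profiles(means, items)
        assert prof[0, 1] == 4.0 and prof[1, 0] == 4.0 and prof[0, 0] == 0.0
        md = mean_difference_matrix(means, items)
        assert md.values[0, 2] == 0.6 and md.method == "mean_difference"


class TestNMDS:
    def test_collinear_points_embed_in_1d_with_zero_stress(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        d = np.abs(x[:, None] - x[None, :])
        res = nmds(d, k=1, seed=11, restarts=10)
        assert res.stress < 1e-6

    def test_3d_construction_reaches_low_stress(self, rng):
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        res = nmds(d, k=3, seed=5, restarts=20)
        assert res.stress < 0.01

    def test_stress_non_increasing_in_k(self, rng):
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        stresses = [nmds(d, k=k, seed=3, restarts=10).stress for k in (1, 2, 3)]
        # Nesting holds up to the optimizer's convergence tolerance: the
        # per-k runs are independent best-of-restarts optimizations.
        assert stresses[0] >= stresses[1] - 5e-3
        assert stresses[1] >= stresses[2] - 5e-3

    def test_deterministic_under_seed(self, rng):
        pts = rng.normal(size=(7, 2))
        d = squareform(pdist(pts))
        r1 = nmds(d, k=2, seed=42, restarts=5)
        r2 = nmds(d, k=2, seed=42, restarts=5)
        assert r1.stress == r2.stress
        assert np.array_equal(r1.coords, r2.coords)

    def test_stress_invariant_under_configuration_rotation(self, rng):
        pts = rng.normal(size=(8, 2))
        d = squareform(pdist(pts))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        assert np.isclose(kruskal_stress(pts, d), kruskal_stress(pts @ R, d), atol=1e-12)

    def test_agrees_with_sklearn_smacof(self, rng):
        """Best-of-restarts stress matches sklearn's independent SMACOF
        (scored by the same stress-1) within optimization tolerance."""
        from sklearn.manifold import smacof as sk_smacof

        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        for k in (2, 3):
            mine = nmds(d, k=k, seed=9, restarts=10).stress
            best_ref = min(
                kruskal_stress(
                    sk_smacof(d, metric=False, n_components=k, n_init=1,
                              random_state=100 + i, normalized_stress=True,
                              max_iter=500, eps=1e-9)[0],
                    d,
                )
                for i in range(10)
            )
            assert abs(mine - best_ref) < 5e-3

    def test_k_out_of_range_rejected(self, rng):
        d = squareform(pdist(rng.normal(size=(5, 2))))
        for bad in (0, 5):
            with pytest.raises(ValueError):
                nmds(d, k=bad, seed=0)


class TestPCoAScree:
    def test_exact_2d_configuration(self, rng):
        pts = rng.normal(size=(10, 2))
        fr, eig, neg = pcoa_scree(squareform(pdist(pts)))
        assert len(fr) == 2 and np.isclose(fr.sum(), 1.0)
        assert neg.size == 0

    def test_1d_configuration_single_positive_eigenvalue(self):
        x = np.array([0.0, 1.0, 2.5, 4.0])
        fr, eig, neg = pcoa_scree(np.abs(x[:, None] - x[None, :]))
        assert len(fr) == 1 and np.isclose(fr[0], 1.0)

    def test_matches_skbio_oracle_on_bray_curtis(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix

        prof = rng.uniform(0.1, 10, size=(7, 5))
        d = bray_curtis(prof)
        fr, eig, neg = pcoa_scree(d)
        ref = skbio_pcoa(DistanceMatrix(d.values), method="eigh")
        ref_pos = np.sort(ref.eigvals[ref.eigvals > 1e-12].to_numpy())[::-1]
        got_pos = eig[eig > 1e-12]
        assert np.allclose(got_pos, ref_pos, atol=1e-8)
        assert np.isclose(fr.sum(), 1.0)
        # Non-Euclidean input: negative eigenvalues are reported rather
        # than clamped to zero (as the reference implementation does).
        assert neg.size == (eig < -1e-12).sum()
        assert neg.size >= 1
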