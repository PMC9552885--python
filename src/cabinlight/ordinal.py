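"""Ordinal rating statistics: signed-rank tests, dissimilarities, ordination.

The rating track works entirely on ordinal data: paired-comparison
difference scores (0-10), 7-point preference ratings, and semantic
differentials (-3..+3).  Accordingly the tools here are rank-based:

* Wilcoxon signed-rank for dependent samples with an asymptotic normal
  p (tie-corrected, no continuity correction) and an exact-enumeration
  fallback for small samples;
* Cohen's r = |z| / sqrt(n) with the conventional semantic labels
  (weak >= 0.10, medium >= 0.25, strong >= 0.40);
* Bray-Curtis dissimilarities (bounded in [0, 1], rank-robust, no
  absolute zero required);
* non-metric MDS (SMACOF majorization with isotonic regression) scored
  by Kruskal stress-1, best of seeded restarts;
* classical-scaling (PCoA) scree fractions as a reference for choosing
  the embedding dimension.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, wilcoxon as _scipy_wilcoxon

__all__ = [
    "WilcoxonResult",
    "DissimilarityMatrix",
    "NMDSResult",
    "wilcoxon_signed_rank",
    "exact_signed_rank_p",
    "cohens_r",
    "effect_label",
    "bray_curtis",
    "mean_difference_matrix",
    "rating_profiles",
    "kruskal_stress",
    "nmds",
    "pcoa_scree",
]


@dataclass
class WilcoxonResult:
    z: float
    p: float
    n_total: int
    n_used: int
    r: float
    label: str
    method: str  # "approx" or "exact"

    def as_dict(self) -> dict:
        return {
            "z": self.z,
            "p": self.p,
            "n_total": self.n_total,
            "n_used": self.n_used,
            "r": self.r,
            "effect": self.label,
            "method": self.method,
        }


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative dissimilarities with a zero diagonal."""

    values: np.ndarray
    labels: list[str]
    method: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("dissimilarities must be nonnegative")
        self.values = v
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count must match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path, method: str = "unknown") -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns), method)


@dataclass
class NMDSResult:
    coords: np.ndarray
    stress: float
    k: int
    seed: int
    restarts: int
    n_iter: int


def exact_signed_rank_p(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Tied absolute differences receive average ranks.  Exponential in the
    number of nonzero differences; intended for small n.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero: test is degenerate")
    if n > 20:
        raise ValueError("exact enumeration limited to n <= 20")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = ranks.sum()
    # Distance of W+ from its null mean, two-sided.
    mu = total / 2.0
    obs_dev = abs(w_plus - mu)
    count = 0
    for signs in range(1 << n):
        w = 0.0
        for i in range(n):
            if signs >> i & 1:
                w += ranks[i]
        if abs(w - mu) >= obs_dev - 1e-12:
            count += 1
    return count / (1 << n)


def wilcoxon_signed_rank(a, b, method: str = "auto") -> WilcoxonResult:
    """Wilcoxon signed-rank test for paired ordinal vectors.

    Zero differences are dropped (the classic rule); tied absolute
    differences receive average ranks.  The asymptotic path computes z
    from the normal approximation with tie-corrected variance and no
    continuity correction, p = 2(1 - Phi(|z|)).  ``method`` "auto"
    routes to exact enumeration when fewer than 5 nonzero differences
    remain; "exact" forces enumeration; "approx" forces the normal
    approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    d = a - b
    n_total = len(d)
    d_nz = d[d != 0]
    n_used = len(d_nz)
    if n_used == 0:
        raise ValueError("all differences are zero: test is degenerate")

    # Signed z from the tie-corrected normal approximation (also reported
    # alongside the exact p, for the effect size).
    res = _scipy_wilcoxon(
        a, b, zero_method="wilcox", correction=False, method="approx"
    )
    z = float(res.zstatistic)

    if method == "exact" or (method == "auto" and n_used < 5):
        p = exact_signed_rank_p(d)
        used_method = "exact"
    elif method in ("auto", "approx"):
        p = float(res.pvalue)
        used_method = "approx"
    else:
        raise ValueError(f"unknown method {method!r}")

    r, label = cohens_r(z, n_used)
    return WilcoxonResult(
        z=z, p=p, n_total=n_total, n_used=n_used, r=r, label=label, method=used_method
    )


def effect_label(r: float) -> str:
    if r >= 0.40:
        return "strong"
    if r >= 0.25:
        return "medium"
    if r >= 0.10:
        return "weak"
    return "below-weak"


def cohens_r(z: float, n_used: int):
    """Effect size r = |z| / sqrt(n) with its semantic label."""
    if n_used <= 0:
        raise ValueError("n_used must be positive")
    r = abs(z) / np.sqrt(n_used)
    return float(r), effect_label(r)


def bray_curtis(profiles, labels: list[str] | None = None) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarities between rows of a nonnegative matrix.

    d(u, v) = sum|u_i - v_i| / sum(u_i + v_i); bounded in [0, 1] with 0
    for identical rows and 1 for disjoint supports.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must be a 2-D items x features matrix")
    if np.any(profiles < 0):
        raise ValueError("Bray-Curtis requires nonnegative entries")
    if np.any(profiles.sum(axis=1) == 0):
        raise ValueError("Bray-Curtis is undefined for all-zero rows")
    d = squareform(pdist(profiles, metric="braycurtis"))
    if labels is None:
        labels = [f"item{i + 1}" for i in range(profiles.shape[0])]
    return DissimilarityMatrix(values=d, labels=list(labels), method="bray_curtis")


def rating_profiles(mean_ratings: pd.Series, items: list[str]) -> np.ndarray:
    """Per-item profiles from paired-comparison mean difference ratings.

    ``mean_ratings`` is indexed by frozenset-like pairs (i, j) of item
    labels; the profile of item i is its vector of mean difference
    ratings against every item (own position 0), so every two profiles
    share an aligned feature space.
    """
    idx = {it: k for k, it in enumerate(items)}
    prof = np.zeros((len(items), len(items)))
    for (i, j), v in mean_ratings.items():
        prof[idx[i], idx[j]] = v
        prof[idx[j], idx[i]] = v
    return prof


def mean_difference_matrix(
    mean_ratings: pd.Series, items: list[str]
) -> DissimilarityMatrix:
    """Direct dissimilarities: mean difference rating of each pair.

    The alternative construction to Bray-Curtis profiles; values are
    normalized to [0, 1] by the scale maximum of 10.
    """
    prof = rating_profiles(mean_ratings, items) / 10.0
    np.fill_diagonal(prof, 0.0)
    return DissimilarityMatrix(values=prof, labels=list(items), method="mean_difference")


def _monotone_disparities(dist: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Monotone (isotonic) regression of distances on dissimilarity ranks."""
    dhat = np.empty_like(dist)
    dhat[order] = isotonic_regression(dist[order], increasing=True).x
    return dhat


def kruskal_stress(coords: np.ndarray, dissim: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against dissimilarities.

    Disparities are the isotonic (monotone nondecreasing) regression of
    the configuration distances on the dissimilarities;
    stress-1 = sqrt(sum (d - dhat)^2 / sum d^2).
    """
    dist = pdist(coords)
    dvec = squareform(np.asarray(dissim, dtype=float), checks=False)
    dhat = _monotone_disparities(dist, np.argsort(dvec, kind="stable"))
    denom = float(np.sum(dist**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def _smacof_single(
    dvec: np.ndarray,
    order: np.ndarray,
    n: int,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    eps: float,
):
    """One SMACOF run: majorization with monotone-regressed disparities.

    Each iteration replaces the dissimilarities by the isotonic
    regression of the current distances on their ranks (rescaled to the
    usual sum-of-squares normalization) and applies the Guttman
    transform.  Returns (coords, stress-1, iterations)."""
    m = len(dvec)
    X = rng.standard_normal((n, k))
    iu = np.triu_indices(n, 1)
    old = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        dist = pdist(X)
        dhat = _monotone_disparities(dist, order)
        norm = np.sqrt((dhat**2).sum())
        if norm == 0:
            break
        dhat = dhat * np.sqrt(m) / norm
        # Guttman transform with unit weights.
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        B = np.zeros((n, n))
        B[iu] = -ratio
        B.T[iu] = -ratio
        B[np.diag_indices(n)] = -B.sum(axis=1)
        X = B @ X / n
        denom = (dist**2).sum()
        stress = np.sqrt(((dist - dhat) ** 2).sum() / denom) if denom > 0 else 0.0
        if old - stress < eps:
            break
        old = stress
    return X, it


def nmds(
    d: DissimilarityMatrix | np.ndarray,
    k: int,
    seed: int,
    restarts: int = 20,
    max_iter: int = 500,
    eps: float = 1e-9,
) -> NMDSResult:
    """Non-metric MDS by SMACOF majorization with monotone regression.

    Runs ``restarts`` seeded random initializations and keeps the
    configuration with the lowest Kruskal stress-1 (recomputed from the
    final coordinates, so the reported stress does not depend on the
    optimizer's internal normalization).  Deterministic given ``seed``.
    Stress is non-increasing in k up to the convergence tolerance of
    the independent per-k optimizations.
    """
    values = d.values if isinstance(d, DissimilarityMatrix) else np.asarray(d, dtype=float)
    n = values.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"embedding dimension k={k} must lie in [1, {n - 1}]")
    dvec = squareform(values, checks=False)
    order = np.argsort(dvec, kind="stable")
    best = None
    rng = np.random.default_rng(np.random.SeedSequence([seed, k, 71]))
    for _ in range(restarts):
        coords, n_iter = _smacof_single(dvec, order, n, k, rng, max_iter, eps)
        stress = kruskal_stress(coords, values)
        if best is None or stress < best[0]:
            best = (stress, coords, n_iter)
    stress, coords, n_iter = best
    return NMDSResult(
        coords=coords, stress=stress, k=k, seed=seed, restarts=restarts, n_iter=int(n_iter)
    )


def pcoa_scree(d: DissimilarityMatrix | np.ndarray):
    """Classical-scaling (PCoA) variance fractions per component.

    Double-centers -0.5 * d^2 and eigendecomposes; fractions are the
    positive eigenvalues divided by their sum.  Negative eigenvalues
    (possible for non-Euclidean dissimilarities such as Bray-Curtis)
    are returned separately.
    """
    values = d.values if isinstance(d, DissimilarityMatrix) else np.asarray(d, dtype=float)
    n = values.shape[0]
    A = -0.5 * values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals = np.linalg.eigvalsh((B + B.T) / 2.0)[::-1]
    pos = eigvals[eigvals > 1e-12]
    neg = eigvals[eigvals < -1e-12]
    fractions = pos / pos.sum() if pos.size else np.array([])
    return fractions, eigvals, neg


def wilcoxon_pair_table(
    ratings: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """All-pairs Wilcoxon table over the columns of a rating matrix.

    ``ratings`` is subjects x items; each row of the output compares two
    item columns as dependent samples.  Degenerate pairs (all
    differences zero) are reported with NaN statistics.
    """
    rows = []
    for i, j in combinations(ratings.columns, 2):
        try:
            res = wilcoxon_signed_rank(ratings[i].to_numpy(), ratings[j].to_numpy())
            rows.append(
                {
                    "item_a": i,
                    "item_b": j,
                    **res.as_dict(),
                    "significant": res.p < alpha,
                }
            )
        except ValueError:
            rows.append(
                {
                    "item_a": i,
                    "item_b": j,
                    "z": np.nan,
                    "p": np.nan,
                    "n_total": len(ratings),
                    "n_used": 0,
                    "r": np.nan,
                    "effect": "degenerate",
                    "method": "none",
                    "significant": False,
                }
            )
    return pd.DataFrame(rows)
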