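"""Ordinal similarity track: paired comparisons -> Wilcoxon -> nMDS -> scree.

Generates a subjects x pairs table of 0-10 difference ratings for 8
luminaire settings from a known 3-D latent configuration, then runs the
similarity pipeline: a Wilcoxon signed-rank table against the
largest-difference reference pair, Bray-Curtis dissimilarities between
settings, non-metric MDS for k = 1..4, and PCoA scree fractions.
"""

import tempfile
from pathlib import Path

from cabinlight import (
    LatentRatingSpec,
    RunConfig,
    gen_paired_ratings,
    run_similarity_pipeline,
)

ratings, true_d, latent = gen_paired_ratings(
    LatentRatingSpec(n_items=8, k_true=3, n_subjects=148, noise=1.0, seed=3)
)
ratings.columns = ["|".join(c) for c in ratings.columns]

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig(out_dir=str(Path(tmp) / "run"), seed=3, k_max=4, restarts=20)
    report = run_similarity_pipeline(cfg, ratings)

wil = report["wilcoxon"]
print(f"{len(wil)} paired comparisons; reference pair: {wil['reference'].iloc[0]}")
sig = wil[wil["significant"]]
print(f"{len(sig)} pairs differ from the reference at alpha = 0.05; e.g.:")
row = sig.iloc[0]
print(f"  {row['pair']}: z = {row['z']:.3f}, p = {row['p']:.3g}, "
      f"r = {row['r']:.3f} ({row['effect']})")

print("\nnMDS stress by embedding dimension:")
for res in report["nmds"]:
    print(f"  k = {res['k']}: stress-1 = {res['stress']:.4f}")

fr = report["scree"]["fractions"]
print(f"\nscree: first three components explain {100 * sum(fr[:3]):.0f}% "
      "of the dissimilarity variance")
print()
print("Stress drops to (near) zero at the latent dimensionality k = 3,")
print("matching the scree elbow: three dimensions describe the settings.")
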