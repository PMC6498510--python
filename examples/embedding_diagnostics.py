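"""How faithful is a conventional MDS plot?  Stress and Shepard diagnostics.

Embeds a clustered score matrix with Kruskal nonmetric MDS, then quantifies
the distortion: total squared-residual stress, the Shepard pairs (embedded
vs true distance for every point pair), and the per-point distortion that
pinpoints which samples the plot misplaces most.
"""

import numpy as np

from focusmds import (
    kruskal_mds, manhattan_distances, normalized_stress,
    per_point_distortion, shepard, total_stress,
)
from focusmds.synthetic import clustered_features

scores, _ = clustered_features(n_samples=40, n_features=120, n_clusters=3,
                               separation=3.0, seed=1)
dist = manhattan_distances(scores)

res = kruskal_mds(dist)
print(f"Kruskal MDS converged={res.converged} after {res.iterations} iterations; "
      f"nonmetric stress-1 (vs disparities) = {res.stress1:.2e}")

emb = res.embedding
print(f"raw stress  sum (D-d)^2            : {total_stress(dist, emb):.4g}")
print(f"metric stress-1  sqrt(.../sum D^2) : {normalized_stress(dist, emb):.4f}")
print("(nonmetric stress-1 only penalises rank-order violations; the metric")
print(" variant compares distances on their actual scale)")

sh = shepard(dist, emb)
spread = np.abs(sh.D - sh.d)
print(f"\nShepard pairs: {len(sh)}; median |D - d| = {np.median(spread):.1f}, "
      f"worst = {spread.max():.1f}")
print("pairs far off the identity line are where the plot misleads")

per = per_point_distortion(dist, emb).sort_values(ascending=False)
print("\nmost distorted samples (top 3):")
for lab, v in per.head(3).items():
    print(f"  {lab}: {v:.4g}")
print("a high value means that sample's plotted position misstates its true distances")
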