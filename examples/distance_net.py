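"""Spotting dimension-reduction artifacts with a distance-net overlay.

Connects every pair of samples whose *feature-space* distance is at or
below a threshold, drawn over the 2-D layout.  Pairs that sit close on the
plot but carry no edge are exactly the discrepancies the embedding
introduced: plot proximity without true similarity.
"""

import numpy as np

from focusmds import build_distnet, edge_presence, kruskal_mds, manhattan_distances, scale_bounds
from focusmds.synthetic import clustered_features

scores, _ = clustered_features(n_samples=30, n_features=100, n_clusters=3,
                               separation=2.0, seed=5)
dist = manhattan_distances(scores)
layout = kruskal_mds(dist).embedding

lo, hi = scale_bounds(dist)
t = float(np.percentile(dist.condensed(), 25))
graph = build_distnet(dist, layout, threshold=t, softness=0.1 * (hi - lo))
print(f"distance scale [{lo:.0f}, {hi:.0f}]; threshold t = {t:.0f}")
print(f"{graph.n_edges} edges connect truly similar pairs "
      f"(weights fade from 1 to 0 over the softness band)")

# find the worst "close on the plot, far in feature space" pair
D = layout.pairwise_distances()
n = dist.n
worst, pair = -1.0, None
order = np.argsort(D[np.triu_indices(n, 1)])
iu, ju = np.triu_indices(n, 1)
for k in order[: n]:  # the n closest plotted pairs
    i, j = int(iu[k]), int(ju[k])
    if not edge_presence(dist, dist.labels[i], dist.labels[j], t):
        rank = (dist.condensed() < dist.values[i, j]).mean()
        if rank > worst:
            worst, pair = rank, (dist.labels[i], dist.labels[j])
if pair:
    a, b = pair
    print(f"\nexample discrepancy: {a} and {b} are among the closest pairs on the plot,")
    print(f"but their true distance {dist.values[dist.index(a), dist.index(b)]:.0f} "
          f"exceeds the threshold (top {100 * (1 - worst):.0f}% of all pairs)")
    print("no edge connects them: the plot, not the data, put them together")
else:
    print("\nevery close plotted pair is also truly similar at this threshold")
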