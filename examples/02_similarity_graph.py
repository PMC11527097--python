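"""Build a patient-similarity graph and show how K controls its sparsity.

Edges carry cosine similarity between samples' feature vectors; the
threshold epsilon is derived so the average number of retained connections
per node (self-connection included) is the smallest achievable value >= K.
"""

import numpy as np

import sguq

matrices, labels, _ = sguq.generate(sguq.routing_fixture_spec(0, n_samples=80,
                                                              n_features=30))
X = matrices[0]

for K in (1, 2, 5, 10):
    g = sguq.build_graph(X, K)
    avg_edges = (g.adjacency != 0).sum() / g.n + 1  # +1 for the self-connection
    print(f"K={K:2d}: epsilon={g.threshold_epsilon:.4f}  "
          f"avg connections/node (incl. self)={avg_edges:.2f}")

g = sguq.build_graph(X, 2)
row_sums = g.normalized_adjacency.sum(axis=1)
print(f"normalized adjacency: symmetric={np.allclose(g.normalized_adjacency, g.normalized_adjacency.T)}, "
      f"row sums in [{row_sums.min():.3f}, {row_sums.max():.3f}]")
# With K=1 only self-connections survive and the normalized adjacency is the
# identity: the graph convolution then degenerates to a plain dense network.
g1 = sguq.build_graph(X, 1)
print(f"K=1 gives the identity: {np.array_equal(g1.normalized_adjacency, np.eye(g1.n))}")
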