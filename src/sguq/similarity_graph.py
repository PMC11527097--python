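"""Patient-similarity graphs from cosine similarity, with K-controlled sparsity.

Each sample is a node.  Edges carry the cosine similarity of the two samples'
feature vectors and are kept only when the similarity reaches a threshold
``epsilon``.  ``epsilon`` is not set directly: the user chooses ``K``, the
average number of retained connections per node *including* the
self-connection, and ``epsilon`` is derived from the empirical similarity
distribution so the average retained count is the smallest achievable value
>= K.  ``K = 1`` therefore keeps self-connections only and the normalized
adjacency collapses to the identity, which makes the downstream graph
convolution degenerate to an ordinary fully connected network.

The graph convolution consumes the symmetrically normalized adjacency
``A_norm = D^{-1/2} (A + I) D^{-1/2}`` with ``D_ii = sum_j (A + I)_ij``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import ZeroNormSampleError
from .omics_io import OmicsMatrix


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity of two nonzero vectors; symmetric, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ZeroNormSampleError("cosine similarity undefined for a zero-norm vector")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def pairwise_cosine(values: np.ndarray, sample_ids=None) -> np.ndarray:
    """Full n x n cosine-similarity matrix with an exact unit diagonal."""
    values = np.asarray(values, dtype=float)
    norms = np.linalg.norm(values, axis=1)
    zero = np.nonzero(norms == 0.0)[0]
    if zero.size:
        name = sample_ids[zero[0]] if sample_ids is not None else f"index {zero[0]}"
        raise ZeroNormSampleError(f"sample {name} has a zero-norm feature vector")
    unit = values / norms[:, None]
    sims = np.clip(unit @ unit.T, -1.0, 1.0)
    sims = (sims + sims.T) / 2.0
    np.fill_diagonal(sims, 1.0)
    return sims


def epsilon_for_K(similarities: np.ndarray, K: float) -> float:
    """Threshold so the average retained count per node (self included) is the
    smallest achievable value >= K.

    Candidates are the observed similarity values (plus a sentinel above the
    maximum); candidates are scanned from the largest down and the first whose
    average count reaches K wins, so ties at the threshold are all retained.
    Deterministic by construction.
    """
    S = np.asarray(similarities, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of nodes n={n}")
    values = np.unique(S)  # ascending
    sentinel = np.nextafter(values[-1], np.inf)
    candidates = np.concatenate([values, [sentinel]])[::-1]
    flat = np.sort(S, axis=None)
    for eps in candidates:
        # count of entries >= eps via binary search on the sorted flat matrix
        count = flat.size - np.searchsorted(flat, eps, side="left")
        if count / n >= K:
            return float(eps)
    raise AssertionError("unreachable: K <= n guarantees a feasible threshold")


@dataclass
class SimilarityGraph:
    """Thresholded cosine-similarity adjacency and its normalization."""

    modality_name: str
    n: int
    adjacency: np.ndarray
    normalized_adjacency: np.ndarray
    sparsity_K: float
    threshold_epsilon: float
    sample_ids: list[str] | None = None

    _csr_cache: sp.csr_matrix | None = None

    @property
    def normalized_csr(self) -> sp.csr_matrix:
        """Sparse view of the normalized adjacency (cached)."""
        if self._csr_cache is None:
            self._csr_cache = sp.csr_matrix(self.normalized_adjacency)
        return self._csr_cache

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.normalized_adjacency).tobytes())
        return h.hexdigest()


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^{-1/2}(A + I)D^{-1/2}, D = row sums of A + I."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    with_self = A + np.eye(n)
    degrees = with_self.sum(axis=1)
    if (degrees <= 0).any():
        raise ValueError("non-positive node degree; adjacency too negative to normalize")
    inv_sqrt = 1.0 / np.sqrt(degrees)
    return inv_sqrt[:, None] * with_self * inv_sqrt[None, :]


def build_graph(
    X: OmicsMatrix | np.ndarray, K: float, modality_name: str | None = None
) -> SimilarityGraph:
    """Build the sample-similarity graph for one omics matrix.

    ``A_ij = s(x_i, x_j)`` when ``i != j`` and the similarity reaches the
    derived threshold, else 0; the diagonal of ``A`` is zero (self-connections
    enter through the ``+ I`` of the normalization).
    """
    if isinstance(X, OmicsMatrix):
        values, ids = X.values, X.sample_ids
        name = modality_name or X.modality_name
    else:
        values, ids = np.asarray(X, dtype=float), None
        name = modality_name or "unnamed"
    if values.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    n = values.shape[0]
    if n == 1:
        # single node: no off-diagonal candidates; normalized graph is [[1]]
        return SimilarityGraph(name, 1, np.zeros((1, 1)), np.ones((1, 1)), K, 1.0, ids)
    sims = pairwise_cosine(values, ids)
    eps = epsilon_for_K(sims, K)
    A = np.where(sims >= eps, sims, 0.0)
    np.fill_diagonal(A, 0.0)
    return SimilarityGraph(name, n, A, normalize_adjacency(A), float(K), eps, ids)


def export_edge_list(graph: SimilarityGraph, path: str | Path) -> Path:
    """Debug export of A as a (sample_i, sample_j, weight) TSV, i < j."""
    path = Path(path)
    ids = graph.sample_ids or [str(i) for i in range(graph.n)]
    with open(path, "w") as fh:
        fh.write("sample_id_i\tsample_id_j\tweight\n")
        rows, cols = np.nonzero(np.triu(graph.adjacency, k=1))
        for i, j in zip(rows, cols):
            fh.write(f"{ids[i]}\t{ids[j]}\t{graph.adjacency[i, j]:.10g}\n")
    return path
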