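"""Posterior post-processing: theta recovery, topic alignment across label
switching, clustering of topic samples pooled over chains, and collapse of
near-empty topics.

Because theta is integrated out during sampling, it is recovered from the
assignment count tables; because topic labels are arbitrary within and
across chains, topics are matched either greedily against a reference
(simulations, where the truth is known) or by community detection on a
shared-nearest-neighbour graph of all posterior topic vectors (real data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .inference import PosteriorSamples

__all__ = [
    "TopicSet",
    "theta_from_counts",
    "align_topics_greedy",
    "cluster_topics",
    "collapse_near_empty",
]


@dataclass
class TopicSet:
    """Cluster-averaged topics with provenance.

    ``support[c]`` counts the distinct chains whose samples contributed to
    cluster c; ``alpha`` carries the per-cluster average of the aligned
    Dirichlet entries when available.
    """

    topics: np.ndarray                       # (K', S) averaged phi
    support: np.ndarray                      # (K',) chain support
    alpha: np.ndarray | None = None          # (K',) aligned average
    provenance: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.topics.shape[0]


def theta_from_counts(N_row, alpha) -> np.ndarray:
    """Recover topic weights from assignment counts:
    theta_t = (N_t + alpha_t) / (N + sum alpha).  Accepts a single row or a
    (D, K) table; returns simplex vector(s)."""
    N = np.asarray(N_row, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(N < 0) or np.any(alpha <= 0):
        raise ValueError("counts must be non-negative, alpha positive")
    num = N + alpha
    return num / num.sum(axis=-1, keepdims=True)


def _cosine_sim(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity; all-zero vectors get similarity 0."""
    An = np.linalg.norm(A, axis=1, keepdims=True)
    Bn = np.linalg.norm(B, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (A @ B.T) / (An * Bn.T)
    return np.nan_to_num(sim, nan=0.0)


def align_topics_greedy(inferred: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Greedy cosine matching of inferred topics to reference topics.

    Inferred topics are visited in order of their best available cosine
    similarity; each matched reference topic is removed from further
    matching.  Ties break toward the lower reference index.  If the
    reference has fewer rows it is padded with zero topics.  Returns ``perm``
    such that ``inferred[k]`` corresponds to ``reference[perm[k]]``.
    """
    inferred = np.asarray(inferred, dtype=float)
    reference = np.asarray(reference, dtype=float)
    K = inferred.shape[0]
    if reference.shape[0] < K:
        pad = np.zeros((K - reference.shape[0], reference.shape[1]))
        reference = np.vstack([reference, pad])
    sim = _cosine_sim(inferred, reference)
    perm = np.full(K, -1, dtype=int)
    free_inf = set(range(K))
    free_ref = set(range(reference.shape[0]))
    for _ in range(K):
        best = (-np.inf, None, None)
        for i in sorted(free_inf):
            for j in sorted(free_ref):
                if sim[i, j] > best[0]:
                    best = (sim[i, j], i, j)
        _, i, j = best
        perm[i] = j
        free_inf.discard(i)
        free_ref.discard(j)
    return perm


def _snn_graph(X: np.ndarray, k: int, scheme: str = "rank"):
    """Shared-nearest-neighbour graph over rows of X (Euclidean k-NN).

    ``rank`` weights follow the scran convention: for two vertices sharing a
    neighbour, the weight is k - r/2 with r the smallest sum of the
    neighbour's ranks in the two lists (a vertex ranks 0 in its own list);
    ``jaccard`` uses the Jaccard overlap of the two neighbourhoods.
    """
    import igraph
    from sklearn.neighbors import NearestNeighbors

    n = X.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, idx = nn.kneighbors(X)  # idx[:, 0] is the vertex itself
    rank = {}
    for v in range(n):
        for r, u in enumerate(idx[v]):
            rank[(v, u)] = r
    edges, weights = [], []
    neigh = [set(row) for row in idx]
    for v in range(n):
        for u in range(v + 1, n):
            shared = neigh[v] & neigh[u]
            if not shared:
                continue
            if scheme == "rank":
                r = min(rank[(v, s)] + rank[(u, s)] for s in shared)
                w = k - r / 2.0
            elif scheme == "jaccard":
                w = len(shared) / len(neigh[v] | neigh[u])
            else:
                raise ValueError(f"unknown SNN scheme: {scheme!r}")
            if w > 0:
                edges.append((v, u))
                weights.append(float(w))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_topics(samples: PosteriorSamples, k_snn: int | None = None,
                   scheme: str = "rank", resolution: float = 1.0,
                   seed: int = 0) -> TopicSet:
    """Cluster all posterior topic vectors pooled over chains and average
    within clusters.

    A shared-nearest-neighbour graph with k = (n_chains * n_samples_per_chain)
    / 2 is partitioned with the Louvain algorithm; this k is small enough
    (each true topic contributes n_chains * n_samples samples) that distinct
    topics are unlikely to merge.  Per-cluster alpha follows each sample's
    topic label through the clustering.
    """
    X = samples.all_phi()
    n_total, K, S = X.shape
    flat = X.reshape(n_total * K, S)
    chain_of = np.repeat(samples.chain_labels(), K)
    alpha_of = np.tile(samples.alpha, n_total)

    if k_snn is None:
        per_chain = n_total // max(samples.n_chains, 1)
        k_snn = (samples.n_chains * per_chain) // 2
    if flat.shape[0] < 2:
        raise ValueError("need at least two topic samples to cluster")
    if k_snn >= flat.shape[0]:
        warnings.warn("k exceeds number of samples; reducing")
        k_snn = flat.shape[0] - 1

    g = _snn_graph(flat, k_snn, scheme=scheme)
    import random

    import igraph

    igraph.set_random_number_generator(random.Random(seed))
    labels = np.asarray(
        g.community_multilevel(weights="weight", resolution=resolution).membership
    )
    clusters = np.unique(labels)
    topics = np.stack([flat[labels == c].mean(axis=0) for c in clusters])
    support = np.array(
        [len(np.unique(chain_of[labels == c])) for c in clusters]
    )
    alpha = np.array([alpha_of[labels == c].mean() for c in clusters])
    order = np.argsort(-topics.sum(axis=1))  # densest first, empty last
    return TopicSet(
        topics=topics[order], support=support[order], alpha=alpha[order],
        provenance={"labels": labels, "order": order, "k_snn": k_snn},
    )


def collapse_near_empty(ts: TopicSet, cosine_thresh: float = 0.1,
                        manhattan_thresh: float = 1.0,
                        n_keep: int | None = None) -> TopicSet:
    """Agglomeratively merge (average linkage) cluster-averaged topics that
    are too similar, until every remaining pair is distinct — cosine distance
    above ``cosine_thresh`` and Manhattan distance above ``manhattan_thresh``.

    Near-empty topics differ only in low-probability noise, so their
    Manhattan distances are tiny even when their cosine distances are not;
    requiring both distances to clear their thresholds is what lets them
    collapse into a single empty topic.  ``n_keep`` forces the number of
    retained topics instead (manual override).
    """
    groups = [[i] for i in range(ts.K)]

    def group_mean(g):
        return ts.topics[g].mean(axis=0)

    while len(groups) > 1:
        means = np.stack([group_mean(g) for g in groups])
        cos = cdist(means, means, metric="cosine")
        cos = np.nan_to_num(cos, nan=0.0)  # all-zero topics: distance 0
        man = cdist(means, means, metric="cityblock")
        np.fill_diagonal(cos, np.inf)
        np.fill_diagonal(man, np.inf)
        mergeable = (cos <= cosine_thresh) | (man <= manhattan_thresh)
        if n_keep is not None:
            if len(groups) <= n_keep:
                break
            i, j = np.unravel_index(np.argmin(man + cos), man.shape)
        else:
            if not mergeable.any():
                break
            cand = np.argwhere(mergeable)
            i, j = min(map(tuple, cand), key=lambda p: man[p] + cos[p])
        a, b = sorted((i, j))
        groups[a] = groups[a] + groups[b]
        del groups[b]

    topics = np.stack([group_mean(g) for g in groups])
    support = np.array([ts.support[g].max() for g in groups])
    alpha = (np.array([ts.alpha[g].sum() for g in groups])
             if ts.alpha is not None else None)
    return TopicSet(topics=topics, support=support, alpha=alpha,
                    provenance={"groups": groups, "parent": ts.provenance})
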