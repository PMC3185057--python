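"""Single-linkage divergence clustering of unidentified fragments.

Sequences that cannot be assigned against the reference are grouped
into minimum putative species: two fragments are linked when their
pairwise mismatch score is at most 5% over an alignment covering at
least 95% of the shorter fragment, and clusters are the connected
components of that link graph (single linkage, the behaviour of
Blastclust). The number of clusters is a floor on the number of
species present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin

from .align import align_pair
from .seqio import QueryFragment


@dataclass(frozen=True)
class ClusteringParams:
    max_divergence: float = 0.05      # "differing more than 5%" splits
    min_length_compared: float = 0.95  # of the shorter sequence

    def __post_init__(self) -> None:
        if not (0 < self.max_divergence <= 1 and 0 < self.min_length_compared <= 1):
            raise ValueError("parameters must lie in (0, 1]")


@dataclass
class ClusterSet:
    """A partition of the input sequence ids."""

    clusters: list[list[str]]
    params: ClusteringParams

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def pair_links(a: QueryFragment, b: QueryFragment, params: ClusteringParams) -> bool:
    """True when two fragments belong to the same putative species.

    The alignment must cover ``min_length_compared`` of the shorter
    fragment and diverge by at most ``max_divergence`` (exactly 5%
    still links; "more than 5%" splits). Pairs failing the coverage
    requirement contribute no edge.
    """
    short, long_ = (a, b) if a.length <= b.length else (b, a)
    res = align_pair(
        short.sequence,
        long_.sequence,
        query_id=short.seq_id,
        ref_id=long_.seq_id,
        min_coverage=params.min_length_compared,
    )
    if res is None:
        return False
    return res.mismatch_score <= params.max_divergence


def cluster(
    sequences: list[QueryFragment],
    params: ClusteringParams = ClusteringParams(),
) -> ClusterSet:
    """Partition fragments into single-linkage divergence clusters.

    The partition is independent of input order: cluster members are
    sorted by seq_id and clusters by their first member.
    """
    n = len(sequences)
    if n == 0:
        return ClusterSet(clusters=[], params=params)
    order = sorted(range(n), key=lambda i: sequences[i].seq_id)
    rows, cols = [], []
    for ii in range(n):
        for jj in range(ii + 1, n):
            i, j = order[ii], order[jj]
            if pair_links(sequences[i], sequences[j], params):
                rows += [ii, jj]
                cols += [jj, ii]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    groups: dict[int, list[str]] = {}
    for pos, lab in enumerate(labels):
        groups.setdefault(lab, []).append(sequences[order[pos]].seq_id)
    clusters = sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
    return ClusterSet(clusters=clusters, params=params)


def min_richness(clusters: ClusterSet) -> int:
    """Minimum cumulated species richness: the number of clusters."""
    return clusters.n_clusters


class DivergenceClusterer(BaseEstimator, ClusterMixin):
    """Single-linkage sequence clusterer with a scikit-learn surface.

    Parameters
    ----------
    max_divergence : float
        Maximum pairwise mismatch score for two fragments to link.
    min_length_compared : float
        Minimum aligned fraction of the shorter fragment.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster label per input fragment (input order).
    cluster_set_ : ClusterSet
        The partition as id lists.
    n_clusters_ : int
        Number of clusters (the minimum richness).
    """

    def __init__(self, max_divergence: float = 0.05, min_length_compared: float = 0.95):
        self.max_divergence = max_divergence
        self.min_length_compared = min_length_compared

    def fit(self, X: list[QueryFragment], y=None):
        params = ClusteringParams(self.max_divergence, self.min_length_compared)
        cs = cluster(list(X), params)
        self.cluster_set_ = cs
        self.n_clusters_ = cs.n_clusters
        label_of = {
            sid: k for k, members in enumerate(cs.clusters) for sid in members
        }
        self.labels_ = np.array([label_of[q.seq_id] for q in X], dtype=int)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
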