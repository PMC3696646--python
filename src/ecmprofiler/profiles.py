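"""Abundance-profile clustering and per-cluster GO term enrichment.

Proteins are clustered agglomeratively on 1 - r_u, where r_u is the uncentered
Pearson correlation r_u(x, y) = sum(x*y) / sqrt(sum(x^2) * sum(y^2)) — the
cosine of the angle between raw (not mean-centered) profiles, which makes
similarity scale-invariant and zero-anchored, the natural choice for
normalized spectrum-count profiles where absence really is zero. Clusters are
the maximal dendrogram subtrees whose root merge similarity is at least a
threshold (default 0.5). Each cluster is tested for over-represented GO terms
with the hypergeometric upper tail against a background, and p-values are
Benjamini-Hochberg adjusted across the terms tested within the cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .matrix import AbundanceMatrix

__all__ = [
    "uncentered_pearson",
    "ClusterSet",
    "cluster_proteins",
    "EnrichmentResult",
    "enrich_cluster",
]

logger = logging.getLogger(__name__)


def uncentered_pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Uncentered Pearson correlation (cosine similarity of raw profiles)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be 1-D vectors of equal length >= 2")
    nx, ny = np.sqrt((x * x).sum()), np.sqrt((y * y).sum())
    if nx == 0.0 or ny == 0.0:
        raise ValueError("uncentered Pearson undefined for a zero-norm vector")
    return float((x * y).sum() / (nx * ny))


@dataclass
class ClusterSet:
    """Dendrogram plus flat clusters extracted at a similarity threshold.

    ``clusters`` holds the multi-protein clusters (maximal subtrees whose root
    merge similarity >= ``threshold``), ordered by their smallest leaf index;
    proteins whose subtree never reaches the threshold appear in
    ``singletons``. ``linkage_matrix`` is a scipy linkage over ``proteins``.
    """

    proteins: list[str]
    linkage_matrix: np.ndarray
    clusters: list[list[str]]
    singletons: list[str]
    threshold: float
    leaf_order: list[str]
    dropped: list[str]

    @property
    def assignments(self) -> dict[str, int]:
        """Protein -> cluster index (singletons excluded)."""
        return {p: i for i, members in enumerate(self.clusters) for p in members}


def cluster_proteins(
    matrix: AbundanceMatrix,
    linkage: str = "average",
    threshold: float = 0.5,
) -> ClusterSet:
    """Agglomeratively cluster protein abundance profiles.

    Distance is 1 - r_u; linkage defaults to average (UPGMA). Proteins with
    all-zero profiles have undefined similarity and are dropped with a
    warning. Flat clusters are cut where the cophenetic merge distance is at
    most 1 - threshold, which yields exactly the maximal subtrees whose root
    merge similarity >= threshold. Given a fixed input order the result is
    deterministic (scipy breaks ties by merge order over leaf indices).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0,1]")
    X = matrix.values.to_numpy(dtype=float)
    norms = np.sqrt((X * X).sum(axis=1))
    keep = norms > 0.0
    dropped = [p for p, k in zip(matrix.proteins, keep) if not k]
    if dropped:
        logger.warning("dropping %d all-zero profile(s): %s", len(dropped), dropped)
    proteins = [p for p, k in zip(matrix.proteins, keep) if k]
    if len(proteins) < 2:
        raise ValueError("need at least two proteins with non-zero profiles")
    X = X[keep]

    dist = pdist(X, metric="cosine")  # cosine distance == 1 - uncentered Pearson
    dist = np.clip(dist, 0.0, 2.0)
    Z = hierarchy.linkage(dist, method=linkage)
    labels = hierarchy.fcluster(Z, t=1.0 - threshold, criterion="distance")

    groups: dict[int, list[str]] = {}
    for protein, label in zip(proteins, labels):
        groups.setdefault(int(label), []).append(protein)
    index = {p: i for i, p in enumerate(proteins)}
    multi = sorted(
        (members for members in groups.values() if len(members) > 1),
        key=lambda m: min(index[p] for p in m),
    )
    singletons = [m[0] for m in groups.values() if len(m) == 1]
    singletons.sort(key=index.get)
    leaf_order = [proteins[i] for i in hierarchy.leaves_list(Z)]
    return ClusterSet(proteins, Z, multi, singletons, threshold, leaf_order, dropped)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one GO term in one cluster."""

    term_id: str
    cluster_id: int
    k: int  # annotated proteins in the cluster
    K: int  # annotated proteins in the background
    n: int  # cluster size
    N: int  # background size
    p_value: float
    q_value: float
    significant: bool  # q_value <= alpha at the alpha the test was run with


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_cluster(
    cluster: Iterable[str],
    annotations: Mapping[str, set[str]],
    background: Iterable[str],
    alpha: float = 0.05,
    cluster_id: int = 0,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Test every term annotated in the cluster for over-representation.

    ``annotations`` maps symbol -> GO terms, already restricted to the domain
    of interest (e.g. biological process). The background must contain the
    cluster. With ``ease=True`` a conservative variant subtracts one observed
    success before taking the tail (the EASE score), deflating marginal
    single-gene hits. Results are BH-adjusted across the terms tested in this
    cluster and sorted by ascending p-value, ties by term id.
    """
    cluster = list(dict.fromkeys(cluster))
    background = list(dict.fromkeys(background))
    bg = set(background)
    if not set(cluster) <= bg:
        raise ValueError("background must contain the cluster")
    N, n = len(background), len(cluster)

    term_bg: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for symbol in background:
        for term in annotations.get(symbol, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
    for symbol in cluster:
        for term in annotations.get(symbol, ()):
            term_k[term] = term_k.get(term, 0) + 1

    terms = sorted(term_k)
    pvals = []
    for term in terms:
        k, K = term_k[term], term_bg[term]
        kk = max(k - 1, 0) if ease else k
        pvals.append(hypergeom_upper_tail(kk, K, n, N) if kk > 0 else 1.0)
    if not terms:
        return []
    qvals = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            term, cluster_id, term_k[term], term_bg[term], n, N, float(p), float(q), bool(q <= alpha)
        )
        for term, p, q in zip(terms, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
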