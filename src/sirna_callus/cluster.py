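"""Expression-pattern clustering and functional-term over-representation.

Target genes are grouped by their three stage-vs-CK log2 fold changes with
Euclidean K-means (k-means++ seeding, best of many restarts, k = 3 by
default — the three callus-induction archetypes: sustained up, sustained
down, transient up).  Cluster labels are relabeled by descending mean
Stage-I fold change so that numbering is stable across runs.

Each cluster is then tested for term over-representation with a one-sided
upper-tail hypergeometric test against the background gene set, BH-adjusted
within the cluster; the headline flag is the raw p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.cluster import KMeans

from .stats import bh_adjust

__all__ = [
    "PatternProfile",
    "EnrichmentResult",
    "kmeans_profiles",
    "hypergeometric_enrichment",
]


@dataclass
class PatternProfile:
    gene_id: str
    features: np.ndarray  # log2 fold change vs CK at Stages I, II, III
    cluster: int | None = None


@dataclass
class EnrichmentResult:
    cluster: int
    term_id: str
    term_name: str
    k_in: int
    n_cluster: int
    K_in: int
    N_bg: int
    p: float
    q: float
    significant: bool


def kmeans_profiles(
    profiles: list[PatternProfile],
    k: int = 3,
    seed: int = 0,
    restarts: int = 50,
) -> tuple[list[PatternProfile], np.ndarray]:
    """Euclidean K-means over fold-change profiles, deterministic per seed.

    Runs k-means++ ``restarts`` times and keeps the solution with the
    lowest within-cluster sum of squares; clusters are renumbered 1..k by
    descending mean Stage-I feature.  Returns the profiles with ``cluster``
    filled plus the (k, 3) centroid matrix in the same label order.
    """
    if not 1 <= k <= len(profiles):
        raise ValueError(f"k={k} must be between 1 and the number of profiles")
    X = np.array([p.features for p in profiles], dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles must be finite (pseudocount upstream)")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    raw_labels = km.fit_predict(X)
    order = np.argsort(-km.cluster_centers_[:, 0], kind="stable")
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    for p, lbl in zip(profiles, raw_labels):
        p.cluster = relabel[int(lbl)]
    centroids = km.cluster_centers_[order]
    return profiles, centroids


def hypergeometric_enrichment(
    cluster_genes: set[str],
    background_genes: set[str],
    annotation_map: dict[str, set[str]],
    term_names: dict[str, str] | None = None,
    p_thresh: float = 0.05,
    cluster: int = 0,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of terms in a cluster.

    ``annotation_map`` maps gene -> set of term ids.  Terms with no
    annotated gene inside the cluster are not reported.  p is the
    upper-tail probability of drawing at least ``k_in`` annotated genes in
    a cluster-sized sample from the background; BH adjustment runs across
    the reported terms; ``significant`` flags raw p below ``p_thresh``.
    """
    if not cluster_genes <= background_genes:
        missing = sorted(cluster_genes - background_genes)[:3]
        raise ValueError(f"cluster genes absent from background: {missing}...")
    term_names = term_names or {}
    N = len(background_genes)
    n = len(cluster_genes)
    term_bg: dict[str, int] = {}
    term_in: dict[str, int] = {}
    for gene in background_genes:
        for term in annotation_map.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in cluster_genes:
                term_in[term] = term_in.get(term, 0) + 1
    terms = sorted(term_in)
    if not terms:
        return []
    pvals = np.array(
        [sps.hypergeom.sf(term_in[t] - 1, N, term_bg[t], n) for t in terms]
    )
    pvals = np.minimum(pvals, 1.0)
    qvals = bh_adjust(pvals)
    return [
        EnrichmentResult(
            cluster=cluster,
            term_id=t,
            term_name=term_names.get(t, ""),
            k_in=term_in[t],
            n_cluster=n,
            K_in=term_bg[t],
            N_bg=N,
            p=float(pvals[i]),
            q=float(qvals[i]),
            significant=bool(pvals[i] < p_thresh),
        )
        for i, t in enumerate(terms)
    ]
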