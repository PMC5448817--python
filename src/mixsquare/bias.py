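"""Discovering dominant positional bias types.

Estimated fragment-start distributions are length-normalized onto a fixed
number of relative-position bins, optionally peak-scaled to a maximum of
one (which tightens the L1 distance between visually similar shapes),
hierarchically clustered with UPGMA (average linkage) under the L1
distance, and the tree is traversed top-down retaining the largest nodes
above a minimum membership fraction.  When descending a level shrinks a
node without changing the median shape, the top node is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy

__all__ = [
    "NormalizedDistribution",
    "BiasCluster",
    "bin_profile",
    "select_distributions",
    "upgma_cluster",
    "extract_clusters",
    "cluster_bias_profiles",
]


@dataclass
class NormalizedDistribution:
    """A length-normalized fragment-start profile for one transcript."""

    transcript_id: str
    length: int
    profile: np.ndarray  # sums to 1 over n_bins relative positions
    scaled: np.ndarray | None = None  # peak-scaled copy (max = 1)


@dataclass
class BiasCluster:
    member_ids: list[str]
    median_profile: np.ndarray
    fraction: float
    lengths: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def bin_profile(distribution, n_bins: int = 100) -> np.ndarray:
    """Aggregate a per-base start distribution onto relative-position bins,
    preserving total mass."""
    p = np.asarray(distribution, dtype=float)
    L = len(p)
    idx = (np.arange(L) * n_bins) // L
    out = np.zeros(n_bins)
    np.add.at(out, idx, p)
    return out


def select_distributions(
    records,
    min_count: float = 100,
    length_range: tuple[int, int] | None = None,
    n_bins: int = 100,
    peak_scale: bool = False,
) -> list[NormalizedDistribution]:
    """Filter transcripts by estimated fragment count (and optionally
    length) and length-normalize their start distributions.

    ``records`` is an iterable of ``(transcript_id, length, est_count,
    distribution)`` tuples or of fitted results' per-transcript entries.
    """
    out = []
    for rec in records:
        tid, length, count, dist = rec
        if count < min_count:
            continue
        if length_range is not None and not (length_range[0] <= length <= length_range[1]):
            continue
        prof = bin_profile(dist, n_bins)
        total = prof.sum()
        if total <= 0:
            continue
        prof = prof / total
        scaled = prof / prof.max() if peak_scale else None
        out.append(NormalizedDistribution(tid, int(length), prof, scaled))
    if not out:
        raise ValueError("no distributions pass the selection filters")
    return out


def upgma_cluster(profiles: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) hierarchical clustering under L1 distance.

    Returns the scipy linkage matrix.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    return hierarchy.linkage(profiles, method="average", metric="cityblock")


def _node_members(node):
    return node.pre_order(lambda leaf: leaf.id)


def extract_clusters(
    linkage_matrix: np.ndarray,
    profiles: np.ndarray,
    min_fraction: float = 0.05,
    shape_tol: float = 0.15,
    ids: list[str] | None = None,
    lengths: list[int] | None = None,
) -> list[BiasCluster]:
    """Top-down traversal of the UPGMA tree.

    Maximal nodes holding at least ``min_fraction`` of all profiles are
    retained; if a qualifying node's only qualifying child has the same
    median shape (L1 below ``shape_tol``), the top node is reported.
    Profiles outside every reported cluster form the implicit "other"
    remainder (reported fractions sum to at most 1).
    """
    profiles = np.asarray(profiles, dtype=float)
    total_n = profiles.shape[0]
    threshold = min_fraction * total_n
    tree = hierarchy.to_tree(linkage_matrix)

    def median_of(node):
        return np.median(profiles[_node_members(node)], axis=0)

    def collect(node):
        members = _node_members(node)
        if len(members) < threshold:
            return []
        if node.is_leaf():
            return [node]
        children = [c for c in (node.left, node.right) if c is not None]
        qualifying = [c for c in children if c.count >= threshold]
        if not qualifying:
            return [node]
        if len(qualifying) == 1:
            child = qualifying[0]
            d = float(np.abs(median_of(child) - median_of(node)).sum())
            if d < shape_tol:
                return [node]  # shrinks without changing shape: keep top
            return collect(child)
        found = []
        for c in qualifying:
            found.extend(collect(c))
        return found

    clusters = []
    for node in collect(tree):
        members = _node_members(node)
        clusters.append(
            BiasCluster(
                member_ids=[ids[m] if ids else str(m) for m in members],
                median_profile=np.median(profiles[members], axis=0),
                fraction=len(members) / total_n,
                lengths=[lengths[m] for m in members] if lengths else [],
            )
        )
    clusters.sort(key=lambda c: -c.size)
    return clusters


def cluster_bias_profiles(
    distributions: list[NormalizedDistribution],
    mode: str = "maqc",
    min_fraction: float = 0.05,
    shape_tol: float = 0.15,
) -> list[BiasCluster]:
    """End-to-end clustering of selected distributions.

    ``maqc`` mode clusters the sum-1 profiles; ``seqc`` mode clusters
    peak-scaled profiles (max = 1).  Input order is made irrelevant by
    sorting on transcript id before building the tree.
    """
    if mode not in ("maqc", "seqc"):
        raise ValueError(f"unknown mode {mode!r}")
    distributions = sorted(distributions, key=lambda d: d.transcript_id)
    if mode == "seqc":
        mat = np.array(
            [d.scaled if d.scaled is not None else d.profile / d.profile.max() for d in distributions]
        )
    else:
        mat = np.array([d.profile for d in distributions])
    Z = upgma_cluster(mat)
    return extract_clusters(
        Z,
        mat,
        min_fraction=min_fraction,
        shape_tol=shape_tol,
        ids=[d.transcript_id for d in distributions],
        lengths=[d.length for d in distributions],
    )
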