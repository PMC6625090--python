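"""Oligomer population classification by proximity threshold.

Gold particles closer than a fixed linkage distance (default 15 nm,
about three gold diameters plus antibody reach) are treated as part of
one oligomer. Particles are partitioned into connected components of
the proximity graph (single linkage: a chain 0-10-20 nm is one trimer
even though its ends are 20 nm apart); components are mapped to the
monomer / dimer / trimer / higher-multimer (>= 4) classes and reported
both as component counts and as fractions of particles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .geometry import PointPattern, PointPatternError

__all__ = ["OligomerDistribution", "classify_oligomers", "CLASS_NAMES"]

CLASS_NAMES = ("monomer", "dimer", "trimer", "multimer")


def _size_class(size: int) -> str:
    return CLASS_NAMES[min(size, 4) - 1]


@dataclass(frozen=True)
class OligomerDistribution:
    """Cluster-size partition of a pattern at one linkage threshold."""

    threshold: float
    cluster_sizes: tuple
    counts: dict
    particle_fractions: dict
    linkage: str = "single"

    @property
    def n_particles(self) -> int:
        return int(sum(self.cluster_sizes))

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def cluster_fractions(self) -> dict:
        """Fractions of clusters (not particles) per class."""
        total = self.n_clusters
        return {k: self.counts[k] / total for k in CLASS_NAMES}


def _component_labels_single(points: np.ndarray, threshold: float) -> np.ndarray:
    tree = cKDTree(points)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    n = len(points)
    if len(pairs) == 0:
        return np.arange(n)
    data = np.ones(len(pairs))
    graph = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def _component_labels_complete(points: np.ndarray, threshold: float) -> np.ndarray:
    if len(points) == 1:
        return np.zeros(1, dtype=int)
    z = linkage(pdist(points), method="complete")
    return fcluster(z, t=threshold, criterion="distance")


def classify_oligomers(
    pattern: PointPattern,
    threshold: float = 15.0,
    method: str = "single",
) -> OligomerDistribution:
    """Partition particles into oligomer classes at a distance threshold.

    ``method='single'`` (default) links any pair within ``threshold`` nm
    and takes connected components; ``method='complete'`` requires every
    within-cluster pair to be within the threshold (complete-linkage cut).
    """
    if pattern.n == 0:
        raise PointPatternError("cannot classify an empty pattern")
    if threshold <= 0:
        raise PointPatternError(f"threshold must be > 0, got {threshold}")
    if method == "single":
        labels = _component_labels_single(pattern.points, threshold)
    elif method == "complete":
        labels = _component_labels_complete(pattern.points, threshold)
    else:
        raise PointPatternError(f"unknown linkage method {method!r}")

    _, sizes = np.unique(labels, return_counts=True)
    counts = {k: 0 for k in CLASS_NAMES}
    particles = {k: 0 for k in CLASS_NAMES}
    for size in sizes:
        cls = _size_class(int(size))
        counts[cls] += 1
        particles[cls] += int(size)
    fractions = {k: particles[k] / pattern.n for k in CLASS_NAMES}
    return OligomerDistribution(
        threshold=float(threshold),
        cluster_sizes=tuple(int(s) for s in sizes),
        counts=counts,
        particle_fractions=fractions,
        linkage=method,
    )
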