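"""Host-provirus bipartite network construction and rare-node pruning.

The network is a binary incidence matrix ``a`` with hosts on rows and viral
clusters (genus-level provirus groupings) on columns; ``a[i, j] = 1`` records
that at least one provirus of cluster *j* occurs in the genome of host *i*.
Before specialization is computed, singleton and doubleton nodes (network
degree 1 or 2) are pruned, because low-degree clusters are dominated by
fragmentary provirus calls and would inflate the number of perfect
specialists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

PruneMode = Literal["clusters_then_orphans", "iterative_both"]

__all__ = [
    "IncidenceMatrix",
    "PrunedNetwork",
    "NetworkError",
    "EmptyNetworkError",
    "build_network",
    "prune_rare",
    "degree_summary",
]


class NetworkError(ValueError):
    """Malformed input to a network operation."""


class EmptyNetworkError(NetworkError):
    """Raised when pruning (or construction) leaves no nodes."""


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary host x viral-cluster incidence matrix.

    Attributes
    ----------
    host_ids, cluster_ids
        Row / column labels in stable first-appearance order.
    a
        ``(I, J)`` array with entries in {0, 1}.
    """

    host_ids: tuple[str, ...]
    cluster_ids: tuple[str, ...]
    a: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a)
        if a.ndim != 2:
            raise NetworkError("incidence matrix must be 2-dimensional")
        if a.shape != (len(self.host_ids), len(self.cluster_ids)):
            raise NetworkError(
                f"matrix shape {a.shape} does not match "
                f"{len(self.host_ids)} hosts x {len(self.cluster_ids)} clusters"
            )
        if len(set(self.host_ids)) != len(self.host_ids):
            raise NetworkError("duplicate host ids")
        if len(set(self.cluster_ids)) != len(self.cluster_ids):
            raise NetworkError("duplicate cluster ids")
        if a.size and not np.isin(a, (0, 1)).all():
            raise NetworkError("incidence entries must be 0 or 1")
        object.__setattr__(self, "a", a.astype(np.int8))

    @property
    def n_hosts(self) -> int:
        return len(self.host_ids)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def n_links(self) -> int:
        return int(self.a.sum())

    def host_degrees(self) -> np.ndarray:
        return self.a.sum(axis=1).astype(np.int64)

    def cluster_degrees(self) -> np.ndarray:
        return self.a.sum(axis=0).astype(np.int64)

    def to_edges(self) -> list[tuple[str, str]]:
        """Edge list (host_id, cluster_id) in row-major matrix order."""
        rows, cols = np.nonzero(self.a)
        return [(self.host_ids[i], self.cluster_ids[j]) for i, j in zip(rows, cols)]

    def subset(self, host_keep: np.ndarray, cluster_keep: np.ndarray) -> "IncidenceMatrix":
        hosts = tuple(h for h, k in zip(self.host_ids, host_keep) if k)
        clusters = tuple(c for c, k in zip(self.cluster_ids, cluster_keep) if k)
        return IncidenceMatrix(hosts, clusters, self.a[np.ix_(host_keep, cluster_keep)])


@dataclass(frozen=True)
class PrunedNetwork:
    """Result of :func:`prune_rare`: the retained matrix plus a removal audit."""

    matrix: IncidenceMatrix
    removed_hosts: tuple[tuple[str, str], ...] = field(default_factory=tuple)
    removed_clusters: tuple[tuple[str, str], ...] = field(default_factory=tuple)
    prune_mode: PruneMode = "clusters_then_orphans"


def build_network(edges: Iterable[Sequence[str]]) -> IncidenceMatrix:
    """Build the incidence matrix from (host_id, cluster_id) co-occurrence pairs.

    Duplicate pairs collapse to a single link (presence/absence). Row and
    column order follow first appearance in the edge stream, so output is
    reproducible for a fixed input order.
    """
    host_index: dict[str, int] = {}
    cluster_index: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    n = 0
    for n, edge in enumerate(edges, start=1):
        if len(edge) != 2:
            raise NetworkError(f"edge #{n} is malformed (expected 2 fields): {edge!r}")
        h, c = str(edge[0]).strip(), str(edge[1]).strip()
        if not h or not c:
            raise NetworkError(f"edge #{n} has a blank id: {edge!r}")
        hi = host_index.setdefault(h, len(host_index))
        ci = cluster_index.setdefault(c, len(cluster_index))
        pairs.add((hi, ci))
    if n == 0:
        raise EmptyNetworkError("empty edge list")
    a = np.zeros((len(host_index), len(cluster_index)), dtype=np.int8)
    rows, cols = zip(*pairs)
    a[list(rows), list(cols)] = 1
    return IncidenceMatrix(tuple(host_index), tuple(cluster_index), a)


def prune_rare(
    matrix: IncidenceMatrix,
    mode: PruneMode = "clusters_then_orphans",
    min_degree: int = 3,
) -> PrunedNetwork:
    """Remove singleton/doubleton nodes (degree < ``min_degree``).

    ``clusters_then_orphans`` (default) drops every viral cluster of degree
    < ``min_degree`` and then drops hosts left with no partners. Hosts of
    degree 1-2 whose partners survive are retained; this is the reading
    consistent with a post-pruning mean host degree well below 3.
    ``iterative_both`` alternately drops hosts and clusters of degree
    < ``min_degree`` until a fixed point, the stricter interpretation.
    """
    if mode not in ("clusters_then_orphans", "iterative_both"):
        raise NetworkError(f"unknown prune mode: {mode!r}")
    removed_hosts: list[tuple[str, str]] = []
    removed_clusters: list[tuple[str, str]] = []
    current = matrix

    def drop(m: IncidenceMatrix, host_keep: np.ndarray, cluster_keep: np.ndarray,
             reason_host: str, reason_cluster: str) -> IncidenceMatrix:
        hdeg, cdeg = m.host_degrees(), m.cluster_degrees()
        removed_hosts.extend(
            (h, f"{reason_host} (degree {hdeg[i]})")
            for i, h in enumerate(m.host_ids) if not host_keep[i]
        )
        removed_clusters.extend(
            (c, f"{reason_cluster} (degree {cdeg[j]})")
            for j, c in enumerate(m.cluster_ids) if not cluster_keep[j]
        )
        return m.subset(host_keep, cluster_keep)

    if mode == "clusters_then_orphans":
        ckeep = current.cluster_degrees() >= min_degree
        current = drop(current, np.ones(current.n_hosts, bool), ckeep,
                       "", f"cluster degree < {min_degree}")
        hkeep = current.host_degrees() >= 1
        current = drop(current, hkeep, np.ones(current.n_clusters, bool),
                       "orphaned by cluster pruning", "")
    else:
        while True:
            hkeep = current.host_degrees() >= min_degree
            ckeep = current.cluster_degrees() >= min_degree
            if hkeep.all() and ckeep.all():
                break
            current = drop(current, hkeep, ckeep,
                           f"host degree < {min_degree}",
                           f"cluster degree < {min_degree}")
            if current.n_hosts == 0 or current.n_clusters == 0:
                break

    if current.n_hosts == 0 or current.n_clusters == 0 or current.n_links == 0:
        raise EmptyNetworkError(
            f"pruning removed the whole network "
            f"({len(removed_hosts)} hosts, {len(removed_clusters)} clusters dropped)"
        )
    return PrunedNetwork(current, tuple(removed_hosts), tuple(removed_clusters), mode)


def degree_summary(matrix: IncidenceMatrix) -> dict:
    """Per-node degrees plus link count and host-degree mean/SD."""
    hdeg = matrix.host_degrees()
    cdeg = matrix.cluster_degrees()
    assert hdeg.sum() == cdeg.sum() == matrix.n_links
    return {
        "host_degrees": dict(zip(matrix.host_ids, hdeg.tolist())),
        "cluster_degrees": dict(zip(matrix.cluster_ids, cdeg.tolist())),
        "n_links": matrix.n_links,
        "mean_host_degree": float(hdeg.mean()) if hdeg.size else float("nan"),
        "sd_host_degree": float(hdeg.std(ddof=1)) if hdeg.size > 1 else float("nan"),
    }
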