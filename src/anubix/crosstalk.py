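"""Crosstalk counting between a query set and a pathway.

Crosstalk is the ordered-pair link count k = Σ_{i∈Q} Σ_{j∈P} a_ij over the
network adjacency: every gene of Q contributes its links into P, so an
edge with both endpoints in the overlap Q∩P is counted twice (once from
each side). The number of possible links is n = |Q||P| − |Q∩P| — all
ordered pairs minus the |Q∩P| zero-diagonal self pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import GeneSet, MappedQuery, Network, map_query

__all__ = [
    "CrosstalkObservation",
    "count_crosstalk",
    "possible_links",
    "observe",
    "pathway_degree_array",
]


def _as_members(obj: GeneSet | MappedQuery | Iterable[str]) -> frozenset[str]:
    if isinstance(obj, GeneSet):
        return obj.members
    if isinstance(obj, MappedQuery):
        return obj.mapped_members
    return frozenset(obj)


def count_crosstalk(
    query: GeneSet | MappedQuery | Iterable[str],
    pathway: GeneSet | MappedQuery | Iterable[str],
    network: Network,
) -> int:
    """Ordered-pair crosstalk degree k between two gene sets.

    Both sets must be subsets of the network universe. Implemented as
    per-gene neighbor-set intersections; the result equals a double loop
    over the dense adjacency matrix.
    """
    q = _as_members(query)
    p = _as_members(pathway)
    for g in q | p:
        if g not in network:
            raise KeyError(f"gene {g!r} not in network")
    return sum(len(network.neighbors(g) & p) for g in q)


def possible_links(q_size: int, p_size: int, overlap: int) -> int:
    """Number of possible links n = q_size·p_size − overlap."""
    if q_size < 0 or p_size < 0 or overlap < 0:
        raise ValueError("sizes and overlap must be non-negative")
    if overlap > min(q_size, p_size):
        raise ValueError("overlap cannot exceed the smaller set size")
    return q_size * p_size - overlap


@dataclass(frozen=True)
class CrosstalkObservation:
    """Observed crosstalk between one (query, pathway) pair."""

    k: int
    n: int
    overlap: int
    q_size: int
    p_size: int

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError(f"k={self.k} outside [0, n={self.n}]")
        if self.n != self.q_size * self.p_size - self.overlap:
            raise ValueError("n must equal q_size*p_size - overlap")
        if self.overlap > min(self.q_size, self.p_size):
            raise ValueError("overlap exceeds the smaller set size")


def observe(
    query: GeneSet | MappedQuery,
    pathway: GeneSet,
    network: Network,
    universe: str = "network",
) -> CrosstalkObservation:
    """Bundle the crosstalk degree and possible-link count for one pair.

    With ``universe="network"`` (default) the pathway is intersected with
    the network before counting and ``p_size`` is the post-intersection
    size; genes without links cannot contribute crosstalk, and retaining
    them would deflate the null. ``universe="full"`` keeps the full
    pathway size in n.
    """
    if universe not in ("network", "full"):
        raise ValueError(f"unknown universe mode {universe!r}")
    mq = query if isinstance(query, MappedQuery) else map_query(query, network)
    qm = mq.mapped_members
    if not qm:
        raise ValueError("query has empty network support")
    p_net = pathway.network_members(network)
    if universe == "network":
        p_size = len(p_net)
        overlap = len(qm & p_net)
    else:
        p_size = len(pathway.members)
        overlap = len(qm & pathway.members)
    k = count_crosstalk(qm, p_net, network)
    n = possible_links(len(qm), p_size, overlap)
    return CrosstalkObservation(k=k, n=n, overlap=overlap, q_size=len(qm), p_size=p_size)


def pathway_degree_array(network: Network, pathway: GeneSet | Iterable[str]) -> np.ndarray:
    """Per-gene link count into the pathway, aligned with ``network.genes``.

    ``d[i] = |N(gene_i) ∩ P|``; the crosstalk of any gene set to P is the
    sum of d over its members, which is how null sampling and the batch
    benchmarks count crosstalk in vectorized form.
    """
    members = _as_members(pathway) if not isinstance(pathway, GeneSet) else pathway.members
    mask = network.member_mask(members)
    d = np.zeros(network.n_genes, dtype=np.int64)
    if network.n_edges:
        u = network.edge_index[:, 0]
        v = network.edge_index[:, 1]
        sel = mask[v]
        if sel.any():
            d += np.bincount(u[sel], minlength=network.n_genes)
        sel = mask[u]
        if sel.any():
            d += np.bincount(v[sel], minlength=network.n_genes)
    return d
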