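"""Network and gene-set input/output.

Functional-association networks are undirected, unweighted gene graphs
loaded from tab- (or whitespace-) separated edge lists, optionally filtered
at a link-confidence cutoff. Gene sets — pathway databases and query sets
alike — are read from GMT files (``id<TAB>description<TAB>gene...``) or
from a two-column long-format TSV. Reactome-style parent→child hierarchies
can be collapsed so that small leaf pathways are absorbed into their
parents until a target mean pathway size is reached.

Gene identifiers are opaque, case-sensitive strings; no identifier
translation is performed here.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "GeneSet",
    "GeneSetCollection",
    "MappedQuery",
    "load_network",
    "load_gene_sets",
    "load_hierarchy",
    "collapse_hierarchy",
    "map_query",
]


class Network:
    """Undirected gene network with a symmetric, zero-diagonal adjacency.

    The gene universe is stored in canonical (lexicographic) order so that
    loading the same edge list in any row order yields an identical object.
    Self-links are dropped on construction; duplicate and reversed duplicate
    edges collapse to a single undirected link.

    Parameters
    ----------
    edges
        Iterable of ``(gene_a, gene_b)`` pairs.
    genes
        Additional genes to include in the universe even if they carry no
        link (e.g. a gene whose only stated link was a self-link).
    """

    def __init__(self, edges: Iterable[tuple[str, str]], genes: Iterable[str] = ()) -> None:
        nodes: set[str] = set(genes)
        pairs: set[tuple[str, str]] = set()
        for a, b in edges:
            nodes.add(a)
            nodes.add(b)
            if a == b:  # zero diagonal
                continue
            pairs.add((a, b) if a < b else (b, a))
        self.genes: tuple[str, ...] = tuple(sorted(nodes))
        self.gene_index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}
        nbrs: dict[str, set[str]] = {g: set() for g in self.genes}
        for a, b in sorted(pairs):
            nbrs[a].add(b)
            nbrs[b].add(a)
        self._neighbors: dict[str, frozenset[str]] = {g: frozenset(s) for g, s in nbrs.items()}
        if pairs:
            self.edge_index: np.ndarray = np.array(
                [[self.gene_index[a], self.gene_index[b]] for a, b in sorted(pairs)],
                dtype=np.int64,
            )
        else:
            self.edge_index = np.empty((0, 2), dtype=np.int64)

    # -- basic queries -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.edge_index.shape[0])

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_index

    def neighbors(self, gene: str) -> frozenset[str]:
        return self._neighbors[gene]

    def degree(self, gene: str) -> int:
        return len(self._neighbors[gene])

    @property
    def degrees(self) -> np.ndarray:
        """Per-gene link counts, aligned with :attr:`genes`."""
        d = np.zeros(self.n_genes, dtype=np.int64)
        if self.n_edges:
            d += np.bincount(self.edge_index[:, 0], minlength=self.n_genes)
            d += np.bincount(self.edge_index[:, 1], minlength=self.n_genes)
        return d

    def member_mask(self, members: Iterable[str]) -> np.ndarray:
        """Boolean mask over :attr:`genes` for the given members.

        Members absent from the network are silently ignored.
        """
        mask = np.zeros(self.n_genes, dtype=bool)
        for g in members:
            i = self.gene_index.get(g)
            if i is not None:
                mask[i] = True
        return mask

    def has_edge(self, a: str, b: str) -> bool:
        return b in self._neighbors.get(a, frozenset())

    def to_networkx(self, members: Iterable[str] | None = None):
        """Return a :class:`networkx.Graph`, optionally induced on ``members``."""
        import networkx as nx

        g = nx.Graph()
        if members is None:
            g.add_nodes_from(self.genes)
            g.add_edges_from((self.genes[i], self.genes[j]) for i, j in self.edge_index)
        else:
            keep = {m for m in members if m in self.gene_index}
            g.add_nodes_from(sorted(keep))
            for m in sorted(keep):
                for nb in self._neighbors[m]:
                    if nb in keep and m < nb:
                        g.add_edge(m, nb)
        return g

    def write_edge_list(self, path: str | Path) -> None:
        """Write the network as a two-column TSV edge list.

        Isolated genes are emitted as self-link lines (which reload as a
        gene with no edges), so a round trip preserves the gene universe.
        """
        path = Path(path)
        linked = set()
        with path.open("w") as fh:
            for i, j in self.edge_index:
                a, b = self.genes[i], self.genes[j]
                linked.add(a)
                linked.add(b)
                fh.write(f"{a}\t{b}\n")
            for g in self.genes:
                if g not in linked:
                    fh.write(f"{g}\t{g}\n")  # self-link: keeps gene, adds no edge

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Network(n_genes={self.n_genes}, n_edges={self.n_edges})"


def load_network(
    path: str | Path,
    confidence_cutoff: float | None = None,
    strict: bool = True,
) -> Network:
    """Load an undirected network from a TSV/whitespace edge list.

    Each non-comment line must have at least two columns (the two
    endpoints); an optional third numeric column is a link confidence.
    When ``confidence_cutoff`` is given, edges with confidence below the
    cutoff are excluded entirely — genes appearing only in such edges do
    not enter the gene universe. Lines without a confidence column are
    always kept. Self-links contribute their gene to the universe but no
    edge.

    Raises
    ------
    ValueError
        On lines with fewer than two columns, on a non-numeric confidence
        when a cutoff is given, or (with ``strict=True``, the default) on
        an empty network.
    """
    path = Path(path)
    genes: set[str] = set()
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}")
            a, b = parts[0], parts[1]
            if confidence_cutoff is not None and len(parts) >= 3:
                try:
                    conf = float(parts[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric confidence {parts[2]!r}"
                    ) from exc
                if conf < confidence_cutoff:
                    continue
            genes.add(a)
            genes.add(b)
            if a != b:
                edges.append((a, b))
    if strict and not genes:
        raise ValueError(f"{path}: no genes after filtering (empty network)")
    return Network(edges, genes)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (query list or curated pathway)."""

    id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("gene set id must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def network_members(self, network: Network) -> frozenset[str]:
        """Members present in the network universe."""
        return frozenset(g for g in self.members if g in network)


class GeneSetCollection:
    """An ordered collection of uniquely identified gene sets.

    May carry a parent→children hierarchy over set ids (Reactome style);
    the hierarchy must reference only ids present in the collection and be
    acyclic.
    """

    def __init__(
        self,
        sets: Sequence[GeneSet],
        hierarchy: Mapping[str, Sequence[str]] | None = None,
        notes: dict | None = None,
    ) -> None:
        ids = [s.id for s in sets]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate gene set ids: {sorted(dup)}")
        self.sets: list[GeneSet] = list(sets)
        self._by_id: dict[str, GeneSet] = {s.id: s for s in sets}
        self.notes: dict = dict(notes or {})
        if hierarchy is not None:
            hierarchy = {p: tuple(cs) for p, cs in hierarchy.items()}
            known = set(self._by_id)
            for p, cs in hierarchy.items():
                for node in (p, *cs):
                    if node not in known:
                        raise ValueError(f"hierarchy references unknown set id {node!r}")
            _check_acyclic(hierarchy)
        self.hierarchy: dict[str, tuple[str, ...]] | None = (
            dict(hierarchy) if hierarchy is not None else None
        )

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._by_id[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sets]

    def mean_size(self) -> float:
        if not self.sets:
            return 0.0
        return float(np.mean([len(s) for s in self.sets]))

    def write_gmt(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            for s in self.sets:
                genes = "\t".join(sorted(s.members))
                fh.write(f"{s.id}\t{s.name or s.id}\t{genes}\n")


def _check_acyclic(hierarchy: Mapping[str, Sequence[str]]) -> None:
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(node: str, stack: list[str]) -> None:
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            raise ValueError(f"hierarchy cycle through {node!r}")
        state[node] = 0
        for child in hierarchy.get(node, ()):
            visit(child, stack + [node])
        state[node] = 1

    for root in hierarchy:
        visit(root, [])


def load_gene_sets(path: str | Path, fmt: str = "gmt") -> GeneSetCollection:
    """Read gene sets from GMT (default) or two-column long-format TSV.

    GMT lines are ``id<TAB>description<TAB>gene1<TAB>gene2...``; lines with
    fewer than three fields are an error. Duplicate genes within a line are
    deduplicated with a warning; duplicate set ids are an error. The long
    format is ``set_id<TAB>gene``, one membership per line.
    """
    path = Path(path)
    if fmt not in ("gmt", "long"):
        raise ValueError(f"unknown gene-set format {fmt!r}")
    sets: list[GeneSet] = []
    if fmt == "gmt":
        seen: set[str] = set()
        with path.open() as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
                set_id, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
                if set_id in seen:
                    raise ValueError(f"{path}:{lineno}: duplicate gene set id {set_id!r}")
                seen.add(set_id)
                if len(set(genes)) < len(genes):
                    warnings.warn(
                        f"{path}:{lineno}: duplicate genes in set {set_id!r} deduplicated",
                        stacklevel=2,
                    )
                sets.append(GeneSet(id=set_id, name=name, members=frozenset(genes)))
    else:
        grouped: dict[str, set[str]] = {}
        order: list[str] = []
        with path.open() as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: long format needs exactly 2 columns")
                sid, gene = parts
                if sid not in grouped:
                    grouped[sid] = set()
                    order.append(sid)
                grouped[sid].add(gene)
        sets = [GeneSet(id=sid, name=sid, members=frozenset(grouped[sid])) for sid in order]
    return GeneSetCollection(sets)


def load_hierarchy(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a parent→child relation from a two-column TSV (parent_id, child_id)."""
    path = Path(path)
    rel: dict[str, list[str]] = defaultdict(list)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: hierarchy line needs exactly 2 columns")
            parent, child = parts
            rel[parent].append(child)
    return {p: tuple(cs) for p, cs in rel.items()}


def collapse_hierarchy(
    collection: GeneSetCollection,
    size_threshold: int,
    target_mean_size: int,
) -> GeneSetCollection:
    """Absorb small leaf sets into their parents until the mean size target.

    Iteratively, every leaf set (one with no remaining children) smaller
    than the current threshold is merged (set union) into its parent and
    removed. When no merge is possible at the current threshold, the
    threshold is raised by one; iteration stops once the mean set size
    reaches ``target_mean_size`` or no set with a surviving parent remains.
    Small sets without a parent are kept as-is and recorded in
    ``notes["unmerged_small"]``.

    The returned collection carries no hierarchy.
    """
    if collection.hierarchy is None:
        raise ValueError("collection has no hierarchy to collapse")
    members: dict[str, set[str]] = {s.id: set(s.members) for s in collection}
    names: dict[str, str] = {s.id: s.name for s in collection}
    order: list[str] = [s.id for s in collection]

    # Deterministic single parent per child: lexicographically first parent.
    parent_of: dict[str, str] = {}
    for parent in sorted(collection.hierarchy):
        for child in collection.hierarchy[parent]:
            if child not in parent_of or parent < parent_of[child]:
                parent_of[child] = parent
    children_of: dict[str, set[str]] = defaultdict(set)
    for child, parent in parent_of.items():
        children_of[parent].add(child)

    threshold = size_threshold

    def mean_size() -> float:
        return sum(len(m) for m in members.values()) / len(members)

    while members and mean_size() < target_mean_size:
        merged = False
        for sid in sorted(members):
            if children_of.get(sid):
                continue  # not a leaf
            if len(members[sid]) >= threshold:
                continue
            parent = parent_of.get(sid)
            if parent is None or parent not in members:
                continue
            members[parent] |= members[sid]
            del members[sid]
            children_of[parent].discard(sid)
            parent_of.pop(sid, None)
            merged = True
            break
        if merged:
            continue
        mergeable = any(
            not children_of.get(sid) and parent_of.get(sid) in members for sid in members
        )
        if not mergeable:
            break
        threshold += 1

    unmerged_small = sorted(
        sid for sid, mem in members.items() if len(mem) < size_threshold
    )
    if unmerged_small:
        logger.info(
            "%d sets below the size threshold had no parent to merge into", len(unmerged_small)
        )
    new_sets = [
        GeneSet(id=sid, name=names[sid], members=frozenset(members[sid]))
        for sid in order
        if sid in members
    ]
    return GeneSetCollection(new_sets, hierarchy=None, notes={"unmerged_small": unmerged_small})


@dataclass(frozen=True)
class MappedQuery:
    """A query gene set partitioned by network membership."""

    original: GeneSet
    mapped_members: frozenset[str]
    dropped: frozenset[str]

    def __post_init__(self) -> None:
        if self.mapped_members | self.dropped != self.original.members:
            raise ValueError("mapped_members and dropped must partition the query")
        if self.mapped_members & self.dropped:
            raise ValueError("mapped_members and dropped must be disjoint")

    @property
    def id(self) -> str:
        return self.original.id

    @property
    def size(self) -> int:
        return len(self.mapped_members)


def map_query(query: GeneSet, network: Network) -> MappedQuery:
    """Partition a query into network-supported and dropped members.

    Raises
    ------
    ValueError
        If no query member is present in the network ("query has no
        network support").
    """
    mapped = frozenset(g for g in query.members if g in network)
    dropped = query.members - mapped
    if not mapped:
        raise ValueError(f"query {query.id!r} has no network support")
    if dropped:
        logger.info("query %s: dropped %d/%d members not in the network",
                    query.id, len(dropped), len(query.members))
    return MappedQuery(original=query, mapped_members=mapped, dropped=frozenset(dropped))
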