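"""Seeded synthetic networks with planted pathway modules.

Generates a background gene network (scale-free preferential attachment
or Erdős–Rényi) with planted, densely intra-connected modules — the
synthetic stand-ins for curated pathways — plus random or pathway-enriched
query gene sets. Planted modules with p_in well above the background link
density reproduce the overdispersed crosstalk null distributions that real
pathways exhibit, so every downstream component can be exercised without
external data.

RNG streams are derived from the master seed by fixed offsets (background,
module edges, queries), so each artifact is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil, comb
from pathlib import Path

import networkx as nx
import numpy as np

from .io import GeneSet, GeneSetCollection, Network

__all__ = ["SynthSpec", "generate_network", "generate_query", "write_fixture"]

_BACKGROUNDS = ("scale_free", "erdos_renyi")

# Fixed sub-stream offsets from the master seed.
_OFF_BACKGROUND = 0
_OFF_MODULES = 1
_OFF_QUERIES = 2


@dataclass(frozen=True)
class SynthSpec:
    """Specification of a synthetic network with planted modules.

    Defaults: 2000 genes, scale-free background (3 attachments per new
    node), 10 modules of 80 genes with within-module link probability
    0.25 and module-to-outside probability 0.005 — small enough for
    minute-scale runs, dense enough that module nulls are clearly
    overdispersed.
    """

    n_genes: int = 2000
    background_model: str = "scale_free"
    p_bg: float = 0.005
    m_attach: int = 3
    modules: tuple[tuple[int, float], ...] = tuple((80, 0.25) for _ in range(10))
    p_out: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_model not in _BACKGROUNDS:
            raise ValueError(f"unknown background model {self.background_model!r}")
        if sum(size for size, _ in self.modules) > self.n_genes:
            raise ValueError("module sizes exceed the gene universe")
        probs = [self.p_bg, self.p_out, *(p for _, p in self.modules)]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.background_model == "scale_free" and self.m_attach >= self.n_genes:
            raise ValueError("m_attach must be smaller than n_genes")


def _gene_name(i: int) -> str:
    return f"G{i:06d}"


def generate_network(spec: SynthSpec) -> tuple[Network, GeneSetCollection, dict]:
    """Realize a synthetic network, its planted pathways, and a manifest.

    Background edges follow the chosen model; within each planted module
    every gene pair is additionally linked with probability p_in, and
    every (module gene, outside gene) pair with probability p_out. The
    manifest records the generating parameters, realized edge counts, and the expected
    within-module edge count C(size, 2)·p_in per module.
    """
    n = spec.n_genes
    bg_seed = int(np.random.SeedSequence([spec.seed, _OFF_BACKGROUND]).generate_state(1)[0])
    if spec.background_model == "scale_free":
        g = nx.barabasi_albert_graph(n, spec.m_attach, seed=bg_seed)
    else:
        g = nx.fast_gnp_random_graph(n, spec.p_bg, seed=bg_seed)
    edges = {(min(u, v), max(u, v)) for u, v in g.edges()}
    n_background = len(edges)

    mod_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _OFF_MODULES]))
    perm = mod_rng.permutation(n)
    pathways: list[GeneSet] = []
    module_stats = []
    cursor = 0
    all_idx = np.arange(n)
    for j, (size, p_in) in enumerate(spec.modules):
        block = np.sort(perm[cursor:cursor + size])
        cursor += size
        iu, ju = np.triu_indices(size, k=1)
        hit = mod_rng.random(iu.shape[0]) < p_in
        internal = 0
        for a, b in zip(block[iu[hit]], block[ju[hit]]):
            pair = (int(min(a, b)), int(max(a, b)))
            if pair not in edges:
                edges.add(pair)
            internal += 1
        outside = np.setdiff1d(all_idx, block, assume_unique=False)
        if spec.p_out > 0 and outside.size:
            n_pairs = size * outside.size
            hits = np.nonzero(mod_rng.random(n_pairs) < spec.p_out)[0]
            mi = block[hits // outside.size]
            oi = outside[hits % outside.size]
            for a, b in zip(mi, oi):
                edges.add((int(min(a, b)), int(max(a, b))))
        module_id = f"M{j + 1:02d}"
        pathways.append(GeneSet(
            id=module_id,
            name=f"planted module {j + 1} (size={size}, p_in={p_in})",
            members=frozenset(_gene_name(i) for i in block),
        ))
        module_stats.append({
            "id": module_id,
            "size": size,
            "p_in": p_in,
            "realized_internal_trials": internal,
            "expected_internal_edges": comb(size, 2) * p_in,
        })

    genes = [_gene_name(i) for i in range(n)]
    network = Network(
        ((_gene_name(a), _gene_name(b)) for a, b in edges),
        genes=genes,
    )
    manifest = {
        "n_genes": n,
        "background_model": spec.background_model,
        "p_bg": spec.p_bg,
        "m_attach": spec.m_attach,
        "p_out": spec.p_out,
        "seed": spec.seed,
        "n_edges": network.n_edges,
        "n_background_edges": n_background,
        "modules": module_stats,
    }
    return network, GeneSetCollection(pathways), manifest


def generate_query(
    mode: str,
    size: int,
    network: Network,
    pathways: GeneSetCollection | None = None,
    pathway_id: str | None = None,
    fraction: float | None = None,
    rng: np.random.Generator | int | None = None,
    query_id: str = "query",
) -> GeneSet:
    """Draw a random or pathway-enriched query gene set.

    ``mode="random"`` samples ``size`` distinct network genes uniformly.
    ``mode="enriched"`` takes ⌈fraction·size⌉ genes from the named planted
    pathway and the remainder from outside it, producing a positive
    control with tunable signal strength.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if size > network.n_genes:
        raise ValueError("query size exceeds the network universe")
    genes = np.array(network.genes)
    if mode == "random":
        chosen = rng.choice(genes, size=size, replace=False)
    elif mode == "enriched":
        if pathways is None or pathway_id is None or fraction is None:
            raise ValueError("enriched mode needs pathways, pathway_id and fraction")
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        members = sorted(pathways[pathway_id].network_members(network))
        n_in = ceil(fraction * size)
        if n_in > len(members):
            raise ValueError(
                f"pathway {pathway_id!r} has only {len(members)} network genes, "
                f"need {n_in} for the enriched portion"
            )
        outside = np.array(sorted(set(network.genes) - set(members)))
        if size - n_in > outside.size:
            raise ValueError("not enough genes outside the pathway")
        inside = rng.choice(np.array(members), size=n_in, replace=False) if n_in else np.array([])
        rest = rng.choice(outside, size=size - n_in, replace=False)
        chosen = np.concatenate([inside, rest])
    else:
        raise ValueError(f"unknown query mode {mode!r}")
    return GeneSet(id=query_id, name=query_id, members=frozenset(str(x) for x in chosen))


def write_fixture(
    spec: SynthSpec,
    outdir: str | Path,
    n_random_queries: int = 10,
    query_size: int = 110,
    enriched_fraction: float = 0.5,
) -> dict[str, Path]:
    """Write a complete text fixture: network, pathways, queries, manifest.

    Queries are ``n_random_queries`` random sets plus one enriched set per
    planted module at ``enriched_fraction``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network, pathways, manifest = generate_network(spec)
    qrng = np.random.default_rng(np.random.SeedSequence([spec.seed, _OFF_QUERIES]))
    queries = [
        generate_query("random", query_size, network, rng=qrng, query_id=f"RND{i + 1:03d}")
        for i in range(n_random_queries)
    ]
    for pw in pathways:
        queries.append(generate_query(
            "enriched", query_size, network, pathways=pathways, pathway_id=pw.id,
            fraction=enriched_fraction, rng=qrng, query_id=f"ENR_{pw.id}",
        ))
    paths = {
        "network": outdir / "network.tsv",
        "pathways": outdir / "pathways.gmt",
        "queries": outdir / "queries.gmt",
        "manifest": outdir / "manifest.json",
    }
    network.write_edge_list(paths["network"])
    pathways.write_gmt(paths["pathways"])
    GeneSetCollection(queries).write_gmt(paths["queries"])
    manifest = dict(manifest)
    manifest["queries"] = {
        "n_random": n_random_queries,
        "query_size": query_size,
        "enriched_fraction": enriched_fraction,
    }
    with paths["manifest"].open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
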