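"""Evaluation protocols: false positives, true positives, stability, topology.

The FP benchmark tests many random gene sets against every pathway — for a
calibrated test ~5% of p-values should fall below 0.05 for each pathway,
and the p-value distribution should be uniform up to the discreteness of
the statistic. The TP benchmark bisects each pathway into two halves with
similar gene and link counts (optionally sharing an emulated overlap) and
asks whether the test reconnects them. Stability analysis measures the
coefficient of variation of the null mean across regenerated nulls to
decide how many random samples are enough. Topology diagnostics
(intralink fraction, maximal cliques, pairwise overlap) characterize how
community-like each pathway is — the property that breaks methods whose
null treats pathways as random gene sets.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .crosstalk import count_crosstalk, observe, pathway_degree_array
from .io import GeneSet, GeneSetCollection, Network, map_query
from .inference import bh_adjust, mid_p_from_fit
from .null_model import (
    BetaBinomialFit,
    NullModelStore,
    betabinom_logpmf,
    fit_beta_binomial,
    sample_index_sets,
    sample_null,
)

logger = logging.getLogger(__name__)

__all__ = [
    "fp_benchmark",
    "bisect_pathway",
    "emulate_overlap",
    "tp_benchmark",
    "roc_points",
    "roc_auc",
    "stability_analysis",
    "intralink_fraction",
    "count_maximal_cliques",
    "pairwise_overlap",
]


def _subseed(seed: int, tag: str, *extra: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), zlib.crc32(tag.encode()), *extra])


def midp_batch(ks: np.ndarray, ns: np.ndarray, fit: BetaBinomialFit) -> np.ndarray:
    """Vectorized mid p-values for many (k, n) observations under one fit.

    Observations share fitted (α, β) but may differ in n (the observed
    overlap varies); the pmf and its tail are computed once per distinct n.
    """
    ks = np.asarray(ks, dtype=np.int64)
    ns = np.asarray(ns, dtype=np.int64)
    out = np.empty(ks.shape[0], dtype=np.float64)
    if fit.fallback == "binomial":
        out = sps.binom.sf(ks, ns, fit.p_hat) + 0.5 * sps.binom.pmf(ks, ns, fit.p_hat)
    elif fit.fallback == "empirical":
        counts = fit.sample.counts
        m = counts.shape[0]
        out = (counts[None, :] > ks[:, None]).mean(axis=1) + 0.5 * (
            counts[None, :] == ks[:, None]
        ).mean(axis=1)
        return np.clip(out, 1.0 / (2 * m), 1.0 - 1e-16)
    else:
        for n in np.unique(ns):
            sel = ns == n
            pmf = np.exp(betabinom_logpmf(np.arange(n + 1), int(n), fit.alpha, fit.beta))
            # sf_excl[k] = P(X > k); mid = sf_excl[k] + pmf[k]/2
            sf_excl = np.concatenate([np.cumsum(pmf[::-1])[::-1][1:], [0.0]])
            kk = ks[sel]
            out[sel] = sf_excl[kk] + 0.5 * pmf[kk]
    return np.clip(out, 1e-300, 1.0 - 1e-16)


# ---------------------------------------------------------------------------
# False-positive benchmark
# ---------------------------------------------------------------------------

def fp_benchmark(
    network: Network,
    pathways: GeneSetCollection,
    n_sets: int = 10000,
    set_size: int = 110,
    m: int = 2000,
    seed: int = 0,
    alpha_level: float = 0.05,
    fdr_level: float = 0.05,
    universe: str = "network",
    store: NullModelStore | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-pathway false-positive rates for random query gene sets.

    Draws ``n_sets`` random sets of ``set_size`` network genes, tests each
    against every pathway, and records per pathway the fraction of mid
    p-values below ``alpha_level`` (the FPR), the fraction significant
    after per-query BH correction, and the KS distance of the p-values to
    U(0,1) — a descriptive uniformity statistic; mid-p discreteness makes
    a strict KS test inappropriate. Pathways with no links at all are
    flagged untestable and excluded from the summary.

    Returns ``(rows, summary)``; summary includes the grand-mean FPR.
    """
    if set_size > network.n_genes:
        raise ValueError("set_size exceeds the network universe")
    pathway_list = list(pathways)
    columns = ["pathway_id", "n_tests", "fpr", "fpr_fdr", "uniformity_stat", "testable"]
    if n_sets == 0 or not pathway_list:
        return pd.DataFrame(columns=columns), {
            "n_sets": n_sets, "set_size": set_size, "mean_fpr": float("nan")
        }
    if store is None:
        store = NullModelStore(network, m=m, seed=seed, universe=universe)
    rng = np.random.default_rng(_subseed(seed, "fp_queries"))
    idx = sample_index_sets(rng, network.n_genes, set_size, n_sets)

    rows = []
    pmat: dict[str, np.ndarray] = {}
    for pw in pathway_list:
        p_net = pw.network_members(network)
        d = pathway_degree_array(network, p_net)
        if d.sum() == 0:
            logger.warning("pathway %s has no incident links; untestable", pw.id)
            rows.append({
                "pathway_id": pw.id, "n_tests": 0, "fpr": float("nan"),
                "fpr_fdr": float("nan"), "uniformity_stat": float("nan"),
                "testable": False,
            })
            continue
        mask = network.member_mask(p_net)
        k = d[idx].sum(axis=1)
        ov = mask[idx].sum(axis=1)
        n_obs = set_size * len(p_net) - ov
        _, fit = store.get(pw, set_size)
        ps = midp_batch(k, n_obs, fit)
        pmat[pw.id] = ps
        rows.append({
            "pathway_id": pw.id,
            "n_tests": n_sets,
            "fpr": float((ps < alpha_level).mean()),
            "fpr_fdr": float("nan"),  # filled below
            "uniformity_stat": float(sps.kstest(ps, "uniform").statistic),
            "testable": True,
        })

    # Per-query BH across testable pathways (the single-submission scenario).
    if pmat:
        ids = list(pmat)
        pall = np.column_stack([pmat[i] for i in ids])  # (n_sets, n_pathways)
        qall = np.empty_like(pall)
        for i in range(pall.shape[0]):
            qall[i] = bh_adjust(pall[i])
        fdr_rate = (qall < fdr_level).mean(axis=0)
        per_id = dict(zip(ids, fdr_rate))
        for row in rows:
            if row["testable"]:
                row["fpr_fdr"] = float(per_id[row["pathway_id"]])

    df = pd.DataFrame(rows, columns=columns)
    testable = df[df["testable"]]
    summary = {
        "n_sets": n_sets,
        "set_size": set_size,
        "m": store.m,
        "seed": seed,
        "alpha_level": alpha_level,
        "fdr_level": fdr_level,
        "n_pathways": len(pathway_list),
        "n_testable": int(len(testable)),
        "mean_fpr": float(testable["fpr"].mean()) if len(testable) else float("nan"),
        "mean_fpr_fdr": float(testable["fpr_fdr"].mean()) if len(testable) else float("nan"),
    }
    return df, summary


# ---------------------------------------------------------------------------
# True-positive (bisection) benchmark
# ---------------------------------------------------------------------------

def _internal_links(members: set[str], network: Network) -> int:
    return sum(
        1
        for g in members
        for nb in network.neighbors(g)
        if nb in members and g < nb
    )


def bisect_pathway(
    pathway: GeneSet,
    network: Network,
    rng: np.random.Generator | int | None = None,
    max_swaps: int = 200,
) -> tuple[GeneSet, GeneSet]:
    """Split a pathway into two parts with similar gene and link counts.

    Starts from a random balanced split (size difference ≤ 1) of the
    pathway's network genes, then greedily swaps single gene pairs between
    the parts whenever the swap reduces the absolute difference in
    within-part link counts, for at most ``max_swaps`` attempts. The
    result is deterministic given the seed and locally minimal: no single
    accepted swap could further reduce the link imbalance when the
    hill-climb stops early.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    members = sorted(pathway.network_members(network))
    if len(members) < 4:
        raise ValueError(f"pathway {pathway.id!r} has fewer than 4 network genes")
    perm = rng.permutation(len(members))
    half = (len(members) + 1) // 2
    part1 = {members[i] for i in perm[:half]}
    part2 = {members[i] for i in perm[half:]}
    l1 = _internal_links(part1, network)
    l2 = _internal_links(part2, network)
    p1_sorted, p2_sorted = sorted(part1), sorted(part2)
    for _ in range(max_swaps):
        if abs(l1 - l2) == 0:
            break
        u = p1_sorted[rng.integers(len(p1_sorted))]
        v = p2_sorted[rng.integers(len(p2_sorted))]
        nu, nv = network.neighbors(u), network.neighbors(v)
        a_uv = 1 if v in nu else 0
        d1u = len(nu & part1)  # u not its own neighbor (zero diagonal)
        d1v = len(nv & part1)
        d2v = len(nv & part2)
        d2u = len(nu & part2)
        new_l1 = l1 - d1u + d1v - a_uv
        new_l2 = l2 - d2v + d2u - a_uv
        if abs(new_l1 - new_l2) < abs(l1 - l2):
            part1.remove(u); part1.add(v)
            part2.remove(v); part2.add(u)
            l1, l2 = new_l1, new_l2
            p1_sorted, p2_sorted = sorted(part1), sorted(part2)
    return (
        GeneSet(id=f"{pathway.id}::part1", name=f"{pathway.name} (part 1)",
                members=frozenset(part1)),
        GeneSet(id=f"{pathway.id}::part2", name=f"{pathway.name} (part 2)",
                members=frozenset(part2)),
    )


def emulate_overlap(
    part1: GeneSet,
    part2: GeneSet,
    overlap_count: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[GeneSet, GeneSet]:
    """Copy ``overlap_count`` random genes of part2 into part1.

    Membership is only added, never removed, so part2 — the "pathway"
    side of the reunification test — stays intact, and the parts end up
    sharing exactly ``overlap_count`` genes.
    """
    if overlap_count < 0 or overlap_count > min(len(part1), len(part2)):
        raise ValueError("infeasible overlap_count")
    if overlap_count == 0:
        return part1, part2
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pool = sorted(part2.members - part1.members)
    already = len(part2.members & part1.members)
    need = overlap_count - already
    if need > len(pool):
        raise ValueError("infeasible overlap_count")
    chosen = rng.choice(pool, size=need, replace=False) if need > 0 else []
    return (
        GeneSet(id=part1.id, name=part1.name,
                members=part1.members | frozenset(chosen)),
        part2,
    )


def tp_benchmark(
    network: Network,
    pathways: GeneSetCollection,
    overlap_table: dict[str, int] | None = None,
    m: int = 2000,
    seed: int = 0,
    fdr_level: float = 0.05,
    min_size: int = 4,
    universe: str = "network",
) -> tuple[pd.DataFrame, dict]:
    """Pathway-bisection true-positive benchmark.

    Each pathway is bisected into halves with similar gene/link counts;
    after adding the emulated overlap (default 0), part 1 is run as the
    query against part 2 as the pathway through the full pipeline. A true
    positive is a reunification test significant at FDR < ``fdr_level``
    (BH across all bisection tests). Too-small pathways are skipped and
    logged.
    """
    overlap_table = overlap_table or {}
    store = NullModelStore(network, m=m, seed=seed, universe=universe)
    rows = []
    for pw in pathways:
        if len(pw.network_members(network)) < min_size:
            logger.info("pathway %s too small to bisect; skipped", pw.id)
            continue
        rng = np.random.default_rng(_subseed(seed, pw.id, 0xB15EC7))
        part1, part2 = bisect_pathway(pw, network, rng=rng)
        ov = int(overlap_table.get(pw.id, 0))
        part1, part2 = emulate_overlap(part1, part2, ov, rng=rng)
        mq = map_query(part1, network)
        obs = observe(mq, part2, network, universe=universe)
        _, fit = store.get(part2, mq.size)
        p = mid_p_from_fit(obs.k, obs.n, fit)
        rows.append({
            "pathway_id": pw.id,
            "part1_size": len(part1.members),
            "part2_size": len(part2.members),
            "part1_links": _internal_links(set(part1.members), network),
            "part2_links": _internal_links(set(part2.members), network),
            "overlap_emulated": ov,
            "k": obs.k,
            "n": obs.n,
            "p_value": p,
        })
    df = pd.DataFrame(rows, columns=[
        "pathway_id", "part1_size", "part2_size", "part1_links", "part2_links",
        "overlap_emulated", "k", "n", "p_value",
    ])
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        tpr = float((df["q_value"] < fdr_level).mean())
    else:
        df["q_value"] = pd.Series(dtype=float)
        tpr = float("nan")
    summary = {
        "n_pathways": len(df),
        "m": m,
        "seed": seed,
        "fdr_level": fdr_level,
        "tpr": tpr,
    }
    return df, summary


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_points(tp_pvalues, fp_pvalues) -> np.ndarray:
    """ROC curve from TP and FP p-value pools.

    Sweeps the significance threshold over the union of observed p-values;
    returns an (n, 2) array of (FPR, TPR) points, starting at (0, 0) and
    ending at (1, 1), non-decreasing in both coordinates.
    """
    tp = np.asarray(tp_pvalues, dtype=np.float64)
    fp = np.asarray(fp_pvalues, dtype=np.float64)
    if tp.size == 0 or fp.size == 0:
        raise ValueError("both p-value pools must be non-empty")
    thresholds = np.unique(np.concatenate([tp, fp]))
    pts = [(0.0, 0.0)]
    for t in thresholds:
        pts.append((float((fp <= t).mean()), float((tp <= t).mean())))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return np.array(pts)


def roc_auc(points: np.ndarray) -> float:
    """Trapezoidal area under an ROC curve from :func:`roc_points`."""
    pts = np.asarray(points, dtype=np.float64)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


# ---------------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------------

def stability_analysis(
    network: Network,
    pathways: GeneSetCollection,
    query: GeneSet,
    sample_sizes: list[int],
    reps: int = 100,
    seed: int = 0,
    cv_threshold: float = 0.02,
    universe: str = "network",
) -> tuple[pd.DataFrame, dict]:
    """Sampling stability of the null mean and of the resulting p-values.

    For each pathway and each null sample count m, the null distribution
    is regenerated ``reps`` times; CV = SD/mean of the per-replicate null
    means measures how stable the null is, and the SD of log(mid p) across
    replicates measures how much the reported p-value moves between runs.
    The summary gives, per m, the fraction of pathways with CV below the
    threshold (2% by default).
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    mq = map_query(query, network)
    rows = []
    for pw in pathways:
        p_net = pw.network_members(network)
        if not p_net:
            logger.warning("pathway %s has no network members; skipped", pw.id)
            continue
        obs = observe(mq, pw, network, universe=universe)
        for m in sample_sizes:
            means = np.empty(reps)
            logps = np.empty(reps)
            for r in range(reps):
                rng = np.random.default_rng(_subseed(seed, pw.id, int(m), r))
                samp = sample_null(network, pw, mq.size, m=int(m), rng=rng, universe=universe)
                fit = fit_beta_binomial(samp)
                means[r] = samp.mean()
                logps[r] = np.log(mid_p_from_fit(obs.k, obs.n, fit))
            grand = means.mean()
            cv = float(means.std(ddof=1) / grand) if grand > 0 else float("nan")
            rows.append({
                "pathway_id": pw.id,
                "n_samples": int(m),
                "cv": cv,
                "sd_log_midp": float(logps.std(ddof=1)),
            })
    df = pd.DataFrame(rows, columns=["pathway_id", "n_samples", "cv", "sd_log_midp"])
    frac = {}
    for m in sample_sizes:
        sub = df[df["n_samples"] == int(m)]["cv"].dropna()
        frac[int(m)] = float((sub < cv_threshold).mean()) if len(sub) else float("nan")
    summary = {
        "reps": reps,
        "seed": seed,
        "cv_threshold": cv_threshold,
        "fraction_below_threshold": frac,
    }
    return df, summary


# ---------------------------------------------------------------------------
# Pathway-topology diagnostics
# ---------------------------------------------------------------------------

def intralink_fraction(pathway: GeneSet, network: Network) -> float:
    """Internal edges over all edges touching the pathway (NaN if isolated).

    High values mean the pathway behaves like an isolated community — the
    regime where random-gene-set null models are most miscalibrated.
    """
    members = pathway.network_members(network)
    internal = 0
    incident = 0
    for g in members:
        for nb in network.neighbors(g):
            if nb in members:
                if g < nb:
                    internal += 1
                    incident += 1
            else:
                incident += 1
    if incident == 0:
        return float("nan")
    return internal / incident


def count_maximal_cliques(pathway: GeneSet, network: Network, min_size: int = 1) -> int:
    """Number of maximal cliques of the pathway's induced subgraph.

    Uses Bron–Kerbosch enumeration (networkx). Isolated vertices count as
    maximal 1-cliques by default; ``min_size=2`` restricts to cliques with
    at least one edge.
    """
    import networkx as nx

    g = network.to_networkx(pathway.members)
    if g.number_of_nodes() == 0:
        return 0
    return sum(1 for c in nx.find_cliques(g) if len(c) >= min_size)


def pairwise_overlap(pathways: GeneSetCollection) -> pd.DataFrame:
    """Shared fraction of the union, |A∩B|/|A∪B|, per unordered pair."""
    sets = list(pathways)
    if len(sets) < 2:
        raise ValueError("need at least 2 gene sets")
    rows = []
    for a, b in itertools.combinations(sets, 2):
        union = a.members | b.members
        shared = len(a.members & b.members) / len(union) if union else 0.0
        rows.append({"id1": a.id, "id2": b.id, "shared_fraction_of_union": shared})
    return pd.DataFrame(rows, columns=["id1", "id2", "shared_fraction_of_union"])
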