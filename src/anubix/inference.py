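"""Mid p-values, FDR correction, and the enrichment result table.

The test is one-tailed for enrichment only: H0 is "no more links between
Q and P than expected by chance", H1 "more links than expected". Because
the null is discrete, ordinary p-values are conservative; the mid p-value
— half the probability of the observed statistic plus the probability of
more extreme values, P(X > k) + ½·P(X = k) — is used instead. Tail sums
are exact over the discrete support; no normal approximation is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .crosstalk import observe
from .io import GeneSet, GeneSetCollection, MappedQuery, Network, map_query
from .null_model import BetaBinomialFit, NullModelStore, betabinom_logpmf

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "mid_p_value",
    "mid_p_binomial",
    "mid_p_empirical",
    "mid_p_from_fit",
    "bh_adjust",
    "run_anubix",
    "pvalue_confidence_interval",
    "RESULT_COLUMNS",
]

#: Output column order of the result table.
RESULT_COLUMNS = [
    "query_id", "pathway_id", "k", "n", "overlap",
    "alpha", "beta", "mid_p", "q_value", "flags",
]

_MIDP_FLOOR = 1e-300
_MIDP_CEIL = 1.0 - 1e-16


@dataclass(frozen=True)
class EnrichmentResult:
    """One (query, pathway) enrichment test result."""

    query_id: str
    pathway_id: str
    k: int
    n: int
    overlap: int
    alpha: float
    beta: float
    mid_p: float
    q_value: float
    flags: frozenset[str]


def _clip_p(p: float) -> float:
    return float(min(max(p, _MIDP_FLOOR), _MIDP_CEIL))


def mid_p_value(k_obs: int, n: int, alpha: float, beta: float) -> float:
    """Mid p-value under BetaBinom(n, α, β): P(X > k) + ½·P(X = k).

    The tail is summed exactly over the discrete support k_obs..n.
    """
    if not 0 <= k_obs <= n:
        raise ValueError(f"k_obs={k_obs} outside [0, n={n}]")
    pmf = np.exp(betabinom_logpmf(np.arange(k_obs, n + 1), n, alpha, beta))
    return _clip_p(float(pmf[1:].sum() + 0.5 * pmf[0]))


def mid_p_binomial(k_obs: int, n: int, p: float) -> float:
    """Mid p-value under Binomial(n, p) — the α+β→∞ limit of the null."""
    if not 0 <= k_obs <= n:
        raise ValueError(f"k_obs={k_obs} outside [0, n={n}]")
    return _clip_p(float(stats.binom.sf(k_obs, n, p) + 0.5 * stats.binom.pmf(k_obs, n, p)))


def mid_p_empirical(k_obs: int, counts: np.ndarray) -> float:
    """Mid p-value against the raw null sample itself.

    Used when the sample is degenerate (zero variance) and no parametric
    fit exists. An m-draw empirical null cannot resolve probabilities
    below half a count, so the floor is 1/(2m).
    """
    counts = np.asarray(counts)
    m = counts.shape[0]
    p = float((counts > k_obs).mean() + 0.5 * (counts == k_obs).mean())
    return float(min(max(p, 1.0 / (2 * m)), _MIDP_CEIL))


def mid_p_from_fit(k_obs: int, n: int, fit: BetaBinomialFit) -> float:
    """Dispatch the mid p-value on the fit's fallback mode."""
    if fit.fallback == "empirical":
        if fit.sample is None:
            raise ValueError("empirical fallback requires the fit to carry its sample")
        return mid_p_empirical(k_obs, fit.sample.counts)
    if fit.fallback == "binomial":
        return mid_p_binomial(k_obs, n, fit.p_hat)
    return mid_p_value(k_obs, n, fit.alpha, fit.beta)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_anubix(
    queries: GeneSetCollection | Iterable[GeneSet],
    pathways: GeneSetCollection | Iterable[GeneSet],
    network: Network,
    m: int = 2000,
    seed: int = 0,
    correction_scope: str = "per_query",
    universe: str = "network",
    store: NullModelStore | None = None,
) -> pd.DataFrame:
    """Full crosstalk enrichment of every query against every pathway.

    For each pair: map the query onto the network, count observed and
    possible links, fetch (or build) the cached beta-binomial null at the
    mapped query size, and compute the mid p-value. BH correction is
    applied per query (default — each query is an independent submission
    corrected over the pathways it is compared to) or globally.

    Returns a DataFrame with columns :data:`RESULT_COLUMNS`, sorted by
    (query_id, mid_p). Queries with no network support are skipped with a
    warning; pathways with no network members are skipped likewise.
    """
    if correction_scope not in ("per_query", "global"):
        raise ValueError(f"unknown correction scope {correction_scope!r}")
    queries = list(queries)
    pathway_list = list(pathways)
    if store is None:
        store = NullModelStore(network, m=m, seed=seed, universe=universe)

    usable_pathways = []
    for p in pathway_list:
        if p.network_members(network):
            usable_pathways.append(p)
        else:
            logger.warning("pathway %s has no network members; skipped", p.id)

    rows: list[EnrichmentResult] = []
    for q in queries:
        try:
            mq = map_query(q, network)
        except ValueError:
            logger.warning("query %s has no network support; skipped", q.id)
            continue
        low_support = mq.size < max(5, len(q.members) // 2)
        for p in usable_pathways:
            obs = observe(mq, p, network, universe=store.universe)
            _, fit = store.get(p, mq.size)
            midp = mid_p_from_fit(obs.k, obs.n, fit)
            flags = set()
            if fit.degenerate:
                flags.add("degenerate")
            if fit.fallback == "binomial":
                flags.add("binomial_fallback")
            if low_support:
                flags.add("low_support")
            rows.append(EnrichmentResult(
                query_id=q.id, pathway_id=p.id, k=obs.k, n=obs.n, overlap=obs.overlap,
                alpha=fit.alpha, beta=fit.beta, mid_p=midp, q_value=float("nan"),
                flags=frozenset(flags),
            ))

    df = pd.DataFrame(
        [{
            "query_id": r.query_id, "pathway_id": r.pathway_id, "k": r.k, "n": r.n,
            "overlap": r.overlap, "alpha": r.alpha, "beta": r.beta, "mid_p": r.mid_p,
            "q_value": r.q_value, "flags": ",".join(sorted(r.flags)),
        } for r in rows],
        columns=RESULT_COLUMNS,
    )
    if len(df):
        if correction_scope == "per_query":
            df["q_value"] = df.groupby("query_id", sort=False)["mid_p"].transform(
                lambda p: bh_adjust(p.to_numpy())
            )
        else:
            df["q_value"] = bh_adjust(df["mid_p"].to_numpy())
        df = df.sort_values(["query_id", "mid_p"], kind="mergesort").reset_index(drop=True)
    return df


def pvalue_confidence_interval(
    replicate_mid_ps: Sequence[float] | np.ndarray,
    level: float = 0.95,
) -> tuple[float, float]:
    """Normal-theory confidence interval for a sampled p-value.

    P-values from sampled nulls are point estimates; across R independent
    null regenerations the interval is mean ± z·SD/√R by the central limit
    theorem. When all replicates are positive the interval is computed on
    log(p) and back-transformed (p-value spread is proportional to the
    p-value's magnitude); otherwise on the linear scale. Clipped to [0, 1].
    """
    ps = np.asarray(replicate_mid_ps, dtype=np.float64)
    if ps.size < 2:
        raise ValueError("need at least 2 replicates")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    r = ps.size
    if np.all(ps > 0):
        x = np.log(ps)
        half = z * x.std(ddof=1) / np.sqrt(r)
        lo, hi = np.exp(x.mean() - half), np.exp(x.mean() + half)
    else:
        half = z * ps.std(ddof=1) / np.sqrt(r)
        lo, hi = ps.mean() - half, ps.mean() + half
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))
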