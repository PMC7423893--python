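# Methods

## Statistic and null model

The crosstalk between a query gene set Q and a pathway P over an
undirected, unweighted network is the ordered-pair link count
k = Σ_{i∈Q} Σ_{j∈P} a_ij. Counting ordered pairs means an edge whose two
endpoints both lie in Q∩P contributes twice — overlap between query and
pathway deliberately boosts the statistic — while the zero diagonal
(a_ii = 0) removes self-pairs, giving n = |Q||P| − |Q∩P| possible links.

The null hypothesis is that Q has no more links to P than a random gene
set of the same size. Rather than deriving the null analytically from a
randomness assumption about P (which real pathways violate badly), the
null is *sampled*: m random sets of |Q| distinct genes are drawn
uniformly from the network universe and their crosstalk to the intact
pathway recorded. Draws may include pathway genes; the resulting overlap
is double-counted exactly as in the observed statistic, so null and
observation live on the same scale.

If every gene pair carried an independent, equal link probability, the
counts would be binomial in n. They are not: pathway members have very
unequal degrees, and a random draw either hits or misses the few
high-degree genes, inflating the variance. On the default synthetic
fixture the variance/mean ratio of a planted-module null is ~9–10; the
package's dispersion diagnostic shows values above 1 for essentially
every structured pathway. The null is therefore fitted with the
beta-binomial

f(k | n, α, β) = C(n, k) · B(k+α, n−k+β) / B(α, β),

a binomial whose success probability is Beta(α, β)-distributed. Its
variance exceeds the binomial's by the factor (α+β+n)/(α+β+1) ≥ 1, and
it reduces to the binomial as α+β → ∞, so the fit adapts per pathway to
however much overdispersion the sampling reveals. A plain binomial fit
(p̂ = mean/n) is retained as the diagnostic baseline that shows *why*
the flexible family is needed.

## Maximum-likelihood fitting

The log-likelihood of a sample k₁..k_m is, per observation,

log C(n,k) + logΓ(α+k) + logΓ(β+n−k) − logΓ(α+β+n)
− logΓ(α) − logΓ(β) + logΓ(α+β);

the binomial-coefficient term does not depend on (α, β) and is dropped
from the objective. The negative log-likelihood is minimized by
Nelder–Mead in (log α, log β) — the log parameterization enforces
positivity without constraints — with convergence tolerance 1e-8 on both
the objective and the simplex, and at most 2000 iterations. The starting
point is the method of moments: with sample mean m̄ and variance v,
p₀ = m̄/n, ρ₀ = clamp((v/(n·p₀(1−p₀)) − 1)/(n−1), 1e-6, 1−1e-6),
α₀ = p₀(1−ρ₀)/ρ₀, β₀ = (1−p₀)(1−ρ₀)/ρ₀. Everything is evaluated in
log-gamma space; non-finite objective values are returned as +inf so the
simplex retreats.

Failure modes are encoded in flags, never raised:

- **Zero-variance sample** (e.g. a pathway with no links, or a draw size
  equal to the universe): the fit is degenerate and p-values fall back
  to the empirical distribution itself. An m-draw empirical null cannot
  resolve probabilities below half a count, so these p-values are
  floored at 1/(2m) rather than the generic 1e-300 floor.
- **Binomial limit**: when the fitted α̂+β̂ exceeds 1e7 the two families
  are numerically indistinguishable and the binomial at p̂ is used. In
  addition, because a finite sample from a true binomial is frequently a
  little overdispersed by chance — yielding large-but-finite MLEs that
  never reach any fixed cap — the binomial limit is also declared when
  the beta-binomial's likelihood gain over the binomial at p̂ is small:
  2·(ll_bb − ll_bin) < 3.84, the conventional χ²₁ 5% critical value
  (conservative here, since the boundary null is the mixture
  ½χ²₀ + ½χ²₁). Genuinely overdispersed pathway nulls exceed this by
  orders of magnitude, so the guard only fires when the two models are
  practically equivalent.

## P-values and correction

The mid p-value P(X > k) + ½·P(X = k) is used because ordinary p-values
on a discrete support are conservative (the observed atom's full mass
makes them stochastically larger than uniform). The tail is summed
exactly over the support — n is at most ~10⁵ in practice, so no normal
approximation is needed — and floored at 1e-300 and capped just below 1
so that log transforms are always defined. The test is one-tailed for
enrichment only; depletion is out of scope.

Two n's appear, deliberately. The fitted null uses the overlap-free
n = |Q|·|P|: each random draw has its own (tiny, variable) overlap with
the pathway, and in a universe of thousands of genes the expected
overlap is a fraction of a percent of n. The observed statistic uses the
per-observation n = |Q||P| − |Q∩P|. Both conventions are recorded in the
output so the discrepancy is auditable; it moves the tail probability
negligibly (n changes by parts in 10³ at most for realistic overlaps).

Pathways are intersected with the network universe before counting and
|P| is the post-intersection size (`universe="network"`, the default):
genes without links cannot carry crosstalk, and retaining them would
deflate the null mean relative to the observation. `universe="full"`
keeps the full pathway size for users who prefer the raw annotation.

Multiple testing uses Benjamini–Hochberg step-up q-values (via
statsmodels), by default *per query* — each query is treated as an
independent submission corrected over the pathways it is compared to,
the single-user scenario — with a `global` mode for batch studies.
Confidence intervals for sampled p-values across R null regenerations
use the central limit theorem, computed on log(p) and back-transformed
when all replicates are positive (p-value spread scales with p-value
magnitude), linear otherwise, clipped to [0, 1].

Null samples and fits are cached per (pathway, query size) within a run.
Each cache entry derives its RNG stream from the master seed, a CRC of
the pathway id, and the set size, so results are independent of
evaluation order and safely parallelizable.

## Benchmarks

- **False positives**: n_sets random query sets (default 10,000 of size
  110, the scale used for full studies; tests use hundreds to low
  thousands) are tested against every pathway. Per pathway the FPR is
  the raw fraction of mid p-values below 0.05; FDR-based rates after
  per-query BH are reported separately, as is the KS distance to U(0,1)
  — a descriptive uniformity statistic only, since mid-p discreteness
  staggers the attainable values. Pathways with no incident links are
  flagged untestable and excluded from summaries.
- **True positives**: each pathway is bisected into halves with similar
  gene and link counts, optionally given an emulated membership overlap,
  and half 1 is run as the query against half 2; a TP is a
  reunification significant at FDR < 0.05. The bisection algorithm is a
  random balanced split refined by a greedy single-swap hill-climb on
  the absolute within-part link-count difference (at most 200 attempts,
  stopping early at perfect balance); it is deterministic given the
  seed. Overlap emulation adds shared genes to the query half without
  removing any from the pathway half, which must stay a real pathway
  fragment.
- **Stability**: for each pathway and each null size m the null is
  regenerated `reps` times; CV = SD/mean of the null means quantifies
  sampling noise (it scales as the null SD over mean times 1/√m), and
  the SD of log mid-p across replicates shows how much reported
  p-values move. The default operating point, m = 2000, puts the
  fixture pathways' CV well under the 2% working threshold.
- **Topology diagnostics**: intralink fraction (edges inside the pathway
  over edges touching it), maximal-clique counts of the induced subgraph
  (Bron–Kerbosch via networkx; isolated vertices count as 1-cliques by
  default, restrictable to size ≥ 2), and pairwise Jaccard overlap
  between pathways. These quantify the "pathways are communities, not
  random sets" premise and correlate with the miscalibration of
  binomial-style nulls.

## Synthetic data

The generator plants densely connected modules in a background graph:
scale-free (Barabási–Albert, 3 attachments per node) or Erdős–Rényi
background, then each within-module pair linked with p_in and each
module–outside pair with p_out on top of the background. The default
fixture — 2000 genes, ten 80-gene modules, p_in = 0.25, p_out = 0.005 —
mimics the relevant features of real pathway/network data at desk scale:
pathway-sized modules, heavy-tailed background degrees, and strongly
overdispersed pathway nulls (var/mean ≈ 9 on the first planted module).
Module sizes and the 110-gene query size match typical curated-pathway
and experimental-gene-list sizes. Each artifact (background, module
edges, query batches) draws from its own RNG stream at a fixed offset
from the master seed, so any one of them can be regenerated alone.

What the generator does *not* emulate: correlated pathway membership
(real pathway databases share large gene fractions), annotation noise,
degree–pathway correlations beyond what preferential attachment gives,
or weighted/directed evidence. Passing the synthetic benchmarks
therefore demonstrates the statistical machinery is correct and
calibrated under controlled overdispersion, not that any particular
biological database is well modelled.

## Hierarchy collapsing and I/O conventions

Reactome-style hierarchies are collapsed by iteratively merging leaf
sets smaller than a size threshold into their (lexicographically first)
parent; when no merge is possible at the current threshold it is raised
by one, until the mean set size reaches the target (80 genes, the
typical KEGG pathway size) or nothing mergeable remains. Small sets
without a parent are kept and flagged. The schedule is deterministic, so
the operation is reproducible.

Networks load from whitespace/TSV edge lists; when a confidence cutoff
is given, sub-threshold edges are dropped *including their genes* — the
universe is the post-filter network, matching the convention that only
linked genes can participate in crosstalk. Self-links contribute their
gene but no edge; duplicate and reversed edges collapse; the gene order
is canonical (sorted), so shuffled inputs load identically. Gene sets
use GMT (or a two-column long TSV); gene identifiers are opaque,
case-sensitive strings — identifier mapping is upstream of this tool.

## Problem sizes and known limitations

The test suite and the acceptance script run everything at desk scale:
1000 random queries for calibration, 100 planted-module nulls for the
overdispersion check, 30 replicates over m ∈ {100, 500, 2000} for
stability, and 50 modules on a 5000-gene network for discrimination —
sizes chosen so the full suite completes in about a minute while leaving
the statistical claims testable (binomial standard errors well inside
the asserted tolerances).

Limitations: no depletion or two-tailed testing; no network
randomization or analytic (hypergeometric/χ²) null backends beyond the
binomial diagnostic; confidence scores are used only for thresholding,
never as weights; p-values below the empirical resolution rely entirely
on the beta-binomial tail being a faithful extrapolation of the sampled
null; and compute cost scales linearly in the number of distinct
(pathway, query-size) pairs, since each needs its own sampled null.
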