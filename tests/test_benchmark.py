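import numpy as np
import pytest
from scipy import stats as sps

from anubix import (
    GeneSet,
    GeneSetCollection,
    Network,
    NullModelStore,
    SynthSpec,
    generate_network,
    generate_query,
    mid_p_value,
)
from anubix.benchmark import (
    bisect_pathway,
    count_maximal_cliques,
    emulate_overlap,
    fp_benchmark,
    intralink_fraction,
    midp_batch,
    pairwise_overlap,
    roc_auc,
    roc_points,
    stability_analysis,
    tp_benchmark,
)
from anubix.inference import mid_p_binomial
from anubix.null_model import sample_index_sets
from anubix.crosstalk import pathway_degree_array


class TestMidpBatch:
    def test_matches_scalar_mid_p(self, small_fixture):
        net, pathways, _ = small_fixture
        store = NullModelStore(net, m=400, seed=1)
        _, fit = store.get(pathways.sets[0], 40)
        rng = np.random.default_rng(0)
        ns = np.full(20, fit.n) - rng.integers(0, 5, 20)
        ks = np.array([int(rng.integers(0, n // 50)) for n in ns])
        batch = midp_batch(ks, ns, fit)
        for k, n, p in zip(ks, ns, batch):
            assert p == pytest.approx(mid_p_value(int(k), int(n), fit.alpha, fit.beta),
                                      rel=1e-10)


class TestFPBenchmark:
    def test_zero_sets_gives_empty_table(self, small_fixture):
        net, pathways, _ = small_fixture
        df, summary = fp_benchmark(net, pathways, n_sets=0, set_size=20, m=100, seed=0)
        assert len(df) == 0 and np.isnan(summary["mean_fpr"])

    def test_unlinked_pathway_flagged_untestable(self, gs):
        net = Network([("a", "b")], genes=["a", "b", "p1", "p2", "x"])
        pws = GeneSetCollection([gs("p1", "p2", id="ISOLATED"), gs("a", "b", id="LINKED")])
        df, summary = fp_benchmark(net, pws, n_sets=50, set_size=2, m=100, seed=0)
        row = df.set_index("pathway_id").loc["ISOLATED"]
        assert not row["testable"] and np.isnan(row["fpr"])
        assert summary["n_testable"] == 1

    def test_calibrated_on_planted_modules(self, small_fixture):
        net, pathways, _ = small_fixture
        df, summary = fp_benchmark(net, pathways, n_sets=400, set_size=60, m=1000, seed=2)
        # each pathway's FPR within 3 binomial SEs of 0.05 at n=400
        se = np.sqrt(0.05 * 0.95 / 400)
        assert (np.abs(df["fpr"] - 0.05) < 3 * se + 0.01).all()
        assert 0.03 < summary["mean_fpr"] < 0.07


class TestBisection:
    def test_four_cycle_balanced_and_link_even(self):
        net = Network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        pw = GeneSet(id="P", name="", members=frozenset("abcd"))
        p1, p2 = bisect_pathway(pw, net, rng=0)
        assert {len(p1), len(p2)} == {2}
        assert p1.members | p2.members == pw.members
        assert not p1.members & p2.members
        links = lambda part: sum(
            1 for g in part.members for nb in net.neighbors(g)
            if nb in part.members and g < nb
        )
        assert links(p1) == links(p2)

    def test_six_clique_split_three_three(self):
        genes = list("abcdef")
        edges = [(x, y) for i, x in enumerate(genes) for y in genes[i + 1:]]
        net = Network(edges)
        pw = GeneSet(id="K6", name="", members=frozenset(genes))
        p1, p2 = bisect_pathway(pw, net, rng=1)
        assert len(p1) == 3 and len(p2) == 3
        links = lambda part: sum(
            1 for g in part.members for nb in net.neighbors(g)
            if nb in part.members and g < nb
        )
        assert links(p1) == 3 and links(p2) == 3

    def test_isolated_genes_any_split_valid(self):
        net = Network([], genes=list("wxyz"))
        pw = GeneSet(id="P", name="", members=frozenset("wxyz"))
        p1, p2 = bisect_pathway(pw, net, rng=3)
        assert len(p1) == 2 and len(p2) == 2

    def test_deterministic_given_seed(self, small_fixture):
        net, pathways, _ = small_fixture
        a1, a2 = bisect_pathway(pathways.sets[0], net, rng=9)
        b1, b2 = bisect_pathway(pathways.sets[0], net, rng=9)
        assert a1.members == b1.members and a2.members == b2.members

    def test_too_small_pathway(self, path_network):
        pw = GeneSet(id="P", name="", members=frozenset("abc"))
        with pytest.raises(ValueError, match="fewer than 4"):
            bisect_pathway(pw, path_network, rng=0)


class TestEmulateOverlap:
    def setup_method(self):
        self.p1 = GeneSet(id="A", name="", members=frozenset({"a", "b"}))
        self.p2 = GeneSet(id="B", name="", members=frozenset({"c", "d"}))

    def test_zero_overlap_is_identity(self):
        q1, q2 = emulate_overlap(self.p1, self.p2, 0, rng=0)
        assert q1.members == self.p1.members and q2.members == self.p2.members

    def test_single_shared_gene(self):
        q1, q2 = emulate_overlap(self.p1, self.p2, 1, rng=0)
        assert q2.members == self.p2.members
        assert len(q1.members & q2.members) == 1
        assert q1.members - q2.members == {"a", "b"}

    def test_full_overlap_makes_superset(self):
        q1, q2 = emulate_overlap(self.p1, self.p2, 2, rng=0)
        assert q1.members >= q2.members

    def test_infeasible_overlap(self):
        with pytest.raises(ValueError, match="infeasible"):
            emulate_overlap(self.p1, self.p2, 3, rng=0)


class TestTPBenchmark:
    def test_planted_modules_reconnect(self, small_fixture):
        net, pathways, _ = small_fixture
        df, summary = tp_benchmark(net, pathways, m=500, seed=4)
        assert len(df) == len(pathways.sets)
        assert summary["tpr"] >= 0.9

    def test_random_vertex_sets_do_not_reconnect(self):
        # no planted structure at all: halves of a random set are unrelated
        spec = SynthSpec(n_genes=500, background_model="erdos_renyi", p_bg=0.02,
                         m_attach=3, modules=(), p_out=0.0, seed=6)
        net, _, _ = generate_network(spec)
        rng = np.random.default_rng(6)
        fake = GeneSetCollection([
            GeneSet(id=f"R{i}", name="",
                    members=frozenset(rng.choice(net.genes, 40, replace=False)))
            for i in range(12)
        ])
        _, summary = tp_benchmark(net, fake, m=500, seed=6)
        assert summary["tpr"] <= 0.35  # indistinguishable from the FP level

    def test_overlap_table_applied(self, small_fixture):
        net, pathways, _ = small_fixture
        table = {pathways.sets[0].id: 3}
        df, _ = tp_benchmark(net, GeneSetCollection([pathways.sets[0]]),
                             overlap_table=table, m=300, seed=1)
        assert df.iloc[0]["overlap_emulated"] == 3


class TestROC:
    def test_perfect_separation(self):
        pts = roc_points([0.001] * 10, [0.9] * 10)
        assert any(np.allclose(p, (0.0, 1.0)) for p in pts)
        assert roc_auc(pts) == pytest.approx(1.0)

    def test_identical_distributions_near_diagonal(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=2000)
        q = rng.uniform(size=2000)
        auc = roc_auc(roc_points(p, q))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_tied_threshold(self):
        pts = roc_points([0.5, 0.5], [0.5])
        assert pts.shape[0] == 2  # (0,0) and the single all-inclusive threshold
        assert np.allclose(pts[1], (1.0, 1.0))

    def test_monotone_coordinates(self):
        rng = np.random.default_rng(13)
        pts = roc_points(rng.uniform(size=50), rng.uniform(size=60))
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            roc_points([], [0.5])


class TestStability:
    def test_degenerate_null_has_zero_cv(self, gs):
        # drawing the full universe every time makes the null deterministic
        net = Network([("a", "b"), ("b", "c")])
        pws = GeneSetCollection([gs("a", "b", id="P")])
        query = gs("a", "b", "c", id="Q")
        df, _ = stability_analysis(net, pws, query, sample_sizes=[5], reps=5, seed=0)
        assert df.iloc[0]["cv"] == 0.0

    def test_cv_shrinks_with_more_samples(self, small_fixture):
        net, pathways, _ = small_fixture
        query = generate_query("random", 60, net, rng=0, query_id="Q")
        pws = GeneSetCollection(pathways.sets[:2])
        df, summary = stability_analysis(net, pws, query, sample_sizes=[50, 800],
                                         reps=15, seed=1)
        mean_cv = df.groupby("n_samples")["cv"].mean()
        assert mean_cv[800] < mean_cv[50]
        frac = summary["fraction_below_threshold"]
        assert frac[800] >= frac[50]


class TestTopology:
    def test_isolated_clique_intralink_one(self):
        net = Network([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y")])
        pw = GeneSet(id="P", name="", members=frozenset("abc"))
        assert intralink_fraction(pw, net) == 1.0

    def test_external_star_intralink_zero(self):
        net = Network([("hub", "a"), ("hub", "b"), ("hub", "c")])
        pw = GeneSet(id="P", name="", members=frozenset("abc"))
        assert intralink_fraction(pw, net) == 0.0

    def test_half_internal(self):
        net = Network([("a", "b"), ("b", "x")])
        pw = GeneSet(id="P", name="", members=frozenset("ab"))
        assert intralink_fraction(pw, net) == 0.5

    def test_no_incident_links_undefined(self):
        net = Network([("x", "y")], genes=["x", "y", "a"])
        pw = GeneSet(id="P", name="", members=frozenset("a"))
        assert np.isnan(intralink_fraction(pw, net))

    def test_triangle_single_clique(self):
        net = Network([("a", "b"), ("b", "c"), ("a", "c")])
        pw = GeneSet(id="P", name="", members=frozenset("abc"))
        assert count_maximal_cliques(pw, net) == 1

    def test_path_two_cliques(self):
        net = Network([("a", "b"), ("b", "c")])
        pw = GeneSet(id="P", name="", members=frozenset("abc"))
        assert count_maximal_cliques(pw, net) == 2

    def test_isolated_vertices_counted_unless_restricted(self):
        net = Network([("a", "b")], genes=["a", "b", "solo"])
        pw = GeneSet(id="P", name="", members=frozenset({"a", "b", "solo"}))
        assert count_maximal_cliques(pw, net) == 2
        assert count_maximal_cliques(pw, net, min_size=2) == 1

    def test_pairwise_overlap_table(self, gs):
        coll = GeneSetCollection([
            gs("a", "b", "c", id="X"),
            gs("b", "c", "d", id="Y"),
            gs("p", "q", id="Z"),
        ])
        df = pairwise_overlap(coll).set_index(["id1", "id2"])
        assert df.loc[("X", "Y"), "shared_fraction_of_union"] == pytest.approx(0.5)
        assert df.loc[("X", "Z"), "shared_fraction_of_union"] == 0.0
        ident = pairwise_overlap(GeneSetCollection([gs("a", id="A"), gs("a", id="B")]))
        assert ident["shared_fraction_of_union"].iloc[0] == 1.0


class TestIntralinkFPRAssociation:
    def test_binomial_null_fpr_tracks_intralink_fraction(self):
        """A deliberately miscalibrated binomial null produces more false
        positives for pathways that behave like isolated communities."""
        sizes_p_in = ((50, 0.02), (50, 0.08), (50, 0.2), (50, 0.35), (50, 0.5))
        spec = SynthSpec(n_genes=600, background_model="erdos_renyi", p_bg=0.01,
                         m_attach=3, modules=sizes_p_in, p_out=0.01, seed=14)
        net, pathways, _ = generate_network(spec)
        rng = np.random.default_rng(14)
        idx = sample_index_sets(rng, net.n_genes, 60, 400)
        fprs, intras = [], []
        for pw in pathways:
            d = pathway_degree_array(net, pw)
            k = d[idx].sum(axis=1)
            n = 60 * len(pw.network_members(net))
            p_hat = k.mean() / n  # binomial null fitted to the same draws
            ps = np.array([mid_p_binomial(int(kk), n, p_hat) for kk in k])
            fprs.append((ps < 0.05).mean())
            intras.append(intralink_fraction(pw, net))
        rho = sps.spearmanr(intras, fprs).statistic
        assert rho > 0.5
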