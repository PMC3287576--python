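import numpy as np
import pytest

import ncanet as nn
from ncanet.prior import ConnectivityPrior


def brute_force_identifiability(support, n_conditions, seed=0):
    """Independent oracle: explicit rank computations on 3 random fillings."""
    rng = np.random.default_rng(seed)
    support = np.asarray(support, dtype=bool)
    L = support.shape[1]

    def generic_rank(pattern):
        if pattern.size == 0:
            return 0
        ranks = []
        for _ in range(3):
            vals = rng.uniform(1.0, 2.0, size=pattern.shape)
            vals *= np.where(rng.random(pattern.shape) < 0.5, -1.0, 1.0)
            ranks.append(np.linalg.matrix_rank(np.where(pattern, vals, 0.0)))
        return max(ranks)

    c1 = generic_rank(support) == L
    c2 = True
    for j in range(L):
        keep = ~support[:, j]
        sub = np.delete(support[keep], j, axis=1)
        if generic_rank(sub) < L - 1:
            c2 = False
    c3 = L <= n_conditions
    return c1, c2, c3


def random_prior(rng, max_genes=15, max_tfs=5):
    """Random support with every row and column nonempty."""
    while True:
        L = int(rng.integers(1, max_tfs + 1))
        N = int(rng.integers(L, max_genes + 1))
        support = rng.random((N, L)) < rng.uniform(0.15, 0.6)
        for j in range(L):
            if not support[:, j].any():
                support[rng.integers(N), j] = True
        if support.any(axis=1).all():
            strengths = np.where(support, rng.uniform(0.3, 1.0, (N, L)), 0.0)
            return ConnectivityPrior(
                [f"T{j}" for j in range(L)], [f"g{i}" for i in range(N)],
                support, strengths)


class TestCorrelationMatrix:
    def test_diagonal_symmetry_and_range(self, noisy_truth):
        R = nn.correlation_matrix(noisy_truth.expression)
        M = R.to_numpy()
        np.testing.assert_allclose(np.diag(M), 1.0)
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        assert M.min() >= -1.0 and M.max() <= 1.0

    def test_exact_anticorrelation(self):
        vals = np.array([[0.0, 1.0, 2.0], [0.0, -2.0, -4.0]])
        E = nn.ExpressionMatrix(["a", "b"], ["c", "s1", "s2"], vals, "c")
        R = nn.correlation_matrix(E)
        assert R.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_pair(self):
        vals = np.array([[0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 4.0]])
        E = nn.ExpressionMatrix(["a", "b"], ["c", "s1", "s2", "s3"], vals, "c")
        r = nn.correlation_matrix(E).loc["a", "b"]
        # Pearson r of (1,2,3,4) vs (1,2,3,5) computed by hand
        assert r == pytest.approx(0.9827, abs=5e-5)

    def test_constant_rows_reported_as_zero(self):
        vals = np.array([[0.0, 1.0, 2.0], [0.0, 0.0, 0.0]])
        E = nn.ExpressionMatrix(["a", "flat"], ["c", "s1", "s2"], vals, "c")
        R = nn.correlation_matrix(E)
        assert R.loc["a", "flat"] == 0.0
        assert "flat" in R.attrs["constant_genes"]

    def test_too_few_genes_rejected(self, toy_expression):
        with pytest.raises(ValueError):
            nn.correlation_matrix(toy_expression, ["g1"])


class TestClusterGenes:
    def test_identical_rows_merge_at_zero(self):
        vals = np.array([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0], [0.0, -1.0, 1.5]])
        E = nn.ExpressionMatrix(["a", "b", "z"], ["c", "s1", "s2"], vals, "c")
        d = nn.cluster_genes(E)
        first = d.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_first_merge_is_most_correlated_pair(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=6)
        base -= base[0]
        near = base + 0.01 * rng.normal(size=6)
        near -= near[0]
        far = rng.normal(size=6)
        far -= far[0]
        E = nn.ExpressionMatrix(["g1", "g2", "g3"],
                                [f"s{i}" for i in range(6)],
                                np.vstack([base, near, far]), "s0")
        d = nn.cluster_genes(E)
        assert {int(d.merges[0][0]), int(d.merges[0][1])} == {0, 1}

    def test_cut_at_zero_gives_singletons(self, noisy_truth):
        d = nn.cluster_genes(noisy_truth.expression)
        labels = d.cut(0.0)
        assert len(set(labels.values())) == len(labels)

    def test_leaves_are_input_genes_exactly_once(self, noisy_truth):
        genes = noisy_truth.expression.gene_ids[:10]
        d = nn.cluster_genes(noisy_truth.expression, genes)
        assert sorted(d.leaf_order) == sorted(genes)


class TestBuildPrior:
    def make_expr(self):
        # TF tracks a bump; targets scale it; outsider is independent
        rng = np.random.default_rng(2)
        t = np.arange(7.0)
        bump = np.exp(-0.5 * ((t - 3) / 1.2) ** 2)
        rows = {
            "TF1": bump,
            "hi_pos": 1.9 * bump + 0.001 * rng.normal(size=7),
            "hi_neg": -1.4 * bump + 0.001 * rng.normal(size=7),
            "uncorr": rng.normal(size=7),
        }
        vals = np.vstack([v - v[0] for v in rows.values()])
        return nn.ExpressionMatrix(list(rows), [f"s{i}" for i in range(7)],
                                   vals, "s0")

    def test_correlated_cocluster_genes_kept_with_signed_strength(self):
        E = self.make_expr()
        prior = nn.build_prior(E, ["TF1"], r_threshold=0.9, cut_height=0.1)
        d = dict(((tf, g), s) for tf, g, s in prior.edges())
        assert ("TF1", "hi_pos") in d and d[("TF1", "hi_pos")] > 0.9
        assert ("TF1", "hi_neg") in d and d[("TF1", "hi_neg")] < -0.9
        assert ("TF1", "uncorr") not in d
        assert ("TF1", "TF1") not in d  # no trivial self-pair

    def test_high_r_outside_cluster_excluded(self):
        E = self.make_expr()
        # a tiny cut height isolates every gene -> no co-membership
        with pytest.raises(ValueError, match="empty support"):
            nn.build_prior(E, ["TF1"], r_threshold=0.9, cut_height=1e-12)

    def test_support_shrinks_with_threshold(self, noisy_truth):
        E = noisy_truth.expression
        tfs = noisy_truth.prior.tf_ids
        lo = nn.build_prior(E, tfs, r_threshold=0.6, cut_height=0.8)
        hi = nn.build_prior(E, tfs, r_threshold=0.9, cut_height=0.8)
        lo_edges = {(t, g) for t, g, _ in lo.edges()}
        hi_edges = {(t, g) for t, g, _ in hi.edges()}
        assert hi_edges <= lo_edges

    def test_missing_tf_rejected(self, noisy_truth):
        with pytest.raises(ValueError, match="absent"):
            nn.build_prior(noisy_truth.expression, ["NOPE"])


class TestIdentifiability:
    def test_trivial_single_tf(self):
        prior = ConnectivityPrior(["T"], ["g"], np.array([[True]]),
                                  np.array([[1.0]]))
        assert nn.check_identifiability(prior, 1).passed

    def test_duplicate_support_columns_fail(self):
        # identical support columns are generically full rank, but deleting
        # either TF removes every gene, so the reduced-rank criterion fails
        support = np.array([[1, 1], [1, 1], [1, 1]], dtype=bool)
        prior = ConnectivityPrior(["T1", "T2"], ["a", "b", "c"], support,
                                  np.where(support, 0.5, 0.0))
        rep = nn.check_identifiability(prior, 5)
        assert not rep.passed
        assert set(rep.violating_tfs) == {"T1", "T2"}

    def test_shared_support_counterexample_fails_criterion_ii(self):
        # two TFs sharing their entire (2-gene) support: removing either TF
        # removes both genes and leaves nothing to give the other TF rank
        support = np.array([
            [1, 1],
            [1, 1],
        ], dtype=bool)
        prior = ConnectivityPrior(["T1", "T2"], ["a", "b"], support,
                                  np.where(support, 0.4, 0.0))
        rep = nn.check_identifiability(prior, 5)
        assert not rep.passed
        assert set(rep.violating_tfs) or not rep.full_column_rank

    def test_too_many_tfs_for_conditions(self):
        rng = np.random.default_rng(0)
        prior = nn.generate_prior_topology(30, 5, edges_per_gene=2, seed=4)
        rep = nn.check_identifiability(prior, 3)
        assert not rep.conditions_ok and not rep.passed
        assert nn.check_identifiability(prior, 5).conditions_ok

    def test_matches_brute_force_on_random_priors(self):
        rng = np.random.default_rng(42)
        agree = 0
        for trial in range(100):
            prior = random_prior(rng)
            rep = nn.check_identifiability(prior, 4, seed=trial)
            c1, c2, c3 = brute_force_identifiability(prior.support, 4,
                                                     seed=1000 + trial)
            assert rep.full_column_rank == c1
            assert rep.reduced_rank_ok == c2
            assert rep.conditions_ok == c3
            agree += 1
        assert agree == 100


class TestReduceToIdentifiable:
    def test_identifiable_prior_is_fixed_point(self):
        prior = nn.generate_prior_topology(20, 3, edges_per_gene=2, seed=1)
        reduced, removed = nn.reduce_to_identifiable(prior, 7)
        assert removed == []
        assert reduced.tf_ids == prior.tf_ids
        np.testing.assert_array_equal(reduced.support, prior.support)

    def test_duplicated_column_pruned_to_identifiable(self):
        base = nn.generate_prior_topology(20, 3, edges_per_gene=2, seed=2)
        # duplicate the first TF column under a new name
        support = np.hstack([base.support, base.support[:, [0]]])
        strengths = np.hstack([base.initial_strengths,
                               base.initial_strengths[:, [0]]])
        prior = ConnectivityPrior(base.tf_ids + ["DUP"], base.gene_ids,
                                  support, strengths)
        assert not nn.check_identifiability(prior, 7).passed
        reduced, removed = nn.reduce_to_identifiable(prior, 7)
        assert len(removed) == 1
        assert removed[0] in ("TF000", "DUP")
        assert nn.check_identifiability(reduced, 7).passed

    def test_l_greater_than_m_prunes_to_m(self):
        prior = nn.generate_prior_topology(40, 6, edges_per_gene=2, seed=3)
        reduced, removed = nn.reduce_to_identifiable(prior, 4)
        assert reduced.n_tfs <= 4
        assert nn.check_identifiability(reduced, 4).passed

    def test_output_always_identifiable_on_random_priors(self):
        rng = np.random.default_rng(9)
        for trial in range(20):
            prior = random_prior(rng)
            try:
                reduced, _ = nn.reduce_to_identifiable(prior, 4, seed=trial)
            except ValueError:
                continue
            assert nn.check_identifiability(reduced, 4, seed=trial).passed


class TestPriorIO:
    def test_edge_list_round_trip(self, small_truth, tmp_path):
        p = tmp_path / "prior.tsv"
        nn.save_prior(small_truth.prior, p)
        back = nn.load_prior(p)
        assert back.tf_ids == small_truth.prior.tf_ids
        assert set(back.gene_ids) == set(small_truth.prior.gene_ids)
        orig = dict(((t, g), s) for t, g, s in small_truth.prior.edges())
        loaded = dict(((t, g), s) for t, g, s in back.edges())
        assert orig == loaded
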