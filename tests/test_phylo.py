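"""Tree I/O, Brownian covariance, multivariate K, squared-change parsimony."""

import numpy as np
import pytest
import scipy.optimize
import scipy.stats

from conftest import random_binary_tree
from enamelgmm.phylo import (
    kmult,
    phylo_covariance,
    phylogeny_from_newick_string,
    phylomorphospace,
    read_newick,
    squared_change_parsimony,
)
from enamelgmm.synthetic import simulate_bm_means


class TestNewick:
    def test_parse_basic(self):
        phy = phylogeny_from_newick_string("((A:1,B:1):1,C:2);")
        assert sorted(phy.tip_labels) == ["A", "B", "C"]
        assert len(phy.tree.seed_node.child_nodes()) == 2

    def test_round_trip_on_random_tree(self, tmp_path, rng):
        nwk = random_binary_tree([f"t{i}" for i in range(10)], rng)
        phy = phylogeny_from_newick_string(nwk)
        path = tmp_path / "t.nwk"
        phy.write_newick(path)
        back = read_newick(path)
        assert sorted(back.tip_labels) == sorted(phy.tip_labels)
        C0, o0 = phylo_covariance(phy)
        C1, o1 = phylo_covariance(back)
        perm = [o1.index(t) for t in o0]
        np.testing.assert_allclose(C1[np.ix_(perm, perm)], C0, atol=1e-9)

    def test_missing_lengths_need_flag(self):
        with pytest.raises(ValueError, match="branch lengths"):
            phylogeny_from_newick_string("((A,B),C);")
        phy = phylogeny_from_newick_string("((A,B),C);", unit_lengths=True)
        C, _ = phylo_covariance(phy)
        assert C.max() == pytest.approx(2.0)


class TestPhyloCovariance:
    def test_star_tree_gives_identity(self):
        phy = phylogeny_from_newick_string("(A:1,B:1,C:1,D:1);")
        C, _ = phylo_covariance(phy)
        np.testing.assert_allclose(C, np.eye(4), atol=1e-12)

    def test_toy_tree_path_arithmetic(self):
        phy = phylogeny_from_newick_string("((A:1,B:1):1,C:2);")
        C, order = phylo_covariance(phy)
        i = {t: k for k, t in enumerate(order)}
        assert C[i["A"], i["B"]] == pytest.approx(1.0)
        assert C[i["A"], i["A"]] == pytest.approx(2.0)
        assert C[i["A"], i["C"]] == pytest.approx(0.0)

    def test_matches_shared_path_brute_force(self, rng):
        nwk = random_binary_tree(list("ABCDEF"), rng)
        phy = phylogeny_from_newick_string(nwk)
        C, order = phylo_covariance(phy)
        # brute force: shared root-to-tip edge sets
        tree = phy.tree
        paths = {}
        for leaf in tree.leaf_node_iter():
            edges = []
            node = leaf
            while node.parent_node is not None:
                edges.append((id(node), node.edge.length))
                node = node.parent_node
            paths[leaf.taxon.label] = edges
        for a in order:
            for b in order:
                shared = {e for e, _ in paths[a]} & {e for e, _ in paths[b]}
                expect = sum(l for e, l in paths[a] if e in shared)
                assert C[order.index(a), order.index(b)] == pytest.approx(expect)

    def test_ultrametric_tree_has_constant_diagonal(self, default_tree):
        C, _ = phylo_covariance(default_tree)
        np.testing.assert_allclose(np.diag(C), np.diag(C)[0], atol=1e-9)


from conftest import univariate_blomberg_k as _univariate_blomberg_k


class TestKmult:
    def test_univariate_equals_blomberg_formula(self, rng):
        for rep in range(10):
            nwk = random_binary_tree([f"s{i}" for i in range(8)], rng)
            phy = phylogeny_from_newick_string(nwk)
            C, order = phylo_covariance(phy)
            y = rng.normal(size=8)
            res = kmult(y[:, None], phy, order, n_perm=99, seed=rep)
            assert res.k_obs == pytest.approx(
                _univariate_blomberg_k(y, C), abs=1e-10
            )

    def test_rotation_invariance(self, default_tree, rng):
        Y, order = simulate_bm_means(default_tree, np.zeros(6), 1.0, seed=5)
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        r1 = kmult(Y, default_tree, order, n_perm=99, seed=0)
        r2 = kmult(Y @ Q, default_tree, order, n_perm=99, seed=0)
        assert r1.k_obs == pytest.approx(r2.k_obs, abs=1e-8)

    def test_identical_tip_values_raise(self, default_tree):
        Y = np.ones((10, 4))
        with pytest.raises(ValueError, match="zero variance"):
            kmult(Y, default_tree, default_tree.tip_labels, n_perm=99)

    def test_pvalue_convention_add_one(self, default_tree, rng):
        Y, order = simulate_bm_means(default_tree, np.zeros(3), 1.0, seed=2)
        res = kmult(Y, default_tree, order, n_perm=199, seed=0)
        count = int(np.sum(res.permutation_distribution >= res.k_obs))
        assert res.p_perm == pytest.approx((1 + count) / 200)
        assert res.p_perm > 0

    def test_species_tree_intersection(self, default_tree, rng):
        # data for 12 species, tree has 10: intersection is analyzed
        species = list(default_tree.tip_labels) + ["MNG", "HBR"]
        Y = rng.normal(size=(12, 4))
        res = kmult(Y, default_tree, species, n_perm=99, seed=0)
        assert res.k_obs > 0

    def test_permutation_pvalues_uniform_under_null(self, default_tree):
        # tip-randomized BM data: the permutation p-value should be U(0,1)
        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            Y, order = simulate_bm_means(default_tree, np.zeros(5), 1.0, seed=rep)
            Y = Y[rng.permutation(len(order))]       # destroy the signal
            res = kmult(Y, default_tree, order, n_perm=99, seed=rep + 1)
            pvals.append(res.p_perm)
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_iid_tips_give_low_k_and_calibrated_test(self, default_tree):
        ks, rejections = [], 0
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            Y = rng.normal(size=(10, 5))
            res = kmult(Y, default_tree, default_tree.tip_labels,
                        n_perm=99, seed=rep)
            ks.append(res.k_obs)
            rejections += res.p_perm <= 0.05
        assert np.mean(ks) < 1.0
        # binomial 95% interval for rate 0.05 at 200 draws
        assert 3 <= rejections <= 17


class TestSquaredChangeParsimony:
    def test_two_tip_closed_form(self):
        phy = phylogeny_from_newick_string("(A:2,B:3);")
        anc = squared_change_parsimony(phy, np.array([[1.0], [11.0]]), ["A", "B"])
        expect = (1 / 2 + 11 / 3) / (1 / 2 + 1 / 3)
        assert anc.root_value[0] == pytest.approx(expect, abs=1e-12)

    def test_constant_field(self, default_tree):
        Y = np.full((10, 3), 7.5)
        anc = squared_change_parsimony(default_tree, Y, default_tree.tip_labels)
        for v in anc.node_values.values():
            np.testing.assert_allclose(v, 7.5, atol=1e-9)

    def test_objective_matches_numeric_minimizer(self, rng):
        nwk = random_binary_tree(list("ABCDE"), rng)
        phy = phylogeny_from_newick_string(nwk)
        Y = rng.normal(size=(5, 1))
        anc = squared_change_parsimony(phy, Y, phy.tip_labels)
        lengths = {}
        ids = {}
        from enamelgmm.phylo import _node_ids

        ids = _node_ids(phy)
        for node in phy.tree.preorder_node_iter():
            for ch in node.child_nodes():
                lengths[(ids[id(node)], ids[id(ch)])] = ch.edge.length
        internal = sorted(anc.node_values)
        tipvals = {t: Y[i, 0] for i, t in enumerate(phy.tip_labels)}

        def objective(x):
            vals = {**tipvals, **dict(zip(internal, x))}
            return sum(
                (vals[p] - vals[c]) ** 2 / l for (p, c), l in lengths.items()
            )

        x0 = np.zeros(len(internal))
        opt = scipy.optimize.minimize(objective, x0, method="BFGS", tol=1e-12)
        ours = objective([anc.node_values[k][0] for k in internal])
        assert ours == pytest.approx(opt.fun, abs=1e-6)

    def test_root_equals_gls_ml_estimate(self, rng):
        for rep in range(10):
            nwk = random_binary_tree([f"x{i}" for i in range(6)], rng)
            phy = phylogeny_from_newick_string(nwk)
            C, order = phylo_covariance(phy)
            Y = rng.normal(size=(6, 2))
            Yo = Y[[phy.tip_labels.index(t) for t in order]]
            anc = squared_change_parsimony(phy, Y, phy.tip_labels)
            Ci = np.linalg.inv(C)
            one = np.ones(6)
            gls = (one @ Ci @ Yo) / (one @ Ci @ one)
            np.testing.assert_allclose(anc.root_value, gls, atol=1e-8)


class TestPhylomorphospace:
    def test_node_coords_consistent_with_scp(self, default_tree):
        Y, order = simulate_bm_means(default_tree, np.zeros(40), 1.0, seed=9)
        pms = phylomorphospace(Y, order, default_tree)
        scores = pms.pca.retained_scores
        anc = squared_change_parsimony(default_tree, scores, order)
        for nid, v in anc.node_values.items():
            np.testing.assert_allclose(pms.node_coords[nid], v, atol=1e-9)
        np.testing.assert_allclose(
            pms.node_coords[pms.root_id], anc.root_value, atol=1e-9
        )

    def test_plot_writes_figure(self, default_tree, tmp_path):
        from enamelgmm.plot import plot_phylomorphospace

        Y, order = simulate_bm_means(default_tree, np.zeros(10), 1.0, seed=4)
        pms = phylomorphospace(Y, order, default_tree)
        out = tmp_path / "pms.svg"
        plot_phylomorphospace(pms, out, title="test")
        assert out.stat().st_size > 0

    def test_sister_tips_cluster_under_strong_signal(self):
        # with strong Brownian signal, sister species should usually be
        # mutual nearest neighbours in the (PC1, PC2) plane
        phy = phylogeny_from_newick_string(
            "((A:0.05,B:0.05):1,((C:0.05,D:0.05):1,(E:0.05,F:0.05):1):0.5);"
        )
        sisters = [("A", "B"), ("C", "D"), ("E", "F")]
        hits = 0
        trials = 100
        for rep in range(trials):
            Y, order = simulate_bm_means(phy, np.zeros(10), 1.0, seed=rep)
            pms = phylomorphospace(Y, order, phy)
            pts = {t: pms.tip_coords[t][:2] for t in order}
            ok = True
            for a, b in sisters:
                da = {t: np.linalg.norm(pts[a] - pts[t]) for t in order if t != a}
                if min(da, key=da.get) != b:
                    ok = False
                    break
            hits += ok
        assert hits >= 80
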