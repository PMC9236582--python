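"""Likelihood engine: pruning correctness, optimization, rates, tabular I/O."""

import warnings

import numpy as np
import pytest
from scipy import stats

from sitelasso import likelihood, models, trees
from sitelasso.errors import ValidationError
from sitelasso.msa_io import Alignment, compress_patterns
from sitelasso.simulate import simulate_alignment
from oracles import brute_force_site_lls


def _two_taxon_tree(length):
    t = trees.PhyloTree()
    a, b = t.new_node(), t.new_node()
    t.names[a], t.names[b] = "x", "y"
    t.add_edge(a, b, length)
    return t, a, b


def _random_instance(rng, alphabet):
    n = int(rng.integers(3, 6))
    m = int(rng.integers(2, 8))
    if alphabet == "dna":
        model = models.build_model(
            "GTR", exchangeabilities=rng.uniform(0.2, 2.0, 6),
            frequencies=rng.dirichlet(np.ones(4) * 8),
            alpha=float(rng.uniform(0.3, 2.0)) if rng.random() < 0.5 else None,
            n_categories=3)
    else:
        n = min(n, 4)  # keep the 20-state enumeration cheap
        name = ["WAG", "JTT", "LG"][int(rng.integers(3))]
        alpha = float(rng.uniform(0.3, 2.0)) if rng.random() < 0.5 else None
        model = models.build_model(name, alpha=alpha, n_categories=2)
    tree = trees.random_tree([f"t{i}" for i in range(n)], rng, 0.25)
    sim = simulate_alignment(tree, model, m, rng)
    return tree, sim.alignment, model


class TestSiteLogLikelihoods:
    def test_two_taxa_zero_distance(self):
        jc = models.jukes_cantor()
        aln = Alignment(["x", "y"], np.array([list("ACGT")] * 2), "dna")
        t, *_ = _two_taxon_tree(0.0)
        vec = likelihood.site_log_likelihoods(t, aln, jc)
        assert np.allclose(vec.values, np.log(0.25), atol=1e-12)

    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(8):
            tree, aln, model = _random_instance(rng, "dna" if trial % 2 else "aa")
            mine = likelihood.site_log_likelihoods(tree, aln, model).values
            oracle = brute_force_site_lls(tree, aln, model)
            assert np.abs(mine - oracle).max() < 1e-8

    def test_virtual_root_placement_is_irrelevant(self, rng):
        tree, aln, model = _random_instance(rng, "dna")
        internals = [v for v in tree.adj if not tree.is_leaf(v)]
        base = likelihood.site_log_likelihoods(tree, aln, model, root=internals[0]).values
        for r in internals[1:]:
            other = likelihood.site_log_likelihoods(tree, aln, model, root=r).values
            assert np.abs(base - other).max() < 1e-10

    def test_leaf_order_permutation_invariance(self, rng):
        tree, aln, model = _random_instance(rng, "dna")
        perm = rng.permutation(aln.n_taxa)
        shuffled = Alignment([aln.taxa[i] for i in perm], aln.matrix[perm], "dna")
        a = likelihood.site_log_likelihoods(tree, aln, model).values
        b = likelihood.site_log_likelihoods(tree, shuffled, model).values
        assert np.allclose(a, b, atol=1e-12)

    def test_taxa_mismatch_rejected(self):
        jc = models.jukes_cantor()
        aln = Alignment(["x", "z"], np.array([list("AC")] * 2), "dna")
        t, *_ = _two_taxon_tree(0.1)
        with pytest.raises(ValidationError):
            likelihood.site_log_likelihoods(t, aln, jc)

    def test_jc_depends_only_on_pattern_class(self):
        # under JC, relabeling states permutes nothing observable
        jc = models.jukes_cantor()
        t = trees.random_tree(list("abcd"), 0, 0.2)
        aln1 = Alignment(list("abcd"), np.array([["A"], ["A"], ["C"], ["G"]]), "dna")
        aln2 = Alignment(list("abcd"), np.array([["T"], ["T"], ["G"], ["A"]]), "dna")
        v1 = likelihood.site_log_likelihoods(t, aln1, jc).values
        v2 = likelihood.site_log_likelihoods(t, aln2, jc).values
        assert v1[0] == pytest.approx(v2[0], abs=1e-12)


class TestTotalLogLikelihood:
    def test_equals_per_site_sum_and_compression_consistent(self, rng):
        tree, aln, model = _random_instance(rng, "dna")
        vec = likelihood.site_log_likelihoods(tree, aln, model)
        total = likelihood.total_log_likelihood(tree, aln, model)
        assert total == pytest.approx(vec.values.sum(), abs=1e-9)
        # duplicating sites exactly doubles the log-likelihood
        dup = Alignment(aln.taxa, np.hstack([aln.matrix, aln.matrix]), "dna")
        assert likelihood.total_log_likelihood(tree, dup, model) == pytest.approx(
            2 * total, abs=1e-8)

    def test_single_site_alignment(self):
        jc = models.jukes_cantor()
        t = trees.random_tree(list("abcd"), 1, 0.1)
        aln = Alignment(list("abcd"), np.array([["A"], ["C"], ["G"], ["T"]]), "dna")
        vec = likelihood.site_log_likelihoods(t, aln, jc)
        assert likelihood.total_log_likelihood(t, aln, jc) == pytest.approx(vec.values[0])


class TestBranchLengthOptimization:
    def test_jc_pairwise_distance_closed_form(self, rng):
        jc = models.jukes_cantor()
        m = 4000
        a = rng.integers(0, 4, m)
        b = a.copy()
        flip = rng.random(m) < 0.18
        b[flip] = (a[flip] + rng.integers(1, 4, flip.sum())) % 4
        chars = np.array(list("ACGT"))
        aln = Alignment(["x", "y"], np.stack([chars[a], chars[b]]), "dna")
        t, u, v = _two_taxon_tree(0.5)
        opt = likelihood.optimize_branch_lengths(t, aln, jc)
        p = flip.mean()
        assert opt.adj[u][v] == pytest.approx(-0.75 * np.log(1 - 4 * p / 3), abs=1e-6)

    def test_monotone_and_fixed_point(self, rng):
        model = models.build_model("GTR", alpha=0.8, n_categories=4)
        true = trees.random_tree([f"t{i}" for i in range(7)], 11, 0.12)
        sim = simulate_alignment(true, model, 500, 12)
        for seed in range(5):
            start = trees.random_tree(sim.alignment.taxa, seed, 0.3)
            before = likelihood.total_log_likelihood(start, sim.alignment, model)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                opt = likelihood.optimize_branch_lengths(start, sim.alignment, model)
            after = likelihood.total_log_likelihood(opt, sim.alignment, model)
            assert after >= before - 1e-6
            # optimizing again changes the log-likelihood by < tol
            opt2 = likelihood.optimize_branch_lengths(opt, sim.alignment, model)
            again = likelihood.total_log_likelihood(opt2, sim.alignment, model)
            assert abs(again - after) < 0.01 + 1e-9


class TestAlphaEstimation:
    def test_recovers_simulated_shape(self):
        model = models.build_model("GTR", alpha=0.5, n_categories=4)
        true = trees.random_tree([f"t{i}" for i in range(15)], 21, 0.1)
        sim = simulate_alignment(true, model, 5000, 22)
        est = likelihood.estimate_alpha(true, sim.alignment, model.with_alpha(1.0))
        assert 0.4 <= est <= 0.62

    def test_no_heterogeneity_signal_hits_upper_region(self):
        # data simulated under a homogeneous rate: the gamma shape estimate
        # should run toward the upper bound (no among-site variation to fit)
        homo = models.build_model("GTR")  # single rate category
        t = trees.random_tree([f"t{i}" for i in range(10)], 1, 0.1)
        sim = simulate_alignment(t, homo, 3000, 2)
        gamma_model = models.build_model("GTR", alpha=1.0, n_categories=4)
        est = likelihood.estimate_alpha(t, sim.alignment, gamma_model,
                                        optimize_lengths=False, rounds=1)
        assert est >= 50

    def test_matches_grid_scan(self):
        model = models.build_model("GTR", alpha=0.7, n_categories=4)
        true = trees.random_tree([f"t{i}" for i in range(8)], 5, 0.1)
        sim = simulate_alignment(true, model, 800, 6)
        est = likelihood.estimate_alpha(true, sim.alignment, model,
                                        optimize_lengths=False, rounds=1)
        grid = np.exp(np.linspace(np.log(0.02), np.log(100), 50))
        lls = [likelihood.total_log_likelihood(true, sim.alignment, model.with_alpha(a))
               for a in grid]
        best = grid[int(np.argmax(lls))]
        # agreement within the grid's own resolution
        assert abs(np.log(est) - np.log(best)) <= np.log(grid[1] / grid[0]) + 1e-9


class TestSiteRates:
    def test_constant_column_is_slowest(self):
        model = models.build_model("GTR", alpha=0.8, n_categories=4)
        t = trees.random_tree(list("abcde"), 3, 0.15)
        mat = np.array([list("AA"), list("AC"), list("AG"), list("AT"), list("AC")])
        aln = Alignment(list("abcde"), mat, "dna")
        r = likelihood.site_rates_empirical_bayes(t, aln, model)
        assert r.raw[0] < r.raw[1]

    def test_single_category_degenerates_to_flag(self):
        model = models.jukes_cantor()  # no gamma
        t = trees.random_tree(list("abcd"), 1, 0.1)
        aln = Alignment(list("abcd"), np.array([list("ACGT")] * 4), "dna")
        r = likelihood.site_rates_empirical_bayes(t, aln, model)
        assert r.degenerate
        assert np.allclose(r.raw, 1.0) and np.allclose(r.standardized, 0.0)

    def test_recovers_true_rate_ranking(self):
        model = models.build_model("GTR", alpha=0.5, n_categories=4)
        true = trees.random_tree([f"t{i}" for i in range(15)], 31, 0.1)
        sim = simulate_alignment(true, model, 2000, 32)
        r = likelihood.site_rates_empirical_bayes(true, sim.alignment, model)
        rho = stats.spearmanr(r.raw, sim.site_rates).statistic
        assert rho >= 0.7
        assert abs(r.standardized.mean()) < 1e-10
        assert r.standardized.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestTabularIO:
    def test_site_ll_table_and_weights_round_trip(self, tmp_path):
        vec = likelihood.SiteLLVector(np.array([-1.5, -2.25, -0.125]))
        path = tmp_path / "lls.tsv"
        likelihood.write_site_ll_table(path, [("T1", vec)])
        lines = path.read_text().splitlines()
        assert lines[0] == "tree_id\tsite\tll"
        assert lines[1].split("\t") == ["T1", "1", "-1.5"]

        wpath = tmp_path / "w.tsv"
        likelihood.write_site_weights(wpath, [2, 5], [0.5, 3.0])
        sites0, w = likelihood.read_site_weights(wpath)
        assert sites0.tolist() == [1, 4] and w.tolist() == [0.5, 3.0]

    def test_nonpositive_weights_rejected(self, tmp_path):
        wpath = tmp_path / "w.tsv"
        wpath.write_text("site\tweight\n3\t0.0\n")
        with pytest.raises(ValidationError):
            likelihood.read_site_weights(wpath)
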