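import numpy as np
import pandas as pd
import pytest
from scipy.special import xlogy

from coexnet import inference
from coexnet.datatypes import CoexpressionNetwork
from coexnet.inference import MIEstimatorConfig, estimate_mi

from conftest import make_annotation, make_network, make_study


class TestMIEstimator:
    def test_symmetry_exact(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        assert estimate_mi(x, y) == estimate_mi(y, x)

    def test_rank_invariance(self, rng):
        x = rng.standard_normal(300)
        y = 0.7 * x + rng.standard_normal(300)
        base = estimate_mi(x, y)
        assert estimate_mi(np.exp(x), y) == base
        assert estimate_mi(x, 3.0 * y - 11.0) == base
        assert estimate_mi(np.exp(2 * x), np.tanh(y)) == base

    def test_identity_equals_marginal_entropy(self, rng):
        # MI(x, x) must equal the (Miller-Madow corrected) entropy of the
        # binned marginal, the maximum attainable value
        x = rng.standard_normal(137)
        cfg = MIEstimatorConfig()
        b = cfg.bins_for(len(x))
        binned = inference.equal_frequency_bins(x, b)
        p = np.bincount(binned, minlength=b) / len(x)
        h_mm = -float(xlogy(p, p).sum()) + (np.count_nonzero(p) - 1) / (2 * len(x))
        assert estimate_mi(x, x) == pytest.approx(h_mm, abs=1e-12)

    def test_independent_permutation_within_own_null(self, rng):
        x = rng.standard_normal(1000)
        y = rng.permutation(x)
        obs = estimate_mi(x, y)
        null = np.array([estimate_mi(x, rng.permutation(y)) for _ in range(300)])
        lo, hi = np.quantile(null, [0.025, 0.975])
        assert lo <= obs <= hi

    @pytest.mark.parametrize("rho", [0.3, 0.6, 0.9])
    def test_gaussian_closed_form(self, rho):
        rng = np.random.default_rng(42)
        n = 2000
        z = rng.standard_normal((2, n))
        x, y = z[0], rho * z[0] + np.sqrt(1 - rho**2) * z[1]
        truth = -0.5 * np.log(1 - rho**2)
        assert estimate_mi(x, y) == pytest.approx(truth, abs=0.08)

    def test_constant_vector_is_zero_with_warning(self, rng):
        x = np.ones(50)
        y = rng.standard_normal(50)
        with pytest.warns(UserWarning, match="constant"):
            assert estimate_mi(x, y) == 0.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            estimate_mi(np.arange(5.0), np.arange(5.0))

    def test_nonnegative(self, rng):
        for _ in range(20):
            x = rng.standard_normal(64)
            y = rng.standard_normal(64)
            assert estimate_mi(x, y) >= 0.0

    def test_chunked_matches_single_pair(self, rng):
        mat = rng.standard_normal((6, 120))
        b = inference.default_n_bins(120)
        bins = inference.equal_frequency_bins(mat, b).astype(np.int64)
        ii, jj = inference._pair_index(6)
        bulk = inference._chunked_joint_mi(bins, ii, jj, b, chunk=4)
        for idx, (i, j) in enumerate(zip(ii, jj)):
            assert bulk[idx] == pytest.approx(estimate_mi(mat[i], mat[j]), abs=1e-12)


class TestPermutationPvalues:
    def test_score_below_all_null_gives_one(self):
        p = inference.pvalues_from_null(np.array([0.0]), np.linspace(0.1, 1, 100))
        assert p[0] == 1.0

    def test_score_above_all_null_gives_pseudocount(self):
        p = inference.pvalues_from_null(np.array([2.0]), np.linspace(0.1, 1, 10_000))
        assert p[0] == pytest.approx(1 / 10_001)

    def test_equal_scores_equal_pvalues(self, rng):
        null = rng.random(500)
        p = inference.pvalues_from_null(np.array([0.4, 0.4]), null)
        assert p[0] == p[1]

    def test_monotone_in_score(self, rng):
        null = rng.random(1000)
        scores = np.sort(rng.random(50))
        p = inference.pvalues_from_null(scores, null)
        assert (np.diff(p) <= 0).all()

    def test_end_to_end_attaches_valid_pvalues(self, rng):
        mat = rng.standard_normal((10, 60))
        mat[1] = mat[0] + 0.01 * rng.standard_normal(60)  # one real edge
        study = make_study(mat, [f"g{i:02d}" for i in range(10)], ["a"] * 30 + ["b"] * 30)
        cfg = MIEstimatorConfig(seed=3, n_permutations=500)
        net = inference.build_network(study, "a", measure="mi", cfg=cfg, n_permutations=500)
        assert net.edges["p_value"].between(0, 1).all()
        # the planted pair must get the most significant p-value
        best = net.edges.iloc[0]
        assert {best["gene_a"], best["gene_b"]} == {"g00", "g01"}
        assert best["p_value"] == net.edges["p_value"].min()


class TestSelection:
    def test_identity_when_k_is_total(self):
        net = make_network([("a", "b", 5.0), ("a", "c", 4.0), ("b", "c", 3.0)])
        assert inference.select_top_edges(net, 3).edges.equals(net.edges)

    def test_top_two_of_five(self):
        net = make_network(
            [("a", "b", 5.0), ("a", "c", 4.0), ("a", "d", 3.0), ("a", "e", 2.0), ("a", "f", 1.0)]
        )
        top = inference.select_top_edges(net, 2)
        assert list(top.edges["score"]) == [5.0, 4.0]

    def test_invalid_k(self):
        net = make_network([("a", "b", 1.0)])
        with pytest.raises(ValueError):
            inference.select_top_edges(net, 0)
        with pytest.raises(ValueError):
            inference.select_top_edges(net, 2)

    def test_topk_nesting(self, rng):
        edges = [(f"a{i:03d}", f"b{i:03d}", float(s)) for i, s in enumerate(rng.random(40))]
        net = make_network(edges)
        prev: set = set()
        for k in range(1, 41):
            cur = set(map(tuple, inference.select_top_edges(net, k).edges[["gene_a", "gene_b"]].values))
            assert prev <= cur
            prev = cur

    def test_deterministic_tie_break(self):
        net = make_network([("x", "y", 1.0), ("a", "b", 1.0), ("m", "n", 1.0)])
        top = inference.select_top_edges(net, 2)
        assert list(top.edges["gene_a"]) == ["a", "m"]


class TestCisTransLabels:
    def test_basic_labels(self, two_chrom_annotation):
        net = make_network([("gA", "gB", 1.0), ("gA", "gC", 0.9)])
        labelled = inference.label_cis_trans(net, two_chrom_annotation)
        by_pair = {
            (r.gene_a, r.gene_b): r.cis for r in labelled.edges.itertuples()
        }
        assert bool(by_pair[("gA", "gB")]) is True  # same chromosome
        assert bool(by_pair[("gA", "gC")]) is False

    def test_single_chromosome_network_all_cis(self, two_chrom_annotation):
        net = make_network([("gA", "gB", 1.0)])
        labelled = inference.label_cis_trans(net, two_chrom_annotation)
        assert labelled.cis_fraction() == 1.0

    def test_missing_gene_raises_with_names(self, two_chrom_annotation):
        net = make_network([("gA", "zz", 1.0)])
        with pytest.raises(ValueError, match="zz"):
            inference.label_cis_trans(net, two_chrom_annotation)


class TestCurvesAndHistograms:
    def _labelled(self, two_chrom_annotation, edges):
        return inference.label_cis_trans(make_network(edges), two_chrom_annotation)

    def test_all_cis_curve_constant(self, two_chrom_annotation):
        net = self._labelled(
            two_chrom_annotation, [("gA", "gB", 3.0), ("gC", "gD", 2.0)]
        )
        curve = inference.cis_fraction_curve(net, [1, 2])
        assert list(curve["cis_fraction"]) == [1.0, 1.0]

    def test_total_k_gives_overall_fraction(self, two_chrom_annotation):
        net = self._labelled(
            two_chrom_annotation,
            [("gA", "gB", 3.0), ("gA", "gC", 2.0), ("gC", "gD", 1.0)],
        )
        curve = inference.cis_fraction_curve(net, [3])
        assert curve["cis_fraction"].iloc[0] == pytest.approx(net.cis_fraction())

    def test_unsorted_grid_raises(self, two_chrom_annotation):
        net = self._labelled(two_chrom_annotation, [("gA", "gB", 3.0)])
        with pytest.raises(ValueError, match="sorted"):
            inference.cis_fraction_curve(net, [2, 1])

    def test_histogram_conservation(self, two_chrom_annotation, rng):
        edges_a = [("gA", "gB", 0.5), ("gA", "gC", 0.2), ("gC", "gD", 0.8)]
        edges_b = [("gA", "gD", 0.4), ("gB", "gC", 0.6)]
        na = self._labelled(two_chrom_annotation, edges_a)
        nb = self._labelled(two_chrom_annotation, edges_b)
        h_all = inference.score_histograms(na, nb, "all", n_bins=10)
        h_cis = inference.score_histograms(na, nb, "cis", n_bins=10)
        h_trans = inference.score_histograms(na, nb, "trans", n_bins=10)
        assert h_all["count_a"].sum() == len(na)
        assert h_all["count_b"].sum() == len(nb)
        # strata conserve counts per network even if binned on their own range
        assert h_cis["count_a"].sum() + h_trans["count_a"].sum() == len(na)
        assert h_cis["count_b"].sum() + h_trans["count_b"].sum() == len(nb)

    def test_empty_stratum_all_zero(self, two_chrom_annotation):
        na = self._labelled(two_chrom_annotation, [("gA", "gB", 0.5)])
        nb = self._labelled(two_chrom_annotation, [("gC", "gD", 0.7)])
        h = inference.score_histograms(na, nb, "trans", n_bins=5)
        assert h["count_a"].sum() == 0 and h["count_b"].sum() == 0


class TestPearsonMatrix:
    def test_unit_diagonal_and_symmetry(self, two_chrom_annotation, rng):
        mat = rng.standard_normal((4, 40))
        study = make_study(mat, ["gA", "gB", "gC", "gD"], ["a"] * 20 + ["b"] * 20)
        cm = inference.pearson_matrix(study, two_chrom_annotation)
        assert np.allclose(np.diag(cm.to_numpy()), 1.0)
        assert np.allclose(cm.to_numpy(), cm.to_numpy().T)

    def test_independent_genes_near_zero(self, two_chrom_annotation):
        rng = np.random.default_rng(7)
        mat = rng.standard_normal((4, 10_000))
        study = make_study(mat, ["gA", "gB", "gC", "gD"], ["a"] * 5000 + ["b"] * 5000)
        cm = inference.pearson_matrix(study, two_chrom_annotation)
        off = cm.to_numpy()[np.triu_indices(4, 1)]
        assert (np.abs(off) < 0.05).all()

    def test_position_ordering(self):
        ann = make_annotation(
            [
                ("g3", "2", 100, 200, "+"),
                ("g1", "1", 500, 600, "+"),
                ("g2", "1", 100, 200, "+"),
            ]
        )
        rng = np.random.default_rng(0)
        study = make_study(rng.standard_normal((3, 20)), ["g1", "g2", "g3"], ["a"] * 10 + ["b"] * 10)
        cm = inference.pearson_matrix(study, ann)
        assert list(cm.index) == ["g2", "g1", "g3"]

    def test_planted_blocks_dominate(self):
        from coexnet import simulate

        genome = simulate.default_genome(120)
        ann = simulate.generate_annotation(genome, seed=1)
        mods = simulate.make_cis_modules(ann, 2, 5, 0.9, seed=2)
        cfg = simulate.SyntheticStudyConfig(
            genome=genome,
            modules={"healthy": mods, "tumor": mods},
            n_samples_per_group={"healthy": 150, "tumor": 2},
            noise_sd=0.1,
            seed=3,
        )
        study = simulate.generate_expression(cfg, ann)
        cm = inference.pearson_matrix(study, ann, group="healthy")
        chrom_of = dict(zip(ann["gene"], ann["chrom"]))
        within = []
        for m in mods:
            sub = cm.loc[list(m.gene_ids), list(m.gene_ids)].to_numpy()
            within.append(np.abs(sub[np.triu_indices(len(m.gene_ids), 1)]).mean())
        genes = list(cm.index)
        cross = [
            abs(cm.iloc[i, j])
            for i in range(0, len(genes), 7)
            for j in range(i + 1, len(genes), 11)
            if chrom_of[genes[i]] != chrom_of[genes[j]]
        ]
        assert min(within) > np.mean(cross) + 0.3


class TestBuildNetwork:
    def test_constant_gene_dropped_with_warning(self, rng):
        mat = rng.standard_normal((5, 30))
        mat[2] = 1.0
        study = make_study(mat, list("abcde"), ["x"] * 15 + ["y"] * 15)
        with pytest.warns(UserWarning, match="constant"):
            net = inference.build_network(study, "x", measure="pearson")
        assert "c" not in set(net.edges["gene_a"]) | set(net.edges["gene_b"])

    def test_pearson_scores_match_numpy(self, rng):
        mat = rng.standard_normal((4, 50))
        study = make_study(mat, list("abcd"), ["x"] * 25 + ["y"] * 25)
        net = inference.build_network(study, "x", measure="pearson")
        ref = np.corrcoef(mat[:, :25])
        lookup = {(r.gene_a, r.gene_b): r.score for r in net.edges.itertuples()}
        names = list("abcd")
        for i in range(4):
            for j in range(i + 1, 4):
                assert lookup[(names[i], names[j])] == pytest.approx(abs(ref[i, j]), abs=1e-12)

    def test_pcut_filters_before_topk(self, rng):
        mat = rng.standard_normal((8, 60))
        mat[1] = mat[0] + 0.01 * rng.standard_normal(60)
        study = make_study(mat, [f"g{i}" for i in range(8)], ["x"] * 30 + ["y"] * 30)
        cfg = MIEstimatorConfig(seed=0, n_permutations=400)
        net = inference.build_network(
            study, "x", measure="mi", cfg=cfg, p_cut=2 / 401, top_k=10
        )
        assert len(net) <= 10
        assert (net.edges["p_value"] <= 2 / 401).all()
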