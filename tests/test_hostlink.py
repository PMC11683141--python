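import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rhizoguild as rg


class TestFpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"s": [10]}, index=["g"])
        out = rg.fpkm(counts, pd.Series({"g": 1000}), pd.Series({"s": 1_000_000}))
        assert out.loc["g", "s"] == pytest.approx(10.0)

    def test_doubling_total_halves(self):
        counts = pd.DataFrame({"s1": [8], "s2": [8]}, index=["g"])
        out = rg.fpkm(
            counts, pd.Series({"g": 500}), pd.Series({"s1": 1e6, "s2": 2e6})
        )
        assert out.loc["g", "s1"] == pytest.approx(2 * out.loc["g", "s2"])

    def test_matches_per_cell_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(20)]
        samples = [f"s{j}" for j in range(4)]
        counts = pd.DataFrame(rng.integers(0, 100, (20, 4)), index=genes,
                              columns=samples)
        lengths = pd.Series(rng.integers(200, 3000, 20), index=genes)
        totals = pd.Series(rng.integers(int(1e6), int(2e7), 4), index=samples)
        out = rg.fpkm(counts, lengths, totals)
        for g, s in itertools.product(genes, samples):
            expected = counts.loc[g, s] * 1e9 / (lengths[g] * totals[s])
            assert out.loc[g, s] == pytest.approx(expected)

    def test_zero_length_error(self):
        counts = pd.DataFrame({"s": [1]}, index=["g"])
        with pytest.raises(ValueError, match="g"):
            rg.fpkm(counts, pd.Series({"g": 0}), pd.Series({"s": 1e6}))


class TestStageProfiles:
    def test_constant_gene_dropped(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [1.0, 5.0], "s3": [1.0, 9.0], "s4": [1.0, 3.0]},
            index=["flat", "var"],
        )
        stages = pd.Series(["2YV", "2YV", "2YF", "2YF"],
                           index=["s1", "s2", "s3", "s4"])
        with pytest.warns(UserWarning, match="zero-variance"):
            prof = rg.stage_profiles(expr, stages)
        assert list(prof.index) == ["var"]

    def test_rows_standardized(self, scenario):
        b = scenario.expression
        f = rg.fpkm(b.counts, b.gene_lengths, b.mapped_totals)
        prof = rg.stage_profiles(f, b.sample_stages, stage_order=rg.ROOT_STAGES)
        assert np.allclose(prof.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(prof.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_two_gene_hand_computed(self):
        expr = pd.DataFrame(
            {"a1": [2.0, 0.0], "a2": [4.0, 2.0], "b1": [8.0, 1.0], "b2": [10.0, 3.0]},
            index=["g1", "g2"],
        )
        stages = pd.Series(["2YV", "2YV", "2YF", "2YF"], index=expr.columns)
        prof = rg.stage_profiles(expr, stages, stage_order=["2YV", "2YF"])
        # g1 stage means: 3, 9 -> z = (-1, 1)
        assert prof.loc["g1"].tolist() == pytest.approx([-1.0, 1.0])


class TestFuzzyCMeans:
    def test_memberships_sum_to_one_and_labels(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.05, (30, 4)) + np.array([1.0, -1.0, 1.0, -1.0])
        b = rng.normal(0, 0.05, (30, 4)) + np.array([-1.0, 1.0, -1.0, 1.0])
        prof = pd.DataFrame(np.vstack([a, b]),
                            index=[f"g{i}" for i in range(60)])
        cl = rg.fuzzy_cmeans(prof, k=2, seed=0)
        assert np.allclose(cl.membership.sum(axis=1), 1.0, atol=1e-9)
        from sklearn.metrics import adjusted_rand_score

        truth = [0] * 30 + [1] * 30
        ari = adjusted_rand_score(truth, cl.labels.factorize()[0])
        assert ari == 1.0

    def test_objective_nonincreasing(self):
        rng = np.random.default_rng(2)
        prof = pd.DataFrame(rng.normal(size=(80, 5)),
                            index=[f"g{i}" for i in range(80)])
        cl = rg.fuzzy_cmeans(prof, k=4, seed=3)
        assert (np.diff(cl.objective) <= 1e-8).all()

    def test_point_on_centroid_limit_rule(self):
        # duplicate a point many times so a centroid lands on it exactly
        prof = pd.DataFrame(
            [[0.0, 0.0]] * 10 + [[5.0, 5.0]] * 10,
            index=[f"g{i}" for i in range(20)],
        )
        cl = rg.fuzzy_cmeans(prof, k=2, seed=1)
        assert np.allclose(cl.membership.max(axis=1), 1.0)

    def test_parameter_validation(self):
        prof = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            rg.fuzzy_cmeans(prof, k=5)
        with pytest.raises(ValueError):
            rg.fuzzy_cmeans(prof, k=2, fuzzifier=1.0)


class TestTrendMatch:
    def make_clustering(self, centroids: dict):
        stages = list(rg.ROOT_STAGES)
        cents = pd.DataFrame(centroids, index=stages).T
        genes = [f"g{i}" for i in range(10)]
        membership = pd.DataFrame(
            1.0 / len(cents), index=genes, columns=cents.index
        )
        return rg.FuzzyClustering(
            k=len(cents), fuzzifier=1.25, membership=membership,
            centroids=cents, labels=membership.idxmax(axis=1),
        )

    def test_perfect_match_and_antimatch(self):
        d = pd.Series([0.2, 0.25, 0.3, 0.4, 0.6, 0.8], index=rg.ROOT_STAGES)
        cl = self.make_clustering({"C1": d.to_numpy(), "C2": -d.to_numpy()})
        out = rg.trend_match(cl, d)
        assert out.iloc[0]["cluster"] == "C1"
        assert out.iloc[0]["score"] == pytest.approx(1.0)
        assert out.iloc[1]["score"] == pytest.approx(-1.0)

    def test_too_few_shared_stages(self):
        d = pd.Series([0.2, 0.8], index=["3YF", "3YR"])
        cl = self.make_clustering({"C1": np.arange(6.0)})
        with pytest.raises(ValueError):
            rg.trend_match(cl, d)

    def test_spearman_option(self):
        d = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5, 0.9], index=rg.ROOT_STAGES)
        cl = self.make_clustering({"C1": np.exp(d.to_numpy())})
        out = rg.trend_match(cl, d, method="spearman")
        assert out.iloc[0]["score"] == pytest.approx(1.0)


class TestEnrich:
    def test_whole_pathway_smallest_p(self):
        universe = [f"g{i}" for i in range(40)]
        pathways = {
            "hit": set(universe[:8]),
            "miss1": set(universe[10:18]),
            "miss2": set(universe[20:28]),
        }
        out = rg.enrich(universe[:8], pathways, universe)
        assert out.iloc[0]["pathway"] == "hit"
        assert out.iloc[0]["p"] < out.iloc[1]["p"]

    def test_exact_combinatorial_oracle(self):
        from math import comb

        n_univ, n_path, n_set, k = 20, 5, 6, 4
        universe = [f"g{i}" for i in range(n_univ)]
        pathway = set(universe[:n_path])
        gene_set = universe[:k] + universe[n_path : n_path + (n_set - k)]
        out = rg.enrich(gene_set, {"pw": pathway}, universe)
        oracle = sum(
            comb(n_path, i) * comb(n_univ - n_path, n_set - i)
            for i in range(k, min(n_path, n_set) + 1)
        ) / comb(n_univ, n_set)
        assert out.iloc[0]["p"] == pytest.approx(oracle, abs=1e-12)

    def test_zero_overlap_p_near_one(self):
        universe = [f"g{i}" for i in range(30)]
        out = rg.enrich(universe[20:25], {"pw": set(universe[:5])}, universe)
        assert out.iloc[0]["k"] == 0
        assert out.iloc[0]["p"] > 0.3

    def test_empty_pathway_skipped(self):
        universe = ["a", "b"]
        out = rg.enrich(["a"], {"ghost": {"zzz"}}, universe)
        assert out.empty


class TestCoexpressionNetwork:
    def test_duplicate_gene_edge_retained(self):
        rng = np.random.default_rng(3)
        base = rng.random(12)
        expr = pd.DataFrame(
            {f"s{i}": [base[i], base[i], rng.random()] for i in range(12)},
            index=["g1", "g1_copy", "noise"],
        )
        net = rg.coexpression_network(expr, rho_min=0.9, q_max=0.05)
        assert net.has_edge("g1", "g1_copy")
        assert net.edges["g1", "g1_copy"]["rho"] == pytest.approx(1.0)

    def test_independent_genes_yield_no_edges(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(
                rng.normal(size=(30, 20)), index=[f"g{i}" for i in range(30)]
            )
            net = rg.coexpression_network(expr)
            hits += net.number_of_edges() > 0
        assert hits <= 1

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(
            rng.normal(size=(10, 15)), index=[f"g{i}" for i in range(10)]
        )
        expr.iloc[1] = expr.iloc[0] * 2 + rng.normal(0, 0.01, 15)  # strong pair
        rho_min, q_max = 0.5, 0.05
        net = rg.coexpression_network(expr, rho_min=rho_min, q_max=q_max)
        # oracle
        pairs = list(itertools.combinations(expr.index, 2))
        raw = []
        for a, b in pairs:
            rho, p = stats.spearmanr(expr.loc[a], expr.loc[b])
            raw.append((a, b, rho, p))
        from statsmodels.stats.multitest import multipletests

        q = multipletests([r[3] for r in raw], method="fdr_bh")[1]
        expected = {
            frozenset((a, b))
            for (a, b, rho, _), qq in zip(raw, q)
            if rho > rho_min and qq < q_max
        }
        got = {frozenset(e) for e in net.edges}
        assert got == expected

    def test_needs_six_samples(self):
        expr = pd.DataFrame(np.random.default_rng(0).random((4, 5)))
        with pytest.raises(ValueError):
            rg.coexpression_network(expr)


class TestSubnetworkAndTFs:
    def make_star(self):
        net = nx.Graph()
        net.add_edges_from(
            [("hub", f"leaf{i}", {"rho": 0.95}) for i in range(4)]
            + [("far1", "far2", {"rho": 0.99})]
        )
        return net

    def test_star_center_keeps_whole_star(self):
        net = self.make_star()
        sub, isolated = rg.pathway_subnetwork(net, ["hub"])
        assert set(sub.nodes) == {"hub", "leaf0", "leaf1", "leaf2", "leaf3"}
        assert isolated == []

    def test_neighbor_of_neighbor_excluded(self):
        net = nx.path_graph(["a", "b", "c", "d"])
        sub, _ = rg.pathway_subnetwork(net, ["a"])
        assert set(sub.nodes) == {"a", "b"}

    def test_matches_bfs_depth1_oracle(self):
        rng = np.random.default_rng(5)
        net = nx.gnp_random_graph(30, 0.15, seed=2)
        seeds = [0, 5, 9]
        sub, _ = rg.pathway_subnetwork(net, seeds)
        expected = set(seeds)
        for s in seeds:
            expected |= set(net.neighbors(s))
        assert set(sub.nodes) == expected

    def test_missing_pathway_gene_isolated(self):
        net = self.make_star()
        _, isolated = rg.pathway_subnetwork(net, ["hub", "absent"])
        assert isolated == ["absent"]

    def test_tf_bipartite_toy(self):
        net = nx.Graph()
        net.add_edge("tf1", "bio1", rho=0.95)
        net.add_edge("tf2", "bio1", rho=0.92)
        net.add_edge("tf1", "tf2", rho=0.99)  # TF-TF: excluded
        net.add_edge("bio1", "bio2", rho=0.97)  # gene-gene: excluded
        out = rg.tf_bipartite(
            net, {"tf1": "MYB", "tf2": "NAC"}, ["bio1", "bio2"]
        )
        assert len(out) == 2
        assert set(out["tf"]) == {"tf1", "tf2"}
        assert set(out["tf_family"]) == {"MYB", "NAC"}
        assert (out["gene"] == "bio1").all()
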