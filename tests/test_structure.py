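import itertools

import numpy as np
import pandas as pd
import pytest

import rhizoguild as rg


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        table = rg.FeatureTable(
            pd.DataFrame({"a": [5, 5, 0], "b": [5, 5, 0], "c": [0, 0, 10]},
                         index=["x", "y", "z"])
        )
        dm = rg.bray_curtis(table)
        assert dm.to_frame().loc["a", "b"] == 0.0
        assert dm.to_frame().loc["a", "c"] == 1.0

    def test_hand_computed(self, toy_table):
        dm = rg.bray_curtis(toy_table)
        # x=(6,4,0), y=(2,4,4): (4+0+4)/(8+8+4) = 0.4
        assert dm.to_frame().loc["s1", "s2"] == pytest.approx(0.4)

    def test_zero_sum_sample_error(self):
        table = rg.FeatureTable(pd.DataFrame({"a": [1], "b": [0]}, index=["x"]))
        with pytest.raises(rg.ValidationError, match="b"):
            rg.bray_curtis(table)


class TestPcoa:
    def test_line_recovery(self):
        """Distances from collinear points: axis 1 recovers the line."""
        pts = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        ids = [f"s{i}" for i in range(5)]
        d = np.abs(pts[:, None] - pts[None, :])
        ord_res = rg.pcoa(rg.DistanceMatrix(ids, d))
        axis1 = ord_res.coordinates.iloc[:, 0].to_numpy()
        r = abs(np.corrcoef(axis1, pts)[0, 1])
        assert r > 0.999

    def test_percent_explained_sums_to_one(self, scenario, assignment):
        bac = scenario.dataset.bacterial.subset_samples(
            scenario.dataset.bacterial.sample_ids[:20]
        )
        ord_res = rg.pcoa(rg.bray_curtis(bac))
        assert ord_res.proportion_explained.sum() == pytest.approx(1.0)

    def test_duplicate_samples_identical_coordinates(self):
        table = rg.FeatureTable(
            pd.DataFrame({"a": [3, 1], "b": [3, 1], "c": [0, 5]}, index=["x", "y"])
        )
        ord_res = rg.pcoa(rg.bray_curtis(table))
        assert np.allclose(
            ord_res.coordinates.loc["a"], ord_res.coordinates.loc["b"], atol=1e-9
        )

    def test_matches_scikit_bio(self):
        """Independent cross-check of eigenvalues against scikit-bio."""
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(0)
        x = rng.random((8, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        ids = [f"s{i}" for i in range(8)]
        ours = rg.pcoa(rg.DistanceMatrix(ids, d))
        theirs = skbio_pcoa(SkbioDM(d, ids), method="eigh")
        np.testing.assert_allclose(
            ours.eigenvalues[:4],
            np.asarray(theirs.eigvals)[:4],
            rtol=1e-8, atol=1e-10,
        )

    def test_non_symmetric_rejected(self):
        m = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(rg.ValidationError):
            rg.DistanceMatrix(["a", "b"], m)


class TestPermanova:
    def test_r2_identity(self, scenario, metadata_factory):
        bac = scenario.dataset.bacterial.subset_samples(
            scenario.dataset.bacterial.sample_ids[:30]
        )
        dm = rg.bray_curtis(bac)
        res = rg.permanova(dm, scenario.dataset.metadata, "stage", n_perm=99, seed=1)
        assert res.r2 == pytest.approx(1 - res.ss_within / res.ss_total)
        assert res.ss_among + res.ss_within == pytest.approx(res.ss_total)

    def test_degenerate_separated_groups(self, metadata_factory):
        """Two internally (near-)homogeneous, mutually distinct groups:
        R² → 1 and the permutation p reaches its floor 1/(1+n_perm)."""
        cols = {}
        for i in range(10):
            cols[f"a{i}"] = [90 + (i == 0), 10]  # one-read jitter keeps F finite
            cols[f"b{i}"] = [10, 90 + (i == 0)]
        table = rg.FeatureTable(pd.DataFrame(cols, index=["x", "y"]))
        md = metadata_factory(table.sample_ids, ["BL", "2YV"] * 10)
        res = rg.permanova(rg.bray_curtis(table), md, "stage", n_perm=999, seed=3)
        assert res.r2 == pytest.approx(1.0, abs=1e-3)
        assert res.p == pytest.approx(1 / (1 + 999))

    def test_singleton_group_error(self, metadata_factory):
        table = rg.FeatureTable(
            pd.DataFrame({"a": [1, 2], "b": [2, 1], "c": [3, 3]}, index=["x", "y"])
        )
        md = metadata_factory(["a", "b", "c"], ["BL", "BL", "2YV"])
        with pytest.raises(ValueError):
            rg.permanova(rg.bray_curtis(table), md, "stage")

    def test_sample_order_invariance(self, metadata_factory, neutral_table_factory):
        table = neutral_table_factory(5, n_taxa=20, depth=200, n_samples=12)
        md = metadata_factory(table.sample_ids, ["BL"] * 6 + ["2YV"] * 6)
        dm = rg.bray_curtis(table)
        res1 = rg.permanova(dm, md, "stage", n_perm=199, seed=9)
        shuffled = table.subset_samples(table.sample_ids[::-1])
        res2 = rg.permanova(rg.bray_curtis(shuffled), md, "stage", n_perm=199, seed=9)
        assert res1.pseudo_f == pytest.approx(res2.pseudo_f)
        assert res1.p == res2.p

    def test_pseudo_f_matches_scikit_bio(self, metadata_factory,
                                         neutral_table_factory):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        table = neutral_table_factory(6, n_taxa=25, depth=300, n_samples=12)
        md = metadata_factory(table.sample_ids, ["BL"] * 4 + ["2YV"] * 4 + ["3YR"] * 4)
        dm = rg.bray_curtis(table)
        ours = rg.permanova(dm, md, "stage", n_perm=99, seed=0)
        theirs = skbio_permanova(
            SkbioDM(dm.matrix, dm.sample_ids),
            md.data.loc[dm.sample_ids, "stage"].to_numpy(),
            permutations=99,
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_stage_effect_detected_on_selected_scenario(self, scenario, assignment):
        """Stage-driven selection in the generator shows up as a
        significant stage effect on the beneficial subcommunity."""
        bac = scenario.dataset.bacterial
        pbb = rg.subset_by_guild(bac, assignment, "PBB")
        dm = rg.bray_curtis(pbb)
        res = rg.permanova(dm, scenario.dataset.metadata, "stage", n_perm=199, seed=2)
        assert res.p <= 0.05


class TestBetaDispersion:
    def test_identical_group_zero(self, metadata_factory):
        table = rg.FeatureTable(
            pd.DataFrame(
                {"a1": [5, 5], "a2": [5, 5], "b1": [1, 9], "b2": [2, 8]},
                index=["x", "y"],
            )
        )
        md = metadata_factory(["a1", "a2", "b1", "b2"], ["BL", "BL", "2YV", "2YV"])
        disp = rg.beta_dispersion(rg.bray_curtis(table), md, "stage")
        assert disp.loc["a1", "distance_to_centroid"] == pytest.approx(0.0, abs=1e-9)
        assert disp.loc["a2", "distance_to_centroid"] == pytest.approx(0.0, abs=1e-9)

    def test_two_points_half_distance(self, metadata_factory):
        table = rg.FeatureTable(
            pd.DataFrame({"a": [10, 0], "b": [0, 10]}, index=["x", "y"])
        )
        md = metadata_factory(["a", "b"], ["BL", "BL"])
        dm = rg.bray_curtis(table)
        disp = rg.beta_dispersion(dm, md, "stage")
        pair = dm.to_frame().loc["a", "b"]
        assert np.allclose(disp["distance_to_centroid"], pair / 2)

    def test_matches_bruteforce_euclidean(self, metadata_factory):
        """On a Euclidean distance matrix the PCoA-space centroid distance
        equals the direct coordinate-space computation."""
        rng = np.random.default_rng(1)
        pts = rng.random((9, 3))
        ids = [f"s{i}" for i in range(9)]
        from scipy.spatial.distance import pdist, squareform

        dm = rg.DistanceMatrix(ids, squareform(pdist(pts)))
        md = metadata_factory(ids, ["BL"] * 5 + ["2YV"] * 4)
        disp = rg.beta_dispersion(dm, md, "stage")
        for label, idx in (("BL", range(5)), ("2YV", range(5, 9))):
            centroid = pts[list(idx)].mean(axis=0)
            for i in idx:
                expected = np.linalg.norm(pts[i] - centroid)
                assert disp.loc[ids[i], "distance_to_centroid"] == pytest.approx(
                    expected, abs=1e-8
                )

    def test_singleton_group_nan_with_warning(self, metadata_factory):
        table = rg.FeatureTable(
            pd.DataFrame({"a": [5, 1], "b": [1, 5], "c": [3, 3]}, index=["x", "y"])
        )
        md = metadata_factory(["a", "b", "c"], ["BL", "BL", "2YV"])
        with pytest.warns(UserWarning, match="2YV"):
            disp = rg.beta_dispersion(rg.bray_curtis(table), md, "stage")
        assert np.isnan(disp.loc["c", "distance_to_centroid"])


class TestSimper:
    def test_decomposition_identity(self, scenario):
        bac = scenario.dataset.bacterial.subset_samples(
            scenario.dataset.bacterial.sample_ids[:30]
        )
        res = rg.simper(bac, scenario.dataset.metadata, "stage")
        dm = rg.bray_curtis(bac).to_frame()
        labels = scenario.dataset.metadata.stage_series(bac.sample_ids)
        for (ga, gb), contrib in res.pairwise.items():
            ia = labels.index[labels == ga]
            ib = labels.index[labels == gb]
            mean_bc = np.mean([dm.loc[a, b] for a in ia for b in ib])
            assert contrib.sum() == pytest.approx(mean_bc, abs=1e-12)

    def test_absent_taxon_zero(self, metadata_factory):
        table = rg.FeatureTable(
            pd.DataFrame(
                {"a": [3, 0, 0], "b": [1, 2, 0], "c": [0, 3, 0], "d": [2, 2, 0]},
                index=["x", "y", "ghost"],
            )
        )
        md = metadata_factory(["a", "b", "c", "d"], ["BL", "BL", "2YV", "2YV"])
        res = rg.simper(table, md, "stage")
        assert res.overall_ranking["ghost"] == 0.0

    def test_two_taxon_hand_computed(self, metadata_factory):
        table = rg.FeatureTable(
            pd.DataFrame({"a": [6, 4], "b": [2, 8]}, index=["x", "y"])
        )
        md = metadata_factory(["a", "b"], ["BL", "2YV"])
        res = rg.simper(table, md, "stage")
        contrib = res.pairwise[("BL", "2YV")]
        assert contrib["x"] == pytest.approx(4 / 20)
        assert contrib["y"] == pytest.approx(4 / 20)


class TestLocalPolynomialFit:
    def test_constant(self):
        x = np.arange(7.0)
        out = rg.local_polynomial_fit(x, np.full(7, 3.0), span=0.8)
        assert np.allclose(out["fitted"], 3.0)

    def test_linear_recovered(self):
        x = np.arange(10.0)
        y = 2.0 * x - 1.0
        out = rg.local_polynomial_fit(x, y, span=1.0)
        assert np.max(np.abs(out["fitted"] - (2.0 * out["x"] - 1.0))) < 1e-10

    def test_matches_tricube_oracle(self):
        """Agrees with a direct tricube-weighted local-linear solve."""
        rng = np.random.default_rng(2)
        x = np.sort(rng.random(25)) * 10
        y = np.sin(x) + rng.normal(0, 0.1, 25)
        span = 0.5
        out = rg.local_polynomial_fit(x, y, span=span, grid=x)
        k = int(span * len(x))
        for grid_i in range(5, 20):  # interior points
            x0 = x[grid_i]
            dist = np.abs(x - x0)
            h = np.sort(dist)[k - 1]
            w = np.clip(1 - (dist / h) ** 3, 0, None) ** 3
            wmask = w > 0
            X = np.column_stack([np.ones(wmask.sum()), x[wmask] - x0])
            W = np.diag(w[wmask])
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[wmask])
            assert out["fitted"].iloc[grid_i] == pytest.approx(beta[0], abs=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError):
            rg.local_polynomial_fit([1, 2, 3], [1, 2, 3], span=0.5)
        with pytest.raises(ValueError):
            rg.local_polynomial_fit(np.arange(10.0), np.arange(10.0), span=0.05)
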