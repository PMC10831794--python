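"""Statistics, trend tools, quantification and pathway projection."""

import numpy as np
import pandas as pd
import pytest

from metaline import analyze, simdata
from metaline.analyze import PathwayGraph
from tests.conftest import make_matrix


def random_matrix(n_samples=8, n_features=20, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(10.0, 1.0, size=(n_samples, n_features))
    data = {f"f{i}": {f"s{j}": X[j, i] for j in range(n_samples)}
            for i in range(n_features)}
    return make_matrix(data)


class TestFoldChange:
    def test_identical_groups_null(self):
        m = make_matrix({"f": {"a1": 100.0, "a2": 110.0, "b1": 100.0,
                               "b2": 110.0}})
        out = analyze.fold_change_tests(m, ["a1", "a2"], ["b1", "b2"])
        assert out["log2fc"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] > 0.9

    def test_planted_fourfold_recovered_at_q05(self):
        rng = np.random.default_rng(2)
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        data = {}
        for i in range(30):
            fc = 4.0 if i < 5 else 1.0
            vals = {}
            for s in samples:
                mean = 1000.0 * (fc if s.startswith("b") else 1.0)
                vals[s] = mean * rng.lognormal(0.0, 0.1)
            data[f"f{i}"] = vals
        m = make_matrix(data)
        out = analyze.fold_change_tests(m, [s for s in samples if s[0] == "a"],
                                        [s for s in samples if s[0] == "b"])
        hits = set(np.flatnonzero((out["q"] < 0.05).to_numpy()))
        assert hits == {0, 1, 2, 3, 4}
        assert (out["log2fc"].iloc[:5] > 1.5).all()

    def test_all_missing_group_flagged(self):
        m = make_matrix({"f": {"a1": 100.0, "a2": 90.0, "b1": np.nan,
                               "b2": np.nan}})
        out = analyze.fold_change_tests(m, ["a1", "a2"], ["b1", "b2"])
        assert out["flag"].iloc[0] == "group_all_missing"
        assert np.isnan(out["p"].iloc[0])

    def test_stars_convention(self):
        assert analyze.significance_stars(0.04) == "*"
        assert analyze.significance_stars(0.009) == "**"
        assert analyze.significance_stars(0.0009) == "***"
        assert analyze.significance_stars(0.00009) == "****"
        assert analyze.significance_stars(0.2) == ""


class TestPCA:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(3)
        data = {}
        for i in range(15):
            vals = {}
            for j in range(10):
                shift = 5.0 if j < 5 else -5.0
                vals[f"s{j}"] = 100.0 + (shift if i < 8 else 0.0) + rng.normal()
            data[f"f{i}"] = vals
        res = analyze.pca(make_matrix(data), 2)
        pc1 = res.scores["PC1"].to_numpy()
        assert (np.sign(pc1[:5]) != np.sign(pc1[5:])).all()

    def test_scores_orthogonal(self):
        res = analyze.pca(random_matrix(), 3)
        S = res.scores.to_numpy()
        G = S.T @ S
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_csv_import_equivalent(self, tmp_path):
        from metaline import msio

        m = random_matrix()
        path = str(tmp_path / "m.csv")
        msio.export_matrix(m, path)
        res1 = analyze.pca(m, 2)
        res2 = analyze.pca(msio.import_matrix_csv(path), 2)
        assert np.allclose(res1.scores.values, res2.scores.values, atol=1e-8)


class TestCPCA:
    def test_single_block_equals_pca(self):
        m = random_matrix()
        p = analyze.pca(m, 3)
        c = analyze.cpca([m], 3)
        assert np.abs(p.scores.values - c.super_scores.values).max() < 1e-8
        assert np.abs(p.loadings.values - c.block_loadings[0].values).max() < 1e-8

    def test_identical_blocks_equal_weights(self):
        m = random_matrix()
        c = analyze.cpca([m, m], 2)
        w = c.block_weights.to_numpy()
        assert np.allclose(w[:, 0], w[:, 1], atol=1e-8)

    def test_matches_concatenated_pca_oracle(self):
        """CPCA-W super scores equal PCA scores of the concatenated blocks
        (independent SVD route)."""
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(4)
        b1 = pd.DataFrame(rng.normal(size=(9, 12)))
        b2 = pd.DataFrame(rng.normal(size=(9, 5)))
        c = analyze.cpca([b1, b2], 3, scaling="uv")
        Z = np.hstack([analyze._scale(b1.to_numpy(), "uv"),
                       analyze._scale(b2.to_numpy(), "uv")])
        t = SkPCA(3, svd_solver="full").fit_transform(Z)
        for k in range(3):
            if np.sign(t[0, k]) != np.sign(c.super_scores.values[0, k]):
                t[:, k] *= -1
        assert np.abs(t - c.super_scores.values).max() < 1e-6


class TestPLSDA:
    def test_separates_classes(self):
        rng = np.random.default_rng(5)
        data = {}
        for i in range(12):
            vals = {}
            for j in range(10):
                shift = 3.0 if (j < 5 and i < 6) else 0.0
                vals[f"s{j}"] = 50.0 + shift + rng.normal()
            data[f"f{i}"] = vals
        classes = {f"s{j}": ("A" if j < 5 else "B") for j in range(10)}
        res = analyze.plsda(make_matrix(data), classes, 2)
        assert res.accuracy == 1.0
        assert res.r2y > 0.8


def planted_trend_matrix(seed=0, n_per_group=20, noise=0.25):
    """Features following one of three distinct label trends + noise."""
    rng = np.random.default_rng(seed)
    trends = {0: np.array([1.0, 2.0, 3.0, 4.0]),
              1: np.array([4.0, 3.0, 2.0, 1.0]),
              2: np.array([1.0, 4.0, 1.0, 4.0])}
    samples = [f"t{k}_r{r}" for k in range(4) for r in range(2)]
    labels = {s: s.split("_")[0] for s in samples}
    data, truth = {}, {}
    for g, base in trends.items():
        for i in range(n_per_group):
            fname = f"g{g}_f{i}"
            truth[fname] = g
            vals = {}
            for s in samples:
                lev = base[int(s[1])]
                vals[s] = 1000.0 * lev * rng.lognormal(0.0, noise)
            data[fname] = vals
    m = make_matrix(data)
    rename = dict(zip(data, m.areas.columns))
    return m, labels, {rename[k]: v for k, v in truth.items()}, trends


class TestTrendTools:
    def test_match_trend_equals_direct_correlation_oracle(self):
        m, labels, truth, trends = planted_trend_matrix(seed=1)
        target = trends[0]
        z = analyze.trend_vectors(m, labels, ["t0", "t1", "t2", "t3"])
        # oracle: direct Pearson correlation per feature
        expected = set()
        for name, vec in z.iterrows():
            r = np.corrcoef(vec, target)[0, 1]
            if r >= 0.8:
                expected.add(name)
        got = analyze.match_trend(m, target, 0.8, labels,
                                  ["t0", "t1", "t2", "t3"])
        assert set(got["feature"]) == expected
        assert (got["r"].diff().dropna() <= 1e-12).all()  # sorted

    def test_match_trend_keeps_self_excludes_inverse(self):
        m, labels, truth, trends = planted_trend_matrix(seed=2, noise=0.0)
        got = analyze.match_trend(m, trends[0], 0.8, labels,
                                  ["t0", "t1", "t2", "t3"])
        kept_groups = {truth[f] for f in got["feature"]}
        assert kept_groups == {0}
        assert np.allclose(got["r"], 1.0)

    def test_result_monotone_in_threshold(self):
        m, labels, _, trends = planted_trend_matrix(seed=3)
        sets = []
        for r_min in (-1.0, 0.0, 0.5, 0.9):
            got = analyze.match_trend(m, trends[0], r_min, labels,
                                      ["t0", "t1", "t2", "t3"])
            sets.append(set(got["feature"]))
        for a, b in zip(sets, sets[1:]):
            assert b <= a
        # r_min=-1 returns every non-constant feature
        assert len(sets[0]) == m.areas.shape[1]

    def test_three_planted_groups_recovered(self):
        """K-means and bisecting K-means recover the planted structure at
        ARI >= 0.9 across 10 seeds."""
        from sklearn.metrics import adjusted_rand_score

        for method in ("kmeans", "bisecting"):
            aris = []
            for seed in range(10):
                m, labels, truth, _ = planted_trend_matrix(seed=seed)
                clusters = analyze.cluster_trends(
                    m, 3, method, seed=seed, labels=labels,
                    label_order=["t0", "t1", "t2", "t3"])
                pred, true = [], []
                for ci, cl in enumerate(clusters):
                    for f in cl.members:
                        pred.append(ci)
                        true.append(truth[f])
                aris.append(adjusted_rand_score(true, pred))
            assert np.mean(aris) >= 0.9

    def test_k1_quality_definition(self):
        m, labels, _, _ = planted_trend_matrix(seed=5, noise=0.0)
        (cl,) = analyze.cluster_trends(m, 1, labels=labels,
                                       label_order=["t0", "t1", "t2", "t3"])
        z = analyze.trend_vectors(m, labels, ["t0", "t1", "t2", "t3"])
        mean_trend = z.to_numpy().mean(axis=0)
        rs = [np.corrcoef(row, mean_trend)[0, 1] for row in z.to_numpy()]
        expected = 100.0 * np.mean(np.asarray(rs) >= 0.8)
        assert cl.quality == pytest.approx(expected)

    def test_fixed_seed_reproducible(self):
        m, labels, _, _ = planted_trend_matrix(seed=6)
        kw = dict(labels=labels, label_order=["t0", "t1", "t2", "t3"])
        c1 = analyze.cluster_trends(m, 3, seed=7, **kw)
        c2 = analyze.cluster_trends(m, 3, seed=7, **kw)
        assert [c.members for c in c1] == [c.members for c in c2]

    def test_quality_invariant_to_order_and_affine_scaling(self):
        m, labels, _, _ = planted_trend_matrix(seed=8)
        kw = dict(labels=labels, label_order=["t0", "t1", "t2", "t3"])
        base = analyze.cluster_trends(m, 3, seed=0, **kw)
        # affine rescaling of every feature's areas
        m2 = m.child(m.areas * 7.5 + 0.0, "rescale", {})
        scaled = analyze.cluster_trends(m2, 3, seed=0, **kw)
        assert sorted(c.quality for c in base) == \
            pytest.approx(sorted(c.quality for c in scaled))
        # column order permutation
        m3 = m.child(m.areas[list(reversed(m.areas.columns))], "perm", {})
        perm = analyze.cluster_trends(m3, 3, seed=0, **kw)
        assert sorted(c.quality for c in base) == \
            pytest.approx(sorted(c.quality for c in perm))

    def test_split_preview_does_not_commit(self):
        m, labels, truth, _ = planted_trend_matrix(seed=9, noise=0.0)
        kw = dict(labels=labels, label_order=["t0", "t1", "t2", "t3"])
        clusters = analyze.cluster_trends(m, 2, "bisecting", seed=0, **kw)
        mixed = max(clusters, key=lambda c: len(c.members))
        a, b = analyze.split_cluster(m, mixed, seed=0, **kw)
        assert set(a.members) | set(b.members) == set(mixed.members)
        assert len(mixed.members) == len(a.members) + len(b.members)


class TestCalibration:
    def test_exact_linear_recovery_and_identity(self):
        pts = [(1.0, 1e4), (2.0, 2e4), (5.0, 5e4), (10.0, 1e5)]
        curve = analyze.fit_calibration(pts, "linear", "none")
        assert curve.r2 == pytest.approx(1.0)
        for conc, area in pts:
            assert curve.inverse(curve.predict([conc])[0]) == \
                pytest.approx(conc, rel=1e-9)

    def test_point_exclusion_changes_fit(self):
        pts = [(1.0, 1e4), (2.0, 2e4), (5.0, 5e4), (10.0, 3e5)]  # last off
        full = analyze.fit_calibration(pts)
        trimmed = analyze.fit_calibration(pts, excluded={3})
        refit = analyze.fit_calibration(pts[:3])  # oracle: fit without it
        assert trimmed.coefficients == pytest.approx(refit.coefficients)
        assert trimmed.r2 > full.r2

    def test_extrapolation_flagged(self):
        pts = [(1.0, 1e4), (2.0, 2e4), (5.0, 5e4)]
        curve = analyze.fit_calibration(pts)
        m = make_matrix({"f": {"s1": 3e4, "s2": 9e5}})
        out = analyze.quantify(m, curve, m.feature_names[0])
        assert out.loc["s1", "flag"] == ""
        assert out.loc["s2", "flag"] == "extrapolated"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            analyze.fit_calibration([(1.0, 1.0), (2.0, 2.0)])


class TestPathway:
    def annotations_for(self, matrix, mapping):
        from metaline.annotate import Annotation, PartialScores

        anns = []
        for fname, hmdb in mapping.items():
            anns.append(Annotation(fname, hmdb, hmdb, "[M+H]+",
                                   PartialScores(s_m=100.0), 90.0, "green",
                                   4, "2a", external_ids={"HMDB_ID": hmdb}))
        return anns

    def test_projection_colors_mirror_fold_changes(self, trp_pathway):
        """An IDO1-style design: kynurenine up, tryptophan down."""
        rng = np.random.default_rng(10)
        data = {}
        for name, (a_mean, b_mean) in {
                "trp": (4000.0, 1000.0), "kyn": (500.0, 2500.0)}.items():
            vals = {}
            for j in range(4):
                vals[f"a{j}"] = a_mean * rng.lognormal(0, 0.05)
                vals[f"b{j}"] = b_mean * rng.lognormal(0, 0.05)
            data[name] = vals
        m = make_matrix(data)
        trp_f, kyn_f = m.feature_names
        comparison = analyze.fold_change_tests(
            m, [f"a{j}" for j in range(4)], [f"b{j}" for j in range(4)])
        graph = PathwayGraph.from_json(trp_pathway)
        anns = self.annotations_for(m, {trp_f: "HMDB0000929",
                                        kyn_f: "HMDB0000684"})
        out = analyze.project_pathway(graph, anns, comparison)
        assert out.states["HMDB0000929"] == "down"
        assert out.states["HMDB0000684"] == "up"
        assert out.states["HMDB0000472"] == "absent"

    def test_no_comparison_all_detected_gray(self, trp_pathway):
        m = make_matrix({"trp": {"s": 1.0}})
        graph = PathwayGraph.from_json(trp_pathway)
        anns = self.annotations_for(m, {m.feature_names[0]: "HMDB0000929"})
        out = analyze.project_pathway(graph, anns)
        assert out.states["HMDB0000929"] == "detected"
        assert set(out.states.values()) == {"detected", "absent"}

    def test_annotation_without_external_id_ignored(self, trp_pathway):
        from metaline.annotate import Annotation, PartialScores

        graph = PathwayGraph.from_json(trp_pathway)
        ann = Annotation("f", "x", "x", "[M+H]+", PartialScores(), 50.0,
                         "orange", 2, "3")
        out = analyze.project_pathway(graph, [ann])
        assert set(out.states.values()) == {"absent"}
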