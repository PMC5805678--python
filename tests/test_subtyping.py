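import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from methylscape.subtyping import (
    aggregate_gene_beta,
    aggregate_region_beta,
    call_subclasses,
    cluster_dendrogram,
    delta_vs_healthy,
    harmonize_platforms,
    pca_embed,
    select_hypermethylated_genes,
)
from methylscape.synthetic import (
    CohortConfig,
    generate_cohort,
    generate_manifest,
    generate_pan_cancer,
    generate_references,
)
from methylscape.types import BetaMatrix, SampleSheet

from conftest import make_region_set


def naive_agglomeration_heights(X, method):
    """Independent O(n^3) agglomeration oracle; returns sorted merge heights."""
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                pairs = [D[i, j] for i in clusters[a] for j in clusters[b]]
                d = np.mean(pairs) if method == "average" else np.max(pairs)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return sorted(heights)


@pytest.fixture(scope="module")
def cohort_bundle():
    cfg = CohortConfig(n_probes=6000, seed=19)
    bundle = generate_manifest(cfg)
    cohort = generate_cohort(bundle, cfg)
    refs = generate_references(bundle, cfg)
    return cfg, bundle, cohort, refs


class TestAggregation:
    def test_two_probe_mean(self, tiny_manifest):
        beta = BetaMatrix(
            pd.DataFrame(
                {"s1": [0.2, 0.4, 0.5, 0.5, 0.9, 0.5]},
                index=tiny_manifest.probe_ids,
            )
        )
        out, missing = aggregate_gene_beta(beta, tiny_manifest, ["GENEA"])
        assert out.loc["GENEA", "s1"] == pytest.approx(0.3)
        assert missing == []

    def test_single_probe_gene_identity(self, tiny_manifest, tiny_beta):
        out, _ = aggregate_gene_beta(tiny_manifest and tiny_beta, tiny_manifest, ["GENEB"])
        # GENEB links cg01 and cg04
        expected = tiny_beta.df.loc[["cg01", "cg04"]].mean()
        assert np.allclose(out.loc["GENEB"], expected)

    def test_multi_mapped_probe_contributes_to_both(self, tiny_manifest, tiny_beta):
        out, _ = aggregate_gene_beta(tiny_beta, tiny_manifest, ["GENEA", "GENEB"])
        assert "cg01" in tiny_manifest.gene_probe_map()["GENEA"]
        assert "cg01" in tiny_manifest.gene_probe_map()["GENEB"]
        a = tiny_beta.df.loc[["cg00", "cg01"]].mean()
        b = tiny_beta.df.loc[["cg01", "cg04"]].mean()
        assert np.allclose(out.loc["GENEA"], a)
        assert np.allclose(out.loc["GENEB"], b)

    def test_empty_gene_set_error(self, tiny_manifest, tiny_beta):
        with pytest.raises(ValueError, match="empty gene set"):
            aggregate_gene_beta(tiny_beta, tiny_manifest, [])

    def test_gene_without_probes_reported(self, tiny_manifest, tiny_beta):
        out, missing = aggregate_gene_beta(tiny_beta, tiny_manifest, ["GENEA", "NOPE"])
        assert missing == ["NOPE"]
        assert "NOPE" not in out.index

    def test_region_aggregation_and_empty_drop(self, tiny_manifest, tiny_beta):
        rs = make_region_set(
            "t", [("chr1", 100, 200, "r1"), ("chr9", 0, 50, "empty")]
        )
        out, empty = aggregate_region_beta(tiny_beta, tiny_manifest, rs)
        assert empty == ["empty"]
        members = ["cg01", "cg02", "cg03"]
        assert np.allclose(out.loc["r1"], tiny_beta.df.loc[members].mean())

    def test_aggregation_commutes_with_probe_reordering(self, tiny_manifest, tiny_beta):
        out1, _ = aggregate_gene_beta(tiny_beta, tiny_manifest, ["GENEA", "GENEB"])
        perm = BetaMatrix(tiny_beta.df.iloc[::-1])
        out2, _ = aggregate_gene_beta(perm, tiny_manifest, ["GENEA", "GENEB"])
        pd.testing.assert_frame_equal(out1, out2)

    def test_split_region_probe_weighted_consistency(self, tiny_manifest, tiny_beta):
        whole = make_region_set("w", [("chr1", 99, 200, "r")])
        split = make_region_set(
            "s", [("chr1", 99, 140, "r1"), ("chr1", 140, 200, "r2")]
        )
        out_w, _ = aggregate_region_beta(tiny_beta, tiny_manifest, whole)
        out_s, _ = aggregate_region_beta(tiny_beta, tiny_manifest, split)
        n1, n2 = 2, 2  # cg00,cg01 | cg02,cg03
        recombined = (out_s.loc["r1"] * n1 + out_s.loc["r2"] * n2) / (n1 + n2)
        assert np.allclose(out_w.loc["r"], recombined)


class TestHarmonize:
    def test_identical_features_concatenate(self):
        a = pd.DataFrame({"s1": [0.1, 0.2]}, index=["g1", "g2"])
        b = pd.DataFrame({"s2": [0.3, 0.4]}, index=["g1", "g2"])
        joint, origin, dropped = harmonize_platforms(a, b)
        assert joint.shape == (2, 2)
        assert dropped == {"a": [], "b": []}
        assert origin.tolist() == ["a", "b"]

    def test_missing_feature_dropped_and_reported(self):
        a = pd.DataFrame({"s1": [0.1, 0.2]}, index=["g1", "g2"])
        b = pd.DataFrame({"s2": [0.3]}, index=["g1"])
        joint, _, dropped = harmonize_platforms(a, b)
        assert list(joint.index) == ["g1"]
        assert dropped["a"] == ["g2"]

    def test_pan_cancer_joint_pca_separates(self, cohort_bundle):
        cfg, bundle, cohort, _ = cohort_bundle
        pan = generate_pan_cancer(bundle, cfg, n_samples=12, seed=19)
        genes = bundle.keratin_genes
        feats_a, _ = aggregate_gene_beta(cohort.beta, bundle.manifest, genes)
        feats_b, _ = aggregate_gene_beta(pan.beta, bundle.manifest, genes)
        joint, origin, _ = harmonize_platforms(feats_a, feats_b)
        coords = pca_embed(joint, 2).coordinates
        healthy = cohort.samples.samples_in_group("healthy")
        epsc = cohort.samples.df.query("latent_subclass == 'EpSC_like'").index
        pan_ids = pan.samples.sample_ids
        # dedifferentiated pan-cancer samples sit with the EpSC-like lesions,
        # away from healthy, along PC1
        h = coords.loc[healthy, "PC1"].mean()
        p = coords.loc[pan_ids, "PC1"].mean()
        e = coords.loc[epsc, "PC1"].mean()
        assert abs(p - e) < abs(p - h)


class TestPCA:
    def test_one_dimensional_signal(self):
        X = pd.DataFrame(
            {"a": [0.0, 0.0], "b": [0.01, 0.0], "c": [1.0, 0.0], "d": [1.01, 0.0]},
            index=["f1", "f2"],
        )
        res = pca_embed(X, 2)
        pc1 = res.coordinates["PC1"]
        assert (pc1[["a", "b"]] < pc1[["c", "d"]].min()).all() or (
            pc1[["a", "b"]] > pc1[["c", "d"]].max()
        ).all()
        assert res.explained_variance_ratio[0] > 0.999

    def test_duplicate_samples_identical_coords(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.uniform(size=(5, 4)), columns=list("abcd"))
        X["e"] = X["a"]
        res = pca_embed(X, 2)
        assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["e"])

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(10, 20)))  # 10 features x 20 samples
        res = pca_embed(X, 5)
        M = X.to_numpy().T
        M = M - M.mean(axis=0)
        cov = M.T @ M / (M.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for i in range(5):
            proj = M @ evecs[:, i]
            got = res.coordinates.iloc[:, i].to_numpy()
            assert np.allclose(np.abs(got), np.abs(proj), atol=1e-8)
        total = evals.sum()
        assert np.allclose(
            res.explained_variance_ratio, evals[:5] / total, atol=1e-8
        )

    def test_constant_matrix_error(self):
        X = pd.DataFrame(0.5, index=["f1", "f2"], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="constant"):
            pca_embed(X)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.uniform(size=(6, 8)))
        a = pca_embed(X, 3)
        b = pca_embed(X, 3)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
        for i in range(3):
            row = a.loadings.iloc[i]
            assert row.iloc[int(np.argmax(np.abs(row)))] > 0


class TestDendrogram:
    def test_two_blobs_perfect_split(self):
        rng = np.random.default_rng(3)
        left = rng.normal(0, 0.01, size=(4, 10))
        right = rng.normal(1, 0.01, size=(4, 10))
        X = pd.DataFrame(np.vstack([left, right]).T, columns=list("abcdefgh"))
        res = cluster_dendrogram(X, k=2)
        c = res.clusters
        assert len(set(c[list("abcd")])) == 1
        assert len(set(c[list("efgh")])) == 1
        assert c["a"] != c["e"]

    def test_tied_distances_fixed_tree(self):
        # collinear equally spaced points: exact ties, deterministic
        # lowest-index merge first
        X = pd.DataFrame({"a": [0.0], "b": [1.0], "c": [2.0]})
        res1 = cluster_dendrogram(X)
        res2 = cluster_dendrogram(X)
        assert np.array_equal(res1.linkage, res2.linkage)
        assert res1.linkage[0, 2] == pytest.approx(1.0)
        assert set(res1.linkage[0, :2].astype(int)) == {0, 1}

    @pytest.mark.parametrize("method", ["average", "complete"])
    def test_merge_heights_match_naive_oracle(self, method):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(30, 8))
        feats = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(30)])
        res = cluster_dendrogram(feats, method=method)
        got = sorted(res.linkage[:, 2])
        expected = naive_agglomeration_heights(X, method)
        assert np.allclose(got, expected, atol=1e-10)

    def test_k_exceeds_n_error(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_dendrogram(X, k=5)

    def test_newick_export_parses(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.uniform(size=(4, 6)), columns=list("abcdef"))
        nwk = cluster_dendrogram(X).to_newick()
        assert nwk.endswith(");")
        for label in "abcdef":
            assert label in nwk


class TestSubclassCalling:
    def test_keratin_ari_one(self, cohort_bundle):
        _, bundle, cohort, refs = cohort_bundle
        feats, _ = aggregate_gene_beta(cohort.beta, bundle.manifest, bundle.keratin_genes)
        res = call_subclasses(feats, cohort.samples, method="keratin")
        truth = cohort.samples.df.loc[res.calls.index, "latent_subclass"]
        assert not res.no_structure
        assert adjusted_rand_score(truth, res.calls["subclass"]) == 1.0
        # anchored labels match the planted identity, not only the partition
        assert (res.calls["subclass"] == truth).all()

    def test_enhancer_ari_one_and_agreement(self, cohort_bundle):
        _, bundle, cohort, refs = cohort_bundle
        esc, _ = aggregate_region_beta(
            cohort.beta, bundle.manifest, bundle.region_sets["ESC_enhancer"]
        )
        kc, _ = aggregate_region_beta(
            cohort.beta, bundle.manifest, bundle.region_sets["KC_enhancer"]
        )
        feats = pd.concat([esc, kc.loc[kc.index.difference(esc.index)]])
        res_e = call_subclasses(feats, cohort.samples, method="enhancer")
        truth = cohort.samples.df.loc[res_e.calls.index, "latent_subclass"]
        assert adjusted_rand_score(truth, res_e.calls["subclass"]) == 1.0
        kera, _ = aggregate_gene_beta(
            cohort.beta, bundle.manifest, bundle.keratin_genes
        )
        res_k = call_subclasses(kera, cohort.samples, method="keratin")
        common = res_k.calls.index.intersection(res_e.calls.index)
        agreement = (
            res_k.calls.loc[common, "subclass"] == res_e.calls.loc[common, "subclass"]
        ).mean()
        assert agreement >= 0.95

    def test_zero_separation_reports_no_structure(self):
        cfg = CohortConfig(n_probes=4000, subclass_separation=0.0, seed=29)
        bundle = generate_manifest(cfg)
        cohort = generate_cohort(bundle, cfg)
        feats, _ = aggregate_gene_beta(cohort.beta, bundle.manifest, bundle.keratin_genes)
        res = call_subclasses(feats, cohort.samples, method="keratin")
        if not res.no_structure:  # either outcome is acceptable at null
            truth = cohort.samples.df.loc[res.calls.index, "latent_subclass"]
            assert abs(adjusted_rand_score(truth, res.calls["subclass"])) < 0.3
        else:
            assert res.calls.empty

    def test_epsc_like_cluster_near_esc_reference(self, cohort_bundle):
        _, bundle, cohort, refs = cohort_bundle
        esc_rs = bundle.region_sets["ESC_enhancer"]
        feats, _ = aggregate_region_beta(cohort.beta, bundle.manifest, esc_rs)
        ref_feats, _ = aggregate_region_beta(refs, bundle.manifest, esc_rs)
        res = call_subclasses(feats, cohort.samples, ref_feats, method="enhancer")
        epsc_samples = res.calls.index[res.calls["subclass"] == "EpSC_like"]
        kc_samples = res.calls.index[res.calls["subclass"] == "keratinocyte_like"]
        esc_ref = ref_feats["ESC"].reindex(feats.index)
        d_epsc = np.linalg.norm(
            feats[epsc_samples].mean(axis=1) - esc_ref
        )
        d_kc = np.linalg.norm(feats[kc_samples].mean(axis=1) - esc_ref)
        assert d_epsc < d_kc

    def test_invariant_under_sample_permutation(self, cohort_bundle):
        _, bundle, cohort, _ = cohort_bundle
        feats, _ = aggregate_gene_beta(cohort.beta, bundle.manifest, bundle.keratin_genes)
        res1 = call_subclasses(feats, cohort.samples, method="keratin")
        rng = np.random.default_rng(7)
        perm = feats[rng.permutation(feats.columns)]
        res2 = call_subclasses(perm, cohort.samples, method="keratin")
        s1 = res1.calls["subclass"].sort_index()
        s2 = res2.calls["subclass"].sort_index()
        pd.testing.assert_series_equal(s1, s2)

    def test_every_lesion_sample_called_once(self, cohort_bundle):
        _, bundle, cohort, _ = cohort_bundle
        feats, _ = aggregate_gene_beta(cohort.beta, bundle.manifest, bundle.keratin_genes)
        res = call_subclasses(feats, cohort.samples, method="keratin")
        lesions = cohort.samples.df.query("group in ['AK', 'cSCC']").index
        assert sorted(res.calls.index) == sorted(lesions)

    def test_anchor_free_fallback(self, cohort_bundle):
        _, bundle, cohort, _ = cohort_bundle
        gained, _ = aggregate_region_beta(
            cohort.beta, bundle.manifest, bundle.region_sets["EpSC_gained"]
        )
        lesions = cohort.samples.df.query("group in ['AK', 'cSCC']").index
        feats = gained[list(lesions)]  # no healthy columns, no references
        res = call_subclasses(
            feats,
            cohort.samples,
            method="enhancer",
            fallback_features=list(gained.index),
        )
        truth = cohort.samples.df.loc[res.calls.index, "latent_subclass"]
        assert (res.calls["subclass"] == truth).all()
        assert res.anchor == "fallback:gained_region_mean"


class TestDeltaAndSelection:
    def test_healthy_columns_average_zero(self, cohort_bundle):
        _, bundle, cohort, _ = cohort_bundle
        gained, _ = aggregate_region_beta(
            cohort.beta, bundle.manifest, bundle.region_sets["EpSC_gained"]
        )
        delta = delta_vs_healthy(gained, cohort.samples)
        healthy = cohort.samples.samples_in_group("healthy")
        assert np.allclose(delta[healthy].mean(axis=1), 0.0, atol=1e-12)

    def test_planted_shift_column(self, cohort_bundle):
        _, bundle, cohort, _ = cohort_bundle
        gained, _ = aggregate_region_beta(
            cohort.beta, bundle.manifest, bundle.region_sets["EpSC_gained"]
        )
        shifted = gained.copy()
        shifted["H01"] = gained["H01"] + 0.2
        delta = delta_vs_healthy(shifted, cohort.samples)
        base = delta_vs_healthy(gained, cohort.samples)
        healthy_n = len(cohort.samples.samples_in_group("healthy"))
        expected_shift = 0.2 * (1 - 1 / healthy_n)
        assert np.allclose(
            delta["H01"] - base["H01"], expected_shift, atol=1e-12
        )

    def test_threshold_strictness(self):
        calls = pd.DataFrame(
            {"subclass": ["EpSC_like", "EpSC_like"]},
            index=pd.Index(["x1", "x2"], name="sample_id"),
        )
        delta = pd.DataFrame(
            {"x1": [0.25, 0.15, 0.2], "x2": [0.25, 0.15, 0.2]},
            index=["rA", "rB", "rC"],
        )
        region_genes = {"rA": ("G1", "G2"), "rB": ("G3",), "rC": ("G4",)}
        genes = select_hypermethylated_genes(delta, region_genes, calls, 0.2)
        assert genes == ["G1", "G2"]  # 0.15 below, 0.2 not strictly above

    def test_empty_epsc_subclass_warns(self):
        calls = pd.DataFrame(
            {"subclass": ["keratinocyte_like"]},
            index=pd.Index(["x1"], name="sample_id"),
        )
        delta = pd.DataFrame({"x1": [0.5]}, index=["rA"])
        with pytest.warns(UserWarning, match="no EpSC-like"):
            assert select_hypermethylated_genes(delta, {"rA": ("G",)}, calls) == []

    def test_end_to_end_gene_selection(self, cohort_bundle):
        cfg, bundle, cohort, _ = cohort_bundle
        gained_rs = bundle.region_sets["EpSC_gained"]
        gained, _ = aggregate_region_beta(cohort.beta, bundle.manifest, gained_rs)
        delta = delta_vs_healthy(gained, cohort.samples)
        feats, _ = aggregate_gene_beta(cohort.beta, bundle.manifest, bundle.keratin_genes)
        calls = call_subclasses(feats, cohort.samples, method="keratin").calls
        genes = select_hypermethylated_genes(delta, gained_rs.region_genes, calls)
        # separation 0.3 > 0.2 threshold: all gained-region genes selected
        expected = sorted({g for gs in gained_rs.region_genes.values() for g in gs})
        assert genes == expected
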