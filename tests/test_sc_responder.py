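import anndata as ad
import numpy as np
import pandas as pd
import pytest

from clonotrace.sc_responder import (
    GeneSignature,
    ReferenceMap,
    ScParams,
    build_reference_map,
    call_responders,
    composite_response_score,
    de_logistic,
    deg_count_permutation,
    log_normalize,
    map_to_reference,
    module_score,
    qc_filter,
)
from clonotrace.synthdata import gen_expression_experiment


def _adata(X, genes=None, groups=None, normalized=False):
    X = np.asarray(X)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    obs = pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])])
    if groups is not None:
        obs["group"] = groups
    a = ad.AnnData(X=X.astype(float), obs=obs, var=pd.DataFrame(index=genes))
    a.uns["normalized"] = normalized
    return a


class TestQcFilter:
    def test_cell_gene_count_boundary(self):
        # cell 0 detects 999 genes (removed), cell 1 detects 1000 (kept)
        X = np.zeros((2, 1200))
        X[0, :999] = 1
        X[1, :1000] = 1
        a = _adata(X)
        out, report = qc_filter(a, ScParams(min_genes_per_cell=1000))
        assert list(out.obs_names) == ["c1"]
        assert report["n_cells_removed_low_genes"] == 1

    def test_noninformative_gene_patterns(self):
        genes = ["Gm10073", "2810417H13Rik", "Rps19", "Rpl3", "Gata1", "Epor", "mt-Nd1"]
        X = np.ones((3, len(genes)))
        params = ScParams(min_genes_per_cell=1, max_mito_fraction=1.0)
        out, report = qc_filter(_adata(X, genes=genes), params)
        kept = set(out.var_names)
        assert kept == {"Gata1", "Epor", "mt-Nd1"}
        assert report["n_genes_removed_pattern"] == 4

    def test_mito_fraction_ceiling(self):
        genes = ["Gata1", "mt-Nd1"]
        X = np.array([[90, 10], [85, 15]])  # 10% kept, 15% removed
        out, report = qc_filter(_adata(X, genes=genes), ScParams(min_genes_per_cell=1))
        assert list(out.obs_names) == ["c0"]
        assert report["n_cells_removed_high_mito"] == 1

    def test_idempotent(self, responder_dataset, sc_params):
        norm, _ = responder_dataset
        again, report = qc_filter(norm, sc_params)
        assert report["n_genes_removed_pattern"] == 0
        assert report["n_cells_removed_low_genes"] == 0
        assert again.shape == norm.shape

    def test_everything_removed_errors(self):
        X = np.zeros((2, 1200))
        with pytest.raises(ValueError, match="removed everything"):
            qc_filter(_adata(X), ScParams(min_genes_per_cell=1000))


class TestLogNormalize:
    def test_hand_arithmetic(self):
        a = _adata([[1, 1]])
        out = log_normalize(a, ScParams())
        np.testing.assert_allclose(out.X, np.log1p(5000.0))

    def test_depth_invariance(self):
        a = _adata([[2, 4, 6]])
        b = _adata([[4, 8, 12]])
        np.testing.assert_allclose(log_normalize(a).X, log_normalize(b).X)

    def test_zero_count_stays_zero(self):
        out = log_normalize(_adata([[0, 5]]))
        assert out.X[0, 0] == 0.0

    def test_all_zero_cell_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            log_normalize(_adata([[0, 0]]))


class TestDeLogistic:
    def test_cross_check_against_statsmodels(self, rng):
        """LRT p-values agree with an independent statsmodels fit."""
        import statsmodels.api as sm
        from scipy import stats as sps

        n = 120
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 5))
        X[:, 0] += 0.8 * y  # one real effect
        a = _adata(np.clip(X + 3, 0, None), groups=np.where(y, "EPO", "control"), normalized=True)
        table = de_logistic(a, params=ScParams(min_pct=0.0, logfc_min=0.0, ridge=0.0))
        for j, gene in enumerate(a.var_names):
            x = np.clip(X[:, j] + 3, 0, None)
            full = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
            lr = 2 * (full.llf - null.llf)
            p_ref = sps.chi2.sf(lr, 1)
            assert table.loc[gene, "p_val"] == pytest.approx(p_ref, rel=1e-3, abs=1e-12)

    def test_null_genes_not_flagged(self, null_expression, sc_params):
        norm, _ = null_expression
        table = de_logistic(norm, params=sc_params)
        assert table["deg"].mean() < 0.02

    def test_perfect_separation_flagged_finite(self):
        rng = np.random.default_rng(0)
        n = 200
        y = np.repeat([0, 1], n // 2)
        X = rng.poisson(2.0, size=(n, 3)).astype(float)
        X[y == 1, 0] = 0.0  # expressed in ~all of A, none of B
        a = _adata(X, groups=np.where(y, "EPO", "control"), normalized=True)
        table = de_logistic(a, params=ScParams(min_pct=0.0, logfc_min=0.0))
        assert np.isfinite(table["p_val"]).all()
        assert bool(table.loc["g0", "deg"])

    def test_planted_shift_recovery(self, sc_params):
        adata, truth = gen_expression_experiment(
            responder_fraction=1.0,
            n_cells_per_group=300,
            n_genes=600,
            fold_up=3.0,
            fold_down=3.0,
            seed=3,
        )
        norm = log_normalize(qc_filter(adata, sc_params)[0], sc_params)
        table = de_logistic(norm, params=sc_params)
        hits = set(table.index[table["deg"]])
        planted = set(truth.up_genes) | set(truth.down_genes)
        assert len(hits & planted) / len(planted) >= 0.9
        up_hit = table.loc[table.index.isin(truth.up_genes), "mean_diff"]
        assert (up_hit > 0).all()

    def test_adjusted_p_at_least_raw(self, responder_dataset, sc_params):
        norm, _ = responder_dataset
        table = de_logistic(norm, params=sc_params)
        assert (table["p_val_adj"] >= table["p_val"] - 1e-15).all()
        assert (table["deg"] == (table["p_val_adj"] < sc_params.de_alpha)).all()


class TestDegCountPermutation:
    def test_minimum_attainable_p(self, sc_params):
        adata, _ = gen_expression_experiment(
            responder_fraction=1.0, n_cells_per_group=150, n_genes=400,
            fold_up=3.0, fold_down=3.0, seed=4,
        )
        norm = log_normalize(qc_filter(adata, sc_params)[0], sc_params)
        res = deg_count_permutation(norm, params=sc_params, n_perm=9, seed=0)
        assert res["p_value"] == pytest.approx(1 / 10)

    def test_deterministic_null_counts(self, null_expression, sc_params):
        norm, _ = null_expression
        r1 = deg_count_permutation(norm, params=sc_params, n_perm=5, seed=3)
        r2 = deg_count_permutation(norm, params=sc_params, n_perm=5, seed=3)
        np.testing.assert_array_equal(r1["null_counts"], r2["null_counts"])

    def test_nperm_validated(self, null_expression, sc_params):
        norm, _ = null_expression
        with pytest.raises(ValueError, match="n_perm"):
            deg_count_permutation(norm, params=sc_params, n_perm=0)


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        a = _adata(np.full((10, 200), 3.0), normalized=True)
        s = module_score(a, [f"g{i}" for i in range(5)], ScParams(), seed=0)
        np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_self_background_limit(self, rng):
        # gene set = one whole expression bin, controls drawn from that bin
        X = rng.normal(5, 0.01, size=(20, 240)).clip(0)
        a = _adata(X, normalized=True)
        genes = list(a.var_names)
        s = module_score(a, genes[:10], ScParams(nbins=24, nctrl=100), seed=0)
        assert np.abs(s.to_numpy()).mean() < 0.02

    def test_planted_responders_score_higher(self, responder_dataset, sc_params):
        norm, truth = responder_dataset
        s = module_score(norm, [g for g in truth.up_genes if g in norm.var_names],
                         sc_params, seed=0)
        resp = norm.obs_names.isin(truth.responders)
        assert s[resp].mean() > s[~resp].mean() + 0.2

    def test_deterministic_per_seed(self, responder_dataset, sc_params):
        norm, truth = responder_dataset
        genes = [g for g in truth.up_genes if g in norm.var_names]
        s1 = module_score(norm, genes, sc_params, seed=5)
        s2 = module_score(norm, genes, sc_params, seed=5)
        pd.testing.assert_series_equal(s1, s2)

    def test_empty_intersection_errors(self, responder_dataset, sc_params):
        norm, _ = responder_dataset
        with pytest.raises(ValueError, match="no overlap"):
            module_score(norm, ["NotAGene"], sc_params)

    def test_random_set_null_mean_near_zero(self, null_expression, sc_params):
        norm, _ = null_expression
        rng = np.random.default_rng(9)
        means = []
        for seed in range(10):
            genes = list(rng.choice(norm.var_names, size=25, replace=False))
            s = module_score(norm, genes, sc_params, seed=seed)
            means.append(s.mean())
        assert abs(np.mean(means)) < 0.05


class TestCompositeAndResponders:
    def test_hand_arithmetic(self):
        up = pd.Series([0.4, 0.1], index=["a", "b"])
        down = pd.Series([0.1, 0.2], index=["a", "b"])
        out = composite_response_score(up, down)
        np.testing.assert_allclose(out.to_numpy(), [0.3, -0.1])

    def test_zero_down_is_identity(self):
        up = pd.Series([0.5, 0.2], index=["a", "b"])
        out = composite_response_score(up, pd.Series(0.0, index=up.index))
        pd.testing.assert_series_equal(out, up.rename("response_score"))

    def test_cell_mismatch_errors(self):
        with pytest.raises(ValueError, match="different cells"):
            composite_response_score(
                pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"])
            )

    def test_exactly_top_decile_flagged(self):
        scores = pd.Series(np.arange(100, dtype=float), index=[f"c{i}" for i in range(100)])
        groups = pd.Series("EPO", index=scores.index)
        flags = call_responders(scores, groups, params=ScParams())
        assert int(flags.sum()) == 10
        assert flags[scores > scores.quantile(0.9)].all()

    def test_all_tied_scores_flags_none(self):
        scores = pd.Series(1.0, index=[f"c{i}" for i in range(20)])
        groups = pd.Series("EPO", index=scores.index)
        assert call_responders(scores, groups).sum() == 0

    def test_control_cells_never_flagged(self):
        scores = pd.Series([100.0, 0.0, 1.0, 2.0], index=list("abcd"))
        groups = pd.Series(["control", "EPO", "EPO", "EPO"], index=list("abcd"))
        flags = call_responders(scores, groups)
        assert not flags["a"]

    def test_planted_recovery_f1(self, responder_dataset, sc_params):
        norm, truth = responder_dataset
        up = module_score(norm, [g for g in truth.up_genes if g in norm.var_names],
                          sc_params, seed=0)
        down = module_score(norm, [g for g in truth.down_genes if g in norm.var_names],
                            sc_params, seed=1)
        flags = call_responders(composite_response_score(up, down), norm.obs["group"],
                                params=sc_params)
        called = set(flags.index[flags])
        true = set(truth.responders) & set(norm.obs_names)
        tp = len(called & true)
        f1 = 2 * tp / (len(called) + len(true))
        assert f1 >= 0.9


@pytest.fixture(scope="module")
def clusters():
    rng = np.random.default_rng(2)
    n, g = 120, 300
    X = rng.normal(3, 1, size=(n, g)).clip(0)
    X[n // 2 :, :30] += 4.0  # second cluster shifted in 30 genes
    a = _adata(X, normalized=True)
    a.obs["cluster"] = np.repeat(["c1", "c2"], n // 2)
    return a


class TestReferenceMapping:
    def test_loadings_orthonormal(self, clusters):
        ref = build_reference_map(clusters, ScParams(n_hvg=200))
        gram = ref.loadings.T @ ref.loadings
        np.testing.assert_allclose(gram, np.eye(ref.n_pcs), atol=1e-6)

    def test_deterministic_rebuild(self, clusters):
        r1 = build_reference_map(clusters, ScParams(n_hvg=200))
        r2 = build_reference_map(clusters, ScParams(n_hvg=200))
        np.testing.assert_array_equal(r1.loadings, r2.loadings)
        np.testing.assert_array_equal(r1.embedding, r2.embedding)

    def test_pc1_separates_clusters(self, clusters):
        from sklearn.metrics import silhouette_score

        ref = build_reference_map(clusters, ScParams(n_hvg=200))
        labels = clusters.obs["cluster"].to_numpy()
        assert silhouette_score(ref.ref_pcs[:, :1], labels) > 0.0

    def test_self_mapping_identity_k1(self, clusters):
        ref = build_reference_map(clusters, ScParams(n_hvg=200))
        mapped = map_to_reference(clusters, ref, ScParams(k_neighbors=1))
        np.testing.assert_allclose(mapped[["e1", "e2"]].to_numpy(), ref.embedding, atol=1e-8)

    def test_degenerate_duplicated_neighborhood(self, rng):
        X = rng.normal(3, 1, size=(15, 100)).clip(0)
        X[5:] = X[4]  # one cell duplicated 10 times (rows 4..14 identical)
        a = _adata(X, normalized=True)
        ref = build_reference_map(a, ScParams(n_hvg=80, n_pcs=3))
        query = a[[4]].copy()
        mapped = map_to_reference(query, ref, ScParams(k_neighbors=10, n_pcs=3))
        np.testing.assert_allclose(mapped[["e1", "e2"]].to_numpy()[0], ref.embedding[4], atol=1e-8)

    def test_cluster_queries_land_in_cluster_bbox(self, clusters):
        rng = np.random.default_rng(5)
        ref = build_reference_map(clusters, ScParams(n_hvg=200))
        n, g = 60, clusters.n_vars
        Xq = rng.normal(3, 1, size=(n, g)).clip(0)
        Xq[:, :30] += 4.0  # queries from cluster c2
        q = _adata(Xq, normalized=True)
        q.var_names = clusters.var_names
        mapped = map_to_reference(q, ref, ScParams(k_neighbors=10))
        c2 = ref.embedding[60:]
        lo, hi = c2.min(axis=0), c2.max(axis=0)
        inside = ((mapped[["e1", "e2"]].to_numpy() >= lo) & (mapped[["e1", "e2"]].to_numpy() <= hi)).all(axis=1)
        assert inside.mean() >= 0.95

    def test_save_load_round_trip(self, clusters, tmp_path):
        ref = build_reference_map(clusters, ScParams(n_hvg=200))
        ref.save(tmp_path / "refmap")
        back = ReferenceMap.load(tmp_path / "refmap")
        np.testing.assert_allclose(back.loadings, ref.loadings)
        np.testing.assert_allclose(back.embedding, ref.embedding)
        mapped = map_to_reference(clusters, back, ScParams(k_neighbors=1))
        np.testing.assert_allclose(mapped[["e1", "e2"]].to_numpy(), ref.embedding, atol=1e-8)

    def test_no_shared_genes_errors(self, clusters):
        ref = build_reference_map(clusters, ScParams(n_hvg=200))
        other = _adata(np.ones((2, 3)), genes=["x", "y", "z"], normalized=True)
        with pytest.raises(ValueError, match="no genes"):
            map_to_reference(other, ref, ScParams())


def test_signature_from_deg_table_splits_by_sign():
    deg = pd.DataFrame(
        {"mean_diff": [1.0, -1.0, 0.5], "deg": [True, True, False]},
        index=["up1", "down1", "ns"],
    )
    sig = GeneSignature.from_deg_table(deg)
    assert sig.up == ("up1",) and sig.down == ("down1",)
    with pytest.raises(ValueError, match="overlap"):
        GeneSignature(up=("a",), down=("a",))
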