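"""Disease-axis construction, projection, window enrichment, rank test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from gliaxis import (
    DiseaseAxisModel,
    ExpressionMatrix,
    ProjectionResult,
    build_axis,
    map_orthologues,
    merge_datasets,
    prepare_dataset,
    rank_randomization_test,
    simulate_gene_annotations,
    simulate_meta_datasets,
    window_enrichment,
)
from gliaxis.simulate import SimConfig


def expr(values, meta_cols=None, mode="normalized", genes=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{j}" for j in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(meta_cols or {}, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta, mode)


class TestPrepareDataset:
    def test_count_filter_boundary(self):
        m = expr([[10, 9], [10, 10], [0, 0]], mode="counts")
        out = prepare_dataset(m, min_total_count=20)
        assert list(out.genes) == ["g1"]  # total 19 removed, 20 kept, 0 removed

    def test_log2_stabilization(self):
        m = expr([[3, 7]], mode="counts")
        out = prepare_dataset(m, min_total_count=1)
        np.testing.assert_allclose(out.values.to_numpy(), np.log2([[4.0, 8.0]]))
        assert out.mode == "normalized"

    def test_normalized_passthrough(self):
        m = expr([[1.5, 2.5]])
        assert prepare_dataset(m, 20) is m


class TestMapOrthologues:
    def test_bijective_map_keeps_all(self):
        m = expr(np.eye(3))
        omap = pd.DataFrame({"a": ["g0", "g1", "g2"], "b": ["h0", "h1", "h2"]})
        out = map_orthologues(m, omap)
        assert list(out.genes) == ["h0", "h1", "h2"]

    def test_ambiguous_entries_dropped(self):
        m = expr(np.eye(5))
        omap = pd.DataFrame(
            {
                "a": ["g0", "g1", "g2", "g3", "g3"],
                "b": ["h0", "h1", "h2", "h3a", "h3b"],
            }
        )
        out = map_orthologues(m, omap)
        assert list(out.genes) == ["h0", "h1", "h2"]  # g3 many-to-many, g4 unmapped


class TestBuildAxis:
    def test_single_varying_gene_gets_unit_loading(self):
        values = np.vstack([np.ones(6), [0, 1, 2, 3, 4, 5], np.ones(6)])
        m = expr(values, {"group": ["reference"] * 3 + ["disease"] * 3})
        axis, scores = build_axis(m)
        np.testing.assert_allclose(np.abs(axis.loadings), [0, 1, 0], atol=1e-10)

    def test_analytic_two_gene_covariance(self):
        """Population covariance [[2,1],[1,2]] has top eigenvector (1,1)/sqrt(2)."""
        rng = np.random.default_rng(0)
        cov = np.array([[2.0, 1.0], [1.0, 2.0]])
        X = rng.multivariate_normal([0, 0], cov, size=4000).T
        m = expr(X, {"group": ["disease"] * 2000 + ["reference"] * 2000})
        axis, _ = build_axis(m)
        target = np.array([1.0, 1.0]) / np.sqrt(2)
        assert abs(np.dot(axis.loadings, target)) > 0.99

    def test_orientation_puts_disease_positive(self, small_meta_config):
        datasets, _ = simulate_meta_datasets(small_meta_config)
        model = DiseaseAxisModel().fit(datasets)
        groups = model.adjusted_.sample_meta["group"]
        scores = model.training_scores_
        assert scores[(groups == "disease").to_numpy()].mean() > scores[
            (groups == "reference").to_numpy()
        ].mean()

    def test_constant_matrix_rejected(self):
        m = expr(np.ones((4, 5)), {"group": ["disease"] * 2 + ["reference"] * 3})
        with pytest.raises(ValueError, match="constant"):
            build_axis(m)

    def test_loadings_unit_norm_and_variance_properties(self, small_meta_config):
        datasets, _ = simulate_meta_datasets(small_meta_config)
        model = DiseaseAxisModel().fit(datasets)
        axis = model.axis_
        assert np.linalg.norm(axis.loadings) == pytest.approx(1.0)
        assert axis.variance_explained.sum() <= 1.0 + 1e-10
        # PC1 variance fraction equals score variance over total variance
        X = model.adjusted_.values.to_numpy().T
        Xc = X - X.mean(axis=0)
        ratio = model.training_scores_.var(ddof=1) / Xc.var(axis=0, ddof=1).sum()
        assert axis.variance_explained[0] == pytest.approx(ratio, abs=1e-10)
        assert model.training_scores_.mean() == pytest.approx(0.0, abs=1e-8)

    def test_recovers_planted_axis_after_correction(self, small_meta_config):
        datasets, truth = simulate_meta_datasets(small_meta_config)
        model = DiseaseAxisModel().fit(datasets)
        tr = pd.Series(truth.axis_vector, index=small_meta_config.genes)
        cos = abs(np.dot(model.axis_.loadings, tr[model.axis_.genes].to_numpy()))
        assert cos >= 0.95


class TestProjection:
    def test_training_dataset_projects_to_its_pc1_scores(self, small_meta_config):
        """Self-consistency: a training batch reproduces its PC1 scores
        (up to the documented per-dataset recentering) within 1e-8."""
        datasets, _ = simulate_meta_datasets(small_meta_config)
        model = DiseaseAxisModel().fit(datasets)
        for ds in datasets:
            proj = model.transform(ds)
            ref = model.training_scores_[list(ds.samples)].to_numpy()
            np.testing.assert_allclose(
                proj.scores - proj.scores.mean(), ref - ref.mean(), atol=1e-8
            )

    def test_constant_dataset_scores_zero(self, small_meta_config):
        datasets, _ = simulate_meta_datasets(small_meta_config)
        model = DiseaseAxisModel().fit(datasets)
        genes = datasets[0].genes
        const = ExpressionMatrix(
            pd.DataFrame(
                np.tile(np.linspace(1, 5, len(genes))[:, None], (1, 4)),
                index=genes,
                columns=[f"n{i}" for i in range(4)],
            ),
            pd.DataFrame(index=[f"n{i}" for i in range(4)]),
        )
        proj = model.transform(const)
        np.testing.assert_allclose(proj.scores, 0.0, atol=1e-8)

    def test_heldout_disease_reference_pairs_separate(self, small_meta_config):
        datasets, truth = simulate_meta_datasets(small_meta_config)
        model = DiseaseAxisModel().fit(datasets)
        held_cfg = SimConfig(
            seed=555,
            n_genes=small_meta_config.n_genes,
            n_datasets=2,
            samples_per_dataset=8,
            group_effect=small_meta_config.group_effect,
            noise_sd=0.5,
        )
        held, _ = simulate_meta_datasets(
            held_cfg, truth_overrides={"axis_vector": truth.axis_vector}
        )
        proj = model.transform(held[0])
        groups = held[0].sample_meta["group"].to_numpy()
        assert proj.scores[groups == "disease"].min() > proj.scores[groups == "reference"].max()

    def test_invariant_to_sample_and_dataset_order(self, small_meta_config):
        datasets, _ = simulate_meta_datasets(small_meta_config)
        model = DiseaseAxisModel().fit(datasets)
        new_cfg = SimConfig(seed=9, n_genes=small_meta_config.n_genes,
                            n_datasets=2, samples_per_dataset=8)
        new, _ = simulate_meta_datasets(new_cfg)
        target = new[0]
        p1 = model.transform(target)
        # reversed training order
        model2 = DiseaseAxisModel().fit(datasets[::-1])
        sign = np.sign(np.dot(model.axis_.loadings, model2.axis_.loadings))
        p2 = model2.transform(target)
        np.testing.assert_allclose(p1.scores, sign * p2.scores, atol=1e-6)
        # permuted sample columns
        perm = np.random.default_rng(0).permutation(target.n_samples)
        shuffled = ExpressionMatrix(
            target.values.iloc[:, perm], target.sample_meta.iloc[perm], target.mode
        )
        p3 = model.transform(shuffled)
        np.testing.assert_allclose(
            pd.Series(p3.scores, index=p3.samples)[list(p1.samples)], p1.scores, atol=1e-8
        )

    def test_insufficient_shared_genes_error_states_counts(self, small_meta_config):
        datasets, _ = simulate_meta_datasets(small_meta_config)
        model = DiseaseAxisModel().fit(datasets)
        tiny = ExpressionMatrix(
            datasets[0].values.iloc[:10],
            datasets[0].sample_meta,
        )
        tiny = ExpressionMatrix(
            tiny.values.rename(columns=lambda c: "x" + c),
            tiny.sample_meta.set_index("x" + tiny.sample_meta.index),
        )
        with pytest.raises(ValueError, match="axis genes shared"):
            model.transform(tiny)


@pytest.fixture(scope="module")
def fitted():
    cfg = SimConfig(seed=31, n_genes=1500)
    datasets, truth = simulate_meta_datasets(cfg)
    model = DiseaseAxisModel().fit(datasets)
    return cfg, truth, model


class TestWindowEnrichment:
    def test_window_sizes_enumerate_grid(self, fitted):
        cfg, _, model = fitted
        table = window_enrichment(model.axis_, set(list(cfg.genes)[:50]), set(cfg.genes))
        assert list(table["size"]) == list(range(50, 1001, 50))

    def test_window_as_its_own_annotation_is_minimal_p(self, fitted):
        cfg, _, model = fitted
        top50 = set(model.axis_.ranked_genes("lowest")[:50])
        table = window_enrichment(model.axis_, top50, set(cfg.genes), sizes=[50])
        assert table["overlap"].iloc[0] == 50
        # the most extreme achievable p for this window size
        from gliaxis import log_hypergeom_tail

        assert table["ln_p"].iloc[0] == pytest.approx(
            log_hypergeom_tail(50, 50, 50, cfg.n_genes), rel=1e-9
        )

    def test_correlated_annotation_enriched_at_low_end(self, fitted):
        cfg, truth, model = fitted
        _, sets = simulate_gene_annotations(
            cfg, axis_vector=truth.axis_vector, gwas_correlation=2.0
        )
        table = window_enrichment(model.axis_, sets[0], set(cfg.genes), end="lowest")
        assert (table["p_adj"] < 0.05).any()

    def test_oversized_windows_skipped(self, fitted):
        cfg, _, model = fitted
        table = window_enrichment(
            model.axis_, set(list(cfg.genes)[:20]), set(list(cfg.genes)[:100]),
            sizes=[50, 5000],
        )
        assert list(table["size"]) == [50]


class TestRankRandomization:
    def make_proj(self, scores):
        return ProjectionResult(
            samples=[f"s{i}" for i in range(len(scores))],
            scores=np.asarray(scores, dtype=float),
            n_shared_genes=100,
        )

    def test_query_covering_all_samples_gives_p_one(self):
        proj = self.make_proj(np.arange(6))
        res = rank_randomization_test(proj, list(proj.samples), n_rand=100, rng=0)
        assert res.p_est == 1.0

    def test_extreme_query_reaches_floor(self):
        """Query occupying the strict top ranks: no null draw beats it."""
        proj = self.make_proj(np.arange(30))
        top = [f"s{i}" for i in range(27, 30)]
        res = rank_randomization_test(proj, top, n_rand=99_999, rng=1)
        # ties with the observed maximum can occur only by redrawing the top
        # subset itself: 1/C(30,3) of draws; with none observed r may be 0
        assert res.p_est <= 2 / 4060 + 1e-9
        if res.r == 0:
            assert res.p_est == pytest.approx(1 / 100_000)

    def test_null_p_uniform_over_replicates(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(200):
            proj = self.make_proj(rng.normal(size=24))
            query = list(np.array(proj.samples)[rng.choice(24, 6, replace=False)])
            pvals.append(
                rank_randomization_test(proj, query, n_rand=499, rng=rng).p_est
            )
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_reproducible_and_stable_across_seeds(self):
        proj = self.make_proj(np.random.default_rng(2).normal(size=20))
        query = list(proj.samples[:5])
        p1 = rank_randomization_test(proj, query, n_rand=2000, rng=3).p_est
        p2 = rank_randomization_test(proj, query, n_rand=2000, rng=3).p_est
        assert p1 == p2
        p3 = rank_randomization_test(proj, query, n_rand=2000, rng=4).p_est
        se = np.sqrt(p1 * (1 - p1) / 2000)
        assert abs(p3 - p1) < 3 * se + 1e-3

    def test_unknown_query_sample_rejected(self):
        proj = self.make_proj(np.arange(5))
        with pytest.raises(ValueError, match="not in projection"):
            rank_randomization_test(proj, ["zzz"], n_rand=10)


class TestEstimatorApi:
    def test_get_set_params_roundtrip(self):
        model = DiseaseAxisModel(min_total_count=10)
        params = model.get_params()
        assert params["min_total_count"] == 10
        model.set_params(center_on="train")
        assert model.center_on == "train"

    def test_unfitted_transform_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            DiseaseAxisModel().transform(expr(np.eye(3)))
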