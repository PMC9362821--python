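"""Normalization, HVG selection, scaling, clustering and annotation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import adjusted_rand_score

from nbtme import (
    ClusterLabels,
    CountMatrix,
    MarkerRegistry,
    annotate_clusters,
    cluster_cells,
    load_marker_registry,
    lognormalize,
    scale_genes,
    select_hvg,
    simulate_tme,
)
from nbtme.presets import marker_recovery

from conftest import make_lognorm


def counts_from_dense(dense) -> CountMatrix:
    dense = np.asarray(dense)
    return CountMatrix(
        sp.csr_matrix(dense),
        [f"g{i}" for i in range(dense.shape[0])],
        [f"c{j}" for j in range(dense.shape[1])],
    )


class TestLognormalize:
    @pytest.mark.parametrize(
        "count, total, expected",
        [
            (10, 10_000, np.log1p(10.0)),   # ~2.3979
            (5, 500, np.log1p(100.0)),      # ~4.6151
            (0, 1000, 0.0),
        ],
    )
    def test_closed_form(self, count, total, expected):
        dense = np.array([[count], [total - count]])
        ln = lognormalize(counts_from_dense(dense), scale_factor=10_000)
        assert ln.values.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_total_cell_error_names_cell(self):
        dense = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="c1"):
            lognormalize(counts_from_dense(dense))

    def test_duplicating_a_cell_leaves_values_unchanged(self):
        dense = np.array([[3, 1], [0, 5], [2, 2]])
        ln = lognormalize(counts_from_dense(dense))
        dup = np.hstack([dense, dense[:, [0]]])
        ln_dup = lognormalize(counts_from_dense(dup))
        np.testing.assert_allclose(
            ln_dup.values.iloc[:, 2].to_numpy(), ln.values.iloc[:, 0].to_numpy()
        )

    @given(
        arrays(np.int64, (4, 3), elements=st.integers(min_value=0, max_value=50))
    )
    def test_matches_formula_elementwise(self, dense):
        dense[0, :] += 1  # keep totals positive
        ln = lognormalize(counts_from_dense(dense), scale_factor=7_500)
        totals = dense.sum(axis=0)
        expected = np.log1p(dense * 7_500 / totals)
        np.testing.assert_allclose(ln.values.to_numpy(), expected, atol=1e-12)


class TestSelectHvg:
    def test_bimodal_gene_beats_constants(self):
        values = np.ones((4, 6))
        values[2] = [0, 0, 0, 4, 4, 4]
        ln = make_lognorm(values)
        assert select_hvg(ln, 1) == ["g2"]

    def test_full_selection_is_dispersion_sorted(self):
        rng = np.random.default_rng(1)
        ln = make_lognorm(rng.gamma(1.0, 1.0, size=(10, 30)))
        ranked = select_hvg(ln, 10)
        # brute-force oracle: recompute the dispersion of each gene directly
        X = np.expm1(ln.values.to_numpy())
        disp = {
            g: X[i].var(ddof=1) / X[i].mean()
            for i, g in enumerate(ln.genes)
        }
        expected = sorted(disp, key=lambda g: (-disp[g], g))
        assert ranked == expected

    def test_invalid_n_top(self):
        ln = make_lognorm(np.ones((3, 3)))
        with pytest.raises(ValueError):
            select_hvg(ln, 0)
        with pytest.raises(ValueError):
            select_hvg(ln, 4)


class TestScaleGenes:
    def test_constant_gene_maps_to_zeros(self):
        ln = make_lognorm(np.array([[2.0, 2.0, 2.0], [0.0, 1.0, 2.0]]))
        scaled = scale_genes(ln)
        assert (scaled.iloc[0] == 0).all()

    def test_two_point_standardization_sample_sd(self):
        # values {0, 2}: sd with n-1 is sqrt(2), so scaled = +-1/sqrt(2)
        ln = make_lognorm(np.array([[0.0, 2.0]]))
        scaled = scale_genes(ln)
        np.testing.assert_allclose(
            scaled.iloc[0].to_numpy(), [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
        )

    def test_centering_and_cap(self, rng):
        values = rng.normal(3.0, 2.0, size=(5, 40))
        values[0, 0] = 1e4  # extreme outlier hits the cap
        scaled = scale_genes(make_lognorm(values), cap=3.0)
        means_unclipped = scale_genes(make_lognorm(values), cap=1e9).mean(axis=1)
        assert (means_unclipped.abs() < 1e-9).all()
        assert scaled.abs().max().max() <= 3.0


class TestClusterCells:
    def test_separated_populations_recovered(self):
        cfg = marker_recovery(seed=0, fold_change=8.0, n_populations=2,
                              cells_per_population=200, n_genes=500)
        res = simulate_tme(cfg)
        ln = lognormalize(res.counts["panel"])
        labels = cluster_cells(scale_genes(ln), n_pcs=10, k=2, seed=0)
        assert adjusted_rand_score(res.truth.labels["panel"], labels.labels) >= 0.95

    def test_single_cluster_at_k_one(self, rng):
        scaled = scale_genes(make_lognorm(rng.normal(size=(10, 30))))
        labels = cluster_cells(scaled, n_pcs=5, k=1, seed=0)
        assert labels.n_clusters == 1

    @pytest.mark.parametrize("mode", ["kmeans", "leiden"])
    def test_identical_seed_identical_labels(self, rng, mode):
        scaled = scale_genes(make_lognorm(rng.normal(size=(20, 60))))
        kwargs = {"k": 3} if mode == "kmeans" else {"resolution": 1.0}
        runs = [
            cluster_cells(scaled, n_pcs=5, seed=7, **kwargs) for _ in range(2)
        ]
        pd.testing.assert_series_equal(runs[0].labels, runs[1].labels)

    def test_parameter_errors(self, rng):
        scaled = scale_genes(make_lognorm(rng.normal(size=(10, 8))))
        with pytest.raises(ValueError):
            cluster_cells(scaled, n_pcs=5, k=3, resolution=1.0)
        with pytest.raises(ValueError):
            cluster_cells(scaled, n_pcs=5)
        with pytest.raises(ValueError):
            cluster_cells(scaled, n_pcs=5, k=9)
        with pytest.raises(ValueError):
            cluster_cells(scaled, n_pcs=50, k=2)


class TestAnnotateClusters:
    def _two_cluster_lognorm(self):
        # cluster 0 overexpresses Cd3e only; cluster 1 expresses nothing
        values = np.zeros((3, 8))
        values[0, :4] = 3.0
        ln = make_lognorm(values, genes=["Cd3e", "g1", "g2"])
        labels = ClusterLabels(
            pd.Series([0, 0, 0, 0, 1, 1, 1, 1], index=ln.cells)
        )
        return ln, labels

    def test_cd3e_cluster_annotated_t_cell(self):
        ln, labels = self._two_cluster_lognorm()
        registry = MarkerRegistry({"t_cell": [("Cd3e", "high")]})
        ann = annotate_clusters(ln, labels, registry)
        assert ann.cluster_types[0] == "t_cell"
        assert ann.cluster_types[1] == "undefined"

    def test_registry_without_matching_genes_gives_undefined(self):
        ln, labels = self._two_cluster_lognorm()
        registry = MarkerRegistry({"x": [("absent_gene", "high")]})
        with pytest.warns(UserWarning):
            ann = annotate_clusters(ln, labels, registry)
        assert set(ann.cluster_types.values()) == {"undefined"}

    def test_intermediate_sense_prefers_mid_range_cluster(self):
        values = np.array([[0.0, 2.0, 4.0], [5.0, 0.0, 0.0]])
        ln = make_lognorm(values, genes=["CD14", "other"])
        labels = ClusterLabels(pd.Series([0, 1, 2], index=ln.cells))
        registry = MarkerRegistry({"nc_mono": [("CD14", "intermediate")]})
        ann = annotate_clusters(ln, labels, registry, margin_threshold=-10)
        scores = ann.scores["nc_mono"]
        assert scores.idxmax() == 1

    def test_all_populations_recovered_with_matched_registry(self):
        cfg = marker_recovery(seed=3, fold_change=6.0, n_populations=8,
                              cells_per_population=60, n_genes=500,
                              markers_per_population=10)
        res = simulate_tme(cfg)
        ln = lognormalize(res.counts["panel"])
        truth = res.truth.labels["panel"]
        cats = sorted(truth.unique())
        labels = ClusterLabels(
            pd.Series(truth.map({c: i for i, c in enumerate(cats)}).to_numpy(),
                      index=truth.index)
        )
        registry = MarkerRegistry(
            {
                pop: [(g, "high") for g in genes[:3]]
                for pop, genes in res.truth.marker_sets["panel"].items()
            }
        )
        ann = annotate_clusters(ln, labels, registry)
        assert [ann.cluster_types[i] for i in range(8)] == cats

    def test_relabeling_clusters_leaves_cell_types_unchanged(self):
        ln, labels = self._two_cluster_lognorm()
        registry = MarkerRegistry({"t_cell": [("Cd3e", "high")]})
        ann = annotate_clusters(ln, labels, registry)
        flipped = ClusterLabels(1 - labels.labels)
        ann_f = annotate_clusters(ln, flipped, registry)
        types = labels.with_names(ann.cluster_types).cell_types()
        types_f = flipped.with_names(ann_f.cluster_types).cell_types()
        pd.testing.assert_series_equal(types, types_f)


def test_bundled_registries_load():
    for species in ("mouse", "human"):
        registry = load_marker_registry(species)
        assert len(registry) >= 10
        senses = {s for markers in registry.entries.values() for _, s in markers}
        assert senses <= {"high", "intermediate", "absent"}
    assert "intermediate" in {
        s for _, s in load_marker_registry("human").entries["nc_monocyte"]
    }
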