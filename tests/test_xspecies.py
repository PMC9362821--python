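"""Cross-species panel construction, profiles, dendrograms, projection."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from nbtme import (
    ClusterLabels,
    GeneSet,
    OrthologueTable,
    build_union_geneset,
    cluster_profile_matrix,
    correspondence_score,
    hierarchical_correspondence,
    one_to_one_filter,
    project_signature,
    score_signature,
)

from conftest import make_lognorm


class TestOneToOneFilter:
    def test_multi_mapped_rows_removed(self):
        table = OrthologueTable([("a1", "b1"), ("a2", "b2"), ("a2", "b3")])
        out = one_to_one_filter(table)
        assert list(out.pairs.itertuples(index=False, name=None)) == [("a1", "b1")]

    def test_empty_table(self):
        assert len(one_to_one_filter(OrthologueTable([]))) == 0

    def test_matches_counting_oracle_and_idempotent(self, rng):
        pairs = [(f"a{rng.integers(0, 80)}", f"b{rng.integers(0, 80)}")
                 for _ in range(200)]
        table = OrthologueTable(pairs)
        out = one_to_one_filter(table)
        ca, cb = Counter(p[0] for p in pairs), Counter(p[1] for p in pairs)
        expected = [p for p in pairs if ca[p[0]] == 1 and cb[p[1]] == 1]
        assert list(out.pairs.itertuples(index=False, name=None)) == expected
        assert one_to_one_filter(out).equals(out)


class TestBuildUnionGeneset:
    def test_same_pair_from_both_species_deduplicates(self):
        table = OrthologueTable([("a1", "b1")])
        panel = build_union_geneset(
            [GeneSet("ca", ["a1"])], [GeneSet("cb", ["b1"])], table
        )
        assert len(panel) == 1
        assert panel.iloc[0]["provenance"] == "ca;cb"

    def test_gene_without_table_entry_excluded(self):
        table = OrthologueTable([("a1", "b1")])
        panel = build_union_geneset(
            [GeneSet("ca", ["a1", "a_unmapped"])], [], table
        )
        assert list(panel["gene_a"]) == ["a1"]

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError):
            build_union_geneset([GeneSet("ca", ["zz"])], [], OrthologueTable([]))

    def test_matches_set_algebra_oracle(self, rng):
        n = 60
        table = OrthologueTable([(f"a{i}", f"b{i}") for i in range(n)])
        sets_a = [
            GeneSet(f"ka{k}", [f"a{i}" for i in rng.integers(0, n + 10, size=8)])
            for k in range(3)
        ]
        sets_b = [
            GeneSet(f"kb{k}", [f"b{i}" for i in rng.integers(0, n + 10, size=8)])
            for k in range(3)
        ]
        panel = build_union_geneset(sets_a, sets_b, table)
        expected = set()
        for gs in sets_a:
            expected |= {g for g in gs.genes if int(g[1:]) < n}
        for gs in sets_b:
            expected |= {"a" + g[1:] for g in gs.genes if int(g[1:]) < n}
        assert set(panel["gene_a"]) == expected
        assert len(panel) == len(set(zip(panel["gene_a"], panel["gene_b"])))


def _pair_panel(genes_a, genes_b) -> pd.DataFrame:
    return pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})


class TestClusterProfileMatrix:
    def test_single_cluster_per_species_is_all_zero(self, rng):
        ln_a = make_lognorm(rng.gamma(1, 1, size=(4, 5)), genes=["a0", "a1", "a2", "a3"])
        ln_b = make_lognorm(rng.gamma(1, 1, size=(4, 5)), genes=["b0", "b1", "b2", "b3"])
        lab = lambda ln: ClusterLabels(pd.Series([0] * 5, index=ln.cells))
        panel = _pair_panel(["a0", "a2"], ["b1", "b3"])
        profile = cluster_profile_matrix(ln_a, lab(ln_a), ln_b, lab(ln_b), panel)
        np.testing.assert_allclose(profile.to_numpy(), 0.0)

    def test_identical_cells_cluster_mean_equals_member(self):
        values = np.tile(np.array([[1.0], [2.0]]), (1, 4))
        values_b = np.array([[0.5, 0.5, 3.0, 3.0]])
        ln_a = make_lognorm(values, genes=["a0", "a1"])
        ln_b = make_lognorm(values_b, genes=["b0"])
        lab_a = ClusterLabels(pd.Series([0, 0, 1, 1], index=ln_a.cells))
        lab_b = ClusterLabels(pd.Series([0, 0, 1, 1], index=ln_b.cells))
        from nbtme.xspecies import _cluster_means

        means = _cluster_means(ln_a, lab_a, ["a0", "a1"])
        np.testing.assert_allclose(means[0].to_numpy(), values[:, 0])

    def test_three_cluster_hand_computed_zscores(self):
        # species A: one panel gene, cluster means 1, 2, 3 -> z = -1, 0, 1
        values_a = np.array([[1.0, 1.0, 2.0, 2.0, 3.0, 3.0]])
        values_b = np.array([[4.0, 4.0, 8.0, 8.0]])
        ln_a = make_lognorm(values_a, genes=["a0"])
        ln_b = make_lognorm(values_b, genes=["b0"])
        lab_a = ClusterLabels(pd.Series([0, 0, 1, 1, 2, 2], index=ln_a.cells))
        lab_b = ClusterLabels(pd.Series([0, 0, 1, 1], index=ln_b.cells))
        profile = cluster_profile_matrix(
            ln_a, lab_a, ln_b, lab_b, _pair_panel(["a0"], ["b0"])
        )
        np.testing.assert_allclose(
            profile.to_numpy().ravel(),
            [-1.0, 0.0, 1.0, -1 / np.sqrt(2), 1 / np.sqrt(2)],
            atol=1e-12,
        )

    def test_invariant_to_cell_order_and_relabeling(self, rng):
        values = rng.gamma(1, 1, size=(6, 12))
        ln_a = make_lognorm(values, genes=[f"a{i}" for i in range(6)])
        ln_b = make_lognorm(values[:, :8], genes=[f"b{i}" for i in range(6)])
        lab_a = ClusterLabels(pd.Series([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2],
                                        index=ln_a.cells), names={0: "x", 1: "y", 2: "z"})
        lab_b = ClusterLabels(pd.Series([0, 0, 0, 0, 1, 1, 1, 1],
                                        index=ln_b.cells), names={0: "u", 1: "v"})
        panel = _pair_panel(["a0", "a3", "a5"], ["b1", "b2", "b4"])
        base = cluster_profile_matrix(ln_a, lab_a, ln_b, lab_b, panel)
        perm = rng.permutation(12)
        ln_a_p = make_lognorm(values[:, perm], genes=[f"a{i}" for i in range(6)],
                              cells=[ln_a.cells[i] for i in perm])
        lab_a_p = ClusterLabels(lab_a.labels.map({0: 1, 1: 0, 2: 2}).iloc[perm],
                                names={1: "x", 0: "y", 2: "z"})
        out = cluster_profile_matrix(ln_a_p, lab_a_p, ln_b, lab_b, panel)
        pd.testing.assert_frame_equal(base.sort_index(), out.sort_index())

    def test_missing_panel_gene_errors(self, rng):
        ln = make_lognorm(rng.gamma(1, 1, size=(2, 4)), genes=["a0", "a1"])
        lab = ClusterLabels(pd.Series([0, 0, 1, 1], index=ln.cells))
        with pytest.raises(ValueError, match="absent"):
            cluster_profile_matrix(ln, lab, ln, lab, _pair_panel(["zz"], ["a0"]))


def naive_upgma(X: np.ndarray):
    """O(n^3) average-linkage agglomeration with correlation distance."""

    def cdist(u, v):
        return 1 - np.corrcoef(u, v)[0, 1]

    clusters = {i: [i] for i in range(len(X))}
    active = list(range(len(X)))
    merges = []
    next_id = len(X)
    while len(active) > 1:
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1:]:
                d = np.mean([
                    cdist(X[p], X[q]) for p in clusters[a] for q in clusters[b]
                ])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return merges


class TestHierarchicalCorrespondence:
    def test_identical_rows_merge_first_at_zero(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [5.0, 1.0, 0.0]])
        profile = pd.DataFrame(X, index=["r0", "r1", "r2"])
        dendro = hierarchical_correspondence(profile)
        first = dendro.merges[0]
        assert {first[0], first[1]} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_merge_sequence_matches_naive_oracle(self, rng):
        X = rng.normal(size=(5, 7))
        profile = pd.DataFrame(X, index=[f"r{i}" for i in range(5)])
        dendro = hierarchical_correspondence(profile)
        expected = naive_upgma(X)
        for (a, b, h), (ea, eb, eh) in zip(dendro.merges, expected):
            assert {a, b} == {ea, eb}
            assert h == pytest.approx(eh, abs=1e-9)

    def test_duplicated_rows_give_zero_height_merges(self, rng):
        row = rng.normal(size=6)
        X = np.vstack([row] * 4 + [rng.normal(size=6)])
        dendro = hierarchical_correspondence(pd.DataFrame(X))
        heights = [m[2] for m in dendro.merges]
        assert np.allclose(heights[:3], 0.0, atol=1e-12)
        assert heights[3] > 0
        # UPGMA heights are non-decreasing
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_nan_and_constant_rows_rejected(self):
        bad = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            hierarchical_correspondence(bad)
        const = pd.DataFrame([[1.0, 1.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            hierarchical_correspondence(const)

    def test_newick_export_parses(self, rng):
        import dendropy

        X = rng.normal(size=(4, 6))
        profile = pd.DataFrame(X, index=["w", "x", "y", "z"])
        dendro = hierarchical_correspondence(profile)
        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == {"w", "x", "y", "z"}

    def test_column_axis_clusters_genes(self, rng):
        profile = pd.DataFrame(rng.normal(size=(4, 6)),
                               columns=[f"p{i}" for i in range(6)])
        dendro = hierarchical_correspondence(profile, axis="columns")
        assert sorted(dendro.labels) == sorted(profile.columns)


class TestCorrespondenceScore:
    def _profile(self, rows):
        idx = pd.MultiIndex.from_tuples(
            [(r.split(":")[0], r.split(":")[1]) for r in rows],
            names=["species", "cluster"],
        )
        return idx

    def test_identical_cognates_all_flags_true(self, rng):
        base1, base2 = rng.normal(size=6), rng.normal(size=6)
        X = np.vstack([base1, base2, base1, base2])
        profile = pd.DataFrame(
            X, index=self._profile(["a:p1", "a:p2", "b:p1", "b:p2"])
        )
        out = correspondence_score(
            profile, [(("a", "p1"), ("b", "p1")), (("a", "p2"), ("b", "p2"))]
        )
        assert out["mutual_nearest"].all()
        assert out["joined_first"].all()
        np.testing.assert_allclose(out["distance"], 0.0, atol=1e-12)

    def test_orthogonal_profiles_flags_false(self):
        X = np.array([
            [1.0, 0.0, 0.0, 0.5],
            [0.0, 1.0, 0.5, 0.0],
            [0.0, 0.5, 1.0, 0.0],
            [0.5, 0.0, 0.0, 1.0],
        ])
        profile = pd.DataFrame(
            X, index=self._profile(["a:p1", "a:p2", "b:p1", "b:p2"])
        )
        out = correspondence_score(profile, [(("a", "p1"), ("b", "p1"))])
        assert not out["mutual_nearest"].any()

    def test_mutual_nearest_matches_brute_force(self, rng):
        X = rng.normal(size=(8, 10))
        rows = [f"a:c{i}" for i in range(4)] + [f"b:c{i}" for i in range(4)]
        profile = pd.DataFrame(X, index=self._profile(rows))
        pairs = [(("a", f"c{i}"), ("b", f"c{i}")) for i in range(4)]
        out = correspondence_score(profile, pairs)

        def corr_dist(u, v):
            return 1 - np.corrcoef(u, v)[0, 1]

        for i in range(4):
            d_a = [corr_dist(X[i], X[4 + j]) for j in range(4)]
            d_b = [corr_dist(X[4 + i], X[j]) for j in range(4)]
            expected = (int(np.argmin(d_a)) == i) and (int(np.argmin(d_b)) == i)
            assert out["mutual_nearest"].iloc[i] == expected

    def test_unknown_row_rejected(self, rng):
        profile = pd.DataFrame(
            rng.normal(size=(2, 4)), index=self._profile(["a:p1", "b:p1"])
        )
        with pytest.raises(ValueError):
            correspondence_score(profile, [(("a", "zz"), ("b", "p1"))])


class TestProjectSignature:
    def test_fully_unmapped_signature_errors_with_gene_list(self, rng):
        ln = make_lognorm(rng.gamma(1, 1, size=(5, 4)))
        table = OrthologueTable([("x1", "y1")])
        with pytest.raises(ValueError, match="s1"):
            project_signature(GeneSet("sig", ["s1", "s2"]), table, ln)

    def test_identity_map_reduces_to_direct_scoring(self, rng):
        values = rng.gamma(1, 1, size=(20, 6))
        ln = make_lognorm(values)
        table = OrthologueTable([(g, g) for g in ln.genes])
        sig = GeneSet("s", ["g2", "g8", "g11"])
        projected, report = project_signature(sig, table, ln, seed=9)
        direct = score_signature(ln, GeneSet("s_projected", sig.genes), seed=9)
        np.testing.assert_allclose(
            projected.scores.to_numpy(), direct.scores.to_numpy(), atol=1e-12
        )
        assert report["dropped"] == []

    def test_translation_report(self, rng):
        ln = make_lognorm(rng.gamma(1, 1, size=(4, 4)), genes=["B1", "B2", "B3", "B4"])
        table = OrthologueTable([("a1", "B1"), ("a2", "B2")])
        _score, report = project_signature(GeneSet("s", ["a1", "a2", "a3"]), table, ln)
        assert report["mapped"] == {"a1": "B1", "a2": "B2"}
        assert report["dropped"] == ["a3"]
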