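"""Gene ranking, subset selectors and the optimization/depletion loops."""

import numpy as np
import pytest

import geneso as gs


def table_from(scores: dict[str, list[float]], classes=None):
    genes = list(scores)
    mat = np.array([scores[g] for g in genes], dtype=float)
    classes = classes or [f"c{i}" for i in range(mat.shape[1])]
    return gs.OcclusionScoreTable(genes, classes, mat)


class TestRanking:
    def test_descending_order(self):
        t = table_from({"g1": [0.9], "g2": [0.5], "g3": [0.1]})
        assert gs.rank_by_mean_occlusion(t).gene_ids == ["g1", "g2", "g3"]

    def test_tie_breaks_lexicographically(self):
        t = table_from({"g2": [0.5], "g1": [0.5]})
        assert gs.rank_by_mean_occlusion(t).gene_ids == ["g1", "g2"]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_sort(self, seed):
        rng = np.random.default_rng(seed)
        t = table_from({f"g{i}": list(rng.random(4)) for i in range(25)})
        ranking = gs.rank_by_mean_occlusion(t)
        oracle = sorted(t.gene_ids,
                        key=lambda g: (-t.mean_score_of(g), g))
        assert ranking.gene_ids == oracle

    def test_empty_table_rejected(self):
        with pytest.raises(gs.DataError):
            gs.rank_by_mean_occlusion(
                gs.OcclusionScoreTable([], ["c"], np.empty((0, 1))))


class TestTopFraction:
    def test_ceil_rule(self):
        r = gs.rank_by_mean_occlusion(
            table_from({"g1": [0.9], "g2": [0.5], "g3": [0.1]}))
        assert gs.select_top_fraction(r, 0.33) == ["g1"]
        assert gs.select_top_fraction(r, 1.0) == ["g1", "g2", "g3"]

    def test_third_of_large_list(self):
        n = 19002
        scores = {f"g{i:05d}": [1.0 - i / n] for i in range(n)}
        r = gs.rank_by_mean_occlusion(table_from(scores))
        assert len(gs.select_top_fraction(r, 1 / 3)) == int(np.ceil(n / 3))

    def test_nesting(self):
        rng = np.random.default_rng(1)
        r = gs.rank_by_mean_occlusion(
            table_from({f"g{i}": [rng.random()] for i in range(30)}))
        for f1, f2 in [(0.1, 0.2), (0.2, 0.5), (0.5, 1.0)]:
            assert set(gs.select_top_fraction(r, f1)) <= \
                set(gs.select_top_fraction(r, f2))

    def test_fraction_bounds(self):
        r = gs.rank_by_mean_occlusion(table_from({"g1": [0.5]}))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                gs.select_top_fraction(r, bad)


class TestTopUniquePerClass:
    def test_shared_gene_deduplicated(self):
        t = table_from({"g1": [0.9, 0.9], "g2": [0.1, 0.2]})
        assert gs.select_top_unique_per_class(t, 0.5) == ["g1"]

    def test_disjoint_toplists_union(self):
        t = table_from({"g1": [0.9, 0.0], "g2": [0.0, 0.9], "g3": [0.1, 0.1]})
        assert set(gs.select_top_unique_per_class(t, 1 / 3)) == {"g1", "g2"}

    def test_union_at_least_single_class_toplist(self):
        rng = np.random.default_rng(2)
        t = table_from({f"g{i}": list(rng.random(3)) for i in range(20)})
        union = gs.select_top_unique_per_class(t, 0.25)
        assert len(union) >= int(np.ceil(0.25 * 20))
        assert len(union) == len(set(union))


class TestBaselineSelectors:
    def make_nm(self, values, labels=None):
        values = np.asarray(values, dtype=float)
        genes = [f"g{i}" for i in range(values.shape[0])]
        samples = [f"s{j}" for j in range(values.shape[1])]
        labels = labels or {s: f"c{j % 2}"
                            for j, s in enumerate(samples)}
        return gs.NormalizedMatrix(genes, samples, values, "FPKM", labels)

    def test_mostavi_mean_or_std_filter(self):
        nm = self.make_nm([[150.0, 150.0], [0.5, 0.5], [0.0, 3.0]])
        assert gs.mostavi_select(nm, 1.0) == ["g0", "g2"]

    @pytest.mark.parametrize("seed", range(3))
    def test_mostavi_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        nm = self.make_nm(rng.random((15, 8)) * 5)
        got = gs.mostavi_select(nm, 2.0)
        expected = [g for i, g in enumerate(nm.gene_ids)
                    if nm.values[i].mean() > 2.0 or nm.values[i].std() > 2.0]
        assert got == expected

    def test_zhao_recovers_planted_markers(self):
        cm, truth = gs.simulate_counts(gs.SyntheticConfig(
            n_classes=3, samples_per_class=10, n_genes=40,
            markers_per_class=1, fold_change=10.0, seed=8))
        nm = gs.compute_nrc(cm)
        selected = set(gs.zhao_select(nm, k_per_class=1))
        markers = {g for genes in truth.values() for g in genes}
        assert markers <= selected

    def test_zhao_k_bounds(self):
        rng = np.random.default_rng(0)
        nm = self.make_nm(rng.random((30, 10)))
        assert set(gs.zhao_select(nm, k_per_class=30)) == set(nm.gene_ids)
        assert len(gs.zhao_select(nm, k_per_class=40)) <= 30


class TestOptimizeAndDeplete:
    def test_single_full_fraction_equals_plain_cv(self, small_dataset):
        nm, _ = small_dataset
        rng = np.random.default_rng(0)
        t = table_from({g: list(rng.random(3)) for g in nm.gene_ids})
        cfg = gs.NetworkConfig(hidden_sizes=(6, 4), timesteps=1, epochs=8)
        best, results = gs.optimize_subset(nm, t, [1.0], cfg, k=3, seed=0)
        assert best.fraction == 1.0
        assert set(best.gene_ids) == set(nm.gene_ids)
        plain = gs.cross_validate(
            nm.subset_genes(best.gene_ids), cfg, k=3, repeats=1, seed=0)
        assert best.mean_accuracy == pytest.approx(plain["mean_accuracy"])

    def test_optimize_is_deterministic(self, small_dataset):
        nm, _ = small_dataset
        rng = np.random.default_rng(1)
        t = table_from({g: list(rng.random(3)) for g in nm.gene_ids})
        cfg = gs.NetworkConfig(hidden_sizes=(5,), timesteps=1, epochs=5)
        b1, _ = gs.optimize_subset(nm, t, [0.2, 1.0], cfg, k=3, seed=2)
        b2, _ = gs.optimize_subset(nm, t, [0.2, 1.0], cfg, k=3, seed=2)
        assert b1.fraction == b2.fraction
        np.testing.assert_array_equal(b1.fold_accuracies, b2.fold_accuracies)

    def test_depleting_nothing_changes_nothing(self, small_dataset):
        nm, _ = small_dataset
        cfg = gs.NetworkConfig(hidden_sizes=(5,), timesteps=1, epochs=5)
        delta = gs.depletion_study(nm, nm.gene_ids[:10], set(), cfg,
                                   k=3, seed=0)
        assert delta == 0.0

    def test_depleting_markers_costs_more_than_nulls(self, small_dataset):
        nm, truth = small_dataset
        markers = [g for genes in truth.values() for g in genes]
        nulls = [g for g in nm.gene_ids if g not in markers][:len(markers)]
        cfg = gs.NetworkConfig(hidden_sizes=(8, 6), timesteps=1, epochs=60)
        subset = list(nm.gene_ids)
        d_mark = gs.depletion_study(nm, subset, set(markers), cfg, k=3,
                                    seed=0)
        d_null = gs.depletion_study(nm, subset, set(nulls), cfg, k=3, seed=0)
        assert d_mark > 0
        assert d_mark > abs(d_null)
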