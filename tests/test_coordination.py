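"""Grid selection, density estimation and the coordination test."""

import itertools

import numpy as np
import pytest
from scipy.stats import kstest

from pathdens import GeneSetCollection, grid_density, kl_divergence, select_grid_points
from pathdens.coordination import GridPoints, balanced_kmeans
from pathdens.coordination import test_coordination as coordination_test


class TestBalancedKmeans:
    def test_group_sizes_differ_by_at_most_one(self, rng):
        pts = rng.random((200, 3))
        labels, _ = balanced_kmeans(pts, 100, seed=0)
        sizes = np.bincount(labels)
        assert sizes.min() == sizes.max() == 2

    def test_uneven_division(self, rng):
        labels, _ = balanced_kmeans(rng.random((11, 2)), 3, seed=0)
        assert sorted(np.bincount(labels)) == [3, 4, 4]

    def test_two_blobs_match_exhaustive_balanced_partition(self, rng):
        # 10 points in two well-separated blobs: compare the objective of
        # the returned 2-partition with the exhaustive balanced optimum
        pts = np.vstack([rng.random((5, 2)), rng.random((5, 2)) + 10.0])

        def cost(groups):
            return sum(
                np.sum((pts[list(g)] - pts[list(g)].mean(0)) ** 2) for g in groups
            )

        best = min(
            cost([g, tuple(set(range(10)) - set(g))])
            for g in itertools.combinations(range(10), 5)
        )
        labels, centroids = balanced_kmeans(pts, 2, seed=0)
        got = cost([np.where(labels == 0)[0], np.where(labels == 1)[0]])
        assert got == pytest.approx(best)
        # centroids are inside the blobs, not between them
        for c in centroids:
            assert np.linalg.norm(c - pts[:5].mean(0)) < 1.0 or np.linalg.norm(
                c - pts[5:].mean(0)
            ) < 1.0


class TestGridPoints:
    def test_more_groups_than_cells_rejected(self, small_embedding):
        with pytest.raises(ValueError):
            select_grid_points(small_embedding, n_grid=10**6)

    def test_bandwidth_positive_and_grid_in_scaled_space(self, small_embedding):
        grid = select_grid_points(small_embedding, n_grid=50, seed=0)
        assert grid.bandwidth > 0
        assert grid.coords.shape == (50, small_embedding.dim)

    def test_degenerate_bandwidth_guard(self):
        with pytest.raises(ValueError):
            GridPoints(coords=np.zeros((3, 2)), bandwidth=0.0)


class TestGridDensity:
    def test_matches_brute_force_double_loop(self, rng):
        genes = rng.normal(size=(50, 4))
        grid = GridPoints(coords=rng.normal(size=(20, 4)), bandwidth=0.7)
        dens = grid_density(genes, grid)
        brute = np.zeros(20)
        for j in range(20):
            for i in range(50):
                d = np.linalg.norm(genes[i] - grid.coords[j]) / 0.7
                brute[j] += np.exp(-(d**2) / 2)
        brute /= brute.sum()
        np.testing.assert_allclose(dens, brute, atol=1e-12)

    def test_single_point_on_grid_closed_form(self):
        grid = GridPoints(coords=np.array([[0.0], [3.0]]), bandwidth=2.0)
        dens = grid_density(np.array([[0.0]]), grid)
        raw = np.array([1.0, np.exp(-((3.0 / 2.0) ** 2) / 2)])
        np.testing.assert_allclose(dens, raw / raw.sum(), atol=1e-12)

    def test_union_additivity_before_normalization(self, rng):
        grid = GridPoints(coords=rng.normal(size=(10, 3)), bandwidth=1.0)
        a, b = rng.normal(size=(7, 3)), rng.normal(size=(5, 3))
        # additivity holds on the unnormalized kernel sums
        ra = np.exp(-0.5 * (np.linalg.norm(a[:, None] - grid.coords, axis=2)) ** 2).sum(0)
        rb = np.exp(-0.5 * (np.linalg.norm(b[:, None] - grid.coords, axis=2)) ** 2).sum(0)
        dab = grid_density(np.vstack([a, b]), grid)
        np.testing.assert_allclose(dab, (ra + rb) / (ra + rb).sum(), atol=1e-12)

    def test_empty_point_list_rejected(self):
        grid = GridPoints(coords=np.zeros((2, 1)) + [[0.0], [1.0]], bandwidth=1.0)
        with pytest.raises(ValueError):
            grid_density(np.empty((0, 1)), grid)


class TestKlDivergence:
    def test_identical_distributions_give_zero(self, rng):
        p = rng.random(30)
        p /= p.sum()
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-14)

    def test_point_mass_vs_uniform_is_log_two(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(np.log(2))

    def test_non_negative_on_random_pairs(self, rng):
        for _ in range(1000):
            p = rng.random(8)
            q = rng.random(8)
            assert kl_divergence(p / p.sum(), q / q.sum()) >= -1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence([0.5, 0.5], [1.0])


class TestCoordinationTest:
    def test_planted_markers_significant_random_not(self, small_dataset, small_embedding):
        sets = {"planted": small_dataset.marker_sets["type0.strong"]}
        rng = np.random.default_rng(0)
        for i in range(10):
            sets[f"rand{i}"] = list(
                rng.choice(small_embedding.gene_ids, size=20, replace=False)
            )
        res = {
            r.set_name: r
            for r in coordination_test(
                small_embedding, GeneSetCollection(sets), n_grid=50, n_controls=50, seed=1
            )
        }
        assert res["planted"].fdr < 0.05
        n_sig = sum(1 for n, r in res.items() if n.startswith("rand") and r.p_value < 0.05)
        assert n_sig <= 2

    def test_all_genes_set_is_null(self, small_embedding):
        # the whole-universe set has P = Q exactly; its size-matched
        # controls are also the whole universe, so the null degenerates
        # (zero spread) and the normal p is reported as NA by contract
        res = coordination_test(
            small_embedding,
            GeneSetCollection({"all": list(small_embedding.gene_ids)}),
            n_grid=50,
            n_controls=30,
            seed=0,
        )[0]
        assert res.kld == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(res.p_value)
        assert res.p_empirical > 0.9

    def test_mixture_ordering_on_planted_data(self, small_dataset, small_embedding):
        from pathdens import derive_marker_mixes

        strong = GeneSetCollection(
            {n: g for n, g in small_dataset.marker_sets if n.endswith("strong")}
        )
        mixes = derive_marker_mixes(strong, small_embedding.gene_ids, seed=2)
        res = coordination_test(
            small_embedding, mixes, n_grid=50, n_controls=50, seed=2
        )
        med = {}
        for cat in ("marker", "mix1", "mix3", "random"):
            med[cat] = np.median([r.z for r in res if f".{cat}." in r.set_name])
        # at fixture scale mix3 keeps only 5 marker genes, too few to
        # separate from random; the full four-level ordering is asserted
        # at study scale in the acceptance suite
        assert med["marker"] > med["mix1"] > max(med["mix3"], med["random"])

    def test_null_pvalues_approximately_uniform(self, small_embedding):
        rng = np.random.default_rng(9)
        sets = {
            f"r{i}": list(rng.choice(small_embedding.gene_ids, size=25, replace=False))
            for i in range(200)
        }
        res = coordination_test(
            small_embedding, GeneSetCollection(sets), n_grid=50, n_controls=100, seed=3
        )
        pvals = np.array([r.p_value for r in res])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_seed_reproducibility_bitwise(self, small_dataset, small_embedding):
        sets = GeneSetCollection({"s": small_dataset.marker_sets["type1.strong"]})
        a = coordination_test(small_embedding, sets, n_grid=40, n_controls=30, seed=7)[0]
        b = coordination_test(small_embedding, sets, n_grid=40, n_controls=30, seed=7)[0]
        assert (a.p_value, a.z, a.kld) == (b.p_value, b.z, b.kld)

    def test_tiny_sets_skipped(self, small_embedding):
        sets = GeneSetCollection(
            {"tiny": ["not_a_gene", small_embedding.gene_ids[0]], "ok": small_embedding.gene_ids[:5]}
        )
        res = coordination_test(small_embedding, sets, n_grid=30, n_controls=20, seed=0)
        assert [r.set_name for r in res] == ["ok"]
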