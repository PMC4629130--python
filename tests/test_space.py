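"""Odorant-space geometry: distances, pair ranking, clustering, PCA and
temporal-structure classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cimexolf as co
from cimexolf.errors import (
    DegenerateColumnError,
    InsufficientDataError,
    InvalidParameterError,
    SchemaError,
    UndefinedIndexError,
)
from conftest import toy_matrix


def _random_matrix(seed, n=20):
    rng = np.random.default_rng(seed)
    values = {s: rng.uniform(0, 250, n) for s in co.panel.SENSILLA}
    return toy_matrix(values)


class TestBuildSpace:
    def test_pair_count(self):
        space = co.build_space(_random_matrix(0, n=104))
        assert space.n_pairs == 5356

    def test_pythagorean_distance(self):
        m = toy_matrix(
            dict(zip(co.panel.SENSILLA, [[0.0, 3.0], [0.0, 4.0]] + [[0.0, 0.0]] * 4))
        )
        space = co.build_space(m)
        assert space.condensed[0] == 5.0

    def test_identical_vectors_at_zero_distance(self):
        m = toy_matrix({s: [7.0, 7.0] for s in co.panel.SENSILLA})
        assert co.build_space(m).condensed[0] == 0.0

    def test_missing_sensillum_column_rejected(self):
        m = _random_matrix(1)
        m.mean = m.mean.drop(columns=["E2"])
        with pytest.raises(SchemaError):
            co.build_space(m)

    def test_metric_axioms_hold(self):
        space = co.build_space(_random_matrix(2, n=30))
        d = space.distance_matrix.values
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d >= 0)
        for i, j, k in itertools.combinations(range(30), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestRankPairs:
    @pytest.mark.parametrize("direction", ["closest", "farthest"])
    def test_agrees_with_brute_force_sort(self, direction):
        space = co.build_space(_random_matrix(3, n=15))
        ids = space.odorant_ids
        brute = sorted(
            (
                (space.distance(a, b), a, b)
                for a, b in itertools.combinations(ids, 2)
            ),
            reverse=(direction == "farthest"),
        )
        got = co.rank_pairs(space, 7, direction)
        for row, (dist, a, b) in zip(got.itertuples(), brute[:7]):
            assert {row.odorant_a, row.odorant_b} == {a, b}
            assert np.isclose(row.distance_exact, dist)

    def test_full_ranking_covers_all_pairs(self):
        space = co.build_space(_random_matrix(4, n=10))
        full = co.rank_pairs(space, space.n_pairs, "closest")
        assert len(full) == 45
        assert full["distance_exact"].is_monotonic_increasing

    def test_invalid_k_rejected(self):
        space = co.build_space(_random_matrix(5, n=5))
        with pytest.raises(InvalidParameterError):
            co.rank_pairs(space, 0, "closest")
        with pytest.raises(InvalidParameterError):
            co.rank_pairs(space, 11, "closest")

    def test_farthest_pairs_all_share_nonanal(self, sim_matrix):
        """Nonanal dominates the space: every top-10 farthest pair has it."""
        far = co.rank_pairs(co.build_space(sim_matrix), 10, "farthest")
        assert all(
            "nonanal" in pair
            for pair in zip(far["odorant_a"], far["odorant_b"])
        )


class TestHierarchicalClustering:
    def test_two_items_merge_at_their_distance(self):
        tree = co.hcluster(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert tree.linkage.shape == (1, 4)
        assert tree.heights[0] == 5.0

    def test_two_separated_pairs_recovered_at_k2(self):
        x = np.array([[0.0, 0], [0.1, 0], [10.0, 0], [10.1, 0]])
        cut = co.hcluster(x, labels=list("abcd")).cut(2)
        assert cut["a"] == cut["b"]
        assert cut["c"] == cut["d"]
        assert cut["a"] != cut["c"]
        # oracle: among all 2-partitions, {ab|cd} has the smallest
        # within-group distance sum
        best = min(
            (
                sum(
                    np.linalg.norm(x[i] - x[j])
                    for g in (grp, tuple(set(range(4)) - set(grp)))
                    for i, j in itertools.combinations(g, 2)
                ),
                grp,
            )
            for r in (1, 2)
            for grp in itertools.combinations(range(4), r)
        )
        assert set(best[1]) in ({0, 1}, {2, 3})

    def test_average_linkage_heights_invariant_to_row_order(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 100, size=(12, 6))
        ref = np.sort(co.hcluster(x).heights)
        for seed in range(5):
            perm = np.random.default_rng(seed).permutation(12)
            np.testing.assert_allclose(
                np.sort(co.hcluster(x[perm]).heights), ref, rtol=1e-9
            )

    def test_structural_twins_merge_first(self, ref_matrix):
        """cis- and trans-2-hexen-1-ol pair up before joining anything else."""
        tree = co.hcluster(co.build_space(ref_matrix))
        labels = tree.labels
        ia = labels.index("cis-2-hexen-1-ol")
        ib = labels.index("trans-2-hexen-1-ol")
        for left, right in tree.linkage[:, :2].astype(int):
            if ia in (left, right) or ib in (left, right):
                assert {left, right} == {ia, ib}
                break

    def test_non_finite_distances_rejected(self):
        x = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(InvalidParameterError):
            co.hcluster(x)

    def test_newick_export_contains_all_leaves(self):
        tree = co.hcluster(np.eye(4), labels=list("wxyz"))
        nwk = tree.to_newick()
        assert all(leaf in nwk for leaf in "wxyz")
        assert nwk.endswith(";")


class TestPCA:
    def test_full_decomposition_captures_everything(self):
        pca = co.pca_space(_random_matrix(10), n_components=6)
        assert np.isclose(pca.cumulative_variance, 1.0)
        assert np.isclose(pca.variance_explained.sum(), 1.0)
        # components orthogonal
        load = co.pca_space(_random_matrix(10), 6).loadings.values
        np.testing.assert_allclose(load.T @ load, np.eye(6), atol=1e-9)

    def test_rank_one_structure_loads_on_first_component(self):
        rng = np.random.default_rng(11)
        strength = rng.uniform(0, 200, 40)
        weights = rng.uniform(0.5, 1.5, 6)
        x = np.outer(strength, weights) + rng.normal(0, 1e-3, (40, 6))
        pca = co.pca_space(pd.DataFrame(x, columns=co.panel.SENSILLA), 1)
        assert pca.variance_explained[0] >= 0.99

    def test_scores_reproduce_standardized_distances(self):
        m = _random_matrix(12)
        pca = co.pca_space(m, n_components=6)
        x = m.mean.values
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(
            pdist(pca.scores.values), pdist(z), atol=1e-9
        )

    def test_constant_column_named_in_error(self):
        m = _random_matrix(13)
        m.mean["E1"] = 5.0
        with pytest.raises(DegenerateColumnError, match="E1"):
            co.pca_space(m)

    def test_too_few_odorants_rejected(self):
        with pytest.raises(InsufficientDataError):
            co.pca_space(_random_matrix(14, n=6))


class TestPhasicTonic:
    def test_constant_rate_is_perfectly_tonic(self):
        psth = co.PSTH(np.full(20, 7))
        result = co.phasic_tonic_index(psth)
        assert result.index == 1.0 and result.label == "tonic"

    def test_onset_burst_is_perfectly_phasic(self):
        counts = np.zeros(20, dtype=int)
        counts[0] = 50
        result = co.phasic_tonic_index(co.PSTH(counts))
        assert result.index == 0.0 and result.label == "phasic"

    def test_zero_peak_rejected(self):
        counts = np.zeros(20, dtype=int)
        counts[-1] = 5
        with pytest.raises(UndefinedIndexError):
            co.phasic_tonic_index(co.PSTH(counts))

    def test_phasic_kernel_scores_below_tonic_at_matched_peak(self):
        """Monte-Carlo ordering: exponential-onset vs sustained responses."""

        def index_for(kernel, seed):
            profile = co.ResponseProfile(
                "Dg", "x", baseline_rate=5.0, max_evoked_rate=150.0,
                kernel=kernel,
                phasic_decay_constant=0.15 if kernel == "phasic" else None,
                ec50_dose=-5.0,
            )
            train = co.gen_spike_train(profile, -2.0, 3.5, 1.0, seed=seed)
            return co.phasic_tonic_index(co.compute_psth(train, 1.0)).index

        phasic = [index_for("phasic", s) for s in range(60)]
        tonic = [index_for("tonic", s) for s in range(60)]
        assert np.mean(phasic) < np.mean(tonic)
        assert np.mean(tonic) > 0.5 > np.mean(phasic)


class TestTemporalCluster:
    def _psth(self, counts):
        return co.PSTH(np.asarray(counts, dtype=int))

    def test_identical_psths_merge_at_zero_height(self):
        p = self._psth(np.arange(20))
        tree = co.temporal_cluster([p, p])
        assert tree.heights[0] == 0.0

    def test_kernel_shapes_separate_at_k2(self):
        """Aldehyde-style panel: phasic and tonic time courses split."""
        rng = np.random.default_rng(21)
        phasic_shape = np.round(60 * np.exp(-np.arange(20) / 2.0))
        tonic_shape = np.full(20, 25.0)
        psths, labels, truth = [], [], {}
        for i, (name, kernel) in enumerate(
            [("propanal", "phasic"), ("butanal", "phasic"),
             ("decanal", "phasic"), ("pentanal", "tonic"),
             ("hexanal", "tonic"), ("heptanal", "tonic"),
             ("octanal", "tonic"), ("nonanal", "tonic")]
        ):
            shape = phasic_shape if kernel == "phasic" else tonic_shape
            jitter = rng.poisson(np.maximum(shape, 0.01))
            psths.append(self._psth(jitter))
            labels.append(name)
            truth[name] = kernel
        cut = co.temporal_cluster(psths, labels=labels).cut(2)
        groups = {
            kernel: {cut[n] for n in truth if truth[n] == kernel}
            for kernel in ("phasic", "tonic")
        }
        assert groups["phasic"].isdisjoint(groups["tonic"])
        assert len(groups["phasic"]) == len(groups["tonic"]) == 1

    def test_mismatched_binning_rejected(self):
        a = co.PSTH(np.zeros(20, dtype=int))
        b = co.PSTH(np.zeros(10, dtype=int), window=1.0)
        with pytest.raises(InvalidParameterError):
            co.temporal_cluster([a, b])
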