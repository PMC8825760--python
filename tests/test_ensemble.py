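import numpy as np
import pytest

from pseudoshaper.discrete import PseudotimeSet
from pseudoshaper.ensemble import (
    LoadingTable,
    aggregate,
    first_pc_pseudotime,
    pca_loadings,
    select_correlated,
)
from pseudoshaper.errors import DegenerateInputError, InvalidInputError


def make_set(matrix, k_values=None):
    matrix = np.asarray(matrix)
    if k_values is None:
        k_values = matrix.max(axis=0).astype(int) + 1
    return PseudotimeSet(
        matrix=matrix,
        k_values=np.asarray(k_values),
        kmin=int(np.min(k_values)),
        kmax=int(np.max(k_values)),
    )


def discretized_columns(latent, k_range, rng, noise=0.05):
    """Columns mimicking discrete pseudotimes from one latent ordering."""
    cols = []
    for k in k_range:
        jittered = latent + rng.normal(0, noise, latent.size)
        edges = np.linspace(jittered.min(), jittered.max(), k + 1)[1:-1]
        cols.append(np.digitize(jittered, edges))
    return np.column_stack(cols)


class TestPcaLoadings:
    def test_identical_columns_share_pc1(self):
        col = np.array([0, 1, 2, 3, 4])
        L = pca_loadings(make_set(np.column_stack([col, col]), [5, 5]))
        assert abs(L.pc1_loadings[0]) == pytest.approx(abs(L.pc1_loadings[1]))
        total = sum(L.explained_variance)
        assert L.explained_variance[0] / total == pytest.approx(1.0)

    def test_anticorrelated_columns_load_with_opposite_signs(self):
        col = np.arange(6.0)
        L = pca_loadings(make_set(np.column_stack([col, col[::-1]]), [6, 6]))
        assert abs(L.pc1_loadings[0]) == pytest.approx(abs(L.pc1_loadings[1]))
        assert L.pc1_loadings[0] * L.pc1_loadings[1] < 0

    def test_matches_explicit_correlation_eigendecomposition(self, rng):
        # independent oracle: eigh of the explicit 5x5 correlation matrix
        latent = np.linspace(0, 1, 120)
        M = discretized_columns(latent, range(4, 9), rng, noise=0.2).astype(float)
        P = make_set(M, list(range(4, 9)))
        L = pca_loadings(P)
        corr = np.corrcoef(M, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        for idx, got in ((-1, L.pc1_loadings), (-2, L.pc2_loadings)):
            expect = evecs[:, idx]
            if expect[np.argmax(np.abs(expect))] < 0:
                expect = -expect
            np.testing.assert_allclose(got, expect, atol=1e-8)
        assert L.explained_variance[0] == pytest.approx(evals[-1], abs=1e-8)

    def test_unit_norm_eigenvectors(self, rng):
        M = rng.integers(0, 5, size=(50, 4)).astype(float)
        L = pca_loadings(make_set(M, [5, 5, 5, 5]))
        assert np.linalg.norm(L.pc1_loadings) == pytest.approx(1.0)
        assert np.linalg.norm(L.pc2_loadings) == pytest.approx(1.0)

    def test_zero_variance_columns_are_dropped(self, rng):
        M = np.column_stack(
            [np.arange(10.0), np.full(10, 3.0), rng.normal(size=10)]
        )
        L = pca_loadings(make_set(M, [10, 4, 5]))
        assert L.columns.tolist() == [0, 2]

    def test_all_constant_columns_degenerate(self):
        M = np.ones((10, 3))
        with pytest.raises(DegenerateInputError):
            pca_loadings(make_set(M, [2, 3, 4]))


class TestSelectCorrelated:
    def _table(self, pc1, pc2):
        pc1, pc2 = np.asarray(pc1, float), np.asarray(pc2, float)
        return LoadingTable(
            pc1_loadings=pc1,
            pc2_loadings=pc2,
            explained_variance=(2.0, 1.0),
            columns=np.arange(pc1.size),
        )

    def test_componentwise_magnitude_comparison(self):
        sel = select_correlated(
            self._table([0.9, -0.85, 0.10], [0.10, 0.20, 0.95])
        )
        assert sel.tolist() == [0, 1]

    def test_equal_magnitudes_select_nothing(self):
        # strict inequality fails everywhere -> caller falls back to PC1
        sel = select_correlated(self._table([0.6, -0.6], [-0.6, 0.6]))
        assert sel.size == 0

    def test_mutually_correlated_block_is_selected_completely(self, rng):
        # PC2 is a unit vector: with only equally-correlated columns its
        # mass must fall on some of them, so complete selection of the
        # correlated block requires an uncorrelated column to absorb PC2
        latent = np.linspace(0, 1, 300)
        M = discretized_columns(latent, range(5, 14), rng, noise=0.05)
        corr = np.abs(np.corrcoef(M.astype(float), rowvar=False))
        assert corr[np.triu_indices(9, 1)].min() > 0.9  # block is mutual
        noise = rng.integers(0, 10, 300)
        P = make_set(
            np.column_stack([M, noise]).astype(float), list(range(5, 15))
        )
        sel = select_correlated(pca_loadings(P))
        assert sel.tolist() == list(range(9))

    def test_independent_noise_column_is_excluded(self):
        # 9 columns share a latent ordering, 1 is noise; over 200 draws the
        # noise column must be excluded almost always
        excluded = 0
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            latent = np.linspace(0, 1, 300)
            M = discretized_columns(latent, range(5, 14), rng).astype(float)
            noise = rng.integers(0, 10, 300).astype(float)
            P = make_set(np.column_stack([M, noise]), list(range(5, 15)))
            sel = select_correlated(pca_loadings(P))
            excluded += 9 not in sel
        assert excluded / 200 >= 0.95


class TestAggregate:
    def test_opposite_columns_align_and_average(self):
        M = np.column_stack([[0, 1, 2], [2, 1, 0]]).astype(float)
        P = make_set(M, [3, 3])
        L = pca_loadings(P)
        crude = aggregate(P, L, np.array([0, 1]))
        np.testing.assert_allclose(crude.values, [0.0, 0.5, 1.0], atol=1e-12)

    def test_single_column_is_minmax_scaled(self):
        M = np.column_stack([[0, 1, 2, 3], [0, 1, 2, 3]]).astype(float)
        P = make_set(M, [4, 4])
        L = pca_loadings(P)
        crude = aggregate(P, L, np.array([0]))
        np.testing.assert_allclose(crude.values, [0.0, 1 / 3, 2 / 3, 1.0])
        assert crude.n_selected == 1

    def test_ensemble_at_least_as_good_as_best_column(self, rng):
        # averaging 10 noisy monotone columns should not lose correlation
        latent = np.linspace(0, 1, 400)
        M = discretized_columns(latent, range(5, 15), rng, noise=0.08).astype(float)
        P = make_set(M, list(range(5, 15)))
        L = pca_loadings(P)
        crude = aggregate(P, L, select_correlated(L))
        ens = abs(np.corrcoef(crude.values, latent)[0, 1])
        best = max(
            abs(np.corrcoef(M[:, j], latent)[0, 1]) for j in range(M.shape[1])
        )
        assert ens >= best - 0.02

    def test_invariant_to_flipping_a_column_before_aggregation(self, rng):
        latent = np.linspace(0, 1, 200)
        M = discretized_columns(latent, range(4, 10), rng).astype(float)
        P = make_set(M, list(range(4, 10)))
        L = pca_loadings(P)
        a = aggregate(P, L, select_correlated(L)).values
        M2 = M.copy()
        M2[:, 2] = M2[:, 2].max() - M2[:, 2]
        P2 = make_set(M2, list(range(4, 10)))
        L2 = pca_loadings(P2)
        b = aggregate(P2, L2, select_correlated(L2)).values
        err = min(np.abs(a - b).max(), np.abs(a - (1 - b)).max())
        assert err < 1e-10

    def test_invariant_to_column_order(self, rng):
        latent = np.linspace(0, 1, 150)
        M = discretized_columns(latent, range(4, 10), rng).astype(float)
        perm = rng.permutation(6)
        P1 = make_set(M, list(range(4, 10)))
        P2 = make_set(M[:, perm], [list(range(4, 10))[i] for i in perm])
        a = aggregate(P1, pca_loadings(P1), select_correlated(pca_loadings(P1))).values
        b = aggregate(P2, pca_loadings(P2), select_correlated(pca_loadings(P2))).values
        err = min(np.abs(a - b).max(), np.abs(a - (1 - b)).max())
        assert err < 1e-10

    def test_bounded_in_unit_interval(self, rng):
        latent = np.linspace(0, 1, 100)
        M = discretized_columns(latent, range(3, 9), rng, noise=0.3).astype(float)
        P = make_set(M, list(range(3, 9)))
        L = pca_loadings(P)
        crude = aggregate(P, L, select_correlated(L))
        assert crude.values.min() >= 0.0 and crude.values.max() <= 1.0

    def test_empty_selection_rejected(self):
        M = np.column_stack([[0, 1, 2], [0, 2, 1]]).astype(float)
        P = make_set(M, [3, 3])
        with pytest.raises(InvalidInputError):
            aggregate(P, pca_loadings(P), np.array([], dtype=int))


class TestFirstPc:
    def test_identical_columns_recover_the_ordering(self):
        M = np.column_stack([[0, 1, 2]] * 3).astype(float)
        crude = first_pc_pseudotime(make_set(M, [3, 3, 3]))
        np.testing.assert_allclose(np.sort(crude.values), [0.0, 0.5, 1.0], atol=1e-12)

    def test_matches_explicit_eigendecomposition_scores(self, rng):
        latent = np.linspace(0, 1, 100)
        M = discretized_columns(latent, range(4, 9), rng).astype(float)
        crude = first_pc_pseudotime(make_set(M, list(range(4, 9))))
        Z = (M - M.mean(0)) / M.std(0, ddof=1)
        corr = np.corrcoef(M, rowvar=False)
        _, evecs = np.linalg.eigh(corr)
        scores = Z @ evecs[:, -1]
        scaled = (scores - scores.min()) / (scores.max() - scores.min())
        err = min(
            np.abs(crude.values - scaled).max(),
            np.abs(crude.values - (1 - scaled)).max(),
        )
        assert err < 1e-8

    def test_invariant_to_column_permutation(self, rng):
        latent = np.linspace(0, 1, 80)
        M = discretized_columns(latent, range(3, 8), rng).astype(float)
        perm = rng.permutation(5)
        a = first_pc_pseudotime(make_set(M, list(range(3, 8)))).values
        b = first_pc_pseudotime(
            make_set(M[:, perm], [list(range(3, 8))[i] for i in perm])
        ).values
        err = min(np.abs(a - b).max(), np.abs(a - (1 - b)).max())
        assert err < 1e-10
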