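"""Similarity, soft-threshold adjacency, topological overlap and
scale-free diagnostics."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_symmetric_adjacency
from coexatlas import (
    ExpressionMatrix,
    adjacency,
    build_network,
    connectivity,
    generate_atlas,
    power_sweep,
    scale_free_fit,
    similarity_matrix,
    tom,
)
from coexatlas.network import scale_free_fit_from_connectivity
from oracles import naive_tom


def _em(data):
    data = np.asarray(data, dtype=float)
    return ExpressionMatrix(
        "t",
        pd.DataFrame(
            data,
            index=[f"G{i}" for i in range(data.shape[0])],
            columns=[f"S{j}" for j in range(data.shape[1])],
        ),
    )


class TestSimilarity:
    def test_duplicated_row_gives_one(self):
        s = similarity_matrix(_em([[1, 2, 3, 4], [1, 2, 3, 4], [4, 1, 3, 2]]))
        assert s[0, 1] == pytest.approx(1.0)

    def test_negated_row_gives_one(self):
        s = similarity_matrix(_em([[1, 2, 3, 4], [-1, -2, -3, -4]]))
        assert s[0, 1] == pytest.approx(1.0)

    def test_matches_textbook_pearson(self, small_matrix):
        s = similarity_matrix(small_matrix)
        x = small_matrix.values
        for i in range(3):
            for j in range(3):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                r = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert s[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            similarity_matrix(_em([[1, 1, 1, 1], [1, 2, 3, 4]]))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            similarity_matrix(_em([[1, 2], [3, 1]]))


class TestAdjacency:
    def test_power_one_is_identity(self, rng):
        s = np.abs(np.corrcoef(rng.normal(size=(5, 10))))
        np.testing.assert_allclose(adjacency(s, 1), s)

    def test_known_power(self):
        s = np.array([[1.0, 0.8], [0.8, 1.0]])
        a = adjacency(s, 6)
        assert a[0, 1] == pytest.approx(0.262144, abs=1e-15)
        assert a[0, 0] == 1.0

    def test_invalid_beta(self):
        with pytest.raises(ValueError, match="beta"):
            adjacency(np.eye(2), 0)


class TestTom:
    def test_complete_graph_saturates(self):
        a = np.ones((3, 3))
        np.testing.assert_allclose(tom(a), np.ones((3, 3)))

    def test_empty_graph(self):
        omega = tom(np.eye(3))
        np.testing.assert_allclose(omega, np.eye(3))

    def test_three_node_hand_value(self):
        a = np.array([[1.0, 0.5, 0.4], [0.5, 1.0, 0.2], [0.4, 0.2, 1.0]])
        omega = tom(a)
        # omega_01 = (0.4*0.2 + 0.5) / (min(0.9, 0.7) + 1 - 0.5) = 0.58 / 1.2
        assert omega[0, 1] == pytest.approx(0.58 / 1.2, abs=1e-14)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_symmetric_adjacency(rng, 30)
        np.testing.assert_allclose(tom(a), naive_tom(a), atol=1e-12)

    def test_entries_in_unit_interval_and_symmetric(self, rng):
        for _ in range(5):
            a = random_symmetric_adjacency(rng, 25)
            omega = tom(a)
            assert omega.min() >= 0.0 and omega.max() <= 1.0
            np.testing.assert_allclose(omega, omega.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(omega), 1.0)

    def test_asymmetric_rejected(self):
        a = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            tom(a)

    def test_out_of_range_rejected(self):
        a = np.array([[1.0, 1.5], [1.5, 1.0]])
        with pytest.raises(ValueError, match="0, 1"):
            tom(a)


class TestScaleFree:
    def test_exact_power_law_histogram(self):
        # connectivities at 1, 2, 4, 8 with counts proportional to 1/k:
        # log p(k) vs log k is exactly linear with slope -1
        k = np.concatenate(
            [np.full(80, 1.0), np.full(40, 2.0), np.full(20, 4.0), np.full(10, 8.0)]
        )
        r2, mean_k = scale_free_fit_from_connectivity(k, n_bins=10)
        assert r2 < 0  # decreasing
        assert abs(r2) > 0.99
        assert mean_k == pytest.approx(k.mean())

    def test_regular_graph_flagged_undefined(self):
        a = np.full((6, 6), 0.5)
        np.fill_diagonal(a, 1.0)
        r2, mean_k = scale_free_fit(a)
        assert np.isnan(r2)
        assert mean_k == pytest.approx(2.5)

    def test_n_bins_validated(self):
        with pytest.raises(ValueError, match="n_bins"):
            scale_free_fit(np.eye(3), n_bins=3)


class TestConnectivityMonotonicity:
    def test_mean_connectivity_nonincreasing_in_power(self, rng):
        s = np.abs(np.corrcoef(rng.normal(size=(40, 30))))
        means = [connectivity(adjacency(s, b)).mean() for b in range(1, 21)]
        assert all(m1 - m2 >= -1e-12 for m1, m2 in zip(means, means[1:]))


class TestPowerSweep:
    def test_single_candidate(self, small_matrix):
        diag = power_sweep(small_matrix, powers=[6])
        assert diag.powers == [6]
        assert diag.chosen_power == 6

    def test_default_power_fixed_regardless_of_sweep(self, modular_spec):
        matrices, _ = generate_atlas(modular_spec)
        diag = power_sweep(matrices[0], powers=[1, 2, 6])
        assert diag.chosen_power == 6

    def test_soft_threshold_improves_scale_free_fit(self, modular_spec):
        # modular data plus background: powering down weak background
        # correlations moves the degree distribution toward a power law
        matrices, _ = generate_atlas(modular_spec)
        diag = power_sweep(matrices[0], powers=[1, 6])
        r2_1, r2_6 = diag.signed_r2
        assert abs(r2_6) > abs(r2_1)

    def test_mean_connectivity_nonincreasing(self, modular_spec):
        matrices, _ = generate_atlas(modular_spec)
        diag = power_sweep(matrices[0], powers=list(range(1, 11)))
        mk = diag.mean_connectivity
        assert all(a - b >= -1e-12 for a, b in zip(mk, mk[1:]))

    def test_strict_mode_picks_smallest_power_meeting_criterion(self, modular_spec):
        matrices, _ = generate_atlas(modular_spec)
        diag = power_sweep(matrices[0], powers=list(range(1, 13)), strict=True)
        r2_by_power = dict(zip(diag.powers, diag.signed_r2))
        chosen = diag.chosen_power
        if abs(r2_by_power[chosen]) >= 0.8:
            for p in diag.powers:
                if p < chosen:
                    assert abs(r2_by_power[p]) < 0.8


def test_build_network_assembles_consistent_matrices(small_matrix):
    net = build_network(small_matrix, beta=6)
    np.testing.assert_allclose(net.A, net.S**6)
    np.testing.assert_allclose(net.D, 1.0 - net.Omega)
    assert net.beta == 6
    assert net.gene_ids == small_matrix.gene_ids
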