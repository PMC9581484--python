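import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conspace.blueprint import ConnectivityBlueprint
from conspace.divergence import (
    DivergenceMap,
    bootstrap_divergence,
    corresponding_parcel_divergence,
    divergence_matrix,
    entropy_map,
    joint_divergence,
    min_divergence_map,
    parcellate_divergence,
    rescale_map,
    symmetric_kl,
    xor_divergence,
)
from conspace.io_formats import Parcellation
from conspace.phantom import make_synthetic_blueprints


def oracle_symmetric_kl(p, q, floor=1e-6):
    """Independent brute-force two-term evaluation (element loop)."""
    p = (np.asarray(p) + floor)
    p = p / p.sum()
    q = (np.asarray(q) + floor)
    q = q / q.sum()
    total = 0.0
    for k in range(len(p)):
        total += p[k] * np.log2(p[k] / q[k])
    for k in range(len(p)):
        total += q[k] * np.log2(q[k] / p[k])
    return total


def _bp(matrix, names=None):
    matrix = np.asarray(matrix, dtype=float)
    return ConnectivityBlueprint(
        matrix=matrix,
        tract_names=names or [f"t{k}" for k in range(matrix.shape[1])],
        normalized=True,
    )


def _dirichlet_rows(rng, n, t):
    return rng.dirichlet(np.ones(t), size=n)


class TestSymmetricKL:
    def test_identical_distributions_zero(self):
        assert symmetric_kl(np.array([0.5, 0.5]), np.array([0.5, 0.5])) == 0.0

    def test_hand_case_log2_3(self):
        d = symmetric_kl(np.array([0.75, 0.25]), np.array([0.25, 0.75]))
        assert d == pytest.approx(np.log2(3), abs=1e-3)

    def test_symmetry_random_rows(self, rng):
        for _ in range(20):
            p, q = _dirichlet_rows(rng, 2, 6)
            assert symmetric_kl(p, q) == pytest.approx(symmetric_kl(q, p))

    def test_equals_bruteforce_oracle(self, rng):
        for _ in range(200):
            t = int(rng.integers(2, 12))
            p, q = _dirichlet_rows(rng, 2, t)
            assert symmetric_kl(p, q) == pytest.approx(
                oracle_symmetric_kl(p, q), rel=1e-10
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            symmetric_kl(np.array([0.5, 0.5]), np.array([1 / 3] * 3))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            symmetric_kl(np.array([1.5, -0.5]), np.array([0.5, 0.5]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_nonneg_symmetric_identity_properties(self, seed):
        rng = np.random.default_rng(seed)
        p, q = _dirichlet_rows(rng, 2, 5)
        d = symmetric_kl(p, q)
        assert d >= 0
        assert d == pytest.approx(symmetric_kl(q, p), rel=1e-9, abs=1e-12)
        assert symmetric_kl(p, p) == pytest.approx(0.0, abs=1e-12)
        if not np.allclose(p, q):
            assert d > 0


class TestDivergenceMatrix:
    def test_equal_blueprints_zero_diagonal(self, rng):
        bp = _bp(_dirichlet_rows(rng, 5, 4))
        d = divergence_matrix(bp, bp)
        np.testing.assert_allclose(np.diag(d.values), 0.0, atol=1e-9)

    def test_matches_oracle_loop(self, rng):
        n = _bp(_dirichlet_rows(rng, 3, 5))
        a = _bp(_dirichlet_rows(rng, 4, 5))
        d = divergence_matrix(n, a)
        for i in range(3):
            for j in range(4):
                assert d.values[i, j] == pytest.approx(
                    oracle_symmetric_kl(n.matrix[i], a.matrix[j]), rel=1e-9,
                    abs=1e-12,
                )

    def test_argument_swap_transposes(self, rng):
        n = _bp(_dirichlet_rows(rng, 3, 4))
        a = _bp(_dirichlet_rows(rng, 6, 4))
        d1 = divergence_matrix(n, a)
        d2 = divergence_matrix(a, n)
        np.testing.assert_allclose(d1.values, d2.values.T, atol=1e-12)

    def test_tract_mismatch_rejected(self, rng):
        n = _bp(_dirichlet_rows(rng, 3, 4), names=["a", "b", "c", "d"])
        a = _bp(_dirichlet_rows(rng, 3, 4), names=["a", "b", "c", "e"])
        with pytest.raises(ValueError, match="tract"):
            divergence_matrix(n, a)

    def test_invalid_rows_masked(self, rng):
        m = _dirichlet_rows(rng, 4, 3)
        valid = np.array([True, False, True, True])
        m[1] = 0.0
        bp = ConnectivityBlueprint(
            matrix=m, tract_names=["a", "b", "c"], normalized=True,
            valid_rows=valid,
        )
        other = _bp(_dirichlet_rows(rng, 3, 3), names=["a", "b", "c"])
        d = divergence_matrix(bp, other)
        assert not d.row_valid[1]
        assert np.isfinite(d.values).all()


class TestMinDivergenceMap:
    def test_self_comparison_zero_map_identity_argmin(self, rng):
        rows = _dirichlet_rows(rng, 8, 5)  # distinct rows w.p. 1
        bp = _bp(rows)
        m = min_divergence_map(divergence_matrix(bp, bp))
        np.testing.assert_allclose(m.values, 0.0, atol=1e-9)
        np.testing.assert_array_equal(m.argmin, np.arange(8))

    def test_permutation_recovery(self, rng):
        rows = _dirichlet_rows(rng, 30, 6)
        perm = rng.permutation(30)
        n = _bp(rows)
        a = _bp(rows[perm])
        m = min_divergence_map(divergence_matrix(n, a))
        # vertex i of N matches position of i in the permuted copy
        inverse = np.empty(30, dtype=int)
        inverse[perm] = np.arange(30)
        np.testing.assert_array_equal(m.argmin, inverse[np.arange(30)])

    def test_hand_2x3_matrix(self):
        from conspace.divergence import DivergenceMatrix

        d = DivergenceMatrix(
            values=np.array([[3.0, 1.0, 2.0], [0.5, 4.0, 0.5]]),
            row_valid=np.array([True, True]),
            col_valid=np.array([True, True, True]),
            tract_names=["x"],
        )
        m = min_divergence_map(d)
        np.testing.assert_allclose(m.values, [1.0, 0.5])
        np.testing.assert_array_equal(m.argmin, [1, 0])  # tie breaks low

    def test_fully_masked_row_missing(self, rng):
        from conspace.divergence import DivergenceMatrix

        d = DivergenceMatrix(
            values=np.ones((2, 2)),
            row_valid=np.array([True, False]),
            col_valid=np.array([True, True]),
            tract_names=["x"],
        )
        m = min_divergence_map(d)
        assert np.isnan(m.values[1])
        assert m.argmin[1] == -1


class TestParcellation:
    def _parc(self, labels, exclusions=()):
        names = {int(i): f"p{i}" for i in np.unique(labels)}
        return Parcellation(labels=np.asarray(labels), names=names,
                            exclusions=frozenset(exclusions))

    def test_one_vertex_parcels_identity(self, rng):
        bp_a = _bp(_dirichlet_rows(rng, 4, 3))
        bp_b = _bp(_dirichlet_rows(rng, 4, 3))
        d = divergence_matrix(bp_a, bp_b)
        parc = self._parc(np.arange(4))
        out, row_ids, col_ids = parcellate_divergence(d, parc, parc)
        np.testing.assert_allclose(out, d.values)

    def test_single_parcel_global_median(self, rng):
        bp_a = _bp(_dirichlet_rows(rng, 5, 3))
        bp_b = _bp(_dirichlet_rows(rng, 7, 3))
        d = divergence_matrix(bp_a, bp_b)
        out, *_ = parcellate_divergence(
            d, self._parc(np.zeros(5, dtype=int)), self._parc(np.zeros(7, dtype=int))
        )
        assert out[0, 0] == pytest.approx(np.median(d.values))

    def test_random_20x20_vs_bruteforce_median(self, rng):
        bp_a = _bp(_dirichlet_rows(rng, 20, 4))
        bp_b = _bp(_dirichlet_rows(rng, 20, 4))
        d = divergence_matrix(bp_a, bp_b)
        labels_a = rng.integers(0, 4, size=20)
        labels_b = rng.integers(0, 4, size=20)
        pa, pb = self._parc(labels_a), self._parc(labels_b)
        out, row_ids, col_ids = parcellate_divergence(d, pa, pb)
        for pi, p in enumerate(row_ids):
            for qi, q in enumerate(col_ids):
                block = [
                    d.values[i, j]
                    for i in range(20)
                    for j in range(20)
                    if labels_a[i] == p and labels_b[j] == q
                ]
                if block:
                    assert out[pi, qi] == pytest.approx(np.median(block))

    def test_excluded_parcels_never_enter(self, rng):
        bp = _bp(_dirichlet_rows(rng, 6, 3))
        d = divergence_matrix(bp, bp)
        parc = self._parc([0, 0, 1, 1, 2, 2], exclusions={1})
        out, row_ids, col_ids = parcellate_divergence(d, parc, parc)
        assert row_ids == [0, 2]
        assert out.shape == (2, 2)

    def test_diagonal_requires_matching_schemes(self):
        with pytest.raises(ValueError, match="identical parcel schemes"):
            corresponding_parcel_divergence(np.ones((2, 2)), [0, 1], [0, 2])

    def test_corresponding_parcels_diagonal(self):
        m = np.array([[1.0, 9.0], [9.0, 2.0]])
        out = corresponding_parcel_divergence(m, [3, 5], [3, 5])
        assert out == {3: 1.0, 5: 2.0}


class TestMapAlgebra:
    def _m(self, vals, rescaled=True):
        return DivergenceMap(values=np.asarray(vals, dtype=float), rescaled=rescaled)

    def test_fuzzy_identities(self):
        b = self._m([1.0, 1.0, 0.5])
        c = self._m([1.0, 0.0, 0.5])
        j = joint_divergence(b, c)
        x = xor_divergence(b, c)
        np.testing.assert_allclose(j.values, [1.0, 0.0, 0.25])
        np.testing.assert_allclose(x.values, [0.0, 1.0, 0.5])

    def test_random_maps_match_printed_formulas(self, rng):
        bv = rng.random(50)
        cv = rng.random(50)
        j = joint_divergence(self._m(bv), self._m(cv))
        x = xor_divergence(self._m(bv), self._m(cv))
        np.testing.assert_allclose(j.values, bv * cv)
        np.testing.assert_allclose(x.values, bv + cv - 2 * bv * cv)
        assert (j.values >= 0).all() and (j.values <= 1).all()
        assert (x.values >= 0).all() and (x.values <= 1).all()

    def test_unrescaled_inputs_rejected(self):
        with pytest.raises(ValueError, match="rescale"):
            joint_divergence(self._m([0.5], rescaled=False), self._m([0.5]))
        with pytest.raises(ValueError, match="rescale"):
            xor_divergence(self._m([0.5]), self._m([0.5], rescaled=False))

    def test_rescale_map_minmax(self):
        m = DivergenceMap(values=np.array([1.0, 3.0, 2.0]))
        out = rescale_map(m)
        np.testing.assert_allclose(out.values, [0.0, 1.0, 0.5])
        assert out.rescaled


class TestEntropyMap:
    def test_uniform_row_log2_T(self):
        bp = _bp(np.full((1, 8), 1 / 8))
        assert entropy_map(bp).values[0] == pytest.approx(3.0)

    def test_one_hot_zero_bits(self):
        bp = _bp(np.array([[1.0, 0.0, 0.0]]))
        assert entropy_map(bp).values[0] == 0.0

    def test_hand_case_1p5_bits(self):
        bp = _bp(np.array([[0.5, 0.25, 0.25]]))
        assert entropy_map(bp).values[0] == pytest.approx(1.5)

    def test_invalid_rows_nan(self):
        m = np.array([[0.0, 0.0], [0.5, 0.5]])
        bp = ConnectivityBlueprint(matrix=m, tract_names=["a", "b"],
                                   normalized=True)
        out = entropy_map(bp)
        assert np.isnan(out.values[0])
        assert out.values[1] == pytest.approx(1.0)


class TestBootstrap:
    def _group(self, rng, n, vertices=10, tracts=4, shift=0.0, seed=0):
        data = make_synthetic_blueprints(
            vertices, tracts, n_groups=2, group_shift=shift,
            n_subjects=n, seed=seed,
        )
        names = [f"t{k}" for k in range(tracts)]
        return (
            [_bp(s, names) for s in data[0]],
            [_bp(s, names) for s in data[1]],
        )

    def test_identical_subjects_zero_variance(self, rng):
        a, _ = self._group(rng, 1)
        group = [a[0]] * 5
        mean, var = bootstrap_divergence(group, group, (3, 3), n_iter=10, seed=1)
        np.testing.assert_allclose(var.values, 0.0, atol=1e-12)

    def test_fixed_seed_bit_identical(self, rng):
        ga, gb = self._group(rng, 4, shift=0.2, seed=3)
        r1 = bootstrap_divergence(ga, gb, (3, 3), n_iter=5, seed=9)
        r2 = bootstrap_divergence(ga, gb, (3, 3), n_iter=5, seed=9)
        np.testing.assert_array_equal(r1[0].values, r2[0].values)
        np.testing.assert_array_equal(r1[1].values, r2[1].values)

    def test_shifted_groups_diverge_more(self, rng):
        ga0, gb0 = self._group(rng, 6, shift=0.0, seed=5)
        ga1, gb1 = self._group(rng, 6, shift=0.5, seed=5)
        m0, _ = bootstrap_divergence(ga0, gb0, (4, 4), n_iter=20, seed=2)
        m1, _ = bootstrap_divergence(ga1, gb1, (4, 4), n_iter=20, seed=2)
        assert m1.values.mean() > m0.values.mean()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            bootstrap_divergence([], [], (2, 2))


class TestMonotonicityInvariant:
    def test_mean_min_divergence_nondecreasing_in_shift(self):
        means = []
        for shift in (0.0, 0.2, 0.4):
            data = make_synthetic_blueprints(
                40, 8, n_groups=2, group_shift=shift, n_subjects=8, seed=21
            )
            names = [f"t{k}" for k in range(8)]
            ga = [_bp(s, names) for s in data[0]]
            gb = [_bp(s, names) for s in data[1]]
            from conspace.blueprint import average_blueprints

            d = divergence_matrix(average_blueprints(ga), average_blueprints(gb))
            means.append(np.nanmean(min_divergence_map(d).values))
        assert means[0] < means[1] < means[2]
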