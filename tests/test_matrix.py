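"""Matrix numerics: balancing, O/E, PC1, insulation, DI, MoC, ANOVA."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats

from carna.genome import GenomeAssembly, GenomicInterval, TADSet, Track
from carna.matrix import (
    SparseContactMatrix,
    compartment_pc1,
    cral_compartment_anova,
    de_novo_boundaries,
    delta_di,
    directionality_index,
    expected_by_distance,
    insulation_score,
    kr_balance,
    kr_balance_dense,
    moc,
    oe,
)

BS = 10_000


def one_chrom(n_bins):
    return GenomeAssembly.from_dict({"chr1": n_bins * BS})


def sym_matrix(dense, assembly=None):
    dense = np.asarray(dense, dtype=float)
    asm = assembly or one_chrom(dense.shape[0])
    return SparseContactMatrix(asm, BS, True, sp.csr_matrix(np.triu(dense)))


class TestKRBalance:
    def test_two_by_two_row_sums_equal(self):
        w = kr_balance_dense(np.array([[2.0, 1.0], [1.0, 2.0]]), mask_percentile=0)
        A = np.array([[2.0, 1.0], [1.0, 2.0]]) * np.outer(w, w)
        assert np.all(np.abs(A.sum(axis=1) - 1) < 1e-8)

    def test_doubly_balanced_fixed_point(self):
        # rows already sum to a constant: weights must be equal
        A = np.array([[0.5, 0.5], [0.5, 0.5]])
        w = kr_balance_dense(A, mask_percentile=0)
        assert np.allclose(w[0], w[1])

    def test_zero_row_masked_others_converge(self):
        A = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 0.0]])
        w = kr_balance_dense(A, mask_percentile=0)
        assert np.isnan(w[2]) and np.isfinite(w[:2]).all()
        sub = A[:2, :2] * np.outer(w[:2], w[:2])
        assert np.all(np.abs(sub.sum(axis=1) - 1) < 1e-8)

    def test_balanced_row_sums_on_random_matrix(self, rng):
        n = 50
        A = rng.gamma(2.0, 1.0, (n, n))
        A = np.triu(A) + np.triu(A, 1).T
        mat = sym_matrix(A)
        w = kr_balance(mat)
        good = np.isfinite(w)
        B = A[np.ix_(good, good)] * np.outer(w[good], w[good])
        assert np.all(np.abs(B.sum(axis=1) - 1) < 1e-8)


class TestExpectedOE:
    def test_pure_distance_function_gives_unit_oe(self):
        n = 30
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        mat = sym_matrix(100.0 / (1 + d))
        exp = expected_by_distance(mat, "chr1")
        assert np.allclose(exp, 100.0 / (1 + np.arange(n)))
        ratio = oe(mat).cis_dense("chr1")
        assert np.allclose(ratio, 1.0)

    def test_oe_missing_where_expected_zero(self):
        dense = np.zeros((10, 10))
        dense[0, 5] = dense[5, 0] = 4.0
        mat = sym_matrix(dense)
        r = oe(mat).cis_dense("chr1")
        # distance 5 has one populated pair; its expected is 4/(n-d)
        assert r[0, 5] > 0
        assert r[1, 2] == 0  # expected 0 at distance 1 -> entry absent


class TestCompartmentPC1:
    def _checkerboard(self, n=40, block=10, contrast=0.5, base=200.0):
        lab = (np.arange(n) // block) % 2 == 0
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        same = lab[:, None] == lab[None, :]
        dense = base / (1 + d) * np.where(same, 1 + contrast, 1 - contrast)
        return lab, sym_matrix(dense)

    def test_recovers_planted_blocks(self):
        lab, mat = self._checkerboard()
        orient = Track(mat.assembly, BS, np.where(lab, 1.0, 0.0))
        pc1 = compartment_pc1(mat, orient)
        v = pc1.values
        assert np.isfinite(v).all()
        assert np.array_equal(v > 0, lab)

    def test_sign_follows_orientation_track(self):
        lab, mat = self._checkerboard()
        orient = Track(mat.assembly, BS, np.where(lab, 1.0, 0.0))
        up = compartment_pc1(mat, orient).values
        orient_neg = Track(mat.assembly, BS, -orient.values)
        down = compartment_pc1(mat, orient_neg).values
        assert np.allclose(up, -down)

    def test_constant_matrix_all_missing(self):
        mat = sym_matrix(np.ones((20, 20)))
        orient = Track(mat.assembly, BS, np.arange(20, dtype=float))
        with pytest.warns(UserWarning):
            pc1 = compartment_pc1(mat, orient)
        assert np.isnan(pc1.values).all()


class TestInsulation:
    def test_uniform_matrix_scores_zero_inside(self):
        mat = sym_matrix(np.full((30, 30), 3.0))
        tr = insulation_score(mat, 5)
        v = tr.values
        assert np.allclose(v[5:25], 0.0)
        assert np.isnan(v[:5]).all() and np.isnan(v[25:]).all()

    def test_planted_boundary_is_local_minimum(self):
        n = 40
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        dense = 100.0 / (1 + d)
        dense[:20, 20:] *= 0.2  # depleted crossing square
        dense[20:, :20] *= 0.2
        tr = insulation_score(sym_matrix(dense), 5)
        v = tr.values
        interior = np.arange(5, 35)
        # windows of bins 19 and 20 both lie fully in the depleted cross
        assert interior[np.nanargmin(v[interior])] in (19, 20)

    def test_window_exceeding_chromosome_all_missing(self):
        mat = sym_matrix(np.ones((10, 10)))
        assert np.isnan(insulation_score(mat, 6).values).all()

    def test_scale_invariance(self, rng):
        A = rng.poisson(10, (30, 30)).astype(float)
        A = np.triu(A) + np.triu(A, 1).T
        t1 = insulation_score(sym_matrix(A), 4).values
        t2 = insulation_score(sym_matrix(7.3 * A), 4).values
        assert np.allclose(t1, t2, equal_nan=True)


class TestDirectionalityIndex:
    def test_symmetric_window_gives_zero(self):
        mat = sym_matrix(np.full((20, 20), 2.0))
        v = directionality_index(mat, 4).values
        assert np.allclose(v[4:16], 0.0)

    def test_known_value_a0_b10(self):
        # bin 1 with upstream sum 0 and downstream sum 10 -> DI = +10
        dense = np.zeros((4, 4))
        dense[1, 2] = 10.0
        dense[2, 1] = 10.0
        v = directionality_index(sym_matrix(dense), 1).values
        assert v[1] == pytest.approx(10.0)

    def test_matches_brute_force(self, rng):
        n, w = 25, 3
        A = rng.poisson(5, (n, n)).astype(float)
        A = np.triu(A) + np.triu(A, 1).T
        v = directionality_index(sym_matrix(A), w).values
        for i in range(w, n - w):
            a = sum(A[i, k] for k in range(i - w, i))
            b = sum(A[i, k] for k in range(i + 1, i + w + 1))
            if a == 0 and b == 0:
                expect = 0.0
            else:
                e = (a + b) / 2
                expect = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
            assert v[i] == pytest.approx(expect)

    def test_di_scales_with_matrix(self, rng):
        A = rng.poisson(8, (20, 20)).astype(float)
        A = np.triu(A) + np.triu(A, 1).T
        v1 = directionality_index(sym_matrix(A), 3).values
        v2 = directionality_index(sym_matrix(3 * A), 3).values
        assert np.allclose(v2, 3 * v1, equal_nan=True)

    def test_delta_di_zero_for_identical_tracks(self, rng):
        A = rng.poisson(8, (20, 20)).astype(float)
        A = np.triu(A) + np.triu(A, 1).T
        t = directionality_index(sym_matrix(A), 3)
        for pos in (50_000, 105_000, 120_000):
            assert delta_di(t, t, "chr1", pos) == 0.0


class TestDeNovoBoundaries:
    def _tads(self, edges):
        return TADSet(
            [
                GenomicInterval("chr1", a, b)
                for a, b in zip(edges[:-1], edges[1:])
            ]
        )

    def test_identical_sets_give_none(self):
        t = self._tads([0, 100_000, 200_000, 300_000])
        assert de_novo_boundaries(t, t, tol_bp=BS) == []

    def test_extra_internal_boundary_detected(self):
        wt = self._tads([0, 200_000, 400_000])
        ki = self._tads([0, 100_000, 200_000, 400_000])
        assert de_novo_boundaries(wt, ki, tol_bp=BS) == [("chr1", 100_000)]

    def test_offset_exactly_at_tolerance_is_matched(self):
        wt = self._tads([0, 200_000, 400_000])
        ki = self._tads([0, 210_000, 400_000])
        assert de_novo_boundaries(wt, ki, tol_bp=10_000) == []
        assert de_novo_boundaries(wt, ki, tol_bp=9_999) == [("chr1", 210_000)]


class TestMoC:
    def _partition(self, edges, chrom="chr1"):
        return TADSet(
            [GenomicInterval(chrom, a, b) for a, b in zip(edges[:-1], edges[1:])]
        )

    def test_identical_partitions_score_one(self):
        t = self._partition([0, 30, 70, 100])
        r = moc(t, t)
        assert r.moc == pytest.approx(1.0)

    def test_single_vs_double_split_scores_zero(self):
        a = self._partition([0, 100])
        b = self._partition([0, 50, 100])
        assert moc(a, b).moc == pytest.approx(0.0, abs=1e-12)

    def test_both_single_domain_defined_as_one(self):
        a = self._partition([10, 90])
        b = self._partition([0, 100])
        assert moc(a, b).moc == 1.0

    def test_symmetric_and_bounded_on_random_partitions(self, rng):
        for _ in range(100):
            cuts_a = np.sort(rng.choice(np.arange(1, 100), rng.integers(1, 8), replace=False))
            cuts_b = np.sort(rng.choice(np.arange(1, 100), rng.integers(1, 8), replace=False))
            a = self._partition([0, *cuts_a.tolist(), 100])
            b = self._partition([0, *cuts_b.tolist(), 100])
            m1, m2 = moc(a, b).moc, moc(b, a).moc
            assert m1 == pytest.approx(m2)
            assert 0.0 <= m1 <= 1.0

    def test_matches_brute_force_overlap_sum(self, rng):
        a = self._partition([0, 20, 55, 100])
        b = self._partition([0, 40, 100])
        total = 0.0
        for ai in a.domains():
            for bj in b.domains():
                ov = max(0, min(ai.end, bj.end) - max(ai.start, bj.start))
                total += ov**2 / (len(ai) * len(bj))
        expect = (total - 1) / (np.sqrt(3 * 2) - 1)
        assert moc(a, b).moc == pytest.approx(expect)

    def test_empty_set_rejected(self):
        t = self._partition([0, 100])
        with pytest.raises(ValueError):
            moc(t, TADSet([]))


class TestCralCompartmentAnova:
    def _tracks(self, cral_vals, pc1_vals):
        asm = one_chrom(len(cral_vals))
        return (
            Track(asm, BS, np.asarray(cral_vals, dtype=float)),
            Track(asm, BS, np.asarray(pc1_vals, dtype=float)),
        )

    def test_equal_groups_give_zero_f(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        cral, pc1 = self._tracks(vals, [1, 1, 1, -1, -1, -1])
        r = cral_compartment_anova(cral, pc1)
        assert r.f_stat == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_planted_two_sigma_shift_detected(self, rng):
        a = rng.normal(2.0, 1.0, 500)
        b = rng.normal(0.0, 1.0, 500)
        cral, pc1 = self._tracks(
            np.concatenate([a, b]), np.concatenate([np.ones(500), -np.ones(500)])
        )
        r = cral_compartment_anova(cral, pc1)
        assert r.p_value < 1e-10
        assert r.mean_a > r.mean_b

    def test_f_equals_squared_t(self, rng):
        a = rng.normal(1.0, 1.0, 40)
        b = rng.normal(0.5, 1.2, 60)
        cral, pc1 = self._tracks(
            np.concatenate([a, b]), np.concatenate([np.ones(40), -np.ones(60)])
        )
        r = cral_compartment_anova(cral, pc1)
        t, _ = stats.ttest_ind(a, b)
        assert r.f_stat == pytest.approx(t**2)

    def test_tiny_group_rejected(self):
        cral, pc1 = self._tracks([1.0, 2.0, 3.0], [1, 1, -1])
        with pytest.raises(ValueError):
            cral_compartment_anova(cral, pc1)
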