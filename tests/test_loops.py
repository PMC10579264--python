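"""Loop union/reassignment, APA metrics, CBS classes, delta-peak."""

import numpy as np
import pytest
import scipy.sparse as sp

from carna.genome import GenomeAssembly, GenomicInterval, Loop
from carna.loops import (
    LoopSet,
    apa,
    classify_cbs,
    delta_peak,
    p2m_compare,
    reassign,
    union_loops,
)
from carna.matrix import SparseContactMatrix

BS = 10_000


def loop(chrom, s1, s2, res=10_000):
    return Loop(
        GenomicInterval(chrom, s1, s1 + res),
        GenomicInterval(chrom, s2, s2 + res),
        res,
    )


def asm_for(n_bins):
    return GenomeAssembly.from_dict({"chr1": n_bins * BS})


def matrix_from_dense(dense, asm=None):
    dense = np.asarray(dense, dtype=float)
    asm = asm or asm_for(dense.shape[0])
    return SparseContactMatrix(asm, BS, True, sp.csr_matrix(np.triu(dense)))


class TestUnionReassign:
    def test_one_bin_shift_merges(self):
        a = LoopSet([loop("chr1", 100_000, 600_000)], "A")
        b = LoopSet([loop("chr1", 110_000, 610_000)], "B")
        union = union_loops([a, b])
        assert len(union) == 1
        assert union.loops[0].conditions == frozenset({"A", "B"})

    def test_unique_loop_single_membership(self):
        a = LoopSet([loop("chr1", 100_000, 600_000)], "FL")
        b = LoopSet([loop("chr1", 2_000_000, 2_600_000)], "Ctrl")
        union = union_loops([a, b])
        assert len(union) == 2
        assert reassign(union, a).tolist() == [True, False]

    def test_idempotent(self, rng):
        sets = []
        for cond in ("A", "B"):
            loops = [
                loop("chr1", int(s), int(s) + int(d))
                for s, d in zip(
                    rng.integers(0, 5_000_000, 30), rng.integers(200_000, 900_000, 30)
                )
            ]
            sets.append(LoopSet(loops, cond))
        u1 = union_loops(sets)
        u2 = union_loops([u1])
        assert [l.key() for l in u1] == [l.key() for l in u2]

    def test_every_union_loop_belongs_somewhere(self, rng):
        sets = []
        for cond in ("A", "B", "C"):
            loops = [
                loop("chr1", int(s), int(s) + 500_000)
                for s in rng.integers(0, 5_000_000, 20)
            ]
            sets.append(LoopSet(loops, cond))
        union = union_loops(sets)
        member = np.column_stack([reassign(union, s) for s in sets])
        assert (member.sum(axis=1) >= 1).all()


class TestApa:
    def test_uniform_window_gives_unit_metrics(self):
        n = 200
        mat = matrix_from_dense(np.ones((n, n)))
        lp = loop("chr1", 50 * BS, 150 * BS)
        res = apa(mat, [lp])
        assert res.p2ll == pytest.approx(1.0)
        assert res.p2m == pytest.approx(1.0)
        assert np.isnan(res.zscore_ll)  # sd of uniform corner is 0

    def test_single_loop_aggregate_equals_window(self, rng):
        n = 200
        dense = rng.gamma(2.0, 1.0, (n, n))
        dense = np.triu(dense) + np.triu(dense, 1).T
        mat = matrix_from_dense(dense)
        lp = loop("chr1", 40 * BS, 160 * BS)
        res = apa(mat, [lp])
        i, j = 40, 160
        expect = mat.cis_dense("chr1")[i - 10 : i + 11, j - 10 : j + 11]
        assert np.allclose(res.window, expect)

    def test_near_diagonal_loop_excluded(self):
        n = 200
        mat = matrix_from_dense(np.ones((n, n)))
        lp = loop("chr1", 50 * BS, 70 * BS)  # 20 bins < 3*(2R+1)
        res = apa(mat, [lp])
        assert res.n_excluded == 1 and len(res.used) == 0

    def test_window_off_edge_excluded(self):
        mat = matrix_from_dense(np.ones((100, 100)))
        lp = loop("chr1", 5 * BS, 95 * BS)
        res = apa(mat, [lp])
        assert res.n_excluded == 1

    def test_planted_enrichment_recovered(self):
        n = 300
        dense = np.ones((n, n))
        pixels = [(50, 150), (80, 220), (120, 260)]
        for i, j in pixels:
            dense[i, j] = dense[j, i] = 5.0
        mat = matrix_from_dense(dense)
        loops = [loop("chr1", i * BS, j * BS) for i, j in pixels]
        res = apa(mat, loops)
        assert res.p2ll == pytest.approx(5.0)
        assert len(res.used) == 3


class TestClassifyCbs:
    A1 = GenomicInterval("chr1", 100_000, 110_000)
    A2 = GenomicInterval("chr1", 600_000, 610_000)

    def _classify(self, sites):
        lp = Loop(self.A1, self.A2, 10_000)
        return classify_cbs([lp], sites)[0]

    def test_facing_motifs_convergent(self):
        sites = [(GenomicInterval("chr1", 105_000, 105_020), "+"),
                 (GenomicInterval("chr1", 605_000, 605_020), "-")]
        assert self._classify(sites) == "convergent"

    def test_diverging_motifs_non_convergent(self):
        sites = [(GenomicInterval("chr1", 105_000, 105_020), "-"),
                 (GenomicInterval("chr1", 605_000, 605_020), "+")]
        assert self._classify(sites) == "non-convergent"

    def test_missing_site_means_none(self):
        sites = [(GenomicInterval("chr1", 105_000, 105_020), "+")]
        assert self._classify(sites) == "none"

    def test_both_orientations_favour_convergent(self):
        sites = [
            (GenomicInterval("chr1", 105_000, 105_020), "+"),
            (GenomicInterval("chr1", 106_000, 106_020), "-"),
            (GenomicInterval("chr1", 605_000, 605_020), "-"),
        ]
        assert self._classify(sites) == "convergent"

    def test_mirror_reflection_preserves_class(self):
        # reflect coordinates: anchor order and motif orientations flip
        L = 1_000_000
        lp = Loop(self.A1, self.A2, 10_000)
        sites = [(GenomicInterval("chr1", 105_000, 105_020), "+"),
                 (GenomicInterval("chr1", 605_000, 605_020), "-")]
        ref_lp = Loop(
            GenomicInterval("chr1", L - self.A2.end, L - self.A2.start),
            GenomicInterval("chr1", L - self.A1.end, L - self.A1.start),
            10_000,
        )
        ref_sites = [
            (GenomicInterval("chr1", L - iv.end, L - iv.start),
             "+" if s == "-" else "-")
            for iv, s in sites
        ]
        assert classify_cbs([lp], sites) == classify_cbs([ref_lp], ref_sites)


class TestComparisons:
    def test_identical_matrices_p2m_p_one(self, rng):
        n = 400
        dense = rng.gamma(2.0, 1.0, (n, n))
        dense = np.triu(dense) + np.triu(dense, 1).T
        mat = matrix_from_dense(dense)
        loops = [loop("chr1", int(i) * BS, int(i + 120) * BS) for i in range(20, 260, 12)]
        pa, pb, stat, p = p2m_compare(mat, mat, loops)
        assert p == pytest.approx(1.0)
        assert np.array_equal(pa, pb)

    def test_boosted_pixels_detected(self, rng):
        n = 400
        base = rng.gamma(4.0, 1.0, (n, n))
        base = np.triu(base) + np.triu(base, 1).T
        loops = [loop("chr1", int(i) * BS, int(i + 120) * BS) for i in range(20, 260, 4)]
        boosted = base.copy()
        for lp in loops:
            i, j = lp.anchor1.start // BS, lp.anchor2.start // BS
            boosted[i, j] = boosted[j, i] = boosted[i, j] * 4
        _, _, _, p = p2m_compare(
            matrix_from_dense(base), matrix_from_dense(boosted), loops
        )
        assert p < 1e-6

    def test_delta_peak_thresholds(self):
        n = 200
        ctrl = np.ones((n, n))
        ko = ctrl.copy()
        loops = [
            loop("chr1", 20 * BS, 120 * BS),
            loop("chr1", 40 * BS, 140 * BS),
            loop("chr1", 60 * BS, 160 * BS),
        ]
        total = np.triu(ctrl).sum()
        # deltas of +0.06, +0.04 and 0 CPM units
        ko[20, 120] += 0.06 * total / 1e6
        ko[40, 140] += 0.04 * total / 1e6
        flags = delta_peak(
            matrix_from_dense(ctrl), matrix_from_dense(ko), loops, threshold=0.05
        )
        assert flags == ["increased", "unchanged", "unchanged"]

    def test_delta_peak_identical_matrices_all_unchanged(self, rng):
        dense = rng.poisson(5, (100, 100)).astype(float)
        mat = matrix_from_dense(np.triu(dense) + np.triu(dense, 1).T)
        loops = [loop("chr1", 10 * BS, 80 * BS)]
        assert delta_peak(mat, mat, loops) == ["unchanged"]
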