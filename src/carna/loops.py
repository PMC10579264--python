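"""Chromatin-loop set algebra and aggregate peak analysis (APA).

Loop lists called per condition are merged into a union of unique loops
and re-assigned back to each condition by anchor proximity.  Loop
strength is measured APA-style on observed/expected matrices: P2LL
(peak over lower-left corner box), ZscoreLL, and P2M (peak over window
mean).  CTCF binding-site (CBS) orientation classes and the KO-vs-
control delta-peak rule complete the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genome import GenomicInterval, Loop
from .matrix import SparseContactMatrix

__all__ = [
    "LoopSet",
    "ApaResult",
    "union_loops",
    "reassign",
    "apa",
    "classify_cbs",
    "p2m_compare",
    "delta_peak",
]


@dataclass
class LoopSet:
    loops: list[Loop]
    condition: str = "union"

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for lp in self.loops:
            if lp.key() not in seen:
                seen.add(lp.key())
                deduped.append(lp)
        self.loops = deduped

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)

    @property
    def resolutions(self) -> set[int]:
        return {lp.resolution for lp in self.loops}


def _anchors_match(a: GenomicInterval, b: GenomicInterval, s: int) -> bool:
    return a.chrom == b.chrom and a.start >= b.start - s and a.end <= b.end + s


def _loop_matches(candidate: Loop, reference: Loop, s: int) -> bool:
    return _anchors_match(candidate.anchor1, reference.anchor1, s) and _anchors_match(
        candidate.anchor2, reference.anchor2, s
    )


def union_loops(loop_sets: Iterable[LoopSet]) -> LoopSet:
    """Merge per-condition loops into unique union loops.

    A candidate loop is merged into an existing union loop when both of
    its anchors fall within the +/- s flanks of the union loop's anchors
    (s = the union loop's anchor size); its condition labels are added
    to that loop's membership.  The operation is idempotent.
    """
    union: list[Loop] = []
    for ls in loop_sets:
        for lp in ls:
            merged = False
            for i, u in enumerate(union):
                if _loop_matches(lp, u, u.resolution):
                    union[i] = Loop(
                        u.anchor1, u.anchor2, u.resolution,
                        u.conditions | lp.conditions | frozenset([ls.condition]),
                    )
                    merged = True
                    break
            if not merged:
                union.append(
                    Loop(
                        lp.anchor1, lp.anchor2, lp.resolution,
                        lp.conditions | frozenset([ls.condition]),
                    )
                )
    return LoopSet(union, condition="union")


def reassign(union: LoopSet, loop_set_j: LoopSet) -> np.ndarray:
    """Membership of each union loop in condition j.

    A union loop i with anchor size s belongs to sample j iff both of
    its anchors lie within the +/- s flanks of some loop of j.
    """
    flags = np.zeros(len(union), dtype=bool)
    for i, u in enumerate(union):
        s = u.resolution
        for lp in loop_set_j:
            if _loop_matches(u, lp, s):
                flags[i] = True
                break
    return flags


# ---------------------------------------------------------------------------
# APA


@dataclass
class ApaResult:
    window: np.ndarray  # (2R+1, 2R+1) aggregate mean
    p2ll: float
    zscore_ll: float
    p2m: float
    per_loop_p2m: np.ndarray
    per_loop_p2ll: np.ndarray
    used: list[int] = field(default_factory=list)  # indices into the input
    n_excluded: int = 0


def _loop_pixel(loop: Loop, matrix: SparseContactMatrix) -> tuple[int, int]:
    bs = matrix.bin_size
    i = ((loop.anchor1.start + loop.anchor1.end) // 2) // bs
    j = ((loop.anchor2.start + loop.anchor2.end) // 2) // bs
    return i, j


def apa(
    matrix: SparseContactMatrix,
    loops: Sequence[Loop],
    R_bins: int = 10,
    corner: int = 6,
) -> ApaResult:
    """Aggregate peak analysis on an O/E-normalised symmetric matrix.

    Each loop contributes the (2R+1) x (2R+1) O/E window centered on
    its pixel, rows following anchor1 downward and columns anchor2
    rightward.  Loops closer than 3*(2R+1) bins to the diagonal, or
    whose window leaves the matrix, are excluded and counted.  P2LL
    compares the aggregate center pixel to the mean of the
    ``corner`` x ``corner`` lower-left box; P2M to the whole-window
    mean.
    """
    W = 2 * R_bins + 1
    dense_cache: dict[str, np.ndarray] = {}
    windows = []
    used = []
    p2m_per = []
    p2ll_per = []
    excluded = 0
    for k, lp in enumerate(loops):
        chrom = lp.chrom
        if chrom not in dense_cache:
            dense_cache[chrom] = matrix.cis_dense(chrom)
        D = dense_cache[chrom]
        i, j = _loop_pixel(lp, matrix)
        if abs(j - i) < 3 * W:
            excluded += 1
            continue
        if i - R_bins < 0 or j - R_bins < 0 or i + R_bins >= D.shape[0] or j + R_bins >= D.shape[0]:
            excluded += 1
            continue
        win = D[i - R_bins : i + R_bins + 1, j - R_bins : j + R_bins + 1]
        windows.append(win)
        used.append(k)
        center = win[R_bins, R_bins]
        ll = win[-corner:, :corner]
        p2m_per.append(center / win.mean() if win.mean() > 0 else np.nan)
        p2ll_per.append(center / ll.mean() if ll.mean() > 0 else np.nan)
    if not windows:
        return ApaResult(
            np.full((W, W), np.nan), np.nan, np.nan, np.nan,
            np.array([]), np.array([]), [], excluded,
        )
    agg = np.mean(windows, axis=0)
    center = agg[R_bins, R_bins]
    ll = agg[-corner:, :corner]
    p2ll = center / ll.mean() if ll.mean() > 0 else np.nan
    zll = (center - ll.mean()) / ll.std() if ll.std() > 0 else np.nan
    p2m = center / agg.mean() if agg.mean() > 0 else np.nan
    return ApaResult(
        agg, float(p2ll), float(zll), float(p2m),
        np.array(p2m_per), np.array(p2ll_per), used, excluded,
    )


# ---------------------------------------------------------------------------
# CBS classes


def classify_cbs(
    loops: Sequence[Loop],
    ctcf_sites: Sequence[tuple[GenomicInterval, str]],
) -> list[str]:
    """CTCF-orientation class per loop: convergent / non-convergent / none.

    A loop is convergent iff anchor1 contains a '+' motif and anchor2 a
    '-' motif (motifs facing each other); 'none' iff either anchor
    contains no site; non-convergent otherwise.  Anchors holding both
    orientations count as having both, so convergence takes precedence.
    """
    out = []
    for lp in loops:
        s1 = {s for iv, s in ctcf_sites if iv.overlaps(lp.anchor1)}
        s2 = {s for iv, s in ctcf_sites if iv.overlaps(lp.anchor2)}
        if not s1 or not s2:
            out.append("none")
        elif "+" in s1 and "-" in s2:
            out.append("convergent")
        else:
            out.append("non-convergent")
    return out


# ---------------------------------------------------------------------------
# Condition comparisons


def p2m_compare(
    matrix_a: SparseContactMatrix,
    matrix_b: SparseContactMatrix,
    union: Sequence[Loop],
    R_bins: int = 10,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-loop P2M in two conditions with a paired Wilcoxon test.

    Returns (p2m_a, p2m_b, statistic, p) over the loops usable in both
    matrices.
    """
    res_a = apa(matrix_a, union, R_bins=R_bins)
    res_b = apa(matrix_b, union, R_bins=R_bins)
    shared = sorted(set(res_a.used) & set(res_b.used))
    if len(shared) < 10:
        warnings.warn("fewer than 10 shared loops in P2M comparison")
    ia = {k: n for n, k in enumerate(res_a.used)}
    ib = {k: n for n, k in enumerate(res_b.used)}
    pa = np.array([res_a.per_loop_p2m[ia[k]] for k in shared])
    pb = np.array([res_b.per_loop_p2m[ib[k]] for k in shared])
    ok = np.isfinite(pa) & np.isfinite(pb)
    pa, pb = pa[ok], pb[ok]
    diffs = pb - pa
    if len(diffs) == 0 or np.all(diffs == 0):
        return pa, pb, 0.0, 1.0
    stat, p = stats.wilcoxon(pa, pb, alternative="two-sided")
    return pa, pb, float(stat), float(p)


def delta_peak(
    matrix_ctrl: SparseContactMatrix,
    matrix_ko: SparseContactMatrix,
    loops: Sequence[Loop],
    threshold: float = 0.05,
) -> list[str]:
    """Flag loops by the change of their depth-normalised pixel count.

    Per sample, a loop's peak is its pixel count divided by the total
    read-pair count, scaled to counts per million.  Loops with
    KO - control >= threshold are "increased", <= -threshold
    "decreased", otherwise "unchanged".
    """
    totals = (matrix_ctrl.mass, matrix_ko.mass)
    if min(totals) <= 0:
        raise ValueError("delta_peak needs non-empty matrices")
    dense_c: dict[str, np.ndarray] = {}
    dense_k: dict[str, np.ndarray] = {}
    flags = []
    for lp in loops:
        chrom = lp.chrom
        if chrom not in dense_c:
            dense_c[chrom] = matrix_ctrl.cis_dense(chrom)
            dense_k[chrom] = matrix_ko.cis_dense(chrom)
        i, j = _loop_pixel(lp, matrix_ctrl)
        peak_c = dense_c[chrom][i, j] / totals[0] * 1e6
        peak_k = dense_k[chrom][i, j] / totals[1] * 1e6
        delta = peak_k - peak_c
        if delta >= threshold:
            flags.append("increased")
        elif delta <= -threshold:
            flags.append("decreased")
        else:
            flags.append("unchanged")
    return flags
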