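"""Between-anchor caRNA quantification and ranked-loop enrichment.

The ITA ratio (Inside-loop To Anchor) compares the per-bp caRNA
DNA-end density strictly between a loop's anchors with the density on
the anchors themselves; ranking union loops by ITA and walking a
GSEA-style running sum over one condition's loop membership tests
whether strong loops avoid caRNA-rich interiors.  Target-crossing
selection (e.g. HERV-H caRNA under a loop) and the associated
contingency enrichments reuse :func:`carna.boundary.contingency_test`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boundary import ContingencyTable2x2, EnrichmentResult, contingency_test
from .contacts import PairSet
from .genome import GenomicInterval, Loop
from .ral import rna_in_intervals

__all__ = [
    "ItaAnnotation",
    "GseaCurve",
    "ita_ratio",
    "rank_loops_by_ita",
    "gsea_rank_test",
    "target_crossing_filter",
    "crossing_enrichment",
    "chri_cbs_enrichment",
]


@dataclass(frozen=True)
class ItaAnnotation:
    anchor_density: float  # DNA ends per bp over both anchors
    between_density: float  # DNA ends per bp strictly between anchors
    ita: float

    def __post_init__(self) -> None:
        if self.anchor_density < 0 or self.between_density < 0 or self.ita < 0:
            raise ValueError("densities and ITA must be non-negative")


def between_region(loop: Loop) -> GenomicInterval:
    if loop.anchor1.end >= loop.anchor2.start:
        raise ValueError(
            f"loop {loop.chrom}:{loop.anchor1.start}-{loop.anchor2.end} has "
            "adjacent anchors: no between-anchor region"
        )
    return GenomicInterval(loop.chrom, loop.anchor1.end, loop.anchor2.start)


def ita_ratio(pairs: PairSet, loop: Loop, pseudocount: float = 1.0) -> ItaAnnotation:
    """Between-anchor over anchor caRNA density for one loop.

    Densities are DNA-end counts per bp with ``pseudocount`` reads
    added to each region, so zero-coverage loops stay finite.
    """
    between = between_region(loop)
    n_anchor = int(pairs.dna_in(loop.anchor1).sum() + pairs.dna_in(loop.anchor2).sum())
    n_between = int(pairs.dna_in(between).sum())
    anchor_bp = len(loop.anchor1) + len(loop.anchor2)
    anchor_density = (n_anchor + pseudocount) / anchor_bp
    between_density = (n_between + pseudocount) / len(between)
    return ItaAnnotation(
        anchor_density=anchor_density,
        between_density=between_density,
        ita=between_density / anchor_density,
    )


def rank_loops_by_ita(
    loops: Sequence[Loop], itas: Sequence[float], member_flags: Sequence[bool]
) -> tuple[list[Loop], np.ndarray]:
    """Sort loops by increasing ITA; ties broken by genomic position."""
    order = sorted(
        range(len(loops)), key=lambda i: (itas[i],) + loops[i].key()
    )
    ranked = [loops[i] for i in order]
    flags = np.asarray(member_flags, dtype=bool)[order]
    return ranked, flags


@dataclass
class GseaCurve:
    """Unweighted GSEA running sum over a ranked membership vector.

    ``es[k]`` is the running score after the k-th ranked loop
    (es[0] = es[N] = 0); the permutation p-value tests max |ES|.
    """

    es: np.ndarray
    max_es: float
    min_es: float
    max_abs_es: float
    arg_max: int
    p_value: float
    n_perm: int
    seed: int


def _running_sum(flags: np.ndarray) -> np.ndarray:
    n = len(flags)
    nh = int(flags.sum())
    steps = np.where(flags, 1.0 / nh, -1.0 / (n - nh))
    return np.concatenate([[0.0], np.cumsum(steps)])


def gsea_rank_test(
    member_flags: Sequence[bool], n_perm: int = 1000, seed: int = 0
) -> GseaCurve:
    """Classic unweighted enrichment score over a ranked list.

    Member hits add 1/Nh and misses subtract 1/(N-Nh), so the running
    sum starts and ends at zero.  The p-value is a label-permutation
    test (seeded) on max |ES|.
    """
    flags = np.asarray(member_flags, dtype=bool)
    n = len(flags)
    nh = int(flags.sum())
    if nh == 0 or nh == n:
        raise ValueError("membership must be a proper non-empty subset")
    es = _running_sum(flags)
    max_abs = float(np.max(np.abs(es)))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(flags)
        if np.max(np.abs(_running_sum(perm))) >= max_abs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return GseaCurve(
        es=es,
        max_es=float(es.max()),
        min_es=float(es.min()),
        max_abs_es=max_abs,
        arg_max=int(np.argmax(np.abs(es))),
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def target_crossing_filter(
    pairs: PairSet,
    rna_source: Sequence[GenomicInterval],
    loops: Sequence[Loop],
    min_pairs: int = 2,
) -> np.ndarray:
    """Flag loops strided by caRNA from ``rna_source``.

    A loop is target-crossing iff at least ``min_pairs`` pairs have
    their RNA end in the source intervals and their DNA end strictly
    between the loop's anchors.
    """
    src_mask = rna_in_intervals(pairs, rna_source)
    sub = pairs.subset(src_mask)
    flags = np.zeros(len(loops), dtype=bool)
    for i, lp in enumerate(loops):
        if lp.anchor1.end >= lp.anchor2.start:
            continue
        between = between_region(lp)
        flags[i] = int(sub.dna_in(between).sum()) >= min_pairs
    return flags


def _two_flag_table(
    rows: np.ndarray, cols: np.ndarray
) -> ContingencyTable2x2:
    rows = np.asarray(rows, dtype=bool)
    cols = np.asarray(cols, dtype=bool)
    if rows.all() or not rows.any() or cols.all() or not cols.any():
        raise ValueError("degenerate flag vector: all-true or all-false")
    return ContingencyTable2x2(
        a=int((rows & cols).sum()),
        b=int((rows & ~cols).sum()),
        c=int((~rows & cols).sum()),
        d=int((~rows & ~cols).sum()),
    )


def crossing_enrichment(
    group_flags: Sequence[bool], member_flags: Sequence[bool]
) -> EnrichmentResult:
    """2x2 enrichment of one loop group in a membership class.

    Rows are group / non-group loops, columns member / non-member
    (e.g. RNase-emergent x target-crossing); delegates to
    :func:`contingency_test`.
    """
    return contingency_test(_two_flag_table(np.asarray(group_flags), np.asarray(member_flags)))


def chri_cbs_enrichment(
    chri_flags: Sequence[bool],
    cbs_classes: Sequence[str],
    comparison_mask: Sequence[bool] | None = None,
) -> EnrichmentResult:
    """Enrichment of convergent CBS among CHRI-loops vs a comparison group.

    ``comparison_mask`` restricts the non-CHRI rows to a chosen
    comparison group (all other loops by default).  The 2x2 table is
    (CHRI vs comparison) x (convergent vs not-convergent).
    """
    chri = np.asarray(chri_flags, dtype=bool)
    conv = np.array([c == "convergent" for c in cbs_classes])
    if comparison_mask is None:
        comparison = ~chri
    else:
        comparison = np.asarray(comparison_mask, dtype=bool) & ~chri
    if not comparison.any():
        raise ValueError("empty comparison group")
    keep = chri | comparison
    return contingency_test(_two_flag_table(chri[keep], conv[keep]))
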