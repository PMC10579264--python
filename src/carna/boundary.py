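"""TAD-relative caRNA statistics.

Cross-over contacts are RNA-DNA pairs whose two ends lie on opposite
sides of a TAD boundary; comparing their abundance between conditions in
a 2x2 contingency table (odds ratio, standard error of the log odds
ratio, chi-square) quantifies boundary insulation of RNA-DNA contacts.
The TAD meta-profile rescales each TAD and its equal-length flanks onto
a common axis to show how the attachment of locally transcribed RNA
drops at domain edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contacts import PairSet
from .genome import TADSet

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "MetaProfile",
    "classify_crossover",
    "contingency_test",
    "tad_ral_profile",
    "boundary_dropoff_test",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = condition 1 / condition 2, columns = in-class /
    out-of-class (e.g. cross-over / non-cross-over)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    log_or: float
    selor: float
    chi2: float
    p_value: float
    haldane_corrected: bool = False

    @property
    def whiskers(self) -> tuple[float, float]:
        """exp(log(OR) -/+ SELOR)."""
        return (
            float(np.exp(self.log_or - self.selor)),
            float(np.exp(self.log_or + self.selor)),
        )

    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.log_or - 1.96 * self.selor)),
            float(np.exp(self.log_or + 1.96 * self.selor)),
        )


def classify_crossover(
    pairs: PairSet, chrom: str, boundary: int, window: int = 500_000
) -> tuple[int, int]:
    """Count cross-over and non-cross-over pairs around one boundary.

    Only cis pairs with both ends within ``window`` bp of the boundary
    are considered.  A pair is cross-over iff its RNA and DNA ends lie
    on opposite sides; an end exactly at the boundary belongs to the
    downstream side.
    """
    if chrom not in pairs.assembly or not (
        0 <= boundary <= pairs.assembly.length(chrom)
    ):
        raise ValueError(f"boundary {chrom}:{boundary} outside the assembly")
    df = pairs.df
    cis = (df["rna_chrom"] == chrom) & (df["dna_chrom"] == chrom)
    r = df["rna_pos"].to_numpy()
    d = df["dna_pos"].to_numpy()
    near = (
        cis.to_numpy()
        & (np.abs(r - boundary) <= window)
        & (np.abs(d - boundary) <= window)
    )
    # position >= boundary is "downstream"
    r_side = r[near] >= boundary
    d_side = d[near] >= boundary
    n_cross = int((r_side != d_side).sum())
    return n_cross, int(near.sum()) - n_cross


def contingency_test(
    table: ContingencyTable2x2, yates: bool = False
) -> EnrichmentResult:
    """Odds ratio, SELOR and chi-square for a 2x2 table.

    OR = ad/bc and SELOR = sqrt(1/a + 1/b + 1/c + 1/d).  If any cell is
    zero the Haldane-Anscombe +0.5 correction is applied to OR/SELOR and
    flagged.  The chi-square test (1 df, no continuity correction by
    default) always uses the raw counts; a zero row or column makes the
    test undefined and raises.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero row or column")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    selor = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=yates)
    return EnrichmentResult(
        odds_ratio=float(odds),
        log_or=float(np.log(odds)),
        selor=selor,
        chi2=float(chi2),
        p_value=float(p),
        haldane_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# TAD meta-profile


@dataclass
class MetaProfile:
    """Per-TAD rescaled RAL vectors over [flank | TAD | flank].

    ``vectors`` has one row per TAD and ``3 * bins_per_segment``
    columns; each row is normalised to mean 1.  ``mean`` is the
    column-wise average and (``ci_low``, ``ci_high``) a bootstrap 95%
    band around it.
    """

    vectors: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    bins_per_segment: int
    n_skipped: int = 0


def tad_ral_profile(
    pairs: PairSet,
    tads: TADSet,
    bins_per_segment: int = 50,
    min_tad_size: int = 100_000,
    invert_rna_selection: bool = False,
    n_boot: int = 200,
    seed: int = 0,
) -> MetaProfile:
    """Meta-profile of RAL of TAD-transcribed RNA over rescaled TADs.

    For each TAD of length L, pairs whose RNA end lies inside the TAD
    (or outside, on the same chromosome, when ``invert_rna_selection``)
    contribute their DNA ends, binned over [start - L, end + L) rescaled
    to ``3 * bins_per_segment`` equal bins.  Each TAD's vector is
    normalised to mean 1; TADs whose flanks leave the chromosome are
    skipped and counted.
    """
    m = bins_per_segment
    rows = []
    skipped = 0
    df = pairs.df
    for tad in tads.domains():
        L = len(tad)
        if L < min_tad_size:
            skipped += 1
            continue
        lo, hi = tad.start - L, tad.end + L
        if lo < 0 or hi > pairs.assembly.length(tad.chrom):
            skipped += 1
            continue
        on_chrom = (df["rna_chrom"] == tad.chrom).to_numpy()
        inside = (
            on_chrom
            & (df["rna_pos"].to_numpy() >= tad.start)
            & (df["rna_pos"].to_numpy() < tad.end)
        )
        sel = (on_chrom & ~inside) if invert_rna_selection else inside
        sel &= (df["dna_chrom"] == tad.chrom).to_numpy()
        dna = df["dna_pos"].to_numpy()[sel]
        dna = dna[(dna >= lo) & (dna < hi)]
        vec, _ = np.histogram(dna, bins=3 * m, range=(lo, hi))
        vec = vec.astype(float)
        mu = vec.mean()
        if mu > 0:
            vec /= mu
        rows.append(vec)
    if not rows:
        raise ValueError("no usable TADs for the meta-profile")
    vectors = np.vstack(rows)
    mean = vectors.mean(axis=0)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, vectors.shape[1]))
    for i in range(n_boot):
        idx = rng.integers(0, len(vectors), len(vectors))
        boots[i] = vectors[idx].mean(axis=0)
    lo_b, hi_b = np.percentile(boots, [2.5, 97.5], axis=0)
    return MetaProfile(vectors, mean, lo_b, hi_b, m, skipped)


def boundary_dropoff_test(profile: MetaProfile, k_bins: int = 5) -> tuple[float, float]:
    """Wilcoxon rank-sum of inside-edge vs outside-edge RAL.

    Per TAD, the mean over the ``k_bins`` innermost center-block bins
    adjacent to each boundary is compared with the mean over the
    ``k_bins`` outermost flank bins adjacent to the same boundary;
    values from both boundaries are pooled and tested two-sided.
    Returns (statistic, p).
    """
    m = profile.bins_per_segment
    if k_bins > m:
        raise ValueError("k_bins must be <= bins_per_segment")
    v = profile.vectors
    if len(v) < 10:
        warnings.warn("fewer than 10 TADs; dropoff p-value is unstable")
    inside = np.concatenate(
        [v[:, m : m + k_bins].mean(axis=1), v[:, 2 * m - k_bins : 2 * m].mean(axis=1)]
    )
    outside = np.concatenate(
        [v[:, m - k_bins : m].mean(axis=1), v[:, 2 * m : 2 * m + k_bins].mean(axis=1)]
    )
    stat, p = stats.ranksums(inside, outside)
    return float(stat), float(p)
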