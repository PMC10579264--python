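"""RNA attachment level (RAL) tracks and RNA-association domain calling.

The RAL of a genomic segment with respect to an RNA source is the
number of contact pairs whose RNA end maps to the source and whose DNA
end maps to the segment; the cumulative RAL (cRAL) counts DNA ends over
all RNA.  RNA-association domains are rectangular blocks on the
asymmetric RNA x DNA contact matrix: a narrow RNA-end peak (the block
height) paired with the strongest corresponding DNA-end peak (the block
width).

Peak calling is a fixed-width sliding-window caller with a local
fold-enrichment threshold and a Poisson test against the chromosome-wide
uniform rate, in the spirit of HOMER's findPeaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .contacts import PairSet
from .genome import GenomeAssembly, Gene, GenomicInterval, RepeatElement, Track

log = logging.getLogger(__name__)

__all__ = [
    "RalTrack",
    "Peak1D",
    "DomainCall",
    "ral_track",
    "cral_track",
    "truncated_ral",
    "family_ral",
    "call_peaks_1d",
    "call_domains",
    "domain_stats",
]


@dataclass
class RalTrack(Track):
    source: str = "ALL"
    filters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.source:
            raise ValueError("RAL source descriptor must be non-empty")
        if (self.values[np.isfinite(self.values)] < 0).any():
            raise ValueError("RAL counts must be non-negative")


@dataclass(frozen=True)
class Peak1D:
    interval: GenomicInterval
    count: int
    summit: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("peak count must be >= 1")
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie inside the peak interval")


@dataclass(frozen=True)
class DomainCall:
    rna_peak: Peak1D  # block height
    dna_peak: Peak1D  # block width
    support: int
    diagonal_overlap: bool

    @property
    def width(self) -> int:
        return len(self.dna_peak.interval)

    @property
    def height(self) -> int:
        return len(self.rna_peak.interval)


# ---------------------------------------------------------------------------
# RAL tracks


def _dna_end_track(
    pairs: PairSet, mask: np.ndarray, bin_size: int, source: str, filters: dict
) -> RalTrack:
    asm = pairs.assembly
    offsets = asm.bin_offsets(bin_size)
    vals = np.zeros(asm.total_bins(bin_size))
    df = pairs.df[mask]
    if len(df):
        off = df["dna_chrom"].map(offsets).to_numpy(dtype=np.int64)
        bins = off + df["dna_pos"].to_numpy() // bin_size
        np.add.at(vals, bins, 1)
    return RalTrack(asm, bin_size, vals, source=source, filters=dict(filters))


def ral_track(
    pairs: PairSet,
    source: Gene | GenomicInterval,
    bin_size: int,
    filters: dict | None = None,
) -> RalTrack:
    """Per-bin DNA-end counts of pairs whose RNA end overlaps ``source``."""
    if isinstance(source, Gene):
        interval, label = source.interval, source.id
    else:
        interval, label = source, f"{source.chrom}:{source.start}-{source.end}"
    mask = pairs.rna_in(interval)
    return _dna_end_track(pairs, mask, bin_size, label, filters or {})


def cral_track(pairs: PairSet, bin_size: int, filters: dict | None = None) -> RalTrack:
    """Cumulative RAL: per-bin DNA-end counts over all RNA."""
    mask = np.ones(len(pairs), dtype=bool)
    return _dna_end_track(pairs, mask, bin_size, "ALL", filters or {})


def truncated_ral(track: RalTrack, cap: float) -> RalTrack:
    """Clip track values at ``cap`` (visualisation aid for long tails)."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return RalTrack(
        track.assembly,
        track.bin_size,
        np.minimum(track.values, cap),
        source=track.source,
        filters=dict(track.filters),
    )


def _point_in_union(starts: np.ndarray, ends: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Membership of points in a sorted, merged interval union."""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


def _merged_union(intervals: Sequence[GenomicInterval]) -> dict[str, tuple]:
    by_chrom: dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def rna_in_intervals(pairs: PairSet, intervals: Sequence[GenomicInterval]) -> np.ndarray:
    """Mask of pairs whose RNA end falls in any of ``intervals``."""
    union = _merged_union(intervals)
    mask = np.zeros(len(pairs), dtype=bool)
    chroms = pairs.df["rna_chrom"].to_numpy()
    pos = pairs.df["rna_pos"].to_numpy()
    for chrom, (starts, ends) in union.items():
        m = chroms == chrom
        if m.any():
            mask[m] = _point_in_union(starts, ends, pos[m])
    return mask


def family_ral(
    pairs: PairSet,
    repeats: Sequence[RepeatElement],
    family: str,
    bin_size: int = 500_000,
    filters: dict | None = None,
) -> RalTrack:
    """RAL of caRNA transcribed from repeats of one family (e.g. Alu, L1)."""
    fam = [r.interval for r in repeats if r.family == family]
    if not fam:
        raise ValueError(f"family {family!r} absent from the repeat annotation")
    mask = rna_in_intervals(pairs, fam)
    return _dna_end_track(pairs, mask, bin_size, family, filters or {})


# ---------------------------------------------------------------------------
# Peak calling


def call_peaks_1d(
    positions: np.ndarray,
    chrom: str,
    chrom_length: int,
    peak_size: int,
    min_interval: int,
    fold_threshold: float = 4.0,
    poisson_p: float = 1e-5,
    flank_factor: int = 10,
) -> list[Peak1D]:
    """Fixed-width peak calling on 1D read positions of one chromosome.

    Candidate windows of width ``peak_size`` are anchored at read
    positions, ranked by count (ties leftmost) and accepted greedily
    subject to a center-to-center spacing of at least ``min_interval``.
    An accepted window is reported only if its count exceeds
    ``fold_threshold`` times the local background (read density in a
    ``flank_factor * peak_size`` window around it, scaled to the peak
    width) and a Poisson threshold at ``poisson_p`` against the
    chromosome-wide uniform rate.
    """
    if peak_size <= 0:
        raise ValueError("peak_size must be positive")
    if min_interval < peak_size:
        raise ValueError("min_interval must be >= peak_size")
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    n = len(pos)
    if n == 0:
        return []
    half = peak_size // 2
    # windows starting at each read; the max-count window of fixed width
    # always has its left edge at a read position
    starts = np.unique(pos)
    counts = np.searchsorted(pos, starts + peak_size, side="left") - np.searchsorted(
        pos, starts, side="left"
    )
    centers = starts + half
    order = np.lexsort((centers, -counts))
    lam = n * peak_size / chrom_length  # uniform-rate expectation per window
    min_count = int(stats.poisson.isf(poisson_p, lam)) + 1
    flank_half = flank_factor * peak_size // 2
    accepted: list[int] = []
    peaks: list[Peak1D] = []
    for idx in order:
        c = int(centers[idx])
        cnt = int(counts[idx])
        if cnt < 1:
            continue
        if any(abs(c - a) < min_interval for a in accepted):
            continue
        accepted.append(c)
        # local background: flank window minus the peak window itself
        big = np.searchsorted(pos, c + flank_half, side="left") - np.searchsorted(
            pos, c - flank_half, side="left"
        )
        flank_reads = big - cnt
        bg = flank_reads * peak_size / (flank_factor * peak_size - peak_size)
        if cnt <= fold_threshold * bg:
            continue
        if cnt < min_count:
            continue
        start = max(0, c - half)
        end = min(chrom_length, start + peak_size)
        window = pos[
            np.searchsorted(pos, int(centers[idx]) - half) : np.searchsorted(
                pos, int(centers[idx]) - half + peak_size
            )
        ]
        summit = int(np.median(window)) if len(window) else c
        summit = min(max(summit, start), end - 1)
        peaks.append(Peak1D(GenomicInterval(chrom, start, end), cnt, summit))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def _call_peaks_genomewide(
    chrom_positions: dict[str, np.ndarray],
    assembly: GenomeAssembly,
    peak_size: int,
    min_interval: int,
    **kw,
) -> list[Peak1D]:
    peaks = []
    for chrom in assembly.names:
        p = chrom_positions.get(chrom)
        if p is None or len(p) == 0:
            continue
        peaks.extend(
            call_peaks_1d(
                p, chrom, assembly.length(chrom), peak_size, min_interval, **kw
            )
        )
    return peaks


def call_domains(
    pairs: PairSet,
    rna_peak_size: int = 5_000,
    rna_min_interval: int = 12_000,
    dna_peak_size: int = 25_000,
    dna_min_interval: int = 50_000,
    **peak_kw,
) -> list[DomainCall]:
    """Call RNA-association domains as RNA-peak x DNA-peak blocks.

    RNA-end peaks are called first; for each, the pairs whose RNA end
    lies in the peak are retrieved and their DNA ends are peak-called
    genome-wide; only the DNA peak with the highest read count is kept
    (ties broken by chromosome order, then leftmost).  RNA peaks whose
    retrieved DNA ends yield no DNA peak are dropped and logged.
    """
    asm = pairs.assembly
    rna_by_chrom = {c: pairs.rna_positions(c) for c in asm.names}
    rna_peaks = _call_peaks_genomewide(
        rna_by_chrom, asm, rna_peak_size, rna_min_interval, **peak_kw
    )
    calls: list[DomainCall] = []
    dropped = 0
    chrom_rank = {c: i for i, c in enumerate(asm.names)}
    for rp in rna_peaks:
        mask = pairs.rna_in(rp.interval)
        sub = pairs.subset(mask)
        dna_by_chrom = {c: sub.dna_positions(c) for c in asm.names}
        dna_peaks = _call_peaks_genomewide(
            dna_by_chrom, asm, dna_peak_size, dna_min_interval, **peak_kw
        )
        if not dna_peaks:
            dropped += 1
            continue
        best = min(
            dna_peaks,
            key=lambda p: (-p.count, chrom_rank[p.interval.chrom], p.interval.start),
        )
        calls.append(
            DomainCall(
                rna_peak=rp,
                dna_peak=best,
                support=best.count,
                diagonal_overlap=best.interval.overlaps(rp.interval),
            )
        )
    if dropped:
        log.info("call_domains: %d RNA peaks yielded no DNA peak", dropped)
    return calls


# ---------------------------------------------------------------------------
# Summaries


def _five_number(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(lo),
        "whisker_high": float(hi),
    }


def domain_stats(calls: Sequence[DomainCall]) -> dict:
    """Box-plot style summaries of domain widths and heights (bp).

    Whiskers extend from the hinges to the most extreme values within
    1.5 * IQR of them.
    """
    if not calls:
        raise ValueError("no domain calls to summarise")
    widths = np.array([c.width for c in calls], dtype=float)
    heights = np.array([c.height for c in calls], dtype=float)
    return {"width": _five_number(widths), "height": _five_number(heights)}
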