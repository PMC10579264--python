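"""Genome model and interval primitives.

All coordinates are 0-based, half-open. External formats (1-based
``.pairs``, 0-based BED) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeAssembly",
    "GenomicInterval",
    "Gene",
    "RepeatElement",
    "Loop",
    "TADSet",
    "Track",
]


@dataclass(frozen=True)
class GenomeAssembly:
    """An ordered set of chromosomes with lengths in bp.

    Parameters
    ----------
    names
        Chromosome names, in storage order. Must be unique.
    lengths
        Mapping name -> length in bp; every length must be positive.
    """

    names: tuple[str, ...]
    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        for name in self.names:
            if name not in self.lengths:
                raise ValueError(f"no length for chromosome {name!r}")
            if self.lengths[name] <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @classmethod
    def from_dict(cls, lengths: Mapping[str, int]) -> "GenomeAssembly":
        return cls(tuple(lengths), dict(lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    # ---- binning helpers -------------------------------------------------

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.lengths[chrom] // bin_size)

    def bin_offsets(self, bin_size: int) -> dict[str, int]:
        """Global bin offset of each chromosome's first bin."""
        offsets: dict[str, int] = {}
        total = 0
        for name in self.names:
            offsets[name] = total
            total += self.n_bins(name, bin_size)
        return offsets

    def total_bins(self, bin_size: int) -> int:
        return sum(self.n_bins(name, bin_size) for name in self.names)

    def global_bin(self, chrom: str, pos: int, bin_size: int) -> int:
        return self.bin_offsets(bin_size)[chrom] + pos // bin_size

    def bin_table(self, bin_size: int) -> list[tuple[str, int, int]]:
        """(chrom, start, end) for every global bin, in order."""
        rows = []
        for name in self.names:
            L = self.lengths[name]
            for s in range(0, L, bin_size):
                rows.append((name, s, min(s + bin_size, L)))
        return rows


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def validate(self, assembly: GenomeAssembly) -> None:
        if self.chrom not in assembly:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > assembly.length(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {assembly.length(self.chrom)}"
            )


@dataclass(frozen=True)
class Gene:
    id: str
    interval: GenomicInterval
    strand: str = "."


@dataclass(frozen=True)
class RepeatElement:
    interval: GenomicInterval
    family: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("repeat family must be non-empty")


@dataclass(frozen=True)
class Loop:
    """An intra-chromosomal anchor pair.

    ``anchor1`` lies entirely upstream of ``anchor2``; both anchors have
    width equal to the calling resolution.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    resolution: int
    conditions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchor1.end > self.anchor2.start:
            raise ValueError("anchor1 must lie entirely upstream of anchor2")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    def key(self) -> tuple:
        return (self.chrom, self.anchor1.start, self.anchor2.start, self.resolution)


class TADSet:
    """Sorted, non-overlapping domains per chromosome.

    Boundaries are derived as the midpoints of the gaps between
    consecutive TADs (the gap itself for abutting TADs is the shared
    coordinate).
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping TADs on {chrom}: {a} / {b}")
        self._by_chrom = by_chrom

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def domains(self, chrom: str | None = None) -> list[GenomicInterval]:
        if chrom is not None:
            return list(self._by_chrom.get(chrom, []))
        return [iv for c in sorted(self._by_chrom) for iv in self._by_chrom[c]]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def boundaries(self, chrom: str | None = None) -> list[tuple[str, int]]:
        """Boundary points between consecutive domains.

        The boundary position is the midpoint of the inter-TAD gap
        (equal to the shared coordinate when domains abut).
        """
        chroms = [chrom] if chrom is not None else sorted(self._by_chrom)
        out: list[tuple[str, int]] = []
        for c in chroms:
            ivs = self._by_chrom.get(c, [])
            for a, b in zip(ivs, ivs[1:]):
                out.append((c, (a.end + b.start) // 2))
        return out


@dataclass
class Track:
    """One value per genomic bin over a whole assembly.

    Values are stored as a single float array over the global binning;
    NaN marks missing bins.
    """

    assembly: GenomeAssembly
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = self.assembly.total_bins(self.bin_size)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (expected,):
            raise ValueError(
                f"track length {self.values.shape} != bin count {expected}"
            )

    @classmethod
    def zeros(cls, assembly: GenomeAssembly, bin_size: int) -> "Track":
        return cls(assembly, bin_size, np.zeros(assembly.total_bins(bin_size)))

    @classmethod
    def full_missing(cls, assembly: GenomeAssembly, bin_size: int) -> "Track":
        return cls(
            assembly, bin_size, np.full(assembly.total_bins(bin_size), np.nan)
        )

    def chrom_slice(self, chrom: str) -> slice:
        off = self.assembly.bin_offsets(self.bin_size)
        return slice(off[chrom], off[chrom] + self.assembly.n_bins(chrom, self.bin_size))

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.chrom_slice(chrom)]

    def value_at(self, chrom: str, pos: int) -> float:
        return self.values[self.assembly.global_bin(chrom, pos, self.bin_size)]

    def copy(self) -> "Track":
        return Track(self.assembly, self.bin_size, self.values.copy())
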