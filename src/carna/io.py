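"""Readers and writers for the text formats the pipeline consumes.

Supported dialects: 4DN ``.pairs`` (1-based positions, ``#`` header
lines), BED3/4/6 (0-based half-open), BEDPE, bedGraph, and a two-column
chrom.sizes file.  All conversion to the package's 0-based internal
coordinates happens here.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contacts import PairSet
from .genome import (
    GenomeAssembly,
    GenomicInterval,
    Gene,
    Loop,
    RepeatElement,
    TADSet,
    Track,
)

__all__ = [
    "read_chromsizes",
    "read_pairs",
    "write_pairs",
    "read_bed",
    "read_genes_bed6",
    "read_ctcf_bed6",
    "read_repeats_bed",
    "read_tads_bed",
    "read_bedpe",
    "write_bedpe",
    "write_bedgraph",
    "write_track_bedgraph",
]


def read_chromsizes(path) -> GenomeAssembly:
    """Read a two-column name/length file into a :class:`GenomeAssembly`."""
    names: list[str] = []
    lengths: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, length = line.split()[:2]
        names.append(name)
        lengths[name] = int(length)
    return GenomeAssembly(tuple(names), lengths)


# ---------------------------------------------------------------------------
# .pairs


def read_pairs(
    path, assembly: GenomeAssembly, condition: str = "unnamed", swap_ends: bool = False
) -> tuple[PairSet, int]:
    """Parse a 4DN ``.pairs`` file into a :class:`PairSet`.

    End 1 is taken as the RNA end and end 2 as the DNA end unless
    ``swap_ends``.  1-based file positions become 0-based.  Records on
    chromosomes absent from ``assembly`` are dropped; their count is
    returned alongside the pair set.
    """
    rows = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 7:
                raise ValueError(
                    f"{path}: malformed .pairs line {lineno}: expected >=7 "
                    f"columns, got {len(fields)}"
                )
            _, c1, p1, c2, p2, s1, s2 = fields[:7]
            try:
                p1i, p2i = int(p1) - 1, int(p2) - 1
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed .pairs line {lineno}: non-integer position"
                ) from exc
            if c1 not in assembly or c2 not in assembly:
                dropped += 1
                continue
            rows.append((c1, p1i, s1, c2, p2i, s2))
    if not rows:
        warnings.warn(f"{path}: no pair records parsed")
        df = PairSet.empty_frame()
    else:
        df = pd.DataFrame(
            rows,
            columns=["rna_chrom", "rna_pos", "rna_strand",
                     "dna_chrom", "dna_pos", "dna_strand"],
        )
        if swap_ends:
            df = df.rename(
                columns={
                    "rna_chrom": "dna_chrom", "rna_pos": "dna_pos",
                    "rna_strand": "dna_strand", "dna_chrom": "rna_chrom",
                    "dna_pos": "rna_pos", "dna_strand": "rna_strand",
                }
            )
    return PairSet(df, assembly, condition), dropped


def write_pairs(pairs: PairSet, path) -> None:
    """Write a ``.pairs`` file (1-based positions, 4DN-style header)."""
    asm = pairs.assembly
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#shape: upper triangle\n")
        for name in asm.names:
            fh.write(f"#chromsize: {name} {asm.length(name)}\n")
        fh.write(
            "#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n"
        )
        for i, row in enumerate(pairs.df.itertuples(index=False)):
            fh.write(
                f"r{i}\t{row.rna_chrom}\t{row.rna_pos + 1}\t"
                f"{row.dna_chrom}\t{row.dna_pos + 1}\t"
                f"{row.rna_strand}\t{row.dna_strand}\n"
            )


# ---------------------------------------------------------------------------
# BED family


def _bed_rows(path) -> Iterable[tuple[int, list[str]]]:
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        yield lineno, line.split("\t") if "\t" in line else line.split()


def _check_interval(iv: GenomicInterval, assembly: GenomeAssembly | None, lineno, path):
    if assembly is not None:
        try:
            iv.validate(assembly)
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from exc


def read_bed(path, assembly: GenomeAssembly | None = None) -> list[GenomicInterval]:
    out = []
    for lineno, f in _bed_rows(path):
        iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
        _check_interval(iv, assembly, lineno, path)
        out.append(iv)
    return out


def read_tads_bed(path, assembly: GenomeAssembly | None = None) -> TADSet:
    return TADSet(read_bed(path, assembly))


def read_genes_bed6(path, assembly: GenomeAssembly | None = None) -> list[Gene]:
    out = []
    for lineno, f in _bed_rows(path):
        iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
        _check_interval(iv, assembly, lineno, path)
        strand = f[5] if len(f) > 5 else "."
        out.append(Gene(f[3], iv, strand))
    ids = [g.id for g in out]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate gene ids")
    return out


def read_ctcf_bed6(
    path, assembly: GenomeAssembly | None = None
) -> list[tuple[GenomicInterval, str]]:
    """CTCF binding sites; the BED6 strand column is the motif orientation."""
    out = []
    for lineno, f in _bed_rows(path):
        iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
        _check_interval(iv, assembly, lineno, path)
        strand = f[5] if len(f) > 5 else "."
        if strand not in ("+", "-"):
            raise ValueError(f"{path} line {lineno}: CBS needs +/- orientation")
        out.append((iv, strand))
    return out


def read_repeats_bed(
    path, assembly: GenomeAssembly | None = None
) -> list[RepeatElement]:
    """BED with the family name in column 4."""
    out = []
    for lineno, f in _bed_rows(path):
        if len(f) < 4:
            raise ValueError(f"{path} line {lineno}: repeat BED needs a family column")
        iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
        _check_interval(iv, assembly, lineno, path)
        out.append(RepeatElement(iv, f[3]))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path, names=None) -> None:
    ivs = sorted(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            name = f"\t{names[i]}" if names is not None else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{name}\n")


# ---------------------------------------------------------------------------
# BEDPE (loops)


def read_bedpe(
    path,
    assembly: GenomeAssembly | None = None,
    condition: str | None = None,
) -> list[Loop]:
    """Read loops from BEDPE; anchors swapped (with a warning) if reversed."""
    out = []
    conds = frozenset([condition]) if condition else frozenset()
    for lineno, f in _bed_rows(path):
        if len(f) < 6:
            raise ValueError(f"{path} line {lineno}: BEDPE needs 6 columns")
        a = GenomicInterval(f[0], int(f[1]), int(f[2]))
        b = GenomicInterval(f[3], int(f[4]), int(f[5]))
        _check_interval(a, assembly, lineno, path)
        _check_interval(b, assembly, lineno, path)
        if a.chrom == b.chrom and b.start < a.start:
            warnings.warn(f"{path} line {lineno}: anchors reversed, swapping")
            a, b = b, a
        out.append(Loop(a, b, len(a), conds))
    return out


def write_bedpe(loops: Sequence[Loop], path, extra=None) -> None:
    order = sorted(range(len(loops)), key=lambda i: loops[i].key())
    with open(path, "w") as fh:
        for i in order:
            lp = loops[i]
            tail = f"\t{extra[i]}" if extra is not None else ""
            fh.write(
                f"{lp.anchor1.chrom}\t{lp.anchor1.start}\t{lp.anchor1.end}\t"
                f"{lp.anchor2.chrom}\t{lp.anchor2.start}\t{lp.anchor2.end}{tail}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(
    assembly: GenomeAssembly, bin_size: int, values: np.ndarray, path
) -> None:
    rows = assembly.bin_table(bin_size)
    with open(path, "w") as fh:
        for (chrom, start, end), v in zip(rows, values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")


def write_track_bedgraph(track: Track, path) -> None:
    write_bedgraph(track.assembly, track.bin_size, track.values, path)
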