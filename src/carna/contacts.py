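"""RNA-DNA contact pairs and the standard read-pair filters.

An iMARGI read pair has an RNA end (the transcript) and a DNA end (the
genomic sequence the transcript was crosslinked to).  Pair collections
are stored column-wise in a :class:`pandas.DataFrame` so the filters and
binning are vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import GenomeAssembly, GenomicInterval

__all__ = [
    "ContactPair",
    "PairSet",
    "proximity_filter",
    "distance_filter",
    "bin_pairs",
]

_COLUMNS = ["rna_chrom", "rna_pos", "rna_strand", "dna_chrom", "dna_pos", "dna_strand"]
_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class ContactPair:
    rna_chrom: str
    rna_pos: int
    rna_strand: str
    dna_chrom: str
    dna_pos: int
    dna_strand: str

    def __post_init__(self) -> None:
        if self.rna_strand not in _STRANDS or self.dna_strand not in _STRANDS:
            raise ValueError("strand must be one of +, -, .")

    @property
    def is_cis(self) -> bool:
        return self.rna_chrom == self.dna_chrom

    @property
    def separation(self) -> int | None:
        """|rna_pos - dna_pos| for cis pairs, None for trans."""
        if not self.is_cis:
            return None
        return abs(self.rna_pos - self.dna_pos)


class PairSet:
    """A validated collection of RNA-DNA contact pairs.

    Parameters
    ----------
    df
        Columns ``rna_chrom, rna_pos, rna_strand, dna_chrom, dna_pos,
        dna_strand``; positions 0-based.
    assembly
        Genome the positions refer to.
    condition
        Provenance label (e.g. "Control", "RNase"); must be non-empty.
    """

    def __init__(self, df: pd.DataFrame, assembly: GenomeAssembly, condition: str):
        if not condition:
            raise ValueError("condition label must be non-empty")
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df[_COLUMNS].reset_index(drop=True)
        for side in ("rna", "dna"):
            chroms = df[f"{side}_chrom"]
            pos = df[f"{side}_pos"].to_numpy()
            for chrom in chroms.unique():
                if chrom not in assembly:
                    raise ValueError(f"chromosome {chrom!r} absent from assembly")
                mask = (chroms == chrom).to_numpy()
                if mask.any():
                    p = pos[mask]
                    if p.min() < 0 or p.max() >= assembly.length(chrom):
                        raise ValueError(
                            f"{side} position outside {chrom} in pair set"
                        )
            bad = ~df[f"{side}_strand"].isin(sorted(_STRANDS))
            if bad.any():
                raise ValueError("invalid strand value")
        self.df = df
        self.assembly = assembly
        self.condition = condition

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[ContactPair],
        assembly: GenomeAssembly,
        condition: str = "unnamed",
    ) -> "PairSet":
        rows = [
            (p.rna_chrom, p.rna_pos, p.rna_strand, p.dna_chrom, p.dna_pos, p.dna_strand)
            for p in pairs
        ]
        df = pd.DataFrame(rows, columns=_COLUMNS) if rows else cls.empty_frame()
        return cls(df, assembly, condition)

    @staticmethod
    def empty_frame() -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rna_chrom": pd.Series(dtype=str),
                "rna_pos": pd.Series(dtype=np.int64),
                "rna_strand": pd.Series(dtype=str),
                "dna_chrom": pd.Series(dtype=str),
                "dna_pos": pd.Series(dtype=np.int64),
                "dna_strand": pd.Series(dtype=str),
            }
        )

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield ContactPair(*row)

    def _with(self, df: pd.DataFrame) -> "PairSet":
        out = object.__new__(PairSet)
        out.df = df.reset_index(drop=True)
        out.assembly = self.assembly
        out.condition = self.condition
        return out

    def subset(self, mask: np.ndarray) -> "PairSet":
        return self._with(self.df[mask])

    @property
    def is_cis(self) -> np.ndarray:
        return (self.df["rna_chrom"] == self.df["dna_chrom"]).to_numpy()

    @property
    def separation(self) -> np.ndarray:
        """Cis separation in bp; -1 for trans pairs."""
        sep = np.abs(self.df["rna_pos"].to_numpy() - self.df["dna_pos"].to_numpy())
        return np.where(self.is_cis, sep, -1)

    def rna_positions(self, chrom: str) -> np.ndarray:
        m = (self.df["rna_chrom"] == chrom).to_numpy()
        return np.sort(self.df["rna_pos"].to_numpy()[m])

    def dna_positions(self, chrom: str) -> np.ndarray:
        m = (self.df["dna_chrom"] == chrom).to_numpy()
        return np.sort(self.df["dna_pos"].to_numpy()[m])

    def rna_in(self, interval: GenomicInterval) -> np.ndarray:
        """Boolean mask of pairs whose RNA end falls in ``interval``."""
        df = self.df
        return (
            (df["rna_chrom"] == interval.chrom)
            & (df["rna_pos"] >= interval.start)
            & (df["rna_pos"] < interval.end)
        ).to_numpy()

    def dna_in(self, interval: GenomicInterval) -> np.ndarray:
        df = self.df
        return (
            (df["dna_chrom"] == interval.chrom)
            & (df["dna_pos"] >= interval.start)
            & (df["dna_pos"] < interval.end)
        ).to_numpy()


def proximity_filter(
    pairs: PairSet, min_sep: int = 1000
) -> tuple[PairSet, int]:
    """Drop cis pairs whose two ends map within ``min_sep`` bp.

    Trans pairs are retained unconditionally.  Returns the filtered set
    and the number of removed pairs.
    """
    if min_sep < 0:
        raise ValueError("min_sep must be >= 0")
    sep = pairs.separation
    keep = (sep < 0) | (sep >= min_sep)
    return pairs.subset(keep), int((~keep).sum())


def distance_filter(
    pairs: PairSet, min_cis: int = 200_000, keep_trans: bool = True
) -> tuple[PairSet, int]:
    """Keep cis pairs separated by at least ``min_cis`` bp.

    Trans pairs are kept iff ``keep_trans``.  Returns the filtered set
    and the number of removed pairs.
    """
    if min_cis < 0:
        raise ValueError("min_cis must be >= 0")
    sep = pairs.separation
    cis = sep >= 0
    keep = np.where(cis, sep >= min_cis, keep_trans)
    return pairs.subset(keep), int((~keep).sum())


def bin_pairs(pairs: PairSet, bin_size: int, symmetric: bool):
    """Bin pairs into a sparse contact matrix over the global binning.

    Asymmetric mode maps the RNA end to the row and the DNA end to the
    column.  Symmetric mode (Hi-C-style) places each pair in the upper
    triangle at (min bin, max bin).  Matrix mass always equals the pair
    count.
    """
    from .matrix import SparseContactMatrix

    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    asm = pairs.assembly
    offsets = asm.bin_offsets(bin_size)
    n = asm.total_bins(bin_size)
    df = pairs.df
    off_r = df["rna_chrom"].map(offsets).to_numpy(dtype=np.int64)
    off_d = df["dna_chrom"].map(offsets).to_numpy(dtype=np.int64)
    rows = off_r + df["rna_pos"].to_numpy() // bin_size
    cols = off_d + df["dna_pos"].to_numpy() // bin_size
    if symmetric:
        rows, cols = np.minimum(rows, cols), np.maximum(rows, cols)
    mat = sp.coo_matrix(
        (np.ones(len(df)), (rows, cols)), shape=(n, n)
    ).tocsr()
    return SparseContactMatrix(asm, bin_size, symmetric, mat)
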