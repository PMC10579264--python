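"""Binned contact-matrix numerics.

Matrix balancing (Knight-Ruiz), distance-expected and O/E transforms,
compartment eigenvector (PC1), Crane-style insulation score, the Dixon
directionality index, de novo boundary detection and the Measure of
Concordance between two TAD partitions.

Cis blocks are materialised densely per chromosome: the package targets
matrices of a few thousand bins per chromosome, where dense linear
algebra is both simpler and faster than sparse bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .genome import GenomeAssembly, Track, TADSet

__all__ = [
    "SparseContactMatrix",
    "kr_balance_dense",
    "kr_balance",
    "expected_by_distance",
    "oe",
    "compartment_pc1",
    "insulation_score",
    "directionality_index",
    "delta_di",
    "de_novo_boundaries",
    "moc",
    "ConcordanceResult",
    "cral_compartment_anova",
    "AnovaResult",
]


class SparseContactMatrix:
    """Binned contact counts over a genome-wide binning.

    Symmetric (DNA x DNA) matrices are stored upper-triangle; asymmetric
    (RNA x DNA) matrices store rows as RNA bins and columns as DNA bins.
    Optional per-bin balancing weights are attached after
    :func:`kr_balance`.
    """

    def __init__(
        self,
        assembly: GenomeAssembly,
        bin_size: int,
        symmetric: bool,
        mat: sp.spmatrix,
        weights: np.ndarray | None = None,
    ):
        n = assembly.total_bins(bin_size)
        if mat.shape != (n, n):
            raise ValueError(f"matrix shape {mat.shape} != ({n}, {n})")
        mat = mat.tocsr()
        if mat.nnz and mat.data.min() < 0:
            raise ValueError("contact counts must be non-negative")
        if symmetric:
            # canonicalise to upper triangle
            coo = mat.tocoo()
            r = np.minimum(coo.row, coo.col)
            c = np.maximum(coo.row, coo.col)
            mat = sp.coo_matrix((coo.data, (r, c)), shape=mat.shape).tocsr()
        self.assembly = assembly
        self.bin_size = bin_size
        self.symmetric = symmetric
        self.mat = mat
        self.weights = weights

    @property
    def mass(self) -> float:
        return float(self.mat.sum())

    def chrom_bins(self, chrom: str) -> slice:
        off = self.assembly.bin_offsets(self.bin_size)
        return slice(
            off[chrom], off[chrom] + self.assembly.n_bins(chrom, self.bin_size)
        )

    def cis_dense(self, chrom: str, balanced: bool = False) -> np.ndarray:
        """Dense cis block; symmetrised when the matrix is symmetric."""
        s = self.chrom_bins(chrom)
        block = self.mat[s, s].toarray()
        if self.symmetric:
            block = block + block.T - np.diag(np.diag(block))
        if balanced:
            if self.weights is None:
                raise ValueError("matrix has no balancing weights")
            w = self.weights[s]
            block = block * np.outer(w, w)
            block = np.nan_to_num(block)
        return block


# ---------------------------------------------------------------------------
# Knight-Ruiz balancing


def _kr_newton(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray | None:
    """Knight-Ruiz inner-outer Newton iteration for x with diag(x) A diag(x)
    doubly stochastic.  Returns None on non-convergence."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    rt = tol**2
    v = x * (A @ x)
    rk = 1 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    i = 0
    while rout > rt:
        i += 1
        if i > max_iter:
            return None
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta or ynew.max() >= Delta:
                if ynew.min() <= delta:
                    ind = ap < 0
                    gamma = np.min((delta - y[ind]) / ap[ind]) if ind.any() else 1.0
                else:
                    gamma = 1.0
                if ynew.max() >= Delta:
                    ind = ynew > Delta
                    gamma = min(gamma, np.min((Delta - y[ind]) / ap[ind]))
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 50:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        eta = max(min(g * rat, etamax), 0.5 * rt / max(rout, rt))
    return x


def _sinkhorn(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Iterative proportional scaling fallback (symmetric Sinkhorn)."""
    x = np.ones(A.shape[0])
    for _ in range(max_iter):
        s = A @ x * x
        x = x * np.sqrt(1.0 / np.where(s > 0, s, 1.0))
        err = np.max(np.abs(x * (A @ x) - 1))
        if err < tol:
            break
    return x


def kr_balance_dense(
    A: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    mask_percentile: float = 5.0,
) -> np.ndarray:
    """Balance a dense symmetric matrix; returns per-bin weights.

    Bins with zero marginal, and bins whose marginal falls below the
    ``mask_percentile``-th percentile of the nonzero marginals (a
    sparsity filter), receive NaN weights.  The balanced matrix
    ``w_i A_ij w_j`` has unit row sums over unmasked bins.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    marg = A.sum(axis=1)
    keep = marg > 0
    if keep.any() and mask_percentile > 0:
        cut = np.percentile(marg[keep], mask_percentile)
        keep &= marg >= cut
    w = np.full(n, np.nan)
    if keep.sum() == 0:
        return w
    sub = A[np.ix_(keep, keep)]
    if (sub.sum(axis=1) == 0).any():  # masking emptied some rows
        keep2 = sub.sum(axis=1) > 0
        idx = np.where(keep)[0][keep2]
        keep = np.zeros(n, bool)
        keep[idx] = True
        sub = A[np.ix_(keep, keep)]
    x = _kr_newton(sub, tol, max_iter)
    if x is None:
        warnings.warn("KR did not converge; falling back to iterative scaling")
        x = _sinkhorn(sub, tol, max_iter * 10)
    w[keep] = x
    return w


def kr_balance(
    matrix: SparseContactMatrix, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray:
    """Balance each chromosome's cis block; attaches and returns weights."""
    if not matrix.symmetric:
        raise ValueError("balancing requires a symmetric matrix")
    n = matrix.assembly.total_bins(matrix.bin_size)
    weights = np.full(n, np.nan)
    for chrom in matrix.assembly.names:
        s = matrix.chrom_bins(chrom)
        block = matrix.cis_dense(chrom)
        if block.sum() == 0:
            continue
        weights[s] = kr_balance_dense(block, tol=tol, max_iter=max_iter)
    matrix.weights = weights
    return weights


# ---------------------------------------------------------------------------
# Expected / observed


def expected_by_distance(
    matrix: SparseContactMatrix, chrom: str, balanced: bool = False
) -> np.ndarray:
    """Mean cis count at each bin distance d = 0..n-1 for one chromosome."""
    if not matrix.symmetric:
        raise ValueError("expected-by-distance requires a symmetric cis matrix")
    D = matrix.cis_dense(chrom, balanced=balanced)
    n = D.shape[0]
    exp = np.empty(n)
    for d in range(n):
        exp[d] = np.trace(D, offset=d) / (n - d)
    return exp


def oe(matrix: SparseContactMatrix, balanced: bool = False) -> SparseContactMatrix:
    """Observed/expected transform of every cis block.

    Entries where the distance-expected value is zero are left missing
    (absent from the sparse result).
    """
    asm = matrix.assembly
    n = asm.total_bins(matrix.bin_size)
    out = sp.lil_matrix((n, n))
    for chrom in asm.names:
        s = matrix.chrom_bins(chrom)
        D = matrix.cis_dense(chrom, balanced=balanced)
        exp = expected_by_distance(matrix, chrom, balanced=balanced)
        m = D.shape[0]
        dist = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(exp[dist] > 0, D / exp[dist], 0.0)
        out[s, s] = np.triu(ratio)
    return SparseContactMatrix(asm, matrix.bin_size, True, out.tocsr())


# ---------------------------------------------------------------------------
# Compartments


def compartment_pc1(
    matrix: SparseContactMatrix,
    orient_track: Track,
    balanced: bool = False,
    min_bins: int = 10,
) -> Track:
    """First eigenvector of the cis O/E correlation matrix, per chromosome.

    The sign is oriented so the eigenvector correlates positively with
    ``orient_track`` (gene density by default in the pipeline).
    Chromosomes with fewer than ``min_bins`` informative bins are
    skipped with a warning.
    """
    asm = matrix.assembly
    track = Track.full_missing(asm, matrix.bin_size)
    for chrom in asm.names:
        s = matrix.chrom_bins(chrom)
        D = matrix.cis_dense(chrom, balanced=balanced)
        exp = expected_by_distance(matrix, chrom, balanced=balanced)
        m = D.shape[0]
        dist = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.where(exp[dist] > 0, D / exp[dist], np.nan)
        marg = D.sum(axis=1)
        good = (marg > 0) & (np.nanstd(np.nan_to_num(R), axis=0) > 0)
        sub = R[np.ix_(good, good)]
        sub = np.nan_to_num(sub, nan=0.0)
        if good.sum() < min_bins or np.allclose(sub.std(axis=0), 0):
            warnings.warn(f"{chrom}: too few informative bins for PC1; skipped")
            continue
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(sub, rowvar=False)
        C = np.nan_to_num(C)
        vals, vecs = np.linalg.eigh(C)
        pc1 = vecs[:, -1]
        ref = orient_track.values[s][good]
        ok = np.isfinite(ref)
        if ok.sum() >= 2 and np.std(pc1[ok]) > 0 and np.std(ref[ok]) > 0:
            if np.corrcoef(pc1[ok], ref[ok])[0, 1] < 0:
                pc1 = -pc1
        vals_out = np.full(m, np.nan)
        vals_out[good] = pc1
        track.values[s] = vals_out
    return track


# ---------------------------------------------------------------------------
# Insulation and directionality


def insulation_score(
    matrix: SparseContactMatrix, window_bins: int, balanced: bool = False
) -> Track:
    """Crane-style insulation: mean contact flux across each bin.

    Raw score at bin i is the mean of the square window
    [i-w, i) x (i, i+w]; reported values are log2(raw / chromosome mean
    raw).  Bins within w of either chromosome end are missing.
    """
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    asm = matrix.assembly
    track = Track.full_missing(asm, matrix.bin_size)
    w = window_bins
    for chrom in asm.names:
        s = matrix.chrom_bins(chrom)
        D = matrix.cis_dense(chrom, balanced=balanced)
        n = D.shape[0]
        raw = np.full(n, np.nan)
        for i in range(w, n - w):
            raw[i] = D[i - w : i, i + 1 : i + w + 1].mean()
        mean_raw = np.nanmean(raw) if np.isfinite(raw).any() else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2(raw / mean_raw) if mean_raw and mean_raw > 0 else raw * np.nan
        track.values[s] = vals
    return track


def directionality_index(
    matrix: SparseContactMatrix, window_bins: int, balanced: bool = False
) -> Track:
    """Dixon directionality index per bin.

    With A = contacts to the upstream window and B = downstream,
    E = (A+B)/2:  DI = sign(B-A) * ((A-E)^2/E + (B-E)^2/E); 0 when both
    windows are empty.  Edge bins (incomplete windows) are missing.
    """
    asm = matrix.assembly
    track = Track.full_missing(asm, matrix.bin_size)
    w = window_bins
    for chrom in asm.names:
        s = matrix.chrom_bins(chrom)
        D = matrix.cis_dense(chrom, balanced=balanced)
        n = D.shape[0]
        vals = np.full(n, np.nan)
        for i in range(w, n - w):
            A = D[i, i - w : i].sum()
            B = D[i, i + 1 : i + w + 1].sum()
            if A == 0 and B == 0:
                vals[i] = 0.0
                continue
            E = (A + B) / 2
            di = (A - E) ** 2 / E + (B - E) ** 2 / E
            vals[i] = np.sign(B - A) * di
        track.values[s] = vals
    return track


def delta_di(track_a: Track, track_b: Track, chrom: str, pos: int) -> float:
    """Insulation change at a site between two conditions.

    The site's flanking bins are the last bin fully upstream and the
    first bin fully downstream of ``pos``; for each condition the local
    directionality contrast is |DI(down) - DI(up)| and delta_DI is the
    condition-b contrast minus the condition-a contrast.
    """
    if track_a.bin_size != track_b.bin_size:
        raise ValueError("tracks must share a binning")
    bs = track_a.bin_size
    b = pos // bs
    up = b - 1
    down = b if pos % bs == 0 else b + 1
    off = track_a.assembly.bin_offsets(bs)[chrom]

    def contrast(t: Track) -> float:
        return abs(t.values[off + down] - t.values[off + up])

    return contrast(track_b) - contrast(track_a)


# ---------------------------------------------------------------------------
# TAD-partition comparisons


def de_novo_boundaries(
    tads_wt: TADSet, tads_ki: TADSet, tol_bp: int
) -> list[tuple[str, int]]:
    """Boundaries present in the KI partition but absent from WT.

    A KI boundary within ``tol_bp`` of any WT boundary on the same
    chromosome counts as matched (not de novo).
    """
    wt = {}
    for chrom, pos in tads_wt.boundaries():
        wt.setdefault(chrom, []).append(pos)
    out = []
    for chrom, pos in tads_ki.boundaries():
        ref = wt.get(chrom, [])
        if not any(abs(pos - r) <= tol_bp for r in ref):
            out.append((chrom, pos))
    return out


@dataclass(frozen=True)
class ConcordanceResult:
    moc: float
    n_a: int
    n_b: int


def moc(tads_a: TADSet, tads_b: TADSet) -> ConcordanceResult:
    """Measure of Concordance between two TAD partitions, in [0, 1].

    MoC = 1 when both partitions consist of a single domain; otherwise

        MoC = (1 / (sqrt(N_A * N_B) - 1)) *
              (sum_{i,j} |A_i ∩ B_j|^2 / (|A_i| * |B_j|) - 1)

    with domain lengths in bp.  Identical partitions score exactly 1.
    """
    A = tads_a.domains()
    B = tads_b.domains()
    if not A or not B:
        raise ValueError("MoC requires non-empty TAD sets")
    na, nb = len(A), len(B)
    if na == 1 and nb == 1:
        return ConcordanceResult(1.0, na, nb)
    total = 0.0
    by_chrom: dict[str, list] = {}
    for b in B:
        by_chrom.setdefault(b.chrom, []).append(b)
    for a in A:
        for b in by_chrom.get(a.chrom, []):
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov > 0:
                total += ov * ov / (len(a) * len(b))
    value = (total - 1.0) / (np.sqrt(na * nb) - 1.0)
    return ConcordanceResult(float(np.clip(value, 0.0, 1.0)), na, nb)


# ---------------------------------------------------------------------------
# cRAL vs compartment ANOVA


@dataclass(frozen=True)
class AnovaResult:
    mean_a: float
    mean_b: float
    f_stat: float
    p_value: float
    n_a: int
    n_b: int


def cral_compartment_anova(cral: Track, pc1: Track) -> AnovaResult:
    """One-way ANOVA of cRAL between A (PC1 > 0) and B (PC1 < 0) bins."""
    if cral.bin_size != pc1.bin_size:
        raise ValueError("tracks must be on the same binning")
    x, y = cral.values, pc1.values
    ok = np.isfinite(x) & np.isfinite(y) & (y != 0)
    a = x[ok & (y > 0)]
    b = x[ok & (y < 0)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each compartment group needs at least 2 bins")
    f, p = stats.f_oneway(a, b)
    return AnovaResult(float(a.mean()), float(b.mean()), float(f), float(p),
                       len(a), len(b))
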