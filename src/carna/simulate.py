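"""Seeded generators for RNA-DNA contact pairs and Hi-C matrices.

The generators plant known structure — RNA-association domains, TAD
boundary insulation of RNA-DNA contacts, distance-decay Hi-C with
loops, A/B compartments, and an anti-coupling between loop strength and
between-anchor caRNA — so every pipeline stage can be tested against
ground truth.

Model sketch
------------
Each contact pair picks an RNA source (a gene, a planted domain source,
or a loop-interior caRNA element) and draws its DNA end from a
two-sided exponential displacement with decay scale ``d0``; every TAD
boundary between the two ends independently thins the read with
probability 1 - beta (rejected draws are redrawn, capped).  A fraction
``tau`` of gene reads instead lands uniformly in A-compartment bins
genome-wide.  Hi-C counts are Poisson draws from a 1/(1+d) distance
decay modulated by within-TAD enclosure, a compartment checkerboard,
and per-loop pixel enrichment lambda_eff = 1 + (lambda - 1) *
exp(-gamma * ita), where ita is the loop's planted between-anchor caRNA
intensity — gamma > 0 therefore suppresses loops sitting on caRNA-rich
interiors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contacts import PairSet
from .genome import (
    GenomeAssembly,
    Gene,
    GenomicInterval,
    Loop,
    RepeatElement,
    TADSet,
)
from .matrix import SparseContactMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_pairs",
    "simulate_hic",
    "default_config",
    "rnase_config",
    "small_boundary_config",
    "make_fixture_suite",
]


@dataclass
class SimConfig:
    """Full description of one simulated condition."""

    assembly: GenomeAssembly
    genes: list[Gene]
    gene_weights: np.ndarray
    tads: TADSet
    beta: dict[tuple[str, int], float]  # per-boundary crossing prob
    beta_default: float
    loops: list[Loop]
    loop_lambda: np.ndarray  # pixel enrichment, >= 1
    loop_ita: np.ndarray  # planted between-anchor caRNA intensity, >= 0
    loop_sources: list[GenomicInterval]  # caRNA element per loop (or None)
    domain_sources: list[GenomicInterval]
    domain_targets: list[GenomicInterval]
    d0: float = 200_000.0
    tau: float = 0.05
    a_labels: np.ndarray | None = None  # bool per compartment bin (global)
    compartment_bin_size: int = 500_000
    n_pairs: int = 100_000
    gene_fraction: float = 0.55
    domain_fraction: float = 0.15
    loop_carna_fraction: float = 0.25
    noise_fraction: float = 0.05
    domain_target_prob: float = 0.7
    domain_target_scale: float = 8_000.0
    hic_reads: int = 5_000_000
    hic_bin_size: int = 10_000
    tad_enclosure: float = 2.0
    compartment_strength: float = 0.3
    gamma: float = 0.0
    seed: int = 0
    max_retries: int = 50
    condition: str = "sim"

    def __post_init__(self) -> None:
        if not (0 < self.beta_default <= 1):
            raise ValueError("beta must lie in (0, 1]")
        for b in self.beta.values():
            if not (0 < b <= 1):
                raise ValueError("beta must lie in (0, 1]")
        if (np.asarray(self.loop_lambda) < 1).any():
            raise ValueError("loop lambda must be >= 1")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if not (0 <= self.tau <= 1):
            raise ValueError("tau must lie in [0, 1]")
        for g in self.genes:
            g.interval.validate(self.assembly)

    def lambda_eff(self, gamma: float | None = None) -> np.ndarray:
        g = self.gamma if gamma is None else gamma
        lam = np.asarray(self.loop_lambda, dtype=float)
        ita = np.asarray(self.loop_ita, dtype=float)
        return 1.0 + (lam - 1.0) * np.exp(-g * ita)


@dataclass
class GroundTruth:
    """Planted structure of a simulated condition."""

    domain_sources: list[GenomicInterval]
    domain_targets: list[GenomicInterval]
    boundary_beta: dict[tuple[str, int], float]
    loops: list[Loop]
    loop_lambda: np.ndarray
    loop_lambda_eff: np.ndarray
    loop_ita: np.ndarray
    loop_sources: list[GenomicInterval]
    a_labels: np.ndarray | None
    seed: int


def ground_truth(config: SimConfig) -> GroundTruth:
    return GroundTruth(
        domain_sources=list(config.domain_sources),
        domain_targets=list(config.domain_targets),
        boundary_beta={
            (c, p): config.beta.get((c, p), config.beta_default)
            for c, p in config.tads.boundaries()
        },
        loops=list(config.loops),
        loop_lambda=np.asarray(config.loop_lambda, dtype=float),
        loop_lambda_eff=config.lambda_eff(),
        loop_ita=np.asarray(config.loop_ita, dtype=float),
        loop_sources=list(config.loop_sources),
        a_labels=config.a_labels,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Pair simulation


def _boundary_tables(config: SimConfig):
    """Per-chromosome sorted boundary positions and cumulative log beta."""
    tables = {}
    for chrom in config.assembly.names:
        bnds = [p for c, p in config.tads.boundaries(chrom)]
        bnds.sort()
        betas = np.array(
            [config.beta.get((chrom, p), config.beta_default) for p in bnds]
        )
        cum = np.concatenate([[0.0], np.cumsum(np.log(betas))]) if bnds else np.zeros(1)
        tables[chrom] = (np.array(bnds, dtype=np.int64), cum)
    return tables


def _crossing_prob(tables, chroms, lo, hi):
    out = np.ones(len(lo))
    for chrom in np.unique(chroms):
        m = chroms == chrom
        bnds, cum = tables[chrom]
        if len(bnds) == 0:
            continue
        i0 = np.searchsorted(bnds, lo[m], side="right")
        i1 = np.searchsorted(bnds, hi[m], side="right")
        out[m] = np.exp(cum[i1] - cum[i0])
    return out


def _thinned_reads(rng, config, tables, n: int, propose) -> dict:
    """Sample ``n`` whole reads under boundary thinning.

    ``propose(rng, k)`` draws k candidate reads as a dict of arrays with
    at least ``chrom``, ``rna`` and ``dna``.  A candidate crossing TAD
    boundaries survives with the product of the crossed boundaries'
    beta; rejected candidates are discarded and whole new reads are
    drawn, so accepted reads are i.i.d. from the conditional law.
    After ``max_retries`` rounds any shortfall is filled with
    boundary-confined reads (DNA end clamped to the RNA end's
    position), which the proximity filter later removes.
    """
    kept: list[dict] = []
    remaining = n
    for _ in range(config.max_retries):
        if remaining == 0:
            break
        cand = propose(rng, remaining)
        lengths = np.array(
            [config.assembly.length(c) for c in cand["chrom"]], dtype=np.int64
        )
        valid = (cand["dna"] >= 0) & (cand["dna"] < lengths)
        lo = np.minimum(cand["rna"], cand["dna"])
        hi = np.maximum(cand["rna"], cand["dna"])
        pacc = _crossing_prob(tables, cand["chrom"], lo, hi)
        accept = valid & (rng.random(remaining) < pacc)
        kept.append({k: v[accept] for k, v in cand.items()})
        remaining = int((~accept).sum())
    if remaining:
        cand = propose(rng, remaining)
        cand["dna"] = cand["rna"].copy()
        kept.append(cand)
    return {k: np.concatenate([d[k] for d in kept]) for k in kept[0]}


def _two_sided_exponential(rng, scale: float, size: int) -> np.ndarray:
    mag = rng.exponential(scale, size)
    sign = rng.integers(0, 2, size) * 2 - 1
    return np.round(mag * sign).astype(np.int64)


def simulate_pairs(config: SimConfig) -> tuple[PairSet, GroundTruth]:
    """Simulate an iMARGI-like pair set with planted structure.

    Reads split into four classes by the configured fractions: gene
    background (exponential spreading, ``tau`` trans), domain reads
    (concentrated on the planted DNA target), loop-interior caRNA, and
    uniform noise.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tables = _boundary_tables(config)
    asm = config.assembly
    n = config.n_pairs

    has_loop_carna = (
        len(config.loop_sources) > 0 and np.asarray(config.loop_ita).sum() > 0
    )
    n_domain = round(n * config.domain_fraction) if config.domain_sources else 0
    n_loop = round(n * config.loop_carna_fraction) if has_loop_carna else 0
    n_noise = round(n * config.noise_fraction)
    n_gene = n - n_domain - n_loop - n_noise
    if n_gene < 0:
        raise ValueError("read-class fractions exceed 1")

    frames = []

    # -- gene background reads
    if n_gene > 0 and config.genes:
        n_trans = int(rng.binomial(n_gene, config.tau)) if config.tau > 0 else 0
        n_cis = n_gene - n_trans
        w = np.asarray(config.gene_weights, dtype=float)
        p_gene = w / w.sum()
        g_chrom = np.array([g.interval.chrom for g in config.genes])
        g_start = np.array([g.interval.start for g in config.genes], dtype=np.int64)
        g_len = np.array([len(g.interval) for g in config.genes], dtype=np.int64)
        g_strand = np.array([g.strand for g in config.genes])

        if n_cis > 0:
            def propose_gene(rng_, k):
                gi = rng_.choice(len(config.genes), k, p=p_gene)
                rna = g_start[gi] + rng_.integers(0, g_len[gi])
                dna = rna + _two_sided_exponential(rng_, config.d0, k)
                return {
                    "chrom": g_chrom[gi], "rna": rna, "dna": dna,
                    "strand": g_strand[gi],
                }

            reads = _thinned_reads(rng, config, tables, n_cis, propose_gene)
            frames.append(
                pd.DataFrame(
                    {
                        "rna_chrom": reads["chrom"], "rna_pos": reads["rna"],
                        "rna_strand": reads["strand"],
                        "dna_chrom": reads["chrom"], "dna_pos": reads["dna"],
                        "dna_strand": np.where(rng.random(n_cis) < 0.5, "+", "-"),
                    }
                )
            )
        # trans/long-range: uniform over A-labelled bins genome-wide
        if n_trans > 0:
            if config.a_labels is None:
                raise ValueError("tau > 0 requires A-compartment labels")
            gi = rng.choice(len(config.genes), n_trans, p=p_gene)
            rna = g_start[gi] + rng.integers(0, g_len[gi])
            a_bins = np.where(config.a_labels)[0]
            pick = rng.choice(a_bins, n_trans)
            table = asm.bin_table(config.compartment_bin_size)
            bch = np.array([table[b][0] for b in pick])
            bst = np.array([table[b][1] for b in pick], dtype=np.int64)
            ben = np.array([table[b][2] for b in pick], dtype=np.int64)
            frames.append(
                pd.DataFrame(
                    {
                        "rna_chrom": g_chrom[gi], "rna_pos": rna,
                        "rna_strand": g_strand[gi],
                        "dna_chrom": bch,
                        "dna_pos": bst + rng.integers(0, ben - bst),
                        "dna_strand": np.where(rng.random(n_trans) < 0.5, "+", "-"),
                    }
                )
            )

    # -- domain reads: RNA in the 5 kb source, DNA concentrated on the target
    if n_domain > 0:
        d_chrom = np.array([iv.chrom for iv in config.domain_sources])
        d_start = np.array([iv.start for iv in config.domain_sources], dtype=np.int64)
        d_len = np.array([len(iv) for iv in config.domain_sources], dtype=np.int64)
        t_center = np.array(
            [(iv.start + iv.end) // 2 for iv in config.domain_targets],
            dtype=np.int64,
        )

        def propose_domain(rng_, k):
            di = rng_.integers(0, len(config.domain_sources), k)
            rna = d_start[di] + rng_.integers(0, d_len[di])
            on_target = rng_.random(k) < config.domain_target_prob
            dna = np.where(
                on_target,
                t_center[di]
                + np.round(rng_.laplace(0, config.domain_target_scale, k)).astype(
                    np.int64
                ),
                rna + _two_sided_exponential(rng_, config.d0, k),
            )
            return {"chrom": d_chrom[di], "rna": rna, "dna": dna}

        reads = _thinned_reads(rng, config, tables, n_domain, propose_domain)
        frames.append(
            pd.DataFrame(
                {
                    "rna_chrom": reads["chrom"], "rna_pos": reads["rna"],
                    "rna_strand": np.full(n_domain, "+"),
                    "dna_chrom": reads["chrom"], "dna_pos": reads["dna"],
                    "dna_strand": np.where(rng.random(n_domain) < 0.5, "+", "-"),
                }
            )
        )

    # -- loop-interior caRNA: RNA in the loop's caRNA element, DNA between anchors
    if n_loop > 0:
        ita = np.asarray(config.loop_ita, dtype=float)
        p_loop = ita / ita.sum()
        s_chrom = np.array([iv.chrom for iv in config.loop_sources])
        s_start = np.array([iv.start for iv in config.loop_sources], dtype=np.int64)
        s_len = np.array([len(iv) for iv in config.loop_sources], dtype=np.int64)
        b_start = np.array([lp.anchor1.end for lp in config.loops], dtype=np.int64)
        b_end = np.array([lp.anchor2.start for lp in config.loops], dtype=np.int64)

        def propose_loop(rng_, k):
            li = rng_.choice(len(config.loops), k, p=p_loop)
            rna = s_start[li] + rng_.integers(0, s_len[li])
            dna = b_start[li] + rng_.integers(0, b_end[li] - b_start[li])
            return {"chrom": s_chrom[li], "rna": rna, "dna": dna}

        reads = _thinned_reads(rng, config, tables, n_loop, propose_loop)
        chroms, rna, dna = reads["chrom"], reads["rna"], reads["dna"]
        frames.append(
            pd.DataFrame(
                {
                    "rna_chrom": chroms, "rna_pos": rna,
                    "rna_strand": np.full(n_loop, "+"),
                    "dna_chrom": chroms, "dna_pos": dna,
                    "dna_strand": np.where(rng.random(n_loop) < 0.5, "+", "-"),
                }
            )
        )

    # -- uniform noise
    if n_noise > 0:
        lens = np.array([asm.length(c) for c in asm.names], dtype=float)
        cidx = rng.choice(len(asm.names), n_noise, p=lens / lens.sum())
        chroms = np.array([asm.names[i] for i in cidx])
        clen = np.array([asm.length(c) for c in chroms], dtype=np.int64)
        rna = rng.integers(0, clen)
        dna = rng.integers(0, clen)
        frames.append(
            pd.DataFrame(
                {
                    "rna_chrom": chroms, "rna_pos": rna,
                    "rna_strand": np.where(rng.random(n_noise) < 0.5, "+", "-"),
                    "dna_chrom": chroms, "dna_pos": dna,
                    "dna_strand": np.where(rng.random(n_noise) < 0.5, "+", "-"),
                }
            )
        )

    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = PairSet.empty_frame()
    return PairSet(df, asm, config.condition), ground_truth(config)


# ---------------------------------------------------------------------------
# Hi-C simulation


def simulate_hic(
    config: SimConfig,
    bin_size: int | None = None,
    gamma: float | None = None,
) -> tuple[SparseContactMatrix, GroundTruth]:
    """Poisson Hi-C with distance decay, TADs, compartments and loops.

    The cis rate at bin distance d is proportional to 1/(1+d),
    multiplied by the within-TAD enclosure factor, the compartment
    checkerboard (same-label bins up, cross-label down), and per-loop
    pixel enrichment lambda_eff (the 3x3 neighborhood at half
    strength).  Rates are scaled so the expected genome-wide total is
    ``config.hic_reads``; counts are Poisson, seeded.
    """
    bs = bin_size if bin_size is not None else config.hic_bin_size
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    asm = config.assembly
    lam_eff = config.lambda_eff(gamma)

    rates = {}
    total = 0.0
    for chrom in asm.names:
        nb = asm.n_bins(chrom, bs)
        idx = np.arange(nb)
        D = np.abs(np.subtract.outer(idx, idx))
        rate = 1.0 / (1.0 + D)

        # within-TAD enclosure
        tid = np.full(nb, -1)
        for t, iv in enumerate(config.tads.domains(chrom)):
            tid[iv.start // bs : -(-iv.end // bs)] = t
        same_tad = (tid[:, None] == tid[None, :]) & (tid[:, None] >= 0)
        rate[same_tad] *= config.tad_enclosure

        # compartment checkerboard
        if config.a_labels is not None and config.compartment_strength > 0:
            off = asm.bin_offsets(config.compartment_bin_size)[chrom]
            centers = idx * bs + bs // 2
            comp = config.a_labels[off + centers // config.compartment_bin_size]
            same = comp[:, None] == comp[None, :]
            rate *= np.where(same, 1 + config.compartment_strength,
                             1 - config.compartment_strength)

        # loops
        factor = np.ones_like(rate)
        for k, lp in enumerate(config.loops):
            if lp.chrom != chrom:
                continue
            i = ((lp.anchor1.start + lp.anchor1.end) // 2) // bs
            j = ((lp.anchor2.start + lp.anchor2.end) // 2) // bs
            if i >= nb or j >= nb:
                continue
            le = lam_eff[k]
            sl_i = slice(max(0, i - 1), min(nb, i + 2))
            sl_j = slice(max(0, j - 1), min(nb, j + 2))
            factor[sl_i, sl_j] = np.maximum(factor[sl_i, sl_j], 1 + (le - 1) / 2)
            factor[i, j] = max(factor[i, j], le)
            factor[sl_j, sl_i] = factor[sl_i, sl_j].T  # keep symmetric
            factor[j, i] = factor[i, j]
        rate *= factor

        rate = np.triu(rate)
        rates[chrom] = rate
        total += rate.sum()

    scale = config.hic_reads / total
    n = asm.total_bins(bs)
    rows, cols, data = [], [], []
    offsets = asm.bin_offsets(bs)
    for chrom in asm.names:
        counts = rng.poisson(rates[chrom] * scale)
        r, c = np.nonzero(counts)
        rows.append(r + offsets[chrom])
        cols.append(c + offsets[chrom])
        data.append(counts[r, c])
    mat = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return SparseContactMatrix(asm, bs, True, mat), ground_truth(config)


# ---------------------------------------------------------------------------
# Canonical scenario


def default_config(seed: int = 7, **overrides) -> SimConfig:
    """The canonical Control-like small scenario.

    Two 20 Mb chromosomes; 2.5 Mb alternating A/B compartment blocks;
    10 abutting 1.8 Mb TADs per chromosome (9 boundaries each); 40
    background genes placed in A blocks; 50 planted RNA-association
    domains (5 kb source, 20 kb DNA target at a fixed offset); 60 loops
    (10 kb anchors, 1-1.6 Mb spans, lambda = 5) of which every other
    one carries between-anchor caRNA (planted ITA 2) transcribed from a
    5 kb HERV-H element; CBS classes cycle convergent / non-convergent /
    none.
    """
    L = 20_000_000
    asm = GenomeAssembly.from_dict({"chr1": L, "chr2": L})

    # compartments: blocks of 5 x 500 kb bins, alternating, A first
    comp_bs = 500_000
    labels = []
    for _ in asm.names:
        per = asm.n_bins("chr1", comp_bs)
        labels.append((np.arange(per) // 5) % 2 == 0)
    a_labels = np.concatenate(labels)

    # TADs: 10 abutting 1.8 Mb domains per chromosome
    tads = TADSet(
        [
            GenomicInterval(c, 1_000_000 + k * 1_800_000, 1_000_000 + (k + 1) * 1_800_000)
            for c in asm.names
            for k in range(10)
        ]
    )

    # genes: 100 kb wide, 3 per A block and 2 per B block (mild A bias
    # keeps gene density usable for PC1 orientation)
    genes = []
    for c in asm.names:
        gi = 0
        for block in range(8):  # 2.5 Mb blocks; even = A
            bstart = block * 5 * comp_bs
            per = 3 if block % 2 == 0 else 2
            for j in range(per):
                s = bstart + 300_000 + j * 700_000
                genes.append(
                    Gene(f"G_{c}_{gi}", GenomicInterval(c, s, s + 100_000),
                         "+" if gi % 2 == 0 else "-")
                )
                gi += 1
    gene_weights = np.ones(len(genes))

    # planted domains: 25 per chromosome on a 720 kb grid
    domain_sources, domain_targets = [], []
    for c in asm.names:
        for k in range(25):
            s = 1_200_000 + k * 720_000
            domain_sources.append(GenomicInterval(c, s, s + 5_000))
            off = (50_000, 150_000, 250_000, -100_000, -200_000)[k % 5]
            tc = s + 2_500 + off
            domain_targets.append(GenomicInterval(c, tc - 10_000, tc + 10_000))

    # loops: 3 per TAD (30 per chromosome), nested inside their TAD so
    # interior caRNA is not cut by boundary thinning; spans 1.0/1.3/1.6 Mb
    loops, lam, ita, loop_sources = [], [], [], []
    for c in asm.names:
        for k in range(30):
            t, j = divmod(k, 3)
            tad_start = 1_000_000 + t * 1_800_000
            a1 = tad_start + 60_000 + j * 40_000
            span = (1_000_000, 1_300_000, 1_600_000)[j]
            loops.append(
                Loop(
                    GenomicInterval(c, a1, a1 + 10_000),
                    GenomicInterval(c, a1 + span, a1 + span + 10_000),
                    10_000,
                )
            )
            lam.append(5.0)
            high = k % 2 == 1  # every other loop carries interior caRNA
            ita.append(2.0 if high else 0.0)
            # offset keeps caRNA elements clear of the domain-source grid
            hs = a1 + 10_000 + 260_000
            loop_sources.append(GenomicInterval(c, hs, hs + 5_000))

    cfg = SimConfig(
        assembly=asm,
        genes=genes,
        gene_weights=gene_weights,
        tads=tads,
        beta={},
        beta_default=0.3,
        loops=loops,
        loop_lambda=np.array(lam),
        loop_ita=np.array(ita),
        loop_sources=loop_sources,
        domain_sources=domain_sources,
        domain_targets=domain_targets,
        a_labels=a_labels,
        compartment_bin_size=comp_bs,
        gamma=1.5,
        seed=seed,
        condition="Control",
    )
    return replace(cfg, **overrides) if overrides else cfg


def cbs_sites(config: SimConfig) -> list[tuple[GenomicInterval, str]]:
    """Planted CTCF motif sites realising cycling CBS classes.

    Loop k (within its chromosome) is convergent for k % 3 == 0,
    non-convergent for k % 3 == 1, and has no sites for k % 3 == 2.
    """
    sites = []
    per_chrom: dict[str, int] = {}
    for lp in config.loops:
        k = per_chrom.get(lp.chrom, 0)
        per_chrom[lp.chrom] = k + 1
        a1 = GenomicInterval(lp.chrom, lp.anchor1.start + 4_000, lp.anchor1.start + 4_020)
        a2 = GenomicInterval(lp.chrom, lp.anchor2.start + 4_000, lp.anchor2.start + 4_020)
        if k % 3 == 0:
            sites.append((a1, "+"))
            sites.append((a2, "-"))
        elif k % 3 == 1:
            sites.append((a1, "-"))
            sites.append((a2, "+"))
    return sites


def planted_cbs_classes(config: SimConfig) -> list[str]:
    out = []
    per_chrom: dict[str, int] = {}
    for lp in config.loops:
        k = per_chrom.get(lp.chrom, 0)
        per_chrom[lp.chrom] = k + 1
        out.append(("convergent", "non-convergent", "none")[k % 3])
    return out


def repeat_annotation(config: SimConfig) -> list[RepeatElement]:
    """HERV-H elements at the loop caRNA sources plus scattered Alu/L1."""
    reps = [
        RepeatElement(src, "HERV-H")
        for src, w in zip(config.loop_sources, config.loop_ita)
        if w > 0
    ]
    for c in config.assembly.names:
        L = config.assembly.length(c)
        for k in range(50):
            s = 137_000 + k * 390_000
            if s + 300 < L:
                reps.append(RepeatElement(GenomicInterval(c, s, s + 300), "Alu"))
        for k in range(30):
            s = 310_000 + k * 640_000
            if s + 1_000 < L:
                reps.append(RepeatElement(GenomicInterval(c, s, s + 1_000), "L1"))
    return reps


def rnase_config(base: SimConfig, seed_offset: int = 1) -> SimConfig:
    """RNase-like condition: caRNA thinned 10x, weaker boundary thinning
    of RNA-DNA contacts, and no caRNA-loop coupling (gamma = 0)."""
    return replace(
        base,
        n_pairs=base.n_pairs // 10,
        beta_default=min(1.0, base.beta_default * 2),
        gamma=0.0,
        seed=base.seed + seed_offset,
        condition="RNase",
    )


def condition_loop_sets(config: SimConfig, min_lambda: float = 2.5):
    """Which planted loops are 'called' in each condition.

    A loop belongs to a condition when its effective pixel enrichment
    under that condition's gamma exceeds ``min_lambda``; with coupling
    on, caRNA-rich loops are suppressed in Control and emerge after
    RNase.
    """
    from .loops import LoopSet

    ctrl = [lp for lp, le in zip(config.loops, config.lambda_eff()) if le >= min_lambda]
    rnase = [
        lp for lp, le in zip(config.loops, config.lambda_eff(0.0)) if le >= min_lambda
    ]
    return LoopSet(ctrl, "Control"), LoopSet(rnase, "RNase")


# ---------------------------------------------------------------------------
# Fixture suite


def make_fixture_suite(out_dir, seed: int = 7) -> dict[str, str]:
    """Write the canonical two-condition scenario to ``out_dir``.

    Emits ``.pairs`` for both conditions, gene/TAD/CTCF/repeat BED
    files, per-condition loop BEDPE, Hi-C matrices as MTX plus a bin
    table, a chrom.sizes file and a ground-truth TSV.  Byte-identical
    for identical seeds.
    """
    from scipy.io import mmwrite

    from . import io as cio
    from .io import write_bed, write_bedpe, write_pairs

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed)
    rcfg = rnase_config(cfg)
    paths: dict[str, str] = {}

    with open(out / "chrom.sizes", "w") as fh:
        for c in cfg.assembly.names:
            fh.write(f"{c}\t{cfg.assembly.length(c)}\n")
    paths["chromsizes"] = str(out / "chrom.sizes")

    for label, c in (("control", cfg), ("rnase", rcfg)):
        ps, _ = simulate_pairs(c)
        p = out / f"{label}.pairs"
        write_pairs(ps, p)
        paths[f"{label}_pairs"] = str(p)
        mat, _ = simulate_hic(c)
        mp = out / f"hic_{label}.mtx"
        mmwrite(str(mp), mat.mat)
        paths[f"hic_{label}"] = str(mp)

    with open(out / "bins.bed", "w") as fh:
        for chrom, s, e in cfg.assembly.bin_table(cfg.hic_bin_size):
            fh.write(f"{chrom}\t{s}\t{e}\n")
    paths["bins"] = str(out / "bins.bed")

    with open(out / "genes.bed6", "w") as fh:
        for g in cfg.genes:
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t"
                f"{g.id}\t0\t{g.strand}\n"
            )
    paths["genes"] = str(out / "genes.bed6")

    write_bed(cfg.tads.domains(), out / "tads.bed")
    paths["tads"] = str(out / "tads.bed")

    with open(out / "ctcf.bed6", "w") as fh:
        for iv, strand in cbs_sites(cfg):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tCBS\t0\t{strand}\n")
    paths["ctcf"] = str(out / "ctcf.bed6")

    with open(out / "repeats.bed", "w") as fh:
        for rep in sorted(repeat_annotation(cfg), key=lambda r: (r.interval.chrom, r.interval.start)):
            fh.write(
                f"{rep.interval.chrom}\t{rep.interval.start}\t"
                f"{rep.interval.end}\t{rep.family}\n"
            )
    paths["repeats"] = str(out / "repeats.bed")

    ctrl_loops, rnase_loops = condition_loop_sets(cfg)
    write_bedpe(list(ctrl_loops), out / "loops_control.bedpe")
    write_bedpe(list(rnase_loops), out / "loops_rnase.bedpe")
    paths["loops_control"] = str(out / "loops_control.bedpe")
    paths["loops_rnase"] = str(out / "loops_rnase.bedpe")

    gt = ground_truth(cfg)
    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write("kind\tchrom\tstart\tend\tvalue\n")
        for iv in gt.domain_sources:
            fh.write(f"domain_source\t{iv.chrom}\t{iv.start}\t{iv.end}\t.\n")
        for iv in gt.domain_targets:
            fh.write(f"domain_target\t{iv.chrom}\t{iv.start}\t{iv.end}\t.\n")
        for (c, p), b in sorted(gt.boundary_beta.items()):
            fh.write(f"boundary\t{c}\t{p}\t{p}\t{b:g}\n")
        for lp, le, it in zip(gt.loops, gt.loop_lambda_eff, gt.loop_ita):
            fh.write(
                f"loop\t{lp.chrom}\t{lp.anchor1.start}\t{lp.anchor2.end}\t"
                f"lambda_eff={le:.4g};ita={it:g}\n"
            )
        fh.write(f"seed\t.\t0\t0\t{seed}\n")
    paths["ground_truth"] = str(out / "ground_truth.tsv")
    return paths


# ---------------------------------------------------------------------------
# Small helper scenario for boundary null/recovery studies


def small_boundary_config(
    seed: int, beta: float, n_pairs: int = 4_000
) -> SimConfig:
    """One 4 Mb chromosome with a single TAD boundary at 2 Mb.

    Two 300 kb genes flank the boundary so plenty of reads fall in the
    +/- 500 kb classification window; no loops, domains or trans reads.
    """
    asm = GenomeAssembly.from_dict({"chr1": 4_000_000})
    tads = TADSet(
        [
            GenomicInterval("chr1", 500_000, 2_000_000),
            GenomicInterval("chr1", 2_000_000, 3_500_000),
        ]
    )
    genes = [
        Gene("gL", GenomicInterval("chr1", 1_550_000, 1_850_000), "+"),
        Gene("gR", GenomicInterval("chr1", 2_150_000, 2_450_000), "-"),
    ]
    return SimConfig(
        assembly=asm,
        genes=genes,
        gene_weights=np.ones(2),
        tads=tads,
        beta={},
        beta_default=beta,
        loops=[],
        loop_lambda=np.array([]),
        loop_ita=np.array([]),
        loop_sources=[],
        domain_sources=[],
        domain_targets=[],
        d0=200_000.0,
        tau=0.0,
        a_labels=None,
        n_pairs=n_pairs,
        gene_fraction=1.0,
        domain_fraction=0.0,
        loop_carna_fraction=0.0,
        noise_fraction=0.0,
        seed=seed,
        condition=f"beta{beta:g}",
    )
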