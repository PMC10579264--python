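import numpy as np
import pytest

from carna import contacts, simulate
from carna.genome import GenomeAssembly, GenomicInterval
from carna.contacts import PairSet, ContactPair


@pytest.fixture(scope="session")
def asm_small() -> GenomeAssembly:
    return GenomeAssembly.from_dict({"chr1": 1_000_000, "chr2": 500_000})


def make_pairs(asm, rows, condition="test"):
    """rows: (rna_chrom, rna_pos, dna_chrom, dna_pos) tuples."""
    return PairSet.from_pairs(
        [ContactPair(rc, rp, "+", dc, dp, "-") for rc, rp, dc, dp in rows],
        asm,
        condition,
    )


@pytest.fixture(scope="session")
def control_sim():
    """Canonical Control-like scenario: (config, pairs, ground truth)."""
    cfg = simulate.default_config(7)
    pairs, gt = simulate.simulate_pairs(cfg)
    return cfg, pairs, gt


@pytest.fixture(scope="session")
def control_pairs_filtered(control_sim):
    _, pairs, _ = control_sim
    filtered, _ = contacts.proximity_filter(pairs)
    return filtered


@pytest.fixture(scope="session")
def control_hic(control_sim):
    """Hi-C matrix with full loop strength (no caRNA coupling)."""
    cfg, _, _ = control_sim
    mat, gt = simulate.simulate_hic(cfg, gamma=0.0)
    return cfg, mat, gt


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def interval(chrom, start, end):
    return GenomicInterval(chrom, start, end)
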