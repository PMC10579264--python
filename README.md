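# carna

Joint analysis of chromatin-associated-RNA (caRNA) contact maps and 3D
genome structure.

Assays such as iMARGI produce read pairs with one **RNA end** (a caRNA
molecule) and one **DNA end** (the genomic locus it was crosslinked to),
yielding an *asymmetric* RNA × DNA contact matrix alongside Hi-C's
symmetric DNA × DNA matrix. `carna` implements, as a tested and
reusable library + CLI, the statistics needed to ask how caRNA relates
to genome folding:

- **RNA attachment level (RAL) tracks** — per-bin DNA-end counts for a
  chosen RNA source (a gene, a repeat family such as Alu/L1/HERV-H, or
  all RNA: the cumulative RAL, cRAL), after the standard read-pair
  filters (1 kb proximity filter; ≥ 200 kb cis-separation filter for
  correlation analyses).
- **RNA-association domain calling** — rectangular blocks on the
  asymmetric matrix: a 5 kb RNA-end peak ("height") paired with the
  strongest 25 kb DNA-end peak ("width"), via a fixed-width
  sliding-window peak caller with a 4× local-fold and Poisson
  (p < 1e-5) background test.
- **TAD-relative statistics** — rescaled [flank | TAD | flank]
  meta-profiles of TAD-transcribed RNA; classification of contacts as
  *cross-over* (ends on opposite sides of a boundary); 2×2 contingency
  enrichment with OR = ad/bc, SELOR = √(1/a+1/b+1/c+1/d), whiskers
  exp(log OR ± SELOR) and a 1-df chi-square.
- **Hi-C matrix numerics** — Knight–Ruiz balancing, distance-expected
  and O/E transforms, compartment PC1, Crane insulation score, Dixon
  directionality index and delta-DI, de novo boundary detection, and
  the Measure of Concordance (MoC) between TAD partitions.
- **Loop strength and loop algebra** — union/reassignment of loop
  lists across conditions, aggregate peak analysis (APA) with P2LL /
  ZscoreLL / P2M, CTCF-binding-site orientation classes
  (convergent / non-convergent / none), and the KO-vs-control
  delta-peak rule on depth-normalised pixel counts.
- **Between-anchor caRNA enrichment** — the ITA ratio (between-anchor
  over anchor caRNA density), GSEA-style ranked-loop enrichment with a
  seeded permutation test, and selection of candidate
  caRNA-insulated loops (e.g. RNase-emergent loops strided by ≥ 2
  HERV-H caRNA contacts).
- **A synthetic-data generator** — seeded simulations of pair sets and
  Hi-C matrices with planted domains, boundary insulation (per-boundary
  crossing probability β), loops (enrichment λ), compartments, and an
  explicit anti-coupling between loop strength and between-anchor caRNA
  (λ_eff = 1 + (λ−1)·e^(−γ·ITA)), so every stage can be validated
  against ground truth.

## Worked example

```python
import numpy as np
from carna import simulate, contacts
from carna.boundary import ContingencyTable2x2, classify_crossover, contingency_test
from carna.ral import call_domains

cfg = simulate.default_config(seed=7)           # Control-like condition
pairs, truth = simulate.simulate_pairs(cfg)
pairs, n_removed = contacts.proximity_filter(pairs, min_sep=1000)
print(f"{len(pairs)} pairs kept, {n_removed} removed by the 1 kb proximity filter")

domains = call_domains(pairs)
widths = [d.width for d in domains]
print(f"{len(domains)} RNA-association domains, median width {int(np.median(widths))} bp")

rnase_pairs, _ = simulate.simulate_pairs(simulate.rnase_config(cfg))
chrom, pos = cfg.tads.boundaries()[0]
a_cross, a_non = classify_crossover(pairs, chrom, pos, window=500_000)
b_cross, b_non = classify_crossover(rnase_pairs, chrom, pos, window=500_000)
res = contingency_test(ContingencyTable2x2(a_cross, a_non, b_cross, b_non))
print(f"boundary {chrom}:{pos}  OR = {res.odds_ratio:.2f}  "
      f"95% CI = ({res.ci95()[0]:.2f}, {res.ci95()[1]:.2f})  p = {res.p_value:.2g}")
```

prints

```
99658 pairs kept, 342 removed by the 1 kb proximity filter
51 RNA-association domains, median width 25000 bp
boundary chr1:2800000  OR = 0.47  95% CI = (0.33, 0.68)  p = 4.4e-05
```

The domain caller recovers the 50 planted RNA-association domains (plus
one planted loop-interior caRNA element); the odds ratio at the first
TAD boundary estimates the ratio of the two conditions' planted
boundary-crossing probabilities (0.3 / 0.6 = 0.5) — cross-over RNA-DNA
contacts are half as likely, relative to non-cross-over contacts, in
the Control-like condition as after caRNA depletion.

## Command line

All stages are exposed as `carna` subcommands operating on standard
text formats (4DN `.pairs`, BED, BEDPE, bedGraph, MTX):

```bash
carna simulate --seed 7 --out fixtures/
carna --assembly fixtures/chrom.sizes filter-pairs fixtures/control.pairs filtered.pairs \
      --min-sep 1000
carna --assembly fixtures/chrom.sizes call-domains filtered.pairs domains
carna --assembly fixtures/chrom.sizes crossover fixtures/control.pairs fixtures/rnase.pairs \
      --boundary chr1:2800000 --window 500000
carna moc tads_a.bed tads_b.bed
```

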