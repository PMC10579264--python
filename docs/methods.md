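# Methods

This note documents the statistical conventions, numerical choices and
the synthetic-data model behind `carna`. It is written for a reader who
wants to know exactly what each number means, what the defaults are,
and what passing the test suite does and does not demonstrate.

## Coordinates, formats, filters

All internal coordinates are 0-based half-open. `.pairs` files
(1-based) and BED/BEDPE (0-based) are converted at the I/O boundary;
end 1 of a `.pairs` record is the RNA end and end 2 the DNA end (a
`swap_ends` flag covers other dialects). Strand is carried through but
ignored by every statistic.

Two read-pair filters implement the standard processing conventions for
RNA-DNA contact data:

- **proximity filter** (default `min_sep = 1000` bp): cis pairs whose
  ends map within 1 kb are removed as likely self-ligation artifacts;
  trans pairs are always kept. Applied before every analysis.
- **distance filter** (default `min_cis = 200` kb): correlation-style
  analyses (RAL tracks, ITA) additionally exclude short-range cis
  pairs, which are dominated by nascent-transcription signal near the
  transcription site.

Both filters are idempotent and commute; binning conserves read count
for any bin size (tested properties).

## RAL tracks and domain calling

RAL(source → bin) is the count of pairs with RNA end in the source and
DNA end in the bin; cRAL sums over all RNA and equals the sum of RAL
over any partition of RNA-end space (tested additivity). Repeat-family
RAL restricts RNA ends to annotated elements of one family at a
default 500 kb bin size.

RNA-association domains are rectangular blocks on the asymmetric
matrix. The paper-standard HOMER `findPeaks` step is implemented here
as a minimal fixed-width caller:

1. windows of `peak_size` anchored at read positions are ranked by
   count (ties leftmost) and accepted greedily subject to
   center-to-center spacing ≥ `min_interval`;
2. an accepted window is reported only if its count exceeds 4× the
   local background — the read density in a 10 × `peak_size` window
   around it (peak window excluded, scaled to the peak width, i.e.
   flank count / 9) — and a Poisson tail threshold at p < 1e-5 against
   the chromosome-wide uniform rate.

RNA peaks use `peak_size = 5000` / `min_interval = 12000` bp; the DNA
ends of each RNA peak's pairs are then peak-called genome-wide with
`peak_size = 25000` / `min_interval = 50000` bp and only the
highest-count DNA peak is kept (ties: chromosome order, then
leftmost). Both thresholds are exposed as flags. Because this caller
is a stand-in with its own defaults, absolute domain counts from
published datasets are not comparison targets; recovery is instead
validated on planted domains (recall, precision and ≤ 5 kb RNA-peak /
≤ 12.5 kb DNA-peak localisation on the canonical scenario).

Box-plot summaries of domain width/height follow the usual convention:
whiskers extend from the hinges to the most extreme values within
1.5 × IQR.

## Matrix numerics

- **Balancing**: Knight–Ruiz inner–outer Newton iteration per
  chromosome (tol 1e-8, max 1000 outer iterations), with bins of zero
  marginal, and marginals below the 5th percentile of the nonzero
  marginals, masked first. Non-convergence falls back to symmetric
  iterative proportional scaling with a warning. Balanced row sums are
  1 over unmasked bins.
- **Expected / O/E**: expected(d) is the mean count over all bin pairs
  at distance d within a chromosome (zeros included); O/E entries with
  zero expected are missing.
- **Compartment PC1**: leading eigenvector of the Pearson correlation
  matrix of cis O/E columns, per chromosome; sign oriented to
  correlate positively with a gene-density track (not cRAL, which
  would be circular when cRAL is subsequently compared between
  compartments). Chromosomes with < 10 informative bins are skipped.
- **Insulation** (Crane-style): raw score at bin i is the mean of the
  square [i−w, i) × (i, i+w]; reported as log2(raw / chromosome mean);
  edge bins missing. Invariant under global scaling (tested).
- **Directionality index** (Dixon-style): with A/B the contact sums to
  the upstream/downstream w-bin windows and E = (A+B)/2,
  DI = sign(B−A)·((A−E)²/E + (B−E)²/E), 0 when A = B = 0. delta-DI at
  a site is |DI(down) − DI(up)| in condition b minus the same contrast
  in condition a, where up/down are the last fully-upstream and first
  fully-downstream bins of the site; the window is a free parameter
  (2 Mb-equivalent default) since no canonical value exists.
- **MoC** between TAD partitions A and B (lengths in bp):
  MoC = (Σ_{i,j} |A_i∩B_j|²/(|A_i||B_j|) − 1) / (√(N_A N_B) − 1), with
  MoC := 1 when both partitions are a single domain. Symmetric, in
  [0,1], and 1 iff the partitions coincide (tested).
- **cRAL–compartment ANOVA** groups bins by PC1 sign (A: PC1 > 0, B:
  PC1 < 0) and runs a one-way ANOVA of cRAL across the two groups
  (equivalent to the squared two-sample t statistic; tested).

## Boundary and loop statistics

Cross-over classification considers cis pairs with both ends within
±`window` (default 500 kb) of a boundary; a pair is cross-over iff its
ends fall on opposite sides, with a position exactly at the boundary
assigned downstream (zero-measure for real data). The 2×2 condition ×
cross-over table yields OR = ad/bc, SELOR = √(1/a+1/b+1/c+1/d),
whiskers exp(log OR ∓ SELOR), and a chi-square without continuity
correction (Yates optional); any zero cell triggers the
Haldane–Anscombe +0.5 correction for OR/SELOR and is flagged.

The TAD meta-profile rescales each TAD of length L and its equal-length
flanks onto 3 × `bins_per_segment` bins, bins the DNA ends of pairs
transcribed inside the TAD (or outside, with the inverted selection
flag), normalises each TAD's vector to its own mean, and reports the
across-TAD mean with a bootstrap 95% band (200 resamples, seeded).
The boundary drop-off test pools, over TADs and both boundaries, the
mean RAL of the k innermost center bins vs the k outermost flank bins
and applies a two-sided Wilcoxon rank-sum.

Loop lists are merged by the union/reassignment rule: a loop belongs
to a condition iff both anchors fall within ±s flanks (s = anchor
size) of one of that condition's loops; union construction merges any
candidate matching an existing union loop, making the operation
idempotent. APA stacks (2R+1)² O/E windows (R = 10) over loops at
least 3·(2R+1) bins off the diagonal; P2LL divides the center pixel by
the mean of the 6×6 lower-left box, P2M by the whole-window mean,
ZscoreLL standardises against the corner box. The delta-peak rule
normalises each condition's loop-pixel count to counts per million and
flags |Δ| ≥ 0.05; CPM fixes the otherwise unspecified scale of that
threshold, and both scale and threshold are adjustable.

The ITA ratio uses per-bp densities with a pseudocount of one read per
region: (n_between + 1)/L_between over (n_anchor + 1)/L_anchor, so
zero-coverage loops remain finite and doubling all counts leaves ITA
asymptotically unchanged. GSEA on ITA-ranked union loops is the
classic unweighted running sum (+1/Nh for members, −1/(N−Nh)
otherwise; ties in ITA broken by genomic position for determinism)
with a seeded label-permutation p-value for max |ES|.

## The synthetic-data generator

The generator defines the study conditions for all validation; its
defaults are the canonical scenario.

**Pair model.** Each read picks an RNA source and draws its DNA end
from a two-sided exponential displacement with scale d0 = 200 kb;
every TAD boundary between the two ends independently thins the read
with probability 1 − β. Rejected reads are redrawn *in full* (source
and displacement), so accepted reads are i.i.d. from the conditional
law — this makes the cross-over odds ratio between two conditions
equal the planted β ratio exactly, whereas redrawing only the
displacement re-weights reads by position and biases the OR (observed
≈ +20% in development). A fraction τ = 0.05 of gene reads instead
lands uniformly in A-compartment bins genome-wide, emulating
long-range caRNA trafficking toward active chromatin. Read classes:
55% gene background, 15% domain reads (70% of which target a planted
20 kb DNA region through Laplace(8 kb) noise), 25% loop-interior
caRNA (RNA end in a 5 kb HERV-H element, DNA end uniform between the
loop's anchors), 5% uniform noise.

**Hi-C model.** Cis rates follow 1/(1+d), multiplied by a within-TAD
enclosure factor (2.0), a compartment checkerboard (±0.3 for same- vs
cross-label bins), and per-loop pixel enrichment with the 3×3
neighborhood at half strength; counts are Poisson draws scaled to a
5e6-read total at 10 kb bins. The caRNA–loop anti-coupling is
λ_eff = 1 + (λ−1)·exp(−γ·ITA_planted): with the Control-like γ = 1.5
and planted ITA = 2 on every other loop, caRNA-rich loops are
suppressed (λ_eff ≈ 1.2) and "emerge" in the RNase-like condition
(γ = 0, caRNA thinned 10×, β doubled).

**Canonical scenario** (2 × 20 Mb chromosomes): 2.5 Mb alternating
compartment blocks; 10 abutting 1.8 Mb TADs per chromosome
(β = 0.3 Control-like); 40 background genes (3 per A block, 2 per B
block — the mild A bias both orients PC1 and reflects real gene
density); 50 planted domains on a 720 kb grid; 60 loops of λ = 5
nested 3-per-TAD so planted interior caRNA is not cut by boundary
thinning, with CBS classes cycling convergent / non-convergent / none.
Geometry is laid out deterministically with planted elements kept
≥ 40 kb from the domain-source grid so each structure is individually
resolvable by the peak caller — a property of the planted design, not
a claim about real genomes.

**What the generator does not emulate**: duplicate reads and
mappability artifacts, overdispersion beyond Poisson (a
negative-binomial knob exists only implicitly through config), realistic
sequencing depth (fixtures are 1e4–1e5 pairs vs hundreds of millions in
real libraries), unplaced contigs, and continuous (non-grid) genomic
architecture. Passing the planted-recovery tests therefore shows the
estimators are correct and calibrated under the stated model, not that
they would be unbiased on any real library.

## Validation design

- Closed-form oracles: contingency statistics against independent
  closed-form/statsmodels/permutation computations; rank tests against
  brute-force rank arithmetic at n ≤ 30; MoC and DI against
  hand-computed and brute-force values.
- Conservation laws: binning mass, RAL additivity, KR row sums
  (1e-8), GSEA running-sum closure, MoC symmetry.
- Planted-parameter recovery on the canonical scenario (seed 7):
  domain recall/precision ≥ 0.9, pooled cross-over OR interval
  covering the planted β ratio, aggregate P2LL within 20% of λ = 5,
  PC1–compartment |r| > 0.9.
- Null calibration: 200 seeded replicates with no planted effect —
  95% OR intervals cover 1 at 95% ± 4%, GSEA permutation p uniform
  (KS).
- Determinism: identical seeds give byte-identical fixture files and
  identical end-to-end outputs.

Replicate counts (200) and fixture sizes (1e5 pairs, 2 × 20 Mb) were
chosen as the smallest scales at which the planted effects are
comfortably identifiable; all randomness flows from explicit seeds.

## Known limitations

- The peak caller is a deliberately minimal HOMER-like stand-in; its
  absolute sensitivity differs from HOMER's tag-normalised model, so
  only relative/planted-recovery claims are supported.
- KR balancing is per-chromosome cis only; no trans balancing.
- The delta-DI site convention and DI window, the tallying window for
  cross-over counts, and the delta-peak normalisation scale have no
  canonical published definition; the defaults above are documented
  choices exposed as parameters.
- `union_loops` is quadratic in loop count per chromosome — fine for
  the intended thousands of loops, not for millions of candidate
  pixels.
- MoC is computed genome-wide over all domains, treating domains from
  different chromosomes as non-overlapping (their intersection is
  empty), which matches the per-genome summary use.
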