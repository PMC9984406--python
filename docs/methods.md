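# Methods

This note documents the models, algorithms and numerical choices behind
lsvkit: how gene splicegraphs are built from annotation and RNA-seq
coverage, how percent spliced in (PSI, Ψ) and its change (dPSI, ΔΨ) are
quantified per local splicing variation (LSV), how heterogeneous sample
groups are compared, how alternative-splicing (AS) modules are classified,
and what the synthetic data generator does and does not emulate.

## Splicegraphs and LSVs

A gene is represented as a splicegraph: non-overlapping exons as vertices,
and two kinds of edges — junctions (a donor position spliced to an acceptor
position) and retained introns (the gap between two adjacent exons can be
retained). Coordinates are 0-based half-open on the forward genomic strand;
GFF3 (1-based inclusive) is converted at the parsing boundary. A junction's
interval is exactly the intron it removes: its `start` is the half-open end
of the donor exon, its `end` the start of the acceptor exon.

Parsing merges the exons of all of a gene's transcripts into maximal
intervals and collects one junction per distinct coordinate pair. Wherever a
merged exon fully covers another transcript's junction, the covering exon is
split and an annotated retained intron recorded, so every junction starts
and ends in different exons.

De novo evidence updates the graph. A candidate junction is assigned to a
gene by priority: (1) a gene already containing the junction, (2) a gene
with exons within 400 bp of both junction coordinates, (3) a gene whose
boundaries contain it; ties resolve by nearest boundary midpoint, then
gene id. A de novo element is accepted when, in at least one build group, at
least `min_experiments` experiments each reach the de novo thresholds
(defaults: ≥5 total reads over ≥3 distinct read positions;
`min_experiments = ceil(|group| / 2)`). Annotated edges are retained
unconditionally and merely flagged `passed` at looser thresholds (≥3 reads,
≥2 positions) — the asymmetry demands stronger evidence for unannotated
structure. Accepted junction endpoints extend an existing exon boundary by
at most 400 bp (consistent with the assignment window); farther orphan
endpoints create minimal de novo exons, pairing an acceptor with the next
donor when no exon lies between. Retained introns are then re-derived over
the adjusted exon inventory; each fragment records the original intron
interval whose coverage it inherits, because intron coverage is averaged
over the original region and therefore transfers to any fragment of it.

An LSV is the set of edges leaving (source) or entering (target) a
reference exon, kept when it has ≥2 non-simplified edges going to distinct
exons. Source/target is resolved by strand at definition time; storage is
always forward-strand.

The simplifier removes noise edges from quantification: for every edge,
build group, and each of the (up to two) splits containing it, the edge's
raw read rate is divided by the split's total rate. The edge is flagged
simplified iff the ratio stays below the threshold in every group for both
splits; a split with zero total rate in a group abstains (counts as low),
since absence of usage evidence should permit simplification. Threshold 0
disables the simplifier exactly, and raising the threshold can only
simplify more edges (monotonicity is property-tested).

## Per-position coverage

A spliced read supports a junction at the read offset of its split, giving
`L − 1` possible positions for reads of nominal length `L` (a configuration
value, default 100 — num_positions must not drift with per-read length
variation). Introns are modelled the same way: reads covering the intron
start count like junction reads; reads starting inside the intron add one
raw position per genomic offset; the `L − 1 + intron_length` raw positions
are then aggregated into `L − 1` contiguous bins whose sizes differ by at
most one, each bin carrying the mean of its members (mean coverage is
preserved; reads overlapping only the intron end are attributed via their
start position, mirroring the start-side rule).

Read stacks are handled by a single outlier mask: zero positions are
masked, and each nonzero position is tested against a Poisson with rate
estimated from the *other* nonzero positions; positions with right-tail
probability below α = 10⁻⁷ are masked, all decisions taken simultaneously
in one pass. Measurement error of the total read rate is modelled by M = 30
bootstrap replicates (configurable): sums of n draws with replacement from
the unmasked counts, replaced by Poisson(total) sampling when the unbiased
sample variance falls below the mean (underdispersion), since resampling
cannot widen an underdispersed sample.

SJ files cache one experiment's raw (pre-mask) coverage as a versioned,
terminated text table; floats are written with `repr` so the round trip is
exact and a build from SJ is bit-identical to a build from the alignments
the SJ came from. Truncated or version-mismatched files fail loudly.

## PSI quantification

For an LSV with J edges, reads on edge j follow
`r_j ~ Binomial(Σ r, Ψ_j)` with the generalised Jeffreys prior
`Ψ_j ~ Beta(1/J, 1 − 1/J)`, chosen because observed Ψ concentrates near 0
and 1. Conjugacy gives the closed-form marginal posterior
`Beta(1/J + r_j, 1 − 1/J + Σ_{j'≠j} r_{j'})`. Because all edges share the
same posterior normaliser `1 + Σ r`, the posterior means of an LSV's edges
sum to exactly 1. Inference runs once per bootstrap replicate and the
replicate posteriors are averaged (density and mean), propagating read-rate
uncertainty. Group quantification sums the read rates of experiments that
pass stricter-than-builder thresholds (≥10 reads over ≥3 nonzero positions
per LSV); with no passing experiment the LSV is reported unquantifiable, not
an error.

Densities are discretized to B = 40 bins on [0, 1] by exact Beta CDF
differences — fine enough that the 5% and 20% decision thresholds each span
two full bins. ΔΨ lives on the induced 2B − 1 = 79-point grid. The
independence density is the discrete cross-correlation of the two PSI
densities; the posterior multiplies it by a three-component mixture prior —
a spike at 0 (Beta shape on [−1,1], concentration 2500, sd ≈ 0.01), a
centered component (concentration 45, sd ≈ 0.075) and a uniform slab, with
weights (0.25, 0.50, 0.25) — and renormalises. The prior parameters are
configuration, enforced symmetric about 0; a uniform prior makes the
posterior equal the independence density exactly. Point estimates are
posterior means; confidence is reported as P(|ΔΨ| > C) by summing bins with
|center| > C.

## Heterogeneous-group comparison (HET)

Each experiment is quantified individually; the null hypothesis is that
per-experiment Ψ is identically distributed across the two groups. Four
statistics are used:

* **Welch's t** (unequal variances). Degenerate convention: two exactly
  constant groups give p = 1 when equal, p = 0 otherwise (the test's limit).
* **Mann–Whitney U**, two-sided as `P(|2U − n₁n₂| ≥ |2u − n₁n₂|)` (the null
  is symmetric about n₁n₂/2). Exact for pooled n ≤ 64 via a tie-aware
  dynamic program over tie groups of the pooled values (arrangements counted
  with multinomial weights, U doubled to stay integral under ½-ties); the
  normal approximation with tie and continuity correction is used beyond.
* **TNOM** — the minimum number of misclassified observations over all
  thresholds and both orientations. Its exact null P(TNOM ≤ observed) under
  uniformly random label arrangements is computed by a DP tracking the best
  cut seen so far along the sorted sequence.
* **InfoScore** — the maximum mutual information (bits) between
  side-of-threshold and group label. Its exact null P(S ≥ observed) counts
  the arrangements whose every internal cut stays below the observed score
  (lattice-path DP with forbidden states; score comparisons use a 10⁻¹²
  tolerance so symmetric cuts compare equal).

Thresholds never split tied values: candidate cuts are tie-group
boundaries, in both the statistics and their nulls, which keeps the exact
nulls valid under ties. All three exact nulls are verified against
exhaustive label enumeration for every group-size pair with pooled n ≤ 12.

Since Ψ is estimated, each test is repeated n_rep = 30 times on Ψ values
sampled from the per-experiment posteriors (bin centers weighted by the
averaged discretized density) and the 95th percentile of the p values is
reported by the nearest-rank rule — a deliberately conservative summary
that is not calibrated — alongside the p value computed on the posterior
means. Group medians of posterior means, their difference, and within-group
IQRs are reported for downstream flagging; flags use the quantile p by
default.

## AS modules and event classification

Before module detection, edges whose group-median E[Ψ] stays below the
decomplexify threshold (default 5%) in every group are removed from
consideration (threshold 0 disables the filter; the splicegraph itself is
never modified). A module is a maximal region where more than one junction
path runs in parallel: a boundary between consecutive exons separates
modules iff at most one retained edge crosses it and any single crossing
edge is the constitutive link between the two adjacent exons; additionally,
an exon spanned by no edge is a convergence point, so back-to-back modules
split there and share it as exit/entry exon. Edges belong to exactly one
module; boundary exons may be shared. Modules are not nested (no recursive
definition).

Within a module, every binary sub-pattern is emitted as an event: cassette
exon (CE), tandem cassette (TCE: a chained inclusion path through ≥2 middle
exons plus the skipping junction), multi-exon skipping (MES: entry into the
first and exit from the last of ≥2 skipped exons, regardless of how they
are joined), mutually exclusive exons (MXE), alternative 5'/3' splice sites
(two junctions between the same exon pair sharing one end; names follow the
strand), alternative first/last exons (≥2 terminal exons converging on a
common exon; putative — pAFE/pALE — when a participating terminal exon is
de novo), putative alternative splice sites (pA5SS/pA3SS: a cassette-like
pattern whose inclusion junction is absent, bridged by a sufficiently
retained intron), intron retention (IR: an intron with any parallel
junction path — this broader reading makes every putative-SS module also
contain an IR event, which the redundancy rule below presumes), and
`other` for any ≥2-path module matching nothing. Each event carries
references to both the source-side and target-side LSV quantifications,
because the two views need not agree.

Module labels are the multiset of contained event types after a redundancy
rule: MES enters the label only when its count exceeds the TCE count, and
IR only when its count exceeds the combined putative-SS count. Events are
flagged *changing* when ≥1 event edge has |median difference| ≥ 20% and
every requested statistic's p < 0.05, and *non-changing* when every edge
has |Δmedian| ≤ 5%, all within-group IQRs ≤ 10% and all p ≥ 0.05; the
threshold ordering makes the two flags mutually exclusive by construction.
Edges lacking quantification leave an event unflagged, logged.

## Evaluation statistics

The reproducibility-ratio curve RR(n) is the fraction of the top n events
of one comparison present among the top n of a repeat on disjoint samples;
RR at the first list's significant-event count is the reproducibility
ratio. LSVs sharing a junction are collapsed first (first-ranked kept) to
avoid double-counting classic events. The intra-to-inter ratio divides
significant events in a within-group comparison by those in a
between-group comparison (reported missing when the denominator is zero).
Against simulated truth, events are labelled TP/TN/FP/FN from the tool's
max |ΔΨ| and p against the true max |ΔΨ| with 20%/5%/0.05 thresholds;
anything in the (5%, 20%) band or with conflicting ΔΨ/p is Ambiguous.
Genes take their events' worst label in the order FP > FN > TP > TN (wrong
hits cost follow-up effort; then missed changes), and FDR/FNR/MCC summarise
the gene labels. Ranking for RR from this package's own output orders HET
results by quantile p ascending then |Δmedian| descending, and dPSI results
by P(|ΔΨ| > 0.2) descending.

## Synthetic data generator

The generator works at the coverage level, not the read-sequence level: for
each edge, per-position counts are independent Poisson draws with rate
`depth · rel / (L − 1)`, where `rel` is the fraction of transcripts using
the edge, so edge totals are Poisson(depth · rel) and positions are uniform.
Between-sample heterogeneity draws each sample's isoform abundances from a
Dirichlet centered on the spec with concentration `1/dispersion²`
(dispersion 0 gives exact replicates). The same simulated placements can be
emitted as a minimal SAM file (fixed CIGARs, uniform placements), which by
construction yields coverage identical to the SJ container — this is what
makes the incremental-build equality check meaningful.

Gene templates hand-code their expected splicegraph inventory, planted
event composition, and per-edge true Ψ as functions of the abundances, so
classifier exactness is checked against human-derived bookkeeping rather
than against the code under test. The panel cycles 15 templates covering
all 13 concrete event types plus `other`; the putative-SS templates plant a
minor isoform at 2% so the 5% decomplexify threshold removes the cassette
inclusion junction deterministically, and the pAFE/pALE templates supply de
novo junction evidence through the builder's update path.

What the generator does **not** emulate: sequencing errors, positional and
GC bias, fragment-length distributions, multimapping, annotation errors,
expression-level variation between genes, or correlated noise across
samples. Passing tests therefore demonstrate the correctness of the
algorithms and their calibration under idealised Poisson sampling with
Dirichlet heterogeneity — not performance on real libraries, where read
placement is biased and the binomial read model is only an approximation.

## Study sizes and numerical choices

The validation studies (in `lsvkit.benchmarks`, re-run by
`scripts/acceptance.py`) use: 500 null cassette LSVs with dispersion 0.05,
10 samples per group at depth 100 for type-I calibration (binomial 99% band
around the nominal 0.05, posterior-mean p values); 40 planted ΔΨ = 0.4
events plus 20 null genes for power and false flagging under the full
changing flag (n_rep = 30, all four statistics); 50 LSVs at depth 200 for
PSI recovery (MAE < 0.05); the 20-gene panel for classification exactness.
These sizes give stable pass/fail behaviour across seeds while keeping a
full run under a minute on one CPU.

Other numerics: Beta bin masses via regularised incomplete-beta
differences (never density × width); exact-null p values as rational
fractions converted to float at the end; the InfoScore forbidden-state
comparison and statistic use the same 10⁻¹² tolerance so DP and
enumeration agree exactly; per-(experiment, LSV) RNG streams derived from
the user seed with a CRC32 mix, kept below 2³¹.

## Known limitations

- Exon extension/creation for orphan de novo endpoints uses minimal-width
  exons when no pairing donor exists; real terminal exon extents are not
  inferred.
- The decomplexify filter consumes one median per edge (the larger of the
  source/target views) rather than per-LSV values.
- The MES pattern requires entry and exit junctions into the skipped block;
  compositions where MES outnumbers TCE arise only through simplification
  or de novo structure, so the label rule's "add MES" branch is exercised
  with hand-built modules in the tests.
- The asymptotic Mann–Whitney branch (pooled n > 64) relies on the normal
  approximation; no Edgeworth correction is applied.
- Multi-group ("consistently changing") logic intersects pairwise
  comparisons; no joint multi-group model is provided.
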