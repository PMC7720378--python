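# Methods

This note documents the models and procedures implemented in panelforge,
the parameter choices that matter, and what the synthetic-data tests do and
do not demonstrate about real data.

## Generative model for structured cohorts

`synthetic_data.simulate_populations` draws genotypes under the
Balding–Nichols model. For each locus an ancestral allele frequency *p* is
drawn uniformly from `anc_freq_range` (default (0.1, 0.9) — intermediate
frequencies, where array content and discovery panels concentrate); each
population's frequency is Beta-distributed,

    p_k ~ Beta( p (1−F)/F , (1−p)(1−F)/F ),

so that E[p_k] = p and Var[p_k] = F·p(1−p), making the expected pairwise
FST between populations equal to the generating parameter F. Diploid
genotypes are Binomial(2, p_k). F = 0 bypasses the Beta draw (p_k := p
exactly) rather than evaluating the degenerate parameters. A single shared
F across loci and populations is the simplest model consistent with one
pairwise FST target; it makes parameter-recovery tests well defined.

Defaults emulate a realistic design cohort for a three-species great-ape
genus: 2–3 populations, 50 diploids per population, FST 0.05 for
well-differentiated species pairs (recovery is also exercised at 0.001–0.2),
loci at intermediate ancestral frequency with no linkage disequilibrium, no
missing genotypes and no sequencing error. Real data differ in all four of
the latter respects, so passing tests demonstrate correctness of the
estimators and filters, not robustness to LD, call-rate structure or
ascertainment bias.

Planted hard-filter violations are drawn strictly inside each failing
region (e.g. QD uniform on [0, 1.9] against the cutoff 2.0), never on the
boundary, and violation sets are disjoint across annotation keys, so the
truth manifests give exact expected survivor counts.

## FST estimation and AIM selection

`per_locus_fst` implements the Weir–Cockerham (1984) per-locus estimator
for two populations from the three variance components — among populations
(a), among individuals within populations (b), within individuals (c) —
with θ = a/(a+b+c). It is the field-standard estimator with an exact
small-sample definition, which allows a brute-force oracle in the tests
(loop-based, written independently of the vectorized path, agreement to
1e-10). Monomorphic loci are undefined (NaN) and excluded from ranking;
negative θ at undifferentiated loci is retained, as is standard. Nei's Gst
and Hudson's ratio estimator are available for sensitivity analyses.

For genome-wide recovery checks the multi-locus ratio-of-sums form
Σa / Σ(a+b+c) is used; the plain mean of per-locus θ is close to it at
moderate F but is a ratio average and drifts low at high differentiation.

`select_top_aims` ranks per chromosome *and* per population pair and takes
the top k = 5000 (matching the published workflow's per-chromosome cap);
the panel is the union of (chrom, pos) across pairs, with each locus
reported under its best pair. "Per pair" rather than one global ranking is
the reading that matches the stated panel-size arithmetic of the original
workflow; a single-pair table degenerates to a global per-chromosome
ranking, so both behaviours are reachable. Ties at the k-th rank break by
(chromosome order, position), making the output invariant to row order.

`recommend_min_snps` interpolates between two published anchors — 20,000
SNPs at FST = 0.01 and 100,000 at FST = 0.001 — log-linearly (a straight
line in log-FST / log-N), rounded up to the nearest 1000 and clamped at
the anchors. The anchors are the only constrained points; log–log is the
natural interpolation for a power-law-like requirement and is monotone.

`assignment_validation` centers and unit-scales the dosage matrix, projects
onto the leading principal components (default 10), and evaluates a linear
discriminant by leave-one-out: the PCA is fitted once on the full matrix
(the unsupervised step does not use labels), the discriminant is refitted
with each sample held out. Reported accuracy is the fraction of held-out
samples assigned to their true population. Because AIMs are selected on the
same samples, this mirrors the original workflow's confirmation step and
slightly flatters the panel relative to assigning genuinely new samples.

## Array QC

The platform workflow excludes samples "outside the majority cluster" of a
call-rate vs P10 scatter by eye. panelforge operationalizes this as a
robust distance: both coordinates standardized by median and MAD (scaled
1.4826), squared distances compared to the chi-square(2) quantile at
1 − alpha, default alpha = 0.01. This is a documented stand-in for a visual
step, not a published rule; an explicit exclusion list can be supplied
instead. A zero MAD (constant coordinate) contributes zero for on-median
values and infinity otherwise, so identical cohorts exclude nobody.

The cascade order is fixed and matters: sample exclusion first, then
no-call fraction and MAF recomputed over retained samples, then the SNP
filters (Cluster Sep < 0.3, no-call > 10 %, AB R Mean < 0.12 — strict
inequalities exactly as printed), then biallelic-only, then MAF > 0.01
pooled over callable retained samples. Cluster re-computation itself
(custom cluster files) is out of scope; cluster_sep and ab_r_mean are
consumed as given.

## Probe design

Targets are tiled with 75 nt probes every 25 nt (the midpoint of the
50–100 nt range; the step is a design choice — the published workflow used
proprietary placement software and states no step). Single-base SNP targets
get one probe centered on the SNP (offset 37 for a 75-mer). Probes running
past a contig end are shifted inward, never shortened below 50 nt.

Two uniqueness screens follow:

1. **Overrepresented 15-mers.** Canonical 15-mers (lexicographic min of
   k-mer and reverse complement) are counted over all contigs, skipping
   windows with non-ACGT bases. "Overrepresented" is undefined in the
   published description; the default cutoff is max(10, mean + 5 sd) of the
   observed counts — far above the background of a random genome (counts
   1–2 at the 100 kb scale, ~ Poisson elsewhere) and far below a planted
   repeat family — and is configurable and reported.
2. **Near-match screen.** A non-target site counts when some 30-nt
   subsequence of the probe aligns ungapped with ≥ 27/30 identical bases
   (90 % identity). Matching is exhaustive over all alignment offsets and
   both strands (vectorized equality-cumsum over the padded contig);
   hits overlapping the probe's own source interval are excluded, and hits
   within one probe-length of each other on the same strand merge into one
   site. Probes with ≥ 21 sites are rejected ("fewer than 21" kept). The
   original workflow used SSAHA; its seeding parameters and site semantics
   are unrecoverable, so these semantics (ungapped, strand-wise merge,
   source exclusion) are the package's documented, reproducible
   definition, verified against a plain-Python exhaustive oracle on small
   genomes.

Kept probes whose target is SNP-class and whose interval overlaps no exon
or gene target are assigned concentration 2.0 ("isolated SNPs"),
everything else 1.0.

The design report gives per-target probe counts, rejects by reason, the
covered fraction, and uncovered sub-intervals (a target base is uncovered
iff no kept probe overlaps it — asserted property).

## Intervals, summaries, cost

BED-style 0-based half-open intervals are used everywhere externally;
VCF-style 1-based positions at the record level, with a single conversion
point (`snp_pos_to_interval`). Panel span merges overlapping *and*
touching intervals before summing (span accounting). Chromosome ordering is
natural (chr1 < chr2A < chr2B < … < chrX < chrM < chrUn). Currency is
handled in integer cents; per-sample cost is lane cost divided by samples,
rounded to cents. Multiplexing capacity is
floor(lane_yield × on-target efficiency / (panel span × target coverage)) —
the lane-yield and efficiency assumptions behind published capacity figures
are exposed as explicit parameters rather than guessed.

## Problem sizes and numerical choices

Parameter-recovery checks use 10,000 loci and 50 diploids per population
(recovery of F within 20 % relative at F ≥ 0.01; in practice the
ratio-of-sums estimate lands within ~2 %). Assignment validation uses 3
populations × 50 samples and the top 2000 AIMs. Oracle-equivalence checks
run the exhaustive near-match oracle on genomes of a few kb (it is
quadratic) and the production counter on genomes up to ~100 kb. The
end-to-end synthetic run (simulate → filter → select → design → summarize)
completes in seconds at these sizes.

Degenerate inputs are defined, not patched around: F = 0 skips the Beta
draw; monomorphic loci are NaN, excluded from ranking; empty FST tables
yield an empty panel with a warning; an empty interval set has span 0;
zero-MAD coordinates exclude only off-median samples.

## Known limitations

- No linkage disequilibrium, sex chromosomes, missing genotypes or
  sequencing-error model in the generator; manifests are exact partly
  *because* the data are clean.
- The near-match screen is ungapped; an indel-containing paralog could
  evade it where a gapped aligner would not.
- The robust-distance sample QC is a stand-in for a visual clustering step
  and its alpha is a convention, not a fitted value.
- Multi-allelic records pass hard filtering (flagged) and are excluded at
  AIM selection; mixed SNP/indel records are excluded and counted, by
  default, rather than filtered under either rule set.
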