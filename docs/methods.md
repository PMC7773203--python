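# Methods

This note records the models behind gcn4scope, the defaults and why they
are what they are, what the synthetic data does and does not emulate, and
the numerical conventions that affect results.

## Peak calling

The caller operates on fragment midpoints in fixed, non-overlapping bins
(default 100 bp). The background model is deliberately non-parametric:

- μ = mode of the integer per-bin counts. Ties are broken toward the
  smallest value, making the statistic deterministic. The mode of a sample
  from a flat-topped count distribution (e.g. Poisson with large mean) is a
  noisy location estimate — expect the divisor to wander a few percent
  around the true background mean; the test suite bounds this at 5% on the
  default null simulation.
- x = median absolute deviation of the bins whose count is below the mean
  of all bins. The MAD is unscaled (no 1.4826 normal-consistency factor).
  Restricting to sub-mean bins makes x robust to the right tail that the
  peaks themselves create.
- Background bins are those with counts in [μ − x, μ + x]; the divisor is
  their **mean count**. Normalized coverage is count/divisor, i.e.
  fold-over-background, which is what makes the fixed calling threshold
  of 2 meaningful. Dividing instead by the *total* read count in background
  bins (available as `divisor_mode="total"`) yields values orders of
  magnitude below 1 and requires a user-supplied threshold; it exists for
  completeness, not for use with the default cutoff.

Statistics are pooled genome-wide (one distribution across chromosomes); a
per-chromosome mode would be noisier on small chromosomes and the pooled
form matches the single-distribution reading of the procedure.

Thresholding is strict (> 2), merging is strict (gap < 200 bp), consensus
overlap is inclusive (≥ 50 bp): each boundary convention follows the
wording of the procedure being implemented ("above", "separated by <",
"at least"). The consensus peak spans the union of the contributing
replicate peaks and records their ids; its signal is the max over
contributors. The mock sample is never used in calling; it exists for QC
(replicate correlation, metagene profiles).

Fragment-to-bin assignment by midpoint is a declared convention — the
procedure's source does not state a read-assignment rule, and midpoint
assignment counts every fragment exactly once (bin counts always sum to
the fragment total, which several tests rely on). SAM input follows a
simple fragment model: properly paired records contribute the template
span once (from the leftmost mate), single-end records their aligned
span; secondary/supplementary/unmapped records and MAPQ < 20 are dropped.

## Annotation

Targets: gene ORF overlapping [peak.start − 750, peak.end + 750) by ≥ 1 bp.
The window is half-open, so an ORF starting exactly 750 bp after the peak
end is not a target. Assignment is ORF-based, not TSS-distance-based.

Feature class: decided by the peak midpoint with precedence
promoter > near_TTS > exon > intergenic. The promoter window is
TSS − 1000 .. TSS + 100 in transcript orientation (inclusive ends); the
near-TTS window is 0 .. +250 bp downstream of the TTS. The TTS window is a
declared choice — annotation tools each have their own convention and the
published pie-chart breakdown is not reproducible without the original
tool's internals; the midpoint-precedence classifier is transparent and
single-label by construction (class counts always sum to the peak count).

Motif scanning resolves the IUPAC consensus into a regular expression with
lookahead (so overlapping matches are all reported) and scans both
strands. TGANTCA equals its own reverse complement as a pattern, so every
site yields a hit on each strand at the same position; the analytic
per-position hit rate on random sequence used in tests is
2 × 4 × 4⁻⁷ per position.

## Signal matrices

Coverage matrices span [anchor − flank, anchor + flank) (anchor = TSS or
ATG) with minus-strand rows reversed so negative offsets are always
upstream. Two value semantics:

- `normalized` (default): the peak caller's fold-over-background bin
  values expanded to base resolution as a step function, aggregated into
  columns by mean. One normalization semantics pipeline-wide; profiles are
  in fold-over-background units. Step-function sampling (rather than
  interpolation) keeps peak edges sharp and bin values exact.
- `raw`: fragment-midpoint counts per base, aggregated by sum — under a
  genome-tiling anchor set the matrix total equals the fragment count,
  a conservation property the tests exercise.

Windows that run off a chromosome end are zero-padded and flagged per row.

Region-set signal comparison uses the two-sided Mann–Whitney U test on
per-region mean normalized coverage — a rank-based test chosen because the
quantity compared is a skewed ratio and the published comparison is a
distributional one. The exact null is used when n_A + n_B ≤ 20 and there
are no ties, the normal approximation (without continuity correction, so
identical samples give p = 1) otherwise.

## Expression integration

`de_filter` applies the published cutoffs to an externally supplied DE
table: |log2FC| ≥ log2(fold cutoff) and p ≤ p-cutoff, both inclusive, no
multiple-testing correction (matching the raw-p "stringent cutoff" design;
a Benjamini–Hochberg option exists but is off by default). Orientation is
fixed by the deletion contrast: down in the deletion = activated by the
factor.

`simple_de` is a stand-in so the synthetic pipeline can run end-to-end,
and is clearly labelled as such: CPM normalization, log2 fold change of
mean CPM with pseudocount 0.5, and a two-sided exact binomial test of the
pooled condition counts against the pooled library-size ratio. The
two-sided p is the doubled smaller tail (min(1, 2·min(cdf, sf)); the
"central" convention), which vectorizes over 10⁵ genes and is conservative
for discrete counts. The binomial test ignores between-replicate
overdispersion, so it is approximately calibrated only when replicates are
near-Poisson; with realistic biological dispersion (NB α ≈ 0.01–0.05) it
is strongly anticonservative. Real analyses should supply a DE table from
a proper NB framework; pipeline reports record in their provenance block
that the stand-in produced the DE table.

Gene-set overlap: one-sided Fisher exact test (hypergeometric upper tail)
on [[|A∩B|, |A\B|], [|B\A|, N − |A∪B|]]. The universe N is always an
explicit argument — whether it is "all ORFs" or "all expressed genes"
changes p-values materially, so it is never defaulted silently.

## Composition

%R+K counts R and K over the full sequence including the initiator
methionine; a trailing stop symbol is stripped; X is tolerated (counts in
the length, never as R/K). Fixed bins: bin1 < 10%, bin2 10–13%,
bin3 > 13%, with both boundary values assigned to bin2 (closed middle
interval, configurable) — the published bin edges leave boundary
membership ambiguous, and a closed middle interval is the simplest
single-label rule. A tercile mode (empirical 1/3 quantile cuts) is
provided because the published three-way split is also consistent with
near-tercile binning; neither mode is asserted to be the original.

## Synthetic data

The generator plants known structure so that every downstream stage has a
ground truth:

- **Genome/genes**: i.i.d. bases at 38% GC; one 200 kb chromosome with 80
  non-overlapping genes (ORF 600–1800 bp, 5' UTR 50–200 bp) placed by
  rejection sampling. Toy scale chosen so a full pipeline run takes
  seconds while background bins stay well-populated (~100 fragments/bin).
- **Peaks/motifs**: one randomly resolved TGANTCA instance written into
  the promoter (TSS − 1 kb .. + 100 bp) of each chosen target gene; a
  200–400 bp peak centered on it with 8-fold default enrichment. The
  direct-gene truth sets are recomputed *after* planting with the same
  750 bp ORF rule the annotation stage uses, so the truth invariant ("every
  direct gene is near a peak, no indirect/null gene is") holds even when a
  peak brushes a neighboring gene.
- **ChIP fragments**: a midpoint-rate model — background midpoints uniform
  over the genome, rate multiplied by the enrichment fold inside planted
  peaks for IP samples only; the mock is pure background; 2×10⁵ fragments
  per sample. No shift/extension model, no PCR duplicates, no mappability
  structure: enough to exercise the caller, not a sequencer emulator.
- **Expression counts**: negative binomial (gamma–Poisson) with shared
  dispersion; activated genes have their deletion-condition mean divided
  by 2^effect (default effect 2.0), repressed genes multiplied. Default
  dispersion is 0.001 — deliberately near-Poisson, consistent with the
  tightly correlated replicates the pipeline's QC expects and the regime
  in which the binomial DE stand-in is approximately calibrated. This is
  a known simplification: real bulk RNA-seq dispersions are 10–50× larger,
  and passing calibration tests here says nothing about `simple_de` on
  real data (see above).
- **Proteome**: per-protein target %R+K drawn from three uniform
  components strictly inside the bins (5–9.9, 10.1–12.9, 13.1–20) so that
  rounding to an integer residue count can never cross a bin boundary;
  realized composition is within 0.5 percentage points of target.
  Translation-related genes — defined in the end-to-end study as the
  planted repressed genes plus unregulated extras up to 25% of the genome
  — draw from a ribosomal-protein-like component (14.5–21% R+K, p = 0.95)
  reflecting the strongly basic composition of the real translation
  machinery; the non-translation background uses fractions
  (0.28, 0.57, 0.15), i.e. the overall ~25/50/25 split with the
  translation genes' bin-3 mass removed.

Randomness: each stage derives an independent generator as
`default_rng([seed, stage_constant])` (replicates additionally key on the
replicate index), so stages are individually reproducible and mutually
independent; everything is deterministic given the seed. The truth
manifest is versioned JSON; downstream recovery tests consume only the
manifest, never simulator internals.

What passing the synthetic tests shows: the implementation is faithful to
the stated procedure and recovers planted structure under clean
conditions. What it does not show: robustness to duplicate reads, copy
number, mappability artifacts, overdispersed expression noise, or
non-uniform genomic background — none of which the generator models.

## Numerical and degenerate-input conventions

- Mode ties → smallest count; all-identical bin counts → error; no bins in
  [μ − x, μ + x] or a zero divisor → error advising more data.
- Fewer than 100 bins → error by default (`min_bins` is a parameter; the
  hand-enumerable worked examples in the tests lower it deliberately).
- Exact rank-sum/Fisher branches switch to asymptotics exactly where
  stated (ties, or n_A + n_B > 20); enrichment odds ratios may be
  infinite and are reported as such.
- Empty gene sets, empty region sets, empty matrices, contradictory DE
  tables (a gene both up and down) and unknown IDs raise errors rather
  than degrade silently; unknown IDs in composition sets are dropped with
  a warning because proteome FASTAs and annotations routinely disagree.

## Problem sizes used in validation

The acceptance script and test suite run at the default toy scale (200 kb,
80 genes, 2×10⁵ fragments/sample), 100 independent 10 kb genomes for the
caller-vs-reference equivalence, 1000×1 kb sequences for the motif-scan
oracle, 10⁵ genes for DE calibration, and a 3000-protein proteome with 200
random sets for enrichment-test uniformity — sizes at which every check is
exact or tightly bounded while the whole suite runs in well under a
minute of compute per module.
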