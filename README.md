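# gcn4scope

Tools for dissecting a transcription factor's regulon the way it is done
for Gcn4, the budding-yeast bZIP master regulator of amino-acid
biosynthesis: a bespoke bin-based ChIP-seq peak caller with mode/MAD
background normalization and two-replicate consensus, peak-to-gene
annotation with consensus-motif scanning, integration of binding targets
with differential-expression tables into direct/indirect x
activated/repressed regulon classes, and proteome arginine/lysine
composition binning with gene-set enrichment. A synthetic-data module with
planted ground truth lets the whole pipeline run and be validated
end-to-end without any downloads.

Intended users: computational biologists who want a small, transparent,
fully tested implementation of this analysis style — for reanalysis, for
method comparison, or as a validated scaffold to adapt.

## The method

**Peak calling.** Fragments are counted into non-overlapping 100 bp bins by
midpoint. The background of the bin-count distribution is summarized by

- μ — the mode of the integer bin counts (smallest value on ties), and
- x — the (unscaled) median absolute deviation of the bins whose count lies
  below the mean,

and bins with counts in [μ − x, μ + x] are background bins. Each bin count
is divided by the mean count of the background bins, so normalized signal
is fold-over-background. Runs of bins with normalized signal strictly
above 2 become candidate regions; regions separated by < 200 bp are merged;
a peak is kept only if both IP replicates call it with ≥ 50 bp overlap
(the consensus peak is the union of the contributing replicate peaks). The
mock/control sample never enters calling.

**Annotation.** A gene is a possible binding target of a peak if its ORF
lies within 750 bp of the peak on either side. Peaks are classified by
midpoint against strand-aware windows — promoter (TSS − 1 kb .. TSS + 100 bp
in transcript orientation) > near_TTS > exon > intergenic — and their
sequence is scanned exhaustively on both strands for the IUPAC consensus
TGANTCA (the general-control response element).

**Regulon classes.** With a deletion-vs-WT expression contrast filtered at
fold change ≥ 2 (or 1.5) and p ≤ 1e-4: genes *down* in the deletion are
*activated* by the factor, genes *up* are *repressed*; crossing with the
ChIP target set splits each direction into direct and indirect. Gene-set
overlaps are tested with one-sided Fisher exact tests.

**Composition.** Each protein's %R+K = 100·(#R + #K)/length places it in
bin1 (< 10%), bin2 (10–13%) or bin3 (> 13%); bin-3 membership of a gene set
is tested by Fisher exact, and group compositions are compared by Wilcoxon
rank-sum.

## Worked example

```python
from gcn4scope import simulate_all, call_sample_peaks, consensus_peaks

sim = simulate_all(seed=1)                      # 200 kb, 80 genes, 2 IP reps + mock
peaks1 = call_sample_peaks(sim["chip"][0], sim["chrom_sizes"])
peaks2 = call_sample_peaks(sim["chip"][1], sim["chrom_sizes"])
cons = consensus_peaks(peaks1, peaks2)
print(peaks1.parameters["mu"], len(cons))
```

Running `python examples/01_call_peaks.py` prints:

```
replicate 1 background: mode mu=79, MAD x=6.0, divisor=79.3
peaks per replicate: 20, 20; consensus: 20
planted peaks in truth: 22
```

The background mode (79 fragments per 100 bp bin) and divisor set the
normalization scale; the caller recovers the planted peaks (nearby planted
peaks merge, so 22 planted intervals yield 20 consensus peaks), and each
consensus peak's signal (~8) matches the planted enrichment fold. The other
examples continue the story: `02` annotates the peaks (all promoter-class,
100% carry a TGANTCA variant, by construction), `03` shows the metagene
profile peaking a few hundred bp upstream of the TSS in the IP but flat at
background in the mock, `04` classifies the regulon (78/80 genes match the
planted truth; the two misses are genes just outside the 750 bp window of a
slightly widened called peak), and `05` shows the repressed gene set
landing entirely in the R+K-rich bin3 (Fisher p ≈ 3e-9).

There is also a thin CLI mirroring the modules:

```sh
gcn4scope simulate --seed 1 --outdir run1
gcn4scope callpeaks --ip run1/IP_rep1.bed --ip run1/IP_rep2.bed \
    --chrom-sizes run1/genome.chrom.sizes -o peaks.bed
```

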