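"""Classify direct vs indirect regulon members from ChIP + expression data.

Runs the simplified DE stage on simulated WT vs deletion counts, filters at
the published cutoffs (fold change >= 2, p <= 1e-4), and crosses the result
with the ChIP target list: genes DOWN in the deletion are ACTIVATED by the
factor; those also within 750 bp of a peak are its DIRECT targets.
"""

from gcn4scope import (
    annotate_peaks,
    assign_targets,
    call_sample_peaks,
    classify_regulon,
    consensus_peaks,
    de_filter,
    simple_de,
    simulate_all,
)

sim = simulate_all(seed=1)
cons = consensus_peaks(
    call_sample_peaks(sim["chip"][0], sim["chrom_sizes"]),
    call_sample_peaks(sim["chip"][1], sim["chrom_sizes"]),
)
_, chip_targets = assign_targets(cons, sim["annotation"], window=750)

de = simple_de(sim["counts"], "WT", "del")
up, down = de_filter(de, fc_cutoff=2.0, p_cutoff=1e-4)
regulon = classify_regulon(up, down, chip_targets, sim["annotation"].gene_ids())

print(f"DE at fold >= 2 and p <= 1e-4: {len(up)} up, {len(down)} down in the deletion")
print(f"ChIP target genes (ORF within 750 bp of a peak): {len(chip_targets)}")
print(regulon.value_counts().to_string())
print()
truth_classes = sim["truth"].gene_classes()
agree = sum(regulon[g] == c for g, c in truth_classes.items())
print(f"agreement with planted truth: {agree}/{len(truth_classes)} genes")
# direct_activated genes are the bound-and-downregulated set -- the
# synthetic analogue of a factor's directly activated biosynthetic targets.
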