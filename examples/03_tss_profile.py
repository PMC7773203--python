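"""Metagene binding profile around the TSS of target genes.

Computes a deepTools-style coverage matrix over [TSS - 1 kb, TSS + 1 kb)
for the bound genes (strand-aware, minus-strand rows reversed so upstream
is always left) and prints the mean profile, for the IP and for the mock.
"""

import numpy as np

from gcn4scope import coverage_matrix, profile, simulate_all

sim = simulate_all(seed=1)
truth = sim["truth"]
targets = sorted(truth.direct_activated | truth.direct_repressed)

for sample in (sim["chip"][0], sim["chip"][-1]):
    mat = coverage_matrix(
        sample, sim["annotation"], targets, anchor="tss", flank=1000, colbin=10
    )
    means, _ = profile(mat)
    peak_at = mat.offsets[np.argmax(means)]
    print(f"{sample.sample_id}: profile max {means.max():.2f} at offset {peak_at:+d} bp "
          f"(mean fold-over-background across {len(targets)} genes)")

# The IP profile peaks a few hundred bp upstream of the TSS (where the
# motifs were planted); the mock stays flat near 1 (background level).
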