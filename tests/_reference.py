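"""Independent brute-force reference implementations used as test oracles.

Deliberately written in plain Python (no numpy, no calls into gcn4scope)
as a direct transcription of the published procedure: midpoint binning,
mode/MAD background normalization, strict >threshold runs, transitive
<gap merging, and >=overlap replicate consensus.
"""

from collections import Counter
from statistics import median


def ref_bin_counts(fragments, chrom_len, bin_size):
    n_bins = (chrom_len + bin_size - 1) // bin_size
    counts = [0] * n_bins
    for start, end in fragments:
        counts[((start + end) // 2) // bin_size] += 1
    return counts


def ref_background(counts):
    freq = Counter(counts)
    best = max(freq.values())
    mu = min(v for v, f in freq.items() if f == best)
    mean = sum(counts) / len(counts)
    sub = [c for c in counts if c < mean]
    med = median(sub)
    x = median([abs(c - med) for c in sub])
    background = [c for c in counts if mu - x <= c <= mu + x]
    divisor = sum(background) / len(background)
    return mu, x, divisor


def ref_call(counts, divisor, bin_size, chrom_len, threshold):
    regions = []
    run_start = None
    for i, c in enumerate(counts):
        if c / divisor > threshold:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            regions.append((run_start * bin_size, min(i * bin_size, chrom_len)))
            run_start = None
    if run_start is not None:
        regions.append((run_start * bin_size, min(len(counts) * bin_size, chrom_len)))
    return regions


def ref_merge(regions, merge_gap):
    # repeated-pass transitive closure; terminates because count shrinks
    regions = sorted(regions)
    changed = True
    while changed:
        changed = False
        out = []
        for r in regions:
            if out and r[0] - out[-1][1] < merge_gap and r[0] >= out[-1][0]:
                out[-1] = (out[-1][0], max(out[-1][1], r[1]))
                changed = True
            else:
                out.append(tuple(r))
        regions = out
    return regions


def ref_consensus(peaks_a, peaks_b, min_overlap):
    unions = []
    for a0, a1 in peaks_a:
        for b0, b1 in peaks_b:
            if min(a1, b1) - max(a0, b0) >= min_overlap:
                unions.append((min(a0, b0), max(a1, b1)))
    return ref_merge(unions, merge_gap=1)


def ref_call_sample(fragments, chrom_len, bin_size, threshold, merge_gap):
    counts = ref_bin_counts(fragments, chrom_len, bin_size)
    _, _, divisor = ref_background(counts)
    return ref_merge(ref_call(counts, divisor, bin_size, chrom_len, threshold), merge_gap)


def ref_pipeline_consensus(frags_a, frags_b, chrom_len, bin_size=100, threshold=2.0,
                           merge_gap=200, min_overlap=50):
    pa = ref_call_sample(frags_a, chrom_len, bin_size, threshold, merge_gap)
    pb = ref_call_sample(frags_b, chrom_len, bin_size, threshold, merge_gap)
    return ref_consensus(pa, pb, min_overlap)


def ref_hypergeom_upper_tail(overlap, size_a, size_b, universe):
    """P(X >= overlap) for X ~ Hypergeom(universe, size_a, size_b), exact."""
    from math import comb

    total = comb(universe, size_b)
    acc = 0
    for k in range(overlap, min(size_a, size_b) + 1):
        acc += comb(size_a, k) * comb(universe - size_a, size_b - k)
    return acc / total


def ref_rank_sum_two_sided(vals_a, vals_b):
    """Exact two-sided rank-sum p by enumerating all labelings (no ties)."""
    from itertools import combinations

    def u_stat(group_a, group_b):
        return sum(sum(1 for y in group_b if x > y) for x in group_a)

    u_obs = u_stat(vals_a, vals_b)
    pooled = list(vals_a) + list(vals_b)
    n_a = len(vals_a)
    us = []
    for combo in combinations(range(len(pooled)), n_a):
        chosen = [pooled[i] for i in combo]
        others = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(u_stat(chosen, others))
    p_le = sum(1 for u in us if u <= u_obs) / len(us)
    p_ge = sum(1 for u in us if u >= u_obs) / len(us)
    return min(1.0, 2.0 * min(p_le, p_ge))
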