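"""Bin-based ChIP-seq peak calling with mode/MAD background normalization.

The caller works on fixed-width non-overlapping bins (default 100 bp). Each
fragment is counted once, in the bin containing its midpoint. The background
of the per-bin count distribution is summarized by its mode ``mu`` (most
frequent integer count, smallest on ties) and ``x``, the unscaled median
absolute deviation of the bins whose count lies below the mean. Bins with
counts in [mu - x, mu + x] are background bins; per-bin counts are divided by
the mean count of those background bins, so a normalized value of 1 means
"background level" and the calling threshold of 2 means two-fold over
background. Runs of bins strictly above the threshold become candidate
regions; regions separated by less than 200 bp are merged; and a peak is
accepted only if both replicates call it with at least 50 bp of overlap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from gcn4scope.core_io import FragmentSet

__all__ = [
    "BinnedCoverage",
    "BackgroundStats",
    "Peak",
    "PeakSet",
    "bin_counts",
    "background_stats",
    "normalize_bins",
    "call_regions",
    "merge_regions",
    "consensus_peaks",
    "replicate_correlation",
    "call_sample_peaks",
]

DEFAULT_BIN_SIZE = 100
DEFAULT_THRESHOLD = 2.0
DEFAULT_MERGE_GAP = 200
DEFAULT_MIN_OVERLAP = 50


@dataclass
class BinnedCoverage:
    """Per-chromosome vectors of fragment counts in fixed-width bins."""

    sample_id: str
    bin_size: int
    counts: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]

    @property
    def n_bins(self) -> int:
        return sum(len(v) for v in self.counts.values())

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in sorted(self.counts)])


@dataclass(frozen=True)
class BackgroundStats:
    """Background summary of a per-bin count distribution.

    mu: mode of the integer counts (smallest on tie). x: unscaled median
    absolute deviation of the bins with count below the mean. divisor: mean
    count of the background bins (counts within [mu - x, mu + x]); dividing
    by it puts background bins at ~1.
    """

    mu: int
    x: float
    divisor: float
    n_background_bins: int


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    peak_id: str = ""
    signal: float = 0.0
    source: str = ""
    feature_class: str | None = None
    target_genes: tuple[str, ...] = ()
    motif_count: int = 0

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "Peak") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def sorted(self) -> "PeakSet":
        return PeakSet(
            peaks=sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end)),
            parameters=dict(self.parameters),
        )

    def intervals(self) -> list[tuple[str, int, int]]:
        return [(p.chrom, p.start, p.end) for p in self.peaks]


# ---------------------------------------------------------------------------


def bin_counts(frags: FragmentSet, chrom_sizes: dict[str, int], bin_size: int = DEFAULT_BIN_SIZE) -> BinnedCoverage:
    """Count fragments into fixed-width non-overlapping bins by midpoint.

    A fragment lands in the bin containing floor((start + end) / 2); the
    truncated terminal bin is included, so every fragment is counted exactly
    once and the bin counts sum to ``frags.total_count``.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    counts = {
        chrom: np.zeros(-(-length // bin_size), dtype=np.int64)
        for chrom, length in chrom_sizes.items()
    }
    for chrom, start, end in frags.fragments:
        if chrom not in counts:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        mid = (start + end) // 2
        if mid >= chrom_sizes[chrom]:
            raise ValueError(
                f"fragment ({chrom}, {start}, {end}) midpoint beyond chromosome end"
            )
        counts[chrom][mid // bin_size] += 1
    return BinnedCoverage(sample_id=frags.sample_id, bin_size=bin_size, counts=counts, chrom_sizes=dict(chrom_sizes))


def background_stats(cov: BinnedCoverage, min_bins: int = 100) -> BackgroundStats:
    """Estimate mode/MAD background statistics from pooled bin counts.

    Pooled genome-wide (all chromosomes in one distribution). Raises if there
    are too few bins, the counts are degenerate, or no bins fall in the
    background window [mu - x, mu + x].
    """
    pooled = cov.pooled()
    if len(pooled) < min_bins:
        raise ValueError(f"need >= {min_bins} bins for background estimation, got {len(pooled)}")
    if pooled.min() == pooled.max():
        raise ValueError("all bin counts identical; background statistics undefined")

    values, freqs = np.unique(pooled, return_counts=True)
    mu = int(values[np.argmax(freqs)])  # np.unique sorts, so ties -> smallest

    mean = pooled.mean()
    sub_mean = pooled[pooled < mean]
    if len(sub_mean) == 0:
        raise ValueError("no bins below the mean; cannot compute deviation x")
    x = float(np.median(np.abs(sub_mean - np.median(sub_mean))))

    mask = (pooled >= mu - x) & (pooled <= mu + x)
    n_bg = int(mask.sum())
    if n_bg == 0:
        raise ValueError("no bins in [mu - x, mu + x]; supply more data or larger bins")
    divisor = float(pooled[mask].mean())
    if divisor <= 0:
        raise ValueError("background divisor is zero (mode at 0 with x = 0); data too sparse")
    return BackgroundStats(mu=mu, x=x, divisor=divisor, n_background_bins=n_bg)


def normalize_bins(
    cov: BinnedCoverage, bg: BackgroundStats, divisor_mode: str = "background_mean"
) -> dict[str, np.ndarray]:
    """Divide bin counts by the background divisor (fold-over-background).

    ``divisor_mode="total"`` instead divides by the total read count in
    background bins (the literal reading of the normalization); with it the
    default threshold of 2 is meaningless and callers must supply their own.
    """
    if divisor_mode == "background_mean":
        d = bg.divisor
    elif divisor_mode == "total":
        d = bg.divisor * bg.n_background_bins
    else:
        raise ValueError(f"unknown divisor_mode {divisor_mode!r}")
    return {chrom: counts / d for chrom, counts in cov.counts.items()}


def call_regions(
    normalized: dict[str, np.ndarray],
    chrom_sizes: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[tuple[str, int, int, float]]:
    """Maximal runs of bins with normalized value strictly above threshold.

    Returns genomic intervals (chrom, start, end, max normalized value in the
    run), with the terminal bin clipped to the chromosome length.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out: list[tuple[str, int, int, float]] = []
    for chrom in sorted(normalized):
        vec = normalized[chrom]
        above = vec > threshold  # "above 2" is strict
        if not above.any():
            continue
        padded = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for b0, b1 in zip(starts, ends):
            out.append(
                (
                    chrom,
                    int(b0) * bin_size,
                    min(int(b1) * bin_size, chrom_sizes[chrom]),
                    float(vec[b0:b1].max()),
                )
            )
    return out


def merge_regions(
    regions: list[tuple[str, int, int, float]], merge_gap: int = DEFAULT_MERGE_GAP
) -> list[tuple[str, int, int, float]]:
    """Merge regions whose gap (next.start - prev.end) is strictly < merge_gap.

    Transitive, idempotent and order-invariant; the merged region's signal is
    the max over its members. Accepts (chrom, start, end) triples too, in
    which case signal defaults to 0.
    """
    normalized = [r if len(r) == 4 else (*r, 0.0) for r in regions]
    merged: list[tuple[str, int, int, float]] = []
    for chrom, group in itertools.groupby(
        sorted(normalized), key=lambda r: r[0]
    ):
        cur = None
        for _, start, end, sig in group:
            if cur is None:
                cur = [start, end, sig]
            elif start - cur[1] < merge_gap:
                cur[1] = max(cur[1], end)
                cur[2] = max(cur[2], sig)
            else:
                merged.append((chrom, cur[0], cur[1], cur[2]))
                cur = [start, end, sig]
        if cur is not None:
            merged.append((chrom, cur[0], cur[1], cur[2]))
    return merged


def call_sample_peaks(
    frags: FragmentSet,
    chrom_sizes: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    threshold: float = DEFAULT_THRESHOLD,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> PeakSet:
    """Full single-sample calling: bin, normalize, threshold, merge."""
    cov = bin_counts(frags, chrom_sizes, bin_size)
    bg = background_stats(cov)
    norm = normalize_bins(cov, bg)
    regions = merge_regions(call_regions(norm, chrom_sizes, bin_size, threshold), merge_gap)
    peaks = [
        Peak(chrom=c, start=s, end=e, signal=sig, source=frags.sample_id,
             peak_id=f"{frags.sample_id}_peak_{i + 1}")
        for i, (c, s, e, sig) in enumerate(regions)
    ]
    return PeakSet(
        peaks=peaks,
        parameters={
            "bin_size": bin_size,
            "threshold": threshold,
            "merge_gap": merge_gap,
            "mu": bg.mu,
            "x": bg.x,
            "divisor": bg.divisor,
        },
    )


def consensus_peaks(
    rep_a: PeakSet, rep_b: PeakSet, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> PeakSet:
    """Replicate-consensus peaks: pairs overlapping by >= min_overlap bp.

    Every qualifying pair contributes the union of the two intervals; chained
    unions (one peak in A matched by several in B or vice versa) are merged
    into a single consensus peak. Signal is the max over contributors;
    provenance records the contributing replicate peak ids.
    """
    unions = []
    contributors: list[tuple[str, str]] = []
    for a in rep_a:
        for b in rep_b:
            if a.overlap(b) >= min_overlap:
                unions.append(
                    (a.chrom, min(a.start, b.start), max(a.end, b.end), max(a.signal, b.signal))
                )
                contributors.append((a.peak_id, b.peak_id))
    # chain overlapping unions into single consensus peaks (gap <= 0 merges)
    merged = merge_regions(unions, merge_gap=1) if unions else []
    peaks = []
    for i, (chrom, start, end, sig) in enumerate(merged):
        ids = sorted(
            {pid for (c, s, e, _), pair in zip(unions, contributors)
             if c == chrom and s >= start and e <= end for pid in pair}
        )
        peaks.append(
            Peak(chrom=chrom, start=start, end=end, signal=sig,
                 source="consensus:" + ";".join(ids), peak_id=f"consensus_peak_{i + 1}")
        )
    params = dict(rep_a.parameters)
    params["min_overlap"] = min_overlap
    return PeakSet(peaks=peaks, parameters=params)


def replicate_correlation(
    cov_a: BinnedCoverage,
    cov_b: BinnedCoverage,
    subsample_n: int | None = None,
    seed: int = 0,
    normalized: bool = True,
) -> float:
    """Pearson correlation of (normalized) bin counts between replicates.

    With ``subsample_n`` a seeded random subset of bins is used, mirroring
    the common QC practice of correlating a random sample of positions.
    """
    if cov_a.bin_size != cov_b.bin_size:
        raise ValueError("replicates binned at different bin sizes")
    a, b = cov_a.pooled().astype(float), cov_b.pooled().astype(float)
    if len(a) != len(b):
        raise ValueError("replicates have different bin counts")
    if normalized:
        a = a / background_stats(cov_a).divisor
        b = b / background_stats(cov_b).divisor
    if subsample_n is not None and subsample_n < len(a):
        idx = np.random.default_rng(seed).choice(len(a), size=subsample_n, replace=False)
        a, b = a[idx], b[idx]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in bin counts; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
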