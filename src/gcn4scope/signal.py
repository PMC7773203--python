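"""Anchor-centered coverage matrices, mean profiles and region comparisons.

Coverage matrices are deepTools-style: one row per gene, columns spanning
[anchor - flank, anchor + flank) at ``colbin`` resolution, in transcript
orientation (rows of minus-strand genes are reversed so upstream is always
on the left). Two value semantics are supported: "normalized" samples the
peak caller's fold-over-background bin values (column aggregation by mean),
while "raw" counts fragment midpoints per base (aggregation by sum, so a
genome-tiling anchor set conserves the total fragment count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from gcn4scope.core_io import FragmentSet, GenomeAnnotation
from gcn4scope.peakcall import BinnedCoverage, background_stats, bin_counts, normalize_bins

__all__ = ["CoverageMatrix", "coverage_matrix", "profile", "compare_region_signal"]


@dataclass
class CoverageMatrix:
    """Per-gene coverage around an anchor, transcript-oriented."""

    gene_ids: list[str]
    offsets: np.ndarray  # column start offsets relative to the anchor
    values: np.ndarray  # shape (n_genes, n_cols)
    truncated: np.ndarray  # bool per row: window clipped at a chromosome end
    anchor: str
    flank: int
    colbin: int


def _per_base_tracks(
    frags: FragmentSet,
    ann: GenomeAnnotation,
    values: str,
    bin_size: int,
) -> dict[str, np.ndarray]:
    if values == "raw":
        tracks = {c: np.zeros(l, dtype=float) for c, l in ann.chrom_sizes.items()}
        for chrom, start, end in frags.fragments:
            tracks[chrom][(start + end) // 2] += 1
        return tracks
    if values == "normalized":
        cov = bin_counts(frags, ann.chrom_sizes, bin_size)
        norm = normalize_bins(cov, background_stats(cov))
        # step-function expansion of bin values to base resolution
        return {
            c: np.repeat(norm[c], bin_size)[: ann.chrom_sizes[c]] for c in norm
        }
    raise ValueError(f"unknown values mode {values!r}")


def coverage_matrix(
    frags: FragmentSet,
    ann: GenomeAnnotation,
    gene_ids: list[str],
    anchor: str = "tss",
    flank: int = 1000,
    colbin: int = 10,
    values: str = "normalized",
    bin_size: int = 100,
) -> CoverageMatrix:
    """Coverage over [anchor - flank, anchor + flank) for each gene.

    ``anchor`` is "tss" (transcription start) or "atg" (translation start,
    the 5' ORF boundary). Rows of minus-strand genes are reversed so that
    negative offsets always mean upstream. Windows running off a chromosome
    end are zero-padded and flagged in ``truncated``.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if (2 * flank) % colbin != 0:
        raise ValueError("colbin must divide 2*flank")
    known = {g.gene_id: g for g in ann.genes}
    missing = [gid for gid in gene_ids if gid not in known]
    if missing:
        raise ValueError(f"unknown gene IDs: {missing[:5]}")

    tracks = _per_base_tracks(frags, ann, values, bin_size)
    n_cols = 2 * flank // colbin
    mat = np.zeros((len(gene_ids), n_cols))
    truncated = np.zeros(len(gene_ids), dtype=bool)
    for i, gid in enumerate(gene_ids):
        g = known[gid]
        if anchor == "tss":
            a = g.tss
        elif anchor == "atg":
            a = g.orf_start if g.strand == "+" else g.orf_end - 1
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        track = tracks[g.chrom]
        lo, hi = a - flank, a + flank
        row = np.zeros(2 * flank)
        clip_lo, clip_hi = max(lo, 0), min(hi, len(track))
        if clip_lo > lo or clip_hi < hi:
            truncated[i] = True
        row[clip_lo - lo : clip_hi - lo] = track[clip_lo:clip_hi]
        if g.strand == "-":
            row = row[::-1]
        agg = row.reshape(n_cols, colbin)
        mat[i] = agg.sum(axis=1) if values == "raw" else agg.mean(axis=1)
    return CoverageMatrix(
        gene_ids=list(gene_ids),
        offsets=np.arange(-flank, flank, colbin),
        values=mat,
        truncated=truncated,
        anchor=anchor,
        flank=flank,
        colbin=colbin,
    )


def profile(matrix: CoverageMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Column means of a coverage matrix plus per-column non-truncated counts."""
    if matrix.values.shape[0] == 0:
        raise ValueError("cannot profile an empty matrix")
    means = matrix.values.mean(axis=0)
    n_clean = int((~matrix.truncated).sum())
    return means, np.full(matrix.values.shape[1], n_clean)


def compare_region_signal(
    norm: dict[str, np.ndarray],
    set_a: list[tuple[str, int, int]],
    set_b: list[tuple[str, int, int]],
    bin_size: int = 100,
) -> tuple[float, float, float, float]:
    """Compare normalized signal between two region sets (Mann-Whitney U).

    Per-region signal is the mean normalized bin value over the region.
    Returns (mean_A, mean_B, U statistic for A, two-sided p). The exact null
    is used when nA + nB <= 20 and there are no ties, the normal
    approximation otherwise.
    """
    def region_means(regions):
        vals = []
        for chrom, start, end in regions:
            if end <= start:
                warnings.warn(f"empty region ({chrom}, {start}, {end}) skipped", stacklevel=2)
                continue
            b0, b1 = start // bin_size, -(-end // bin_size)
            vals.append(float(norm[chrom][b0:b1].mean()))
        return vals

    sig_a, sig_b = region_means(set_a), region_means(set_b)
    if not sig_a or not sig_b:
        raise ValueError("both region sets must be non-empty")
    ties = len(set(sig_a) | set(sig_b)) < len(sig_a) + len(sig_b)
    method = "exact" if (len(sig_a) + len(sig_b) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        sig_a, sig_b, alternative="two-sided", method=method, use_continuity=False
    )
    return (
        float(np.mean(sig_a)),
        float(np.mean(sig_b)),
        float(res.statistic),
        float(res.pvalue),
    )
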