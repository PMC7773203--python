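"""Peak-to-gene target assignment, feature classification and motif scanning.

Target assignment follows the ORF-proximity rule: a gene is a possible
binding target of a peak if its ORF lies within 750 bp on either side of the
peak interval. Feature classification is a transparent midpoint classifier
with precedence promoter > near_TTS > exon > intergenic, where the promoter
window is TSS-1000..TSS+100 in transcript orientation. Motif scanning is an
exhaustive IUPAC consensus scan of both strands (default TGANTCA, the bZIP
general-control element).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from intervaltree import IntervalTree

from gcn4scope.core_io import GenomeAnnotation
from gcn4scope.peakcall import Peak, PeakSet

__all__ = [
    "MotifHit",
    "assign_targets",
    "classify_feature",
    "scan_motif",
    "motif_fraction",
    "annotate_peaks",
]

DEFAULT_TARGET_WINDOW = 750
DEFAULT_PROMOTER_WINDOW = (-1000, 100)
DEFAULT_TTS_WINDOW = (0, 250)
DEFAULT_MOTIF = "TGANTCA"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifHit:
    """A consensus-motif match: 0-based start on the forward strand."""

    pos: int
    strand: str
    matched: str


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for sym in motif.upper():
        if sym not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {sym!r} in motif {motif!r}")
        opts = IUPAC[sym]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping matches are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motif(sequence: str, motif: str = DEFAULT_MOTIF) -> list[MotifHit]:
    """All matches of an IUPAC consensus on both strands of ``sequence``.

    Positions are 0-based starts on the forward strand; overlapping matches
    are all reported. A reverse-strand hit at forward position p corresponds
    to a forward hit at len(seq) - len(motif) - p on the reverse complement.
    """
    fwd = _iupac_regex(motif)
    rev = _iupac_regex(revcomp(motif))
    seq = sequence.upper()
    hits = [MotifHit(m.start(), "+", m.group(1)) for m in fwd.finditer(seq)]
    hits += [MotifHit(m.start(), "-", m.group(1)) for m in rev.finditer(seq)]
    hits.sort(key=lambda h: (h.pos, h.strand))
    return hits


def assign_targets(
    peaks: PeakSet, ann: GenomeAnnotation, window: int = DEFAULT_TARGET_WINDOW
) -> tuple[dict[str, list[str]], set[str]]:
    """Genes whose ORF lies within ``window`` bp of each peak.

    A gene is a target of a peak iff its ORF interval overlaps the extended
    interval [peak.start - window, peak.end + window) by at least 1 bp.
    Returns (peak_id -> sorted gene list, flattened unique target set).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for g in ann.genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.orf_start, g.orf_end, g.gene_id)
    per_peak: dict[str, list[str]] = {}
    all_targets: set[str] = set()
    for p in peaks:
        tree = trees.get(p.chrom)
        lo, hi = max(0, p.start - window), p.end + window
        genes = sorted(iv.data for iv in tree.overlap(lo, hi)) if tree else []
        per_peak[p.peak_id] = genes
        all_targets.update(genes)
    return per_peak, all_targets


def classify_feature(
    peak: Peak,
    ann: GenomeAnnotation,
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    tts_window: tuple[int, int] = DEFAULT_TTS_WINDOW,
) -> str:
    """Classify a peak by its midpoint against strand-aware gene windows.

    Offsets are measured in transcript orientation: promoter if the midpoint
    offset from some gene's TSS lies in [promoter_window[0], promoter_window[1]],
    near_TTS if the offset from a TTS lies in [tts_window[0], tts_window[1]]
    (downstream positive), exon if inside an ORF. Precedence:
    promoter > near_TTS > exon > intergenic.
    """
    mid = peak.midpoint
    is_promoter = is_tts = is_exon = False
    for g in ann.genes:
        if g.chrom != peak.chrom:
            continue
        direction = 1 if g.strand == "+" else -1
        tss_off = (mid - g.tss) * direction
        if promoter_window[0] <= tss_off <= promoter_window[1]:
            is_promoter = True
        tts_off = (mid - g.tts) * direction
        if tts_window[0] <= tts_off <= tts_window[1]:
            is_tts = True
        if g.orf_start <= mid < g.orf_end:
            is_exon = True
    if is_promoter:
        return "promoter"
    if is_tts:
        return "near_TTS"
    if is_exon:
        return "exon"
    return "intergenic"


def motif_fraction(
    peaks: PeakSet, genome: dict[str, str], motif: str = DEFAULT_MOTIF
) -> tuple[float, int, int]:
    """Fraction of peaks whose [start, end) sequence has >= 1 motif hit.

    Returns (fraction, n_with_hit, n_peaks).
    """
    n_with = 0
    for p in peaks:
        if p.chrom not in genome or p.end > len(genome[p.chrom]):
            raise ValueError(f"peak {p.peak_id} outside genome sequence")
        if scan_motif(genome[p.chrom][p.start : p.end], motif):
            n_with += 1
    n = len(peaks)
    return (n_with / n if n else 0.0, n_with, n)


def annotate_peaks(
    peaks: PeakSet,
    ann: GenomeAnnotation,
    genome: dict[str, str] | None = None,
    motif: str = DEFAULT_MOTIF,
    target_window: int = DEFAULT_TARGET_WINDOW,
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    tts_window: tuple[int, int] = DEFAULT_TTS_WINDOW,
) -> PeakSet:
    """Attach targets, feature class and motif counts to every peak."""
    per_peak, _ = assign_targets(peaks, ann, target_window)
    out = []
    for p in peaks:
        n_motifs = 0
        if genome is not None:
            n_motifs = len(scan_motif(genome[p.chrom][p.start : p.end], motif))
        out.append(
            replace(
                p,
                feature_class=classify_feature(p, ann, promoter_window, tts_window),
                target_genes=tuple(per_peak[p.peak_id]),
                motif_count=n_motifs,
            )
        )
    return PeakSet(peaks=out, parameters=dict(peaks.parameters))
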