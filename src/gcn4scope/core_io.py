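"""Readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open. BED is native; GFF3 (1-based
closed) is converted at the boundary; SAM positions come from pysam already
0-based. Text files are UTF-8, tab-delimited.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "FragmentSet",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fragments",
    "write_fragments_bed",
    "read_annotation",
    "write_genes_gff3",
    "read_fasta",
    "write_fasta",
    "read_peaks",
    "write_peaks",
    "read_de_table",
    "read_gene_set",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneRecord:
    """A gene with ORF span, strand and transcript start/termination sites.

    ``tss``/``tts`` satisfy tss <= orf_start and tts >= orf_end on the +
    strand (mirrored on -). ``tss_from_orf`` flags genes whose TSS defaulted
    to the 5' ORF boundary because no TSS table entry existed.
    """

    gene_id: str
    chrom: str
    orf_start: int
    orf_end: int
    strand: str
    tss: int
    tts: int
    tss_from_orf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.orf_start < self.orf_end:
            raise ValueError(f"gene {self.gene_id}: invalid ORF span ({self.orf_start}, {self.orf_end})")
        if self.strand == "+":
            if self.tss > self.orf_start or self.tts < self.orf_end:
                raise ValueError(f"gene {self.gene_id}: TSS/TTS not outside ORF on + strand")
        else:
            if self.tss < self.orf_end - 1 or self.tts > self.orf_start:
                raise ValueError(f"gene {self.gene_id}: TSS/TTS not outside ORF on - strand")


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus gene records; the canonical genome model."""

    chrom_sizes: dict[str, int]
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene ID {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
            if g.orf_end > self.chrom_sizes[g.chrom]:
                raise ValueError(f"gene {g.gene_id}: ORF exceeds chromosome length")

    def gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes}

    def get(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class FragmentSet:
    """Mapped sequencing fragments for one sample as (chrom, start, end)."""

    sample_id: str
    fragments: list[tuple[str, int, int]]

    @property
    def total_count(self) -> int:
        return len(self.fragments)


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length', got {line!r}")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: length not an integer: {parts[1]!r}") from exc
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# fragments (BED / SAM)


def read_fragments(
    path,
    fmt: str = "bed",
    min_mapq: int = 20,
    sample_id: str | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> FragmentSet:
    """Read aligned fragments from a BED3+ or SAM file.

    SAM records with mapping quality below ``min_mapq`` are discarded, as are
    unmapped, secondary and supplementary alignments. Properly paired records
    contribute one fragment spanning the template (taken from the leftmost
    mate); single-end records span (pos, pos + aligned length). BED input is
    taken as-is and ``min_mapq`` is ignored (logged).
    """
    sid = sample_id if sample_id is not None else str(path)
    if fmt == "bed":
        if min_mapq:
            logger.info("BED input: min_mapq=%d ignored (no MAPQ in BED)", min_mapq)
        frags = _read_bed3(path, chrom_sizes)
        return FragmentSet(sample_id=sid, fragments=frags)
    if fmt == "sam":
        return FragmentSet(sample_id=sid, fragments=_read_sam(path, min_mapq, chrom_sizes))
    raise ValueError(f"unknown fragment format {fmt!r} (expected 'bed' or 'sam')")


def _read_bed3(path, chrom_sizes) -> list[tuple[str, int, int]]:
    frags: list[tuple[str, int, int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval ({start}, {end})")
            if chrom_sizes is not None and chrom not in chrom_sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            frags.append((chrom, start, end))
    return frags


def _read_sam(path, min_mapq, chrom_sizes) -> list[tuple[str, int, int]]:
    frags: list[tuple[str, int, int]] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            chrom = rec.reference_name
            if chrom_sizes is not None and chrom not in chrom_sizes:
                raise ValueError(f"{path}: unknown chromosome {chrom!r} for read {rec.query_name}")
            if rec.is_paired and rec.is_proper_pair:
                # count the template once, from the leftmost mate
                if rec.template_length <= 0:
                    continue
                frags.append((chrom, rec.reference_start, rec.reference_start + rec.template_length))
            else:
                frags.append((chrom, rec.reference_start, rec.reference_end))
    return frags


def write_fragments_bed(frags: FragmentSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end in frags.fragments:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# gene annotation (BED6 / GFF3 + TSS table)


def read_annotation(
    genes_path,
    chrom_sizes_path=None,
    tss_path=None,
    chrom_sizes: dict[str, int] | None = None,
) -> GenomeAnnotation:
    """Read gene models from BED6 or GFF3 plus an optional TSS/TTS table.

    GFF3 1-based closed coordinates are converted to internal 0-based
    half-open. The TSS table is a TSV with a header row and columns
    ``gene_id``, ``tss``, and optionally ``tts`` (0-based positions). Genes
    without a TSS entry default the TSS to the 5' ORF boundary and the TTS to
    the 3' boundary and are flagged ``tss_from_orf``.
    """
    if chrom_sizes is None:
        if chrom_sizes_path is None:
            raise ValueError("need chrom_sizes or chrom_sizes_path")
        chrom_sizes = read_chrom_sizes(chrom_sizes_path)

    genes_path = str(genes_path)
    if genes_path.endswith((".gff", ".gff3")):
        raw = _read_genes_gff3(genes_path)
    else:
        raw = _read_genes_bed6(genes_path)

    tss_table = _read_tss_table(tss_path) if tss_path is not None else {}
    known_ids = {gid for gid, *_ in raw}
    orphan = set(tss_table) - known_ids
    if orphan:
        warnings.warn(f"TSS table has {len(orphan)} gene IDs absent from annotation", stacklevel=2)

    genes = []
    for gene_id, chrom, start, end, strand in raw:
        entry = tss_table.get(gene_id)
        if entry is None:
            tss = start if strand == "+" else end - 1
            tts = end if strand == "+" else start
            flagged = True
        else:
            tss, tts = entry
            if tts is None:
                tts = end if strand == "+" else start
            flagged = False
        genes.append(
            GeneRecord(gene_id, chrom, start, end, strand, tss=tss, tts=tts, tss_from_orf=flagged)
        )
    return GenomeAnnotation(chrom_sizes=chrom_sizes, genes=genes)


def _read_genes_bed6(path) -> list[tuple[str, str, int, int, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
            out.append((parts[3], parts[0], int(parts[1]), int(parts[2]), parts[5]))
    return out


def _read_genes_gff3(path) -> list[tuple[str, str, int, int, str]]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    out = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        # GFF3 is 1-based closed; internal is 0-based half-open
        out.append((gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand))
    return out


def _read_tss_table(path) -> dict[str, tuple[int, int | None]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "tss" not in df.columns:
        raise ValueError(f"{path}: TSS table needs 'gene_id' and 'tss' columns")
    has_tts = "tts" in df.columns
    table: dict[str, tuple[int, int | None]] = {}
    for row in df.itertuples(index=False):
        table[str(row.gene_id)] = (int(row.tss), int(row.tts) if has_tts else None)
    return table


def write_genes_gff3(ann: GenomeAnnotation, path) -> None:
    """Write gene records as GFF3 (converting back to 1-based closed)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for name, length in ann.chrom_sizes.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in ann.genes:
            fh.write(
                f"{g.chrom}\tgcn4scope\tgene\t{g.orf_start + 1}\t{g.orf_end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_tss_table(ann: GenomeAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\ttss\ttts\n")
        for g in ann.genes:
            fh.write(f"{g.gene_id}\t{g.tss}\t{g.tts}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# peaks (BED6+3)

_PEAK_COLUMNS = 9  # chrom start end id signal strand(.) feature targets motifs


def write_peaks(peaks, path) -> None:
    """Write a PeakSet as BED6+3; round-trips losslessly through read_peaks.

    Columns: chrom, start, end, peak_id, normalized signal, ".",
    feature_class, target_genes (comma-separated), motif_count.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for p in peaks:
            targets = ",".join(p.target_genes) if p.target_genes else "."
            feature = p.feature_class if p.feature_class else "."
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.signal:.6g}\t.\t"
                f"{feature}\t{targets}\t{p.motif_count}\n"
            )


def read_peaks(path):
    """Read a BED6+3 peak file written by :func:`write_peaks`."""
    from gcn4scope.peakcall import Peak, PeakSet

    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < _PEAK_COLUMNS:
                raise ValueError(f"{path}:{lineno}: expected {_PEAK_COLUMNS} columns")
            out.append(
                Peak(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    peak_id=parts[3],
                    signal=float(parts[4]),
                    feature_class=None if parts[6] == "." else parts[6],
                    target_genes=() if parts[7] == "." else tuple(parts[7].split(",")),
                    motif_count=int(parts[8]),
                )
            )
    return PeakSet(peaks=out)


# ---------------------------------------------------------------------------
# DE tables and gene sets


def read_de_table(path):
    """Read a DE result TSV with columns gene_id, log2fc, pvalue."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicate gene IDs {dupes[:5]}")
    bad_p = (df["pvalue"] < 0) | (df["pvalue"] > 1)
    if bad_p.any():
        raise ValueError(f"{path}: p-values outside [0, 1]")
    return df.set_index("gene_id")


def read_gene_set(path) -> set[str]:
    """Read a gene set file: one gene ID per line."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def normalize_gene_id(gene_id: str, strip_version: bool = False) -> str:
    """Optional gene-ID normalization hook (off by default: case-sensitive)."""
    if strip_version and "." in gene_id:
        return gene_id.rsplit(".", 1)[0]
    return gene_id
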