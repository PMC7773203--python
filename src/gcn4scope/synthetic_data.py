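"""Synthetic genome, ChIP, expression and proteome data with planted truth.

Every downstream stage of the pipeline is testable without downloads: this
module builds a toy genome with non-overlapping genes, writes bZIP consensus
motifs (TGANTCA) into the promoters of chosen target genes, plants ChIP
enrichment over those motifs, simulates IP replicates plus a mock sample by
a fragment-midpoint rate model, draws negative-binomial expression counts
with planted activation/repression in the deletion condition, and emits a
proteome whose translation-related genes are R+K rich.

Default scale is one 200 kb chromosome with 80 genes and 2x10^5 fragments
per sample: large enough that background bins are well populated (about 100
fragments per 100 bp bin) and a full pipeline run takes seconds.

Randomness: every operation derives an independent stream from its seed via
``numpy.random.default_rng([seed, STREAM_CONSTANT])``, so the stages are
individually reproducible and mutually independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from gcn4scope.core_io import FragmentSet, GeneRecord, GenomeAnnotation

__all__ = [
    "SyntheticTruth",
    "make_genome",
    "make_genes",
    "plant_motifs_and_peaks",
    "simulate_chip",
    "simulate_de_counts",
    "simulate_proteome",
    "simulate_all",
    "DEFAULTS",
]

TRUTH_SCHEMA_VERSION = 1

# per-stage stream constants for rng derivation
_STREAM = {
    "genome": 1,
    "genes": 2,
    "plant": 3,
    "chip": 4,
    "de": 5,
    "proteome": 6,
    "choose_targets": 7,
    "classes": 8,
}

DEFAULTS = dict(
    n_chrom=1,
    chrom_len=200_000,
    gc=0.38,
    n_genes=80,
    orf_len_range=(600, 1800),
    utr5_range=(50, 200),
    motif="TGANTCA",
    enrichment=8.0,
    peak_width_range=(200, 400),
    depth=200_000,
    frag_len=200,
    n_rep=2,
    n_cond_reps=2,
    nb_dispersion=0.001,
    effect_log2fc=2.0,
    # non-translation background mixture; the overall 25/50/25 proteome split
    # includes the translation genes that dominate bin3, so the background
    # share of bin3 is lower
    bin_fractions=(0.28, 0.57, 0.15),
    n_direct_activated=16,
    n_direct_repressed=6,
    frac_indirect_activated=0.20,
    frac_indirect_repressed=0.15,
    frac_translation=0.25,
)

IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# the 18 non-R/K standard amino acids used to pad simulated proteins
_NON_RK = "ACDEFGHILMNPQSTVWY"


@dataclass
class SyntheticTruth:
    """Planted ground truth consumed by downstream recovery tests."""

    planted_peaks: list[tuple[str, int, int, float]]
    motif_positions: list[tuple[str, int, str]]
    direct_activated: set[str] = field(default_factory=set)
    direct_repressed: set[str] = field(default_factory=set)
    indirect_activated: set[str] = field(default_factory=set)
    indirect_repressed: set[str] = field(default_factory=set)
    null_genes: set[str] = field(default_factory=set)
    rk_bins_truth: dict[str, str] = field(default_factory=dict)
    translation_genes: set[str] = field(default_factory=set)
    seed: int = 0
    schema_version: int = TRUTH_SCHEMA_VERSION

    def gene_classes(self) -> dict[str, str]:
        out = {}
        for label in (
            "direct_activated",
            "direct_repressed",
            "indirect_activated",
            "indirect_repressed",
        ):
            for g in getattr(self, label):
                out[g] = label
        for g in self.null_genes:
            out[g] = "not_regulated"
        return out

    def to_json(self, path) -> None:
        payload = {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "planted_peaks": self.planted_peaks,
            "motif_positions": self.motif_positions,
            "direct_activated": sorted(self.direct_activated),
            "direct_repressed": sorted(self.direct_repressed),
            "indirect_activated": sorted(self.indirect_activated),
            "indirect_repressed": sorted(self.indirect_repressed),
            "null_genes": sorted(self.null_genes),
            "rk_bins_truth": self.rk_bins_truth,
            "translation_genes": sorted(self.translation_genes),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        if d["schema_version"] != TRUTH_SCHEMA_VERSION:
            raise ValueError(f"truth schema version {d['schema_version']} unsupported")
        return cls(
            planted_peaks=[tuple(p) for p in d["planted_peaks"]],
            motif_positions=[tuple(m) for m in d["motif_positions"]],
            direct_activated=set(d["direct_activated"]),
            direct_repressed=set(d["direct_repressed"]),
            indirect_activated=set(d["indirect_activated"]),
            indirect_repressed=set(d["indirect_repressed"]),
            null_genes=set(d["null_genes"]),
            rk_bins_truth=dict(d["rk_bins_truth"]),
            translation_genes=set(d["translation_genes"]),
            seed=d["seed"],
        )


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stage]])


# ---------------------------------------------------------------------------
# genome and genes


def make_genome(
    n_chrom: int = 1, chrom_len: int = 200_000, gc: float = 0.38, seed: int = 0
) -> tuple[dict[str, str], dict[str, int]]:
    """I.i.d. random genome at a stated GC content; deterministic per seed."""
    if not 0 < gc < 1:
        raise ValueError("gc must be a fraction in (0, 1)")
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10000")
    rng = _rng(seed, "genome")
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = {}
    for i in range(n_chrom):
        bases = rng.choice(np.array(list("ACGT")), size=chrom_len, p=probs)
        genome[f"chr{_roman(i + 1)}"] = "".join(bases)
    sizes = {name: len(seq) for name, seq in genome.items()}
    return genome, sizes


def _roman(n: int) -> str:
    numerals = [(10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = ""
    for val, sym in numerals:
        while n >= val:
            out += sym
            n -= val
    return out


def make_genes(
    chrom_sizes: dict[str, int],
    n_genes: int = 80,
    orf_len_range: tuple[int, int] = (600, 1800),
    utr5_range: tuple[int, int] = (50, 200),
    utr3_range: tuple[int, int] = (50, 150),
    seed: int = 0,
    max_attempts: int = 10_000,
) -> GenomeAnnotation:
    """Place non-overlapping genes (ORF + UTRs) by rejection sampling.

    Strands are Bernoulli(0.5); the TSS sits uniformly utr5_range bp
    upstream of the ORF (transcript orientation) and the TTS utr3_range bp
    downstream. Genes do not overlap at the transcript level.
    """
    total = sum(chrom_sizes.values())
    mean_span = (
        sum(orf_len_range) / 2 + sum(utr5_range) / 2 + sum(utr3_range) / 2
    )
    need = int(n_genes * mean_span)
    if need > total:
        raise ValueError(f"genome too small for {n_genes} genes: need about {need} bp, have {total}")
    rng = _rng(seed, "genes")
    chroms = sorted(chrom_sizes)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneRecord] = []
    attempts = 0
    while len(genes) < n_genes:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(f"could not place {n_genes} genes in {max_attempts} attempts")
        chrom = chroms[rng.integers(len(chroms))]
        length = chrom_sizes[chrom]
        orf_len = int(rng.integers(orf_len_range[0], orf_len_range[1] + 1))
        utr5 = int(rng.integers(utr5_range[0], utr5_range[1] + 1))
        utr3 = int(rng.integers(utr3_range[0], utr3_range[1] + 1))
        span = orf_len + utr5 + utr3
        if span + 2 > length:
            continue
        tx_start = int(rng.integers(1, length - span - 1))
        tx_end = tx_start + span
        if any(s < tx_end and tx_start < e for s, e in occupied[chrom]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            orf_start, orf_end = tx_start + utr5, tx_start + utr5 + orf_len
            tss, tts = tx_start, tx_end
        else:
            orf_start, orf_end = tx_start + utr3, tx_start + utr3 + orf_len
            tss, tts = tx_end - 1, tx_start
        occupied[chrom].append((tx_start, tx_end))
        genes.append(
            GeneRecord(
                gene_id=f"SYN{len(genes) + 1:04d}",
                chrom=chrom,
                orf_start=orf_start,
                orf_end=orf_end,
                strand=strand,
                tss=tss,
                tts=tts,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.orf_start))
    return GenomeAnnotation(chrom_sizes=dict(chrom_sizes), genes=genes)


# ---------------------------------------------------------------------------
# motif + peak planting


def _resolve_iupac(motif: str, rng: np.random.Generator) -> str:
    out = []
    for sym in motif.upper():
        if sym not in IUPAC_CHOICES:
            raise ValueError(f"invalid IUPAC symbol {sym!r}")
        choices = IUPAC_CHOICES[sym]
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def plant_motifs_and_peaks(
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    target_genes: set[str],
    motif: str = "TGANTCA",
    enrichment: float = 8.0,
    peak_width_range: tuple[int, int] = (200, 400),
    promoter_window: tuple[int, int] = (-1000, 100),
    seed: int = 0,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Write one motif instance into each target gene's promoter; plant a peak.

    The motif (random IUPAC resolution, random strand) is placed uniformly in
    the promoter window (default TSS-1000..TSS+100 in transcript
    orientation, clipped to the chromosome); the planted peak is centered on
    the motif with a width drawn from ``peak_width_range``. Genes whose
    clipped promoter is shorter than the motif are skipped with a warning
    and excluded from the truth.

    The returned truth has its ``direct_*``/``indirect_*``/``null`` gene
    sets unpopulated except for peak/motif coordinates; use
    :func:`assign_truth_classes` (or :func:`simulate_all`) to fill them.
    """
    import warnings

    rng = _rng(seed, "plant")
    known = {g.gene_id: g for g in annotation.genes}
    missing = target_genes - set(known)
    if missing:
        raise ValueError(f"unknown target genes: {sorted(missing)[:5]}")
    mutable = {c: list(s) for c, s in genome.items()}
    peaks: list[tuple[str, int, int, float]] = []
    motifs: list[tuple[str, int, str]] = []
    planted_for: set[str] = set()
    for gid in sorted(target_genes):
        g = known[gid]
        length = annotation.chrom_sizes[g.chrom]
        if g.strand == "+":
            lo, hi = g.tss + promoter_window[0], g.tss + promoter_window[1]
        else:
            lo, hi = g.tss - promoter_window[1], g.tss - promoter_window[0]
        lo, hi = max(0, lo), min(length, hi)
        if hi - lo < len(motif):
            warnings.warn(f"promoter of {gid} shorter than motif; gene skipped", stacklevel=2)
            continue
        pos = int(rng.integers(lo, hi - len(motif) + 1))
        instance = _resolve_iupac(motif, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        written = instance if strand == "+" else instance.translate(_DNA_COMPLEMENT)[::-1]
        mutable[g.chrom][pos : pos + len(motif)] = list(written)
        motifs.append((g.chrom, pos, strand))
        width = int(rng.integers(peak_width_range[0], peak_width_range[1] + 1))
        center = pos + len(motif) // 2
        peaks.append(
            (g.chrom, max(0, center - width // 2), min(length, center + (width + 1) // 2), enrichment)
        )
        planted_for.add(gid)
    truth = SyntheticTruth(planted_peaks=peaks, motif_positions=motifs, seed=seed)
    return {c: "".join(s) for c, s in mutable.items()}, truth


def assign_truth_classes(
    truth: SyntheticTruth,
    annotation: GenomeAnnotation,
    target_window: int = 750,
    frac_indirect_activated: float = 0.20,
    frac_indirect_repressed: float = 0.15,
    direct_repressed_frac: float = 0.25,
    seed: int = 0,
) -> SyntheticTruth:
    """Partition all genes into the five regulon truth classes.

    Direct genes are recomputed from the planted peaks with the same
    ORF-within-750-bp rule the annotation stage applies, so the invariant
    "every direct gene is near a peak; no indirect/null gene is" holds by
    construction even when a planted peak brushes a neighboring gene.
    """
    rng = _rng(seed, "classes")
    near_peak: set[str] = set()
    for g in annotation.genes:
        for chrom, start, end, _ in truth.planted_peaks:
            if g.chrom == chrom and g.orf_start < end + target_window and start - target_window < g.orf_end:
                near_peak.add(g.gene_id)
                break
    direct = sorted(near_peak)
    n_rep = max(1, int(round(direct_repressed_frac * len(direct)))) if direct else 0
    rep_idx = set(rng.choice(len(direct), size=n_rep, replace=False)) if direct else set()
    truth.direct_repressed = {g for i, g in enumerate(direct) if i in rep_idx}
    truth.direct_activated = set(direct) - truth.direct_repressed

    others = sorted(set(annotation.gene_ids()) - near_peak)
    rng.shuffle(others)
    n_ia = int(round(frac_indirect_activated * len(others)))
    n_ir = int(round(frac_indirect_repressed * len(others)))
    truth.indirect_activated = set(others[:n_ia])
    truth.indirect_repressed = set(others[n_ia : n_ia + n_ir])
    truth.null_genes = set(others[n_ia + n_ir :])
    return truth


# ---------------------------------------------------------------------------
# ChIP fragment simulation


def simulate_chip(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    depth: int = 200_000,
    frag_len: int = 200,
    n_rep: int = 2,
    bin_size: int = 100,
    seed: int = 0,
) -> list[FragmentSet]:
    """Simulate IP replicates plus one mock sample by a midpoint-rate model.

    Background fragment midpoints are uniform over the genome; inside a
    planted peak the local rate is multiplied by that peak's enrichment fold
    for IP samples only. The mock sample is pure background. Replicates are
    i.i.d. given distinct derived seeds. Returns n_rep IP FragmentSets
    followed by the mock.
    """
    n_bins = sum(-(-l // bin_size) for l in annotation.chrom_sizes.values())
    if depth < 10 * n_bins:
        raise ValueError(
            f"depth {depth} too low: need >= 10 fragments per bin ({10 * n_bins}) "
            "for a non-degenerate background mode"
        )
    chroms = sorted(annotation.chrom_sizes)
    offsets = np.cumsum([0] + [annotation.chrom_sizes[c] for c in chroms])
    total_len = int(offsets[-1])

    # per-base relative rate: 1 + (fold - 1) inside IP peaks
    extra_weight = np.zeros(total_len)
    for chrom, start, end, fold in truth.planted_peaks:
        ci = chroms.index(chrom)
        extra_weight[offsets[ci] + start : offsets[ci] + end] = fold - 1.0

    samples = []
    for rep in range(n_rep + 1):
        is_mock = rep == n_rep
        rng = np.random.default_rng([int(seed), _STREAM["chip"], rep])
        weights = np.ones(total_len) + (0.0 if is_mock else extra_weight)
        weights /= weights.sum()
        mids = rng.choice(total_len, size=depth, p=weights)
        frags = []
        for m in np.sort(mids):
            ci = int(np.searchsorted(offsets, m, side="right") - 1)
            local = int(m - offsets[ci])
            chrom = chroms[ci]
            length = annotation.chrom_sizes[chrom]
            start = max(0, local - frag_len // 2)
            end = min(length, local + (frag_len + 1) // 2)
            # keep the midpoint exact even at chromosome edges
            if (start + end) // 2 != local:
                start, end = max(0, 2 * local - end), min(length, 2 * local - start)
            frags.append((chrom, start, end))
        sid = "mock" if is_mock else f"IP_rep{rep + 1}"
        samples.append(FragmentSet(sample_id=sid, fragments=frags))
    return samples


# ---------------------------------------------------------------------------
# expression counts


def simulate_de_counts(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    n_cond_reps: int = 2,
    nb_dispersion: float = 0.001,
    effect_log2fc: float = 2.0,
    mean_range: tuple[float, float] = (20.0, 500.0),
    seed: int = 0,
):
    """Negative-binomial expression counts for WT and deletion conditions.

    Gene base means are log-uniform over ``mean_range``. Activated genes
    (direct or indirect) have their deletion-condition mean divided by
    2**effect_log2fc; repressed genes have it multiplied. Dispersion is the
    NB alpha (var = mu + alpha*mu^2) shared across genes. Returns a pandas
    DataFrame gene x sample with columns WT_1.. and del_1.. .
    """
    import pandas as pd

    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = _rng(seed, "de")
    gene_ids = [g.gene_id for g in annotation.genes]
    base = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=len(gene_ids)))
    classes = truth.gene_classes()
    factor = np.ones(len(gene_ids))
    for i, gid in enumerate(gene_ids):
        cls = classes.get(gid, "not_regulated")
        if cls.endswith("_activated"):
            factor[i] = 2.0 ** (-effect_log2fc)
        elif cls.endswith("_repressed"):
            factor[i] = 2.0**effect_log2fc
    if np.any(base <= 0):
        raise ValueError("non-positive gene means")

    def draw(mu: np.ndarray) -> np.ndarray:
        # NB via gamma-Poisson: shape r = 1/alpha, scale mu*alpha
        r = 1.0 / nb_dispersion
        lam = rng.gamma(shape=r, scale=mu / r)
        return rng.poisson(lam)

    data = {}
    for rep in range(n_cond_reps):
        data[f"WT_{rep + 1}"] = draw(base)
    for rep in range(n_cond_reps):
        data[f"del_{rep + 1}"] = draw(base * factor)
    df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    return df


# ---------------------------------------------------------------------------
# proteome


def simulate_proteome(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    bin_fractions: tuple[float, float, float] = (0.25, 0.50, 0.25),
    translation_gene_set: set[str] | None = None,
    translation_gene_frac: float = 0.20,
    translation_bin3_prob: float = 0.95,
    translation_range: tuple[float, float] = (14.5, 21.0),
    length_range: tuple[int, int] = (150, 600),
    seed: int = 0,
) -> dict[str, str]:
    """Protein sequences whose %R+K follows a three-component mixture.

    Component target ranges sit strictly inside the bins (5-9.9, 10.1-12.9,
    13.1-20 %R+K) so integer rounding of residue counts cannot cross a bin
    boundary; realized composition is within 0.5 percentage points of the
    target. Translation-related genes (``translation_gene_set``, or a random
    ``translation_gene_frac`` share if None) are drawn predominantly (prob
    ``translation_bin3_prob``) from a ribosomal-protein-like high-R+K
    component spanning ``translation_range`` inside bin3. Fills
    ``truth.rk_bins_truth`` and ``truth.translation_genes``.
    """
    if abs(sum(bin_fractions) - 1.0) > 1e-9:
        raise ValueError("bin_fractions must sum to 1")
    rng = _rng(seed, "proteome")
    ranges = {"bin1": (5.0, 9.9), "bin2": (10.1, 12.9), "bin3": (13.1, 20.0)}
    gene_ids = [g.gene_id for g in annotation.genes]
    if translation_gene_set is None:
        n_trans = int(round(translation_gene_frac * len(gene_ids)))
        trans_idx = rng.choice(len(gene_ids), size=n_trans, replace=False)
        translation_gene_set = {gene_ids[int(i)] for i in trans_idx}
    else:
        missing = translation_gene_set - set(gene_ids)
        if missing:
            raise ValueError(f"unknown translation genes: {sorted(missing)[:5]}")
    proteome: dict[str, str] = {}
    for gid in gene_ids:
        if gid in translation_gene_set:
            if rng.random() < translation_bin3_prob:
                comp, (lo, hi) = "bin3", translation_range
            else:
                comp = "bin2"
                lo, hi = ranges[comp]
        else:
            comp = ["bin1", "bin2", "bin3"][rng.choice(3, p=np.asarray(bin_fractions))]
            lo, hi = ranges[comp]
        target = rng.uniform(lo, hi)
        if target > 100:
            raise ValueError("infeasible composition > 100%")
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        n_rk = int(round(target / 100.0 * length))
        rk_part = ["R" if rng.random() < 0.5 else "K" for _ in range(n_rk)]
        other = [(_NON_RK[j]) for j in rng.integers(0, len(_NON_RK), size=length - 1 - n_rk)]
        body = rk_part + other
        rng.shuffle(body)
        proteome[gid] = "M" + "".join(body)
        truth.rk_bins_truth[gid] = comp
        if gid in translation_gene_set:
            truth.translation_genes.add(gid)
    return proteome


# ---------------------------------------------------------------------------
# one-call convenience


def simulate_all(seed: int = 0, **overrides):
    """Build the full default synthetic study; returns a dict of artifacts.

    Keys: genome, chrom_sizes, annotation, truth, chip (list of
    FragmentSets, IP replicates then mock), counts (DataFrame), proteome.
    """
    p = dict(DEFAULTS)
    p.update(overrides)
    genome, sizes = make_genome(p["n_chrom"], p["chrom_len"], p["gc"], seed)
    ann = make_genes(sizes, p["n_genes"], p["orf_len_range"], p["utr5_range"], seed=seed)
    rng = _rng(seed, "choose_targets")
    ids = [g.gene_id for g in ann.genes]
    n_direct = p["n_direct_activated"] + p["n_direct_repressed"]
    chosen = set(np.array(ids)[rng.choice(len(ids), size=n_direct, replace=False)])
    genome, truth = plant_motifs_and_peaks(
        genome, ann, chosen, p["motif"], p["enrichment"], p["peak_width_range"], seed=seed
    )
    truth = assign_truth_classes(
        truth,
        ann,
        frac_indirect_activated=p["frac_indirect_activated"],
        frac_indirect_repressed=p["frac_indirect_repressed"],
        seed=seed,
    )
    chip = simulate_chip(ann, truth, p["depth"], p["frag_len"], p["n_rep"], seed=seed)
    counts = simulate_de_counts(
        ann, truth, p["n_cond_reps"], p["nb_dispersion"], p["effect_log2fc"], seed=seed
    )
    # translation-related genes = the factor-repressed genes plus a few
    # unregulated ones: repression concentrates on the R+K-rich machinery
    rng2 = _rng(seed, "proteome")
    repressed = truth.direct_repressed | truth.indirect_repressed
    n_extra = max(0, int(round(p["frac_translation"] * p["n_genes"])) - len(repressed))
    nulls = sorted(truth.null_genes)
    extra = {nulls[int(i)] for i in rng2.choice(len(nulls), size=min(n_extra, len(nulls)), replace=False)}
    proteome = simulate_proteome(
        ann, truth, p["bin_fractions"], translation_gene_set=repressed | extra, seed=seed
    )
    return {
        "genome": genome,
        "chrom_sizes": sizes,
        "annotation": ann,
        "truth": truth,
        "chip": chip,
        "counts": counts,
        "proteome": proteome,
        "params": p,
    }
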