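"""ChIP-RNA integration: DE filtering, regulon classes, set enrichment.

The regulon classification crosses differential-expression calls from a
deletion-vs-wild-type contrast with ChIP target status. Orientation follows
the deletion contrast: a gene DOWN in the deletion is ACTIVATED by the
factor, and a gene UP is REPRESSED by it. Genes both differentially
expressed and within the peak-proximity window are direct targets; the rest
of the differentially expressed genes are indirect.

``simple_de`` is a deliberately simple stand-in for a full negative-binomial
DE analysis (edgeR/DESeq2 class): CPM normalization, log2 fold change of
mean CPM with a 0.5 pseudocount, and an exact binomial test on pooled counts
against the pooled library-size ratio. It is approximately calibrated only
for near-Poisson replicates and exists so the synthetic pipeline can run
end-to-end; real analyses should supply an externally computed DE table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "de_filter",
    "classify_regulon",
    "set_enrichment",
    "simple_de",
    "REGULON_CLASSES",
]

REGULON_CLASSES = (
    "direct_activated",
    "indirect_activated",
    "direct_repressed",
    "indirect_repressed",
    "not_regulated",
)


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 overlap table with Fisher exact p-value and odds ratio."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    pvalue: float
    universe: int
    overlap_frac_a: float  # |A n B| / |A|
    overlap_frac_b: float  # |A n B| / |B|


def de_filter(
    table: pd.DataFrame,
    fc_cutoff: float = 2.0,
    p_cutoff: float = 1e-4,
    correction: str | None = None,
) -> tuple[set[str], set[str]]:
    """Up/down gene sets at a fold-change and p-value cutoff.

    up = {log2fc >= log2(fc_cutoff), p <= p_cutoff}; down mirrored. Both
    comparisons are inclusive, on raw p-values by default (the stringent
    raw-p design); ``correction="bh"`` applies Benjamini-Hochberg first.
    ``table`` is indexed by gene_id with columns log2fc and pvalue (see
    :func:`gcn4scope.core_io.read_de_table`).
    """
    if fc_cutoff < 1:
        raise ValueError("fc_cutoff must be >= 1 (a fold change)")
    if not 0 < p_cutoff <= 1:
        raise ValueError("p_cutoff must be in (0, 1]")
    pvals = table["pvalue"]
    if correction == "bh":
        pvals = pd.Series(
            stats.false_discovery_control(pvals.to_numpy(), method="bh"),
            index=table.index,
        )
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r} (use 'bh' or None)")
    lfc = np.log2(fc_cutoff)
    passing = table[pvals <= p_cutoff]
    up = set(passing.index[passing["log2fc"] >= lfc])
    down = set(passing.index[passing["log2fc"] <= -lfc])
    return up, down


def classify_regulon(
    up: set[str], down: set[str], chip_targets: set[str], universe: set[str]
) -> pd.Series:
    """Five-way regulon partition of the gene universe.

    With the deletion-vs-WT orientation: direct_activated = down n targets;
    indirect_activated = down \\ targets; direct_repressed = up n targets;
    indirect_repressed = up \\ targets; everything else not_regulated.
    """
    if up & down:
        raise ValueError(f"genes both up and down: {sorted(up & down)[:5]}")
    for name, s in (("up", up), ("down", down)):
        extra = s - universe
        if extra:
            raise ValueError(f"{name} set contains genes outside the universe: {sorted(extra)[:5]}")
    classes = {}
    for g in universe:
        if g in down:
            classes[g] = "direct_activated" if g in chip_targets else "indirect_activated"
        elif g in up:
            classes[g] = "direct_repressed" if g in chip_targets else "indirect_repressed"
        else:
            classes[g] = "not_regulated"
    return pd.Series(classes, name="regulon_class").sort_index()


def set_enrichment(
    set_a: set[str],
    set_b: set[str],
    universe_size: int,
    alternative: str = "greater",
) -> EnrichmentResult:
    """One-sided Fisher exact test of overlap between two gene sets.

    Table: [[|AnB|, |A\\B|], [|B\\A|, N - |AuB|]]; the default alternative
    "greater" tests for enrichment (hypergeometric upper tail).
    """
    n_union = len(set_a | set_b)
    if universe_size < n_union:
        raise ValueError(f"universe size {universe_size} smaller than |A u B| = {n_union}")
    a = len(set_a & set_b)
    b = len(set_a) - a
    c = len(set_b) - a
    d = universe_size - n_union
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(
        table=((a, b), (c, d)),
        odds_ratio=float(odds),
        pvalue=float(p),
        universe=universe_size,
        overlap_frac_a=a / len(set_a) if set_a else 0.0,
        overlap_frac_b=a / len(set_b) if set_b else 0.0,
    )


def _binom_two_sided(k: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Vectorized two-sided exact binomial p (doubled smaller tail)."""
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def simple_de(
    counts: pd.DataFrame,
    condition_a: str = "WT",
    condition_b: str = "del",
) -> pd.DataFrame:
    """Simplified differential expression on a gene x sample count matrix.

    Columns are named ``<condition>_<replicate>``. Returns a DataFrame
    indexed by gene_id with columns log2fc (B vs A, CPM scale, pseudocount
    0.5) and pvalue (two-sided exact binomial on pooled counts against the
    pooled library-size ratio). All-zero genes get log2fc 0, p 1 and are
    flagged in the ``allzero`` column.
    """
    cols_a = [c for c in counts.columns if c.startswith(condition_a + "_")]
    cols_b = [c for c in counts.columns if c.startswith(condition_b + "_")]
    if not cols_a or not cols_b:
        raise ValueError(f"need >= 1 replicate per condition; columns: {list(counts.columns)}")

    lib = counts.sum(axis=0).astype(float)
    cpm = counts / lib * 1e6
    mean_a = cpm[cols_a].mean(axis=1)
    mean_b = cpm[cols_b].mean(axis=1)
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))

    pooled_a = counts[cols_a].sum(axis=1).to_numpy()
    pooled_b = counts[cols_b].sum(axis=1).to_numpy()
    n = pooled_a + pooled_b
    p0 = float(lib[cols_b].sum() / (lib[cols_a].sum() + lib[cols_b].sum()))
    with np.errstate(invalid="ignore"):
        pvals = _binom_two_sided(pooled_b, n, p0)

    allzero = n == 0
    out = pd.DataFrame(
        {
            "log2fc": np.where(allzero, 0.0, log2fc),
            "pvalue": np.where(allzero, 1.0, pvals),
            "allzero": allzero,
        },
        index=counts.index,
    )
    out.index.name = "gene_id"
    return out
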