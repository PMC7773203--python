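"""Proteome arginine/lysine composition binning and enrichment analysis.

Each protein's %R+K (percentage of arginine plus lysine residues, initiator
methionine included) places it in one of three bins: bin1 < 10%,
bin2 10-13% (boundaries inclusive to bin2), bin3 > 13%. Translation-related
proteins are strongly R+K rich, so gene sets repressed by a factor that
supplies these amino acids concentrate in bin3; bin membership of a gene set
is tested with a one-sided Fisher exact test and group compositions are
compared with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gcn4scope.integrate import EnrichmentResult, set_enrichment

__all__ = [
    "ProteomeBins",
    "rk_fraction",
    "bin_proteome",
    "bin_enrichment",
    "composition_compare",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
DEFAULT_LOW = 10.0
DEFAULT_HIGH = 13.0
BIN_LABELS = ("bin1", "bin2", "bin3")


@dataclass
class ProteomeBins:
    """Per-protein %R+K with bin assignment; partitions the proteome."""

    table: pd.DataFrame  # index gene_id; columns length, rk_count, rk_percent, bin
    mode: str
    low: float
    high: float

    def bin_sizes(self) -> dict[str, int]:
        counts = self.table["bin"].value_counts()
        return {b: int(counts.get(b, 0)) for b in BIN_LABELS}

    def members(self, bin_label: str) -> set[str]:
        return set(self.table.index[self.table["bin"] == bin_label])


def rk_fraction(sequence: str) -> float:
    """Percentage of R+K residues in a protein sequence.

    The initiator methionine counts in the length; a trailing stop symbol
    '*' is stripped; 'X' is tolerated (counts in length, never as R or K).
    """
    seq = sequence.upper().rstrip("*")
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid symbols in sequence: {sorted(bad)}")
    return 100.0 * (seq.count("R") + seq.count("K")) / len(seq)


def bin_proteome(
    proteome: dict[str, str],
    mode: str = "fixed",
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> ProteomeBins:
    """Partition a proteome into three %R+K bins.

    ``fixed`` mode uses the cut points (default 10% and 13%), with both
    boundary values assigned to bin2. ``tercile`` mode cuts at the empirical
    1/3 and 2/3 quantiles instead.
    """
    if len(proteome) < 3:
        raise ValueError("need at least 3 proteins to bin")
    rows = []
    for gene_id, seq in proteome.items():
        s = seq.upper().rstrip("*")
        rk = s.count("R") + s.count("K")
        rows.append((gene_id, len(s), rk, rk_fraction(seq)))
    table = pd.DataFrame(rows, columns=["gene_id", "length", "rk_count", "rk_percent"]).set_index(
        "gene_id"
    )
    if mode == "fixed":
        lo, hi = low, high
    elif mode == "tercile":
        lo, hi = np.quantile(table["rk_percent"], [1 / 3, 2 / 3])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pct = table["rk_percent"]
    table["bin"] = np.where(pct < lo, "bin1", np.where(pct > hi, "bin3", "bin2"))
    return ProteomeBins(table=table, mode=mode, low=float(lo), high=float(hi))


def bin_enrichment(
    gene_set: set[str], bins: ProteomeBins, focus_bin: str = "bin3"
) -> tuple[EnrichmentResult, dict[str, float]]:
    """Fisher enrichment of a gene set in one %R+K bin.

    Universe is the binned proteome; gene IDs absent from it are dropped
    with a warning. Returns the enrichment result and the fraction of the
    set falling in each bin.
    """
    if focus_bin not in BIN_LABELS:
        raise ValueError(f"focus_bin must be one of {BIN_LABELS}")
    known = set(bins.table.index)
    matched = gene_set & known
    dropped = gene_set - known
    if dropped:
        warnings.warn(f"{len(dropped)} gene IDs not in binned proteome; dropped", stacklevel=2)
    if not matched:
        raise ValueError("no genes of the set are present in the binned proteome")
    sub = bins.table.loc[sorted(matched)]
    fractions = {b: float((sub["bin"] == b).mean()) for b in BIN_LABELS}
    result = set_enrichment(matched, bins.members(focus_bin), universe_size=len(known))
    return result, fractions


def composition_compare(
    set_a: set[str], bins: ProteomeBins
) -> tuple[float, float, float]:
    """Compare %R+K of a protein set against the rest of the proteome.

    The "rest" group excludes ``set_a``. Two-sided Wilcoxon rank-sum test;
    returns (median_A, median_rest, p).
    """
    pct = bins.table["rk_percent"]
    in_a = pct.index.isin(set_a)
    vals_a = pct[in_a].to_numpy()
    vals_rest = pct[~in_a].to_numpy()
    if len(vals_a) == 0 or len(vals_rest) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(vals_a, vals_rest, alternative="two-sided", use_continuity=False)
    return float(np.median(vals_a)), float(np.median(vals_rest)), float(res.pvalue)
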