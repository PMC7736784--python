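"""Per-round motif counting, abundance ranking and round comparison.

After extraction, each selection round reduces to a count table mapping a
peptide motif (or a joint multi-segment motif such as ``FF/I``) to its
read count.  Ranks are ordinal after sorting by count descending, with
lexicographic tie-breaking so percentiles are reproducible; the
percentile of a motif is ``100 * rank / n_unique``, matching the usual
"top x%" rank-cutoff framing.  Enrichment between rounds uses a
pseudocounted log2 frequency ratio so motifs absent from one round stay
finite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "CountTable",
    "RankReport",
    "count_variants",
    "rank_table",
    "query_rank",
    "enrichment_ratio",
    "top_fraction",
    "write_count_table",
    "read_count_table",
]


@dataclass
class CountTable:
    """Read counts per unique motif for one selection round."""

    round_label: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for motif, c in self.counts.items():
            if not motif:
                raise ValueError("empty motif key")
            if c < 1:
                raise ValueError(f"count for {motif!r} must be >= 1, got {c}")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    @property
    def mean_reads_per_unique(self) -> float:
        return self.total_reads / self.n_unique if self.counts else float("nan")

    def frequencies(self) -> dict[str, float]:
        total = self.total_reads
        return {m: c / total for m, c in self.counts.items()}

    def is_empty(self) -> bool:
        return not self.counts


@dataclass(frozen=True)
class RankReport:
    """Ordinal rank of one motif (1 = most abundant)."""

    motif: str
    rank: int
    reads: int
    percentile: float  # 100 * rank / n_unique, in (0, 100]


def count_variants(peptides: Iterable[str], round_label: str = "") -> CountTable:
    """Exact multiset count of a motif stream.

    An empty stream yields a valid empty table (flagged by ``is_empty``).
    """
    counts: dict[str, int] = {}
    for motif in peptides:
        if not motif:
            raise ValueError("motifs must be non-empty strings")
        counts[motif] = counts.get(motif, 0) + 1
    return CountTable(round_label=round_label, counts=counts)


def rank_table(table: CountTable) -> list[RankReport]:
    """All motifs ranked by count descending, ties broken lexicographically.

    Ranks are ordinal positions 1..n_unique (no tied-rank averaging).
    """
    n = table.n_unique
    if n == 0:
        return []
    ordered = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [RankReport(motif=m, rank=r, reads=c, percentile=100.0 * r / n)
            for r, (m, c) in enumerate(ordered, start=1)]


def query_rank(table: CountTable, motif: str) -> RankReport | None:
    """Rank/percentile of one motif, or None if absent from the table."""
    if motif not in table.counts:
        return None
    c = table.counts[motif]
    # ordinal rank = motifs with more reads, plus lexicographically smaller ties
    rank = 1 + sum(1 for m, k in table.counts.items()
                   if k > c or (k == c and m < motif))
    return RankReport(motif=motif, rank=rank, reads=c,
                      percentile=100.0 * rank / table.n_unique)


def enrichment_ratio(selected: CountTable, reference: CountTable,
                     pseudocount: float = 0.5) -> dict[str, float]:
    """Pseudocounted log2 frequency ratio, selected over reference.

    For each motif in the union U of both tables:
    ``log2(((c_sel + pc) / (N_sel + pc*|U|)) / ((c_ref + pc) / (N_ref + pc*|U|)))``.
    The pseudocount keeps motifs absent from one round finite, and the
    statistic is antisymmetric under swapping the two rounds.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    union = set(selected.counts) | set(reference.counts)
    if not union:
        raise ValueError("both tables are empty")
    u = len(union)
    n_sel = selected.total_reads + pseudocount * u
    n_ref = reference.total_reads + pseudocount * u
    out = {}
    for m in union:
        f_sel = (selected.counts.get(m, 0) + pseudocount) / n_sel
        f_ref = (reference.counts.get(m, 0) + pseudocount) / n_ref
        out[m] = math.log2(f_sel / f_ref)
    return out


def top_fraction(table: CountTable, k: int | None = None,
                 fraction: float | None = None) -> list[str]:
    """The k (or ceil(fraction * n_unique)) most abundant motifs, in rank order."""
    if (k is None) == (fraction is None):
        raise ValueError("give exactly one of k or fraction")
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        k = math.ceil(fraction * table.n_unique)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > table.n_unique:
        warnings.warn(f"requested top {k} of {table.n_unique} motifs; returning all")
        k = table.n_unique
    return [r.motif for r in rank_table(table)[:k]]


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a ranked count table as TSV (motif, reads, frequency, rank)."""
    rows = rank_table(table)
    freqs = table.frequencies()
    df = pd.DataFrame({
        "motif": [r.motif for r in rows],
        "reads": [r.reads for r in rows],
        "frequency": [freqs[r.motif] for r in rows],
        "rank": [r.rank for r in rows],
    })
    df.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path, round_label: str | None = None) -> CountTable:
    df = pd.read_csv(path, sep="\t", dtype={"motif": str})
    label = round_label if round_label is not None else Path(path).stem
    return CountTable(round_label=label,
                      counts=dict(zip(df["motif"], df["reads"].astype(int))))
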