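"""Anchor-based extraction of variable regions from amplicon reads.

Each library read carries its randomized region(s) between constant
anchor sequences.  Extraction slides each anchor along the read with a
Hamming-distance comparison (substitutions only, no indels — appropriate
for short-read substitution-dominated error profiles), cuts out the
region strictly between the 5' and 3' anchors of every segment, and
translates it with the standard genetic code.  Reads are tried on the
forward strand first and, if the policy allows, on the reverse
complement.  Problematic variants are flagged (stop codon, length
mismatch, ambiguous base, low quality) rather than silently dropped;
filtering is a separate, fully accounted step.

Coordinates are 0-based half-open internally; log output is 1-based.
FASTQ qualities are Phred+33.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .codons import reverse_complement, translate
from .library import LibrarySpec, Segment

__all__ = [
    "ReadRecord",
    "SegmentRule",
    "ExtractionRule",
    "ExtractedVariant",
    "FilterPolicy",
    "FilterDecision",
    "locate_anchor",
    "extract_variable_regions",
    "filter_variant",
    "read_sequences",
    "translate",
]

_ACGT = set("ACGT")


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: id, DNA sequence and optional Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError("qualities length must match sequence length")

    def reverse_complement(self) -> "ReadRecord":
        quals = self.qualities[::-1] if self.qualities is not None else None
        return ReadRecord(self.id, reverse_complement(self.sequence), quals)


@dataclass(frozen=True)
class SegmentRule:
    """Anchor pair and expected size for one variable segment."""

    anchor5: str
    anchor3: str
    expected_length_nt: int
    motif_codons: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for name, a in (("anchor5", self.anchor5), ("anchor3", self.anchor3)):
            if len(a) < 8:
                raise ValueError(f"{name} must be at least 8 nt")
            if set(a) - _ACGT:
                raise ValueError(f"{name} must be ACGT-only")
        if self.expected_length_nt % 3 != 0:
            raise ValueError("expected_length_nt must be a multiple of 3")


@dataclass(frozen=True)
class ExtractionRule:
    """How to cut variable region(s) out of a read."""

    segments: tuple[SegmentRule, ...]
    max_mismatches: int = 1
    orientation_policy: str = "both"  # 'forward' | 'both'
    length_tolerance_nt: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("rule needs at least one segment")
        if self.orientation_policy not in ("forward", "both"):
            raise ValueError("orientation_policy must be 'forward' or 'both'")
        if self.max_mismatches < 0 or self.length_tolerance_nt < 0:
            raise ValueError("tolerances must be non-negative")

    @classmethod
    def from_library(cls, spec: LibrarySpec, max_mismatches: int = 1,
                     orientation_policy: str = "both",
                     length_tolerance_nt: int = 0) -> "ExtractionRule":
        segs = tuple(
            SegmentRule(s.anchor5, s.anchor3, s.expected_length_nt, s.motif_mask())
            for s in spec.segments
        )
        return cls(segs, max_mismatches, orientation_policy, length_tolerance_nt)


@dataclass(frozen=True)
class ExtractedVariant:
    """One extracted variable region with translation and reason flags."""

    dna: str
    peptide: str
    segment_index: int
    flags: frozenset[str] = frozenset()
    mean_quality: float | None = None

    def motif(self, motif_codons: tuple[int, ...] | None = None) -> str:
        if motif_codons is None:
            return self.peptide
        return "".join(self.peptide[i] for i in motif_codons)


def locate_anchor(read: ReadRecord | str, anchor: str, max_mismatches: int = 0,
                  start: int = 0) -> int | None:
    """Leftmost position where ``anchor`` matches the read within
    ``max_mismatches`` substitutions (Hamming scan, no indels).

    Returns None when no position qualifies, including when the anchor is
    longer than the (remaining) read.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    m = len(anchor)
    if m == 0:
        raise ValueError("anchor must be non-empty")
    if start < 0:
        raise ValueError("start must be >= 0")
    if m > len(seq) - start:
        return None
    if max_mismatches == 0:
        pos = seq.find(anchor, start)
        return pos if pos >= 0 else None
    s = np.frombuffer(seq[start:].encode("ascii"), dtype=np.uint8)
    a = np.frombuffer(anchor.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mism = (windows != a).sum(axis=1)
    hits = np.flatnonzero(mism <= max_mismatches)
    return start + int(hits[0]) if hits.size else None


def _variant_from_region(dna: str, quals: Sequence[int] | None, index: int,
                         rule: ExtractionRule, seg: SegmentRule) -> ExtractedVariant:
    flags: set[str] = set()
    if abs(len(dna) - seg.expected_length_nt) > rule.length_tolerance_nt:
        flags.add("length_mismatch")
    peptide = ""
    if set(dna) - _ACGT:
        flags.add("ambiguous_base")
    elif len(dna) % 3 == 0 and dna:
        peptide = translate(dna)
        if "*" in peptide:
            flags.add("stop_codon")
    else:
        flags.add("length_mismatch")
    mean_q = float(np.mean(quals)) if quals else None
    return ExtractedVariant(dna, peptide, index, frozenset(flags), mean_q)


def _extract_oriented(read: ReadRecord, rule: ExtractionRule) -> list[ExtractedVariant] | None:
    variants: list[ExtractedVariant] = []
    cursor = 0
    for idx, seg in enumerate(rule.segments):
        p5 = locate_anchor(read, seg.anchor5, rule.max_mismatches, start=cursor)
        if p5 is None:
            return None
        region_start = p5 + len(seg.anchor5)
        p3 = locate_anchor(read, seg.anchor3, rule.max_mismatches, start=region_start)
        if p3 is None:
            return None
        dna = read.sequence[region_start:p3]
        quals = read.qualities[region_start:p3] if read.qualities is not None else None
        variants.append(_variant_from_region(dna, quals, idx, rule, seg))
        cursor = p3 + len(seg.anchor3)
    return variants


def extract_variable_regions(read: ReadRecord, rule: ExtractionRule
                             ) -> list[ExtractedVariant] | None:
    """Extract every segment's variable region from a read, or None.

    A read yields a result only if all segments are found in order on one
    strand (forward first; then the reverse complement under the 'both'
    policy).  Out-of-tolerance lengths are flagged, not dropped.
    """
    result = _extract_oriented(read, rule)
    if result is None and rule.orientation_policy == "both":
        result = _extract_oriented(read.reverse_complement(), rule)
    return result


def joint_motif(variants: Sequence[ExtractedVariant], rule: ExtractionRule) -> str:
    """Joint peptide motif across segments, joined by '/'."""
    return "/".join(v.motif(seg.motif_codons)
                    for v, seg in zip(variants, rule.segments))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterPolicy:
    """Which flagged variants to drop; every drop is counted by reason."""

    drop_stop_codon: bool = True
    drop_length_mismatch: bool = True
    drop_ambiguous_base: bool = True
    min_mean_quality: float | None = 20.0


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: str | None = None


def filter_variant(variant: ExtractedVariant,
                   policy: FilterPolicy = FilterPolicy()) -> FilterDecision:
    """Keep/drop decision for one extracted variant, with a reason code.

    The quality criterion applies only when the read carried qualities.
    """
    if policy.drop_length_mismatch and "length_mismatch" in variant.flags:
        return FilterDecision(False, "length_mismatch")
    if policy.drop_ambiguous_base and "ambiguous_base" in variant.flags:
        return FilterDecision(False, "ambiguous_base")
    if policy.drop_stop_codon and "stop_codon" in variant.flags:
        return FilterDecision(False, "stop_codon")
    if (policy.min_mean_quality is not None and variant.mean_quality is not None
            and variant.mean_quality < policy.min_mean_quality):
        return FilterDecision(False, "low_quality")
    return FilterDecision(True, None)


# ---------------------------------------------------------------------------
# Read I/O (FASTQ / FASTA via Biopython; .gz accepted)
# ---------------------------------------------------------------------------

def read_sequences(path: str | Path, fmt: str | None = None) -> Iterator[ReadRecord]:
    """Stream reads from FASTQ or FASTA (optionally gzip-compressed).

    The format is inferred from the file name unless ``fmt`` is given
    ('fastq' or 'fasta').  FASTA reads carry no qualities, so quality
    filtering is skipped downstream.
    """
    path = Path(path)
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    if fmt is None:
        if name.endswith((".fastq", ".fq")):
            fmt = "fastq"
        elif name.endswith((".fasta", ".fa", ".fna")):
            fmt = "fasta"
        else:
            raise ValueError(f"cannot infer read format from {path.name!r}")
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            quals = rec.letter_annotations.get("phred_quality")
            yield ReadRecord(rec.id, str(rec.seq).upper(),
                             tuple(quals) if quals is not None else None)
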