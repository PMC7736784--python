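"""Randomized-library definitions: primer parsing, diversity, coverage.

A selection library is built by mutagenic PCR with primers carrying
degenerate codons (NNK on the coding strand, MNN when the primer anneals
to the reverse strand).  This module parses such primers into structured
library definitions, and computes the combinatorics a practitioner needs
before sequencing: DNA- and peptide-level diversity, the stop-codon
burden, and the expected sampling coverage at a given read depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import yaml

from .codons import (
    STOP,
    DegenerateCodon,
    GENETIC_CODE,
    IUPAC,
    aa_distribution,
    reverse_complement,
    translate,
)

__all__ = [
    "Segment",
    "LibrarySpec",
    "PrimerDesign",
    "FrameAmbiguityError",
    "parse_degenerate_primer",
    "DiversityReport",
    "library_diversity",
    "coverage_probability",
]

_ACGT = set("ACGT")


class FrameAmbiguityError(ValueError):
    """Degenerate runs cannot be codon-aligned in any consistent frame."""


def _check_acgt(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what} must be non-empty")
    bad = set(seq) - _ACGT
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters {sorted(bad)}")
    return seq


@dataclass
class Segment:
    """One variable region of a library with its constant context.

    A read covering this segment looks like ``upstream + variable + downstream``;
    the wild-type variable-region DNA is ``wildtype``.  ``blocks`` maps codon
    indices *within the variable region* to degenerate codons; unlisted codons
    stay wild type.  Anchors used for extraction are the tail of ``upstream``
    and the head of ``downstream`` (``anchor_length`` nt each).  ``motif_codons``
    restricts which codons of the segment contribute to the reported peptide
    motif (None = all; used when randomized codons are separated by constant
    coding sequence, as in the co-evolution library).
    """

    upstream: str
    wildtype: str
    downstream: str
    blocks: list[tuple[int, DegenerateCodon]] = field(default_factory=list)
    motif_codons: tuple[int, ...] | None = None
    anchor_length: int = 12

    def __post_init__(self) -> None:
        self.upstream = _check_acgt(self.upstream, "upstream context")
        self.wildtype = _check_acgt(self.wildtype, "wild-type segment")
        self.downstream = _check_acgt(self.downstream, "downstream context")
        if len(self.wildtype) % 3 != 0:
            raise ValueError("wild-type segment length must be a multiple of 3")
        n_codons = len(self.wildtype) // 3
        self.blocks = [(int(i), c if isinstance(c, DegenerateCodon) else DegenerateCodon(c))
                       for i, c in self.blocks]
        seen: set[int] = set()
        for i, _ in self.blocks:
            if not 0 <= i < n_codons:
                raise ValueError(f"block codon index {i} outside segment (0..{n_codons - 1})")
            if i in seen:
                raise ValueError(f"overlapping blocks at codon {i}")
            seen.add(i)
        if self.anchor_length < 8:
            raise ValueError("anchors must be at least 8 nt")
        if len(self.upstream) < self.anchor_length or len(self.downstream) < self.anchor_length:
            raise ValueError("constant context shorter than anchor length")
        if self.motif_codons is not None:
            self.motif_codons = tuple(sorted(int(i) for i in self.motif_codons))
            for i in self.motif_codons:
                if not 0 <= i < n_codons:
                    raise ValueError(f"motif codon index {i} outside segment")

    @property
    def n_codons(self) -> int:
        return len(self.wildtype) // 3

    @property
    def anchor5(self) -> str:
        return self.upstream[-self.anchor_length:]

    @property
    def anchor3(self) -> str:
        return self.downstream[:self.anchor_length]

    @property
    def expected_length_nt(self) -> int:
        return len(self.wildtype)

    def motif_mask(self) -> tuple[int, ...]:
        return self.motif_codons if self.motif_codons is not None else tuple(range(self.n_codons))

    def motif_from_peptide(self, peptide: str) -> str:
        return "".join(peptide[i] for i in self.motif_mask())

    def degenerate_codons(self) -> list[DegenerateCodon]:
        return [c for _, c in sorted(self.blocks)]


@dataclass
class LibrarySpec:
    """A randomized library: one or more variable segments in constant context.

    ``coding_template`` (derived) is the wild-type DNA of the full emitted
    read; ``wildtype_dna()`` gives the wild-type variable region(s).
    """

    name: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("library needs at least one segment")

    @property
    def coding_template(self) -> str:
        return "".join(s.upstream + s.wildtype + s.downstream for s in self.segments)

    def wildtype_dna(self) -> tuple[str, ...]:
        return tuple(s.wildtype for s in self.segments)

    def wildtype_motif(self) -> str:
        return "/".join(s.motif_from_peptide(translate(s.wildtype)) for s in self.segments)

    def degenerate_codons(self) -> list[DegenerateCodon]:
        return [c for s in self.segments for c in s.degenerate_codons()]

    def read_template(self, variant_dna: Sequence[str]) -> str:
        """Full read sequence for a variant (one DNA string per segment)."""
        if len(variant_dna) != len(self.segments):
            raise ValueError("one variable-region DNA string required per segment")
        return "".join(s.upstream + d + s.downstream
                       for s, d in zip(self.segments, variant_dna))

    def motif(self, variant_dna: Sequence[str]) -> str:
        """Joint peptide motif for a variant; segments joined by '/'."""
        parts = []
        for seg, dna in zip(self.segments, variant_dna):
            parts.append(seg.motif_from_peptide(translate(dna)))
        return "/".join(parts)

    # -- config round-trip ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "segments": [
                {
                    "upstream": s.upstream,
                    "wildtype": s.wildtype,
                    "downstream": s.downstream,
                    "blocks": [[i, c.triplet] for i, c in s.blocks],
                    "motif_codons": list(s.motif_codons) if s.motif_codons is not None else None,
                    "anchor_length": s.anchor_length,
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LibrarySpec":
        segs = [
            Segment(
                upstream=sd["upstream"],
                wildtype=sd["wildtype"],
                downstream=sd["downstream"],
                blocks=[(i, DegenerateCodon(t)) for i, t in sd.get("blocks", [])],
                motif_codons=tuple(sd["motif_codons"]) if sd.get("motif_codons") else None,
                anchor_length=sd.get("anchor_length", 12),
            )
            for sd in d["segments"]
        ]
        return cls(name=d["name"], segments=segs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "LibrarySpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Primer parsing
# ---------------------------------------------------------------------------

@dataclass
class PrimerDesign:
    """Parsed mutagenic primer, reported in coding-strand orientation.

    ``blocks`` holds one list of degenerate codons per maximal degenerate run,
    5'→3' on the coding strand; ``cores`` are the fixed sequences between
    consecutive runs; ``anchor5``/``anchor3`` the constant flanks outside the
    outermost runs.  ``frame_offset`` is the codon-frame phase (0..2) shared by
    every run; ``codon_indices`` gives, per run, the index of its first codon
    counted from the in-frame start of ``anchor5`` (the last in-frame ATG if
    one exists, else the frame-aligned start of the primer).
    """

    sense_sequence: str
    blocks: list[list[DegenerateCodon]]
    cores: list[str]
    anchor5: str
    anchor3: str
    frame_offset: int
    codon_indices: list[int]

    @property
    def n_degenerate_codons(self) -> int:
        return sum(len(b) for b in self.blocks)


def parse_degenerate_primer(primer: str, strand: str = "forward") -> PrimerDesign:
    """Parse a mutagenic primer into codon-aligned degenerate blocks.

    Reverse-strand primers (MNN-style) are reverse-complemented first so the
    result is always reported on the coding strand.  Maximal runs of
    degenerate positions must fall on a common codon frame; the frame is
    anchored to the in-frame ATG of the 5' constant flank when present.
    Raises :class:`FrameAmbiguityError` if no consistent frame exists and
    ``ValueError`` for a primer with no degenerate position.
    """
    seq = primer.upper()
    bad = set(seq) - set(IUPAC)
    if bad:
        raise ValueError(f"primer contains non-IUPAC characters {sorted(bad)}")
    if strand not in ("forward", "reverse"):
        raise ValueError("strand must be 'forward' or 'reverse'")
    if strand == "reverse":
        seq = reverse_complement(seq)

    degenerate = [len(IUPAC[ch]) > 1 for ch in seq]
    runs: list[tuple[int, int]] = []  # [start, end) of maximal degenerate runs
    i = 0
    while i < len(seq):
        if degenerate[i]:
            j = i
            while j < len(seq) and degenerate[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        raise ValueError("primer has no degenerate position")

    for start, end in runs:
        if (end - start) % 3 != 0:
            raise FrameAmbiguityError(
                f"degenerate run of length {end - start} at {start} is not codon-sized")
    frames = {start % 3 for start, _ in runs}
    if len(frames) > 1:
        raise FrameAmbiguityError(
            f"degenerate runs disagree on codon frame (offsets {sorted(frames)})")
    frame = frames.pop()

    blocks = [[DegenerateCodon(seq[k:k + 3]) for k in range(s, e, 3)] for s, e in runs]
    cores = [seq[runs[k][1]:runs[k + 1][0]] for k in range(len(runs) - 1)]
    anchor5 = seq[:runs[0][0]]
    anchor3 = seq[runs[-1][1]:]

    # codon indexing: prefer the last in-frame ATG of the 5' flank as position 0
    origin = frame
    pos = anchor5.rfind("ATG")
    while pos != -1:
        if pos % 3 == frame:
            origin = pos
            break
        pos = anchor5.rfind("ATG", 0, pos)
    codon_indices = [(s - origin) // 3 for s, _ in runs]

    return PrimerDesign(
        sense_sequence=seq,
        blocks=blocks,
        cores=cores,
        anchor5=anchor5,
        anchor3=anchor3,
        frame_offset=frame,
        codon_indices=codon_indices,
    )


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

class DiversityTooLargeError(ValueError):
    """Exact enumeration requested beyond the configured cap."""


@dataclass(frozen=True)
class DiversityReport:
    """DNA/peptide diversity of a library and its stop-codon burden."""

    dna_count: int
    peptide_count: int          # distinct stop-free variable-region peptides
    stop_fraction: float        # fraction of DNA variants containing >= 1 stop
    method: str                 # 'exact' or 'convolution'

    def to_tsv(self) -> str:
        lines = ["metric\tvalue",
                 f"dna_count\t{self.dna_count}",
                 f"peptide_count\t{self.peptide_count}",
                 f"stop_fraction\t{self.stop_fraction:.6g}",
                 f"method\t{self.method}"]
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        return (f"DNA variants: {self.dna_count:,}\n"
                f"Distinct stop-free peptides: {self.peptide_count:,}\n"
                f"Stop-containing DNA fraction: {self.stop_fraction:.4g}\n"
                f"(computed by {self.method})")


def _codon_aa_sets(codons: Iterable[DegenerateCodon]):
    """Per-codon lists of amino acids, one entry per concrete codon."""
    return [[GENETIC_CODE[c] for c in dc.expand()] for dc in codons]


def library_diversity(spec: LibrarySpec | Sequence[DegenerateCodon],
                      cap: int = 10 ** 7,
                      method: str = "auto") -> DiversityReport:
    """Diversity of a randomized library.

    DNA-level count is the product of the degenerate codons' expansion sizes.
    The distinct stop-free peptide count and the stop-containing DNA fraction
    are computed by exhaustive enumeration of all DNA combinations when that
    product is at most ``cap`` (method='exact'), otherwise from per-codon
    amino-acid distributions (method='convolution'); the two agree because
    randomized codons vary independently.
    """
    codons = spec.degenerate_codons() if isinstance(spec, LibrarySpec) else list(spec)
    codons = [c if isinstance(c, DegenerateCodon) else DegenerateCodon(c) for c in codons]
    if not codons:
        return DiversityReport(1, 1, 0.0, "exact")

    dna_count = math.prod(c.degeneracy for c in codons)
    if method not in ("auto", "exact", "convolution"):
        raise ValueError("method must be auto|exact|convolution")
    use_exact = method == "exact" or (method == "auto" and dna_count <= cap)
    if method == "exact" and dna_count > cap:
        raise DiversityTooLargeError(
            f"{dna_count} DNA combinations exceed exact-enumeration cap {cap}")

    if use_exact:
        aa_lists = _codon_aa_sets(codons)
        peptides: set[tuple[str, ...]] = set()
        n_stop = 0
        for combo in product(*aa_lists):
            if STOP in combo:
                n_stop += 1
            else:
                peptides.add(combo)
        return DiversityReport(dna_count, len(peptides), n_stop / dna_count, "exact")

    peptide_count = 1
    p_no_stop = 1.0
    for c in codons:
        dist = aa_distribution(c)
        peptide_count *= sum(1 for aa in dist.probs if aa != STOP)
        p_no_stop *= 1.0 - dist.stop_probability
    return DiversityReport(dna_count, peptide_count, 1.0 - p_no_stop, "convolution")


def coverage_probability(n_variants: int,
                         n_draws: int,
                         probs: Sequence[float] | None = None,
                         tol: float = 1e-9) -> float:
    """Expected fraction of library variants observed at least once.

    Under uniform sampling this is ``1 - (1 - 1/n)**d``; with explicit
    per-variant probabilities it is the mean of ``1 - (1 - p_i)**d``.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if n_draws < 0:
        raise ValueError("n_draws must be >= 0")
    if probs is None:
        return float(1.0 - (1.0 - 1.0 / n_variants) ** n_draws)
    p = np.asarray(probs, dtype=float)
    if len(p) != n_variants:
        raise ValueError("probs length must equal n_variants")
    if abs(p.sum() - 1.0) > max(tol, 1e-9):
        raise ValueError(f"probabilities sum to {p.sum()}, expected 1")
    return float(np.mean(1.0 - (1.0 - p) ** n_draws))
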