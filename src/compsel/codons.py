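"""Degenerate-codon arithmetic for randomized peptide libraries.

Saturation mutagenesis libraries randomize codons with degenerate IUPAC
triplets, most commonly NNK (N = A/C/G/T, K = G/T), which covers all 20
amino acids with 32 codons and a single amber stop (TAG).  On the reverse
strand an NNK codon reads MNN.  This module expands degenerate codons,
computes the amino-acid distribution each one encodes (the source of the
well-known NNK bias toward Leu/Arg/Ser), and translates DNA with the
standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

__all__ = [
    "IUPAC",
    "GENETIC_CODE",
    "AA_LETTERS",
    "STOP",
    "InvalidCodonError",
    "DegenerateCodon",
    "AminoAcidDistribution",
    "expand_codon",
    "aa_distribution",
    "translate",
    "reverse_complement",
]

# IUPAC nucleotide codes -> set of concrete bases
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# Standard genetic code; stop codons render as '*'
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


class InvalidCodonError(ValueError):
    """Raised for triplets that are not valid IUPAC degenerate codons."""


class TranslationError(ValueError):
    """Raised for DNA that cannot be translated (frame or alphabet)."""


@dataclass(frozen=True)
class DegenerateCodon:
    """A 3-letter IUPAC nucleotide pattern, e.g. ``NNK`` or ``TGG``.

    ``degeneracy`` is the number of concrete codons matching the pattern
    (the product of the per-position degeneracies).
    """

    triplet: str

    def __post_init__(self) -> None:
        t = self.triplet.upper()
        if len(t) != 3:
            raise InvalidCodonError(f"codon must have length 3, got {self.triplet!r}")
        for ch in t:
            if ch not in IUPAC:
                raise InvalidCodonError(f"invalid IUPAC code {ch!r} in {self.triplet!r}")
        object.__setattr__(self, "triplet", t)

    @property
    def degeneracy(self) -> int:
        d = 1
        for ch in self.triplet:
            d *= len(IUPAC[ch])
        return d

    def expand(self) -> list[str]:
        """Every concrete codon matching the pattern, lexicographically."""
        return ["".join(b) for b in product(*(sorted(IUPAC[ch]) for ch in self.triplet))]

    def reverse_complement(self) -> "DegenerateCodon":
        return DegenerateCodon(reverse_complement(self.triplet))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.triplet


@dataclass(frozen=True)
class AminoAcidDistribution:
    """Probabilities over the 20 amino acids plus stop ('*').

    Probabilities must be non-negative and sum to 1 (within 1e-12).
    """

    probs: dict[str, float]

    def __post_init__(self) -> None:
        total = 0.0
        for aa, p in self.probs.items():
            if aa not in AA_LETTERS and aa != STOP:
                raise ValueError(f"unknown amino-acid letter {aa!r}")
            if p < 0:
                raise ValueError(f"negative probability for {aa!r}")
            total += p
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, expected 1")

    def __getitem__(self, aa: str) -> float:
        return self.probs.get(aa, 0.0)

    @property
    def stop_probability(self) -> float:
        return self.probs.get(STOP, 0.0)

    def letters(self) -> list[str]:
        return sorted(self.probs)


def expand_codon(codon: DegenerateCodon | str) -> list[str]:
    """All concrete codons matching a degenerate codon, each once, sorted."""
    if not isinstance(codon, DegenerateCodon):
        codon = DegenerateCodon(codon)
    return codon.expand()


def aa_distribution(codon: DegenerateCodon | str) -> AminoAcidDistribution:
    """Amino-acid distribution encoded by a degenerate codon.

    Probability of each amino acid (and of stop) equals the fraction of
    the codon's expansion translating to it.  For NNK this yields the
    classical 3/32 Leu/Arg/Ser bias and a 1/32 stop fraction.
    """
    expansion = expand_codon(codon)
    tally: dict[str, int] = {}
    for c in expansion:
        aa = GENETIC_CODE[c]
        tally[aa] = tally.get(aa, 0) + 1
    n = len(expansion)
    return AminoAcidDistribution({aa: k / n for aa, k in tally.items()})


def translate(dna: str) -> str:
    """Translate DNA with the standard genetic code; stops render as '*'.

    Raises :class:`TranslationError` if the length is not a multiple of 3
    or the sequence contains non-ACGT characters.
    """
    seq = dna.upper()
    if len(seq) % 3 != 0:
        raise TranslationError(f"length {len(seq)} is not a multiple of 3")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        try:
            out.append(GENETIC_CODE[codon])
        except KeyError:
            raise TranslationError(f"non-ACGT codon {codon!r} at position {i}") from None
    return "".join(out)
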