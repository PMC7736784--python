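"""Built-in library presets for the SpyCatcher–SpyTag selection system.

SpyTag is the 13-residue peptide MGAHIVMVDAYKP whose hydrophobic IVMV core
packs into SpyCatcher and whose aspartate forms the covalent isopeptide
bond.  Three saturation libraries are modeled here, each defined by the
degenerate mutagenesis primers used to build it:

* ``spytag_core_library`` (Lib 1): the four IVMV core residues replaced by
  NNK codons (primer ``SPYTR6.2``, MNN on the reverse strand).
* ``spytag_flank_library`` (Lib 2): the three residues on each side of the
  IVMVD core (GAH and AYK) randomized (primer ``SPYTR5.2``); the 15-nt
  fixed core between the NNK runs translates to IVMVD.
* ``coevolution_library`` (Lib 3): simultaneous randomization of SpyCatcher
  phenylalanines 75 and 92 and the SpyTag core isoleucine, read out as a
  joint motif such as ``FF/I`` from amplicons co-encoding both partners
  (primers ``SpyC-NNK1-R``, ``SpyC-NNK2-F``, ``SpyT-NNK-R``).

Wild-type context comes from the ``SPYTINF-TOP`` cloning oligo.  The
wild-type codons at the two randomized SpyCatcher positions are not fixed
by the primers (which carry MNN/NNK there); the preset uses TTT for both
phenylalanines as representative NNK-compatible placeholders.
"""

from __future__ import annotations

from .codons import DegenerateCodon, translate
from .library import LibrarySpec, Segment, parse_degenerate_primer

__all__ = [
    "SPYTINF_TOP",
    "SPYTR6_2",
    "SPYTR5_2",
    "SPYC_NNK1_R",
    "SPYC_NNK2_F",
    "SPYT_NNK_R",
    "WT_SPYTAG_PEPTIDE",
    "WT_CORE_MOTIF",
    "spytag_core_library",
    "spytag_flank_library",
    "coevolution_library",
    "get_preset",
    "PRESETS",
]

# Cloning / mutagenesis oligos (5'->3')
SPYTINF_TOP = ("AAGGAGATATACATATGGGAGCTCACATCGTGATGGTGGACGCATATAAGCCG"
               "ACTAAGGGATCTACTAGTTCTATGGGAGGCGAAGC")
SPYTR6_2 = ("CATAGAACTAGTAGATCCCTTAGTCGGCTTATATGCGTCMNNMNNMNNMNN"
            "GTGAGCTCCCATATGTATATCTCCTTCTTATACTTAACTAATATAC")
SPYTR5_2 = ("CATAGAACTAGTAGATCCCTTAGTCGGMNNMNNMNNGTCCACCATCACGATMNNMNNMNN"
            "CATATGTATATCTCCTTCTTATACTTAACTAATATAC")
SPYC_NNK1_R = "CAGTAGCCACTTCATACCCGTCCGGTGCGGCGGTTTCCACMNNGGTGTATTTACCTGGGTACAGGT"
SPYC_NNK2_F = "GACGGGTATGAAGTGGCTACTGCAATTACTNNKACCGTAAATGAACAGGGACAGGTCACAG"
SPYT_NNK_R = ("CATAGAACTAGTAGATCCCTTAGTCGGCTTATATGCGTCCACCATCACMNN"
              "GTGAGCTCCCATATGTATATCTCCTTCTTATACTTAACTAATATAC")

# Wild-type SpyTag peptide encoded after the NdeI ATG of SPYTINF-TOP
WT_SPYTAG_PEPTIDE = "GAHIVMVDAYKP"
WT_CORE_MOTIF = "IVMV"

_NNK = DegenerateCodon("NNK")


def wildtype_spytag_coding() -> str:
    """The 36-nt wild-type coding region following the start codon of the
    SPYTINF-TOP oligo; translates to GAHIVMVDAYKP."""
    start = SPYTINF_TOP.index("CATATG") + len("CATATG")
    return SPYTINF_TOP[start:start + 36]


def spytag_core_library() -> LibrarySpec:
    """Lib 1: NNK randomization of the four-residue IVMV core of SpyTag."""
    design = parse_degenerate_primer(SPYTR6_2, strand="reverse")
    (block,) = design.blocks  # one run of 4 NNK codons
    seg = Segment(
        upstream=design.anchor5,
        wildtype="ATCGTGATGGTG",  # IVMV, from the SPYTINF-TOP context
        downstream=design.anchor3,
        blocks=[(i, c) for i, c in enumerate(block)],
    )
    return LibrarySpec(name="spytag-core", segments=[seg])


def spytag_flank_library() -> LibrarySpec:
    """Lib 2: NNK randomization of the GAH/AYK residues flanking IVMVD."""
    design = parse_degenerate_primer(SPYTR5_2, strand="reverse")
    left, right = design.blocks
    (core,) = design.cores  # 15-nt fixed core, translates to IVMVD
    wt_left, wt_right = "GGAGCTCAC", "GCATATAAG"  # GAH / AYK from SPYTINF-TOP
    blocks = [(i, c) for i, c in enumerate(left)]
    offset = (len(wt_left) + len(core)) // 3
    blocks += [(offset + i, c) for i, c in enumerate(right)]
    seg = Segment(
        upstream=design.anchor5,
        wildtype=wt_left + core + wt_right,
        downstream=design.anchor3,
        blocks=blocks,
    )
    return LibrarySpec(name="spytag-flank", segments=[seg])


def coevolution_library() -> LibrarySpec:
    """Lib 3: joint randomization of SpyCatcher F75/F92 and the SpyTag core
    isoleucine; variants are read as a two-segment motif like ``FF/I``."""
    catcher1 = parse_degenerate_primer(SPYC_NNK1_R, strand="reverse")
    catcher2 = parse_degenerate_primer(SPYC_NNK2_F, strand="forward")
    tag = parse_degenerate_primer(SPYT_NNK_R, strand="reverse")

    # overlap-extension join of the two SpyCatcher primers: the 3' flank of
    # the first primer overlaps the 5' flank of the second; merging them gives
    # the constant coding sequence between the two randomized codons
    join_at = catcher1.anchor3.index(catcher2.anchor5[:12])
    between = catcher1.anchor3[:join_at] + catcher2.anchor5
    n_codons = (3 + len(between) + 3) // 3
    catcher_seg = Segment(
        upstream=catcher1.anchor5,
        wildtype="TTT" + between + "TTT",  # F75 ... F92 (placeholder F codons)
        downstream=catcher2.anchor3,
        blocks=[(0, catcher1.blocks[0][0]), (n_codons - 1, catcher2.blocks[0][0])],
        motif_codons=(0, n_codons - 1),
    )
    tag_seg = Segment(
        upstream=tag.anchor5,
        wildtype="ATC",  # SpyTag core isoleucine, from SPYTINF-TOP
        downstream=tag.anchor3,
        blocks=[(0, tag.blocks[0][0])],
        anchor_length=12,
    )
    return LibrarySpec(name="coevolution", segments=[catcher_seg, tag_seg])


PRESETS = {
    "spytag-core": spytag_core_library,
    "spytag-flank": spytag_flank_library,
    "coevolution": coevolution_library,
}


def get_preset(name: str) -> LibrarySpec:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
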