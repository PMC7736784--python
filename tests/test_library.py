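"""Primer parsing, library diversity and sampling coverage."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from compsel.codons import DegenerateCodon, reverse_complement, translate
from compsel.library import (DiversityTooLargeError, FrameAmbiguityError,
                             LibrarySpec, Segment, coverage_probability,
                             library_diversity, parse_degenerate_primer)
from compsel.presets import SPYC_NNK1_R, SPYT_NNK_R, SPYTR5_2, SPYTR6_2


class TestPrimerParsing:
    def test_flank_randomization_primer(self):
        """The Lib-2 primer carries 3 NNK codons on each side of a fixed
        15-nt core encoding the IVMVD peptide."""
        d = parse_degenerate_primer(SPYTR5_2, strand="reverse")
        assert [len(b) for b in d.blocks] == [3, 3]
        assert all(c.triplet == "NNK" for b in d.blocks for c in b)
        assert d.cores == ["ATCGTGATGGTGGAC"]
        assert translate(d.cores[0]) == "IVMVD"

    def test_core_randomization_primer(self):
        """The Lib-1 primer replaces the 4-codon hydrophobic core."""
        d = parse_degenerate_primer(SPYTR6_2, strand="reverse")
        assert [len(b) for b in d.blocks] == [4]
        assert d.anchor5.endswith("GGAGCTCAC")
        assert d.anchor3.startswith("GACGCATATAAG")
        # frame anchored to the in-frame ATG of the 5' flank: block starts
        # 3 codons downstream of the start codon (after GGA GCT CAC)
        assert d.codon_indices == [4]

    @pytest.mark.parametrize("primer", [SPYC_NNK1_R, SPYT_NNK_R])
    def test_single_codon_primers(self, primer):
        d = parse_degenerate_primer(primer, strand="reverse")
        assert [len(b) for b in d.blocks] == [1]
        assert d.blocks[0][0].triplet == "NNK"

    def test_no_degenerate_position_is_an_error(self):
        with pytest.raises(ValueError):
            parse_degenerate_primer("ACGTACGTACGT", strand="forward")

    def test_off_frame_run_is_ambiguous(self):
        with pytest.raises(FrameAmbiguityError):
            parse_degenerate_primer("ACGATGACGNNACGT", strand="forward")

    def test_incongruent_runs_are_ambiguous(self):
        with pytest.raises(FrameAmbiguityError):
            # runs at offsets 3 and 7: frames disagree
            parse_degenerate_primer("ATGNNKANNKACGTA", strand="forward")

    @pytest.mark.parametrize("primer", [SPYTR5_2, SPYTR6_2])
    def test_reverse_complement_round_trip(self, primer):
        """Parsing the reverse complement of the forward output is idempotent."""
        d = parse_degenerate_primer(primer, strand="reverse")
        d2 = parse_degenerate_primer(reverse_complement(d.sense_sequence),
                                     strand="reverse")
        assert d2.sense_sequence == d.sense_sequence
        assert [[c.triplet for c in b] for b in d2.blocks] == \
               [[c.triplet for c in b] for b in d.blocks]
        assert d2.cores == d.cores


class TestDiversity:
    def test_four_nnk_library_by_enumeration(self, lib1):
        rep = library_diversity(lib1, method="exact")
        assert rep.dna_count == 32 ** 4 == 1_048_576
        assert rep.peptide_count == 160_000
        assert rep.method == "exact"

    def test_single_fixed_codon(self):
        rep = library_diversity([DegenerateCodon("TGG")])
        assert (rep.dna_count, rep.peptide_count, rep.stop_fraction) == (1, 1, 0.0)

    def test_single_nnk_stop_fraction(self):
        rep = library_diversity([DegenerateCodon("NNK")], method="exact")
        assert rep.stop_fraction == pytest.approx(1 / 32)
        assert rep.peptide_count == 20

    @given(st.lists(st.sampled_from(["NNK", "NNT", "VNN", "TGG", "RNY"]),
                    min_size=1, max_size=3))
    def test_exact_and_convolution_paths_agree(self, triplets):
        codons = [DegenerateCodon(t) for t in triplets]
        exact = library_diversity(codons, method="exact")
        conv = library_diversity(codons, method="convolution")
        assert exact.dna_count == conv.dna_count
        assert exact.peptide_count == conv.peptide_count
        assert exact.stop_fraction == pytest.approx(conv.stop_fraction)

    def test_cap_exceeded_in_exact_mode(self):
        codons = [DegenerateCodon("NNN")] * 6
        with pytest.raises(DiversityTooLargeError):
            library_diversity(codons, method="exact", cap=10 ** 4)


class TestCoverage:
    def test_zero_draws(self):
        assert coverage_probability(100, 0) == 0.0

    def test_single_variant_single_draw(self):
        assert coverage_probability(1, 1) == 1.0

    def test_poissonized_limit(self):
        """At draws == variants, coverage approaches 1 - 1/e."""
        n = 200_000
        assert coverage_probability(n, n) == pytest.approx(1 - math.exp(-1), abs=1e-4)

    def test_monte_carlo_cross_check(self):
        rng = np.random.default_rng(42)
        n, d = 50, 120
        sims = [np.unique(rng.integers(0, n, size=d)).size / n for _ in range(2000)]
        assert coverage_probability(n, d) == pytest.approx(np.mean(sims), abs=0.01)

    def test_explicit_probabilities(self):
        p = [0.5, 0.25, 0.25]
        expected = np.mean([1 - (1 - pi) ** 4 for pi in p])
        assert coverage_probability(3, 4, probs=p) == pytest.approx(expected)

    def test_unnormalized_probabilities_rejected(self):
        with pytest.raises(ValueError):
            coverage_probability(2, 5, probs=[0.7, 0.5])


class TestLibrarySpecValidation:
    def test_block_outside_segment_rejected(self):
        with pytest.raises(ValueError):
            Segment(upstream="A" * 12, wildtype="ATGGCA",
                    downstream="C" * 12, blocks=[(5, DegenerateCodon("NNK"))])

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError):
            Segment(upstream="A" * 12, wildtype="ATGGCA", downstream="C" * 12,
                    blocks=[(0, DegenerateCodon("NNK")), (0, DegenerateCodon("NNK"))])

    def test_non_codon_wildtype_rejected(self):
        with pytest.raises(ValueError):
            Segment(upstream="A" * 12, wildtype="ATGGC", downstream="C" * 12)

    def test_yaml_round_trip(self, tmp_path, lib2):
        path = tmp_path / "lib.yaml"
        lib2.save(path)
        loaded = LibrarySpec.load(path)
        assert loaded.to_dict() == lib2.to_dict()
        assert loaded.wildtype_motif() == lib2.wildtype_motif()
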