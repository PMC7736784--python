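"""Stochastic selection-round simulator: binding, amplification,
compartment loading, read emission and end-to-end recovery."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from compsel.enrichment import CountTable, count_variants, enrichment_ratio, rank_table
from compsel.extraction import ExtractionRule, extract_variable_regions
from compsel.simulate import (SimulationParams, Variant, VariantPool,
                              amplification_factor, compartmentalize,
                              emit_reads, fraction_bound, nanoluc_ladder,
                              nnk_naive_pool, simulate_round, spike_in_pool,
                              write_fastq)


class TestBindingModel:
    def test_isotherm_midpoint(self):
        assert fraction_bound(100.0, 100.0) == pytest.approx(0.5)

    def test_no_partner_means_no_binding(self):
        assert fraction_bound(5.0, 0.0) == 0.0

    def test_affinity_ladder_endpoints(self):
        """The strongest and weakest reported affinities at 100 nM partner."""
        assert fraction_bound(0.7, 100.0) == pytest.approx(0.9930, abs=1e-4)
        assert fraction_bound(1.9e5, 100.0) == pytest.approx(5.26e-4, abs=1e-6)

    def test_monotone_decreasing_in_kd(self):
        kds = np.logspace(-1, 6, 30)
        fbs = [fraction_bound(k, 100.0) for k in kds]
        assert all(a > b for a, b in zip(fbs, fbs[1:]))


class TestAmplification:
    def test_zero_cycles_is_unity(self):
        assert amplification_factor(0.7, 0, 0.05, 0.9) == 1.0

    def test_saturated_and_unbound_factors(self):
        assert amplification_factor(1.0, 10, 0.05, 0.9) == pytest.approx(1.9 ** 10)
        assert amplification_factor(1.0, 10, 0.05, 0.9) == pytest.approx(613.1, abs=0.1)
        assert amplification_factor(0.0, 10, 0.05, 0.9) == pytest.approx(1.05 ** 10)
        assert amplification_factor(0.0, 10, 0.05, 0.9) == pytest.approx(1.629, abs=1e-3)


class TestCompartmentalization:
    def test_empty_fraction_matches_poisson(self):
        pool = spike_in_pool(None)
        params = SimulationParams(seed=5, n_compartments=100_000, mean_occupancy=0.1)
        occ = compartmentalize(pool, params)
        expected = math.exp(-0.1)
        sigma = math.sqrt(expected * (1 - expected) / params.n_compartments)
        assert abs(occ.empty_fraction - expected) < 3 * sigma

    def test_low_occupancy_limit_is_clonal(self):
        pool = spike_in_pool(None, ratio=1.0)
        params = SimulationParams(seed=5, n_compartments=50_000, mean_occupancy=0.001)
        occ = compartmentalize(pool, params)
        assert occ.polyclonal_fraction < 0.01

    def test_fixed_seed_reproducible(self):
        pool = spike_in_pool(None)
        params = SimulationParams(seed=11)
        a = compartmentalize(pool, params)
        b = compartmentalize(pool, params)
        np.testing.assert_array_equal(a.cell_variant, b.cell_variant)
        np.testing.assert_array_equal(a.cells_per_compartment, b.cells_per_compartment)


class TestSimulateRound:
    def test_frequency_conservation(self):
        pool = nanoluc_ladder()
        run = simulate_round(pool, SimulationParams(seed=1, read_depth=10_000))
        assert run.truth["input_freq"].sum() == pytest.approx(1.0)
        assert run.truth["output_freq"].sum() == pytest.approx(1.0)
        assert run.truth["expected_output_freq"].sum() == pytest.approx(1.0)
        assert run.truth["sampled_reads"].sum() == 10_000

    def test_symmetric_pool_splits_evenly(self):
        entries = [Variant("a", ("ATGGCA",), 10.0, 0.5),
                   Variant("b", ("TGGGCA",), 10.0, 0.5)]
        run = simulate_round(VariantPool(entries),
                             SimulationParams(seed=3, read_depth=100_000))
        f = run.sampled_reads[0] / 100_000
        # combined cell-sampling + read-sampling binomial tolerance
        n_cells = run.truth["input_cells"].sum()
        sigma = 0.5 * math.sqrt(1 / n_cells + 1 / 100_000)
        assert abs(f - 0.5) < 3 * sigma

    def test_neutral_when_efficiencies_equal(self):
        entries = [Variant("a", ("ATGGCA",), 1.0, 0.3),
                   Variant("b", ("TGGGCA",), 1e5, 0.7)]
        params = SimulationParams(seed=4, e_min=0.5, e_max=0.5, read_depth=100_000)
        run = simulate_round(VariantPool(entries), params)
        np.testing.assert_allclose(run.truth["expected_output_freq"],
                                   run.truth["input_freq"], atol=1e-12)
        n_cells = run.truth["input_cells"].sum()
        for f_obs, f_in in zip(run.sampled_reads / 100_000, (0.3, 0.7)):
            sigma = math.sqrt(f_in * (1 - f_in)) * math.sqrt(1 / n_cells + 1 / 100_000)
            assert abs(f_obs - f_in) < 3 * sigma

    def test_expected_enrichment_monotone_in_kd(self):
        kds = [0.7, 10.0, 300.0, 5e3, 1.9e5]
        entries = [Variant(f"v{i}", ("ATGGCA",), kd, 1 / len(kds))
                   for i, kd in enumerate(kds)]
        run = simulate_round(VariantPool(entries), SimulationParams(seed=2))
        expected = run.truth["expected_output_freq"].to_numpy()
        assert all(a >= b for a, b in zip(expected, expected[1:]))

    def test_covalent_threshold_saturates_binding(self):
        entries = [Variant("cov", ("ATGGCA",), 50.0, 1.0)]
        params = SimulationParams(seed=1, covalent_kd_threshold_nm=100.0)
        run = simulate_round(VariantPool(entries), params)
        assert run.truth["fraction_bound"].iloc[0] == 1.0

    def test_spike_in_minority_becomes_majority(self, lib1):
        """A 1:100 high-affinity spike-in dominates reads after one round
        under default efficiencies (fold-change >> 100)."""
        pool = spike_in_pool(lib1, ratio=1 / 100)
        run = simulate_round(pool, SimulationParams(seed=6, read_depth=100_000))
        binder = run.truth.set_index("label")
        assert binder.loc["binder", "sampled_reads"] > 50_000
        # odds-ratio fold-change = ratio of amplification factors (~594/1.63),
        # far larger than the 100x input disadvantage
        fold = (binder.loc["binder", "amplification"]
                / binder.loc["nonbinder", "amplification"])
        assert fold > 100

    def test_affinity_ladder_mean_ordering_over_seeds(self):
        """Strongest >= next-strongest >> weakest across 5 seeds."""
        sums = {"NS1": 0.0, "NS5": 0.0, "NS6": 0.0}
        for seed in range(5):
            run = simulate_round(nanoluc_ladder(),
                                 SimulationParams(seed=seed, read_depth=100_000))
            t = run.truth.set_index("label")["output_freq"]
            for k in sums:
                sums[k] += t[k] / 5
        assert sums["NS1"] >= sums["NS5"] > 10 * sums["NS6"]

    def test_rank_order_recovery_spearman(self):
        """log2 enrichment tracks -log10 Kd: mean Spearman >= 0.9 over an
        8-variant ladder at 1e5 reads, 10 cycles, 5 seeds."""
        kds = np.array([0.7, 3.4, 20.0, 100.0, 500.0, 2.5e3, 1.2e4, 1.9e5])
        rhos = []
        for seed in range(5):
            entries = [Variant(f"v{i}", ("ATGGCA",), kd, 1 / 8)
                       for i, kd in enumerate(kds)]
            run = simulate_round(VariantPool(entries),
                                 SimulationParams(seed=seed, read_depth=100_000))
            sel = CountTable("sel", {e.label: int(c) for e, c in
                                     zip(entries, run.sampled_reads) if c > 0})
            naive_counts = np.random.default_rng(seed + 100).multinomial(
                100_000, [1 / 8] * 8)
            ref = CountTable("naive", {e.label: int(c)
                                       for e, c in zip(entries, naive_counts)})
            enr = enrichment_ratio(sel, ref)
            rhos.append(spearmanr(-np.log10(kds),
                                  [enr[e.label] for e in entries]).statistic)
        assert np.mean(rhos) >= 0.9

    def test_no_cells_is_an_error(self):
        pool = spike_in_pool(None)
        params = SimulationParams(seed=0, n_compartments=1, mean_occupancy=1e-9)
        with pytest.raises(Exception):
            simulate_round(pool, params)


class TestReadEmission:
    def test_error_free_reads_round_trip_through_extraction(self, lib1):
        pool = nnk_naive_pool(lib1, n_variants=100, seed=9,
                              include=[lib1.wildtype_dna()])
        params = SimulationParams(seed=9, read_depth=10_000, error_rate=0.0)
        run = simulate_round(pool, params)
        reads = emit_reads(run)
        rule = ExtractionRule.from_library(lib1)
        truth_motif = {v.label: lib1.motif(v.dna) for v in pool.entries}
        recovered = 0
        for r in reads:
            out = extract_variable_regions(r, rule)
            label = r.id.split("|", 1)[1]
            if out is not None and out[0].peptide == truth_motif[label]:
                recovered += 1
        assert recovered == len(reads) == 10_000

    def test_error_rate_reproduced_in_reads(self, lib1):
        pool = spike_in_pool(lib1)
        params = SimulationParams(seed=12, read_depth=2_000, error_rate=0.01)
        run = simulate_round(pool, params)
        reads = emit_reads(run)
        templates = {v.label: lib1.read_template(v.dna) for v in pool.entries}
        mismatches = bases = 0
        for r in reads:
            t = templates[r.id.split("|", 1)[1]]
            mismatches += sum(a != b for a, b in zip(r.sequence, t))
            bases += len(t)
        # substituting to a random other base always changes the base
        sigma = math.sqrt(0.01 * 0.99 / bases)
        assert abs(mismatches / bases - 0.01) < 3 * sigma

    def test_fixed_seed_emits_identical_fastq(self, tmp_path, lib1):
        pool = spike_in_pool(lib1)
        params = SimulationParams(seed=21, read_depth=200, error_rate=0.005)
        paths = []
        for name in ("a.fastq", "b.fastq"):
            run = simulate_round(pool, params)
            write_fastq(emit_reads(run), tmp_path / name)
            paths.append((tmp_path / name).read_bytes())
        assert paths[0] == paths[1]

    def test_truth_counts_match_emitted_reads(self, lib1):
        pool = spike_in_pool(lib1)
        run = simulate_round(pool, SimulationParams(seed=2, read_depth=500))
        reads = emit_reads(run)
        emitted = {}
        for r in reads:
            label = r.id.split("|", 1)[1]
            emitted[label] = emitted.get(label, 0) + 1
        truth = dict(zip(run.truth["label"], run.truth["sampled_reads"]))
        assert emitted == {k: v for k, v in truth.items() if v > 0}


class TestNaivePool:
    def test_nnk_amino_acid_frequencies(self, lib1):
        """Naive-sample amino-acid frequencies match the NNK distribution
        within 3-sigma multinomial tolerance per letter."""
        from compsel.codons import AA_LETTERS, aa_distribution
        pool = nnk_naive_pool(lib1, n_variants=3_000, seed=17)
        dist = aa_distribution("NNK")
        tally = {}
        n_letters = 0
        for v in pool.entries:
            weight = round(v.frequency * 3_000)
            for aa in lib1.motif(v.dna):
                tally[aa] = tally.get(aa, 0) + weight
                n_letters += weight
        for aa in AA_LETTERS + "*":
            p = dist[aa]
            sigma = math.sqrt(p * (1 - p) / n_letters)
            assert abs(tally.get(aa, 0) / n_letters - p) <= 3 * sigma, aa

    def test_single_variant_pool(self, lib1):
        pool = nnk_naive_pool(lib1, n_variants=1, seed=1)
        assert len(pool.entries) == 1
        assert pool.entries[0].frequency == 1.0

    def test_planted_binder_recovered_as_top_rank(self, lib1):
        """End-to-end: a designated low-Kd wild-type motif ends at rank 1
        after one simulated round and full counting."""
        pool = nnk_naive_pool(lib1, n_variants=500, seed=23,
                              binders={"IVMV": 0.7},
                              include=[lib1.wildtype_dna()])
        run = simulate_round(pool, SimulationParams(seed=23, read_depth=100_000))
        motifs = []
        for motif, n in zip(run.truth["motif"], run.sampled_reads):
            motifs.extend([motif] * int(n))
        top = rank_table(count_variants(motifs))[0]
        assert top.motif == "IVMV"

    def test_pool_frequencies_sum_to_one(self, lib1):
        pool = nnk_naive_pool(lib1, n_variants=777, seed=3)
        assert sum(v.frequency for v in pool.entries) == pytest.approx(1.0)
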