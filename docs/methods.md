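# Methods

This note documents the models, conventions and design choices behind
`compsel`, and what the synthetic-data generator does and does not
emulate.

## Library model

A library is one or more *segments*, each a wild-type variable region
(ACGT, codon-sized) embedded in constant context. Degenerate blocks map
codon indices within the segment to IUPAC triplets (typically NNK).
Primer parsing reverse-complements reverse-strand primers (so MNN runs
become NNK), finds maximal runs of degenerate positions, and requires all
runs to share a codon frame; the frame is anchored to the in-frame ATG of
the 5′ constant flank when one exists. Runs that cannot be codon-aligned
raise a frame-ambiguity error rather than guessing.

Diversity arithmetic treats randomized codons as independent, which they
are by construction. The DNA-level count is the product of expansion
sizes. Distinct stop-free peptides and the stop-containing DNA fraction
are computed by exhaustive enumeration of all codon combinations up to a
cap (default 10⁷ DNA combinations), and by per-codon distribution
products beyond it; the two paths agree exactly for independent codons
and are cross-checked in tests. Peptide-level counting treats a
stop-containing variant as its own category rather than truncating it,
since a truncated peptide is not a functional library member; a flag on
the analysis side allows keeping stop-containing reads in count tables.

Sampling coverage uses the exact occupancy expectation
`1 − (1 − 1/n)^d` (uniform) or the mean of `1 − (1 − p_i)^d` (explicit
probabilities).

## Extraction

Anchors are the last/first `anchor_length` nt (default 12, minimum 8) of
each segment's constant flanks. Matching is a sliding Hamming-distance
scan with a per-anchor mismatch budget (default 1) and **no indels**:
short-read substitution errors dominate on modern platforms, and
indel-tolerant alignment would buy little for 12-mers while complicating
determinism. Ties resolve to the leftmost match. Reads are tried forward
first, then as reverse complements (policy `both`). Multi-segment rules
require all segments in order on one strand, matching amplicons that
co-encode both interaction partners.

The region strictly between anchors is translated with the standard
genetic code; variants are flagged (`stop_codon`, `length_mismatch`,
`ambiguous_base`, `low_quality` by mean Phred, default threshold 20)
rather than silently dropped, and the filter stage counts every drop by
reason so that `reads_in = reads_counted + Σ drops` holds in every run
report. Coordinates are 0-based half-open internally, 1-based in logs.
FASTQ qualities are Phred+33; FASTA input simply skips the quality
filter.

## Counting, ranking, enrichment

Counting is at the peptide level by default (synonymous DNA collapses);
joint multi-segment motifs join segments with `/`. Ranks are ordinal
(1..n_unique) after sorting by count descending with lexicographic
tie-breaking — "the k-th most abundant" is only reproducible with an
explicit tie rule — and the percentile of a motif is
`100 · rank / n_unique`. Enrichment between rounds is

```
log2( (c_sel + pc)/(N_sel + pc·|U|) ÷ (c_ref + pc)/(N_ref + pc·|U|) )
```

over the union U of motifs, with pseudocount pc = 0.5 (half-count
correction; configurable). It is antisymmetric under swapping rounds and
finite for motifs absent from one round.

## Sequence logos

Logos use the classical information-content construction: stop
frequencies are excluded and amino-acid frequencies renormalized; with a
uniform background `IC = log₂20 − H(p)` bits, optionally minus the
small-sample penalty `19/(2·ln2·n)` (clamped at 0); letter heights are
`p · IC` and therefore sum to the position's IC. With a non-uniform
background (e.g. the NNK-encoded amino-acid distribution) IC is the
relative entropy to that background, which shows selection *over*
synthesis bias — useful because NNK alone already favors Leu/Arg/Ser
(3/32 each). Error bars are element-wise SDs over B = 200 bootstrap
resamples of the motif list, seeded and bit-reproducible. How error bars
on published logos of this kind are computed is generally not stated;
the seeded bootstrap is this package's documented choice. By default a
top-k motif list is treated as a set (each unique motif once); a
read-weighted mode is available.

## Selection simulator

One round is modeled as:

1. **Compartmentalization.** Each of `n_compartments` droplets receives
   `Poisson(λ)` cells; occupant identities are i.i.d. draws from current
   variant frequencies. Occupied droplets with more than one distinct
   variant are reported as polyclonal. Occupants amplify independently
   (no cross-talk), the simplest model consistent with clonal read-out;
   at the default λ = 0.1 polyclony is rare anyway.
2. **Binding.** `f_b = C/(C + K_d)` with effective partner concentration
   C (default 100 nM), i.e. a partner-excess Langmuir isotherm. A
   covalent-pair option sets `f_b = 1` below a Kd threshold, reflecting
   irreversible isopeptide-bond partners.
3. **Amplification.** Per-cycle efficiency
   `e = e_min + (e_max − e_min)·f_b`, fold amplification `(1+e)^cycles`.
   This coupling is deliberately phenomenological — the published
   evidence for affinity-coupled amplification is empirical (yield
   correlates with affinity), so the package uses the simplest monotone
   map with the right limits: neutral when `e_min = e_max`, saturating
   in C, strictly decreasing in Kd.
4. **Sequencing.** Post-selection frequencies are proportional to summed
   amplified copies; `read_depth` reads are drawn multinomially, and each
   read is the library context with the variant spliced in, hit by
   uniform base substitutions at `error_rate` with a constant quality
   string consistent with that rate. Read ids embed the ground-truth
   label.

Defaults (all configurable, none presented as measured values):
`cycles = 10` (a typical emulsion-PCR program), `n_compartments = 10⁵`
and `λ = 0.1` as a desk-scale surrogate for clonality — a
`full_scale()` preset honors the ~10⁷-cell experiment — `e_min = 0.05`,
`e_max = 0.9`, `C = 100 nM`, `read_depth = 10⁵`, `error_rate = 0.005`.
The split-luciferase affinity ladder fixture pins the recoverable values
(0.7 nM strongest, 3.4 nM next, 1.9×10⁵ nM weakest, 180 nM read-out
threshold slot) and leaves the intermediate slots configurable.

Naive pools are sampled by per-position draws from the degenerate-codon
expansions, so amino-acid composition reproduces NNK synthesis bias;
designated binder motifs receive low Kds and everything else a
non-binding background Kd (default 1.9×10⁵ nM). Duplicated draws
collapse with summed frequency. In the co-evolution preset the two
randomized SpyCatcher phenylalanine codons are represented by TTT
placeholders (the true construct codons are replaced by the degenerate
primers and are not recoverable from them), and emitted reads
concatenate the two informative cassette windows rather than the full
plasmid amplicon — the intervening vector sequence carries no
information for extraction.

**What passing tests show and what they do not.** The simulator
reproduces Poisson loading statistics, affinity-rank recovery
(Spearman ≥ 0.9 between −log₁₀Kd and log2 enrichment on an 8-variant
ladder at 10⁵ reads over 5 seeds), spike-in takeover (a 1:100
high-affinity minority becomes the read majority in one round), and
exact round-tripping of error-free reads through extraction. It does not
model emulsion physical chemistry, droplet-size variation, PCR kinetics
or plateau effects, polymerase error spectra, chimeras, or paired-end
artifacts; passing tests therefore validate the analysis code and the
qualitative selection logic, not quantitative yields of any wet
experiment.

## Numerical and reproducibility choices

- All randomness in a run flows from one integer seed; independent
  stages use `numpy` seed-sequence substreams, so FASTQ output is
  bit-identical across reruns and stable under stage reordering.
- Expansions, rank tables and TSV outputs are deterministically ordered
  (lexicographic tie-breaks) so diffs are meaningful.
- Frequency/probability validation tolerances: 1e-12 for amino-acid
  distributions, 1e-9 for pool frequencies and PFM rows.
- Degenerate inputs: empty motif streams produce valid empty tables;
  all-stop logo positions are NaN with a warning; bootstrap over fewer
  than two distinct motifs returns zero SDs with a warning; a simulation
  in which no cell is loaded raises an error.

## Problem sizes used in the test and acceptance runs

Simulations in the shipped tests use 10⁵ compartments, read depths of
10³–10⁵ and pools of 2–500 variants; library enumeration is exact up to
the 4×NNK case (1,048,576 combinations). These sizes make every property
statistically decidable at 3σ while keeping the full suite around ten
seconds. Headline sequencing-scale percentiles (ranks 161/96,400 and
52/160,415) are computed on programmatically built count tables at those
exact scales.

## Known limitations

- Anchor matching cannot rescue reads with indels inside an anchor.
- Enrichment across more than two rounds (fitness regression) and
  replicate variance models are out of scope.
- The logo renderer is intentionally minimal; all numeric logo outputs
  are independent of it.
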