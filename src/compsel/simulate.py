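"""Stochastic simulation of one compartmentalized selection round.

The generative model mirrors emulsion-based two-hybrid selection: cells
carrying variant-encoding plasmids are loaded into aqueous compartments
at Poisson occupancy (low mean occupancy keeps compartments clonal);
within each compartment the variant's gene is amplified with a per-cycle
efficiency that increases with the fraction of reporter polymerase bound
by its partner; the pooled amplicons are then sequenced to finite depth
with per-base substitution error.

Binding follows the partner-excess isotherm ``fb = C / (C + Kd)``; the
per-cycle efficiency interpolates linearly between ``e_min`` (unbound)
and ``e_max`` (saturated), giving a fold amplification ``(1 + e)**cycles``.
This affinity-to-amplification coupling is a deliberately simple
phenomenological map: monotone in affinity, neutral when ``e_min == e_max``,
and saturating at high partner concentration.  Covalent partners (e.g. an
isopeptide-bond pair) can be modeled as fully bound below a Kd threshold.

Every stochastic choice flows from a single integer seed, so a run —
including the emitted FASTQ bytes — is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import translate
from .extraction import ReadRecord
from .library import LibrarySpec

__all__ = [
    "Variant",
    "VariantPool",
    "SimulationParams",
    "Occupancy",
    "SimulatedRun",
    "SimulationError",
    "fraction_bound",
    "amplification_factor",
    "compartmentalize",
    "simulate_round",
    "emit_reads",
    "write_fastq",
    "nnk_naive_pool",
    "spike_in_pool",
    "nanoluc_ladder",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Variant:
    """One library member: label, variable-region DNA (one string per
    segment), dissociation constant in nM, and input frequency."""

    label: str
    dna: tuple[str, ...]
    kd_nm: float
    frequency: float

    def __post_init__(self) -> None:
        if self.kd_nm <= 0:
            raise ValueError("Kd must be > 0")
        if self.frequency < 0:
            raise ValueError("frequency must be >= 0")
        if isinstance(self.dna, str):
            object.__setattr__(self, "dna", (self.dna,))
        else:
            object.__setattr__(self, "dna", tuple(self.dna))


@dataclass
class VariantPool:
    """A set of variants with input frequencies summing to 1, plus the
    library context used to embed them into reads (optional when reads
    are not emitted)."""

    entries: list[Variant]
    context: LibrarySpec | None = None

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("pool must contain at least one variant")
        total = sum(v.frequency for v in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"input frequencies sum to {total}, expected 1")
        if self.context is not None:
            n_seg = len(self.context.segments)
            for v in self.entries:
                if len(v.dna) != n_seg:
                    raise ValueError(
                        f"variant {v.label!r} has {len(v.dna)} segment(s), "
                        f"context expects {n_seg}")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([v.frequency for v in self.entries])

    @property
    def kds(self) -> np.ndarray:
        return np.array([v.kd_nm for v in self.entries])

    def motifs(self) -> list[str]:
        if self.context is not None:
            return [self.context.motif(v.dna) for v in self.entries]
        return ["/".join(translate(d) for d in v.dna) for v in self.entries]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of one selection round.

    Defaults are a desk-scale surrogate of a typical emulsion selection:
    1e5 compartments at mean occupancy 0.1 (so ~90% of compartments are
    empty and occupied ones are predominantly clonal), 10 thermal cycles,
    per-cycle efficiencies 0.05 (unbound) to 0.9 (saturated), 100 nM
    effective partner concentration, 1e5 reads and a 0.005 per-base
    substitution error.  ``full_scale()`` gives the 1e7-cell preset.
    """

    n_compartments: int = 100_000
    mean_occupancy: float = 0.1
    cycles: int = 10
    e_min: float = 0.05
    e_max: float = 0.9
    partner_conc_nm: float = 100.0
    read_depth: int = 100_000
    error_rate: float = 0.005
    seed: int = 0
    covalent_kd_threshold_nm: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.e_min <= self.e_max <= 1):
            raise ValueError("need 0 <= e_min <= e_max <= 1")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if self.mean_occupancy <= 0:
            raise ValueError("mean occupancy must be > 0")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.n_compartments < 1 or self.read_depth < 0:
            raise ValueError("n_compartments >= 1 and read_depth >= 0 required")

    @classmethod
    def full_scale(cls, **overrides) -> "SimulationParams":
        """Preset honoring a full-scale selection input of ~1e7 cells."""
        base = dict(n_compartments=100_000_000, mean_occupancy=0.1)
        base.update(overrides)
        return cls(**base)


def fraction_bound(kd_nm: float, partner_conc_nm: float) -> float:
    """Equilibrium fraction bound under partner excess: C / (C + Kd)."""
    if kd_nm <= 0:
        raise ValueError("Kd must be > 0")
    if partner_conc_nm < 0:
        raise ValueError("concentration must be >= 0")
    return partner_conc_nm / (partner_conc_nm + kd_nm)


def amplification_factor(fb: float, cycles: int, e_min: float, e_max: float) -> float:
    """Fold amplification after ``cycles`` with efficiency interpolated
    between e_min (fb=0) and e_max (fb=1): ``(1 + e)**cycles``."""
    e = e_min + (e_max - e_min) * fb
    return float((1.0 + e) ** cycles)


@dataclass
class Occupancy:
    """Compartment loading: per-compartment cell counts and, for each
    cell, its compartment and variant indices."""

    cells_per_compartment: np.ndarray  # (n_compartments,)
    cell_compartment: np.ndarray       # (n_cells,)
    cell_variant: np.ndarray           # (n_cells,)
    n_variants: int

    @property
    def n_cells(self) -> int:
        return int(self.cell_variant.size)

    @property
    def empty_fraction(self) -> float:
        return float(np.mean(self.cells_per_compartment == 0))

    def per_variant_cells(self) -> np.ndarray:
        return np.bincount(self.cell_variant, minlength=self.n_variants)

    @property
    def polyclonal_fraction(self) -> float:
        """Fraction of *occupied* compartments holding >1 distinct variant."""
        occupied = self.cells_per_compartment > 0
        n_occ = int(occupied.sum())
        if n_occ == 0:
            return 0.0
        pairs = np.unique(np.stack([self.cell_compartment, self.cell_variant]), axis=1)
        distinct = np.bincount(pairs[0], minlength=len(self.cells_per_compartment))
        return float(np.sum(distinct > 1) / n_occ)


def compartmentalize(pool: VariantPool, params: SimulationParams,
                     rng: np.random.Generator | None = None) -> Occupancy:
    """Poisson-load compartments with cells drawn from the pool frequencies.

    Compartment cell counts are Poisson(mean_occupancy); occupant
    identities are i.i.d. draws from the current variant frequencies.
    Deterministic given the generator state (or ``params.seed``).
    """
    if rng is None:
        rng = np.random.default_rng([params.seed, 0])
    counts = rng.poisson(params.mean_occupancy, params.n_compartments)
    total = int(counts.sum())
    freqs = pool.frequencies
    variants = rng.choice(len(pool.entries), size=total, p=freqs / freqs.sum())
    comp = np.repeat(np.arange(params.n_compartments), counts)
    return Occupancy(cells_per_compartment=counts, cell_compartment=comp,
                     cell_variant=variants, n_variants=len(pool.entries))


@dataclass
class SimulatedRun:
    """Result of one simulated round: the ground truth table plus the
    pool/params needed to emit reads."""

    pool: VariantPool
    params: SimulationParams
    occupancy: Occupancy
    truth: pd.DataFrame  # label, motif, kd_nm, input_freq, input_cells,
    #                      expected_output_freq, output_freq, sampled_reads

    @property
    def post_frequencies(self) -> np.ndarray:
        return self.truth["output_freq"].to_numpy()

    @property
    def sampled_reads(self) -> np.ndarray:
        return self.truth["sampled_reads"].to_numpy()


def _fractions_bound(pool: VariantPool, params: SimulationParams) -> np.ndarray:
    fb = np.array([fraction_bound(v.kd_nm, params.partner_conc_nm)
                   for v in pool.entries])
    if params.covalent_kd_threshold_nm is not None:
        fb = np.where(pool.kds <= params.covalent_kd_threshold_nm, 1.0, fb)
    return fb


def simulate_round(pool: VariantPool, params: SimulationParams) -> SimulatedRun:
    """Simulate one selection round.

    Each cell's template is amplified by the factor set by its variant's
    affinity; compartments amplify occupants independently (no cross-talk,
    so polyclonal compartments do not rescue weak binders).  Post-selection
    frequencies are proportional to summed amplified copies, and
    ``read_depth`` reads are drawn multinomially from them.
    """
    ss = np.random.SeedSequence(params.seed)
    rng_occ, rng_reads = (np.random.default_rng(s) for s in ss.spawn(2))
    occ = compartmentalize(pool, params, rng_occ)

    fb = _fractions_bound(pool, params)
    amp = np.array([amplification_factor(f, params.cycles, params.e_min, params.e_max)
                    for f in fb])
    cells = occ.per_variant_cells()
    weights = cells * amp
    wsum = weights.sum()
    if wsum <= 0:
        raise SimulationError("no template survived selection (no cells loaded)")
    post = weights / wsum

    input_freq = pool.frequencies
    expected = input_freq * amp
    expected = expected / expected.sum()

    reads = rng_reads.multinomial(params.read_depth, post)
    truth = pd.DataFrame({
        "label": [v.label for v in pool.entries],
        "dna": ["|".join(v.dna) for v in pool.entries],
        "motif": pool.motifs(),
        "kd_nm": pool.kds,
        "fraction_bound": fb,
        "amplification": amp,
        "input_freq": input_freq,
        "input_cells": cells,
        "expected_output_freq": expected,
        "output_freq": post,
        "sampled_reads": reads,
    })
    return SimulatedRun(pool=pool, params=params, occupancy=occ, truth=truth)


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def emit_reads(run: SimulatedRun) -> list[ReadRecord]:
    """Emit the sampled reads as FASTQ-ready records.

    Each read is the library context with the variant's variable region(s)
    spliced in, hit by uniform substitution errors at ``error_rate``; the
    quality string is constant and consistent with that error rate.  Read
    ids embed the ground-truth variant label (``sim_<k>|<label>``).
    Bit-identical for a fixed ``params.seed``.
    """
    pool, params = run.pool, run.params
    if pool.context is None:
        raise SimulationError("pool has no library context; cannot emit reads")
    rng = np.random.default_rng([params.seed, 7])

    q = 40 if params.error_rate <= 0 else int(round(-10 * np.log10(params.error_rate)))
    q = int(np.clip(q, 2, 40))

    counts = run.sampled_reads
    order = rng.permutation(int(counts.sum()))
    variant_of_read = np.repeat(np.arange(len(counts)), counts)[order]

    templates = [np.frombuffer(pool.context.read_template(v.dna).encode("ascii"),
                               dtype=np.uint8) for v in pool.entries]
    labels = [v.label for v in pool.entries]

    reads: list[ReadRecord] = []
    for k, vi in enumerate(variant_of_read):
        seq = templates[vi].copy()
        if params.error_rate > 0:
            mask = rng.random(seq.size) < params.error_rate
            n_err = int(mask.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                seq[mask] = _BASES[(_BASE_INDEX[seq[mask]] + shift) % 4]
        reads.append(ReadRecord(
            id=f"sim_{k:06d}|{labels[vi]}",
            sequence=seq.tobytes().decode("ascii"),
            qualities=(q,) * seq.size,
        ))
    return reads


def write_fastq(reads: Sequence[ReadRecord], path: str | Path) -> None:
    """Write reads as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities if r.qualities is not None else (40,) * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n"
                     + "".join(chr(33 + q) for q in quals) + "\n")


def write_truth(run: SimulatedRun, path: str | Path) -> None:
    run.truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pool constructors
# ---------------------------------------------------------------------------

def nnk_naive_pool(spec: LibrarySpec,
                   n_variants: int,
                   seed: int = 0,
                   binders: Mapping[str, float] | None = None,
                   background_kd_nm: float = 1.9e5,
                   include: Sequence[tuple[str, ...]] = ()) -> VariantPool:
    """Sample a naive library pool by per-position degenerate-codon draws.

    ``n_variants`` DNA variants are drawn (randomized codons sampled
    uniformly from their expansions, so the pool reproduces NNK synthesis
    bias); duplicate draws collapse with summed frequency.  ``include``
    forces specific variants (e.g. the wild type) into the pool, each
    replacing one random draw.  Kds come from ``binders`` (motif -> Kd in
    nM); everything else gets ``background_kd_nm``.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    binders = dict(binders or {})
    rng = np.random.default_rng([seed, 11])

    expansions = []  # per segment: list over codons of (is_block, choices|wt)
    for seg in spec.segments:
        block_map = dict(seg.blocks)
        seg_plan = []
        for ci in range(seg.n_codons):
            wt = seg.wildtype[3 * ci:3 * ci + 3]
            if ci in block_map:
                seg_plan.append(block_map[ci].expand())
            else:
                seg_plan.append([wt])
        expansions.append(seg_plan)

    include = [tuple((d,) if isinstance(d, str) else d) for d in include]
    n_random = n_variants - len(include)
    if n_random < 0:
        raise ValueError("more forced variants than n_variants")

    draws: list[tuple[str, ...]] = list(include)
    for _ in range(n_random):
        variant = tuple(
            "".join(choices[rng.integers(len(choices))] for choices in seg_plan)
            for seg_plan in expansions
        )
        draws.append(variant)

    tally: dict[tuple[str, ...], int] = {}
    for d in draws:
        tally[d] = tally.get(d, 0) + 1

    entries = []
    for i, (dna, k) in enumerate(tally.items()):
        motif = spec.motif(dna)
        kd = binders.get(motif, background_kd_nm)
        entries.append(Variant(label=f"v{i:05d}:{motif}", dna=dna,
                               kd_nm=kd, frequency=k / n_variants))
    return VariantPool(entries=entries, context=spec)


def spike_in_pool(spec: LibrarySpec | None,
                  binder_kd_nm: float = 0.7,
                  nonbinder_kd_nm: float = 1.9e5,
                  ratio: float = 1.0 / 100.0) -> VariantPool:
    """Two-variant spike-in pool: a high-affinity minority (input fraction
    ``ratio/(1+ratio)``) against a non-binding majority — the standard
    model-selection scenario for testing clonal enrichment."""
    f_binder = ratio / (1.0 + ratio)
    if spec is not None:
        wt = spec.wildtype_dna()
        # non-binder: mutate every randomized codon of the wild type to GGT (Gly)
        nb = []
        for seg, d in zip(spec.segments, wt):
            s = list(d)
            for ci, _ in seg.blocks:
                s[3 * ci:3 * ci + 3] = "GGT"
            nb.append("".join(s))
        entries = [
            Variant("binder", wt, binder_kd_nm, f_binder),
            Variant("nonbinder", tuple(nb), nonbinder_kd_nm, 1.0 - f_binder),
        ]
    else:
        entries = [
            Variant("binder", ("ATG",), binder_kd_nm, f_binder),
            Variant("nonbinder", ("GGT",), nonbinder_kd_nm, 1.0 - f_binder),
        ]
    return VariantPool(entries=entries, context=spec)


# Split-luciferase peptide fixture: the two affinities recoverable from the
# reported ladder are fixed (strongest 0.7 nM, next 3.4 nM) and the weakest
# endpoint 1.9e5 nM; the intermediate slots are configurable placeholders.
_DEFAULT_LADDER = {
    "NS1": 0.7,
    "NS2": 15.0,     # placeholder slot
    "NS3": 180.0,    # read-out threshold slot
    "NS4": 2500.0,   # placeholder slot
    "NS5": 3.4,
    "NS6": 1.9e5,
}


def nanoluc_ladder(kds: Mapping[str, float] | None = None) -> VariantPool:
    """Equimolar pool of split-luciferase peptide variants spanning the
    affinity ladder; used as a simulator fixture for rank-order tests."""
    table = dict(_DEFAULT_LADDER)
    if kds:
        table.update(kds)
    n = len(table)
    entries = [Variant(label, ("ATGGCA",), kd, 1.0 / n)
               for label, kd in sorted(table.items())]
    return VariantPool(entries=entries, context=None)
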