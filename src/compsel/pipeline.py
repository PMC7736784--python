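"""Pipeline orchestration: design -> simulate/ingest -> extract -> count ->
rank -> logo, with full read accounting and a reproducible run report.

A run is configured either with an input FASTQ/FASTA of amplicon reads or
with simulation settings (exactly one of the two).  All randomness flows
from the single config seed; re-running an identical config reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (CountTable, count_variants, enrichment_ratio,
                         query_rank, top_fraction, write_count_table)
from .extraction import (ExtractionRule, FilterPolicy, extract_variable_regions,
                         filter_variant, joint_motif, read_sequences)
from .library import LibrarySpec
from .logo import bootstrap_sd, frequency_matrix, information_content, write_matrix_tsv
from .presets import PRESETS, get_preset
from .simulate import (SimulationParams, emit_reads, nnk_naive_pool,
                       simulate_round, write_fastq, write_truth)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline", "compare_rounds"]

log = logging.getLogger("compsel")


class PipelineError(RuntimeError):
    pass


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Exactly one of ``reads`` (path to FASTQ/FASTA) or ``simulate`` (dict of
    simulation settings: ``n_variants``, ``binders`` motif->Kd map, plus any
    :class:`SimulationParams` field) must be set.
    """

    library: str | LibrarySpec = "spytag-core"
    reads: str | None = None
    simulate: dict | None = None
    outdir: str = "compsel_run"
    seed: int = 0
    round_label: str = "round1"
    max_mismatches: int = 1
    orientation_policy: str = "both"
    length_tolerance_nt: int = 0
    min_mean_quality: float | None = 20.0
    keep_stop_codons: bool = False
    reference_motif: str | None = None
    top_k: int = 500
    logo_bootstrap: int = 200
    small_sample_correction: bool = False

    def __post_init__(self) -> None:
        if (self.reads is None) == (self.simulate is None):
            raise ConfigError("exactly one of 'reads' or 'simulate' must be given")

    def library_spec(self) -> LibrarySpec:
        if isinstance(self.library, LibrarySpec):
            return self.library
        if self.library in PRESETS:
            return get_preset(self.library)
        return LibrarySpec.load(self.library)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = {k: (v if not isinstance(v, LibrarySpec) else v.to_dict())
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Per-stage accounting and headline statistics of one run.

    The accounting identity ``reads_in == reads_counted + sum(drops)`` holds
    for every run.
    """

    seed: int
    config_digest: str
    version: str
    reads_in: int
    reads_extracted: int
    reads_counted: int
    drops: dict[str, int]
    n_unique: int
    total_reads: int
    mean_reads_per_unique: float
    reference_motif: str | None
    reference_rank: int | None
    reference_percentile: float | None
    outputs: dict[str, str]

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            f"reads in:            {self.reads_in}",
            f"reads extracted:     {self.reads_extracted}",
            f"reads counted:       {self.reads_counted}",
            f"drops:               {self.drops}",
            f"unique motifs:       {self.n_unique}",
            f"total counted reads: {self.total_reads}",
            f"mean reads/unique:   {self.mean_reads_per_unique:.2f}",
        ]
        if self.reference_motif is not None:
            lines.append(
                f"reference motif {self.reference_motif}: rank {self.reference_rank}"
                f" ({self.reference_percentile:.4f}% of uniques)"
                if self.reference_rank is not None else
                f"reference motif {self.reference_motif}: absent")
        return "\n".join(lines)


def _sim_params_from_config(config: RunConfig) -> tuple[SimulationParams, dict]:
    settings = dict(config.simulate or {})
    pool_keys = {"n_variants", "binders", "background_kd_nm", "include_wildtype"}
    pool_settings = {k: settings.pop(k) for k in list(settings) if k in pool_keys}
    settings.setdefault("seed", config.seed)
    try:
        params = SimulationParams(**settings)
    except TypeError as exc:
        raise ConfigError(f"bad simulation settings: {exc}") from None
    return params, pool_settings


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and write every intermediate as TSV/FASTQ/JSON."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: dict[str, str] = {}
    try:
        spec = config.library_spec()
        log.info("run seed=%d config=%s library=%s", config.seed,
                 config.digest(), spec.name)

        if config.simulate is not None:
            params, pool_settings = _sim_params_from_config(config)
            include = []
            if pool_settings.get("include_wildtype", True):
                include = [spec.wildtype_dna()]
            pool = nnk_naive_pool(
                spec,
                n_variants=int(pool_settings.get("n_variants", 1000)),
                seed=config.seed,
                binders=pool_settings.get("binders"),
                background_kd_nm=float(pool_settings.get("background_kd_nm", 1.9e5)),
                include=include,
            )
            run = simulate_round(pool, params)
            reads = emit_reads(run)
            reads_path = outdir / "simulated_reads.fastq"
            write_fastq(reads, reads_path)
            write_truth(run, outdir / "truth.tsv")
            with open(outdir / "sim_params.yaml", "w") as fh:
                yaml.safe_dump(asdict(params), fh)
            outputs["reads"] = str(reads_path)
            outputs["truth"] = str(outdir / "truth.tsv")
            outputs["sim_params"] = str(outdir / "sim_params.yaml")
            read_iter = iter(reads)
        else:
            outputs["reads"] = str(config.reads)
            read_iter = read_sequences(config.reads)

        rule = ExtractionRule.from_library(
            spec, max_mismatches=config.max_mismatches,
            orientation_policy=config.orientation_policy,
            length_tolerance_nt=config.length_tolerance_nt)
        policy = FilterPolicy(drop_stop_codon=not config.keep_stop_codons,
                              min_mean_quality=config.min_mean_quality)

        motifs: list[str] = []
        extracted_rows = []
        drops: dict[str, int] = {}
        reads_in = 0
        reads_extracted = 0
        for read in read_iter:
            reads_in += 1
            variants = extract_variable_regions(read, rule)
            if variants is None:
                drops["no_anchor"] = drops.get("no_anchor", 0) + 1
                continue
            reads_extracted += 1
            reason = None
            for v in variants:
                decision = filter_variant(v, policy)
                if not decision.keep:
                    reason = decision.reason
                    break
            for v in variants:
                extracted_rows.append((read.id, v.segment_index, v.dna, v.peptide,
                                       ";".join(sorted(v.flags))))
            if reason is not None:
                drops[reason] = drops.get(reason, 0) + 1
                continue
            motifs.append(joint_motif(variants, rule))

        if reads_in == 0:
            raise PipelineError("no reads in input")
        if drops.get("no_anchor", 0) >= 0.99 * reads_in:
            raise PipelineError(
                "anchors missing in >= 99% of reads — wrong library spec for "
                "these reads?")

        pd.DataFrame(extracted_rows,
                     columns=["read_id", "segment", "dna", "peptide", "flags"]
                     ).to_csv(outdir / "extracted.tsv", sep="\t", index=False)
        outputs["extracted"] = str(outdir / "extracted.tsv")
        pd.DataFrame(sorted(drops.items()), columns=["reason", "reads"]
                     ).to_csv(outdir / "drops.tsv", sep="\t", index=False)
        outputs["drops"] = str(outdir / "drops.tsv")

        table = count_variants(motifs, round_label=config.round_label)
        write_count_table(table, outdir / "counts.tsv")
        outputs["counts"] = str(outdir / "counts.tsv")

        ref_rank = ref_pct = None
        if config.reference_motif is not None and not table.is_empty():
            rep = query_rank(table, config.reference_motif)
            if rep is not None:
                ref_rank, ref_pct = rep.rank, rep.percentile

        if not table.is_empty():
            k = min(config.top_k, table.n_unique)
            top = top_fraction(table, k=k)
            pfm = frequency_matrix(top)
            logo = information_content(
                pfm, small_sample_correction=config.small_sample_correction)
            sd = bootstrap_sd(top, B=config.logo_bootstrap, seed=config.seed,
                              small_sample_correction=config.small_sample_correction)
            write_matrix_tsv(pfm, outdir / "pfm.tsv")
            logo_df = logo.to_frame()
            logo_df.to_csv(outdir / "logo.tsv", sep="\t")
            pd.DataFrame(sd, columns=list("ACDEFGHIKLMNPQRSTVWY")
                         ).to_csv(outdir / "logo_sd.tsv", sep="\t")
            outputs["pfm"] = str(outdir / "pfm.tsv")
            outputs["logo"] = str(outdir / "logo.tsv")
            outputs["logo_sd"] = str(outdir / "logo_sd.tsv")

        report = RunReport(
            seed=config.seed,
            config_digest=config.digest(),
            version=__version__,
            reads_in=reads_in,
            reads_extracted=reads_extracted,
            reads_counted=len(motifs),
            drops=drops,
            n_unique=table.n_unique,
            total_reads=table.total_reads,
            mean_reads_per_unique=(table.mean_reads_per_unique
                                   if not table.is_empty() else 0.0),
            reference_motif=config.reference_motif,
            reference_rank=ref_rank,
            reference_percentile=ref_pct,
            outputs=outputs,
        )
        report.save(outdir / "report.json")
        log.info("run complete: %d/%d reads counted, %d unique motifs",
                 len(motifs), reads_in, table.n_unique)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


@dataclass
class ComparisonBundle:
    enrichment: dict[str, float]
    naive_logo_motifs: list[str]
    selected_logo_motifs: list[str]
    outputs: dict[str, str]


def compare_rounds(naive: CountTable, selected: CountTable,
                   top_k: int = 20, outdir: str | Path = "compsel_compare",
                   pseudocount: float = 0.5, bootstrap: int = 200,
                   seed: int = 0) -> ComparisonBundle:
    """Naive-vs-selected comparison: enrichment TSV and paired logo data.

    Motifs in the two rounds must have a common length (after removing
    segment separators); top-k larger than a table falls back to the whole
    table with a warning.
    """
    def _motif_len(t: CountTable) -> set[int]:
        return {len(m.replace("/", "")) for m in t.counts}

    lens = _motif_len(naive) | _motif_len(selected)
    if len(lens) > 1:
        raise ValueError(f"motif length mismatch between rounds: {sorted(lens)}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enr = enrichment_ratio(selected, naive, pseudocount=pseudocount)
    enr_df = pd.DataFrame(sorted(enr.items(), key=lambda kv: -kv[1]),
                          columns=["motif", "log2_enrichment"])
    enr_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    outputs = {"enrichment": str(outdir / "enrichment.tsv")}
    bundles = {}
    for name, table in (("naive", naive), ("selected", selected)):
        motifs = top_fraction(table, k=top_k)  # warns and truncates if oversized
        pfm = frequency_matrix(motifs)
        logo = information_content(pfm)
        sd = bootstrap_sd(motifs, B=bootstrap, seed=seed)
        logo.to_frame().to_csv(outdir / f"logo_{name}.tsv", sep="\t")
        pd.DataFrame(sd, columns=list("ACDEFGHIKLMNPQRSTVWY")
                     ).to_csv(outdir / f"logo_sd_{name}.tsv", sep="\t")
        outputs[f"logo_{name}"] = str(outdir / f"logo_{name}.tsv")
        outputs[f"logo_sd_{name}"] = str(outdir / f"logo_sd_{name}.tsv")
        bundles[name] = motifs

    return ComparisonBundle(enrichment=enr,
                            naive_logo_motifs=bundles["naive"],
                            selected_logo_motifs=bundles["selected"],
                            outputs=outputs)
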