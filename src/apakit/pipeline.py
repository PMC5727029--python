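"""End-to-end pipeline assembly and the run manifest.

Ties the stages together: (simulate | load) -> discover -> annotate ->
APA statistics -> expression -> consequences, writing TSV/BED outputs and a
manifest that echoes every threshold.  Two input paths: a count-matrix fast
path (PAS x sample TSV) and a read path (SAM alignments + genome +
annotation).  With no external inputs the pipeline runs on synthetic data
generated from the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from importlib import metadata as _ilmd
from typing import Optional

import pandas as pd
import yaml

from . import annotation as ann
from . import apa as apa_mod
from . import consequences as cons
from . import discovery as disc
from . import expression as expr
from . import synthetic as syn
from .gene_models import GeneModelSet, load_annotation
from .matrix import PASCountMatrix, make_design

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs carry a .partial suffix."""


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults, echoed into the manifest."""

    # inputs (all optional; missing inputs are simulated)
    path: str = "counts"               # "counts" | "reads"
    genome: Optional[str] = None       # FASTA
    annotation: Optional[str] = None   # GTF
    counts_table: Optional[str] = None # PAS x sample TSV (fast path)
    sam_dir: Optional[str] = None      # directory of <sample_id>.sam (read path)
    sample_sheet: Optional[str] = None # TSV
    gene_counts: Optional[str] = None  # gene x sample TSV (expression)
    mirna_sites: Optional[str] = None  # BED6+2
    domains: Optional[str] = None      # BED6+2

    # discovery
    min_unaligned_t: int = 2
    orientation: str = "sense"
    max_gap: int = 24
    ip_window: int = 10
    ip_min_a: int = 6
    ip_filter: bool = True
    min_cluster_reads: int = 2

    # annotation
    hexamer_window: tuple = (-40, -1)
    utr3_extension: int = 1000

    # APA statistics
    alpha: float = 0.05
    min_delta: float = 0.05
    pseudocount: float = 0.5
    min_gene_reads: int = 20
    n_bins: int = 5
    min_introns: int = 4
    min_reads: int = 2

    # expression
    fc_cut: float = 1.2
    fdr_cut: float = 0.1

    # simulation (used when inputs are missing)
    n_genes: int = 200
    n_replicates: int = 3
    depth: float = 500.0
    dispersion: float = 0.1
    frac_shortened: float = 0.15
    frac_lengthened: float = 0.05
    frac_intronic_activated: float = 0.1
    frac_intronic_repressed: float = 0.03
    program_delta: float = 0.3
    frac_expr_up: float = 0.1
    frac_expr_down: float = 0.05
    expr_fold: float = 2.0

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise PipelineError(f"unknown config keys: {unknown}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.path not in ("counts", "reads"):
            raise PipelineError(f"path must be 'counts' or 'reads', got {self.path!r}")
        if self.path == "reads" and self.counts_table:
            raise PipelineError("read path and counts_table are mutually exclusive")
        if self.counts_table and not self.sample_sheet:
            raise PipelineError("counts_table requires sample_sheet")
        if self.sam_dir and not (self.genome and self.annotation and self.sample_sheet):
            raise PipelineError(
                "sam_dir requires genome, annotation and sample_sheet"
            )
        if self.sam_dir and not os.path.isdir(self.sam_dir):
            raise PipelineError(f"sam_dir not found: {self.sam_dir}")
        for name in ("genome", "annotation", "counts_table", "sample_sheet",
                     "gene_counts", "mirna_sites", "domains"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise PipelineError(f"{name} file not found: {p}")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["hexamer_window"] = list(self.hexamer_window)
        try:
            d["apakit_version"] = _ilmd.version("apakit")
        except _ilmd.PackageNotFoundError:
            d["apakit_version"] = "unknown"
        return d


def _read_genome(path: str) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _program_from_config(cfg: PipelineConfig) -> syn.ApaProgram:
    return syn.ApaProgram(
        frac_shortened=cfg.frac_shortened,
        frac_lengthened=cfg.frac_lengthened,
        frac_intronic_activated=cfg.frac_intronic_activated,
        frac_intronic_repressed=cfg.frac_intronic_repressed,
        delta=cfg.program_delta,
        frac_expr_up=cfg.frac_expr_up,
        frac_expr_down=cfg.frac_expr_down,
        expr_fold=cfg.expr_fold,
    )


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Execute every stage and write the report bundle into `outdir`.

    Returns a dict of the in-memory results keyed by stage.  Deterministic
    for a fixed config (all randomness flows from config.seed); a stage
    failure renames the outputs written so far with a .partial suffix and
    raises :class:`PipelineError`.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []

    def path_of(name: str) -> str:
        p = os.path.join(outdir, name)
        written.append(p)
        return p

    bundle: dict = {}
    try:
        _run_stages(config, outdir, path_of, bundle)
    except Exception as exc:
        for p in written:
            if os.path.exists(p) and os.path.isfile(p):
                os.replace(p, p + ".partial")
        raise PipelineError(f"pipeline failed: {exc}") from exc
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(config.to_manifest(), fh, indent=2, sort_keys=True)
    return bundle


def _run_stages(config, outdir, path_of, bundle) -> None:
    genome = None
    models: Optional[GeneModelSet] = None
    ref = None

    # --- inputs or simulation -------------------------------------------
    need_simulation = config.counts_table is None and config.sam_dir is None
    if config.path == "reads" and config.genome is None and need_simulation is False:
        raise PipelineError("read path with external alignments needs a genome")
    if config.genome:
        genome = _read_genome(config.genome)
    if config.annotation:
        models = load_annotation(config.annotation, utr3_extension=config.utr3_extension)

    if config.sample_sheet:
        design = pd.read_csv(config.sample_sheet, sep="\t", index_col="sample_id")
    else:
        design = make_design(config.n_replicates)
    design.to_csv(path_of("sample_sheet.tsv"), sep="\t", index_label="sample_id")

    sites = cons.read_features(config.mirna_sites) if config.mirna_sites else None
    domains = cons.read_features(config.domains) if config.domains else None

    if need_simulation:
        with_seq = config.path == "reads" or genome is None
        ref = syn.generate_reference(
            syn.ReferenceConfig(n_genes=config.n_genes),
            seed=config.seed,
            program=_program_from_config(config),
            with_sequence=with_seq,
        )
        if with_seq:
            genome = ref.genome
        if models is None:
            models = ref.models
        ref.truth.to_tsv(path_of("truth.tsv"))
        bundle["truth"] = ref.truth
        if sites is None or domains is None:
            gen_sites, gen_domains = syn.generate_features(ref, seed=config.seed + 1)
            sites = sites if sites is not None else gen_sites
            domains = domains if domains is not None else gen_domains

    # --- counts ----------------------------------------------------------
    if config.counts_table:
        matrix = PASCountMatrix.from_tsv(config.counts_table, config.sample_sheet)
    elif config.sam_dir or config.path == "reads":
        if config.sam_dir:
            sam_paths = {
                s: os.path.join(config.sam_dir, f"{s}.sam") for s in design.index
            }
            missing = [p for p in sam_paths.values() if not os.path.exists(p)]
            if missing:
                raise PipelineError(f"missing alignment files: {missing}")
        else:
            sam_paths, _emitted = syn.simulate_reads(
                ref, design, os.path.join(outdir, "reads"),
                depth=config.depth, dispersion=config.dispersion,
                seed=config.seed + 2,
            )
        reads = []
        for sample, sam in sam_paths.items():
            reads.extend(
                disc.extract_pas_reads(
                    sam, sample, genome=genome,
                    min_unaligned_t=config.min_unaligned_t,
                    orientation=config.orientation,
                )
            )
        clusters = disc.cluster_pas(reads, max_gap=config.max_gap)
        clusters = disc.filter_internal_priming(
            clusters, genome, window=config.ip_window, min_a=config.ip_min_a,
            enabled=config.ip_filter,
        )
        disc.write_clusters_bed(clusters, path_of("clusters.bed"))
        matrix = disc.quantify(clusters, design)
    else:
        matrix = syn.simulate_counts(
            ref.truth, design, depth=config.depth,
            dispersion=config.dispersion, seed=config.seed + 2,
        )

    # --- annotation ------------------------------------------------------
    if models is not None and matrix.meta["gene_id"].isna().any():
        matrix = ann.annotate_regions(matrix, models)
    if genome:
        matrix = ann.annotate_hexamers(matrix, genome, window=config.hexamer_window)
    matrix.to_tsv(path_of("pas_table.tsv"))
    bundle["matrix"] = matrix

    census = ann.census(matrix, min_cluster_reads=config.min_cluster_reads)
    census.region_counts.to_csv(path_of("census_regions.tsv"), sep="\t")
    census.hexamer_fractions.to_csv(path_of("census_hexamers.tsv"), sep="\t")
    census.pas_per_gene.to_csv(path_of("census_pas_per_gene.tsv"), sep="\t")
    bundle["census"] = census

    # --- APA statistics --------------------------------------------------
    model = apa_mod.APAUsageModel(
        matrix, alpha=config.alpha, min_delta=config.min_delta,
        pseudocount=config.pseudocount, min_gene_reads=config.min_gene_reads,
    )
    utr3 = model.fit("utr3")
    intronic = model.fit("intronic")
    utr3.events.to_csv(path_of("events_utr3.tsv"), sep="\t", index=False)
    intronic.events.to_csv(path_of("events_intronic.tsv"), sep="\t", index=False)
    bundle["utr3"] = utr3
    bundle["intronic"] = intronic

    bins, bin_p = utr3.autr_bins(n_bins=config.n_bins)
    bins.assign(wilcoxon_p_bin1_vs_bin5=bin_p.p_value).to_csv(
        path_of("autr_bins.tsv"), sep="\t"
    )
    profile = model.intron_position_profile(
        min_introns=config.min_introns, min_reads=config.min_reads
    )
    profile.table.assign(wilcoxon_p_first_vs_last=profile.p_first_vs_last.p_value
                         ).to_csv(path_of("intron_profile.tsv"), sep="\t")
    apa_mod.apa_quadrants(utr3, intronic).to_csv(path_of("quadrants.tsv"), sep="\t")
    utr3.weighted_utr3_lengths().to_csv(path_of("utr3_lengths.tsv"), sep="\t",
                                        index=False)
    bundle["profile"] = profile

    # --- expression ------------------------------------------------------
    if config.gene_counts:
        gene_counts = pd.read_csv(config.gene_counts, sep="\t", index_col="gene_id")
    elif ref is not None:
        gene_counts = syn.simulate_gene_counts(
            ref.truth, design, depth=config.depth * 2,
            dispersion=config.dispersion / 2, seed=config.seed + 3,
        )
    else:
        gene_counts = matrix.gene_totals()
    de = expr.de_test(gene_counts, design, fc_cut=config.fc_cut,
                      fdr_cut=config.fdr_cut)
    de.table.to_csv(path_of("de_table.tsv"), sep="\t", index_label="gene_id")
    bundle["de"] = de

    coupling = expr.apa_expression_coupling(utr3.events, de.table)
    coupling.summary.to_csv(path_of("coupling_utr3.tsv"), sep="\t")
    coupling_i = expr.apa_expression_coupling(intronic.events, de.table)
    coupling_i.summary.to_csv(path_of("coupling_intronic.tsv"), sep="\t")
    bundle["coupling"] = coupling

    # --- consequences ----------------------------------------------------
    if sites is not None and len(sites):
        mir = cons.removed_mirna_sites(utr3.events, sites)
        mir.features.to_csv(path_of("mirna_sites.tsv"), sep="\t", index=False)
        bundle["mirna"] = mir
    if domains is not None and len(domains) and models is not None:
        dom = cons.removed_domains(intronic.events, domains, models)
        dom.features.to_csv(path_of("domains.tsv"), sep="\t", index=False)
        bundle["domains"] = dom
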