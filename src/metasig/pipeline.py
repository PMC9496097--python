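"""End-to-end orchestration: simulate -> profile -> diversity -> annotate ->
quantify -> signatures -> statistics -> report.

A single :class:`PipelineConfig` (YAML-loadable) fixes every threshold and
seed; rerunning the same config reproduces every table byte for byte. Each
stage logs its filter counts (reads classified, ORFs annotated, contigs
discarded, pairs prevalence-filtered) so the audit trail is inspectable, and
a manifest records all parameters used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import CatalogSearcher, annotate_orfs, find_orfs
from .catalog import Catalog, load_catalog
from .diversity import bray_curtis, permanova, shannon
from .profiling import aggregate_matrix, build_index, profile_matrix
from .quantify import count_matrix, gene_level, map_reads, normalize, tmm_factors
from .signatures import (assign_contig_taxon, audit_table, build_signatures,
                         log_ratio_matrix)
from .simulate import CohortBundle, CohortDesign, generate_cohort, synthetic_catalog
from .stats import compare_features, correlate_severity, mann_whitney

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds, seeds and stage toggles for one pipeline run."""
    design: CohortDesign
    catalog: Catalog | None = None
    # classification
    read_confidence: float = 0.5
    contig_confidence: float = 0.01
    read_k: int = 31
    contig_k: int = 21
    # annotation
    identity_min: float = 60.0
    coverage_min: float = 90.0
    min_orf_nt: int = 150
    # quantification
    map_k: int = 15
    # signatures
    fallback_identity_min: float = 90.0
    # testing
    min_prevalence: float = 0.5
    alpha: float = 0.05
    # stage toggles
    run_profiling: bool = True
    run_diversity: bool = True
    run_functional: bool = True
    run_signatures: bool = True
    run_correlations: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design_raw = raw.pop("design", {})
        if "species" not in design_raw:
            raise ValueError("config must provide design.species")
        if "planted_gene_effects" in design_raw:
            design_raw["planted_gene_effects"] = {
                (k.split(";")[0], k.split(";")[1]): v
                for k, v in design_raw["planted_gene_effects"].items()}
        if "contig_length_range" in design_raw:
            design_raw["contig_length_range"] = tuple(design_raw["contig_length_range"])
        design = CohortDesign(**design_raw)
        catalog = None
        cat_raw = raw.pop("catalog", None)
        if isinstance(cat_raw, dict) and "fasta" in cat_raw:
            catalog = load_catalog(cat_raw["fasta"], cat_raw["metadata"])
        elif isinstance(cat_raw, dict):
            catalog = synthetic_catalog(**cat_raw)
        return cls(design=design, catalog=catalog, **raw)

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("catalog", None)
        design = d.pop("design")
        design["planted_gene_effects"] = {
            f"{sp};{eid}": v for (sp, eid), v in design["planted_gene_effects"].items()}
        return {"metasig_version": __version__, "design": design, **d}


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: CohortBundle
    metadata: pd.DataFrame
    profiles: dict[str, pd.DataFrame] = field(default_factory=dict)
    shannon: pd.DataFrame | None = None
    alpha_tests: pd.DataFrame | None = None
    permanova: pd.DataFrame | None = None
    taxa_stats: dict[str, pd.DataFrame] = field(default_factory=dict)
    annotations: list = field(default_factory=list)
    orf_counts: pd.DataFrame | None = None
    tmm: object = None
    orf_abundance: pd.DataFrame | None = None
    gene_abundance: pd.DataFrame | None = None
    gene_stats: pd.DataFrame | None = None
    contig_audit: pd.DataFrame | None = None
    signatures: dict[str, object] = field(default_factory=dict)
    pair_stats: dict[str, pd.DataFrame] = field(default_factory=dict)
    logratio: dict[str, pd.DataFrame] = field(default_factory=dict)
    severity: pd.DataFrame | None = None


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute the configured stages in order and optionally write all tables."""
    rng_seeds = np.random.SeedSequence(config.seed).spawn(4)
    sim_seed, perm_seed_sp, perm_seed_ge, _ = (
        int(s.generate_state(1)[0] % (2 ** 31)) for s in rng_seeds)
    catalog = config.catalog if config.catalog is not None else synthetic_catalog()
    design = dataclasses.replace(config.design, seed=sim_seed)
    logger.info("stage=simulate n_control=%d n_case=%d species=%d",
                design.n_control, design.n_case, len(design.species))
    cohort = generate_cohort(design, catalog)
    result = PipelineResult(config, cohort, cohort.metadata)
    labels = result.metadata["group"]

    read_index = build_index(cohort.genomes, cohort.taxonomy, k=config.read_k)

    if config.run_profiling:
        reads_by_sample = {s.sample_id: s.reads for s in cohort.samples}
        species_profile = profile_matrix(reads_by_sample, read_index,
                                         config.read_confidence)
        result.profiles["species"] = species_profile
        for rank in ("genus", "phylum"):
            result.profiles[rank] = aggregate_matrix(species_profile,
                                                     cohort.taxonomy, rank)
        logger.info("stage=profile species_detected=%d", species_profile.shape[0])
        for rank, prof in result.profiles.items():
            result.taxa_stats[rank] = compare_features(
                prof, labels, min_prevalence=config.min_prevalence,
                alpha=config.alpha)

    if config.run_diversity and "species" in result.profiles:
        rows, tests, perm_rows = {}, [], []
        for rank, seed in (("species", perm_seed_sp), ("genus", perm_seed_ge)):
            prof = result.profiles[rank]
            rows[rank] = prof.apply(lambda c: shannon(c.to_numpy()), axis=0)
            hc = rows[rank][labels == "HC"].to_numpy()
            pwd = rows[rank][labels == "PwD"].to_numpy()
            u, p = mann_whitney(pwd, hc)
            tests.append({"level": rank, "U": u, "p": p})
            pr = permanova(bray_curtis(prof), labels, n_permutations=999, seed=seed)
            perm_rows.append({"level": rank, "pseudo_F": pr.pseudo_F,
                              "p": pr.p_value, "n_permutations": pr.n_permutations})
        result.shannon = pd.DataFrame(rows)
        result.alpha_tests = pd.DataFrame(tests).set_index("level")
        result.permanova = pd.DataFrame(perm_rows).set_index("level")

    if config.run_functional:
        searcher = CatalogSearcher(catalog)
        annotations = []
        orf_seqs: dict[str, str] = {}
        for sample in cohort.samples:
            for contig_id, seq in sample.contigs:
                orfs = find_orfs(contig_id, seq, config.min_orf_nt)
                for orf in orfs:
                    orf_seqs[orf.orf_id] = orf.nt_sequence
                annotations.extend(annotate_orfs(orfs, catalog, config.identity_min,
                                                 config.coverage_min, searcher))
        result.annotations = annotations
        logger.info("stage=annotate orfs=%d annotated=%d", len(orf_seqs),
                    len(annotations))
        from .quantify import build_orf_kmer_index
        orf_index = build_orf_kmer_index(orf_seqs, config.map_k)
        per_sample, lib = {}, {}
        for sample in cohort.samples:
            counts, stats_ = map_reads(sample.reads, orf_seqs, config.map_k,
                                       index=orf_index)
            per_sample[sample.sample_id] = counts
            lib[sample.sample_id] = stats_.total
        result.orf_counts = count_matrix(per_sample, lib)
        result.tmm = tmm_factors(result.orf_counts)
        result.orf_abundance = normalize(result.orf_counts, result.tmm)
        orf_to_enzyme = {a.orf_id: a.enzyme_name for a in annotations}
        result.gene_abundance = gene_level(result.orf_abundance, orf_to_enzyme)
        if not result.gene_abundance.empty:
            result.gene_stats = compare_features(
                result.gene_abundance, labels,
                min_prevalence=config.min_prevalence, alpha=config.alpha)

    if config.run_signatures and result.annotations:
        contig_index = build_index(cohort.genomes, cohort.taxonomy, k=config.contig_k)
        contig_seqs = {cid: seq for s in cohort.samples for cid, seq in s.contigs}
        contig_taxa = {}
        for contig_id in sorted({a.contig_id for a in result.annotations}):
            contig_taxa[contig_id] = assign_contig_taxon(
                contig_id, contig_seqs[contig_id], contig_index, cohort.genomes,
                config.contig_confidence, config.fallback_identity_min)
        result.contig_audit = audit_table(contig_taxa)
        n_discarded = (result.contig_audit["route"] == "discarded").sum()
        logger.info("stage=signatures contigs=%d discarded=%d",
                    len(contig_taxa), int(n_discarded))
        for level in ("genus", "species"):
            table = build_signatures(result.annotations, contig_taxa,
                                     result.orf_abundance, level,
                                     config.min_prevalence)
            result.signatures[level] = table
            result.logratio[level] = log_ratio_matrix(table, labels)
            if not table.abundance.empty:
                flat = table.abundance.copy()
                flat.index = [f"{t}; {g}" for t, g in flat.index]
                result.pair_stats[level] = compare_features(
                    flat, labels, min_prevalence=config.min_prevalence,
                    alpha=config.alpha)

    if config.run_correlations and "species" in result.signatures:
        table = result.signatures["species"].abundance
        if not table.empty:
            result.severity = correlate_severity(
                table, result.metadata[["CES-D", "GAD-7", "HAMD-17"]],
                alpha=config.alpha)

    if outdir is not None:
        write_result(result, outdir)
    return result


def write_result(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def tsv(df, name):
        if df is None:
            return
        df.to_csv(out / name, sep="\t")

    tsv(result.metadata, "metadata.tsv")
    for rank, prof in result.profiles.items():
        tsv(prof, f"profiles_{rank}.tsv")
    tsv(result.shannon, "shannon.tsv")
    tsv(result.alpha_tests, "alpha_tests.tsv")
    tsv(result.permanova, "permanova.tsv")
    for rank, st in result.taxa_stats.items():
        tsv(st, f"taxa_stats_{rank}.tsv")
    tsv(result.orf_counts, "orf_counts.tsv")
    if result.tmm is not None:
        tsv(result.tmm.factors.rename("tmm_factor").to_frame(), "tmm_factors.tsv")
    tsv(result.orf_abundance, "orf_abundance.tsv")
    tsv(result.gene_abundance, "gene_abundance.tsv")
    tsv(result.gene_stats, "gene_stats.tsv")
    tsv(result.contig_audit, "contig_audit.tsv")
    for level, table in result.signatures.items():
        tsv(table.abundance, f"signatures_{level}.tsv")
        tsv(result.logratio.get(level), f"logratio_{level}.tsv")
    for level, st in result.pair_stats.items():
        tsv(st, f"pair_stats_{level}.tsv")
    if result.severity is not None:
        result.severity.to_csv(out / "severity_correlations.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.config.manifest(), fh, indent=2, sort_keys=True)


def summarize_report(result: PipelineResult,
                     min_median_abundance: float = 0.5) -> dict[str, pd.DataFrame]:
    """Display tables: per-level group medians in percent, filtered for display.

    Taxa (and pairs) whose median relative abundance stays at or below
    ``min_median_abundance`` percent in both groups are omitted from the
    display tables only; the statistics in ``taxa_stats`` are computed on the
    full prevalence-filtered families.
    """
    labels = result.metadata["group"]
    report = {}
    for rank, prof in result.profiles.items():
        pct = prof * 100.0
        med_hc = pct.loc[:, labels == "HC"].median(axis=1)
        med_pwd = pct.loc[:, labels == "PwD"].median(axis=1)
        table = pd.DataFrame({"median_HC_pct": med_hc, "median_PwD_pct": med_pwd})
        table = table[(table > min_median_abundance).any(axis=1)]
        stats = result.taxa_stats.get(rank)
        if stats is not None and not stats.empty:
            table = table.join(stats[["p", "q", "significant"]], how="left")
        report[rank] = table.sort_values("median_HC_pct", ascending=False)
    return report
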