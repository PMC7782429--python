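"""End-to-end orchestration: TPM → differential → markers → community →
pathways → ecology, with TSV outputs and a reproducibility manifest.

All stages are the library functions from the sibling modules; this module
only chains them, moves tables on and off disk, and records what happened.
Re-running with identical inputs, parameters and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import __version__
from . import io as nio
from .abundance import AbundanceMatrix, DiffResult, compute_tpm, differential_abundance
from .community import (
    BinRecord,
    aggregate_species,
    bins_from_frame,
    extract_marker_community,
    filter_bins,
    marker_coverage_fraction,
    partition_populations,
    community_table,
)
from .ecology import cca, envfit_all, shannon, simpson, summarize_fermentation
from .markers import MarkerCatalog, cluster_nr, default_marker_catalog, find_marker_genes
from .pathways import (
    PathwayDef,
    compare_populations,
    completeness_table,
    default_pathway_definitions,
    enrich_all,
    load_pathway_definitions,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_core", "write_bundle"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and options of a pipeline run."""

    counts: str = ""
    sample_sheet: str = ""
    ko_map: str = ""
    scaffolds: str = ""
    bins: str = ""
    env: str = ""
    sequences: str = ""
    catalog_manifest: str = ""
    pathway_defs: str = ""
    out_dir: str = "results"

    alpha: float = 0.05
    min_completeness: float = 60.0
    max_contamination: float = 10.0
    max_heterogeneity: float = 10.0
    marker_identity: float = 0.85
    marker_coverage: float = 0.90
    nr_identity: float = 0.90
    nr_coverage: float = 0.90
    peg_counting: str = "peg"          # "peg" | "ko"
    completeness_units: str = "percent"  # bin metrics on disk are percentages
    simpson_variant: str = "gini"
    n_perm: int = 999
    seed: int = 0
    env_constraints: tuple[str, ...] = ("ammonia_mM", "ni_uM", "pH")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = nio.load_yaml(path)
        cfg = cls(**data)
        if "env_constraints" in data:
            cfg.env_constraints = tuple(data["env_constraints"])
        return cfg

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class PipelineResult:
    gene_tpm: AbundanceMatrix
    gene_diff: DiffResult
    ko_diff: DiffResult
    nr_members: dict[str, str]
    marker_hits: list
    qc_bins: list
    aggregates: list
    marker_community: list
    species_diff: DiffResult | None
    populations: dict[str, str]
    community: pd.DataFrame
    completeness_records: pd.DataFrame
    population_comparison: pd.DataFrame
    enrichment: pd.DataFrame
    diversity: pd.DataFrame
    marker_coverage: pd.DataFrame
    ordination: object
    envfit_results: pd.DataFrame
    fermentation: pd.DataFrame
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def _diversity_table(
    species_abundance: pd.DataFrame,
    groups: pd.Series,
    label: str,
    simpson_variant: str,
) -> pd.DataFrame:
    rows = []
    for sample in species_abundance.columns:
        vec = species_abundance[sample].to_numpy(float)
        rows.append(
            {
                "community": label,
                "sample": sample,
                "group": groups[sample],
                "shannon": shannon(vec),
                "simpson": simpson(vec, variant=simpson_variant),
            }
        )
    return pd.DataFrame(rows)


def run_core(
    gene_counts: pd.DataFrame,
    gene_lengths: pd.Series,
    ko_map: Mapping[str, str],
    groups: pd.Series,
    scaffold_genes: Mapping[str, Sequence[str]],
    bins: Sequence[BinRecord],
    env_table: pd.DataFrame | None,
    sequences: Mapping[str, str],
    catalog: MarkerCatalog | None = None,
    pathway_defs: Sequence[PathwayDef] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every analysis stage on in-memory inputs."""
    cfg = config or PipelineConfig()
    catalog = catalog or default_marker_catalog()
    defs = list(pathway_defs or default_pathway_definitions())
    counters: dict[str, int] = {}

    # --- abundance ---------------------------------------------------------
    gene_tpm = _stage("tpm")(compute_tpm)(gene_counts, gene_lengths, groups)
    gene_diff = _stage("differential")(differential_abundance)(gene_tpm, alpha=cfg.alpha)

    ko_series = pd.Series({g: ko_map.get(g) for g in gene_counts.index})
    ko_values = gene_tpm.values.groupby(ko_series).sum()
    ko_matrix = AbundanceMatrix(
        ko_values, pd.Series(1.0, index=ko_values.index), groups, kind="count"
    )
    ko_diff = _stage("differential")(differential_abundance)(ko_matrix, alpha=cfg.alpha)
    counters["genes"] = len(gene_counts)
    counters["kos"] = len(ko_values)

    # --- marker genes ------------------------------------------------------
    @_stage("markers")
    def _markers():
        reps, members = cluster_nr(sequences, cfg.nr_identity, cfg.nr_coverage)
        ko_sub = {g: ko_map[g] for g in reps if g in ko_map}
        hits = find_marker_genes(
            reps, ko_sub, catalog, cfg.marker_identity, cfg.marker_coverage
        )
        return reps, members, hits

    reps, nr_members, marker_hits = _markers()
    counters["nr_representatives"] = len(reps)
    counters["marker_hits"] = len(marker_hits)

    # --- community ---------------------------------------------------------
    @_stage("community")
    def _community():
        scaffold_counts = pd.DataFrame(
            {
                sc: gene_counts.loc[list(g)].sum(axis=0)
                for sc, g in scaffold_genes.items()
            }
        ).T
        scaffold_lengths = pd.Series(
            {
                sc: float(gene_lengths.loc[list(g)].sum())
                for sc, g in scaffold_genes.items()
            }
        )
        scaffold_tpm = compute_tpm(scaffold_counts, scaffold_lengths, groups)
        qc = filter_bins(
            bins, cfg.min_completeness, cfg.max_contamination, cfg.max_heterogeneity
        )
        aggregates = aggregate_species(qc, scaffold_genes, ko_map, scaffold_tpm.values)
        gene_scaffold = {g: sc for sc, gl in scaffold_genes.items() for g in gl}
        marker_community = extract_marker_community(aggregates, marker_hits, gene_scaffold)
        return qc, aggregates, marker_community, gene_scaffold

    qc_bins, aggregates, marker_community, gene_scaffold = _community()
    counters["bins_in"] = len(bins)
    counters["bins_qc"] = len(qc_bins)
    counters["species"] = len(aggregates)
    counters["marker_species"] = len(marker_community)

    species_diff = None
    populations: dict[str, str] = {}
    community_df = pd.DataFrame()
    if aggregates:
        species_abundance = pd.DataFrame(
            {a.species: a.abundance for a in aggregates}
        ).T
        species_matrix = AbundanceMatrix(
            species_abundance,
            pd.Series(1.0, index=species_abundance.index),
            groups,
            kind="count",
        )
        species_diff = _stage("differential")(differential_abundance)(
            species_matrix, alpha=cfg.alpha
        )
        if marker_community:
            populations = partition_populations(
                marker_community, species_diff, cfg.alpha
            )
            community_df = community_table(
                marker_community, species_diff, populations, groups
            )
    else:
        species_abundance = pd.DataFrame(columns=gene_counts.columns)

    # --- pathways ----------------------------------------------------------
    @_stage("pathways")
    def _pathways():
        records = completeness_table(
            {a.species: a.ko_set for a in marker_community},
            {a.species: a.avg_completeness / 100.0 for a in marker_community},
            defs,
            count=cfg.peg_counting,
        )
        comparison = (
            compare_populations(records, populations)
            if populations
            else pd.DataFrame()
        )
        enrichment = enrich_all(ko_diff, defs)
        return records, comparison, enrichment

    records, comparison, enrichment = _pathways()

    # --- ecology -----------------------------------------------------------
    @_stage("ecology")
    def _ecology():
        div = _diversity_table(
            species_abundance, groups, "all_species", cfg.simpson_variant
        ) if len(aggregates) else pd.DataFrame()
        if marker_community:
            marker_abundance = pd.DataFrame(
                {a.species: a.abundance for a in marker_community}
            ).T
            div = pd.concat(
                [
                    div,
                    _diversity_table(
                        marker_abundance, groups, "marker_community",
                        cfg.simpson_variant,
                    ),
                ],
                ignore_index=True,
            )
        coverage_rows = []
        for enzyme in sorted({h.enzyme for h in marker_hits}):
            frac, (lo, hi) = marker_coverage_fraction(
                marker_hits, qc_bins, gene_tpm.values, gene_scaffold, enzyme
            )
            coverage_rows.append(
                {"enzyme": enzyme, "min_fraction": lo, "max_fraction": hi}
            )
        coverage = pd.DataFrame(coverage_rows)
        ordination = None
        envfit_df = pd.DataFrame()
        ferm = pd.DataFrame()
        if env_table is not None and len(aggregates) >= 1:
            constraints = env_table[list(cfg.env_constraints)]
            ordination = cca(species_abundance.T, constraints)
            if not ordination.site_scores.empty:
                numeric = env_table.drop(columns=["group"], errors="ignore")
                envfit_df = envfit_all(
                    ordination.site_scores, numeric,
                    n_perm=cfg.n_perm, seed=cfg.seed,
                )
            ferm = summarize_fermentation(env_table)
        return div, coverage, ordination, envfit_df, ferm

    diversity, coverage, ordination, envfit_df, ferm = _ecology()

    manifest = {
        "package": "nicomm",
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": cfg.digest(),
        "counts": counters,
    }
    return PipelineResult(
        gene_tpm, gene_diff, ko_diff, nr_members, marker_hits, qc_bins,
        aggregates, marker_community, species_diff, populations, community_df,
        records, comparison, enrichment, diversity, coverage, ordination,
        envfit_df, ferm, manifest,
    )


def run_from_bundle(bundle, config: PipelineConfig | None = None, **kwargs) -> PipelineResult:
    """Convenience wrapper running the pipeline on a synthetic bundle."""
    return run_core(
        bundle.gene_counts,
        bundle.gene_lengths,
        bundle.ko_map,
        bundle.truth.group_design,
        bundle.scaffold_genes,
        bundle.bin_table,
        bundle.env_table,
        bundle.sequences,
        config=config,
        **kwargs,
    )


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    """Write every result table as TSV plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref, treat = result.gene_diff.reference, result.gene_diff.treatment
    diff_cols = [f"mean_{ref}", f"mean_{treat}", "log2fc", "p", "q", "direction"]
    nio.write_table(
        out / "gene_differential.tsv",
        result.gene_diff.table[diff_cols].rename_axis("feature_id").reset_index(),
    )
    nio.write_table(
        out / "ko_differential.tsv",
        result.ko_diff.table[diff_cols].rename_axis("feature_id").reset_index(),
    )
    from .markers import write_marker_hits

    write_marker_hits(out / "marker_hits.tsv", result.marker_hits)
    nio.write_table(out / "community.tsv", result.community)
    nio.write_table(out / "pathway_completeness.tsv", result.completeness_records)
    nio.write_table(out / "population_comparison.tsv", result.population_comparison)
    nio.write_table(out / "enrichment.tsv", result.enrichment)
    nio.write_table(out / "diversity.tsv", result.diversity)
    nio.write_table(out / "marker_coverage.tsv", result.marker_coverage)
    nio.write_table(out / "envfit.tsv", result.envfit_results)
    nio.write_table(
        out / "fermentation_summary.tsv", result.fermentation.reset_index()
    )
    if result.ordination is not None and not result.ordination.site_scores.empty:
        nio.write_table(
            out / "cca_site_scores.tsv",
            result.ordination.site_scores.rename_axis("sample").reset_index(),
        )
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load the configured inputs, run every stage, write the result bundle."""
    counts, lengths = nio.read_counts(config.counts)
    groups = nio.read_sample_sheet(config.sample_sheet)
    ko_df = nio.read_table(config.ko_map, required=["gene_id", "ko"])
    ko_map = dict(zip(ko_df["gene_id"], ko_df["ko"]))
    scaff_df = nio.read_table(config.scaffolds, required=["scaffold_id", "genes"])
    scaffold_genes = {
        r.scaffold_id: tuple(str(r.genes).split(";")) for r in scaff_df.itertuples()
    }
    bins = bins_from_frame(nio.read_bin_table(config.bins))
    env = nio.read_env_table(config.env) if config.env else None
    sequences = nio.read_fasta(config.sequences) if config.sequences else {}
    catalog = (
        MarkerCatalog.from_manifest(config.catalog_manifest)
        if config.catalog_manifest
        else None
    )
    defs = (
        load_pathway_definitions(config.pathway_defs)
        if config.pathway_defs
        else None
    )
    result = run_core(
        counts, lengths, ko_map, groups, scaffold_genes, bins, env, sequences,
        catalog=catalog, pathway_defs=defs, config=config,
    )
    write_results(result, config.out_dir)
    return result


def write_bundle(bundle, out_dir: str | Path) -> PipelineConfig:
    """Write a synthetic bundle as the TSV/FASTA inputs the pipeline reads,
    returning a ready-to-run PipelineConfig."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = bundle.gene_counts.copy()
    counts.insert(0, "length", bundle.gene_lengths)
    nio.write_table(
        out / "gene_counts.tsv", counts.rename_axis("feature_id").reset_index()
    )
    nio.write_table(
        out / "samples.tsv",
        bundle.truth.group_design.rename_axis("sample_id").rename("group").reset_index(),
    )
    nio.write_table(
        out / "ko_map.tsv",
        bundle.gene_table[["gene_id", "ko"]],
    )
    scaff = bundle.scaffold_table.copy()
    scaff["genes"] = scaff["genes"].map(";".join)
    nio.write_table(out / "scaffolds.tsv", scaff[["scaffold_id", "genes"]])
    bins_df = pd.DataFrame(
        [
            {
                "bin_id": b.bin_id,
                "scaffold_ids": b.scaffolds,
                "completeness": b.completeness,
                "contamination": b.contamination,
                "strain_heterogeneity": b.strain_heterogeneity,
                "species": b.species,
            }
            for b in bundle.bin_table
        ]
    )
    nio.write_bin_table(out / "bins.tsv", bins_df)
    if bundle.env_table is not None:
        nio.write_table(out / "env.tsv", bundle.env_table.reset_index())
    nio.write_fasta(out / "genes.fasta", bundle.sequences)
    catalog_path = default_marker_catalog().to_manifest(out / "catalog")
    return PipelineConfig(
        counts=str(out / "gene_counts.tsv"),
        sample_sheet=str(out / "samples.tsv"),
        ko_map=str(out / "ko_map.tsv"),
        scaffolds=str(out / "scaffolds.tsv"),
        bins=str(out / "bins.tsv"),
        env=str(out / "env.tsv") if bundle.env_table is not None else "",
        sequences=str(out / "genes.fasta"),
        catalog_manifest=str(catalog_path),
        out_dir=str(out / "results"),
        seed=bundle.truth.seed,
    )
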