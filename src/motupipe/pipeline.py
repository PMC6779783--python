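"""End-to-end orchestration: simulate -> cluster -> profile -> taxonomy ->
core -> stratification, with deterministic seeds throughout.

`run_synthetic_pipeline` is the one-call version used by the analysis
drivers, the smoke tests and the acceptance script; each stage is also
reachable individually through the stage modules.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster, diversity, io, profile, simulate, stats, taxonomy
from .config import DEFAULT_CONFIG, PipelineConfig


@dataclass
class PipelineResult:
    design: simulate.CommunityDesign
    genes: list
    truth: simulate.TruthTable
    catalog: cluster.MOTUCatalog
    layers: dict  # unique_counts / insert_count / coverage / relative_abundance
    rarefied: pd.DataFrame
    core: diversity.CoreSet
    taxonomy_table: pd.DataFrame
    clades: pd.Series
    clade_summary: pd.DataFrame
    profiles: list = field(default_factory=list)
    attribution: pd.DataFrame | None = None

    @property
    def motu_of_population(self) -> pd.Series:
        """Planted population -> recovered mOTU (via the first variant)."""
        g2m = self.catalog.gene_to_motu
        out = {}
        for gid, pid in self.truth.gene_to_population.items():
            out.setdefault(pid, g2m.get(gid))
        return pd.Series(out)


def run_synthetic_pipeline(
    design: simulate.CommunityDesign,
    seed: int = 0,
    config: PipelineConfig = DEFAULT_CONFIG,
    error_rate: float = 0.0,
    gene_length: int = 1095,
    between_population_divergence: float = 0.15,
    rarefy_target: int | str = "auto",
    apply_coverage_filter: bool = True,
    taxonomy_dropout_clade: float = 0.0,
    taxonomy_dropout_all: float = 0.0,
) -> PipelineResult:
    """Run the full marker-gene pipeline on a synthetic community design."""
    genes, truth = simulate.catalog_for_design(
        design,
        gene_length=gene_length,
        between_population_divergence=between_population_divergence,
        seed=seed,
        identity_cutoff=config.identity_cutoff,
    )
    catalog = cluster.cluster_genes(genes, config)

    gene_lengths = {g.id: g.length for g in genes}
    sample_frames = (
        s.records
        for s in simulate.simulate_alignments(
            design, genes, truth, error_rate=error_rate, seed=seed
        )
    )
    layers = profile.profile_sample_stream(
        sample_frames, catalog, gene_lengths, config
    )
    if apply_coverage_filter:
        catalog = cluster.filter_low_abundance(
            catalog, layers["coverage"], config.min_avg_coverage
        )
        active = sorted(catalog.active)
        layers = {
            name: m.loc[[x for x in m.index if x in catalog.active]]
            for name, m in layers.items()
        }
        layers["relative_abundance"] = profile.relative_abundance(
            layers["insert_count"]
        )

    rarefied = diversity.rarefy_matrix(
        layers["unique_counts"], target=rarefy_target, seed=config.rarefaction_seed
    )
    core = diversity.core_set(
        rarefied, design.sample_metadata, layers["relative_abundance"]
    )

    hits = simulate.simulate_best_hits(
        design,
        truth,
        dropout_clade=taxonomy_dropout_clade,
        dropout_all=taxonomy_dropout_all,
        seed=seed,
    )
    ranks = ("domain", "phylum", "clade")
    tax = taxonomy.assign_catalog(catalog, hits, ranks=ranks)
    tax = tax.loc[[m for m in tax.index if m in catalog.active]]
    clades = taxonomy.clade_labels(tax)

    summary = diversity.clade_summaries(
        core, clades, layers["relative_abundance"], rarefied, design.sample_metadata
    )
    profiles = stats.depth_of_max(
        layers["relative_abundance"], design.sample_metadata
    )
    attribution = stats.depth_attribution(
        profiles, layers["relative_abundance"], design.sample_metadata
    )
    return PipelineResult(
        design=design,
        genes=genes,
        truth=truth,
        catalog=catalog,
        layers=layers,
        rarefied=rarefied,
        core=core,
        taxonomy_table=tax,
        clades=clades,
        clade_summary=summary,
        profiles=profiles,
        attribution=attribution,
    )


def write_result(result: PipelineResult, outdir: str) -> list[str]:
    """Write the pipeline outputs as deterministic text files; returns the
    paths written."""
    os.makedirs(outdir, exist_ok=True)
    paths = []

    def p(name):
        paths.append(os.path.join(outdir, name))
        return paths[-1]

    io.write_genes_fasta(result.genes, p("genes.fasta"))
    io.write_catalog_tsv(result.catalog, p("motu_catalog.tsv"))
    for name in ("unique_counts", "insert_count", "coverage", "relative_abundance"):
        io.write_matrix_tsv(result.layers[name], p(f"{name}.tsv"))
    io.write_matrix_tsv(result.rarefied, p("rarefied_counts.tsv"))
    io.write_metadata_tsv(result.design.sample_metadata, p("samples.tsv"))
    core_rows = [
        {"depth": d, "motu_id": m}
        for d in sorted(result.core.core)
        for m in sorted(result.core.core[d])
    ]
    pd.DataFrame(core_rows, columns=["depth", "motu_id"]).to_csv(
        p("core_motus.tsv"), sep="\t", index=False
    )
    result.taxonomy_table.to_csv(p("taxonomy.tsv"), sep="\t")
    result.clade_summary.to_csv(p("clade_summary.tsv"), sep="\t", index=False)
    if result.attribution is not None:
        io.write_matrix_tsv(result.attribution, p("depth_attribution.tsv"))
    return paths
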