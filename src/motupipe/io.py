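"""Readers and writers for the pipeline's on-disk formats.

Genes travel as FASTA (Biopython), alignment records as SAM (pysam; AS:i
score and NM:i edit-distance tags) or as a flat TSV dialect with columns
``insert_id, mate, gene_id, aln_len, n_matches, identity, score,
sample_id`` (plus ``is_partial`` and ``pos``), matrices and metadata as
TSV, and community designs as YAML.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cluster import MOTUCatalog
from .simulate import CommunityDesign, MarkerGene, RECORD_COLUMNS

TSV_DIALECT_COLUMNS = [
    "insert_id",
    "mate",
    "gene_id",
    "aln_len",
    "n_matches",
    "identity",
    "score",
    "sample_id",
    "is_partial",
    "pos",
]


# -- FASTA -------------------------------------------------------------------


def read_genes_fasta(path: str) -> list[MarkerGene]:
    return [
        MarkerGene(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]


def write_genes_fasta(genes: Iterable[MarkerGene], path: str) -> None:
    records = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genes]
    SeqIO.write(records, path, "fasta")


# -- alignment records -------------------------------------------------------


def write_records_tsv(records: pd.DataFrame, path: str) -> None:
    df = records.copy()
    df = df.rename(columns={"aligned_length": "aln_len"})
    cols = [c for c in TSV_DIALECT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_records_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"aln_len": "aligned_length"})
    if "is_partial" not in df.columns:
        df["is_partial"] = False
    df["is_partial"] = df["is_partial"].astype(bool)
    return df


def write_records_sam(
    records: pd.DataFrame,
    genes: Sequence[MarkerGene],
    path: str,
    read_length: int | None = None,
) -> None:
    """Write alignment records as SAM with AS:i and NM:i tags.

    Each record becomes one line; mate flags are set for paired records.
    Mismatch-only alignments are assumed (CIGAR ``<aln_len>M``); the sample
    id travels in the RG tag (one @RG per sample).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": g.id, "LN": g.length} for g in genes],
        "RG": [
            {"ID": str(s)} for s in pd.unique(records["sample_id"])
        ],
    }
    tid = {g.id: i for i, g in enumerate(genes)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for row in records.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = str(row.insert_id)
            a.reference_id = tid[row.gene_id]
            a.reference_start = int(getattr(row, "pos", 0))
            L = int(row.aligned_length)
            a.cigarstring = f"{L}M"
            a.query_sequence = "N" * L
            a.mapping_quality = 255
            flag = 0
            if row.mate in (1, 2):
                flag |= 1  # paired
                flag |= 64 if row.mate == 1 else 128
            a.flag = flag
            nm = L - int(row.n_matches)
            a.set_tag("AS", int(row.score))
            a.set_tag("NM", nm)
            a.set_tag("RG", str(row.sample_id))
            out.write(a)


def read_records_sam(path: str) -> pd.DataFrame:
    """Parse SAM alignments into the record frame.

    Identity derives from NM over the aligned length (CIGAR M/=/X/I
    columns), the score from AS:i, and the sample from the RG tag.  An
    alignment is partial when its aligned length is shorter than the read.
    """
    rows = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as f:
        for a in f:
            if a.is_unmapped:
                continue
            aln_len = sum(
                n for op, n in (a.cigartuples or []) if op in (0, 1, 7, 8)
            )
            nm = int(a.get_tag("NM")) if a.has_tag("NM") else 0
            read_len = a.query_length or aln_len
            mate = 2 if a.is_read2 else 1
            rows.append(
                {
                    "insert_id": a.query_name,
                    "mate": mate,
                    "gene_id": a.reference_name,
                    "aligned_length": aln_len,
                    "n_matches": aln_len - nm,
                    "identity": (aln_len - nm) / aln_len if aln_len else 0.0,
                    "score": int(a.get_tag("AS")) if a.has_tag("AS") else aln_len - nm,
                    "sample_id": a.get_tag("RG") if a.has_tag("RG") else "sample1",
                    "is_partial": aln_len < read_len,
                    "pos": a.reference_start,
                }
            )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


# -- catalogs, matrices, metadata -------------------------------------------


def write_catalog_tsv(catalog: MOTUCatalog, path: str) -> None:
    rows = []
    for motu, members in sorted(catalog.members.items()):
        rep = catalog.representatives.get(motu)
        for g in members:
            rows.append(
                {
                    "gene_id": g,
                    "motu_id": motu,
                    "is_representative": int(g == rep),
                    "removed": catalog.removed.get(motu, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: str) -> MOTUCatalog:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    members: dict[str, list[str]] = {}
    reps: dict[str, str] = {}
    removed: dict[str, str] = {}
    for row in df.itertuples(index=False):
        members.setdefault(row.motu_id, []).append(row.gene_id)
        if row.is_representative:
            reps[row.motu_id] = row.gene_id
        if row.removed:
            removed[row.motu_id] = row.removed
    return MOTUCatalog(members=members, representatives=reps, removed=removed)


def write_matrix_tsv(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "motu_id")


def read_matrix_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata_tsv(metadata: pd.DataFrame, path: str) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- designs -----------------------------------------------------------------


def write_design_yaml(design: CommunityDesign, path: str) -> None:
    doc = {
        "depths": list(design.depths),
        "timepoints": [str(t) for t in design.timepoints],
        "insert_depth_per_sample": design.insert_depth_per_sample,
        "seed": design.seed,
        "populations": [
            {
                "population_id": p.population_id,
                "is_core_at": sorted(p.is_core_at),
                "peak_depth": p.peak_depth,
                "mean_abundance_profile": {
                    str(k): float(v) for k, v in p.mean_abundance_profile.items()
                },
                "temporal_occupancy": {
                    str(k): float(v) for k, v in p.temporal_occupancy.items()
                },
                "n_gene_variants": p.n_gene_variants,
                "intra_population_divergence": p.intra_population_divergence,
                "clade": p.clade,
                "phylum": p.phylum,
            }
            for p in design.populations
        ],
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def write_truth_tsv(truth_frame: pd.DataFrame, path: str) -> None:
    truth_frame.to_csv(path, sep="\t", index=False)
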