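"""Insert-level abundance estimation from filtered read alignments.

The counting unit is the insert (a read pair, or a single read).  Alignments
are filtered on identity and aligned length, each insert is resolved to its
highest-scoring target gene(s) — summing mate scores only when both mates
hit the same gene — and inserts whose best score is shared by genes of more
than one mOTU are flagged as multiple mappers.  Unique inserts are counted
first; multiple mappers are then redistributed proportionally to the unique
count profile in a single second pass (no iterative reassignment).

Alignment record streams are pandas DataFrames with the columns of
:data:`motupipe.simulate.RECORD_COLUMNS` (``pos`` optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import MOTUCatalog
from .config import DEFAULT_CONFIG, PipelineConfig

_REQUIRED = [
    "insert_id",
    "mate",
    "gene_id",
    "aligned_length",
    "n_matches",
    "identity",
    "score",
    "sample_id",
    "is_partial",
]


@dataclass
class InsertAssignments:
    """Per-insert resolution to candidate mOTUs.

    ``table`` has one row per (sample_id, insert_id, motu_id) candidate plus
    a ``status`` column (``unique`` or ``multi``); unique inserts have
    exactly one row, multiple mappers one row per candidate mOTU.
    """

    table: pd.DataFrame

    @property
    def unique(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "unique"]

    @property
    def multi(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "multi"]


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"malformed alignment records: missing columns {missing}")
    if len(records):
        bad = records["n_matches"] > records["aligned_length"]
        if bad.any():
            raise ValueError(
                f"malformed alignment records: n_matches > aligned_length in "
                f"{int(bad.sum())} rows (first: "
                f"{records.loc[bad.idxmax()].to_dict()})"
            )
        err = (
            records["identity"]
            - records["n_matches"] / records["aligned_length"]
        ).abs()
        if (err > 1e-9).any():
            i = err.idxmax()
            raise ValueError(
                f"malformed alignment record: identity inconsistent with "
                f"n_matches/aligned_length at row {i}: {records.loc[i].to_dict()}"
            )


def filter_alignments(
    records: pd.DataFrame,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Apply the mapping filters, preserving record order.

    A record is kept iff identity >= ``min_mapping_identity`` and aligned
    length >= ``min_alignment_length``; partial alignments (not spanning the
    whole read) must instead reach ``min_partial_alignment_length``.
    """
    _check_records(records)
    if not len(records):
        return records.copy()
    min_len = np.where(
        records["is_partial"].to_numpy(dtype=bool),
        config.min_partial_alignment_length,
        config.min_alignment_length,
    )
    keep = (records["identity"].to_numpy() >= config.min_mapping_identity) & (
        records["aligned_length"].to_numpy() >= min_len
    )
    return records[keep].copy()


def resolve_inserts(
    records: pd.DataFrame,
    catalog: MOTUCatalog,
) -> InsertAssignments:
    """Resolve each insert to its best-scoring mOTU candidate set.

    Per insert and target gene, the insert score is the sum of both mates'
    scores when both aligned to that gene, else the single mate's score.
    The genes attaining the maximal insert score define the candidate mOTU
    set; candidates spanning genes of a single mOTU make the insert unique
    at mOTU level, several mOTUs make it a multiple mapper.
    """
    gene_to_motu = catalog.gene_to_motu
    unknown = set(records["gene_id"].unique()) - set(gene_to_motu)
    if unknown:
        raise ValueError(f"alignment records reference unknown genes: {sorted(unknown)[:5]}")
    if not len(records):
        return InsertAssignments(
            pd.DataFrame(columns=["sample_id", "insert_id", "motu_id", "status"])
        )
    per_gene = (
        records.groupby(["sample_id", "insert_id", "gene_id"], sort=False)["score"]
        .sum()
        .reset_index()
    )
    best = per_gene.groupby(["sample_id", "insert_id"], sort=False)["score"].transform(
        "max"
    )
    winners = per_gene[per_gene["score"] == best].copy()
    winners["motu_id"] = winners["gene_id"].map(gene_to_motu)
    cand = winners.drop_duplicates(["sample_id", "insert_id", "motu_id"])[
        ["sample_id", "insert_id", "motu_id"]
    ].copy()
    n_motus = cand.groupby(["sample_id", "insert_id"], sort=False)[
        "motu_id"
    ].transform("size")
    cand["status"] = np.where(n_motus == 1, "unique", "multi")
    return InsertAssignments(cand.reset_index(drop=True))


def count_unique(assignments: InsertAssignments) -> pd.DataFrame:
    """Integer mOTU x sample matrix of uniquely assigned inserts."""
    u = assignments.unique
    if not len(u):
        return pd.DataFrame(dtype=int)
    counts = (
        u.groupby(["motu_id", "sample_id"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    counts.index.name = "motu_id"
    return counts


def redistribute_multimappers(
    unique_counts: pd.DataFrame,
    assignments: InsertAssignments,
) -> pd.DataFrame:
    """Distribute each multiple mapper over its candidate mOTUs
    proportionally to the unique-count profile of its own sample; candidates
    with all-zero unique counts split the insert equally.  Per-sample totals
    are conserved exactly: sum(final) = sum(unique) + number of multi
    inserts."""
    multi = assignments.multi
    final = unique_counts.astype(float).copy()
    if not len(multi):
        return final
    samples = sorted(set(multi["sample_id"]) | set(final.columns))
    motus = final.index.union(pd.Index(multi["motu_id"].unique()))
    final = final.reindex(index=motus, columns=samples, fill_value=0).astype(float)
    m = multi.copy()
    m["u"] = [
        float(final.at[mo, s]) for mo, s in zip(m["motu_id"], m["sample_id"])
    ]
    tot = m.groupby(["sample_id", "insert_id"], sort=False)["u"].transform("sum")
    size = m.groupby(["sample_id", "insert_id"], sort=False)["u"].transform("size")
    m["w"] = np.where(tot > 0, m["u"] / tot.replace(0, np.nan), 1.0 / size)
    add = m.groupby(["motu_id", "sample_id"], sort=True)["w"].sum()
    for (mo, s), w in add.items():
        final.at[mo, s] += w
    final.index.name = "motu_id"
    return final


def compute_coverage(
    records: pd.DataFrame,
    gene_lengths: dict[str, int] | pd.Series,
    catalog: MOTUCatalog,
    weights: pd.Series | None = None,
) -> pd.DataFrame:
    """mOTU x sample coverage from the aligned bases of counted records.

    Per gene, coverage is total aligned bases divided by gene length; per
    mOTU it is the length-weighted mean over member genes (total member
    bases / total member length).  ``weights`` optionally scales each
    record's base contribution (used to spread multi-mapper bases by their
    redistribution fractions).
    """
    lengths = pd.Series(gene_lengths, dtype=float)
    if (lengths <= 0).any():
        bad = lengths[lengths <= 0].index.tolist()
        raise ValueError(f"non-positive gene lengths: {bad}")
    gene_to_motu = catalog.gene_to_motu
    df = records.copy()
    bases = df["aligned_length"].astype(float)
    if weights is not None:
        bases = bases * weights.reindex(df.index).fillna(0.0)
    df["bases"] = bases
    per_gene = df.groupby(["gene_id", "sample_id"], sort=True)["bases"].sum().unstack(
        fill_value=0.0
    )
    rows = {}
    for motu, mem in catalog.members.items():
        present = [g for g in mem if g in per_gene.index]
        total_len = lengths.reindex(mem).sum()
        if present:
            rows[motu] = per_gene.loc[present].sum(axis=0) / total_len
        else:
            rows[motu] = pd.Series(0.0, index=per_gene.columns)
    cov = pd.DataFrame(rows).T
    cov.index.name = "motu_id"
    return cov


def relative_abundance(final_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances: each mOTU's insert count divided by
    the sample's total mapped inserts.  All-zero samples stay all-zero (with
    a warning), not an error.  Rows are mOTUs, columns samples."""
    totals = final_counts.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        import warnings

        warnings.warn(f"samples with no mapped inserts left all-zero: {zero}")
    safe = totals.replace(0, np.nan)
    rel = final_counts.div(safe, axis=1).fillna(0.0)
    rel.index.name = "motu_id"
    return rel


def winning_records(
    records: pd.DataFrame, assignments: InsertAssignments, catalog: MOTUCatalog
) -> tuple[pd.DataFrame, pd.Series]:
    """Select the records of counted (best-scoring) alignments, with a
    per-record weight: 1 for unique inserts, the redistribution fraction
    structure for multi inserts (equal split across candidate mOTUs' genes
    is **not** applied here; weights are per candidate mOTU as resolved
    later).  Returns (records subset, weight series aligned to it)."""
    if not len(records):
        return records.copy(), pd.Series(dtype=float)
    gene_to_motu = catalog.gene_to_motu
    per_gene = (
        records.groupby(["sample_id", "insert_id", "gene_id"], sort=False)["score"]
        .sum()
        .reset_index()
    )
    best = per_gene.groupby(["sample_id", "insert_id"], sort=False)["score"].transform(
        "max"
    )
    winners = per_gene[per_gene["score"] == best][
        ["sample_id", "insert_id", "gene_id"]
    ].copy()
    winners["motu_id"] = winners["gene_id"].map(gene_to_motu)
    # an insert's weight on a candidate mOTU (1 if unique, 1/n_cand if
    # multi) is split evenly over that mOTU's tied winner genes so bases
    # are conserved per insert
    n_genes = winners.groupby(["sample_id", "insert_id", "motu_id"])[
        "gene_id"
    ].transform("size")
    n_cand = (
        assignments.table.groupby(["sample_id", "insert_id"])["motu_id"]
        .size()
        .rename("n_cand")
    )
    winners = winners.join(n_cand, on=["sample_id", "insert_id"])
    winners["weight"] = 1.0 / (winners["n_cand"] * n_genes)
    keyed = records.merge(
        winners[["sample_id", "insert_id", "gene_id", "weight"]],
        on=["sample_id", "insert_id", "gene_id"],
        how="inner",
    )
    return keyed, keyed["weight"]


def profile_sample_stream(
    sample_frames,
    catalog: MOTUCatalog,
    gene_lengths: dict[str, int] | pd.Series,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, pd.DataFrame]:
    """Run filter -> resolve -> count -> redistribute -> coverage over an
    iterable of per-sample record DataFrames, concatenating the per-sample
    results into mOTU x sample matrices.

    Returns a dict with layers ``unique_counts``, ``insert_count``,
    ``coverage`` and ``relative_abundance``.
    """
    uniq_cols, final_cols, cov_cols = {}, {}, {}
    for records in sample_frames:
        if not len(records):
            continue
        sample_id = records["sample_id"].iloc[0]
        kept = filter_alignments(records, config)
        assignments = resolve_inserts(kept, catalog)
        uniq = count_unique(assignments)
        final = redistribute_multimappers(uniq, assignments)
        counted, weights = winning_records(kept, assignments, catalog)
        cov = compute_coverage(counted, gene_lengths, catalog, weights=weights)
        uniq_cols[sample_id] = uniq.get(sample_id, pd.Series(dtype=int))
        final_cols[sample_id] = final.get(sample_id, pd.Series(dtype=float))
        cov_cols[sample_id] = cov.get(sample_id, pd.Series(dtype=float))
    motus = pd.Index(sorted(catalog.members), name="motu_id")
    unique_counts = pd.DataFrame(uniq_cols).reindex(motus).fillna(0).astype(int)
    insert_count = pd.DataFrame(final_cols).reindex(motus).fillna(0.0)
    coverage = pd.DataFrame(cov_cols).reindex(motus).fillna(0.0)
    return {
        "unique_counts": unique_counts,
        "insert_count": insert_count,
        "coverage": coverage,
        "relative_abundance": relative_abundance(insert_count),
    }
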