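"""mOTU taxonomy by strict-majority vote over member-gene best hits.

Each member gene carries the labels of its single best reference hit at a
set of ordered ranks; an mOTU gets the label held by a strict majority
(>50%) of its members that have any label at that rank.  Ties or missing
majorities yield "unassigned", and deeper ranks are truncated at the first
unassigned rank so assignments stay hierarchy-consistent.  mOTUs with a
phylum but no deeper annotation and mOTUs with no annotation at all mirror
the two grey display categories (phylum-only / unannotated).
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .cluster import MOTUCatalog

UNASSIGNED = "unassigned"
DEFAULT_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def majority_assignment(labels: Sequence[str | None]) -> str:
    """Label held by a strict majority of the labelled members, else
    ``unassigned``.  Members without a label at this rank are excluded from
    the denominator; an empty member set is an error."""
    if not len(labels):
        raise ValueError("empty member set")
    present = [l for l in labels if l is not None and l == l and l != ""]
    if not present:
        return UNASSIGNED
    counts = pd.Series(present).value_counts()
    top = counts.iloc[0]
    if top * 2 > len(present) and (counts == top).sum() == 1:
        return str(counts.index[0])
    return UNASSIGNED


def assign_catalog(
    catalog: MOTUCatalog,
    hits: pd.DataFrame,
    ranks: Sequence[str] = DEFAULT_RANKS,
) -> pd.DataFrame:
    """Majority taxonomy per mOTU at every rank.

    ``hits`` is a long table (gene_id, rank, label, score); only each
    gene's best-scoring hit per rank is used.  Returns a mOTU x rank table
    of labels, truncated to ``unassigned`` below the first unassigned rank.
    """
    if len(hits):
        best = (
            hits.sort_values("score", ascending=False)
            .drop_duplicates(["gene_id", "rank"])
            .set_index(["gene_id", "rank"])["label"]
        )
    else:
        best = pd.Series(dtype=object)
    rows = {}
    for motu, members in catalog.members.items():
        row = {}
        blocked = False
        for rank in ranks:
            if blocked:
                row[rank] = UNASSIGNED
                continue
            labels = [best.get((g, rank)) for g in members]
            label = majority_assignment(labels)
            row[rank] = label
            if label == UNASSIGNED:
                blocked = True
        rows[motu] = row
    table = pd.DataFrame.from_dict(rows, orient="index")[list(ranks)]
    table.index.name = "motu_id"
    return table


def clade_labels(
    taxonomy: pd.DataFrame,
    clade_rank: str = "clade",
    phylum_rank: str = "phylum",
) -> pd.Series:
    """Display clade per mOTU: its clade label, else ``phylum-only`` when
    only the phylum is known, else ``unannotated``."""
    if clade_rank in taxonomy.columns:
        clade = taxonomy[clade_rank].copy()
    else:
        clade = pd.Series(UNASSIGNED, index=taxonomy.index)
    phylum = (
        taxonomy[phylum_rank]
        if phylum_rank in taxonomy.columns
        else pd.Series(UNASSIGNED, index=taxonomy.index)
    )
    out = clade.where(clade != UNASSIGNED, other=None)
    out = out.fillna(
        phylum.map(lambda p: "phylum-only" if p != UNASSIGNED else "unannotated")
    )
    out.name = "clade"
    return out
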