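#!/usr/bin/env python
"""Assign each mOTU a taxonomy by strict majority over member-gene best
hits, and map mOTUs to display clades (named clade / phylum-only /
unannotated)."""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

import pandas as pd

from motupipe.io import read_catalog_tsv
from motupipe.taxonomy import assign_catalog, clade_labels

SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch", "pipeline")
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    catalog = read_catalog_tsv(os.path.join(SCRATCH, "motu_catalog.tsv"))
    hits = pd.read_csv(os.path.join(SCRATCH, "best_hits.tsv"), sep="\t")
    table = assign_catalog(catalog, hits, ranks=("domain", "phylum", "clade"))
    table = table.loc[sorted(catalog.active)]
    table.to_csv(os.path.join(SCRATCH, "taxonomy.tsv"), sep="\t")
    labels = clade_labels(table)
    labels.rename_axis("motu_id").reset_index().to_csv(
        os.path.join(SCRATCH, "clades.tsv"), sep="\t", index=False
    )
    breakdown = (
        labels.value_counts().rename_axis("clade").rename("n_motus").reset_index()
    )
    breakdown.to_csv(os.path.join(RESULTS, "clade_breakdown.tsv"), sep="\t", index=False)
    print(breakdown.to_string(index=False))
    grey = labels.isin(["phylum-only", "unannotated"]).mean()
    print(f"fraction of mOTUs without a clade-level assignment: {grey:.3f}")


if __name__ == "__main__":
    main()
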