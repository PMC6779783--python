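import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from motupipe import generate_design, generate_gene_catalog
from motupipe.pipeline import run_synthetic_pipeline

SEVEN_DEPTHS = [25.0, 75.0, 125.0, 200.0, 500.0, 770.0, 1000.0]


def make_records(rows):
    """Build an alignment-record frame from (insert, mate, gene, aln_len,
    n_matches, score, sample, partial) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "insert_id",
            "mate",
            "gene_id",
            "aligned_length",
            "n_matches",
            "score",
            "sample_id",
            "is_partial",
        ],
    )
    df["identity"] = df["n_matches"] / df["aligned_length"]
    return df


@pytest.fixture(scope="session")
def small_community():
    """3 depths x 4 timepoints, 3 core + 8 ephemeral per depth, 3000
    inserts: a fast planted community exercised by several test modules."""
    design = generate_design(
        3,
        8,
        [25.0, 200.0, 1000.0],
        [f"t{i}" for i in range(4)],
        core_abundance_fraction=0.7,
        seed=11,
        insert_depth_per_sample=3000,
    )
    result = run_synthetic_pipeline(design, seed=11)
    return design, result


@pytest.fixture(scope="session")
def planted_catalog():
    """10 populations x 3 variants straddling the clustering cutoff."""
    genes, truth = generate_gene_catalog(
        10,
        3,
        gene_length=1095,
        between_population_divergence=0.15,
        within_population_divergence=0.02,
        seed=7,
    )
    return genes, truth
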