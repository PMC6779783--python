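"""Marker-gene mOTU clustering.

Genes are clustered into near-species-level mOTUs by average-linkage
(UPGMA) agglomeration on pairwise nucleotide-identity distances, cut at a
fixed identity (default 94.8%).  Identity is computed from a global
pairwise alignment: matching columns divided by all alignment columns,
gaps included.  Pairs whose alignment spans fewer than ``min_aligned_bases``
columns are masked and treated as maximally distant, so the distance matrix
stays complete.

The agglomeration is written out by hand rather than delegated to a library
because mOTU partitions must be bit-for-bit reproducible: when two merge
candidates are exactly tied, the pair whose lexicographically smallest
member id is least (then the smaller partner) is merged first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .simulate import MarkerGene

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_VALID = set("ACGTN")


@dataclass
class IdentityMatrix:
    """Symmetric pairwise nucleotide-identity matrix over a gene set.

    ``values[i, j]`` is the identity in [0, 1]; ``masked[i, j]`` flags pairs
    whose alignment failed the minimum-aligned-bases rule (their identity is
    stored as 0, i.e. maximal distance).
    """

    ids: list[str]
    values: np.ndarray
    masked: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("identity matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("identity matrix diagonal must be 1")

    def distances(self) -> np.ndarray:
        return 1.0 - self.values


@dataclass
class MOTUCatalog:
    """Partition of genes into mOTUs, with filter flags and representatives.

    Filtering removes whole clusters, never members: removed clusters stay
    in ``members`` with a reason in ``removed`` so the partition over all
    input genes is preserved.
    """

    members: dict[str, list[str]]  # motu_id -> ordered member gene ids
    representatives: dict[str, str] = field(default_factory=dict)
    removed: dict[str, str] = field(default_factory=dict)  # motu_id -> reason

    @property
    def active(self) -> dict[str, list[str]]:
        return {m: g for m, g in self.members.items() if m not in self.removed}

    @property
    def gene_to_motu(self) -> dict[str, str]:
        return {g: m for m, genes in self.members.items() for g in genes}

    def __len__(self) -> int:
        return len(self.active)


def pairwise_identity(
    gene_a: MarkerGene | str,
    gene_b: MarkerGene | str,
    min_aligned_bases: int = DEFAULT_CONFIG.min_aligned_bases,
) -> float:
    """Global-alignment nucleotide identity, or NaN when masked.

    Identity is matches / alignment columns of a Needleman-Wunsch alignment
    (gap columns count in the denominator).  Returns NaN when the alignment
    spans fewer than ``min_aligned_bases`` columns.
    """
    a = gene_a.seq if isinstance(gene_a, MarkerGene) else gene_a
    b = gene_b.seq if isinstance(gene_b, MarkerGene) else gene_b
    for name, s in (("first", a), ("second", b)):
        if not s:
            raise ValueError(f"{name} sequence is empty")
        bad = set(s.upper()) - _VALID
        if bad:
            raise ValueError(f"{name} sequence has invalid characters {sorted(bad)}")
    return _identity_core(a.upper(), b.upper(), min_aligned_bases)


def _identity_core(a: str, b: str, min_aligned_bases: int) -> float:
    # canonical argument order: edlib's optimal path (and hence the column
    # count) can differ between directions, so order the pair to make the
    # identity exactly symmetric
    if (len(b), b) < (len(a), a):
        a, b = b, a
    res = edlib.align(a, b, task="path", mode="NW")
    matches = columns = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    if columns < min_aligned_bases:
        return float("nan")
    return matches / columns


def build_identity_matrix(
    genes: Sequence[MarkerGene],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> IdentityMatrix:
    """All-vs-all pairwise identities for a gene catalog."""
    ids = [g.id for g in genes]
    if len(ids) < 2:
        raise ValueError("need at least 2 genes")
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate gene ids: {dupes}")
    n = len(genes)
    seqs = []
    for g in genes:
        s = g.seq.upper()
        if not s:
            raise ValueError(f"gene {g.id} has an empty sequence")
        bad = set(s) - _VALID
        if bad:
            raise ValueError(f"gene {g.id} has invalid characters {sorted(bad)}")
        seqs.append(s)
    values = np.eye(n)
    masked = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            ident = _identity_core(seqs[i], seqs[j], config.min_aligned_bases)
            if np.isnan(ident):
                masked[i, j] = masked[j, i] = True
                ident = 0.0
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(ids=ids, values=values, masked=masked)


def _tie_key(members_a: list[str], members_b: list[str]) -> tuple[str, str]:
    lo_a, lo_b = min(members_a), min(members_b)
    return (min(lo_a, lo_b), max(lo_a, lo_b))


#: Distances within this tolerance are treated as exactly tied, and the cut
#: threshold is applied with the same slack; this keeps the partition
#: invariant to float summation order (Lance-Williams updates vs direct
#: means over gene pairs agree only up to rounding).
MERGE_EPS = 1e-12


def average_linkage_cluster(
    matrix: IdentityMatrix,
    identity_cutoff: float = DEFAULT_CONFIG.identity_cutoff,
) -> MOTUCatalog:
    """UPGMA agglomeration cut at ``1 - identity_cutoff`` distance.

    Clusters are merged while any two have average pairwise distance at or
    below the cutoff distance; the average is the arithmetic mean over all
    cross-cluster gene pairs (maintained by the Lance-Williams size-weighted
    update).  Candidate merges whose distances agree within ``MERGE_EPS``
    are ordered by the lexicographically smallest member ids, making the
    partition fully deterministic.
    """
    threshold = 1.0 - identity_cutoff
    n = len(matrix.ids)
    dist = matrix.distances().astype(float).copy()
    np.fill_diagonal(dist, np.inf)
    clusters: dict[int, list[str]] = {i: [matrix.ids[i]] for i in range(n)}
    sizes = np.ones(n)
    alive = np.ones(n, dtype=bool)
    while alive.sum() > 1:
        dmin = dist.min()
        if dmin > threshold + MERGE_EPS:
            break
        ii, jj = np.nonzero(dist <= dmin + MERGE_EPS)
        pairs = [(int(a), int(b)) for a, b in zip(ii, jj) if a < b]
        i, j = min(pairs, key=lambda p: _tie_key(clusters[p[0]], clusters[p[1]]))
        ni, nj = sizes[i], sizes[j]
        merged_row = (ni * dist[i] + nj * dist[j]) / (ni + nj)
        dist[i] = merged_row
        dist[:, i] = merged_row
        dist[i, i] = np.inf
        dist[j, :] = np.inf
        dist[:, j] = np.inf
        clusters[i] = sorted(clusters[i] + clusters[j])
        sizes[i] = ni + nj
        alive[j] = False
        del clusters[j]
    ordered = sorted((min(m), m) for m in clusters.values())
    members = {f"motu{k + 1:05d}": mem for k, (_, mem) in enumerate(ordered)}
    return MOTUCatalog(members=members)


def filter_low_abundance(
    catalog: MOTUCatalog,
    coverage: pd.DataFrame,
    min_avg_coverage: float = DEFAULT_CONFIG.min_avg_coverage,
) -> MOTUCatalog:
    """Flag mOTUs whose mean per-sample coverage is ``min_avg_coverage`` or
    less as removed (strict "or less": mean exactly at the threshold is
    removed).  The mean is over all samples in ``coverage``'s columns."""
    removed = dict(catalog.removed)
    for motu in catalog.members:
        if motu in removed:
            continue
        if motu not in coverage.index:
            raise ValueError(f"no coverage row for mOTU {motu}")
        if float(coverage.loc[motu].mean()) <= min_avg_coverage:
            removed[motu] = "low_abundance_removed"
    return MOTUCatalog(
        members=dict(catalog.members),
        representatives=dict(catalog.representatives),
        removed=removed,
    )


def curate_singletons(
    catalog: MOTUCatalog,
    genes: Iterable[MarkerGene],
    max_length_deviation: float = 0.30,
) -> MOTUCatalog:
    """Optional proxy for manual curation of aberrant singleton mOTUs.

    Removes singleton clusters whose gene length deviates from the catalog
    median gene length by more than ``max_length_deviation`` (fractional).
    Off by default in the pipeline; manual curation is not reproducible, so
    this mechanical rule is explicit and opt-in.
    """
    lengths = {g.id: g.length for g in genes}
    median = float(np.median(list(lengths.values())))
    removed = dict(catalog.removed)
    for motu, mem in catalog.members.items():
        if motu in removed or len(mem) != 1:
            continue
        if abs(lengths[mem[0]] - median) / median > max_length_deviation:
            removed[motu] = "singleton_removed"
    return MOTUCatalog(
        members=dict(catalog.members),
        representatives=dict(catalog.representatives),
        removed=removed,
    )


def select_representatives(
    catalog: MOTUCatalog,
    genes: Iterable[MarkerGene],
) -> MOTUCatalog:
    """Pick each mOTU's longest member gene as its representative; equal
    lengths break toward the lexicographically smaller gene id."""
    lengths = {g.id: g.length for g in genes}
    reps = {}
    for motu, mem in catalog.members.items():
        missing = [g for g in mem if g not in lengths]
        if missing:
            raise ValueError(f"mOTU {motu} members missing from gene set: {missing}")
        reps[motu] = min(mem, key=lambda g: (-lengths[g], g))
    return MOTUCatalog(
        members=dict(catalog.members),
        representatives=reps,
        removed=dict(catalog.removed),
    )


def cluster_genes(
    genes: Sequence[MarkerGene],
    config: PipelineConfig = DEFAULT_CONFIG,
    curate: bool = False,
) -> MOTUCatalog:
    """Convenience: identity matrix -> UPGMA -> representatives."""
    matrix = build_identity_matrix(genes, config)
    catalog = average_linkage_cluster(matrix, config.identity_cutoff)
    if curate:
        catalog = curate_singletons(catalog, genes)
    return select_representatives(catalog, genes)
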