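"""Synthetic depth-stratified marker-gene communities with full ground truth.

The generator emulates the structure of an open-ocean time-series metagenome
survey reduced to a single universal marker gene: a handful of clades, each
containing many near-identical gene variants; a small set of temporally
persistent, high-abundance "core" populations per depth; a long tail of
ephemeral low-abundance variants; strongly depth-localised abundance
profiles; and paired-read (insert) sampling with substitution sequencing
error.  Every stage of the downstream pipeline can therefore be tested
against planted truth without any external data or aligner.

The mutation model is substitution-only, so percent identities are exact
arithmetic on planted difference positions, and all variants of one
population fall into one mOTU by construction whenever the intra-population
divergence is kept below the clustering cutoff distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Marine clade -> phylum pairs used to label synthetic populations.
DEFAULT_CLADES: tuple[tuple[str, str], ...] = (
    ("SAR11", "Proteobacteria"),
    ("Prochlorococcus", "Cyanobacteria"),
    ("SAR324", "Proteobacteria"),
    ("SAR86", "Proteobacteria"),
    ("Nitrosopelagicus", "Thaumarchaeota"),
    ("SAR202", "Chloroflexi"),
    ("MGII", "Euryarchaeota"),
    ("Flavobacteriaceae", "Bacteroidetes"),
)

RECORD_COLUMNS = [
    "insert_id",
    "mate",
    "gene_id",
    "aligned_length",
    "n_matches",
    "identity",
    "score",
    "sample_id",
    "is_partial",
    "pos",
]


@dataclass(frozen=True)
class MarkerGene:
    """One marker-gene nucleotide sequence."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class PopulationSpec:
    """One planted population: a set of near-identical gene variants with a
    depth-localised abundance profile."""

    population_id: str
    is_core_at: frozenset
    peak_depth: float
    mean_abundance_profile: dict  # depth -> nonnegative raw weight
    temporal_occupancy: dict  # depth -> fraction of timepoints present
    n_gene_variants: int
    intra_population_divergence: float
    clade: str = ""
    phylum: str = ""

    def __post_init__(self) -> None:
        if self.n_gene_variants < 1:
            raise ValueError("n_gene_variants must be >= 1")
        for d in self.is_core_at:
            if self.temporal_occupancy.get(d, 1.0) != 1.0:
                raise ValueError(
                    f"population {self.population_id} is core at depth {d} "
                    "but has temporal occupancy < 1 there"
                )


@dataclass
class CommunityDesign:
    """Realised depth x time community: per-sample true relative abundances.

    ``true_abundance`` is a population x sample DataFrame whose columns sum
    to 1; ``sample_metadata`` maps sample ids to (depth, timepoint).
    """

    depths: list
    timepoints: list
    populations: list  # of PopulationSpec
    insert_depth_per_sample: int
    seed: int
    sample_metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    true_abundance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.depths) < 2 or len(self.timepoints) < 2:
            raise ValueError("a community design needs >= 2 depths and >= 2 timepoints")
        if self.insert_depth_per_sample <= 0:
            raise ValueError("insert_depth_per_sample must be positive")
        if len(self.true_abundance):
            sums = self.true_abundance.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("per-sample true abundances must sum to 1")

    @property
    def core_populations(self) -> dict:
        """depth -> list of population ids planted as core at that depth."""
        out: dict = {d: [] for d in self.depths}
        for p in self.populations:
            for d in p.is_core_at:
                out[d].append(p.population_id)
        return out


@dataclass
class TruthTable:
    """Planted ground truth accumulated across the generation stages."""

    gene_to_population: pd.Series  # index gene_id -> population_id
    true_abundance: pd.DataFrame | None = None  # population x sample
    insert_sources: pd.DataFrame | None = None  # sample_id, insert_id, gene_id
    gene_taxonomy: pd.DataFrame | None = None  # gene_id, rank, label, score


@dataclass
class SampleAlignments:
    """Alignment records and per-insert truth for one sample."""

    sample_id: str
    records: pd.DataFrame
    insert_sources: pd.DataFrame  # insert_id, gene_id


# ---------------------------------------------------------------------------
# gene catalogs


def _mutate(seq: np.ndarray, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute ``n_sites`` distinct positions, always to a different base."""
    out = seq.copy()
    if n_sites == 0:
        return out
    pos = rng.choice(len(seq), size=n_sites, replace=False)
    shift = rng.integers(1, 4, size=n_sites).astype(np.uint8)
    out[pos] = (out[pos] + shift) % 4
    return out


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


_ASCII_TO_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ASCII_TO_CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    """ACGT string -> 0..3 codes."""
    return _ASCII_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def generate_gene_catalog(
    n_populations: int,
    variants_per_population: int | tuple[int, int] | Sequence[int],
    gene_length: int = 1095,
    between_population_divergence: float = 0.15,
    within_population_divergence: float = 0.02,
    seed: int = 0,
    identity_cutoff: float = 0.948,
    population_ids: Sequence[str] | None = None,
) -> tuple[list[MarkerGene], TruthTable]:
    """Generate a star-phylogeny catalog of marker-gene variants.

    Each population descends from a common root mutated at
    ``between_population_divergence / 2`` of its sites, so two populations
    differ by ~``between_population_divergence`` in expectation; each variant
    mutates its population ancestor at ``within_population_divergence`` of
    sites, so variants differ pairwise by at most twice that.

    ``variants_per_population`` may be a single count, an inclusive
    ``(low, high)`` range sampled per population, or an explicit per-
    population sequence.
    """
    if gene_length < 100:
        raise ValueError(f"gene_length must be >= 100, got {gene_length}")
    if not (
        within_population_divergence
        < 1.0 - identity_cutoff
        <= between_population_divergence
    ):
        raise ValueError(
            "divergence ordering violated: need within_population_divergence "
            f"({within_population_divergence}) < 1 - identity_cutoff "
            f"({1.0 - identity_cutoff:.4f}) <= between_population_divergence "
            f"({between_population_divergence})"
        )
    rng = np.random.default_rng(seed)
    if isinstance(variants_per_population, int):
        n_variants = [variants_per_population] * n_populations
    elif (
        isinstance(variants_per_population, tuple)
        and len(variants_per_population) == 2
        and all(isinstance(v, int) for v in variants_per_population)
        and len(variants_per_population) != n_populations
    ):
        lo, hi = variants_per_population
        n_variants = rng.integers(lo, hi + 1, size=n_populations).tolist()
    else:
        n_variants = list(variants_per_population)
        if len(n_variants) != n_populations:
            raise ValueError("per-population variant counts must match n_populations")
    if population_ids is None:
        population_ids = [f"pop{i + 1:04d}" for i in range(n_populations)]

    root = rng.integers(0, 4, size=gene_length).astype(np.uint8)
    n_between = int(round(between_population_divergence / 2.0 * gene_length))
    n_within = int(round(within_population_divergence * gene_length))

    genes: list[MarkerGene] = []
    gene_pop: dict[str, str] = {}
    for pid, k in zip(population_ids, n_variants):
        ancestor = _mutate(root, n_between, rng)
        for j in range(k):
            variant = _mutate(ancestor, n_within, rng)
            gid = f"{pid}.v{j + 1:02d}"
            genes.append(MarkerGene(gid, _decode(variant)))
            gene_pop[gid] = pid
    truth = TruthTable(gene_to_population=pd.Series(gene_pop, name="population_id"))
    return genes, truth


# ---------------------------------------------------------------------------
# community designs


def generate_design(
    n_core_per_depth: int,
    n_ephemeral_per_depth: int,
    depths: Sequence,
    timepoints: Sequence,
    core_abundance_fraction: float = 0.7,
    seed: int = 0,
    ephemeral_occupancy: float = 0.5,
    insert_depth_per_sample: int = 50_000,
    depth_leak: float = 1e-5,
    variants_per_population: int | tuple[int, int] = (1, 3),
    within_population_divergence: float = 0.02,
    abundance_jitter_sigma: float = 0.5,
    clades: Sequence[tuple[str, str]] = DEFAULT_CLADES,
) -> CommunityDesign:
    """Plant a depth x time community with persistent core populations.

    At each depth, ``n_core_per_depth`` populations are planted as core
    (present at every timepoint) and jointly hold exactly
    ``core_abundance_fraction`` of that depth's abundance in every sample;
    ``n_ephemeral_per_depth`` ephemeral populations share the remainder and
    are each present at only ``ephemeral_occupancy`` of timepoints.  Every
    population peaks at its home depth, decaying by ``depth_leak`` per
    stratum on either side, so planted populations are effectively
    depth-exclusive at realistic sequencing depths.
    """
    if not depths or not timepoints:
        raise ValueError("design error: depths and timepoints must be non-empty")
    if not 0.0 < core_abundance_fraction <= 1.0:
        raise ValueError("core_abundance_fraction must be in (0, 1]")
    if n_core_per_depth < 0 or n_ephemeral_per_depth < 0:
        raise ValueError("population counts must be >= 0")
    depths = list(depths)
    timepoints = list(timepoints)
    rng = np.random.default_rng(seed)
    depth_index = {d: i for i, d in enumerate(depths)}

    if isinstance(variants_per_population, int):
        draw_variants = lambda: variants_per_population  # noqa: E731
    else:
        lo, hi = variants_per_population
        draw_variants = lambda: int(rng.integers(lo, hi + 1))  # noqa: E731

    populations: list[PopulationSpec] = []
    counter = itertools.count(1)
    for d in depths:
        for kind, n, core in (
            ("core", n_core_per_depth, True),
            ("eph", n_ephemeral_per_depth, False),
        ):
            for _ in range(n):
                pid = f"{kind}{next(counter):04d}_d{depth_index[d]}"
                base = float(rng.lognormal(0.0, 0.75 if core else 1.0))
                profile = {
                    d2: base * depth_leak ** abs(depth_index[d2] - depth_index[d])
                    for d2 in depths
                }
                occupancy = {
                    d2: 1.0 if core else ephemeral_occupancy for d2 in depths
                }
                clade, phylum = clades[int(rng.integers(len(clades)))]
                populations.append(
                    PopulationSpec(
                        population_id=pid,
                        is_core_at=frozenset([d]) if core else frozenset(),
                        peak_depth=d,
                        mean_abundance_profile=profile,
                        temporal_occupancy=occupancy,
                        n_gene_variants=draw_variants(),
                        intra_population_divergence=within_population_divergence,
                        clade=clade,
                        phylum=phylum,
                    )
                )

    design = CommunityDesign(
        depths=depths,
        timepoints=timepoints,
        populations=populations,
        insert_depth_per_sample=insert_depth_per_sample,
        seed=seed,
    )
    _realize_abundances(design, rng, core_abundance_fraction, abundance_jitter_sigma)
    return design


def _realize_abundances(
    design: CommunityDesign,
    rng: np.random.Generator,
    core_fraction: float,
    jitter_sigma: float,
) -> None:
    """Draw per-sample true abundances.

    Log-normal jitter is applied around each population's depth profile,
    then the core block (populations planted as core at the sample's depth)
    is renormalised to exactly ``core_fraction`` and everything else to the
    remainder, so the planted core abundance fraction is a sharp per-sample
    ground truth rather than a noisy expectation.
    """
    pops = design.populations
    pids = [p.population_id for p in pops]
    meta_rows = []
    cols = {}
    for d in design.depths:
        is_core = np.array([d in p.is_core_at for p in pops])
        profile = np.array([p.mean_abundance_profile.get(d, 0.0) for p in pops])
        occupancy = np.array([p.temporal_occupancy.get(d, 1.0) for p in pops])
        for t_i, t in enumerate(design.timepoints):
            sample_id = f"S_d{design.depths.index(d)}_t{t_i}"
            present = rng.random(len(pops)) < occupancy
            raw = profile * rng.lognormal(0.0, jitter_sigma, size=len(pops)) * present
            v = np.zeros(len(pops))
            core_sum = raw[is_core].sum()
            rest_sum = raw[~is_core].sum()
            if core_sum > 0 and rest_sum > 0:
                v[is_core] = raw[is_core] / core_sum * core_fraction
                v[~is_core] = raw[~is_core] / rest_sum * (1.0 - core_fraction)
            elif core_sum > 0:
                v[is_core] = raw[is_core] / core_sum
            elif rest_sum > 0:
                v[~is_core] = raw[~is_core] / rest_sum
            else:
                raise ValueError(f"sample {sample_id} has no abundance at all")
            cols[sample_id] = v
            meta_rows.append({"sample_id": sample_id, "depth": d, "timepoint": t})
    design.true_abundance = pd.DataFrame(cols, index=pd.Index(pids, name="population_id"))
    design.sample_metadata = pd.DataFrame(meta_rows)


def catalog_for_design(
    design: CommunityDesign,
    gene_length: int = 1095,
    between_population_divergence: float = 0.15,
    seed: int | None = None,
    identity_cutoff: float = 0.948,
) -> tuple[list[MarkerGene], TruthTable]:
    """Generate the marker-gene catalog matching a design's populations."""
    pops = design.populations
    genes, truth = generate_gene_catalog(
        n_populations=len(pops),
        variants_per_population=[p.n_gene_variants for p in pops],
        gene_length=gene_length,
        between_population_divergence=between_population_divergence,
        within_population_divergence=max(
            p.intra_population_divergence for p in pops
        ),
        seed=design.seed if seed is None else seed,
        identity_cutoff=identity_cutoff,
        population_ids=[p.population_id for p in pops],
    )
    truth.true_abundance = design.true_abundance
    return genes, truth


def inject_export(
    design: CommunityDesign,
    population_ids: Sequence[str],
    target_depths: Sequence,
    level: float = 1e-3,
) -> None:
    """Inject surface populations into deeper samples at a low level.

    Emulates particle export: the named populations receive an added
    relative abundance ``level`` (scaled by their rank order) in every
    sample at the target depths; the non-core block of those samples is
    rescaled so columns still sum to 1 and planted core fractions are
    untouched.
    """
    meta = design.sample_metadata
    core_at = design.core_populations
    ab = design.true_abundance
    for d in target_depths:
        core_ids = set(core_at.get(d, []))
        samples = meta.loc[meta["depth"] == d, "sample_id"]
        for s in samples:
            col = ab[s].copy()
            noncore = [p for p in ab.index if p not in core_ids]
            budget = col.loc[noncore].sum()
            add = pd.Series(0.0, index=ab.index)
            for r, pid in enumerate(population_ids):
                if pid in core_ids:
                    raise ValueError(f"cannot export into core population {pid}")
                add.loc[pid] = level / (r + 1)
            col.loc[noncore] = col.loc[noncore] + add.loc[noncore]
            col.loc[noncore] *= budget / col.loc[noncore].sum()
            ab[s] = col


# ---------------------------------------------------------------------------
# alignment simulation


class _CatalogIndex:
    """Precomputed per-gene candidate targets and difference positions."""

    def __init__(self, genes: Sequence[MarkerGene], emission_radius: float):
        self.genes = list(genes)
        self.ids = [g.id for g in genes]
        self.arrays = [_encode(g.seq) for g in genes]
        self.lengths = np.array([g.length for g in genes])
        # candidates[i] -> list of (j, sorted positions where gene i != gene j)
        self.candidates: list[list[tuple[int, np.ndarray]]] = [[] for _ in genes]
        by_length: dict[int, list[int]] = {}
        for i, L in enumerate(self.lengths):
            by_length.setdefault(int(L), []).append(i)
        for L, idxs in by_length.items():
            if len(idxs) < 2:
                continue
            mat = np.stack([self.arrays[i] for i in idxs])
            max_diff = int(emission_radius * L)
            # chunked pairwise hamming to bound memory
            chunk = max(1, 2_000_000 // (len(idxs) * L) + 1)
            for a0 in range(0, len(idxs), chunk):
                block = mat[a0 : a0 + chunk]
                diffs = (block[:, None, :] != mat[None, :, :]).sum(axis=2)
                for a_off, row in enumerate(diffs):
                    a = a0 + a_off
                    for b in range(len(idxs)):
                        if b == a or row[b] > max_diff:
                            continue
                        i, j = idxs[a], idxs[b]
                        pos = np.flatnonzero(self.arrays[i] != self.arrays[j])
                        self.candidates[i].append((j, pos))


def simulate_alignments(
    design: CommunityDesign,
    catalog: Sequence[MarkerGene],
    truth: TruthTable,
    error_rate: float = 0.0,
    paired: bool = True,
    seed: int = 0,
    read_length: int = 150,
    insert_size: int = 300,
    mismatch_penalty: int = 4,
    min_emit_identity: float = 0.90,
    emission_radius: float = 0.12,
) -> Iterator[SampleAlignments]:
    """Simulate per-sample read-to-gene alignment records with truth.

    Inserts are drawn multinomially from the design's true abundances
    (population abundance split evenly over its gene variants).  Each insert
    yields records against its source gene and against every catalog gene
    within ``emission_radius`` full-gene divergence whose read-window
    identity reaches ``min_emit_identity`` — a stand-in for an aligner's
    seeding sensitivity.  The alignment score is
    ``n_matches - mismatch_penalty * n_mismatches``.  Deterministic given
    ``seed``; one independent substream per sample.
    """
    if not catalog:
        raise ValueError("empty catalog")
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError(f"error_rate must be in [0, 0.05], got {error_rate}")
    index = _CatalogIndex(catalog, emission_radius)
    id_to_idx = {g: i for i, g in enumerate(index.ids)}

    # per-gene sampling probabilities: population abundance / n variants
    pop_of = truth.gene_to_population
    genes_by_pop: dict[str, list[int]] = {}
    for gid, pid in pop_of.items():
        if gid not in id_to_idx:
            continue
        genes_by_pop.setdefault(pid, []).append(id_to_idx[gid])

    meta = design.sample_metadata
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(meta))
    for row, child in zip(meta.itertuples(index=False), child_seeds):
        rng = np.random.default_rng(child)
        yield _simulate_sample(
            design,
            index,
            genes_by_pop,
            str(row.sample_id),
            rng,
            error_rate,
            paired,
            read_length,
            insert_size,
            mismatch_penalty,
            min_emit_identity,
        )


def _simulate_sample(
    design: CommunityDesign,
    index: _CatalogIndex,
    genes_by_pop: dict,
    sample_id: str,
    rng: np.random.Generator,
    error_rate: float,
    paired: bool,
    read_length: int,
    insert_size: int,
    mismatch_penalty: int,
    min_emit_identity: float,
) -> SampleAlignments:
    n_genes = len(index.ids)
    probs = np.zeros(n_genes)
    ab = design.true_abundance[sample_id]
    for pid, g_idx in genes_by_pop.items():
        a = float(ab.get(pid, 0.0))
        if a > 0:
            probs[g_idx] = a / len(g_idx)
    total = probs.sum()
    if total <= 0:
        raise ValueError(f"sample {sample_id} has zero total abundance")
    probs /= total
    counts = rng.multinomial(design.insert_depth_per_sample, probs)

    frames = []
    src_rows = []
    insert_counter = 0
    for g_i in np.flatnonzero(counts):
        c = int(counts[g_i])
        L = int(index.lengths[g_i])
        ins = min(insert_size, L)
        R = min(read_length, ins)
        starts = rng.integers(0, L - ins + 1, size=c)
        iid = np.array(
            [f"{sample_id}.i{insert_counter + k}" for k in range(c)], dtype=object
        )
        insert_counter += c
        src_rows.append(pd.DataFrame({"insert_id": iid, "gene_id": index.ids[g_i]}))

        mates = [(1, starts)] + ([(2, starts + ins - R)] if paired else [])
        # sequencing errors: exact positions + substituted bases per read
        err_by_read: list[tuple[np.ndarray, np.ndarray]] | None = None
        n_err = None
        if error_rate > 0:
            err_by_read = []
            n_err = {}
            for mate, a in mates:
                k_vec = rng.binomial(R, error_rate, size=c)
                n_err[mate] = k_vec
                for k, a0 in zip(k_vec, a):
                    if k == 0:
                        err_by_read.append((np.empty(0, dtype=int), np.empty(0, dtype=np.uint8)))
                    else:
                        pos = a0 + rng.choice(R, size=int(k), replace=False)
                        shift = rng.integers(1, 4, size=int(k)).astype(np.uint8)
                        base = (index.arrays[g_i][pos] + shift) % 4
                        err_by_read.append((pos, base))

        targets = [(g_i, None)] + index.candidates[g_i]
        for t_i, diff_pos in targets:
            for m_off, (mate, a) in enumerate(mates):
                b = a + R
                if diff_pos is None:
                    wd = np.zeros(c, dtype=int)
                else:
                    wd = np.searchsorted(diff_pos, b) - np.searchsorted(diff_pos, a)
                if error_rate == 0:
                    mm = wd
                else:
                    mm = wd.copy()
                    t_arr = index.arrays[t_i]
                    dset = set() if diff_pos is None else set(diff_pos.tolist())
                    for r in range(c):
                        pos, base = err_by_read[m_off * c + r]
                        if len(pos) == 0:
                            continue
                        for p_e, b_e in zip(pos, base):
                            if a[r] <= p_e < b[r]:
                                if p_e in dset:
                                    if b_e == t_arr[p_e]:
                                        mm[r] -= 1
                                else:
                                    mm[r] += 1
                identity = (R - mm) / R
                keep = identity >= min_emit_identity
                if not keep.any():
                    continue
                n_matches = R - mm[keep]
                frames.append(
                    pd.DataFrame(
                        {
                            "insert_id": iid[keep],
                            "mate": mate,
                            "gene_id": index.ids[t_i],
                            "aligned_length": R,
                            "n_matches": n_matches,
                            "identity": identity[keep],
                            "score": n_matches - mismatch_penalty * mm[keep],
                            "sample_id": sample_id,
                            "is_partial": False,
                            "pos": a[keep],
                        }
                    )
                )
    if frames:
        records = pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]
    else:
        records = pd.DataFrame(columns=RECORD_COLUMNS)
    sources = (
        pd.concat(src_rows, ignore_index=True)
        if src_rows
        else pd.DataFrame(columns=["insert_id", "gene_id"])
    )
    sources.insert(0, "sample_id", sample_id)
    return SampleAlignments(sample_id=sample_id, records=records, insert_sources=sources)


def simulate_all(
    design: CommunityDesign,
    catalog: Sequence[MarkerGene],
    truth: TruthTable,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Materialise all samples' records and insert truth (small designs)."""
    recs, srcs = [], []
    for sample in simulate_alignments(design, catalog, truth, **kwargs):
        recs.append(sample.records)
        srcs.append(sample.insert_sources)
    return pd.concat(recs, ignore_index=True), pd.concat(srcs, ignore_index=True)


def simulate_best_hits(
    design: CommunityDesign,
    truth: TruthTable,
    dropout_clade: float = 0.0,
    dropout_all: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a per-gene best-hit taxonomy table from the planted clade labels.

    With probability ``dropout_clade`` a gene loses its clade-rank hit
    (phylum-only annotation); with probability ``dropout_all`` it loses all
    hits (unannotated).  Hit scores are arbitrary positive numbers.
    """
    rng = np.random.default_rng(seed)
    lab = {p.population_id: (p.phylum, p.clade) for p in design.populations}
    rows = []
    for gid, pid in truth.gene_to_population.items():
        if pid not in lab:
            continue
        phylum, clade = lab[pid]
        u = rng.random()
        if u < dropout_all:
            continue
        score = float(rng.integers(200, 800))
        rows.append({"gene_id": gid, "rank": "domain", "label": "Bacteria", "score": score})
        rows.append({"gene_id": gid, "rank": "phylum", "label": phylum, "score": score})
        if rng.random() >= dropout_clade:
            rows.append({"gene_id": gid, "rank": "clade", "label": clade, "score": score})
    return pd.DataFrame(rows, columns=["gene_id", "rank", "label", "score"])


def write_reads_fastq(
    design: CommunityDesign,
    catalog: Sequence[MarkerGene],
    truth: TruthTable,
    path_r1: str,
    path_r2: str,
    sample_id: str,
    error_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 150,
    insert_size: int = 300,
) -> int:
    """Write actual paired reads for one sample as FASTQ, for use with real
    aligners.  Reads are drawn from the same community model but are an
    independent draw, not record-level matched to :func:`simulate_alignments`.
    Returns the number of inserts written.
    """
    rng = np.random.default_rng(seed)
    by_id = {g.id: _encode(g.seq) for g in catalog}
    pop_of = truth.gene_to_population
    genes_by_pop: dict[str, list[str]] = {}
    for gid, pid in pop_of.items():
        genes_by_pop.setdefault(pid, []).append(gid)
    ab = design.true_abundance[sample_id]
    gids, probs = [], []
    for pid, glist in genes_by_pop.items():
        a = float(ab.get(pid, 0.0))
        for g in glist:
            gids.append(g)
            probs.append(a / len(glist))
    probs = np.asarray(probs)
    probs /= probs.sum()
    counts = rng.multinomial(design.insert_depth_per_sample, probs)
    n = 0
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for gid, c in zip(gids, counts):
            arr = by_id[gid]
            L = len(arr)
            ins = min(insert_size, L)
            R = min(read_length, ins)
            for _ in range(int(c)):
                p = int(rng.integers(0, L - ins + 1))
                for f, a0, rc in ((f1, p, False), (f2, p + ins - R, True)):
                    read = arr[a0 : a0 + R].copy()
                    if error_rate > 0:
                        k = rng.binomial(R, error_rate)
                        if k:
                            pos = rng.choice(R, size=k, replace=False)
                            read[pos] = (read[pos] + rng.integers(1, 4, size=k)) % 4
                    if rc:
                        read = 3 - read[::-1]
                    name = f"{sample_id}.i{n}/{2 if rc else 1}"
                    f.write(f"@{name}\n{_decode(read)}\n+\n{'I' * R}\n")
                n += 1
    return n
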