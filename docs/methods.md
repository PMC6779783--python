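# Methods

This note documents the models, conventions, numerical choices and known
limitations of the pipeline. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## mOTU clustering

**Identity convention.** Pairwise nucleotide identity is computed from a
Needleman–Wunsch global alignment (edlib): identity = matching columns /
all alignment columns, with gap columns counted in the denominator. The
convention is a package decision — tools delegate it to their aligner and
rarely state it — and is applied uniformly, so the clustering is
self-consistent. To make identity exactly symmetric the argument pair is
put in a canonical order before aligning (optimal alignments are not
unique, and edlib's traceback can otherwise pick paths with different
column counts in the two directions). Pairs whose alignment spans fewer
than `min_aligned_bases` (default 20) columns are masked and assigned
distance 1.0 rather than dropped, so the distance matrix stays complete for
average linkage; under a global alignment this can only trigger when both
sequences are themselves shorter than the threshold.

**Agglomeration.** UPGMA (arithmetic-mean linkage) on d = 1 − identity,
merging while any two clusters' mean distance is at or below
1 − `identity_cutoff` (default 94.8% identity, the near-species operating
point for this marker gene). The implementation maintains distances by the
size-weighted Lance–Williams update; the test suite checks it against a
brute-force oracle that recomputes every inter-cluster mean from the gene
pair matrix at every step. Distances within 1e-12 are treated as exactly
tied — Lance–Williams updates and direct means agree only up to float
rounding — and tied merges are ordered by the lexicographically smallest
member id (then the partner's), which makes the partition fully
deterministic. The agglomeration is hand-written rather than delegated to
`scipy.cluster.hierarchy` precisely because of this documented tie rule.

**Filters.** mOTUs whose mean per-sample coverage (over *all* samples, not
just samples where the mOTU occurs) is ≤ 0.5× are removed — the bound is
inclusive. Removal drops whole clusters only, so the partition over input
genes is preserved with a removal reason attached. The aberrant-singleton
curation of real catalogs is inherently manual; the package offers an
explicit, off-by-default proxy (`curate_singletons`) that removes singleton
clusters whose gene length deviates from the catalog median by more than
30%. Representatives are each mOTU's longest gene; length ties break to the
lexicographically smaller id.

## Abundance estimation

Alignment records carry per-mate identity, aligned length and score.
Filters: identity ≥ 95% and aligned length ≥ 45 nt, or ≥ 60 nt when the
alignment does not span the whole read ("partial" is defined as
aligned_length < read length). Per insert and candidate gene, the insert
score sums both mates' scores only when both mates hit that same gene;
mates hitting different genes keep their own scores with no pairing bonus.
The best-scoring gene(s) define the candidate set at mOTU level: ties
*within* one mOTU leave the insert unique (counting happens at mOTU level),
ties across mOTUs flag a multiple mapper. Redistribution is a single second
pass — each multi insert is split over its candidate mOTUs proportionally
to the sample's unique-count profile — not an iterative EM. When every
candidate has zero unique counts the insert is split equally; this fallback
is a package decision, as is restricting coverage to the counted
(best-scoring) alignments, with multi-insert bases spread by the same
redistribution fractions and split evenly over tied winner genes so bases
are conserved per insert. mOTU coverage aggregates member genes by total
bases over total length (length-weighted mean).

## Rarefaction, core sets, richness

Uniquely mapping insert counts are down-sampled once per sample, without
replacement (multivariate hypergeometric, numpy Generator), to the dataset
minimum per-sample total by default — the conventional target for a fixed
dataset, overridable. The draw is seeded; each sample gets an independent
seed-derived substream so results do not depend on processing order.
Presence means rarefied count ≥ 1 (no abundance threshold). A depth's core
set is the exact intersection of its samples' presence sets; total richness
is the union. Core abundance fractions sum relative abundance over core
mOTUs per sample, then average over the depth's samples. Clade summaries
restrict all of the above to each clade's mOTUs; mOTUs with a phylum but no
clade and mOTUs with no annotation are aggregated as `phylum-only` and
`unannotated`.

## Taxonomy

Per rank, an mOTU takes the label held by a strict majority (>50%) of its
member genes that have any label at that rank; genes without the rank are
excluded from the denominator, and ties or missing majorities give
`unassigned`. Both choices are package decisions where conventions differ.
Ranks below the first unassigned rank are truncated, which enforces
hierarchy consistency. Manual, tree-based clade reconciliation is out of
scope; a user-supplied gene → clade table plays that role.

## Stratification statistics

Per-mOTU depth profiles average relative abundance over each depth's time
points; the peak depth is the argmax with exact ties resolved to the
shallowest depth. The attribution matrix groups each depth's mean
abundances by the contributing mOTUs' peak depths; per-depth column sums
equal the included total by construction (checked to 1e-9). Spearman
correlations use average ranks for ties with the large-sample t
approximation for p. Partial correlations are first-order partials computed
*on the Spearman correlations* (matching the pairing of rank correlation
with partial correlation in ecological practice), with p from the t
approximation at n − 3 degrees of freedom; the observation unit for the
abundance–richness analysis is one (clade, depth) pair. Top-N overlap
breaks ties at rank N by mOTU id and flags vectors with fewer than N
nonzero entries.

## Synthetic communities

The generator emulates the structure this kind of survey sees: a few
dozen populations per depth, each a bundle of near-identical gene variants;
a small persistent high-abundance core; a long tail of ephemeral,
temporally patchy populations; sharp depth localisation; paired-insert
sampling with substitution errors.

- **Gene catalogs** are star phylogenies: population ancestors mutate a
  common root at half the between-population divergence (pairwise
  difference ≈ the nominal value in expectation); variants mutate their
  ancestor at the within-population divergence, so variant pairs differ by
  at most twice that. Mutations are substitutions only — identity
  arithmetic stays exact and each population provably forms one cluster
  whenever within-divergence is below the cutoff distance. Indels are a
  possible extension, not modelled. Defaults: gene length 1095 nt, 15%
  between, 2% within.
- **Designs** plant, per depth, `n_core` persistent populations (occupancy
  1 at their depth) and `n_ephemeral` patchy ones (occupancy 0.5 by
  default). Per-sample abundances apply log-normal jitter (σ = 0.5) around
  each population's depth profile, then renormalise the core block to
  exactly the planted core fraction (default 0.7, the centre of the
  50–85% range such communities show) and everything else to the
  remainder. The block-wise renormalisation is deliberate: a single global
  normalisation would let ephemeral presence/absence move the realised
  core fraction by far more than counting noise, making the planted
  fraction a fuzzy target; block-wise it is a sharp per-sample ground
  truth, with composition *within* each block still log-normally variable.
- **Depth profiles** decay multiplicatively by `depth_leak` (default 1e-5)
  per stratum away from the peak. The default plants effectively
  depth-exclusive populations: the residual leak sits orders of magnitude
  below the detection limit of a few-thousand-insert rarefaction, so a
  population persistent at one depth cannot masquerade as core at a
  neighbouring depth. Cross-depth transport (the sinking-cells signal that
  makes surface populations re-appear in the mesopelagic) is modelled
  explicitly and separately by `inject_export`, which adds chosen
  populations at a low level to deeper samples while leaving planted core
  fractions untouched.
- **Alignment records** are emitted directly instead of FASTQ plus an
  external aligner: this removes a tool dependency while exercising
  exactly the downstream contract. Records are generated for the source
  gene and every catalog gene within an emission radius (full-gene
  divergence ≤ 0.12 by default) whose read-window identity reaches the
  emission floor (0.90) — a stand-in for an aligner's seeding sensitivity;
  records between the floor and the 95% mapping filter exist, so the
  filters do real work. Scores are `matches − 4 × mismatches` per mate.
  With a nonzero error rate, error positions and substituted bases are
  drawn exactly per read and intersected with the planted difference
  positions, so per-record identities are exact under the substitution
  model (a fully vectorised path handles the zero-error case). Paired
  inserts are two 150 nt reads spanning a 300 nt insert; both defaults are
  configurable. A FASTQ writer (`write_reads_fastq`) exists for users who
  want to run real aligners; its reads are an independent draw from the
  same model, not record-matched.
- The abundance distribution of the ephemeral tail is not constrained by
  the study design this emulates; log-normal weights are a stand-in choice,
  flagged here.

**What passing tests show — and don't.** The synthetic model omits indels,
chimeras, assembly and gene-prediction artefacts, platform-specific error
profiles, and uneven insert-size distributions. Recovery results on it
demonstrate the pipeline's arithmetic and logic (clustering fidelity,
conservation through redistribution, core-set semantics, statistical
estimators), not robustness to those real-data pathologies.

## Problem sizes and determinism

The planted-recovery checks run the full design scale this survey uses —
7 depths × 12 time points, 5 core + 20 ephemeral populations per depth,
50,000 inserts per sample — at three seeds; unit and property tests use
smaller communities (hundreds to thousands of inserts). Every stochastic
component takes an explicit seed, and per-sample substreams are spawned
from a root `SeedSequence`, so identical seeds give byte-identical output
files (checked end to end).

## Known limitations

- Single marker gene only; linking mOTUs across different marker genes is
  deliberately out of scope.
- No diversity indices beyond richness (no Shannon/Chao1), no
  occupancy-abundance modelling, no multiple-testing correction across
  clades (the analysis reports two headline correlations).
- The equal-split fallback for multi-mappers with all-zero unique
  candidates, the all-sample coverage mean, and the observation unit for
  the correlation analysis are documented decisions where the underlying
  conventions are genuinely open.
- Clade abundance can in principle confound within-clade richness
  estimates even after rarefaction; the partial-correlation analysis
  controls total richness but cannot fully resolve that caveat.
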