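# motupipe

Marker-gene mOTU profiling of depth-stratified, time-series ocean
metagenomes: near-species clustering of a universal single-copy marker
gene, insert-level abundance estimation with multi-mapper redistribution,
temporally persistent ("core") population detection per depth, and
depth-stratification statistics — exercised end to end on synthetic
communities with planted ground truth.

## The problem

Open-ocean bacterioplankton communities are strongly structured by depth
and surprisingly stable in time. To see that structure at near-species
resolution without reference genomes, single-copy universal marker genes
(such as the ribosome-associated GTPase COG0012, median length 1095 nt)
extracted from metagenome assemblies can be clustered into marker-gene
operational taxonomic units (mOTUs) and quantified by read mapping across
a depth × time sample grid. The central ecological objects are the
**core-mOTUs** of each depth — mOTUs present at *every* time point sampled
at that depth — which are few but carry most of the community's abundance.

## What the package computes

- **Clustering** (`motupipe.cluster`): all-vs-all pairwise nucleotide
  identity (global alignment; identity = matching columns / all alignment
  columns, gaps included; pairs under 20 aligned columns are masked to
  maximal distance), average-linkage (UPGMA) agglomeration on
  d = 1 − identity cut at 94.8% identity, removal of mOTUs at mean
  coverage ≤ 0.5×, longest-member representatives.
- **Abundance** (`motupipe.profile`): alignment filters (identity ≥ 95%,
  length ≥ 45 nt, ≥ 60 nt for partial alignments); per insert the score of
  each candidate gene is the sum of both mates' scores when both hit that
  gene; the best-scoring gene(s) define the insert's mOTU; inserts tied
  across mOTUs are multiple mappers, redistributed in a single second pass
  proportionally to the unique-count profile:
  `final(m) = unique(m) + Σ_multi unique(m) / Σ_{m'∈cand} unique(m')`.
  Coverage is aligned bases / gene length; relative abundance is insert
  count over the sample's mapped total.
- **Core diversity** (`motupipe.diversity`): one seeded multivariate-
  hypergeometric rarefaction of uniquely mapping insert counts to the
  dataset minimum; richness = mOTUs with count ≥ 1; per-depth core set =
  intersection of time-point presence sets; total richness = union.
- **Taxonomy** (`motupipe.taxonomy`): strict-majority (>50%) vote per rank
  over member-gene best hits, truncated below the first unassigned rank.
- **Stratification statistics** (`motupipe.stats`): per-mOTU depth of
  highest mean relative abundance and the cumulative attribution of each
  depth's community to peak depths; Spearman rank correlations; first-order
  partial correlations on Spearman correlations,
  `r_xy·z = (r_xy − r_xz r_yz) / √((1 − r_xz²)(1 − r_yz²))`, p-values from
  the t approximation with n − 3 degrees of freedom; top-N rank-abundance
  overlap between depths.
- **Synthetic communities** (`motupipe.simulate`): planted depth × time
  designs (core + ephemeral populations, exact per-sample core abundance
  fraction, depth-exclusive profiles, configurable temporal occupancy),
  substitution-only marker-gene catalogs with controlled within/between
  population divergence, and paired-insert alignment records with exact
  identities and scores under a substitution error model — plus full truth
  tables so every stage is checkable.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
community (7 depths × 12 monthly time points; 5 core + 20 ephemeral
populations per depth; core populations planted at 70% of each sample's
abundance; 10,000 inserts per sample):

```bash
python analysis/01_simulate_community.py
python analysis/02_cluster_motus.py
python analysis/03_profile_abundances.py
python analysis/04_assign_taxonomy.py
python analysis/05_core_richness.py
python analysis/06_stratification_stats.py
```

which prints (abridged):

```
 n_genes  n_motus  n_planted_populations  clusters_pure  populations_unsplit
     347      175                    175           True                 True
 n_motus_profiled  n_low_coverage_removed  mean_abs_abundance_error
              165                      10                   0.00015
 depth  core_richness  total_richness  core_abundance_fraction
 125.0              5              24                   0.7000
 200.0              5              23                   0.7047
 ...
35 distinct core-mOTUs across depths (21.2% of all mOTUs)
clade_abundance core_richness total_richness 0.8242  0.7589  7.9e-12  58
share of community abundance attributed to its own depth: 1.000
```

Reading: the 347 simulated gene variants cluster into exactly the 175
planted populations; relative abundances are recovered to ~1.5 × 10⁻⁴ mean
absolute error; each depth's recovered core is exactly the 5 planted
persistent populations holding ~70% of the abundance; clade abundance and
within-clade core richness correlate strongly even after controlling for
total richness; and the community is fully depth-specific, as planted.
Small summary tables land in `results/`, bulky intermediates in
`scratch/`.

A `motupipe` CLI mirrors the stages (`motupipe simulate | cluster |
profile | taxonomy | core | stats ...`) for use on real gene FASTA +
SAM/TSV alignment inputs.

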