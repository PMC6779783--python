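"""Synthetic community generator: catalogs, designs, alignment records."""

import numpy as np
import pandas as pd
import pytest

from motupipe import MarkerGene, generate_design, generate_gene_catalog
from motupipe.cluster import pairwise_identity
from motupipe.simulate import (
    CommunityDesign,
    PopulationSpec,
    inject_export,
    simulate_alignments,
    simulate_all,
    simulate_best_hits,
    write_reads_fastq,
)


class TestGeneCatalog:
    def test_two_singleton_populations(self):
        genes, truth = generate_gene_catalog(
            2, 1, gene_length=1095, between_population_divergence=0.10,
            within_population_divergence=0.0, seed=1,
        )
        assert len(genes) == 2
        assert truth.gene_to_population.nunique() == 2
        ident = pairwise_identity(genes[0], genes[1])
        assert 0.85 < ident < 0.95  # ~10% divergent

    def test_zero_within_divergence_identical_variants(self):
        genes, _ = generate_gene_catalog(
            1, 5, within_population_divergence=0.0, seed=2
        )
        assert len({g.seq for g in genes}) == 1

    def test_divergence_ordering_error_names_both_values(self):
        with pytest.raises(ValueError, match="0.1.*0.05|0.05.*0.1"):
            generate_gene_catalog(
                2, 1, between_population_divergence=0.05,
                within_population_divergence=0.1,
            )

    def test_deterministic_given_seed(self):
        a, _ = generate_gene_catalog(4, 2, seed=9)
        b, _ = generate_gene_catalog(4, 2, seed=9)
        assert [(g.id, g.seq) for g in a] == [(g.id, g.seq) for g in b]

    def test_min_gene_length(self):
        with pytest.raises(ValueError, match="gene_length"):
            generate_gene_catalog(2, 1, gene_length=50)

    def test_identities_straddle_cutoff(self, planted_catalog):
        """Exhaustive pairwise identities, recomputed with the clustering
        module's aligner, fall in the planted bands around 94.8%."""
        genes, truth = planted_catalog
        pop = truth.gene_to_population
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                ident = pairwise_identity(genes[i], genes[j])
                if pop[genes[i].id] == pop[genes[j].id]:
                    assert ident > 0.948
                else:
                    assert ident < 0.948


class TestDesign:
    def test_all_core_boundary(self):
        d = generate_design(
            3, 0, [25, 200], ["t0", "t1"], core_abundance_fraction=1.0, seed=0
        )
        core_at = d.core_populations
        for row in d.sample_metadata.itertuples(index=False):
            col = d.true_abundance[row.sample_id]
            assert col[col.index.isin(core_at[row.depth])].sum() == pytest.approx(1.0)

    def test_planted_core_fraction_exact_by_summation(self):
        d = generate_design(
            5, 20, [25, 75, 125], [f"t{i}" for i in range(6)],
            core_abundance_fraction=0.7, seed=3,
        )
        core_at = d.core_populations
        for row in d.sample_metadata.itertuples(index=False):
            col = d.true_abundance[row.sample_id]
            frac = col[col.index.isin(core_at[row.depth])].sum()
            assert frac == pytest.approx(0.7, abs=1e-9)
            assert col.sum() == pytest.approx(1.0, abs=1e-9)

    def test_ephemeral_occupancy_half(self):
        d = generate_design(
            2, 30, [25, 200], [f"t{i}" for i in range(20)],
            ephemeral_occupancy=0.5, seed=4,
        )
        meta = d.sample_metadata
        eph = [p.population_id for p in d.populations if not p.is_core_at]
        presences = []
        for p in d.populations:
            if p.is_core_at:
                continue
            home = p.peak_depth
            samples = meta.loc[meta["depth"] == home, "sample_id"]
            pres = (d.true_abundance.loc[p.population_id, samples] > 0).mean()
            presences.append(pres)
        # mean occupancy over 60 ephemerals x 20 timepoints ~ Binomial
        assert np.mean(presences) == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(len(eph) * 20))

    def test_profiles_peak_at_home_depth(self):
        d = generate_design(2, 2, [25, 200, 1000], ["t0", "t1"], seed=5)
        for p in d.populations:
            prof = p.mean_abundance_profile
            assert max(prof, key=prof.get) == p.peak_depth

    def test_empty_depths_error(self):
        with pytest.raises(ValueError, match="design error"):
            generate_design(1, 1, [], ["t0", "t1"])

    def test_core_occupancy_invariant(self):
        with pytest.raises(ValueError, match="core.*occupancy|occupancy.*core"):
            PopulationSpec(
                population_id="p",
                is_core_at=frozenset([25]),
                peak_depth=25,
                mean_abundance_profile={25: 1.0},
                temporal_occupancy={25: 0.5},
                n_gene_variants=1,
                intra_population_divergence=0.0,
            )

    def test_design_needs_two_depths_and_timepoints(self):
        with pytest.raises(ValueError, match=">= 2"):
            generate_design(1, 1, [25], ["t0", "t1"])


def tiny_design(**kw):
    args = dict(
        n_core_per_depth=2,
        n_ephemeral_per_depth=2,
        depths=[25.0, 1000.0],
        timepoints=["t0", "t1"],
        core_abundance_fraction=0.7,
        seed=6,
        insert_depth_per_sample=500,
        variants_per_population=1,
    )
    args.update(kw)
    return generate_design(**args)


class TestAlignments:
    def test_insert_conservation_and_determinism(self):
        d = tiny_design()
        genes, truth = _catalog(d)
        runs = []
        for _ in range(2):
            recs, srcs = simulate_all(d, genes, truth, seed=8)
            runs.append((recs, srcs))
            for sid, grp in srcs.groupby("sample_id"):
                assert len(grp) == d.insert_depth_per_sample
        pd.testing.assert_frame_equal(runs[0][0], runs[1][0])
        pd.testing.assert_frame_equal(runs[0][1], runs[1][1])

    def test_no_ambiguity_regime_unique_counts_match_draw(self):
        """Mutually <90%-identical genes: every insert aligns only to its
        source, so per-gene record counts equal the multinomial draw."""
        d = tiny_design()
        genes, truth = _catalog(d, between=0.2)
        recs, srcs = simulate_all(d, genes, truth, seed=9)
        # each record's gene is the insert's true source
        merged = recs.merge(srcs, on=["sample_id", "insert_id"], suffixes=("", "_true"))
        assert (merged["gene_id"] == merged["gene_id_true"]).all()
        counts = srcs.groupby(["sample_id", "gene_id"]).size()
        rec_counts = recs[recs["mate"] == 1].groupby(["sample_id", "gene_id"]).size()
        pd.testing.assert_series_equal(counts, rec_counts, check_names=False)

    def test_identical_genes_emit_equal_score_ties(self):
        d = tiny_design(n_core_per_depth=1, n_ephemeral_per_depth=0,
                        core_abundance_fraction=1.0)
        genes, truth = _catalog(d)
        twin = MarkerGene("twin", genes[0].seq)
        genes2 = list(genes) + [twin]
        truth.gene_to_population.loc["twin"] = "twin_pop"
        recs, _ = simulate_all(d, genes2, truth, seed=10)
        src_gene = genes[0].id
        per_insert = recs[recs["mate"] == 1].groupby("insert_id")["gene_id"].nunique()
        from_twin_source = recs[recs["gene_id"].isin([src_gene, "twin"])]
        # every insert from the twinned sequence hits both copies with equal scores
        wide = from_twin_source.pivot_table(
            index=["insert_id", "mate"], columns="gene_id", values="score"
        )
        if src_gene in wide.columns and "twin" in wide.columns:
            both = wide.dropna()
            assert len(both) > 0
            assert (both[src_gene] == both["twin"]).all()

    def test_error_rate_produces_binomial_identity_spread(self):
        d = tiny_design(insert_depth_per_sample=2000)
        genes, truth = _catalog(d, between=0.2)
        recs, _ = simulate_all(d, genes, truth, error_rate=0.01, seed=11)
        own = recs  # all records are vs own gene in this regime
        R = int(own["aligned_length"].iloc[0])
        # identity < 95% iff > floor(0.05*R) errors on the read
        from scipy.stats import binom

        thresh = R - int(np.ceil(0.95 * R)) + 1
        p_low = binom.sf(thresh - 1, R, 0.01)
        frac = (own["identity"] < 0.95).mean()
        n = len(own)
        assert abs(frac - p_low) < 3 * np.sqrt(p_low * (1 - p_low) / n) + 1e-12

    def test_error_records_identity_consistent(self):
        d = tiny_design()
        genes, truth = _catalog(d)
        recs, _ = simulate_all(d, genes, truth, error_rate=0.02, seed=12)
        assert np.allclose(recs["identity"], recs["n_matches"] / recs["aligned_length"])
        assert (recs["n_matches"] <= recs["aligned_length"]).all()

    def test_empty_catalog_errors(self):
        d = tiny_design()
        genes, truth = _catalog(d)
        with pytest.raises(ValueError, match="empty catalog"):
            next(simulate_alignments(d, [], truth, seed=0))

    def test_error_rate_bounds(self):
        d = tiny_design()
        genes, truth = _catalog(d)
        with pytest.raises(ValueError, match="error_rate"):
            next(simulate_alignments(d, genes, truth, error_rate=0.2, seed=0))

    def test_unpaired_emits_single_mate(self):
        d = tiny_design()
        genes, truth = _catalog(d)
        recs, _ = simulate_all(d, genes, truth, paired=False, seed=13)
        assert set(recs["mate"]) == {1}


def _catalog(design, between=0.15):
    from motupipe.simulate import catalog_for_design

    return catalog_for_design(design, between_population_divergence=between)


class TestTaxonomyAndExportHelpers:
    def test_best_hits_carry_planted_labels(self):
        d = tiny_design()
        genes, truth = _catalog(d)
        hits = simulate_best_hits(d, truth, seed=1)
        lab = {p.population_id: p.clade for p in d.populations}
        clade_hits = hits[hits["rank"] == "clade"].set_index("gene_id")["label"]
        for gid, pid in truth.gene_to_population.items():
            assert clade_hits[gid] == lab[pid]

    def test_dropout_removes_hits(self):
        d = tiny_design()
        genes, truth = _catalog(d)
        hits = simulate_best_hits(d, truth, dropout_all=1.0, seed=1)
        assert hits.empty

    def test_inject_export_preserves_column_sums_and_core_fraction(self):
        d = generate_design(
            2, 10, [25.0, 1000.0], ["t0", "t1", "t2"], seed=14,
            core_abundance_fraction=0.6,
        )
        surface_eph = [
            p.population_id
            for p in d.populations
            if not p.is_core_at and p.peak_depth == 25.0
        ][:3]
        before = d.true_abundance.copy()
        inject_export(d, surface_eph, [1000.0], level=1e-3)
        sums = d.true_abundance.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)
        deep = d.sample_metadata.loc[d.sample_metadata["depth"] == 1000.0, "sample_id"]
        core_deep = d.core_populations[1000.0]
        for s in deep:
            col = d.true_abundance[s]
            assert col[col.index.isin(core_deep)].sum() == pytest.approx(0.6, abs=1e-9)
            assert (col.loc[surface_eph] > 0).all()

    def test_fastq_writer_round_trip(self, tmp_path):
        d = tiny_design(insert_depth_per_sample=50)
        genes, truth = _catalog(d)
        s = d.sample_metadata["sample_id"].iloc[0]
        r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        n = write_reads_fastq(d, genes, truth, str(r1), str(r2), s, seed=3)
        assert n == 50
        lines = r1.read_text().strip().split("\n")
        assert len(lines) == 200
        assert set(lines[1]) <= set("ACGT")
        assert len(lines[1]) == 150
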