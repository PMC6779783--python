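"""Abundance profiling: filters, insert resolution, redistribution,
coverage, relative abundance."""

import math

import numpy as np
import pandas as pd
import pytest

from motupipe import PipelineConfig
from motupipe.cluster import MOTUCatalog
from motupipe.profile import (
    InsertAssignments,
    compute_coverage,
    count_unique,
    filter_alignments,
    redistribute_multimappers,
    relative_abundance,
    resolve_inserts,
    winning_records,
)

from conftest import make_records

CFG = PipelineConfig()
CATALOG = MOTUCatalog(members={"mA": ["gA1", "gA2"], "mB": ["gB1"], "mC": ["gC1"]})


def rec(insert, mate, gene, aln, matches, score, sample="s1", partial=False):
    return (insert, mate, gene, aln, matches, score, sample, partial)


class TestFilter:
    def test_kept_and_dropped_thresholds(self):
        df = make_records(
            [
                rec("i1", 1, "gA1", 50, 48, 48),  # 0.96, 50 nt -> kept
                rec("i2", 1, "gA1", 200, 188, 140),  # 0.94 -> dropped
            ]
        )
        out = filter_alignments(df, CFG)
        assert list(out["insert_id"]) == ["i1"]

    @pytest.mark.parametrize(
        "aln,partial,kept",
        [
            (44, False, False),
            (45, False, True),
            (50, True, False),
            (59, True, False),
            (60, True, True),
        ],
    )
    def test_length_boundaries(self, aln, partial, kept):
        df = make_records([rec("i", 1, "gA1", aln, aln, aln, partial=partial)])
        assert (len(filter_alignments(df, CFG)) == 1) is kept

    def test_order_preserved_and_idempotent(self):
        rows = [rec(f"i{k}", 1, "gA1", 50 + k, 50 + k, 10, partial=bool(k % 2)) for k in range(20)]
        df = make_records(rows)
        once = filter_alignments(df, CFG)
        twice = filter_alignments(once, CFG)
        pd.testing.assert_frame_equal(once, twice)
        assert list(once.index) == sorted(once.index)

    def test_malformed_record_errors_with_context(self):
        df = make_records([rec("i1", 1, "gA1", 50, 60, 10)])
        with pytest.raises(ValueError, match="malformed"):
            filter_alignments(df, CFG)

    def test_empty_stream(self):
        df = make_records([])
        assert len(filter_alignments(df, CFG)) == 0


class TestResolve:
    def test_single_candidate_sums_mates(self):
        df = make_records(
            [
                rec("i1", 1, "gA1", 100, 100, 80),
                rec("i1", 2, "gA1", 100, 95, 75),
            ]
        )
        a = resolve_inserts(df, CATALOG)
        assert list(a.table["status"]) == ["unique"]
        assert list(a.table["motu_id"]) == ["mA"]

    def test_equal_scores_across_motus_flag_multi(self):
        df = make_records(
            [
                rec("i1", 1, "gA1", 100, 100, 100),
                rec("i1", 1, "gB1", 100, 100, 100),
            ]
        )
        a = resolve_inserts(df, CATALOG)
        assert set(a.table["status"]) == {"multi"}
        assert set(a.table["motu_id"]) == {"mA", "mB"}

    def test_mate_sum_beats_single_higher_mate(self):
        # X: 60 + 60 = 120 beats Y: 90
        df = make_records(
            [
                rec("i1", 1, "gA1", 100, 90, 60),
                rec("i1", 1, "gB1", 100, 98, 90),
                rec("i1", 2, "gA1", 100, 90, 60),
            ]
        )
        a = resolve_inserts(df, CATALOG)
        assert list(a.table["status"]) == ["unique"]
        assert list(a.table["motu_id"]) == ["mA"]

    def test_tie_within_one_motu_is_unique(self):
        df = make_records(
            [
                rec("i1", 1, "gA1", 100, 100, 100),
                rec("i1", 1, "gA2", 100, 100, 100),
            ]
        )
        a = resolve_inserts(df, CATALOG)
        assert list(a.table["status"]) == ["unique"]

    def test_unknown_gene_errors(self):
        df = make_records([rec("i1", 1, "ghost", 100, 100, 100)])
        with pytest.raises(ValueError, match="ghost"):
            resolve_inserts(df, CATALOG)


class TestCounting:
    def _assign(self, rows):
        return InsertAssignments(
            pd.DataFrame(rows, columns=["sample_id", "insert_id", "motu_id", "status"])
        )

    def test_no_unique_inserts_zero_vector(self):
        a = self._assign([("s1", "i1", "mA", "multi"), ("s1", "i1", "mB", "multi")])
        assert count_unique(a).empty

    def test_simple_counts(self):
        rows = [("s1", f"a{k}", "mA", "unique") for k in range(30)]
        rows += [("s1", f"b{k}", "mB", "unique") for k in range(10)]
        c = count_unique(self._assign(rows))
        assert c.loc["mA", "s1"] == 30 and c.loc["mB", "s1"] == 10

    def test_worked_redistribution_30_10_plus_8(self):
        rows = [("s1", f"a{k}", "mA", "unique") for k in range(30)]
        rows += [("s1", f"b{k}", "mB", "unique") for k in range(10)]
        for k in range(8):
            rows += [("s1", f"m{k}", "mA", "multi"), ("s1", f"m{k}", "mB", "multi")]
        a = self._assign(rows)
        final = redistribute_multimappers(count_unique(a), a)
        assert final.loc["mA", "s1"] == pytest.approx(36.0)
        assert final.loc["mB", "s1"] == pytest.approx(12.0)

    def test_zero_unique_fallback_splits_equally(self):
        rows = [
            ("s1", "u1", "mC", "unique"),
            ("s1", "m1", "mA", "multi"),
            ("s1", "m1", "mB", "multi"),
        ]
        a = self._assign(rows)
        final = redistribute_multimappers(count_unique(a), a)
        assert final.loc["mA", "s1"] == pytest.approx(0.5)
        assert final.loc["mB", "s1"] == pytest.approx(0.5)

    def test_no_multi_is_identity(self):
        rows = [("s1", f"a{k}", "mA", "unique") for k in range(5)]
        a = self._assign(rows)
        u = count_unique(a)
        final = redistribute_multimappers(u, a)
        pd.testing.assert_frame_equal(final, u.astype(float))

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_on_random_assignments(self, seed):
        rng = np.random.default_rng(seed)
        motus = [f"m{k}" for k in range(rng.integers(2, 8))]
        rows = []
        n_multi = 0
        for i in range(int(rng.integers(10, 200))):
            if rng.random() < 0.7:
                rows.append(("s1", f"i{i}", rng.choice(motus), "unique"))
            else:
                n_multi += 1
                cands = rng.choice(motus, size=rng.integers(2, len(motus) + 1), replace=False)
                rows += [("s1", f"i{i}", c, "multi") for c in cands]
        a = self._assign(rows)
        u = count_unique(a)
        final = redistribute_multimappers(u, a)
        assert math.fsum(final["s1"]) == pytest.approx(u["s1"].sum() + n_multi if len(u) else n_multi, abs=1e-9)

    def test_singleton_multi_candidates_fixed_point(self):
        # if every "multi" set were a singleton it would be unique; check
        # redistribution equals unique + those inserts when candidates
        # resolve within one mOTU
        rows = [("s1", "u1", "mA", "unique"), ("s1", "u2", "mA", "unique")]
        a = self._assign(rows)
        final = redistribute_multimappers(count_unique(a), a)
        assert final.loc["mA", "s1"] == 2.0


class TestCoverage:
    def test_single_alignment(self):
        cat = MOTUCatalog(members={"m": ["g"]})
        df = make_records([rec("i1", 1, "g", 150, 150, 150)])
        cov = compute_coverage(df, {"g": 1500}, cat)
        assert cov.loc["m", "s1"] == pytest.approx(0.1)

    def test_ten_alignments(self):
        cat = MOTUCatalog(members={"m": ["g"]})
        df = make_records([rec(f"i{k}", 1, "g", 150, 150, 150) for k in range(10)])
        cov = compute_coverage(df, {"g": 1000}, cat)
        assert cov.loc["m", "s1"] == pytest.approx(1.5)

    def test_motu_coverage_is_length_weighted(self):
        cat = MOTUCatalog(members={"m": ["g1", "g2"]})
        df = make_records(
            [rec("i1", 1, "g1", 100, 100, 100), rec("i2", 1, "g2", 300, 300, 300)]
        )
        cov = compute_coverage(df, {"g1": 1000, "g2": 3000}, cat)
        assert cov.loc["m", "s1"] == pytest.approx(400 / 4000)

    def test_zero_length_errors(self):
        cat = MOTUCatalog(members={"m": ["g"]})
        df = make_records([rec("i1", 1, "g", 100, 100, 100)])
        with pytest.raises(ValueError, match="length"):
            compute_coverage(df, {"g": 0}, cat)


class TestRelativeAbundance:
    def test_simple_fractions(self):
        counts = pd.DataFrame({"s1": [60.0, 40.0]}, index=["mA", "mB"])
        rel = relative_abundance(counts)
        assert rel["s1"].tolist() == pytest.approx([0.6, 0.4])

    def test_single_motu(self):
        counts = pd.DataFrame({"s1": [17.0]}, index=["mA"])
        assert relative_abundance(counts)["s1"].iloc[0] == 1.0

    def test_zero_sample_warns_not_errors(self):
        counts = pd.DataFrame({"s1": [0.0, 0.0]}, index=["mA", "mB"])
        with pytest.warns(UserWarning, match="s1"):
            rel = relative_abundance(counts)
        assert (rel["s1"] == 0).all()

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(6, 4)).astype(float),
            index=[f"m{k}" for k in range(6)],
            columns=[f"s{k}" for k in range(4)],
        )
        counts.iloc[0] += 1  # no all-zero columns
        rel = relative_abundance(counts)
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-9)


class TestEndToEndRecovery:
    def test_relative_abundance_recovers_planted_truth(self, small_community):
        """With zero sequencing error and well-separated populations the
        estimated per-sample relative abundances match the planted truth to
        within 3 binomial standard errors."""
        design, result = small_community
        rel = result.layers["relative_abundance"]
        motu_of = result.motu_of_population
        n = design.insert_depth_per_sample
        checked = 0
        for s in design.true_abundance.columns:
            truth_col = design.true_abundance[s]
            for pid, true_p in truth_col.items():
                motu = motu_of.get(pid)
                if motu is None or motu not in rel.index or true_p < 0.01:
                    continue
                est = rel.loc[motu, s]
                se = np.sqrt(true_p * (1 - true_p) / n)
                assert abs(est - true_p) < 3 * se + 0.005
                checked += 1
        assert checked > 50

    def test_estimates_converge_with_insert_depth(self):
        """Mean absolute abundance error shrinks as insert depth grows."""
        from motupipe import generate_design
        from motupipe.pipeline import run_synthetic_pipeline

        errs = []
        for n in (300, 3000, 30000):
            d = generate_design(
                2, 3, [25.0, 1000.0], ["t0", "t1"], seed=21,
                insert_depth_per_sample=n, variants_per_population=1,
            )
            res = run_synthetic_pipeline(d, seed=21, apply_coverage_filter=False)
            motu_of = res.motu_of_population
            rel = res.layers["relative_abundance"]
            diffs = []
            for s in d.true_abundance.columns:
                for pid, true_p in d.true_abundance[s].items():
                    m = motu_of.get(pid)
                    if m in rel.index:
                        diffs.append(abs(rel.loc[m, s] - true_p))
            errs.append(np.mean(diffs))
        assert errs[0] > errs[1] > errs[2]
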