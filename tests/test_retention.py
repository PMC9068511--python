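"""Retention estimators, fold changes, ranking and enrichment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from isoretain.counting import (
    CDS,
    FIVE_PRIME_UTR,
    FeatureCountsTable,
    GeneCounts,
    IntronCounts,
)
from isoretain.errors import InvalidPairingError, UndefinedRateError
from isoretain.retention import (
    RetentionRecord,
    bh_adjust,
    density_rate,
    fold_changes,
    hypergeom_enrichment,
    junction_rate,
    normalize_to_control,
    rank_by_fold,
    retention_density,
    retention_junction,
)


def table_for(cds_count, cds_length, introns):
    gc = GeneCounts(gene_id="g", strand="+", cds_length=cds_length,
                    cds_count=cds_count)
    pos = 0
    for klass, count, length, n5, n3 in introns:
        gc.introns.append(
            IntronCounts(interval=(pos, pos + length), klass=klass, count=count,
                         n5=n5, n3=n3)
        )
        pos += length + 10
    return FeatureCountsTable(genes={"g": gc}, read_length=50)


class TestDensityEstimator:
    def test_worked_example(self):
        assert density_rate(10, 100, 200, 1000) == pytest.approx(0.5)

    def test_zero_intron_reads_give_zero_rate(self):
        assert density_rate(0, 100, 200, 1000) == 0.0

    def test_multiple_cds_introns_pooled_jointly(self):
        counts = table_for(100, 500, [(CDS, 5, 50, 0, 0), (CDS, 15, 150, 0, 0)])
        (rec,) = retention_density(counts, "g", CDS)
        assert rec.r == pytest.approx((20 / 200) / (100 / 500))
        assert rec.r == pytest.approx(0.5)

    def test_utr_introns_scored_separately(self):
        counts = table_for(
            100, 500,
            [(FIVE_PRIME_UTR, 10, 100, 0, 0), (FIVE_PRIME_UTR, 40, 100, 0, 0)],
        )
        recs = retention_density(counts, "g", FIVE_PRIME_UTR)
        assert len(recs) == 2
        assert recs[0].r == pytest.approx((10 / 100) / (100 / 500))
        assert recs[1].r == pytest.approx((40 / 100) / (100 / 500))

    def test_zero_cds_reads_raise(self):
        counts = table_for(0, 500, [(CDS, 5, 50, 0, 0)])
        with pytest.raises(UndefinedRateError):
            retention_density(counts, "g", CDS)

    @given(st.integers(1, 1000))
    def test_scale_invariance(self, c):
        base = density_rate(10, 100, 200, 1000)
        assert density_rate(10 * c, 100, 200 * c, 1000) == pytest.approx(base)


class TestJunctionEstimator:
    def test_worked_example(self):
        assert junction_rate(20, 30, 50, 200, 1000) == pytest.approx(2.5)

    def test_zero_boundary_reads_give_zero(self):
        assert junction_rate(0, 0, 50, 200, 1000) == 0.0

    def test_zero_cds_reads_raise(self):
        counts = table_for(0, 500, [(CDS, 5, 50, 3, 4)])
        with pytest.raises(UndefinedRateError):
            retention_junction(counts, "g")

    def test_agrees_with_density_on_fully_retained_simulation(self):
        from isoretain.counting import build_counts_table
        from isoretain.synthetic import SimTruth, sim_reads
        from isoretain.validation import recovery_gene_models

        models = recovery_gene_models(n_genes=2)
        truth = [SimTruth(gene_id=m.gene_id, rho_utr=1.0) for m in models]
        reads = sim_reads(models, truth, depth=2000.0, seed=5)
        counts = build_counts_table(reads, models, read_length=50)
        for m in models:
            (dens,) = retention_density(counts, m.gene_id, FIVE_PRIME_UTR)
            (junc,) = retention_junction(counts, m.gene_id)
            assert junc.r == pytest.approx(dens.r, rel=0.15)

    def test_rank_correlated_with_density_at_high_depth(self):
        from isoretain.counting import build_counts_table
        from isoretain.synthetic import SimTruth, gen_gene_models, sim_reads

        rng = np.random.default_rng(3)
        models = gen_gene_models(30, frac_utr_intron=1.0, seed=3,
                                 frac_cds_intron=0.0)
        truth = [
            SimTruth(gene_id=m.gene_id, rho_utr=float(rng.uniform(0.05, 0.95)))
            for m in models
        ]
        reads = sim_reads(models, truth, depth=3000.0, seed=4)
        counts = build_counts_table(reads, models, read_length=50)
        dens, junc = [], []
        for m in models:
            dens.append(retention_density(counts, m.gene_id, FIVE_PRIME_UTR)[0].r)
            junc.append(retention_junction(counts, m.gene_id)[0].r)
        rho, _ = spearmanr(dens, junc)
        assert rho > 0.9


class TestFoldChange:
    def rec(self, r, gene="g", klass=CDS):
        return RetentionRecord(gene_id=gene, intron_class=klass, r=r,
                               method="density")

    def test_basic_ratio(self):
        fold = normalize_to_control(self.rec(0.4), self.rec(0.2), pseudocount=1e-9)
        assert fold == pytest.approx(2.0, rel=1e-6)

    def test_equal_rates_give_one_for_any_pseudocount(self):
        for eps in (1e-6, 0.01, 1.0):
            assert normalize_to_control(self.rec(0.3), self.rec(0.3), eps) == 1.0

    def test_zero_control_with_stated_pseudocount(self):
        fold = normalize_to_control(self.rec(0.1), self.rec(0.0), pseudocount=0.01)
        assert fold == pytest.approx(0.11 / 0.01)

    def test_mismatched_records_raise(self):
        other = RetentionRecord(gene_id="h", intron_class=CDS, r=0.2,
                                method="density")
        with pytest.raises(InvalidPairingError):
            normalize_to_control(self.rec(0.4), other, pseudocount=0.01)

    def test_fold_changes_pairs_by_key(self):
        treated = [self.rec(0.4, "a"), self.rec(0.2, "b")]
        control = [self.rec(0.2, "a")]
        out = fold_changes(treated, control, pseudocount=1e-9)
        assert len(out) == 1
        assert out[0].gene_id == "a"
        assert out[0].fold_vs_control == pytest.approx(2.0, rel=1e-6)


class TestRanking:
    def fold_rec(self, gene, fold):
        return RetentionRecord(gene_id=gene, intron_class=CDS, r=1.0,
                               method="density", fold_vs_control=fold)

    def test_descending_order(self):
        recs = [self.fold_rec("a", 3), self.fold_rec("b", 1), self.fold_rec("c", 2)]
        assert rank_by_fold(recs) == ["a", "c", "b"]

    def test_ties_break_lexicographically(self):
        recs = [self.fold_rec(g, 1.0) for g in ("c", "a", "b")]
        assert rank_by_fold(recs) == ["a", "b", "c"]

    def test_gene_uses_maximum_fold_across_records(self):
        recs = [
            self.fold_rec("a", 1.0),
            RetentionRecord(gene_id="a", intron_class=FIVE_PRIME_UTR, r=1.0,
                            method="density", fold_vs_control=5.0),
            self.fold_rec("b", 3.0),
        ]
        assert rank_by_fold(recs) == ["a", "b"]

    def test_agrees_with_independent_sort(self, rng):
        folds = rng.random(100)
        recs = [self.fold_rec(f"g{i:03d}", f) for i, f in enumerate(folds)]
        expected = [f"g{i:03d}" for i in np.argsort(-folds, kind="stable")]
        assert rank_by_fold(recs) == expected

    def test_empty_input(self):
        assert rank_by_fold([]) == []


class TestEnrichment:
    def test_exact_tail_example(self):
        # N=10, K=5, n=4, k=4: p = C(5,4)*C(5,0)/C(10,4) = 5/210
        ranked = ["s0", "s1", "s2", "s3", "o0", "s4", "o1", "o2", "o3", "o4"]
        gene_set = {"s0", "s1", "s2", "s3", "s4"}
        res = hypergeom_enrichment(ranked, gene_set, top_n=4)
        assert res.k == 4
        assert res.p == pytest.approx(5 / 210)

    def test_empty_set_gives_p_one(self):
        res = hypergeom_enrichment(["a", "b", "c"], set(), top_n=2)
        assert res.k == 0 and res.K == 0
        assert res.p == 1.0

    def test_top_n_out_of_range(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["a", "b"], {"a"}, top_n=3)

    def test_tail_matches_monte_carlo(self, rng):
        # N=20, K=8, n=6: compare exact tail with draw frequency
        universe = [f"g{i}" for i in range(20)]
        gene_set = set(universe[:8])
        ranked = list(universe)
        rng.shuffle(ranked)
        res = hypergeom_enrichment(ranked, gene_set, top_n=6)
        n_draws = 100_000
        hits = 0
        arr = np.array([g in gene_set for g in universe])
        for _ in range(n_draws):
            k = arr[rng.choice(20, size=6, replace=False)].sum()
            hits += k >= res.k
        mc = hits / n_draws
        se = np.sqrt(mc * (1 - mc) / n_draws)
        assert abs(res.p - mc) < 3 * max(se, 1e-4)


class TestBHAdjust:
    def test_step_up_worked_example(self):
        assert bh_adjust([0.005, 0.04, 0.2]) == pytest.approx([0.015, 0.06, 0.2])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_independent_step_up(self, rng):
        pvals = rng.random(50)
        # independent step-up reimplementation
        order = np.argsort(pvals)
        n = len(pvals)
        adj = np.empty(n)
        prev = 1.0
        for rank_idx in range(n - 1, -1, -1):
            i = order[rank_idx]
            val = min(prev, pvals[i] * n / (rank_idx + 1))
            adj[i] = val
            prev = val
        assert np.allclose(bh_adjust(list(pvals)), adj, atol=1e-12)
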