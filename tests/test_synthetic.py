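"""Generators: determinism, forced cases, and closed-form expectations."""

import numpy as np
import pytest

from isoretain.counting import FIVE_PRIME_UTR, build_counts_table
from isoretain.synthetic import (
    FlowSimParams,
    GradientGrid,
    SimTruth,
    SurvivalSimParams,
    gen_gene_models,
    high_mode_fraction,
    make_grid,
    mixture_median,
    mixture_trough,
    sim_flow_grid,
    sim_reads,
    sim_survival,
)
from isoretain.validation import recovery_gene_models


class TestGenGeneModels:
    def test_forced_utr_intron(self):
        (model,) = gen_gene_models(1, frac_utr_intron=1.0, seed=7)
        utr_introns = [iv for iv in model.introns if iv[2] == FIVE_PRIME_UTR]
        assert len(utr_introns) == 1

    def test_same_seed_identical_output(self):
        a = gen_gene_models(25, seed=13)
        b = gen_gene_models(25, seed=13)
        assert a == b

    def test_different_seed_differs(self):
        assert gen_gene_models(25, seed=13) != gen_gene_models(25, seed=14)

    def test_no_overlaps_anywhere(self):
        models = gen_gene_models(50, seed=1)
        by_chrom = {}
        for m in models:
            lo, hi = m.span
            by_chrom.setdefault(m.chrom, []).append((lo, hi))
            # intra-gene: introns pairwise disjoint (brute force)
            ivs = [(a, b) for a, b, _ in m.introns]
            for i in range(len(ivs)):
                for j in range(i + 1, len(ivs)):
                    assert ivs[i][1] <= ivs[j][0] or ivs[j][1] <= ivs[i][0]
        for spans in by_chrom.values():
            for i in range(len(spans)):
                for j in range(i + 1, len(spans)):
                    a, b = spans[i], spans[j]
                    assert a[1] <= b[0] or b[1] <= a[0]

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gen_gene_models(0)
        with pytest.raises(ValueError):
            gen_gene_models(5, frac_rp=1.5)


class TestSimReads:
    def test_rho_zero_no_single_block_intron_overlap(self):
        models = recovery_gene_models(n_genes=1)
        truth = [SimTruth(gene_id=models[0].gene_id, rho_utr=0.0)]
        reads = sim_reads(models, truth, depth=500.0, seed=1)
        a, b, _ = models[0].introns[0]
        for read in reads:
            if read.contiguous:
                (s, e), = read.blocks
                assert not (s < b and e > a)

    def test_rho_one_no_junction_spanning_reads(self):
        models = recovery_gene_models(n_genes=1)
        truth = [SimTruth(gene_id=models[0].gene_id, rho_utr=1.0)]
        reads = sim_reads(models, truth, depth=500.0, seed=2)
        assert all(read.contiguous for read in reads)

    def test_density_ratio_matches_rho(self):
        """Closed-form: intron/CDS read density ratio approximates rho."""
        rho = 0.3
        models = recovery_gene_models(n_genes=1)
        truth = [SimTruth(gene_id=models[0].gene_id, rho_utr=rho)]
        reads = sim_reads(models, truth, depth=2000.0, seed=3)
        counts = build_counts_table(reads, models, read_length=50)
        gc = counts[models[0].gene_id]
        ratio = (gc.introns[0].count / gc.introns[0].length) / (
            gc.cds_count / gc.cds_length
        )
        n_intron = gc.introns[0].count
        sigma = rho / np.sqrt(n_intron)  # binomial-scale error on the ratio
        assert abs(ratio - rho) < 3 * sigma

    def test_determinism(self):
        models = gen_gene_models(10, seed=5)
        truth = [SimTruth(gene_id=m.gene_id, rho_utr=0.4, rho_cds=0.2)
                 for m in models]
        assert sim_reads(models, truth, depth=100, seed=9) == sim_reads(
            models, truth, depth=100, seed=9
        )

    def test_short_gene_skipped_with_warning(self):
        from isoretain.counting import GeneModel

        tiny = GeneModel(gene_id="tiny", chrom="c", strand="+", cds=(100, 120))
        truth = [SimTruth(gene_id="tiny")]
        with pytest.warns(UserWarning, match="shorter than read length"):
            reads = sim_reads([tiny], truth, depth=1000.0, read_length=500, seed=0,
                              utr5_length=0, utr3_length=0)
        assert reads == []

    def test_block_lengths_sum_to_read_length(self):
        models = gen_gene_models(10, seed=5)
        truth = [SimTruth(gene_id=m.gene_id, rho_utr=0.4, rho_cds=0.2)
                 for m in models]
        for read in sim_reads(models, truth, depth=100, seed=9):
            assert read.read_length == 50


class TestSimFlowGrid:
    def test_logistic_limits(self):
        params = FlowSimParams()
        assert high_mode_fraction(10**4.5, params) > 0.99
        assert high_mode_fraction(params.m_star, params) == pytest.approx(0.5)

    def test_empty_grid_gives_empty_list(self):
        grid = GradientGrid(conc_a=np.array([]), conc_b=np.array([]))
        assert sim_flow_grid(grid, FlowSimParams(n_cells=10), seed=0) == []

    def test_sample_median_matches_analytic(self):
        params = FlowSimParams(n_cells=10_000)
        grid = GradientGrid(conc_a=np.array([0.5]), conc_b=np.array([0.5]))
        (well,) = sim_flow_grid(grid, params, seed=4)
        observed = well.observed()
        se_log = 1.2533 * params.sigma / np.sqrt(params.n_cells)
        # conservative allowance: mixture quantile density is lower than a
        # single component's, widening the median's sampling error
        assert abs(
            np.log10(np.median(observed.values)) - np.log10(well.true_median)
        ) < 5 * se_log

    def test_fraction_above_trough_matches_p(self):
        params = FlowSimParams(n_cells=20_000)
        grid = GradientGrid(conc_a=np.array([0.4]), conc_b=np.array([0.6]))
        (well,) = sim_flow_grid(grid, params, seed=8)
        trough = 10 ** mixture_trough(well.true_p, params)
        frac = float(np.mean(well.observed().values > trough))
        # analytic mass above the trough
        from scipy.stats import norm

        t_log = np.log10(trough)
        p = well.true_p
        expected = p * norm.sf((t_log - params.mu_high) / params.sigma) + (
            1 - p
        ) * norm.sf((t_log - params.mu_low) / params.sigma)
        sigma = np.sqrt(expected * (1 - expected) / params.n_cells)
        assert abs(frac - expected) < 3 * sigma

    def test_truth_median_monotone_in_p(self):
        params = FlowSimParams()
        medians = [mixture_median(p, params) for p in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(a < b for a, b in zip(medians, medians[1:]))
        assert medians[2] == pytest.approx(10**2.0, rel=1e-6)


class TestSimSurvival:
    def test_rate_equal_populations_exchangeable_parameters(self):
        params = SurvivalSimParams(rate_low=0.2, rate_high=0.2)
        table = sim_survival(params, seed=0)
        stats = table.groupby("population")["colonies"].mean()
        # identical rates: means differ only by sampling noise
        assert abs(stats["low"] - stats["high"]) < 5 * np.sqrt(stats.mean())

    def test_zero_cfu0_all_zero(self):
        params = SurvivalSimParams(cfu0=0.0)
        table = sim_survival(params, seed=0)
        assert (table["colonies"] == 0).all()

    def test_mean_matches_poisson_expectation(self):
        params = SurvivalSimParams(
            rate_low=0.1, rate_high=0.1, cfu0=100.0, timepoints=(10.0,),
            replicates=1000,
        )
        table = sim_survival(params, seed=6)
        expected = 100 * np.exp(-1.0)
        se = np.sqrt(expected / 1000)
        sub = table[table["population"] == "low"]
        assert abs(sub["colonies"].mean() - expected) < 3 * se

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SurvivalSimParams(rate_low=-0.1)

    def test_determinism(self):
        params = SurvivalSimParams()
        assert sim_survival(params, seed=3).equals(sim_survival(params, seed=3))


class TestMakeGrid:
    def test_grid_dimensions_and_uniqueness(self):
        grid = make_grid(n_rows=4, n_cols=6, max_a=2.0, max_b=3.0)
        wells = grid.wells
        assert len(wells) == 24
        assert len({w[0] for w in wells}) == 24
        assert max(w[1] for w in wells) == 2.0
        assert max(w[2] for w in wells) == 3.0
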