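"""Ground-truth recovery and calibration studies.

Each function here runs a complete, seeded simulate→analyse experiment and
returns summary numbers, so the same code backs both the test suite and the
reproduction script.  Independent brute-force oracles for the counting and
trough-depth operations also live here: they deliberately use the naive
all-pairs / all-triples formulation so they share no logic with the
production code paths they check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bimodality import grid_bimodality_map, trough_depth
from .counting import (
    CDS,
    FIVE_PRIME_UTR,
    FeatureCountsTable,
    GeneModel,
    ReadRecord,
    build_counts_table,
)
from .growth import fit_growth_rate
from .resampling import poisson_bootstrap_p
from .retention import (
    enrichment_table,
    fold_changes,
    rank_by_fold,
    retention_density,
    retention_table,
)
from .synthetic import (
    FlowSimParams,
    SimTruth,
    SurvivalSimParams,
    gen_gene_models,
    make_grid,
    mixture_median,
    sim_flow_grid,
    sim_growth_curves,
    sim_reads,
    sim_survival,
)

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_counts(
    reads: list[ReadRecord], models: list[GeneModel]
) -> FeatureCountsTable:
    """All-pairs overlap counting: every read against every feature.

    O(reads x features) full boolean matrix; independent of the grouped
    per-chromosome implementation in :mod:`isoretain.counting`.
    """
    table = FeatureCountsTable(genes={})
    from .counting import GeneCounts, IntronCounts

    for model in models:
        gc = GeneCounts(
            gene_id=model.gene_id,
            strand=model.strand,
            cds_length=model.cds_exonic_length,
            labels=model.labels,
        )
        for read in reads:
            if read.chrom != model.chrom:
                continue
            if any(
                bs < pe and be > ps
                for bs, be in read.blocks
                for ps, pe in model.cds_parts
            ):
                gc.cds_count += 1
        for a, b, klass in model.sorted_introns:
            ic = IntronCounts(interval=(a, b), klass=klass)
            for read in reads:
                if read.chrom != model.chrom:
                    continue
                if any(bs < b and be > a for bs, be in read.blocks):
                    ic.count += 1
                if read.contiguous:
                    (bs, be), = read.blocks
                    left = bs < a < be
                    right = bs < b < be
                    n5, n3 = (left, right) if model.strand == "+" else (right, left)
                    ic.n5 += int(n5)
                    ic.n3 += int(n3)
            gc.introns.append(ic)
        table.genes[model.gene_id] = gc
    return table


def brute_force_trough_depth(freqs: np.ndarray) -> float:
    """Exhaustive scan over every (left peak, trough, right peak) bin triple."""
    freqs = np.asarray(freqs, dtype=float)
    n = freqs.size
    best = 0.0
    for t in range(1, n - 1):
        for i in range(t):
            for j in range(t + 1, n):
                depth = min(freqs[i], freqs[j]) - freqs[t]
                if depth > best:
                    best = depth
    return best


# ---------------------------------------------------------------------------
# retention-rate recovery
# ---------------------------------------------------------------------------

def recovery_gene_models(
    n_genes: int = 3, intron_length: int = 1500, cds_length: int = 1500
) -> list[GeneModel]:
    """Calibration genes for the estimator-recovery benchmark.

    One 5'UTR intron per gene with intron length equal to the (contiguous)
    CDS length, so the read-length edge effect on start positions is
    identical for both features and cancels in the density ratio.  One gene
    per toy chromosome keeps counting trivial to reason about.
    """
    models = []
    for g in range(n_genes):
        start = 1000
        utr1 = (start, start + 200)
        intron = (utr1[1], utr1[1] + intron_length)
        utr2 = (intron[1], intron[1] + 100)
        cds = (utr2[1], utr2[1] + cds_length)
        models.append(
            GeneModel(
                gene_id=f"cal{g:02d}",
                chrom=f"chr_cal_{g}",
                strand="+",
                cds=cds,
                introns=((intron[0], intron[1], FIVE_PRIME_UTR),),
            )
        )
    return models


@dataclass
class RecoveryResult:
    rhos: np.ndarray
    bias: np.ndarray  # per rho, over seeds
    rmse: np.ndarray
    slope: float
    intercept: float
    n_points: int
    expected_intron_reads: float  # at the smallest nonzero rho


def retention_recovery(
    seed: int = 0,
    rhos: np.ndarray | None = None,
    n_seeds: int = 20,
    n_genes: int = 3,
    depth: float = 1300.0,
    read_length: int = 50,
) -> RecoveryResult:
    """Density-estimator recovery over a retention-fraction grid.

    For every rho in the grid and every replicate seed, reads are simulated
    from the calibration genes, counted, and the density estimate compared
    to the generating rho.  The default depth puts ~200 expected intron
    reads per gene at rho = 0.1.
    """
    if rhos is None:
        rhos = np.round(np.arange(0.0, 1.01, 0.1), 10)
    models = recovery_gene_models(n_genes=n_genes)
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=n_seeds)
    estimates = np.zeros((len(rhos), n_seeds))
    for i, rho in enumerate(rhos):
        truth = [
            SimTruth(gene_id=m.gene_id, rho_utr=float(rho), abundance=1.0)
            for m in models
        ]
        for j, s in enumerate(sub_seeds):
            reads = sim_reads(models, truth, depth=depth, read_length=read_length,
                              seed=int(s) + i)
            counts = build_counts_table(reads, models, read_length=read_length)
            per_gene = []
            for m in models:
                recs = retention_density(counts, m.gene_id, FIVE_PRIME_UTR)
                per_gene.extend(rec.r for rec in recs)
            estimates[i, j] = float(np.mean(per_gene))
    bias = estimates.mean(axis=1) - rhos
    rmse = np.sqrt(((estimates - rhos[:, None]) ** 2).mean(axis=1))
    xs = np.repeat(rhos, n_seeds)
    ys = estimates.ravel()
    slope, intercept = np.polyfit(xs, ys, 1)
    li = 1500  # matches recovery_gene_models default
    exp_reads = depth / 1000.0 * min(r for r in rhos if r > 0) * (li + read_length - 1)
    return RecoveryResult(
        rhos=np.asarray(rhos),
        bias=bias,
        rmse=rmse,
        slope=float(slope),
        intercept=float(intercept),
        n_points=len(rhos) * n_seeds,
        expected_intron_reads=float(exp_reads),
    )


# ---------------------------------------------------------------------------
# counting oracle equivalence
# ---------------------------------------------------------------------------

def random_counting_instance(
    rng: np.random.Generator,
    max_reads: int = 10_000,
    max_genes: int = 33,
) -> tuple[list[ReadRecord], list[GeneModel]]:
    """A random (possibly overlapping) annotation plus random reads."""
    n_genes = int(rng.integers(1, max_genes + 1))
    chroms = [f"c{k}" for k in range(int(rng.integers(1, 4)))]
    models = []
    for g in range(n_genes):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        cds_start = int(rng.integers(0, 5000))
        cds_len = int(rng.integers(100, 2000))
        cds = (cds_start, cds_start + cds_len)
        introns = []
        if rng.random() < 0.7:  # CDS intron strictly inside the span
            margin = max(10, cds_len // 10)
            a = int(rng.integers(cds_start + margin, cds_start + cds_len - margin - 20))
            b = a + int(rng.integers(20, max(21, cds_len // 3)))
            b = min(b, cds_start + cds_len - margin)
            if b > a:
                introns.append((a, b, CDS))
        if rng.random() < 0.5:  # 5'UTR intron left of the span
            b = cds_start - int(rng.integers(5, 200))
            a = b - int(rng.integers(20, 400))
            if a > 0:
                introns.append((a, b, FIVE_PRIME_UTR))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(
            GeneModel(
                gene_id=f"r{g}", chrom=chrom, strand=strand, cds=cds,
                introns=tuple(introns),
            )
        )
    n_reads = int(10 ** rng.uniform(1.5, np.log10(max_reads)))
    reads = []
    for _ in range(n_reads):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, 7000))
        if rng.random() < 0.8:
            reads.append(ReadRecord(chrom=chrom, blocks=((start, start + 50),)))
        else:
            l1 = int(rng.integers(5, 46))
            gap = int(rng.integers(20, 500))
            s2 = start + l1 + gap
            reads.append(
                ReadRecord(chrom=chrom, blocks=((start, start + l1), (s2, s2 + 50 - l1)))
            )
    return reads, models


def counting_oracle_check(seed: int = 0, n_instances: int = 100) -> int:
    """Number of count mismatches vs the all-pairs oracle (0 = exact agreement)."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_instances):
        reads, models = random_counting_instance(rng)
        fast = build_counts_table(reads, models)
        slow = brute_force_counts(reads, models)
        for gid in fast.genes:
            f, s = fast[gid], slow[gid]
            if f.cds_count != s.cds_count:
                mismatches += 1
            for fi, si in zip(f.introns, s.introns):
                if (fi.count, fi.n5, fi.n3) != (si.count, si.n5, si.n3):
                    mismatches += 1
    return mismatches


# ---------------------------------------------------------------------------
# trough-depth oracle equivalence
# ---------------------------------------------------------------------------

def random_histogram(rng: np.random.Generator, n_bins: int = 40) -> np.ndarray:
    """Random non-negative frequency vector, occasionally sparse."""
    freqs = rng.random(n_bins)
    if rng.random() < 0.3:
        freqs[rng.random(n_bins) < 0.5] = 0.0
    total = freqs.sum()
    return freqs / total if total > 0 else freqs


def random_unimodal_histogram(rng: np.random.Generator, n_bins: int = 40) -> np.ndarray:
    """Random single-peak shape: increasing then decreasing."""
    peak = int(rng.integers(0, n_bins))
    left = np.sort(rng.random(peak))
    right = np.sort(rng.random(n_bins - peak))[::-1]
    freqs = np.concatenate([left, right])
    return freqs / freqs.sum()


def trough_oracle_check(
    seed: int = 0, n_random: int = 500, n_unimodal: int = 1000
) -> tuple[int, int]:
    """(mismatches vs triple-scan oracle, nonzero depths on unimodal shapes)."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_random):
        freqs = random_histogram(rng)
        d_fast = trough_depth(freqs, smooth_window=1).d
        d_slow = brute_force_trough_depth(freqs)
        if np.count_nonzero(freqs) < 3:
            d_slow = 0.0  # guard shared by definition
        if abs(d_fast - d_slow) > 1e-12:
            mismatches += 1
    unimodal_nonzero = 0
    for _ in range(n_unimodal):
        freqs = random_unimodal_histogram(rng)
        if trough_depth(freqs, smooth_window=1).d != 0.0:
            unimodal_nonzero += 1
    return mismatches, unimodal_nonzero


# ---------------------------------------------------------------------------
# bimodality-peak recovery
# ---------------------------------------------------------------------------

@dataclass
class PeakRecoveryResult:
    hits: int
    n_seeds: int
    m_star_median: float
    tolerance: float
    peaks: list[float]


def bimodality_peak_recovery(
    seed: int = 0,
    n_seeds: int = 20,
    n_rows: int = 24,
    n_cols: int = 24,
    n_cells: int = 2000,
    smooth_window: int = 5,
    running_window: int = 30,
) -> PeakRecoveryResult:
    """Does the pooled depth-vs-median curve peak at the p = 0.5 median?

    The generating mixture's analytic median at p = 0.5 is the ground
    truth; the tolerance is one inter-well spacing of the distinct true
    medians around that point.
    """
    params = FlowSimParams(n_cells=n_cells)
    grid = make_grid(n_rows=n_rows, n_cols=n_cols)
    m_half = mixture_median(0.5, params)

    # distinct true medians across the grid (dose ramp levels), for spacing
    wells0 = sim_flow_grid(grid, params, seed=seed)
    uniq = np.unique([w.true_median for w in wells0])
    below = uniq[uniq < m_half]
    above = uniq[uniq > m_half]
    spacing = max(
        m_half - below.max() if below.size else 0.0,
        above.min() - m_half if above.size else 0.0,
    )

    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=n_seeds)
    peaks = []
    hits = 0
    for s in sub_seeds:
        wells = sim_flow_grid(grid, params, seed=int(s))
        observed = [w.observed() for w in wells]
        _, _, m_peak = grid_bimodality_map(
            observed, smooth_window=smooth_window, running_window=running_window
        )
        peaks.append(float("nan") if m_peak is None else m_peak)
        if m_peak is not None and abs(m_peak - m_half) <= spacing:
            hits += 1
    return PeakRecoveryResult(
        hits=hits,
        n_seeds=n_seeds,
        m_star_median=m_half,
        tolerance=float(spacing),
        peaks=peaks,
    )


# ---------------------------------------------------------------------------
# bootstrap calibration and power
# ---------------------------------------------------------------------------

def bootstrap_type1_rate(
    seed: int = 0,
    n_datasets: int = 500,
    n_surrogates: int = 2000,
    alpha: float = 0.05,
) -> float:
    """Two-sided rejection rate under the bootstrap's own null."""
    null_params = SurvivalSimParams(
        rate_low=0.2, rate_high=0.2, cfu0=100.0, timepoints=(0.0, 2.0, 4.0, 6.0),
        replicates=2,
    )
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=n_datasets)
    rejections = 0
    for s in sub_seeds:
        table = sim_survival(null_params, seed=int(s))
        res = poisson_bootstrap_p(table, n_surrogates=n_surrogates, seed=int(s) + 1)
        if res.p_two_sided <= alpha:
            rejections += 1
    return rejections / n_datasets


def bootstrap_power(
    seed: int = 0, n_runs: int = 100, n_surrogates: int = 2000
) -> float:
    """Fraction of strong-effect runs with two-sided p < 0.01."""
    params = SurvivalSimParams()  # defaults are the strong-effect scenario
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=n_runs)
    hits = 0
    for s in sub_seeds:
        table = sim_survival(params, seed=int(s))
        res = poisson_bootstrap_p(table, n_surrogates=n_surrogates, seed=int(s) + 1)
        if res.p_two_sided < 0.01:
            hits += 1
    return hits / n_runs


# ---------------------------------------------------------------------------
# end-to-end enrichment
# ---------------------------------------------------------------------------

def _condition_truth(
    models: list[GeneModel], rng: np.random.Generator, stressed: bool
) -> list[SimTruth]:
    truth = []
    for m in models:
        if stressed and "RP" in m.labels:
            rho = float(rng.uniform(0.4, 0.7))
        elif stressed:
            rho = float(rng.uniform(0.02, 0.12))
        else:
            rho = float(rng.uniform(0.02, 0.08))
        truth.append(
            SimTruth(gene_id=m.gene_id, rho_utr=rho, rho_cds=rho, abundance=1.0)
        )
    return truth


def enrichment_success_rate(
    seed: int = 0,
    n_runs: int = 100,
    n_genes: int = 100,
    depth: float = 400.0,
    n_decoys: int = 5,
) -> float:
    """Fraction of runs where the RP set has the smallest adjusted p.

    A stress-like condition raises the retention fraction of RP-labelled
    genes only; records are fold-normalized to a no-stress control, genes
    ranked, and the RP set competes against size-matched random decoy sets.
    """
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=n_runs)
    successes = 0
    for s in sub_seeds:
        rng = np.random.default_rng(int(s))
        models = gen_gene_models(
            n_genes=n_genes, frac_rp=0.2, frac_utr_intron=0.4, seed=int(s),
            frac_cds_intron=0.6,
        )
        control_truth = _condition_truth(models, rng, stressed=False)
        treated_truth = _condition_truth(models, rng, stressed=True)
        control_reads = sim_reads(models, control_truth, depth=depth, seed=int(s) + 1)
        treated_reads = sim_reads(models, treated_truth, depth=depth, seed=int(s) + 2)
        control_counts = build_counts_table(control_reads, models)
        treated_counts = build_counts_table(treated_reads, models)
        control_recs, _ = retention_table(control_counts, method="density")
        treated_recs, _ = retention_table(treated_counts, method="density")
        folds = fold_changes(treated_recs, control_recs)
        ranked = rank_by_fold(folds)
        if not ranked:
            continue
        rp_set = {m.gene_id for m in models if "RP" in m.labels} & set(ranked)
        if not rp_set:
            continue
        universe = list(ranked)
        sets = {"RP": rp_set}
        for d in range(n_decoys):
            decoy = rng.choice(universe, size=min(len(rp_set), len(universe)),
                               replace=False)
            sets[f"decoy{d}"] = set(decoy.tolist())
        top_n = max(1, len(ranked) // 10)
        results = enrichment_table(ranked, sets, top_n=top_n)
        best = min(results, key=lambda r: (r.p_adj, r.p, r.set_name != "RP"))
        if best.set_name == "RP":
            successes += 1
    return successes / n_runs


# ---------------------------------------------------------------------------
# growth-rate recovery
# ---------------------------------------------------------------------------

def growth_rate_recovery(
    seed: int = 0, n_seeds: int = 20, rate_true: float = 0.35, noise_sd: float = 0.002
) -> tuple[float, float]:
    """(noiseless |error|, mean |error| over noisy logistic curves)."""
    noiseless = sim_growth_curves(
        rate_true=0.4, od0=0.005, capacity=float("inf"), background=0.0,
        noise_sd=0.0, seed=0,
    )
    fit0 = fit_growth_rate(noiseless, 0.01, 1.0)
    err0 = abs(fit0.rate - 0.4)
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=n_seeds)
    errs = []
    for s in sub_seeds:
        curve = sim_growth_curves(
            rate_true=rate_true, od0=0.005, capacity=1.4, background=0.04,
            noise_sd=noise_sd, seed=int(s),
        )
        curve.background = None  # exercise background estimation
        fit = fit_growth_rate(curve, 0.02, 0.2)
        errs.append(abs(fit.rate - rate_true))
    return float(err0), float(np.mean(errs))
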