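"""Seeded synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here, so the estimators
are testable against a known latent state without any external download:

* toy gene models with classified introns and an optional "RP" label,
* single-end reads drawn from a mixture of spliced and intron-retained
  isoforms at a known per-intron retention fraction rho,
* per-well flow-cytometry samples from a two-component log-normal mixture
  whose high-mode fraction is a logistic function of the dose-driven target
  median (emulating bimodality that peaks at an intermediate median level),
* colony counts decaying exponentially with Poisson plating noise,
* logistic OD growth curves with background offset and Gaussian noise.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .counting import CDS, FIVE_PRIME_UTR, GeneModel, ReadRecord
from .growth import GrowthCurve

logger = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 50  # single-end 50 bp, the primary library layout
GENES_PER_CHROM = 16


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimTruth:
    """Latent state per gene: retention fractions and expression level."""

    gene_id: str
    rho_utr: float = 0.0
    rho_cds: float = 0.0
    abundance: float = 1.0

    def __post_init__(self) -> None:
        for rho in (self.rho_utr, self.rho_cds):
            if not 0.0 <= rho <= 1.0:
                raise ValueError("retention fractions must lie in [0, 1]")
        if not self.abundance > 0:
            raise ValueError("abundance must be positive")

    def rho_for(self, klass: str) -> float:
        return self.rho_utr if klass == FIVE_PRIME_UTR else self.rho_cds


@dataclass
class FlowSimParams:
    """Two-component log10-normal expression mixture across a dose grid.

    ``m_star`` is the median level of maximal bimodality (the putative
    unstable fixed point); the high-mode fraction of a well is
    p = logistic((log10 m_target - log10 m_star) / slope).
    """

    mu_low: float = 1.0  # log10 fluorescence mean, low mode
    mu_high: float = 3.0
    sigma: float = 0.25  # common log10 s.d.
    m_star: float = 100.0  # 10 ** ((mu_low + mu_high) / 2) by default
    slope: float = 0.25  # logistic steepness on the log10 scale
    n_cells: int = 10_000
    fsc_mu: float = 5.0  # log10 forward-scatter location
    fsc_sigma: float = 0.1
    dose_response: Callable[[float, float], float] | None = None

    def __post_init__(self) -> None:
        if not self.mu_low < self.mu_high:
            raise ValueError("mu_low must be below mu_high")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass(frozen=True)
class SurvivalSimParams:
    """Exponentially decaying CFU counts for two sorted populations."""

    rate_low: float = 0.05  # death rate per hour, low-expression population
    rate_high: float = 0.5
    cfu0: float = 200.0
    timepoints: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0)
    replicates: int = 2

    def __post_init__(self) -> None:
        if self.rate_low < 0 or self.rate_high < 0:
            raise ValueError("death rates must be non-negative")
        if self.cfu0 < 0:
            raise ValueError("cfu0 must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.timepoints:
            raise ValueError("timepoints must be non-empty")


@dataclass
class GradientGrid:
    """Rows x cols of (concA, concB) well coordinates."""

    conc_a: np.ndarray  # per-row drug A concentration
    conc_b: np.ndarray  # per-column drug B concentration

    def __post_init__(self) -> None:
        self.conc_a = np.asarray(self.conc_a, dtype=float)
        self.conc_b = np.asarray(self.conc_b, dtype=float)
        if (self.conc_a < 0).any() or (self.conc_b < 0).any():
            raise ValueError("concentrations must be non-negative")

    @property
    def wells(self) -> list[tuple[str, float, float]]:
        out = []
        for i, ca in enumerate(self.conc_a):
            for j, cb in enumerate(self.conc_b):
                out.append((f"r{i:02d}c{j:02d}", float(ca), float(cb)))
        return out


def make_grid(
    n_rows: int = 24, n_cols: int = 24, max_a: float = 1.0, max_b: float = 1.0
) -> GradientGrid:
    return GradientGrid(
        conc_a=np.linspace(0.0, max_a, n_rows),
        conc_b=np.linspace(0.0, max_b, n_cols),
    )


@dataclass
class SimulatedWell:
    """Raw flow channels plus the generating truth for one well."""

    well_id: str
    conc_a: float
    conc_b: float
    fitc: np.ndarray
    fsc: np.ndarray
    true_p: float  # generating high-mode fraction
    true_median: float  # analytic median of the generating mixture
    target_median: float  # dose-response target fed to the logistic

    def observed(self):
        """FSC-normalized WellDistribution, exercising the normalization step."""
        from .bimodality import WellDistribution, normalize_fluorescence

        values, _ = normalize_fluorescence(self.fitc, self.fsc)
        return WellDistribution(
            well_id=self.well_id,
            conc_a=self.conc_a,
            conc_b=self.conc_b,
            values=values,
        )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def gen_gene_models(
    n_genes: int,
    frac_rp: float = 0.15,
    frac_utr_intron: float = 0.4,
    seed: int = 0,
    *,
    frac_cds_intron: float = 0.5,
    cds_length: tuple[int, int] = (600, 3000),
    intron_length: tuple[int, int] = (100, 600),
    utr_exon_lengths: tuple[int, int] = (150, 80),
    gap: tuple[int, int] = (200, 800),
) -> list[GeneModel]:
    """Non-overlapping toy gene models on one or more chromosomes.

    Each gene carries a CDS span and at most one 5'UTR intron (probability
    ``frac_utr_intron``) plus at most one CDS intron (``frac_cds_intron``);
    a ``frac_rp`` subset is tagged "RP" for enrichment tests.  Genes are
    laid out left to right with random gaps, ``GENES_PER_CHROM`` per toy
    chromosome, so non-overlap holds by construction.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for name, frac in (
        ("frac_rp", frac_rp),
        ("frac_utr_intron", frac_utr_intron),
        ("frac_cds_intron", frac_cds_intron),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    models: list[GeneModel] = []
    utr1_len, utr2_len = utr_exon_lengths
    for g in range(n_genes):
        chrom = f"chr_sim_{g // GENES_PER_CHROM + 1}"
        if g % GENES_PER_CHROM == 0:
            cursor = 1000
        has_utr_intron = rng.random() < frac_utr_intron
        has_cds_intron = rng.random() < frac_cds_intron
        is_rp = rng.random() < frac_rp
        strand = "+" if rng.random() < 0.5 else "-"
        lc = int(rng.integers(cds_length[0], cds_length[1] + 1))
        li_utr = int(rng.integers(intron_length[0], intron_length[1] + 1))
        li_cds = int(rng.integers(intron_length[0], intron_length[1] + 1))

        # Build the transcribed layout 5'->3', then place genomically.
        segments: list[tuple[int, str]] = []  # (length, role)
        if has_utr_intron:
            segments += [(utr1_len, "utr_exon"), (li_utr, "utr_intron")]
        segments += [(utr2_len, "utr_exon")]
        if has_cds_intron:
            half = lc // 2
            segments += [(half, "cds"), (li_cds, "cds_intron"), (lc - half, "cds")]
        else:
            segments += [(lc, "cds")]
        if strand == "-":
            segments = segments[::-1]

        pos = cursor
        cds_lo = cds_hi = None
        introns = []
        for length, role in segments:
            iv = (pos, pos + length)
            if role == "cds":
                cds_lo = iv[0] if cds_lo is None else cds_lo
                cds_hi = iv[1]
            elif role == "utr_intron":
                introns.append((iv[0], iv[1], FIVE_PRIME_UTR))
            elif role == "cds_intron":
                introns.append((iv[0], iv[1], CDS))
            pos += length
        models.append(
            GeneModel(
                gene_id=f"g{g:04d}",
                chrom=chrom,
                strand=strand,
                cds=(cds_lo, cds_hi),
                introns=tuple(introns),
                labels=frozenset({"RP"}) if is_rp else frozenset(),
            )
        )
        cursor = pos + int(rng.integers(gap[0], gap[1] + 1))
    return models


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _kept_segments(
    model: GeneModel,
    spliced_out: list[tuple[int, int]],
    utr5_length: int = 0,
    utr3_length: int = 0,
) -> list[tuple[int, int]]:
    """Genomic segments of an isoform, merging genomically contiguous pieces.

    The annotated span (CDS hull plus introns) is extended by stylized UTR
    exons on both sides: a 5'UTR intron is always flanked by UTR exon, and
    transcripts run past the stop codon.
    """
    lo, hi = model.span
    ext_left = utr5_length if model.strand == "+" else utr3_length
    ext_right = utr3_length if model.strand == "+" else utr5_length
    lo = max(0, lo - ext_left)
    hi = hi + ext_right
    segs: list[tuple[int, int]] = []
    pos = lo
    for a, b in sorted(spliced_out):
        if a > pos:
            segs.append((pos, a))
        pos = b
    if hi > pos:
        segs.append((pos, hi))
    return segs


def _blocks_for_read(
    start: int, read_length: int, segs: list[tuple[int, int]], cum: np.ndarray
) -> tuple[tuple[int, int], ...]:
    """Map a transcript-coordinate read to genomic blocks."""
    end = start + read_length
    blocks = []
    for k, (gs, ge) in enumerate(segs):
        s = max(start, int(cum[k]))
        e = min(end, int(cum[k + 1]))
        if e > s:
            blocks.append((gs + s - int(cum[k]), gs + e - int(cum[k])))
    return tuple(blocks)


def sim_reads(
    models: list[GeneModel],
    truth: list[SimTruth],
    depth: float,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int = 0,
    utr5_length: int = 100,
    utr3_length: int = 100,
) -> list[ReadRecord]:
    """Single-end reads from a spliced/retained isoform mixture.

    Per gene, each intron is retained independently with its truth
    retention fraction; read starts are uniform along the chosen isoform at
    a per-start-position rate of ``depth * abundance / 1000`` (so ``depth``
    is the expected read count per kilobase of isoform at unit abundance).
    The transcript extends past the annotated span (CDS hull plus introns)
    by stylized UTR exons of ``utr5_length`` and ``utr3_length`` bases, so
    features near the transcript ends get the same read-start allowance as
    interior ones.  Reads from spliced isoforms that cross a junction
    become multi-block records; reads inside retained regions stay
    single-block.  Genes whose shortest isoform is shorter than the read
    length are skipped with a warning.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if depth <= 0:
        raise ValueError("depth must be positive")
    truth_by_gene = {t.gene_id: t for t in truth}
    missing = [m.gene_id for m in models if m.gene_id not in truth_by_gene]
    if missing:
        raise ValueError(f"no truth for genes: {missing[:5]}")
    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    for model in models:
        t = truth_by_gene[model.gene_id]
        introns = model.sorted_introns
        rate = depth * t.abundance / 1000.0
        # enumerate retention configurations over this gene's introns
        n_i = len(introns)
        for config in range(2**n_i):
            prob = 1.0
            spliced_out = []
            for bit, (a, b, klass) in enumerate(introns):
                rho = t.rho_for(klass)
                if config >> bit & 1:  # retained
                    prob *= rho
                else:
                    prob *= 1.0 - rho
                    spliced_out.append((a, b))
            if prob == 0.0:
                continue
            segs = _kept_segments(
                model, spliced_out, utr5_length=utr5_length, utr3_length=utr3_length
            )
            lengths = np.array([e - s for s, e in segs], dtype=np.int64)
            total = int(lengths.sum())
            if total < read_length:
                warnings.warn(
                    f"gene {model.gene_id}: isoform shorter than read length; skipped",
                    stacklevel=2,
                )
                continue
            cum = np.concatenate([[0], np.cumsum(lengths)])
            n_starts = total - read_length + 1
            n_reads = rng.poisson(rate * prob * n_starts)
            if n_reads == 0:
                continue
            starts = rng.integers(0, n_starts, size=n_reads)
            ends = starts + read_length
            i0 = np.searchsorted(cum, starts, side="right") - 1
            i1 = np.searchsorted(cum, ends - 1, side="right") - 1
            single = i0 == i1
            gs = np.array([s for s, _ in segs], dtype=np.int64)
            off = starts[single] - cum[i0[single]]
            for seg_idx, o in zip(i0[single], off):
                s = int(gs[seg_idx] + o)
                reads.append(ReadRecord(chrom=model.chrom, blocks=((s, s + read_length),)))
            for s0 in starts[~single]:
                reads.append(
                    ReadRecord(
                        chrom=model.chrom,
                        blocks=_blocks_for_read(int(s0), read_length, segs, cum),
                    )
                )
    return reads


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------

def logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def high_mode_fraction(target_median: float, params: FlowSimParams) -> float:
    """p = logistic((log10 m - log10 m_star) / slope)."""
    return float(
        logistic((np.log10(target_median) - np.log10(params.m_star)) / params.slope)
    )


def mixture_median(p: float, params: FlowSimParams) -> float:
    """Analytic median of the two-component log10-normal mixture."""
    if p <= 0:
        return float(10**params.mu_low)
    if p >= 1:
        return float(10**params.mu_high)

    def cdf_minus_half(x: float) -> float:
        return (
            p * norm.cdf((x - params.mu_high) / params.sigma)
            + (1 - p) * norm.cdf((x - params.mu_low) / params.sigma)
            - 0.5
        )

    lo = params.mu_low - 8 * params.sigma
    hi = params.mu_high + 8 * params.sigma
    return float(10 ** brentq(cdf_minus_half, lo, hi))


def mixture_trough(p: float, params: FlowSimParams) -> float:
    """log10 location of the mixture density minimum between the two modes."""
    from scipy.optimize import minimize_scalar

    def pdf(x: float) -> float:
        return p * norm.pdf(x, params.mu_high, params.sigma) + (1 - p) * norm.pdf(
            x, params.mu_low, params.sigma
        )

    res = minimize_scalar(pdf, bounds=(params.mu_low, params.mu_high), method="bounded")
    return float(res.x)


def linear_log_dose_response(
    grid: GradientGrid, params: FlowSimParams
) -> Callable[[float, float], float]:
    """Default dose map: target log10-median falls linearly with total dose.

    The drug-free well targets mu_high, the doubly-max-dosed well mu_low,
    i.e. stress monotonically lowers the expression target.
    """
    max_a = float(grid.conc_a.max()) if grid.conc_a.size and grid.conc_a.max() > 0 else 1.0
    max_b = float(grid.conc_b.max()) if grid.conc_b.size and grid.conc_b.max() > 0 else 1.0

    def dose_response(ca: float, cb: float) -> float:
        u = 0.5 * (ca / max_a + cb / max_b)
        mu = params.mu_high - (params.mu_high - params.mu_low) * u
        return float(10**mu)

    return dose_response


def sim_flow_grid(
    grid: GradientGrid, params: FlowSimParams, seed: int = 0
) -> list[SimulatedWell]:
    """Simulate per-well flow-cytometry samples over a two-drug gradient.

    Per well the dose response sets a target median, the logistic sets the
    high-mode fraction p, and cells are drawn from the log10-normal mixture.
    FITC is the expression value multiplied by an independently log-normal
    forward scatter, so downstream FITC/FSC normalization recovers the
    expression distribution exactly.
    """
    dose_response = params.dose_response or linear_log_dose_response(grid, params)
    rng = np.random.default_rng(seed)
    wells = []
    for well_id, ca, cb in grid.wells:
        target = dose_response(ca, cb)
        p = high_mode_fraction(target, params)
        comp = rng.random(params.n_cells) < p
        mu = np.where(comp, params.mu_high, params.mu_low)
        log_expr = rng.normal(mu, params.sigma)
        fsc = 10 ** rng.normal(params.fsc_mu, params.fsc_sigma, params.n_cells)
        fitc = 10**log_expr * fsc
        wells.append(
            SimulatedWell(
                well_id=well_id,
                conc_a=ca,
                conc_b=cb,
                fitc=fitc,
                fsc=fsc,
                true_p=p,
                true_median=mixture_median(p, params),
                target_median=target,
            )
        )
    return wells


# ---------------------------------------------------------------------------
# survival and growth
# ---------------------------------------------------------------------------

def sim_survival(params: SurvivalSimParams, seed: int = 0) -> pd.DataFrame:
    """CFU counts: Poisson(cfu0 * exp(-rate_pop * t)) per replicate."""
    rng = np.random.default_rng(seed)
    rows = []
    for pop, rate in (("low", params.rate_low), ("high", params.rate_high)):
        for t in params.timepoints:
            lam = params.cfu0 * np.exp(-rate * t)
            counts = rng.poisson(lam, size=params.replicates)
            for rep, c in enumerate(counts):
                rows.append(
                    {
                        "population": pop,
                        "timepoint_h": float(t),
                        "replicate": rep,
                        "colonies": int(c),
                    }
                )
    return pd.DataFrame(rows)


def sim_growth_curves(
    rate_true: float,
    od0: float = 0.005,
    capacity: float = 1.5,
    background: float = 0.04,
    noise_sd: float = 0.002,
    times: np.ndarray | None = None,
    seed: int = 0,
    well_id: str = "sim",
) -> GrowthCurve:
    """Logistic OD trajectory plus background offset and Gaussian noise.

    An infinite capacity gives a pure exponential.  The returned curve has
    ``background`` filled in, so fits can use the exact offset; pass
    ``background=None`` downstream to exercise background estimation.
    """
    if times is None:
        times = np.arange(0.0, 16.0, 0.25)
    times = np.asarray(times, dtype=float)
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if np.isfinite(capacity) and not od0 < capacity:
        raise ValueError("od0 must be below capacity")
    rng = np.random.default_rng(seed)
    if np.isinf(capacity):
        od = od0 * np.exp(rate_true * times)
    else:
        od = capacity / (1.0 + (capacity / od0 - 1.0) * np.exp(-rate_true * times))
    od = od + background + rng.normal(0.0, noise_sd, times.size) if noise_sd > 0 else od + background
    return GrowthCurve(well_id=well_id, times=times, od=od, background=background)
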