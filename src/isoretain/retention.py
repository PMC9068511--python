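"""Intron-retention statistics, control normalization and set enrichment.

The retention rate r of an intron is the ratio of its read density to the
read density of the host gene's exonic CDS:

    r = (I / L_I) / (C / L_C)          (density estimator)

where I and C are read counts and L_I, L_C feature lengths.  Genes with
several CDS introns pool them into one joint record (counts and lengths are
summed); each 5'UTR intron is scored separately.  The junction variant uses
contiguous reads spanning the two intron boundaries instead of the intron
body:

    r = ((n5 + n3) / 2 / read_length) / (C / L_C)

Treated rates are normalized to a no-stress control as a pseudocounted fold
change, genes are ranked by fold change, and label sets (e.g. ribosomal
protein genes) are tested for enrichment in the top of the ranking with a
hypergeometric tail probability, Benjamini–Hochberg corrected across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .counting import CDS, FIVE_PRIME_UTR, FeatureCountsTable
from .errors import InvalidPairingError, UndefinedRateError

DEFAULT_PSEUDOCOUNT_SCALE = 1e-3


@dataclass(frozen=True)
class RetentionRecord:
    gene_id: str
    intron_class: str
    r: float
    method: str  # "density" | "junction"
    intron_index: int | None = None  # set for per-intron (5'UTR / junction) records
    fold_vs_control: float | None = None

    @property
    def key(self) -> tuple:
        return (self.gene_id, self.intron_class, self.method, self.intron_index)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float | None = None


def density_rate(
    intron_count: float, intron_length: float, cds_count: float, cds_length: float
) -> float:
    """r = (I/L_I) / (C/L_C); undefined when the CDS has no reads."""
    if intron_length <= 0 or cds_length <= 0:
        raise ValueError("feature lengths must be positive")
    if cds_count <= 0:
        raise UndefinedRateError("CDS count is zero; retention rate undefined")
    return (intron_count / intron_length) / (cds_count / cds_length)


def junction_rate(
    n5: float, n3: float, read_length: int, cds_count: float, cds_length: float
) -> float:
    """r = ((n5+n3)/2 / read_length) / (C/L_C)."""
    if read_length < 2:
        raise ValueError("read_length must be >= 2")
    if cds_length <= 0:
        raise ValueError("cds_length must be positive")
    if cds_count <= 0:
        raise UndefinedRateError("CDS count is zero; retention rate undefined")
    boundary_density = ((n5 + n3) / 2.0) / read_length
    return boundary_density / (cds_count / cds_length)


def retention_density(
    counts: FeatureCountsTable, gene_id: str, intron_class: str
) -> list[RetentionRecord]:
    """Density-estimator records for one gene and intron class.

    CDS introns are treated jointly (one record); 5'UTR introns separately
    (one record per intron, indexed in genomic order).
    """
    gc = counts[gene_id]
    introns = gc.introns_of_class(intron_class)
    if not introns:
        return []
    if gc.cds_count <= 0:
        raise UndefinedRateError(f"{gene_id}: CDS count is zero")
    if intron_class == CDS:
        total = sum(ic.count for ic in introns)
        length = sum(ic.length for ic in introns)
        r = density_rate(total, length, gc.cds_count, gc.cds_length)
        return [RetentionRecord(gene_id, CDS, r, "density")]
    records = []
    for ic in introns:
        idx = gc.introns.index(ic)
        r = density_rate(ic.count, ic.length, gc.cds_count, gc.cds_length)
        records.append(
            RetentionRecord(gene_id, FIVE_PRIME_UTR, r, "density", intron_index=idx)
        )
    return records


def retention_junction(
    counts: FeatureCountsTable, gene_id: str, read_length: int | None = None
) -> list[RetentionRecord]:
    """Junction-estimator records for every intron of one gene."""
    gc = counts[gene_id]
    if gc.cds_count <= 0:
        raise UndefinedRateError(f"{gene_id}: CDS count is zero")
    rl = read_length if read_length is not None else counts.read_length
    if rl is None:
        raise ValueError("read_length unknown; pass it explicitly")
    records = []
    for idx, ic in enumerate(gc.introns):
        r = junction_rate(ic.n5, ic.n3, rl, gc.cds_count, gc.cds_length)
        records.append(
            RetentionRecord(gene_id, ic.klass, r, "junction", intron_index=idx)
        )
    return records


def retention_table(
    counts: FeatureCountsTable,
    method: str = "density",
    read_length: int | None = None,
) -> tuple[list[RetentionRecord], list[str]]:
    """All retention records for a counts table.

    Genes whose CDS has zero reads yield no records and are returned in the
    second element (flagged, not silently imputed).
    """
    records: list[RetentionRecord] = []
    undefined: list[str] = []
    for gene_id, gc in counts.genes.items():
        if not gc.introns:
            continue
        if gc.cds_count <= 0:
            undefined.append(gene_id)
            continue
        if method == "density":
            for klass in (FIVE_PRIME_UTR, CDS):
                records.extend(retention_density(counts, gene_id, klass))
        elif method == "junction":
            records.extend(retention_junction(counts, gene_id, read_length))
        else:
            raise ValueError(f"unknown method {method!r}")
    return records, undefined


def default_pseudocount(records: list[RetentionRecord]) -> float:
    """1e-3 of the median nonzero rate across the supplied records."""
    nonzero = [rec.r for rec in records if rec.r > 0]
    if not nonzero:
        return 1e-6
    return DEFAULT_PSEUDOCOUNT_SCALE * float(np.median(nonzero))


def normalize_to_control(
    treated: RetentionRecord, control: RetentionRecord, pseudocount: float
) -> float:
    """Pseudocounted fold change (r_t + eps) / (r_c + eps)."""
    if treated.key != control.key:
        raise InvalidPairingError(
            f"cannot pair {treated.key} with {control.key}"
        )
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return (treated.r + pseudocount) / (control.r + pseudocount)


def fold_changes(
    treated: list[RetentionRecord],
    control: list[RetentionRecord],
    pseudocount: float | None = None,
) -> list[RetentionRecord]:
    """Pair treated records with control records and attach fold changes.

    Records without a counterpart in the other condition are dropped.  The
    default pseudocount is derived from the pooled nonzero rates.
    """
    if pseudocount is None:
        pseudocount = default_pseudocount(list(treated) + list(control))
    by_key = {rec.key: rec for rec in control}
    out = []
    for rec in treated:
        ctrl = by_key.get(rec.key)
        if ctrl is None:
            continue
        fold = normalize_to_control(rec, ctrl, pseudocount)
        out.append(replace(rec, fold_vs_control=fold))
    return out


def rank_by_fold(records: list[RetentionRecord]) -> list[str]:
    """Genes ranked by descending fold change.

    A gene with several records (both intron classes, or several 5'UTR
    introns) contributes its maximum fold change.  Ties break
    lexicographically by gene id for determinism.
    """
    best: dict[str, float] = {}
    for rec in records:
        if rec.fold_vs_control is None:
            continue
        prev = best.get(rec.gene_id)
        if prev is None or rec.fold_vs_control > prev:
            best[rec.gene_id] = rec.fold_vs_control
    return [g for g, _ in sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))]


def hypergeom_enrichment(
    ranked: list[str], gene_set: set[str], top_n: int, set_name: str = "set"
) -> EnrichmentResult:
    """Hypergeometric tail P[X >= k] for set members among the top of a ranking."""
    N = len(ranked)
    if not 1 <= top_n <= N:
        raise ValueError(f"top_n must be in [1, {N}], got {top_n}")
    universe = set(ranked)
    members = gene_set & universe
    K = len(members)
    top = set(ranked[:top_n])
    k = len(top & members)
    p = float(hypergeom.sf(k - 1, N, K, top_n))
    return EnrichmentResult(set_name=set_name, k=k, K=K, n=top_n, N=N, p=min(p, 1.0))


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def enrichment_table(
    ranked: list[str], gene_sets: dict[str, set[str]], top_n: int
) -> list[EnrichmentResult]:
    """Score several gene sets against one ranking, BH-corrected across sets."""
    results = [
        hypergeom_enrichment(ranked, genes, top_n, set_name=name)
        for name, genes in sorted(gene_sets.items())
    ]
    adj = bh_adjust([res.p for res in results])
    return [replace(res, p_adj=a) for res, a in zip(results, adj)]
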