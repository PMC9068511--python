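"""Feature counting for intron-retention analysis.

Genes are annotated with a CDS span and a set of classified introns
(``five_prime_utr`` or ``cds``).  Aligned reads are block-structured
intervals: a single-block read is contiguous on the genome, a multi-block
read spans one or more splice junctions.  Counting follows the
feature-counting convention used by standard tools: a read is assigned to a
feature if any of its blocks overlaps the feature by at least one base, and
intron and CDS counters are independent (one read may increment both).  A
spliced read whose gap covers an intron therefore never counts towards that
intron.

All coordinates are 0-based half-open; the SAF interchange format
(1-based inclusive) is converted at the I/O boundary (see :mod:`isoretain.io`).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

FIVE_PRIME_UTR = "five_prime_utr"
CDS = "cds"
INTRON_CLASSES = (FIVE_PRIME_UTR, CDS)

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """A gene with a CDS span and zero or more classified introns.

    ``cds`` is the genomic span of the coding sequence; introns of class
    ``cds`` may lie inside it (the exonic CDS used for counting is the span
    minus any contained introns).  Introns of class ``five_prime_utr`` lie
    outside the CDS span, on the 5' side given the strand.
    """

    gene_id: str
    chrom: str
    strand: str
    cds: Interval
    introns: tuple[tuple[int, int, str], ...] = ()
    labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        s, e = self.cds
        if not e > s:
            raise ValueError(f"{self.gene_id}: CDS interval must have positive length")
        seen = sorted((a, b) for a, b, _ in self.introns)
        for (a, b, klass) in self.introns:
            if not b > a:
                raise ValueError(f"{self.gene_id}: intron must have positive length")
            if klass not in INTRON_CLASSES:
                raise ValueError(
                    f"{self.gene_id}: unknown intron class {klass!r}; "
                    f"allowed: {INTRON_CLASSES}"
                )
        for (a1, b1), (a2, b2) in zip(seen, seen[1:]):
            if a2 < b1:
                raise ValueError(f"{self.gene_id}: introns overlap")

    @property
    def sorted_introns(self) -> list[tuple[int, int, str]]:
        return sorted(self.introns, key=lambda t: t[0])

    @property
    def cds_parts(self) -> list[Interval]:
        """Exonic CDS intervals: the CDS span minus any contained introns."""
        parts = [self.cds]
        for a, b, _ in self.sorted_introns:
            new: list[Interval] = []
            for s, e in parts:
                if b <= s or a >= e:
                    new.append((s, e))
                    continue
                if s < a:
                    new.append((s, a))
                if b < e:
                    new.append((b, e))
            parts = new
        return parts

    @property
    def cds_exonic_length(self) -> int:
        return sum(e - s for s, e in self.cds_parts)

    @property
    def span(self) -> Interval:
        """Genomic span covering CDS and all introns."""
        starts = [self.cds[0]] + [a for a, _, _ in self.introns]
        ends = [self.cds[1]] + [b for _, b, _ in self.introns]
        return min(starts), max(ends)


@dataclass(frozen=True)
class ReadRecord:
    """A block-structured aligned read; single-block means contiguous."""

    chrom: str
    blocks: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("read must have at least one block")
        prev_end = None
        for s, e in self.blocks:
            if not e > s:
                raise ValueError("read blocks must have positive length")
            if prev_end is not None and s < prev_end:
                raise ValueError("read blocks must be ascending and non-overlapping")
            prev_end = e

    @property
    def read_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def contiguous(self) -> bool:
        return len(self.blocks) == 1


@dataclass
class IntronCounts:
    """Counts attached to one annotated intron."""

    interval: Interval
    klass: str
    count: int = 0
    n5: int = 0
    n3: int = 0

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class GeneCounts:
    gene_id: str
    strand: str
    cds_length: int
    cds_count: int = 0
    introns: list[IntronCounts] = field(default_factory=list)
    labels: frozenset[str] = frozenset()

    def introns_of_class(self, klass: str) -> list[IntronCounts]:
        return [ic for ic in self.introns if ic.klass == klass]


@dataclass
class FeatureCountsTable:
    """Per-gene intron/CDS counts plus per-intron junction-end counts."""

    genes: dict[str, GeneCounts]
    read_length: int | None = None
    ignored_reads: int = 0

    def __getitem__(self, gene_id: str) -> GeneCounts:
        return self.genes[gene_id]


def _blocks_by_chrom(
    reads: list[ReadRecord],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Flatten read blocks into per-chromosome (start, end, read index) arrays."""
    acc: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for idx, read in enumerate(reads):
        for s, e in read.blocks:
            acc[read.chrom].append((s, e, idx))
    out = {}
    for chrom, triples in acc.items():
        arr = np.asarray(triples, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return out


def _distinct_reads_overlapping(
    parts: list[Interval],
    bs: np.ndarray,
    be: np.ndarray,
    rid: np.ndarray,
) -> int:
    """Number of distinct reads with >=1 bp block overlap with any part."""
    mask = np.zeros(bs.shape, dtype=bool)
    for s, e in parts:
        mask |= (bs < e) & (be > s)
    if not mask.any():
        return 0
    return int(np.unique(rid[mask]).size)


def _modal_read_length(reads: list[ReadRecord]) -> int | None:
    if not reads:
        return None
    counts = Counter(r.read_length for r in reads)
    return counts.most_common(1)[0][0]


def count_features(
    reads: list[ReadRecord], models: list[GeneModel]
) -> FeatureCountsTable:
    """Count reads into intron and exonic-CDS features.

    A read increments a feature's count iff any of its blocks overlaps the
    feature by at least one base.  Counters are independent across features;
    reads on chromosomes absent from the annotation are ignored (their number
    is recorded on the returned table and logged).
    """
    table = FeatureCountsTable(genes={}, read_length=_modal_read_length(reads))
    by_chrom = _blocks_by_chrom(reads)
    known_chroms = {m.chrom for m in models}
    ignored = set()
    for chrom, (_, _, rid) in by_chrom.items():
        if chrom not in known_chroms:
            ignored.update(np.unique(rid).tolist())
    table.ignored_reads = len(ignored)
    if table.ignored_reads:
        logger.info("ignored %d reads on unannotated chromosomes", table.ignored_reads)

    empty = (
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int64),
    )
    for model in models:
        bs, be, rid = by_chrom.get(model.chrom, empty)
        gc = GeneCounts(
            gene_id=model.gene_id,
            strand=model.strand,
            cds_length=model.cds_exonic_length,
            labels=model.labels,
        )
        gc.cds_count = _distinct_reads_overlapping(model.cds_parts, bs, be, rid)
        for a, b, klass in model.sorted_introns:
            ic = IntronCounts(interval=(a, b), klass=klass)
            ic.count = _distinct_reads_overlapping([(a, b)], bs, be, rid)
            gc.introns.append(ic)
        table.genes[model.gene_id] = gc
    return table


def count_intron_end_overlaps(
    reads: list[ReadRecord], models: list[GeneModel]
) -> dict[tuple[str, int], tuple[int, int]]:
    """Count contiguous reads spanning each intron boundary.

    Only single-block reads are considered, mirroring the requirement that a
    junction-informative read align contiguously across the exon–intron
    boundary.  A read counts towards a boundary coordinate ``b`` iff it covers
    at least one base on each side, i.e. ``start < b < end``.  The (n5, n3)
    order follows the transcript orientation: on the minus strand the genomic
    right boundary is the 5' end.

    Returns a mapping ``(gene_id, intron_index) -> (n5, n3)`` with introns
    indexed in genomic order.
    """
    singles: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for read in reads:
        if read.contiguous:
            singles[read.chrom].append(read.blocks[0])
    arrs = {
        chrom: (np.asarray([s for s, _ in ivs]), np.asarray([e for _, e in ivs]))
        for chrom, ivs in singles.items()
    }
    out: dict[tuple[str, int], tuple[int, int]] = {}
    for model in models:
        ss, ee = arrs.get(model.chrom, (np.empty(0, dtype=np.int64),) * 2)
        for idx, (a, b, _klass) in enumerate(model.sorted_introns):
            left = int(np.count_nonzero((ss < a) & (ee > a)))
            right = int(np.count_nonzero((ss < b) & (ee > b)))
            n5, n3 = (left, right) if model.strand == "+" else (right, left)
            out[(model.gene_id, idx)] = (n5, n3)
    return out


def build_counts_table(
    reads: list[ReadRecord],
    models: list[GeneModel],
    read_length: int | None = None,
) -> FeatureCountsTable:
    """Run both counting passes and return one populated table."""
    table = count_features(reads, models)
    ends = count_intron_end_overlaps(reads, models)
    for model in models:
        gc = table.genes[model.gene_id]
        for idx, ic in enumerate(gc.introns):
            ic.n5, ic.n3 = ends[(model.gene_id, idx)]
    if read_length is not None:
        table.read_length = read_length
    return table
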