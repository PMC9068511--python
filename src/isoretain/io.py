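"""Readers and writers for the plain-text interchange formats.

* SAF annotation (GeneID, Chr, Start, End, Strand; 1-based inclusive as
  consumed by standard feature counters).  Feature classes ride on a GeneID
  suffix convention: ``<gene>::cds`` for (exonic) CDS parts,
  ``<gene>::intron_utr`` for 5'UTR introns, ``<gene>::intron_cds`` for CDS
  introns.  Internal coordinates are 0-based half-open; conversion happens
  here and only here.
* reads as a BED12-style TSV subset (chrom, start, end, name, score,
  strand, blockCount, blockSizes, blockStarts),
* per-cell flow CSV (well, conc_a, conc_b, fitc_h, fsc_h),
* survival CFU CSV, long-format OD CSV, gene-set TSV, counts TSV.

Every writer has a matching reader and round-trips.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import (
    CDS,
    FIVE_PRIME_UTR,
    FeatureCountsTable,
    GeneCounts,
    GeneModel,
    IntronCounts,
    ReadRecord,
)
from .errors import SafFormatError
from .growth import GrowthCurve
from .synthetic import SimulatedWell

SAF_HEADER = ["GeneID", "Chr", "Start", "End", "Strand"]
_SUFFIX_TO_CLASS = {"intron_utr": FIVE_PRIME_UTR, "intron_cds": CDS}
_CLASS_TO_SUFFIX = {v: k for k, v in _SUFFIX_TO_CLASS.items()}
ALLOWED_SUFFIXES = ("cds", "intron_utr", "intron_cds")


# ---------------------------------------------------------------------------
# SAF
# ---------------------------------------------------------------------------

def write_saf(models: list[GeneModel], path: str | Path) -> None:
    """Write gene models as SAF rows (1-based inclusive coordinates)."""
    rows = []
    for m in models:
        for s, e in m.cds_parts:
            rows.append((f"{m.gene_id}::cds", m.chrom, s + 1, e, m.strand))
        for s, e, klass in m.sorted_introns:
            suffix = _CLASS_TO_SUFFIX[klass]
            rows.append((f"{m.gene_id}::{suffix}", m.chrom, s + 1, e, m.strand))
    with open(path, "w") as fh:
        fh.write("\t".join(SAF_HEADER) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_saf(path: str | Path) -> list[GeneModel]:
    """Parse a SAF file back into gene models.

    Rows are grouped by the GeneID prefix before the ``::`` suffix; the CDS
    span is the hull of the cds rows (they are stored minus any contained
    introns).  Labels do not travel through SAF; see :func:`read_gene_sets`.
    """
    per_gene: dict[str, dict] = defaultdict(lambda: {"cds": [], "introns": []})
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip().split("\t") != SAF_HEADER:
            raise SafFormatError(f"line 1: expected header {SAF_HEADER}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise SafFormatError(f"line {lineno}: expected 5 columns, got {len(fields)}")
            gene_field, chrom, start_s, end_s, strand = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as err:
                raise SafFormatError(f"line {lineno}: non-integer coordinates") from err
            if "::" not in gene_field:
                raise SafFormatError(
                    f"line {lineno}: GeneID {gene_field!r} lacks a feature suffix; "
                    f"allowed suffixes: {ALLOWED_SUFFIXES}"
                )
            gene_id, suffix = gene_field.rsplit("::", 1)
            if suffix not in ALLOWED_SUFFIXES:
                raise SafFormatError(
                    f"line {lineno}: unknown suffix {suffix!r}; "
                    f"allowed suffixes: {ALLOWED_SUFFIXES}"
                )
            iv = (start - 1, end)  # 1-based inclusive -> 0-based half-open
            entry = per_gene[gene_id]
            if gene_id not in order:
                order.append(gene_id)
            entry["chrom"] = chrom
            entry["strand"] = strand
            if suffix == "cds":
                entry["cds"].append(iv)
            else:
                entry["introns"].append((iv[0], iv[1], _SUFFIX_TO_CLASS[suffix]))
    models = []
    for gene_id in order:
        entry = per_gene[gene_id]
        if not entry["cds"]:
            raise SafFormatError(f"gene {gene_id}: no cds rows")
        cds_lo = min(s for s, _ in entry["cds"])
        cds_hi = max(e for _, e in entry["cds"])
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=entry["chrom"],
                strand=entry["strand"],
                cds=(cds_lo, cds_hi),
                introns=tuple(sorted(entry["introns"])),
            )
        )
    return models


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def write_gene_sets(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("set_name\tgene_id\n")
        for name in sorted(sets):
            for gene in sorted(sets[name]):
                fh.write(f"{name}\t{gene}\n")


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    return {
        name: set(group["gene_id"]) for name, group in df.groupby("set_name")
    }


def attach_labels(models: list[GeneModel], sets: dict[str, set[str]]) -> list[GeneModel]:
    """Return models with label sets rebuilt from gene-set membership."""
    from dataclasses import replace

    out = []
    for m in models:
        labels = frozenset(name for name, genes in sets.items() if m.gene_id in genes)
        out.append(replace(m, labels=labels))
    return out


# ---------------------------------------------------------------------------
# reads (BED12-style subset)
# ---------------------------------------------------------------------------

BED_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "blockCount", "blockSizes", "blockStarts",
]


def write_reads_bed(reads: list[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(BED_COLUMNS) + "\n")
        for i, read in enumerate(reads):
            start = read.blocks[0][0]
            end = read.blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in read.blocks)
            offsets = ",".join(str(s - start) for s, _ in read.blocks)
            fh.write(
                f"{read.chrom}\t{start}\t{end}\tread{i}\t0\t.\t"
                f"{len(read.blocks)}\t{sizes}\t{offsets}\n"
            )


def read_reads_bed(path: str | Path) -> list[ReadRecord]:
    df = pd.read_csv(path, sep="\t")
    reads = []
    for row in df.itertuples(index=False):
        start = int(row.start)
        sizes = [int(x) for x in str(row.blockSizes).split(",")]
        offsets = [int(x) for x in str(row.blockStarts).split(",")]
        blocks = tuple(
            (start + off, start + off + size) for off, size in zip(offsets, sizes)
        )
        reads.append(ReadRecord(chrom=row.chrom, blocks=blocks))
    return reads


# ---------------------------------------------------------------------------
# flow cytometry cells
# ---------------------------------------------------------------------------

def write_cells_csv(wells: list[SimulatedWell], path: str | Path) -> None:
    """One row per cell: well, conc_a, conc_b, fitc_h, fsc_h."""
    frames = []
    for w in wells:
        frames.append(
            pd.DataFrame(
                {
                    "well": w.well_id,
                    "conc_a": w.conc_a,
                    "conc_b": w.conc_b,
                    "fitc_h": w.fitc,
                    "fsc_h": w.fsc,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cells_csv(path: str | Path) -> list[SimulatedWell]:
    """Rebuild per-well raw channel arrays (truth fields are NaN)."""
    df = pd.read_csv(path)
    wells = []
    for (well, ca, cb), group in df.groupby(["well", "conc_a", "conc_b"], sort=True):
        wells.append(
            SimulatedWell(
                well_id=str(well),
                conc_a=float(ca),
                conc_b=float(cb),
                fitc=group["fitc_h"].to_numpy(),
                fsc=group["fsc_h"].to_numpy(),
                true_p=float("nan"),
                true_median=float("nan"),
                target_median=float("nan"),
            )
        )
    return wells


def write_flow_truth_csv(wells: list[SimulatedWell], path: str | Path) -> None:
    pd.DataFrame(
        {
            "well": [w.well_id for w in wells],
            "conc_a": [w.conc_a for w in wells],
            "conc_b": [w.conc_b for w in wells],
            "true_p": [w.true_p for w in wells],
            "true_median": [w.true_median for w in wells],
            "target_median": [w.target_median for w in wells],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# survival and growth tables
# ---------------------------------------------------------------------------

def write_survival_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    from .resampling import validate_survival_table

    return validate_survival_table(pd.read_csv(path))


def write_growth_csv(curves: list[GrowthCurve], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"well": c.well_id, "time_h": c.times, "od": c.od})
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_growth_csv(path: str | Path) -> list[GrowthCurve]:
    df = pd.read_csv(path)
    curves = []
    for well, group in df.groupby("well", sort=True):
        group = group.sort_values("time_h")
        curves.append(
            GrowthCurve(
                well_id=str(well),
                times=group["time_h"].to_numpy(),
                od=group["od"].to_numpy(),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# counts and results tables
# ---------------------------------------------------------------------------

def write_counts_tsv(table: FeatureCountsTable, path: str | Path) -> None:
    rows = []
    for gene_id, gc in table.genes.items():
        rows.append(
            {
                "gene_id": gene_id, "feature": "cds", "klass": "cds", "index": -1,
                "start": -1, "end": -1, "count": gc.cds_count,
                "length": gc.cds_length, "n5": 0, "n3": 0,
                "strand": gc.strand, "labels": ";".join(sorted(gc.labels)),
            }
        )
        for idx, ic in enumerate(gc.introns):
            rows.append(
                {
                    "gene_id": gene_id, "feature": "intron", "klass": ic.klass,
                    "index": idx, "start": ic.interval[0], "end": ic.interval[1],
                    "count": ic.count, "length": ic.length, "n5": ic.n5, "n3": ic.n3,
                    "strand": gc.strand, "labels": ";".join(sorted(gc.labels)),
                }
            )
    header = list(rows[0].keys()) if rows else [
        "gene_id", "feature", "klass", "index", "start", "end",
        "count", "length", "n5", "n3", "strand", "labels",
    ]
    pd.DataFrame(rows, columns=header).to_csv(
        path, sep="\t", index=False
    )


def read_counts_tsv(path: str | Path, read_length: int | None = None) -> FeatureCountsTable:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    genes: dict[str, GeneCounts] = {}
    for row in df.itertuples(index=False):
        labels = frozenset(str(row.labels).split(";")) - {""}
        gc = genes.get(row.gene_id)
        if gc is None:
            gc = GeneCounts(
                gene_id=row.gene_id, strand=row.strand, cds_length=0, labels=labels
            )
            genes[row.gene_id] = gc
        if row.feature == "cds":
            gc.cds_count = int(row.count)
            gc.cds_length = int(row.length)
        else:
            gc.introns.append(
                IntronCounts(
                    interval=(int(row.start), int(row.end)),
                    klass=row.klass,
                    count=int(row.count),
                    n5=int(row.n5),
                    n3=int(row.n3),
                )
            )
    return FeatureCountsTable(genes=genes, read_length=read_length)


def write_retention_tsv(records, path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "intron_class": [r.intron_class for r in records],
            "intron_index": [
                -1 if r.intron_index is None else r.intron_index for r in records
            ],
            "method": [r.method for r in records],
            "r": [r.r for r in records],
            "fold_vs_control": [
                np.nan if r.fold_vs_control is None else r.fold_vs_control
                for r in records
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def write_enrichment_tsv(results, path: str | Path) -> None:
    pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
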