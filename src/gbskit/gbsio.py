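"""Readers and writers for the interchange formats, plus a desk-scale
FASTQ demultiplexer.

Formats:

* genotype matrices — TSV, lines as rows, loci as columns, calls as
  A/B/H/N characters;
* genetic maps — CSV with locus, linkage_group, position_cm, status and
  optional placement-provenance columns;
* tag counts — long TSV (line, tag, count);
* SNP catalogs — TSV with name, bracketed context, alleles, p-value,
  source;
* VCF export (write-only): reference-free calls on contig "UNPLACED"
  with positions equal to 1-based catalog order, alleles A/B as
  placeholder REF/ALT;
* barcode key files — CSV with flowcell, lane, barcode, sample.

Parsers reject malformed rows with the offending position named rather
than silently coercing; writers sort keys so output is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    CHAR_TO_CODE,
    CODE_TO_CHAR,
    ConfigurationError,
    FormatError,
    GeneticMap,
    GenotypeMatrix,
    SnpCall,
    TagCatalog,
)

log = logging.getLogger("gbskit")

CUTSITE_REMNANT = "TGCAG"  # PstI cuts CTGCA^G, leaving TGCAG on the read


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def write_genotype_matrix(G: GenotypeMatrix, path) -> None:
    G.to_chars().to_csv(path, sep="\t", index_label="line")


def read_genotype_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="line", dtype=str)
    df.index = df.index.astype(str)
    for j, col in enumerate(df.columns):
        bad = ~df[col].isin(CHAR_TO_CODE)
        if bad.any():
            line = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"{path}: invalid call {df[col][bad].iloc[0]!r} "
                f"at line {line!r}, locus {col!r}"
            )
    return GenotypeMatrix.from_chars(df)


# ---------------------------------------------------------------------------
# genetic maps
# ---------------------------------------------------------------------------

def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path)
    try:
        df["position_cm"] = df["position_cm"].astype(float)
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: bad map table: {exc}") from exc
    return GeneticMap(df)


# ---------------------------------------------------------------------------
# tag counts
# ---------------------------------------------------------------------------

def write_tag_counts(catalog: TagCatalog, path) -> None:
    """Long-format TSV (line, tag, count), zero counts omitted."""
    long = (
        catalog.counts.stack()
        .rename_axis(["line", "tag"])
        .rename("count")
        .reset_index()
    )
    long = long[long["count"] > 0].sort_values(["line", "tag"], kind="stable")
    long.to_csv(path, sep="\t", index=False)


def read_tag_counts(path, pairs: list | None = None) -> TagCatalog:
    df = pd.read_csv(path, sep="\t", dtype={"line": str, "tag": str})
    if not {"line", "tag", "count"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns line, tag, count")
    if (df["count"] < 0).any():
        row = df[df["count"] < 0].iloc[0]
        raise FormatError(f"{path}: negative count for {row['line']}/{row['tag']}")
    wide = df.pivot_table(
        index="line", columns="tag", values="count", aggfunc="sum", fill_value=0
    )
    wide = wide.sort_index()
    tags = sorted(wide.columns)
    return TagCatalog(tags=tags, counts=wide[tags].astype(np.int64), pairs=pairs or [])


# ---------------------------------------------------------------------------
# SNP catalogs
# ---------------------------------------------------------------------------

def write_snp_catalog(snps: Sequence[SnpCall], path) -> None:
    rows = [
        {
            "name": s.name,
            "context": s.context,
            "alleles": "/".join(s.alleles),
            "p_value": s.p_value,
            "source": s.source_pipeline,
        }
        for s in sorted(snps, key=lambda s: s.name)
    ]
    pd.DataFrame(rows, columns=["name", "context", "alleles", "p_value", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_snp_catalog(path) -> list[SnpCall]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            SnpCall(
                name=str(row["name"]),
                context=str(row["context"]),
                alleles=tuple(str(row["alleles"]).split("/")),
                p_value=float(row["p_value"]),
                source_pipeline=str(row["source"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path, contig: str = "UNPLACED") -> None:
    """Write calls as a minimal VCF 4.2 file.

    Reference-free dialect: all records sit on one placeholder contig,
    POS is the 1-based catalog index, REF/ALT are the symbolic alleles
    A and B, genotypes 0/0, 0/1, 1/1 or ./. .
    """
    gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        samples = "\t".join(str(s) for s in G.lines)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        calls = G.calls.to_numpy()
        for j, locus in enumerate(G.loci):
            row = "\t".join(gt[int(c)] for c in calls[:, j])
            fh.write(f"{contig}\t{j + 1}\t{locus}\tA\tB\t.\t.\t.\tGT\t{row}\n")


# ---------------------------------------------------------------------------
# barcode key files and demultiplexing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeyFileEntry:
    flowcell: str
    lane: str
    barcode: str
    sample: str


def read_key_file(path) -> list[KeyFileEntry]:
    df = pd.read_csv(path, dtype=str)
    required = {"flowcell", "lane", "barcode", "sample"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: key file needs columns {sorted(required)}")
    entries = [
        KeyFileEntry(r.flowcell, r.lane, r.barcode, r.sample)
        for r in df.itertuples()
    ]
    validate_key_entries(entries)
    return entries


def validate_key_entries(entries: Iterable[KeyFileEntry]) -> None:
    seen = set()
    by_lane: dict[tuple, list[str]] = {}
    for e in entries:
        if not 4 <= len(e.barcode) <= 10 or set(e.barcode) - set("ACGT"):
            raise ConfigurationError(f"invalid barcode {e.barcode!r}")
        key = (e.flowcell, e.lane, e.barcode)
        if key in seen:
            raise ConfigurationError(f"duplicate key entry {key}")
        seen.add(key)
        by_lane.setdefault((e.flowcell, e.lane), []).append(e.barcode)
    for lane, codes in by_lane.items():
        codes = sorted(codes)
        for a, b in zip(codes, codes[1:]):
            if b.startswith(a):
                raise ConfigurationError(
                    f"barcodes not prefix-free in lane {lane}: {a!r} prefixes {b!r}"
                )


@dataclass
class DemuxResult:
    reads_by_sample: dict
    counts_by_sample: pd.Series
    total_reads: int
    good_barcoded_fraction: float


def demultiplex(
    fastq_path,
    entries: Sequence[KeyFileEntry],
    cutsite_remnant: str = CUTSITE_REMNANT,
) -> DemuxResult:
    """Assign FASTQ reads to samples by exact barcode match.

    A read is assigned iff it starts with a barcode immediately
    followed by the restriction cut-site remnant and contains no 'N';
    the barcode is trimmed from the retained sequence.  Per-sample read
    counts feed the depth index.
    """
    validate_key_entries(entries)
    by_barcode = {e.barcode: e.sample for e in entries}
    reads: dict = {e.sample: [] for e in entries}
    total = 0
    good = 0
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        total += 1
        seq = str(rec.seq)
        if "N" in seq:
            continue
        for bc, sample in by_barcode.items():
            if seq.startswith(bc + cutsite_remnant):
                reads[sample].append(seq[len(bc):])
                good += 1
                break
    counts = pd.Series({s: len(v) for s, v in sorted(reads.items())}, dtype=int)
    frac = good / total if total else 0.0
    log.info("demultiplexed %d reads, %.1f%% good barcoded", total, 100 * frac)
    return DemuxResult(
        reads_by_sample=reads,
        counts_by_sample=counts,
        total_reads=total,
        good_barcoded_fraction=frac,
    )


# ---------------------------------------------------------------------------
# experiment curves and placement report
# ---------------------------------------------------------------------------

def write_curve_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_placement_report_html(gmap: GeneticMap, path) -> None:
    """One HTML table per linkage group listing placed loci with their
    anchors and rf provenance."""
    parts = ["<html><body><h1>Marker placement report</h1>"]
    for lg in gmap.linkage_groups:
        sub = gmap.group(lg)
        parts.append(f"<h2>Linkage group {lg}</h2>")
        parts.append(sub.to_html(index=False))
    parts.append("</body></html>")
    Path(path).write_text("\n".join(parts))
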