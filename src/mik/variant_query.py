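"""Intersect variants (VCF) or single genome coordinates with an Exp-MiBR
table — the desk-side equivalent of the published web query service.

Variants are matched by their anchor position (the 1-based POS converted to a
single internal 0-based base); span-aware matching of indels is available via
a flag.  Added INFO fields are strippable, reproducing the input body.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .genome_io import GenomicInterval, VcfFile, VcfRecord, read_vcf
from .mibr_core import ExpMiBR

INFO_KEYS = ("MIBR_ID", "MIBR_GENE", "MIBR_PART", "MIBR_NDS", "MIBR_MIRNAS")

INFO_HEADER_LINES = [
    '##INFO=<ID=MIBR_ID,Number=.,Type=String,Description="Overlapping miRNA-binding region id">',
    '##INFO=<ID=MIBR_GENE,Number=.,Type=String,Description="Gene of the overlapping binding region">',
    '##INFO=<ID=MIBR_PART,Number=.,Type=String,Description="mRNA part of the overlapping binding region">',
    '##INFO=<ID=MIBR_NDS,Number=.,Type=String,Description="Supporting dataset count of the overlapping binding region">',
    '##INFO=<ID=MIBR_MIRNAS,Number=.,Type=String,Description="miRNAs bound at the overlapping region">',
]

_POINT_RE = re.compile(r"^(?P<seqid>[\w.]+):(?P<pos>[\d,]+)$")


@dataclass
class QueryHit:
    seqid: str
    position: int  # 1-based, as queried
    region: ExpMiBR
    offset: int  # 0-based offset of the position within the region

    def __post_init__(self) -> None:
        iv = self.region.interval
        if not (iv.start <= self.position - 1 < iv.end):
            raise ValueError("hit position outside its region")


def parse_point(text: str) -> tuple[str, int]:
    """Parse 'chr2:216499'-style coordinates (1-based; commas allowed)."""
    m = _POINT_RE.match(text.strip())
    if m is None:
        raise ValueError(
            f"malformed coordinate {text!r}; expected <seqid>:<1-based position>"
        )
    return m.group("seqid"), int(m.group("pos").replace(",", ""))


def query_point(
    seqid: str, position_1based: int, regions: Sequence[ExpMiBR]
) -> list[QueryHit]:
    """All regions whose half-open interval contains the queried base."""
    if position_1based < 1:
        raise ValueError("position must be >= 1 (1-based)")
    pos0 = position_1based - 1
    hits = []
    for region in regions:
        iv = region.interval
        if iv.seqid == seqid and iv.start <= pos0 < iv.end:
            hits.append(QueryHit(seqid, position_1based, region, pos0 - iv.start))
    return hits


def _matching_regions(
    rec: VcfRecord, regions: Sequence[ExpMiBR], span_aware: bool
) -> list[ExpMiBR]:
    pos0 = rec.pos - 1
    if span_aware:
        ref = rec.fields[3]
        end0 = pos0 + max(1, len(ref))
    else:
        end0 = pos0 + 1
    out = []
    for region in regions:
        iv = region.interval
        if iv.seqid == rec.chrom and iv.start < end0 and pos0 < iv.end:
            out.append(region)
    return out


def _info_value(regions: Sequence[ExpMiBR], key: str) -> str:
    def one(r: ExpMiBR) -> str:
        ann = r.annotation
        if key == "MIBR_ID":
            return r.region_id
        if key == "MIBR_GENE":
            return (ann.gene_id if ann and ann.gene_id else ".")
        if key == "MIBR_PART":
            return ann.part if ann else "intergenic"
        if key == "MIBR_NDS":
            return str(len(r.datasets))
        if key == "MIBR_MIRNAS":
            return "|".join(sorted(r.mirnas)) or "."
        raise KeyError(key)

    return ",".join(one(r) for r in regions)


def annotate_vcf(
    vcf_path: str | Path,
    regions: Sequence[ExpMiBR],
    out_path: Optional[str | Path] = None,
    size_limit_mb: float = 20.0,
    span_aware: bool = False,
    assembly: Optional[str] = None,
    table_assembly: Optional[str] = None,
) -> tuple[VcfFile, pd.DataFrame]:
    """Annotate a VCF against the region table.

    Variants inside a region gain MIBR_* INFO fields; the rest pass through
    untouched, in input order.  Returns the annotated VCF object plus a TSV-
    ready hit table.  Declared assembly mismatch between query and table is a
    hard error; no liftover is attempted.
    """
    if assembly is not None and table_assembly is not None and assembly != table_assembly:
        raise ValueError(
            f"assembly mismatch: query declares {assembly!r}, table {table_assembly!r}"
        )
    vcf = read_vcf(vcf_path, size_limit_mb=size_limit_mb)
    hits_rows = []
    for rec in vcf.records:
        matched = _matching_regions(rec, regions, span_aware)
        if not matched:
            continue
        additions = ";".join(f"{k}={_info_value(matched, k)}" for k in INFO_KEYS)
        rec.info = additions if rec.info == "." else f"{rec.info};{additions}"
        for region in matched:
            ann = region.annotation
            hits_rows.append(
                (
                    rec.chrom, rec.pos, rec.fields[3], rec.fields[4],
                    region.region_id,
                    ann.gene_id if ann and ann.gene_id else ".",
                    ann.part if ann else "intergenic",
                    len(region.datasets),
                    "|".join(sorted(region.mirnas)) or ".",
                )
            )
    header = list(vcf.header)
    header[-1:-1] = INFO_HEADER_LINES  # keep #CHROM last
    annotated = VcfFile(header, vcf.records)
    hits = pd.DataFrame(
        hits_rows,
        columns=["chrom", "pos", "ref", "alt", "region_id", "gene_id", "part",
                 "n_datasets", "mirnas"],
    )
    if out_path is not None:
        annotated.write(out_path)
    return annotated, hits


def strip_annotations(vcf: VcfFile) -> VcfFile:
    """Remove MIBR_* INFO fields and header lines, restoring '.' when the
    INFO column becomes empty — the inverse of :func:`annotate_vcf`."""
    header = [
        line for line in vcf.header
        if not any(f"##INFO=<ID={k}," in line for k in INFO_KEYS)
    ]
    records = []
    for rec in vcf.records:
        fields = list(rec.fields)
        entries = [
            e for e in fields[7].split(";")
            if e and e.split("=", 1)[0] not in INFO_KEYS
        ]
        fields[7] = ";".join(entries) if entries else "."
        records.append(VcfRecord(fields))
    return VcfFile(header, records)
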