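"""Data model, file I/O and transcript<->genome coordinate projection.

All internal coordinates are 0-based half-open on a single assembly.
VCF positions (1-based) and BED intervals (already 0-based half-open) are
converted at the boundary; cross-assembly liftover is out of scope and inputs
are assumed pre-lifted, with the assembly recorded in dataset manifests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: single-label annotation precedence, highest first
DEFAULT_PRECEDENCE = ("CDS", "UTR3", "UTR5", "ncRNA_exonic", "intronic", "intergenic")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Strand-aware 0-based half-open span on a named sequence."""

    seqid: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seqid:
            raise ValueError("seqid must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seqid}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def strand_compatible(self, other: "GenomicInterval") -> bool:
        # '.' (unknown) is compatible with either strand
        return "." in (self.strand, other.strand) or self.strand == other.strand

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Overlap in nt with another interval; 0 if different seqid or
        incompatible strand."""
        if self.seqid != other.seqid or not self.strand_compatible(other):
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, seqid: str, pos: int) -> bool:
        return self.seqid == seqid and self.start <= pos < self.end


@dataclass
class Transcript:
    """Ordered (by genomic start) non-overlapping exons on one seqid/strand,
    with an optional genomic CDS span."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds: Optional[tuple[int, int]] = None  # genomic (start, end), half-open

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        seqids = {e.seqid for e in exons}
        strands = {e.strand for e in exons}
        if len(seqids) != 1 or len(strands) != 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons must share seqid and strand"
            )
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        object.__setattr__(self, "exons", exons)
        if self.cds is not None:
            cs, ce = self.cds
            if not (cs < ce):
                raise ValueError(f"transcript {self.transcript_id}: empty CDS span")
            covered = sum(
                max(0, min(ce, e.end) - max(cs, e.start)) for e in exons
            )
            if covered == 0:
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS outside exon union"
                )

    @property
    def seqid(self) -> str:
        return self.exons[0].seqid

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seqid, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    biotype: str  # "coding" | "noncoding"
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def seqid(self) -> str:
        return next(iter(self.transcripts.values())).seqid

    @property
    def span(self) -> GenomicInterval:
        txs = list(self.transcripts.values())
        start = min(t.span.start for t in txs)
        end = max(t.span.end for t in txs)
        return GenomicInterval(self.seqid, start, end, txs[0].strand)


@dataclass
class InteractionRecord:
    """One chimera-derived miRNA -> target-region pairing.

    ``blocks`` holds 1-3 genomic (or transcript-space) spans: an interaction
    footprint split across exons yields one block per exon.
    """

    mirna: str
    blocks: tuple[GenomicInterval, ...]
    dataset: str
    chimera: str
    cell_line: str = ""
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("interaction must have at least one block")
        blocks = tuple(sorted(self.blocks, key=lambda b: b.start))
        if len({(b.seqid, b.strand) for b in blocks}) != 1:
            raise ValueError(
                f"chimera {self.chimera}: blocks must share seqid and strand"
            )
        for a, b in zip(blocks, blocks[1:]):
            if a.end > b.start:
                raise ValueError(f"chimera {self.chimera}: overlapping blocks")
        object.__setattr__(self, "blocks", blocks)

    @property
    def seqid(self) -> str:
        return self.blocks[0].seqid

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def length(self) -> int:
        return sum(b.length for b in self.blocks)


@dataclass
class PeakRecord:
    """One CLIP binding region (no miRNA identity)."""

    interval: GenomicInterval
    dataset: str
    cell_line: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        if not self.dataset:
            raise ValueError("peak dataset id must be non-empty")


@dataclass
class Annotation:
    gene_id: Optional[str]
    part: str  # one of DEFAULT_PRECEDENCE


# ---------------------------------------------------------------------------
# coordinate projection
# ---------------------------------------------------------------------------

def _exons_in_transcription_order(
    exons: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    exons = sorted(exons, key=lambda e: e.start)
    if exons[0].strand == "-":
        exons = exons[::-1]
    return exons


def project_to_genome(
    start: int, end: int, transcript: Transcript | Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Project a transcript-coordinate interval [start, end) onto the genome.

    Transcript position 0 is the transcription start: the leftmost base of the
    exon union on '+' transcripts and the rightmost base on '-' transcripts.
    Returns 1..k genomic blocks sorted by genomic start whose lengths sum to
    ``end - start``.
    """
    exons = transcript.exons if isinstance(transcript, Transcript) else tuple(transcript)
    name = transcript.transcript_id if isinstance(transcript, Transcript) else "<exons>"
    tlen = sum(e.length for e in exons)
    if not (0 <= start < end):
        raise ValueError(f"invalid transcript interval [{start}, {end})")
    if end > tlen:
        raise ValueError(
            f"interval [{start}, {end}) exceeds length {tlen} of transcript {name}"
        )
    strand = exons[0].strand
    blocks: list[GenomicInterval] = []
    offset = 0
    for exon in _exons_in_transcription_order(exons):
        lo = max(start, offset)
        hi = min(end, offset + exon.length)
        if lo < hi:
            if strand == "-":
                g_start = exon.end - (hi - offset)
                g_end = exon.end - (lo - offset)
            else:
                g_start = exon.start + (lo - offset)
                g_end = exon.start + (hi - offset)
            blocks.append(GenomicInterval(exon.seqid, g_start, g_end, strand))
        offset += exon.length
    return sorted(blocks, key=lambda b: b.start)


def project_to_transcript(
    blocks: Sequence[GenomicInterval],
    transcript: Transcript | Sequence[GenomicInterval],
) -> tuple[int, int]:
    """Inverse of :func:`project_to_genome`.

    Every block must lie within a single exon and the blocks must form one
    contiguous transcript-space interval.
    """
    exons = transcript.exons if isinstance(transcript, Transcript) else tuple(transcript)
    name = transcript.transcript_id if isinstance(transcript, Transcript) else "<exons>"
    if not blocks:
        raise ValueError("empty block list")
    strand = exons[0].strand
    # cumulative transcript offsets per exon, in transcription order
    offsets: dict[GenomicInterval, int] = {}
    offset = 0
    for exon in _exons_in_transcription_order(exons):
        offsets[exon] = offset
        offset += exon.length

    spans: list[tuple[int, int]] = []
    for block in blocks:
        host = None
        for exon in exons:
            if exon.seqid == block.seqid and exon.start <= block.start and block.end <= exon.end:
                host = exon
                break
        if host is None:
            raise ValueError(
                f"block [{block.start}, {block.end}) on {block.seqid} is not "
                f"contained in a single exon of transcript {name}"
            )
        if strand == "-":
            t_start = offsets[host] + (host.end - block.end)
        else:
            t_start = offsets[host] + (block.start - host.start)
        spans.append((t_start, t_start + block.length))
    spans.sort()
    for (_, a_end), (b_start, _) in zip(spans, spans[1:]):
        if a_end != b_start:
            raise ValueError(
                f"blocks do not form a contiguous transcript interval on {name}"
            )
    return spans[0][0], spans[-1][1]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _transcript_parts(
    tx: Transcript, coding: bool
) -> list[tuple[GenomicInterval, str]]:
    """Decompose a transcript into labeled genomic segments (exonic parts only;
    introns are handled against the transcript span)."""
    parts: list[tuple[GenomicInterval, str]] = []
    if not coding or tx.cds is None:
        for e in tx.exons:
            parts.append((e, "ncRNA_exonic"))
        return parts
    cs, ce = tx.cds
    left_label = "UTR5" if tx.strand != "-" else "UTR3"
    right_label = "UTR3" if tx.strand != "-" else "UTR5"
    for e in tx.exons:
        if e.start < cs:
            seg_end = min(e.end, cs)
            parts.append((GenomicInterval(e.seqid, e.start, seg_end, e.strand), left_label))
        o_start, o_end = max(e.start, cs), min(e.end, ce)
        if o_start < o_end:
            parts.append((GenomicInterval(e.seqid, o_start, o_end, e.strand), "CDS"))
        if e.end > ce:
            seg_start = max(e.start, ce)
            parts.append((GenomicInterval(e.seqid, seg_start, e.end, e.strand), right_label))
    return parts


class GeneModelIndex:
    """Per-seqid index over gene models for repeated annotation queries."""

    def __init__(self, genes: Iterable[GeneModel], precedence: Sequence[str] = DEFAULT_PRECEDENCE):
        self.precedence = tuple(precedence)
        self._rank = {p: i for i, p in enumerate(self.precedence)}
        self._by_seqid: dict[str, list[tuple[GeneModel, Transcript]]] = {}
        for gene in genes:
            for tx in gene.transcripts.values():
                self._by_seqid.setdefault(tx.seqid, []).append((gene, tx))

    def genes_on(self, seqid: str) -> list[GeneModel]:
        seen: dict[str, GeneModel] = {}
        for gene, _ in self._by_seqid.get(seqid, []):
            seen[gene.gene_id] = gene
        return list(seen.values())

    def annotate(self, interval: GenomicInterval) -> Annotation:
        best: Optional[tuple[int, str, Optional[str]]] = None
        for gene, tx in self._by_seqid.get(interval.seqid, []):
            if interval.overlap_length(tx.span) == 0:
                continue
            labels = [
                lab
                for seg, lab in _transcript_parts(tx, gene.biotype == "coding")
                if interval.overlap_length(seg) > 0
            ]
            if not labels:
                labels = ["intronic"]
            for lab in labels:
                cand = (self._rank[lab], lab, gene.gene_id)
                if best is None or cand[0] < best[0]:
                    best = cand
        if best is None:
            return Annotation(None, "intergenic")
        return Annotation(best[2], best[1])


def annotate_interval(
    interval: GenomicInterval,
    genes: Iterable[GeneModel] | GeneModelIndex,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> Annotation:
    """Assign exactly one part label (and the owning gene, if any) to an
    interval.  When the interval overlaps several parts or transcripts, the
    highest-precedence part wins (CDS first by default)."""
    index = genes if isinstance(genes, GeneModelIndex) else GeneModelIndex(genes, precedence)
    return index.annotate(interval)


# ---------------------------------------------------------------------------
# TSV readers/writers
# ---------------------------------------------------------------------------

INTERACTION_COLUMNS = ["seqid", "start", "end", "strand", "mirna", "dataset", "chimera", "cell_line"]
PEAK_COLUMNS = ["seqid", "start", "end", "strand", "dataset", "cell_line", "method"]
GTF_LITE_COLUMNS = [
    "gene_id", "gene_name", "biotype", "transcript_id", "feature",
    "seqid", "start", "end", "strand",
]


def read_interactions(path: str | Path, coordinate_space: str = "genome") -> list[InteractionRecord]:
    """Read chimeric interaction records from TSV.

    Rows sharing (dataset, chimera) are the exon blocks of one chimera and are
    grouped into a single record. Malformed rows (start >= end) are rejected
    and logged with their line number; a missing required column is a hard
    error.
    """
    if coordinate_space not in ("transcript", "genome"):
        raise ValueError(f"unknown coordinate space {coordinate_space!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: dict[tuple[str, str], dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        try:
            start, end = int(row.start), int(row.end)
            iv = GenomicInterval(str(row.seqid), start, end, str(row.strand))
        except (ValueError, TypeError) as exc:
            log.warning("%s line %d: rejected row (%s)", path, i, exc)
            continue
        key = (str(row.dataset), str(row.chimera))
        rec = records.setdefault(
            key,
            {"mirna": str(row.mirna), "cell_line": str(row.cell_line), "blocks": []},
        )
        rec["blocks"].append(iv)
    return [
        InteractionRecord(
            mirna=rec["mirna"],
            blocks=tuple(rec["blocks"]),
            dataset=dataset,
            chimera=chimera,
            cell_line=rec["cell_line"],
        )
        for (dataset, chimera), rec in records.items()
    ]


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for b in rec.blocks:
            rows.append(
                (b.seqid, b.start, b.end, b.strand, rec.mirna, rec.dataset, rec.chimera, rec.cell_line)
            )
    pd.DataFrame(rows, columns=INTERACTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peaks(path: str | Path) -> list[PeakRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    peaks = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            iv = GenomicInterval(str(row.seqid), int(row.start), int(row.end), str(row.strand))
        except (ValueError, TypeError) as exc:
            log.warning("%s line %d: rejected row (%s)", path, i, exc)
            continue
        peaks.append(PeakRecord(iv, str(row.dataset), str(row.cell_line), str(row.method)))
    return peaks


def write_peaks(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    rows = [
        (p.interval.seqid, p.interval.start, p.interval.end, p.interval.strand,
         p.dataset, p.cell_line, p.method)
        for p in peaks
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a GTF-lite TSV (exon and CDS rows) into gene models."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GTF_LITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    genes: dict[str, GeneModel] = {}
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_cds: dict[str, list[tuple[int, int]]] = {}
    tx_gene: dict[str, str] = {}
    for row in df.itertuples(index=False):
        gid, tid = str(row.gene_id), str(row.transcript_id)
        if gid not in genes:
            genes[gid] = GeneModel(gid, str(row.gene_name), str(row.biotype))
        tx_gene[tid] = gid
        iv = (str(row.seqid), int(row.start), int(row.end), str(row.strand))
        if row.feature == "exon":
            tx_exons.setdefault(tid, []).append(GenomicInterval(*iv))
        elif row.feature == "CDS":
            tx_cds.setdefault(tid, []).append((int(row.start), int(row.end)))
        else:
            raise ValueError(f"{path}: unknown feature {row.feature!r}")
    for tid, exons in tx_exons.items():
        cds = None
        if tid in tx_cds:
            cds = (min(s for s, _ in tx_cds[tid]), max(e for _, e in tx_cds[tid]))
        gid = tx_gene[tid]
        genes[gid].transcripts[tid] = Transcript(tid, gid, tuple(exons), cds)
    return list(genes.values())


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        for tx in g.transcripts.values():
            for e in tx.exons:
                rows.append((g.gene_id, g.gene_name, g.biotype, tx.transcript_id,
                             "exon", e.seqid, e.start, e.end, e.strand))
            if tx.cds is not None:
                cs, ce = tx.cds
                for e in tx.exons:
                    o_start, o_end = max(e.start, cs), min(e.end, ce)
                    if o_start < o_end:
                        rows.append((g.gene_id, g.gene_name, g.biotype, tx.transcript_id,
                                     "CDS", e.seqid, o_start, o_end, e.strand))
    pd.DataFrame(rows, columns=GTF_LITE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED6 and VCF
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str, str]]:
    """Read BED6; returns (interval, name, score) triples. BED is already
    0-based half-open so coordinates pass through unchanged."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path} line {i}: expected 6 BED columns")
            seqid, start, end, name, score, strand = fields[:6]
            out.append((GenomicInterval(seqid, int(start), int(end), strand), name, score))
    return out


def write_bed(regions: Iterable[tuple[GenomicInterval, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, name, score in regions:
            fh.write(f"{iv.seqid}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


@dataclass
class VcfRecord:
    """One VCF body line, kept as raw fields for lossless rewriting."""

    fields: list[str]  # CHROM POS ID REF ALT QUAL FILTER INFO [...]

    @property
    def chrom(self) -> str:
        return self.fields[0]

    @property
    def pos(self) -> int:
        """1-based position as written in the file."""
        return int(self.fields[1])

    @property
    def point(self) -> GenomicInterval:
        """Internal 0-based half-open single-base interval."""
        return GenomicInterval(self.chrom, self.pos - 1, self.pos, ".")

    @property
    def info(self) -> str:
        return self.fields[7]

    @info.setter
    def info(self, value: str) -> None:
        self.fields[7] = value

    def line(self) -> str:
        return "\t".join(self.fields)


@dataclass
class VcfFile:
    header: list[str]  # '##' meta lines plus the '#CHROM' column line
    records: list[VcfRecord]

    @property
    def version(self) -> str:
        for line in self.header:
            if line.startswith("##fileformat="):
                return line.split("=", 1)[1]
        return ""

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for line in self.header:
                fh.write(line + "\n")
            for rec in self.records:
                fh.write(rec.line() + "\n")


def read_vcf(path: str | Path, size_limit_mb: float = 20.0) -> VcfFile:
    """Read a VCF v4.0/v4.1 file with the standard 8 fixed columns.

    Files larger than ``size_limit_mb`` are refused, mirroring the upload
    limit of the original query service.
    """
    path = Path(path)
    size_mb = path.stat().st_size / 1e6
    if size_mb > size_limit_mb:
        raise ValueError(
            f"{path}: file is {size_mb:.1f} MB, over the {size_limit_mb:.0f} MB limit"
        )
    header: list[str] = []
    records: list[VcfRecord] = []
    saw_columns = False
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##"):
                header.append(line)
            elif line.startswith("#CHROM"):
                header.append(line)
                saw_columns = True
            elif line:
                fields = line.split("\t")
                if len(fields) < 8:
                    raise ValueError(f"{path} line {i}: fewer than 8 VCF columns")
                int(fields[1])  # POS must parse
                records.append(VcfRecord(fields))
    if not header or not header[0].startswith("##fileformat=VCF"):
        raise ValueError(f"{path}: missing or unparseable ##fileformat header")
    if not saw_columns:
        raise ValueError(f"{path}: missing #CHROM column header")
    version = header[0].split("=", 1)[1]
    if version not in ("VCFv4.0", "VCFv4.1"):
        raise ValueError(f"{path}: unsupported VCF version {version!r}")
    return VcfFile(header, records)
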