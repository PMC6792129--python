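"""Consensus calling of experimentally confirmed miRNA-binding regions
(Exp-MiBRs) from merged CLIP peaks and chimeric interactions.

Every covered genomic position accumulates an evidence set whose units are
either a non-chimeric CLIP dataset (a GSM contributes at most once per
position, however many of its peaks stack there) or an individual chimera
(each chimeric read is its own unit, so two chimeras from one dataset count
twice).  An Exp-MiBR is a maximal run of >= L consecutive positions each
supported by >= n units; the default L=10, n=2 asks every base to be seen
independently at least twice.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    Annotation,
    GeneModelIndex,
    GenomicInterval,
    InteractionRecord,
    PeakRecord,
)

Evidence = tuple  # ("ds", dataset) or ("ch", dataset, chimera)


@dataclass
class SupportProfile:
    """Sparse per-position evidence sets, keyed by (seqid, strand)."""

    positions: dict[tuple[str, str], dict[int, set]] = field(
        default_factory=lambda: defaultdict(lambda: defaultdict(set))
    )
    #: evidence unit -> (cell line, miRNA or None), for region characterization
    unit_meta: dict[Evidence, tuple[str, Optional[str]]] = field(default_factory=dict)

    def add_interval(self, iv: GenomicInterval, unit: Evidence,
                     cell_line: str = "", mirna: Optional[str] = None) -> None:
        strands = ("+", "-") if iv.strand == "." else (iv.strand,)
        for strand in strands:
            track = self.positions[(iv.seqid, strand)]
            for pos in range(iv.start, iv.end):
                track[pos].add(unit)
        self.unit_meta[unit] = (cell_line, mirna)

    def covered_positions(self) -> int:
        seen: dict[str, set] = defaultdict(set)
        for (seqid, _), track in self.positions.items():
            seen[seqid].update(track.keys())
        return sum(len(s) for s in seen.values())


@dataclass
class ExpMiBR:
    interval: GenomicInterval
    support_min: int
    support_max: int
    datasets: frozenset[str]
    cell_lines: frozenset[str] = frozenset()
    mirnas: frozenset[str] = frozenset()
    annotation: Optional[Annotation] = None

    @property
    def region_id(self) -> str:
        iv = self.interval
        return f"{iv.seqid}:{iv.start}-{iv.end}({iv.strand})"


def build_support_profile(
    peaks: Iterable[PeakRecord] = (),
    interactions: Iterable[InteractionRecord] = (),
) -> SupportProfile:
    """Union per-position evidence from CLIP peaks and chimera blocks.

    Idempotent under duplicated peak rows of one dataset (set semantics) and
    invariant to input order.  A chimera's parent dataset does not also count
    as a non-chimeric unit for that chimera's positions.
    """
    profile = SupportProfile()
    for peak in peaks:
        profile.add_interval(peak.interval, ("ds", peak.dataset), peak.cell_line)
    for rec in interactions:
        unit = ("ch", rec.dataset, rec.chimera)
        for block in rec.blocks:
            profile.add_interval(block, unit, rec.cell_line, rec.mirna)
    return profile


def extract_regions(
    profile: SupportProfile,
    min_length: int = 10,
    min_support: int = 2,
    mode: str = "run",
) -> list[ExpMiBR]:
    """All maximal runs of consecutive positions with evidence count >=
    ``min_support`` whose length is >= ``min_length``.

    ``mode='run'`` (default) emits the qualifying run itself, trimmed to the
    supported positions; ``mode='merged'`` expands each qualifying run to the
    full merged footprint (any evidence) containing it.
    """
    if min_length < 1 or min_support < 1:
        raise ValueError("min_length and min_support must be >= 1")
    if mode not in ("run", "merged"):
        raise ValueError(f"unknown mode {mode!r}")
    regions: list[ExpMiBR] = []
    for (seqid, strand), track in sorted(profile.positions.items()):
        if not track:
            continue
        positions = np.array(sorted(track.keys()))
        counts = np.array([len(track[p]) for p in positions])
        qualifying = counts >= min_support
        runs = _maximal_runs(positions, qualifying)
        emitted: set[tuple[int, int]] = set()
        for run_start, run_end in runs:
            if run_end - run_start < min_length:
                continue
            if mode == "merged":
                run_start, run_end = _expand_to_footprint(positions, run_start, run_end)
                if (run_start, run_end) in emitted:
                    continue  # footprint already reported for an earlier run
                emitted.add((run_start, run_end))
            member = [p for p in range(run_start, run_end) if p in track]
            units = set().union(*(track[p] for p in member))
            per_pos = [len(track[p]) for p in member]
            datasets = frozenset(u[1] for u in units)
            cell_lines = frozenset(
                profile.unit_meta.get(u, ("", None))[0] for u in units
            ) - {""}
            mirnas = frozenset(
                m for u in units
                if (m := profile.unit_meta.get(u, ("", None))[1]) is not None
            )
            regions.append(
                ExpMiBR(
                    GenomicInterval(seqid, run_start, run_end, strand),
                    support_min=min(per_pos),
                    support_max=max(per_pos),
                    datasets=datasets,
                    cell_lines=cell_lines,
                    mirnas=mirnas,
                )
            )
    return regions


def _maximal_runs(positions: np.ndarray, qualifying: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of *consecutive genomic positions* that qualify."""
    runs: list[tuple[int, int]] = []
    run_start: Optional[int] = None
    prev: Optional[int] = None
    for pos, ok in zip(positions.tolist(), qualifying.tolist()):
        if ok and run_start is not None and pos == prev + 1:
            prev = pos
            continue
        if run_start is not None:
            runs.append((run_start, prev + 1))
            run_start = None
        if ok:
            run_start, prev = pos, pos
    if run_start is not None:
        runs.append((run_start, prev + 1))
    return runs


def _expand_to_footprint(positions: np.ndarray, start: int, end: int) -> tuple[int, int]:
    """Grow [start, end) to the maximal covered run of consecutive positions
    containing it (any evidence count)."""
    pos_set = set(positions.tolist())
    while start - 1 in pos_set:
        start -= 1
    while end in pos_set:
        end += 1
    return start, end


def parameter_grid(
    profile: SupportProfile,
    lengths: Sequence[int] = range(1, 26),
    supports: Sequence[int] = range(1, 11),
    mode: str = "merged",
) -> pd.DataFrame:
    """Region counts over an (L, n) grid; rows are L values, columns n values.

    The default ``mode='merged'`` counts merged coverage footprints that
    harbor a qualifying run (>= L consecutive positions at support >= n);
    these counts are non-increasing in n at fixed L and in L at fixed n.
    ``mode='run'`` counts the maximal qualifying runs themselves, which is
    not monotone in n at small L: demanding more support can split one long
    run into several shorter ones.
    """
    if not len(lengths) or not len(supports):
        raise ValueError("empty parameter ranges")
    if mode not in ("run", "merged"):
        raise ValueError(f"unknown mode {mode!r}")
    data = {}
    for n in supports:
        # one pass per n: per-footprint max qualifying-run length (merged) or
        # the multiset of run lengths (run) determines counts for every L
        key_lengths: list[int] = []
        for (seqid, strand), track in profile.positions.items():
            positions = np.array(sorted(track.keys()))
            if positions.size == 0:
                continue
            counts = np.array([len(track[p]) for p in positions])
            runs = _maximal_runs(positions, counts >= n)
            if mode == "run":
                key_lengths.extend(e - s for s, e in runs)
            else:
                best: dict[tuple[int, int], int] = {}
                for s, e in runs:
                    fp = _expand_to_footprint(positions, s, e)
                    best[fp] = max(best.get(fp, 0), e - s)
                key_lengths.extend(best.values())
        arr = np.array(key_lengths or [0])
        data[n] = [int((arr >= L).sum()) for L in lengths]
    return pd.DataFrame(data, index=pd.Index(lengths, name="L")).rename_axis(
        columns="n"
    )


def characterize_regions(
    regions: Iterable[ExpMiBR],
    gene_index: Optional[GeneModelIndex] = None,
) -> list[ExpMiBR]:
    """Attach gene/part annotation to regions (dataset, cell-line and miRNA
    lists are already aggregated during extraction)."""
    out = []
    for region in regions:
        if gene_index is not None:
            region.annotation = gene_index.annotate(region.interval)
        else:
            region.annotation = Annotation(None, "intergenic")
        out.append(region)
    return out


@dataclass
class TissueSummary:
    exclusive: dict[str, int]  # cell line -> regions seen only there
    shared: int  # regions seen in >1 cell line
    ubiquitous: list[str]  # region ids seen in >= k cell lines
    k: int


def tissue_summary(regions: Sequence[ExpMiBR], k: int = 7) -> TissueSummary:
    """Exclusive/shared partition of regions by cell line, plus the
    'housekeeping' set seen in >= k cell lines (default 7 of the 9-line
    vocabulary)."""
    exclusive: dict[str, int] = defaultdict(int)
    shared = 0
    ubiquitous: list[str] = []
    for region in regions:
        lines = region.cell_lines
        if len(lines) == 1:
            exclusive[next(iter(lines))] += 1
        elif len(lines) > 1:
            shared += 1
        if len(lines) >= k:
            ubiquitous.append(region.region_id)
    return TissueSummary(dict(exclusive), shared, ubiquitous, k)


@dataclass
class CoverageSummary:
    seqid: str
    covered_fraction: float
    genes_touched: int
    genes_total: int


def sequence_coverage(
    regions: Sequence[ExpMiBR],
    seqid: str,
    seq_length: int,
    gene_index: Optional[GeneModelIndex] = None,
) -> CoverageSummary:
    """Fraction of a sequence covered by the union of regions, plus the count
    of its genes touched exonically (used in the paper-scale analysis for the
    mitochondrial genome)."""
    if seq_length <= 0:
        raise ValueError(f"unknown or zero-length seqid {seqid!r}")
    covered: set[int] = set()
    on_seq = [r for r in regions if r.interval.seqid == seqid]
    for region in on_seq:
        covered.update(range(region.interval.start, region.interval.end))
    genes_touched = 0
    genes_total = 0
    if gene_index is not None:
        for gene in gene_index.genes_on(seqid):
            genes_total += 1
            exons = [
                e
                for tx in gene.transcripts.values()
                for e in tx.exons
            ]
            if any(
                r.interval.overlap_length(e) > 0 for r in on_seq for e in exons
            ):
                genes_touched += 1
    return CoverageSummary(seqid, len(covered) / seq_length, genes_touched, genes_total)


# ---------------------------------------------------------------------------
# table I/O (columns mirror the published region catalogue)
# ---------------------------------------------------------------------------

MIBR_COLUMNS = [
    "seqid", "start", "end", "strand", "region_id", "gene_id", "part",
    "n_datasets", "datasets", "cell_lines", "mirnas", "support_min", "support_max",
]


def write_mibr_table(regions: Iterable[ExpMiBR], path: str | Path) -> None:
    rows = []
    for r in regions:
        ann = r.annotation or Annotation(None, "intergenic")
        rows.append(
            (
                r.interval.seqid, r.interval.start, r.interval.end, r.interval.strand,
                r.region_id, ann.gene_id or ".", ann.part,
                len(r.datasets), ",".join(sorted(r.datasets)) or ".",
                ",".join(sorted(r.cell_lines)) or ".",
                ",".join(sorted(r.mirnas)) or ".",
                r.support_min, r.support_max,
            )
        )
    pd.DataFrame(rows, columns=MIBR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mibr_table(path: str | Path) -> list[ExpMiBR]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MIBR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    regions = []
    for row in df.itertuples(index=False):
        def _split(v: str) -> frozenset[str]:
            return frozenset() if v == "." else frozenset(str(v).split(","))

        region = ExpMiBR(
            GenomicInterval(str(row.seqid), int(row.start), int(row.end), str(row.strand)),
            support_min=int(row.support_min),
            support_max=int(row.support_max),
            datasets=_split(row.datasets),
            cell_lines=_split(row.cell_lines),
            mirnas=_split(row.mirnas),
            annotation=Annotation(
                None if row.gene_id == "." else str(row.gene_id), str(row.part)
            ),
        )
        regions.append(region)
    return regions
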