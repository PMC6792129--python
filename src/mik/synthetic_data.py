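"""Synthetic genomes, chimeric interaction sets, CLIP peak replicates,
expression tables and conservation tracks with planted ground truth.

The generators emulate the statistical shape of AGO-CLIP interactome data:
interaction footprints of ~37 +/- 19 nt with ~19% split across two exons,
replicate CLIP peak sets sharing true binding regions, miRNA cohorts whose
expression-to-interaction ratio R carries planted type-1 (abundant, few
targets) and type-2 (promiscuous, modest expression) outliers, and genes with
planted sponge-like interaction loads.  Every planted fact is recorded in a
:class:`TruthManifest` sufficient to predict the output of each pipeline
stage.

The miRNA cohort is built from four background strata (mid-ratio bulk, a
high-expression stratum, a high-ratio stratum and a low-ratio stratum) whose
expression and interaction quotas are chosen so that no background miRNA can
sit strictly outside both nearest-rank percentile cutoffs at once; planted
type-1/type-2 miRNAs are therefore the only strict exceedances by
construction, with comfortable margins rather than exact ties.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import genome_io
from .genome_io import (
    GeneModel,
    GenomicInterval,
    InteractionRecord,
    PeakRecord,
    Transcript,
)

CELL_LINE_VOCAB = (
    "HEK293", "Huh7.5", "HeLa", "HFF", "BC-1", "BC-3", "EF3D", "LCL35", "LCL",
)

DEFAULT_SEQ_LENGTHS = {"chr1": 500_000, "chr2": 484_000, "chrM": 16_000}

INTERACTION_LENGTH_MEAN = 37.2
INTERACTION_LENGTH_SD = 19.4
INTERACTION_LENGTH_BOUNDS = (8, 200)
MULTI_EXON_FRACTION = 0.19


@dataclass
class TruthManifest:
    seed: int
    true_regions: list[dict] = field(default_factory=list)
    expected_mibr: list[dict] = field(default_factory=list)
    sponge_genes: dict[str, int] = field(default_factory=dict)
    nonexpressed_interacting_genes: list[str] = field(default_factory=list)
    type1_mirnas: list[str] = field(default_factory=list)
    type2_mirnas: list[str] = field(default_factory=list)
    mirna_quotas: dict[str, int] = field(default_factory=dict)
    planted_common: int = 0
    fp_peaks_per_dataset: dict[str, int] = field(default_factory=dict)
    seq_lengths: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _interval_dict(iv: GenomicInterval) -> dict:
    return {"seqid": iv.seqid, "start": iv.start, "end": iv.end, "strand": iv.strand}


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def gen_genome(
    seed: int,
    n_genes: int = 200,
    seq_lengths: Optional[dict[str, int]] = None,
    noncoding_fraction: float = 0.2,
    max_exons: int = 5,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping gene models packed along each sequence.

    Nuclear genes carry 1..``max_exons`` exons (120-300 nt) separated by
    80-400 nt introns on either strand; coding genes get a CDS flanked by
    UTRs.  A compact chrM-like contig, when present, is packed with
    single-exon genes.  Deterministic for a seed; raises if the gene quota
    does not fit.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    seq_lengths = dict(seq_lengths or DEFAULT_SEQ_LENGTHS)
    seqids = list(seq_lengths)
    total = sum(seq_lengths.values())
    # largest-remainder apportionment of the gene quota across contigs
    raw = {s: n_genes * seq_lengths[s] / total for s in seqids}
    quotas = {s: int(raw[s]) for s in seqids}
    for s in sorted(seqids, key=lambda s: raw[s] - quotas[s], reverse=True):
        if sum(quotas.values()) >= n_genes:
            break
        quotas[s] += 1

    genes: list[GeneModel] = []
    gi = 0
    for seqid in seqids:
        cursor = int(rng.integers(200, 800))
        compact = seq_lengths[seqid] < 50_000
        for _ in range(quotas[seqid]):
            strand = "+" if rng.random() < 0.5 else "-"
            if compact:
                n_ex = 1
                exon_lens = [int(rng.integers(600, 1500))]
                intron_lens = []
            else:
                n_ex = int(rng.integers(1, max_exons + 1))
                exon_lens = [int(rng.integers(120, 301)) for _ in range(n_ex)]
                intron_lens = [int(rng.integers(80, 401)) for _ in range(n_ex - 1)]
            span = sum(exon_lens) + sum(intron_lens)
            if cursor + span > seq_lengths[seqid]:
                raise ValueError(
                    f"cannot pack {quotas[seqid]} genes into {seqid} "
                    f"({seq_lengths[seqid]} nt)"
                )
            exons = []
            pos = cursor
            for k, elen in enumerate(exon_lens):
                exons.append(GenomicInterval(seqid, pos, pos + elen, strand))
                pos += elen
                if k < len(intron_lens):
                    pos += intron_lens[k]
            gid = f"G{gi:04d}"
            noncoding = compact or rng.random() < noncoding_fraction
            cds = None
            if not noncoding:
                # CDS covers the exon union minus short UTRs at both ends
                tlen = sum(exon_lens)
                utr_a = int(rng.integers(20, max(21, tlen // 5)))
                utr_b = int(rng.integers(20, max(21, tlen // 5)))
                if utr_a + utr_b + 30 > tlen:
                    utr_a = utr_b = max(1, tlen // 10)
                blocks = genome_io.project_to_genome(utr_a, tlen - utr_b, exons)
                cds = (blocks[0].start, blocks[-1].end)
            tx = Transcript(f"{gid}.t1", gid, tuple(exons), cds)
            gene = GeneModel(gid, f"GENE{gi:04d}", "noncoding" if noncoding else "coding")
            gene.transcripts[tx.transcript_id] = tx
            genes.append(gene)
            gi += 1
            cursor = pos + int(rng.integers(200, 2001))
    return genes, seq_lengths


# ---------------------------------------------------------------------------
# interaction footprints
# ---------------------------------------------------------------------------

def _calibrated_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter such that the [lo, hi]-truncated normal has the
    requested mean (plain truncation would inflate it)."""
    loc = mean
    for _ in range(40):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        drift = stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean
        if abs(drift) < 1e-9:
            break
        loc -= drift
    return loc


def _length_sampler(rng: np.random.Generator, n: int,
                    mean: float = INTERACTION_LENGTH_MEAN,
                    sd: float = INTERACTION_LENGTH_SD) -> np.ndarray:
    lo, hi = INTERACTION_LENGTH_BOUNDS
    loc = _calibrated_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    draws = stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)
    return np.maximum(lo, np.round(draws)).astype(int)


def _place_in_transcript(
    tx: Transcript, length: int, rng: np.random.Generator, want_multi_exon: bool
) -> tuple[int, int]:
    """Pick a transcript-space interval of the given length, optionally
    straddling an exon junction."""
    length = min(length, tx.length)
    if want_multi_exon and len(tx.exons) > 1 and length >= 2:
        boundaries = np.cumsum([e.length for e in tx.exons])[:-1]
        b = int(boundaries[rng.integers(0, len(boundaries))])
        start = b - int(rng.integers(1, length))
        start = max(0, min(start, tx.length - length))
        return start, start + length
    start = int(rng.integers(0, tx.length - length + 1))
    return start, start + length


def gen_interactions(
    genes: Sequence[GeneModel],
    mirna_quotas: dict[str, int],
    dataset: str,
    cell_line: str,
    seed: int,
    gene_quotas: Optional[dict[str, int]] = None,
    eligible_genes: Optional[Sequence[str]] = None,
    multi_exon_frac: float = MULTI_EXON_FRACTION,
    length_mean: float = INTERACTION_LENGTH_MEAN,
    length_sd: float = INTERACTION_LENGTH_SD,
    fill_cap: int = 30,
) -> list[InteractionRecord]:
    """Chimera-derived interaction records honoring per-miRNA record quotas
    and optional per-gene minimum record quotas.

    Footprint lengths follow a truncated normal (mean 37.2, sd 19.4, bounded
    to [8, 200]); a ``multi_exon_frac`` fraction of placements straddle an
    exon junction where the host transcript allows it.
    """
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genes}
    pool = list(eligible_genes) if eligible_genes is not None else list(by_id)

    mirna_list = [m for m, q in sorted(mirna_quotas.items()) for _ in range(q)]
    rng.shuffle(mirna_list)
    n = len(mirna_list)

    gene_list: list[str] = []
    for gid, q in sorted((gene_quotas or {}).items()):
        gene_list.extend([gid] * q)
    if len(gene_list) > n:
        raise ValueError("gene quotas exceed total interaction records")
    # heavy-tailed per-gene placement weights: most genes draw few or no
    # records, a handful draw many, as in observed interaction tallies; the
    # random fill is capped below the sponge threshold and skips quota genes,
    # so planted interaction loads stay the only extreme ones
    fill_pool = [g for g in pool if g not in (gene_quotas or {})]
    weights = rng.lognormal(0.0, 1.5, size=len(fill_pool))
    weights /= weights.sum()
    fill = [
        fill_pool[i]
        for i in rng.choice(len(fill_pool), size=n - len(gene_list), p=weights)
    ]
    tally = {g: fill.count(g) for g in set(fill)}
    below_cap = [g for g in fill_pool if tally.get(g, 0) < fill_cap]
    for k, gid in enumerate(fill):
        if tally[gid] > fill_cap:
            tally[gid] -= 1
            new = below_cap[int(rng.integers(0, len(below_cap)))]
            while tally.get(new, 0) >= fill_cap:
                new = below_cap[int(rng.integers(0, len(below_cap)))]
            tally[new] = tally.get(new, 0) + 1
            fill[k] = new
    gene_list.extend(fill)
    rng.shuffle(gene_list)

    lengths = _length_sampler(rng, n, length_mean, length_sd)
    records = []
    for k in range(n):
        gene = by_id[gene_list[k]]
        tx = max(gene.transcripts.values(), key=lambda t: t.length)
        want_multi = rng.random() < multi_exon_frac
        start, end = _place_in_transcript(tx, int(lengths[k]), rng, want_multi)
        blocks = genome_io.project_to_genome(start, end, tx)
        records.append(
            InteractionRecord(
                mirna=mirna_list[k],
                blocks=tuple(blocks),
                dataset=dataset,
                chimera=f"{dataset}_c{k:05d}",
                cell_line=cell_line,
                gene_id=gene.gene_id,
            )
        )
    return records


# ---------------------------------------------------------------------------
# true binding regions and CLIP peaks
# ---------------------------------------------------------------------------

def gen_true_regions(
    genes: Sequence[GeneModel],
    n_regions: int,
    seed: int,
    min_len: int = 12,
    max_len: int = 60,
    chrm_regions: int = 20,
) -> list[GenomicInterval]:
    """Plant non-adjacent single-exon binding regions in exonic space,
    with a dense extra allocation on a chrM-like compact contig (if present)
    to exercise sequence-coverage summaries."""
    rng = np.random.default_rng(seed)
    occupied: dict[str, set[int]] = {}
    regions: list[GenomicInterval] = []

    def try_place(gene: GeneModel) -> Optional[GenomicInterval]:
        tx = max(gene.transcripts.values(), key=lambda t: t.length)
        exon = tx.exons[rng.integers(0, len(tx.exons))]
        length = int(rng.integers(min_len, max_len + 1))
        if exon.length < length:
            length = exon.length
        start = exon.start + int(rng.integers(0, exon.length - length + 1))
        iv = GenomicInterval(exon.seqid, start, start + length, exon.strand)
        occ = occupied.setdefault(iv.seqid, set())
        footprint = set(range(iv.start - 1, iv.end + 1))  # 1 nt separation
        if occ & footprint:
            return None
        occ.update(range(iv.start, iv.end))
        return iv

    compact = [g for g in genes if g.seqid.endswith("M")]
    nuclear = [g for g in genes if not g.seqid.endswith("M")]
    for _ in range(n_regions * 4):
        if len(regions) >= n_regions:
            break
        gene = nuclear[rng.integers(0, len(nuclear))]
        iv = try_place(gene)
        if iv is not None:
            regions.append(iv)
    placed_m = 0
    for _ in range(chrm_regions * 4):
        if placed_m >= chrm_regions or not compact:
            break
        gene = compact[rng.integers(0, len(compact))]
        iv = try_place(gene)
        if iv is not None:
            regions.append(iv)
            placed_m += 1
    return regions


def gen_clip_peaks(
    true_regions: Sequence[GenomicInterval],
    n_datasets: int,
    seed: int,
    jitter_sd: float = 0.0,
    fp_rate: int = 0,
    coverage_p: float = 1.0,
    cell_line_map: Optional[dict[str, str]] = None,
    seq_lengths: Optional[dict[str, int]] = None,
) -> tuple[list[PeakRecord], list[GenomicInterval], dict[str, int]]:
    """Replicate CLIP peak sets sharing the true regions.

    Each dataset covers each true region with probability ``coverage_p``,
    with optionally jittered boundaries, plus ``fp_rate`` uniformly placed
    false-positive peaks private to that dataset.  Returns the peaks, the
    expected consensus truth (runs of >= 10 consecutive positions covered by
    >= 2 datasets, computed by direct per-position counting over the emitted
    peaks) and the per-dataset false-positive counts.
    """
    if n_datasets < 2:
        raise ValueError("need >= 2 datasets to exercise the n=2 support rule")
    rng = np.random.default_rng(seed)
    seq_lengths = dict(seq_lengths or DEFAULT_SEQ_LENGTHS)
    datasets = [f"SIMGSM{d:03d}" for d in range(n_datasets)]
    if cell_line_map is None:
        cell_line_map = {
            ds: CELL_LINE_VOCAB[d % len(CELL_LINE_VOCAB)]
            for d, ds in enumerate(datasets)
        }
    peaks: list[PeakRecord] = []
    fp_counts: dict[str, int] = {}
    for ds in datasets:
        for region in true_regions:
            if rng.random() > coverage_p:
                continue
            start, end = region.start, region.end
            if jitter_sd > 0:
                start = max(0, start + int(round(rng.normal(0, jitter_sd))))
                end = end + int(round(rng.normal(0, jitter_sd)))
                if end - start < 1:
                    end = start + 1
            peaks.append(
                PeakRecord(
                    GenomicInterval(region.seqid, start, end, region.strand),
                    ds, cell_line_map[ds], "HITS-CLIP",
                )
            )
        fp_counts[ds] = fp_rate
        for _ in range(fp_rate):
            seqid = list(seq_lengths)[int(rng.integers(0, len(seq_lengths)))]
            length = int(rng.integers(15, 60))
            start = int(rng.integers(0, seq_lengths[seqid] - length))
            strand = "+" if rng.random() < 0.5 else "-"
            peaks.append(
                PeakRecord(
                    GenomicInterval(seqid, start, start + length, strand),
                    ds, cell_line_map[ds], "HITS-CLIP",
                )
            )
    expected = _expected_consensus(peaks, min_support=2, min_length=10)
    return peaks, expected, fp_counts


def _expected_consensus(
    peaks: Sequence[PeakRecord], min_support: int, min_length: int
) -> list[GenomicInterval]:
    """Per-position counting of distinct datasets (independent of the
    consensus caller): runs of >= min_length consecutive positions covered by
    >= min_support datasets."""
    cover: dict[tuple[str, str], dict[int, set[str]]] = {}
    for p in peaks:
        strands = ("+", "-") if p.interval.strand == "." else (p.interval.strand,)
        for strand in strands:
            track = cover.setdefault((p.interval.seqid, strand), {})
            for pos in range(p.interval.start, p.interval.end):
                track.setdefault(pos, set()).add(p.dataset)
    out: list[GenomicInterval] = []
    for (seqid, strand), track in sorted(cover.items()):
        good = sorted(p for p, ds in track.items() if len(ds) >= min_support)
        run: list[int] = []
        for pos in good + [None]:
            if run and (pos is None or pos != run[-1] + 1):
                if len(run) >= min_length:
                    out.append(GenomicInterval(seqid, run[0], run[-1] + 1, strand))
                run = []
            if pos is not None:
                run.append(pos)
    return out


# ---------------------------------------------------------------------------
# expression with planted miRNA types and sponge genes
# ---------------------------------------------------------------------------

@dataclass
class MirnaCohortPlan:
    quotas: dict[str, int]  # interaction records per miRNA
    target_expression: dict[str, float]  # normalized-scale expression target
    type1: list[str]
    type2: list[str]


def plan_mirna_cohort(
    seed: int,
    n_background: int = 194,
    n_type1: int = 3,
    n_type2: int = 3,
) -> MirnaCohortPlan:
    """Lay out the miRNA cohort strata (see module docstring).

    Background strata: bulk (ratio 20-60, 1-8 records), high-expression
    (20-30 records, ratio 35-55), high-ratio (1-2 records, expression
    150-400) and low-ratio (ratio 3-8, 3-8 records).  Planted type-1:
    expression 5e4, one record; planted type-2: expression 60, 60 records.
    Stratum boundaries leave multiplicative margin around every nearest-rank
    percentile cutoff, so planting never depends on exact ties.
    """
    if n_background + n_type1 + n_type2 < 10:
        raise ValueError("cohort too small to plant types")
    if n_background < 80:
        raise ValueError("need >= 80 background miRNAs for the strata layout")
    rng = np.random.default_rng(seed)
    quotas: dict[str, int] = {}
    target: dict[str, float] = {}
    n_hi_expr = n_hi_ratio = n_lo_ratio = max(5, round(n_background * 0.10))
    n_bulk = n_background - n_hi_expr - n_hi_ratio - n_lo_ratio
    i = 0

    def add(n_records: int, expr: float) -> str:
        nonlocal i
        mid = f"mir-{i:04d}"
        quotas[mid] = n_records
        target[mid] = expr
        i += 1
        return mid

    for _ in range(n_bulk):
        q = int(rng.integers(1, 9))
        add(q, q * rng.uniform(20, 60))
    for _ in range(n_hi_expr):
        q = int(rng.integers(20, 31))
        add(q, q * rng.uniform(35, 55))
    for _ in range(n_hi_ratio):
        q = int(rng.integers(1, 3))
        add(q, rng.uniform(150, 400))
    for _ in range(n_lo_ratio):
        q = int(rng.integers(3, 9))
        add(q, q * rng.uniform(3, 8))
    type1 = [add(1, 50_000.0) for _ in range(n_type1)]
    type2 = [add(60, 60.0) for _ in range(n_type2)]
    return MirnaCohortPlan(quotas, target, type1, type2)


def gen_expression(
    genes: Sequence[GeneModel],
    plan: MirnaCohortPlan,
    planted_sponges: Sequence[str],
    nonexpressed_interacting: Sequence[str],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Transcript tpm table (2 replicates), miRNA count matrix (2 samples)
    and the transcript->gene map.

    Sample 2 of the count matrix is an exact doubling of sample 1, so the
    median-of-ratios normalized means land on the plan's expression targets
    (up to integer rounding of counts).  Sponge and other interacting genes
    are kept expressed; a declared subset stays at zero tpm to model
    chimera-only detections.
    """
    sponge_set = set(planted_sponges)
    silent = set(nonexpressed_interacting)
    if sponge_set & silent:
        raise ValueError("planted sets must be disjoint")
    rng = np.random.default_rng(seed)
    tx_rows = {}
    tx2gene = {}
    for g in genes:
        for tx in g.transcripts.values():
            tx2gene[tx.transcript_id] = g.gene_id
            if g.gene_id in silent:
                base = 0.0
            elif g.gene_id in sponge_set:
                base = rng.uniform(200, 2000)
            else:
                base = float(rng.lognormal(1.5, 1.2))
            reps = [
                max(0.0, base * rng.uniform(0.85, 1.15)) if base > 0 else 0.0
                for _ in range(2)
            ]
            tx_rows[tx.transcript_id] = reps
    tpm = pd.DataFrame.from_dict(
        tx_rows, orient="index", columns=["rep1", "rep2"]
    ).rename_axis("transcript_id")

    sqrt2 = float(np.sqrt(2.0))
    counts_a = {
        mid: max(1, int(round(expr / sqrt2)))
        for mid, expr in plan.target_expression.items()
    }
    counts = pd.DataFrame(
        {
            "s1": pd.Series(counts_a),
            "s2": pd.Series({m: 2 * c for m, c in counts_a.items()}),
        }
    ).rename_axis("mirna")
    return tpm, counts, tx2gene


# ---------------------------------------------------------------------------
# query VCF fixture
# ---------------------------------------------------------------------------

def gen_query_vcf(
    regions: Sequence[GenomicInterval],
    seq_lengths: dict[str, int],
    path: str | Path,
    seed: int,
    n_variants: int = 10,
    n_inside: int = 4,
) -> list[bool]:
    """Write a VCF v4.1 with ``n_inside`` variants planted inside regions and
    the rest planted strictly outside every region.  Returns the
    inside/outside flag per written variant (in file order)."""
    rng = np.random.default_rng(seed)
    if n_inside > n_variants:
        raise ValueError("n_inside cannot exceed n_variants")
    if n_inside > 0 and not regions:
        raise ValueError("no regions to plant variants into")
    occupied: dict[str, set[int]] = {}
    for r in regions:
        occupied.setdefault(r.seqid, set()).update(range(r.start, r.end))
    rows: list[tuple[str, int, bool]] = []
    for _ in range(n_inside):
        r = regions[int(rng.integers(0, len(regions)))]
        pos0 = int(rng.integers(r.start, r.end))
        rows.append((r.seqid, pos0 + 1, True))
    while sum(1 for _, _, inside in rows if not inside) < n_variants - n_inside:
        seqid = list(seq_lengths)[int(rng.integers(0, len(seq_lengths)))]
        pos0 = int(rng.integers(0, seq_lengths[seqid]))
        if pos0 in occupied.get(seqid, set()):
            continue
        rows.append((seqid, pos0 + 1, False))
    rng.shuffle(rows)  # type: ignore[arg-type]
    bases = "ACGT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.1\n")
        fh.write("##source=mik-sim\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for k, (seqid, pos, _) in enumerate(rows):
            ref = bases[int(rng.integers(0, 4))]
            alt = bases[(bases.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            fh.write(f"{seqid}\t{pos}\tv{k}\t{ref}\t{alt}\t.\tPASS\t.\n")
    return [inside for _, _, inside in rows]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_all(
    seed: int,
    outdir: str | Path,
    n_genes: int = 200,
    n_datasets: int = 5,
    n_true_regions: int = 100,
    n_common: int = 40,
    n_b_records: int = 400,
) -> TruthManifest:
    """Generate every input format plus ``truth.json`` under ``outdir``.

    Defaults are noise-free where a planted truth must be exactly
    recoverable (CLIP coverage probability 1, no boundary jitter, no false
    positives); sizes keep a full pipeline run in seconds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(8)]

    genes, seq_lengths = gen_genome(seeds[0], n_genes=n_genes)
    genome_io.write_gene_models(genes, outdir / "genome.tsv")

    plan = plan_mirna_cohort(seeds[1])
    coding_pool = [g.gene_id for g in genes if not g.seqid.endswith("M")]
    rng = np.random.default_rng(seeds[2])
    picks = rng.choice(len(coding_pool), size=8, replace=False)
    sponges = [coding_pool[i] for i in picks[:3]]
    silent = [coding_pool[i] for i in picks[3:]]

    tpm, counts, tx2gene = gen_expression(genes, plan, sponges, silent, seeds[3])
    tpm.to_csv(outdir / "transcript_tpm.tsv", sep="\t")
    counts.to_csv(outdir / "mirna_counts.tsv", sep="\t")
    pd.Series(tx2gene, name="gene_id").rename_axis("transcript_id").to_csv(
        outdir / "tx2gene.tsv", sep="\t"
    )

    gene_quotas = {g: 60 for g in sponges}
    gene_quotas.update({g: 1 for g in silent})
    # restrict random placements to genes that pass the 1-tpm expression call,
    # so the non-expressed-interacting truth set is exactly the silent plant
    gene_tpm = tpm.groupby(pd.Series(tx2gene)).sum()
    retained = set(gene_tpm.index[(gene_tpm.mean(axis=1) >= 1.0)
                                  & (gene_tpm >= 1.0).any(axis=1)])
    eligible = [g for g in coding_pool if g not in silent and g in retained]
    interactions_a = gen_interactions(
        genes, plan.quotas, dataset="SIM_CLASH", cell_line="HEK293",
        seed=seeds[4], gene_quotas=gene_quotas, eligible_genes=eligible,
    )
    genome_io.write_interactions(interactions_a, outdir / "interactions_a.tsv")

    # dataset B: planted common placements copied from A plus independent fill
    rng_b = np.random.default_rng(seeds[5])
    chosen = rng_b.choice(len(interactions_a), size=n_common, replace=False)
    interactions_b: list[InteractionRecord] = []
    for k, idx in enumerate(sorted(chosen)):
        src = interactions_a[int(idx)]
        interactions_b.append(
            InteractionRecord(
                mirna=src.mirna, blocks=src.blocks, dataset="SIM_CLEAR",
                chimera=f"SIM_CLEAR_shared{k:05d}", cell_line="Huh7.5",
                gene_id=src.gene_id,
            )
        )
    fill_quota = {f"mirB-{j:03d}": 1 for j in range(n_b_records - n_common)}
    interactions_b.extend(
        gen_interactions(
            genes, fill_quota, dataset="SIM_CLEAR", cell_line="Huh7.5",
            seed=seeds[5], eligible_genes=eligible,
        )
    )
    genome_io.write_interactions(interactions_b, outdir / "interactions_b.tsv")

    true_regions = gen_true_regions(genes, n_true_regions, seeds[6])
    peaks, expected, fp_counts = gen_clip_peaks(
        true_regions, n_datasets=n_datasets, seed=seeds[7],
        seq_lengths=seq_lengths,
    )
    genome_io.write_peaks(peaks, outdir / "clip_peaks.tsv")
    _write_phylop_and_mature(genes, plan, seq_lengths, outdir, seeds[2])
    gen_query_vcf(expected, seq_lengths, outdir / "query.vcf", seeds[2])

    manifest = TruthManifest(
        seed=seed,
        true_regions=[_interval_dict(r) for r in true_regions],
        expected_mibr=[_interval_dict(r) for r in expected],
        sponge_genes={g: 60 for g in sponges},
        nonexpressed_interacting_genes=silent,
        type1_mirnas=plan.type1,
        type2_mirnas=plan.type2,
        mirna_quotas=plan.quotas,
        planted_common=n_common,
        fp_peaks_per_dataset=fp_counts,
        seq_lengths=seq_lengths,
    )
    manifest.to_json(outdir / "truth.json")
    return manifest


def _write_phylop_and_mature(
    genes: Sequence[GeneModel],
    plan: MirnaCohortPlan,
    seq_lengths: dict[str, int],
    outdir: Path,
    seed: int,
) -> None:
    """Mature miRNA coordinates tiled into intergenic tail space plus a
    per-base conservation track: planted types near 0.97, background near
    0.30 — the qualitative contrast between functional and bulk miRNAs."""
    rng = np.random.default_rng(seed)
    tail_start = max(
        (g.span.end for g in genes if g.seqid == "chr1"), default=0
    ) + 1000
    planted = set(plan.type1) | set(plan.type2)
    mature_rows = []
    phylop_rows = []
    pos = tail_start
    for mid in sorted(plan.quotas):
        if pos + 22 >= seq_lengths["chr1"]:
            break
        mature_rows.append(("chr1", pos, pos + 22, mid, 0, "+"))
        level = rng.normal(0.97, 0.01) if mid in planted else rng.normal(0.30, 0.05)
        for p in range(pos, pos + 22):
            phylop_rows.append(("chr1", p, round(float(np.clip(level + rng.normal(0, 0.02), -1, 1)), 4)))
        pos += 40
    pd.DataFrame(
        mature_rows, columns=["seqid", "start", "end", "mirna", "score", "strand"]
    ).to_csv(outdir / "mature_mirnas.tsv", sep="\t", index=False)
    pd.DataFrame(phylop_rows, columns=["seqid", "pos", "score"]).to_csv(
        outdir / "phylop.tsv", sep="\t", index=False
    )
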