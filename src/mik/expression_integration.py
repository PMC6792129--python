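"""Expression summarization and expression-aware classification.

Gene expression is summarized from transcript-level tpm (sum over transcripts
within replicate, then mean across replicates).  miRNA counts are normalized
by median-of-ratios size factors.  Genes are categorized by how many chimera
interactions they carry (a gene with >= ``sponge_cutoff`` records behaves as a
miRNA sponge); miRNAs are typed by the ratio R = expression / interaction
count, with type 1 (high expression, few interactions, R and expression above
the 90th percentile) and type 2 (R below the 10th percentile, interactions
above the 90th) read off nearest-rank percentiles with strict inequalities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModelIndex, InteractionRecord, Transcript, project_to_transcript

log = logging.getLogger(__name__)

GENE_CATEGORIES = (
    "non_expressed_interacting",
    "expressed_0",
    "expressed_1_8",
    "high_interacting",
    "sponge_like",
)


@dataclass
class ExpressionTable:
    """Replicate expression values for one entity class (transcripts, genes
    or miRNAs), tagged with the unit they are measured in."""

    values: pd.DataFrame  # index: entity id; columns: replicates
    unit: str  # tpm | counts | normalized_counts

    def __post_init__(self) -> None:
        if self.unit not in ("tpm", "counts", "normalized_counts"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.values.shape[1] < 1:
            raise ValueError("expression table needs at least one replicate")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def mean(self) -> pd.Series:
        return self.values.mean(axis=1)


@dataclass
class GeneInteractionSummary:
    gene_id: str
    expression: float
    n_interactions: int
    n_distinct_mirnas: int
    category: str


@dataclass
class MirnaSummary:
    mirna: str
    expression: float
    expressed: bool
    n_interactions: int
    ratio: Optional[float]  # R = expression / n_interactions; None when no interactions
    mirna_type: str = "none"  # type1 | type2 | none
    phylop_mean: Optional[float] = None


# ---------------------------------------------------------------------------
# expression summarization
# ---------------------------------------------------------------------------

def summarize_gene_expression(
    transcript_tpm: ExpressionTable,
    tx2gene: Mapping[str, str],
    min_total_tpm: float = 1.0,
    min_replicate_tpm: float = 1.0,
) -> ExpressionTable:
    """Gene-level tpm: sum transcript tpm within each replicate, keep genes
    whose across-replicate mean is >= ``min_total_tpm`` AND that reach
    ``min_replicate_tpm`` in at least one replicate.

    Transcripts absent from the mapping are excluded and logged.
    """
    if transcript_tpm.unit != "tpm":
        raise ValueError("transcript table must be in tpm")
    df = transcript_tpm.values
    known = df.index.isin(tx2gene.keys())
    for tid in df.index[~known]:
        log.warning("transcript %s absent from tx->gene mapping; excluded", tid)
    df = df.loc[known]
    gene_ids = pd.Series({tid: tx2gene[tid] for tid in df.index})
    gene_df = df.groupby(gene_ids).sum()
    keep = (gene_df.mean(axis=1) >= min_total_tpm) & (
        (gene_df >= min_replicate_tpm).any(axis=1)
    )
    return ExpressionTable(gene_df.loc[keep], "tpm")


def mor_size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors: per sample, the median over entities
    (restricted to entities with a nonzero geometric mean across samples) of
    count / geometric mean.  Falls back to all-ones with a warning when every
    entity contains a zero."""
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    log_geomean = log_mat.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        log.warning("every entity has a zero count; size factors set to 1")
        return np.ones(mat.shape[1])
    factors = np.exp(
        np.median(log_mat[usable] - log_geomean[usable, None], axis=0)
    )
    return factors


def normalize_mirna_counts(
    counts: pd.DataFrame,
    expressed_cutoff: float = 3.0,
) -> tuple[ExpressionTable, pd.Series, np.ndarray]:
    """Normalize a miRNA count matrix (rows: miRNAs; columns: samples) by
    median-of-ratios size factors.

    Returns the normalized table, a boolean "expressed" flag per miRNA
    (normalized mean >= ``expressed_cutoff``) and the size factors.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples to estimate size factors")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    factors = mor_size_factors(counts)
    normalized = counts / factors
    table = ExpressionTable(normalized, "normalized_counts")
    expressed = table.mean >= expressed_cutoff
    return table, expressed, factors


# ---------------------------------------------------------------------------
# interaction counting and categorization
# ---------------------------------------------------------------------------

def count_interactions(
    interactions: Sequence[InteractionRecord],
    level: str,
) -> pd.DataFrame:
    """Record-level interaction tallies.

    ``level='gene'``: per gene, the number of chimera records plus the number
    of distinct miRNA partners (requires gene assignment on the records).
    ``level='mirna'``: per miRNA, record count plus distinct gene partners.
    """
    if level not in ("gene", "mirna"):
        raise ValueError(f"unknown level {level!r}")
    counts: dict[str, int] = {}
    partners: dict[str, set] = {}
    for rec in interactions:
        if level == "gene":
            key = rec.gene_id
            partner = rec.mirna
        else:
            key = rec.mirna
            partner = rec.gene_id
        if key is None:
            continue
        counts[key] = counts.get(key, 0) + 1
        partners.setdefault(key, set()).add(partner)
    ids = sorted(counts)
    return pd.DataFrame(
        {
            "n_interactions": [counts[k] for k in ids],
            "n_distinct_partners": [
                len(partners[k] - {None}) for k in ids
            ],
        },
        index=pd.Index(ids, name=level),
    )


def assign_genes(
    interactions: Iterable[InteractionRecord],
    index: GeneModelIndex,
) -> list[InteractionRecord]:
    """Attach a gene id to each record via single-label annotation of its
    footprint (first block's annotation wins only if later blocks are
    intergenic)."""
    out = []
    for rec in interactions:
        gene = None
        for block in rec.blocks:
            ann = index.annotate(block)
            if ann.gene_id is not None:
                gene = ann.gene_id
                break
        rec.gene_id = gene
        out.append(rec)
    return out


def categorize_genes(
    gene_expression: ExpressionTable,
    interaction_counts: pd.DataFrame,
    high_cutoff: int = 9,
    sponge_cutoff: int = 50,
) -> list[GeneInteractionSummary]:
    """Partition genes by expression status and interaction load.

    Expressed genes split at 0 / 1..high_cutoff-1 / >=high_cutoff /
    >=sponge_cutoff interactions; genes with interactions but no detected
    expression are flagged separately (candidate mapping artifacts or
    AGO-protected fragments).
    """
    if sponge_cutoff < high_cutoff:
        raise ValueError("sponge_cutoff must be >= high_cutoff")
    expr = gene_expression.mean
    out: list[GeneInteractionSummary] = []
    gene_ids = set(expr.index) | set(interaction_counts.index)
    for gid in sorted(gene_ids):
        n = int(interaction_counts["n_interactions"].get(gid, 0))
        n_mirnas = int(interaction_counts["n_distinct_partners"].get(gid, 0))
        expressed = gid in expr.index
        if not expressed and n == 0:
            continue  # silent genes with no evidence carry no category
        if not expressed:
            cat = "non_expressed_interacting"
        elif n >= sponge_cutoff:
            cat = "sponge_like"
        elif n >= high_cutoff:
            cat = "high_interacting"
        elif n >= 1:
            cat = "expressed_1_8"
        else:
            cat = "expressed_0"
        out.append(
            GeneInteractionSummary(
                gid, float(expr.get(gid, 0.0)), n, n_mirnas, cat
            )
        )
    return out


# ---------------------------------------------------------------------------
# miRNA typing
# ---------------------------------------------------------------------------

def nearest_rank_percentile(values: Sequence[float], pct: float) -> float:
    """Nearest-rank percentile: the value at rank ceil(pct/100 * N) of the
    ascending sort (1-based)."""
    arr = sorted(values)
    if not arr:
        raise ValueError("empty cohort")
    rank = max(1, math.ceil(pct / 100.0 * len(arr)))
    return arr[rank - 1]


def build_mirna_summaries(
    normalized: ExpressionTable,
    expressed: pd.Series,
    interaction_counts: pd.DataFrame,
) -> list[MirnaSummary]:
    """Combine normalized expression and interaction tallies into per-miRNA
    summaries; R is defined only for interacting miRNAs."""
    mean_expr = normalized.mean
    ids = sorted(set(mean_expr.index) | set(interaction_counts.index))
    out = []
    for mid in ids:
        e = float(mean_expr.get(mid, 0.0))
        n = int(interaction_counts["n_interactions"].get(mid, 0))
        out.append(
            MirnaSummary(
                mirna=mid,
                expression=e,
                expressed=bool(expressed.get(mid, False)),
                n_interactions=n,
                ratio=(e / n) if n > 0 else None,
            )
        )
    return out


def classify_mirna_types(
    summaries: Sequence[MirnaSummary],
    pct_hi: float = 90.0,
    pct_lo: float = 10.0,
) -> tuple[list[MirnaSummary], dict[str, float]]:
    """Type miRNAs from the cohort of expressed AND interacting miRNAs.

    type 1: expression > P90(expression) and R > P90(R) — abundant miRNAs
    with few targets. type 2: R < P10(R) and interactions > P90(interactions)
    — promiscuous miRNAs at modest expression.  Percentiles are nearest-rank
    on the filtered cohort; comparisons are strict, so exact ties with the
    cutoff do not qualify.
    """
    cohort = [s for s in summaries if s.expressed and s.n_interactions > 0]
    cutoffs: dict[str, float] = {}
    if len(cohort) < 10:
        log.warning("only %d expressed+interacting miRNAs; no types called", len(cohort))
        for s in summaries:
            s.mirna_type = "none"
        return list(summaries), cutoffs
    expr = [s.expression for s in cohort]
    ratios = [s.ratio for s in cohort]
    counts = [float(s.n_interactions) for s in cohort]
    cutoffs = {
        "expression_hi": nearest_rank_percentile(expr, pct_hi),
        "ratio_hi": nearest_rank_percentile(ratios, pct_hi),
        "ratio_lo": nearest_rank_percentile(ratios, pct_lo),
        "interactions_hi": nearest_rank_percentile(counts, pct_hi),
    }
    in_cohort = {s.mirna for s in cohort}
    for s in summaries:
        s.mirna_type = "none"
        if s.mirna not in in_cohort:
            continue
        if s.expression > cutoffs["expression_hi"] and s.ratio > cutoffs["ratio_hi"]:
            s.mirna_type = "type1"
        elif s.ratio < cutoffs["ratio_lo"] and s.n_interactions > cutoffs["interactions_hi"]:
            s.mirna_type = "type2"
    return list(summaries), cutoffs


# ---------------------------------------------------------------------------
# conservation and positional profiles
# ---------------------------------------------------------------------------

def conservation_means(
    groups: Mapping[str, Sequence[str]],
    phylop: Mapping[str, Mapping[int, float]],
    mature_coords: Mapping[str, "object"],
) -> dict[str, float]:
    """Mean conservation per miRNA group.

    Per miRNA: mean of per-base phyloP over its mature span (missing bases
    skipped); per group: mean of the per-miRNA means.  miRNAs with no scored
    base are excluded and logged; an empty group is an error.
    """
    out: dict[str, float] = {}
    for group, mirnas in groups.items():
        if not mirnas:
            raise ValueError(f"group {group!r} is empty")
        per_mirna: list[float] = []
        for mid in mirnas:
            iv = mature_coords.get(mid)
            if iv is None:
                log.warning("miRNA %s has no mature coordinates; excluded", mid)
                continue
            track = phylop.get(iv.seqid, {})
            scores = [track[p] for p in range(iv.start, iv.end) if p in track]
            if not scores:
                log.warning("miRNA %s has no scored bases; excluded", mid)
                continue
            per_mirna.append(float(np.mean(scores)))
        if not per_mirna:
            raise ValueError(f"group {group!r} has no scorable miRNAs")
        out[group] = float(np.mean(per_mirna))
    return out


def interaction_profile(
    transcript: Transcript,
    interactions: Sequence[InteractionRecord],
    bin_size: int = 50,
) -> np.ndarray:
    """Per-bin interaction counts along a transcript.

    Bin i covers transcript positions [bin_size*i, bin_size*(i+1)); an
    interaction increments every bin its footprint overlaps; the trailing
    partial bin is kept.  Interactions whose blocks do not map cleanly onto
    the transcript's exons are skipped.
    """
    n_bins = math.ceil(transcript.length / bin_size)
    profile = np.zeros(n_bins, dtype=int)
    for rec in interactions:
        try:
            t_start, t_end = project_to_transcript(rec.blocks, transcript)
        except ValueError:
            continue
        first = t_start // bin_size
        last = (t_end - 1) // bin_size
        profile[first : last + 1] += 1
    return profile
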