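"""Analysis thresholds, loadable from YAML.

Defaults mirror the published analysis: 1 tpm gene expression call, 10 tpm
cross-cell-line comparison filter, 3-count miRNA expression cutoff, 9 and 50
interaction cutoffs for high-interacting and sponge-like genes, 90th/10th
percentile cutoffs for miRNA typing, and the L=10 / n=2 consensus rule.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml


@dataclass
class Thresholds:
    min_gene_tpm: float = 1.0
    cross_line_tpm: float = 10.0
    mirna_expressed_counts: float = 3.0
    high_interacting: int = 9
    sponge_like: int = 50
    pct_hi: float = 90.0
    pct_lo: float = 10.0
    mibr_min_length: int = 10
    mibr_min_support: int = 2
    ubiquity_cell_lines: int = 7
    vcf_size_limit_mb: float = 20.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Thresholds":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {f.name: getattr(self, f.name) for f in fields(self)}, fh
            )
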