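"""Numeric cutoffs used across the pipeline, collected in one configurable home.

The defaults are the published analysis settings: adjusted p < 0.05 with a
fold change of at least 1.5 in either direction for differential expression,
a merged count of at least 10 per exon per condition for the splicing test,
at least 10 informative reads per heterozygote for allelic-imbalance testing,
r^2 >= 0.8 for linkage-disequilibrium proxy confirmation, a >1% cross-tissue
marker-read share as the contamination flag, and a total of at least 20 counts
for a gene to enter distribution summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class Thresholds:
    padj_cut: float = 0.05
    fc_cut: float = 1.5
    exon_min_count: int = 10
    ase_min_reads: int = 10
    proxy_r2_min: float = 0.8
    contamination_pct: float = 1.0
    cluster_min_count: int = 20

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {value}")
        if not 0.0 < self.padj_cut < 1.0:
            raise ValueError(f"padj_cut must be in (0, 1), got {self.padj_cut}")

    @classmethod
    def from_yaml(cls, path) -> "Thresholds":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)
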