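"""In-memory containers for gene- and exon-level count data.

Counts are held as pandas DataFrames of non-negative integers; the companion
sample sheet carries the per-sample ``group`` (disease stage: normal, iAMD,
NEO) and ``tissue`` (RPE_choroid or retina) labels that every downstream
contrast needs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = ("group", "tissue")

EXON_KEY_COLUMNS = ("gene", "exon_index", "chrom", "start", "end")


def _validate_counts(counts: pd.DataFrame, what: str) -> pd.DataFrame:
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].tolist()[:5]
        raise ValueError(f"duplicate {what} keys: {dupes}")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in count table")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values), atol=0, rtol=0):
            raise ValueError(f"{what} counts must be integers")
        counts = counts.astype(np.int64)
        values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError(f"{what} counts must be non-negative")
    return counts.astype(np.int64)


def _validate_samples(samples: pd.DataFrame, columns: pd.Index) -> pd.DataFrame:
    missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise ValueError(f"sample sheet missing columns: {missing_cols}")
    unknown = set(samples.index) - set(columns)
    if unknown:
        raise ValueError(f"sample sheet lists unknown samples: {sorted(unknown)}")
    missing = set(columns) - set(samples.index)
    if missing:
        raise ValueError(f"samples absent from sample sheet: {sorted(missing)}")
    return samples.loc[list(columns)]


class CountMatrix:
    """Gene-level counts (genes x samples) with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene symbol, one integer column per sample.
    samples
        DataFrame indexed by sample identifier with ``group`` and ``tissue``
        columns; must cover exactly the count columns.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame):
        self.counts = _validate_counts(counts, "gene")
        self.samples = _validate_samples(samples, self.counts.columns)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_in(self, group: str | None = None, tissue: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if group is not None:
            mask &= self.samples["group"] == group
        if tissue is not None:
            mask &= self.samples["tissue"] == tissue
        return list(self.samples.index[mask])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(self.counts[sample_ids], self.samples.loc[sample_ids])

    def __repr__(self) -> str:
        return f"<CountMatrix {self.counts.shape[0]} genes x {self.counts.shape[1]} samples>"


class ExonCountMatrix:
    """Exon-level counts keyed by (gene, exon_index) with exon intervals.

    ``exons`` carries one row per (gene, exon_index) with ``chrom``, ``start``,
    ``end`` (0-based half-open genomic coordinates of the composite gene's
    merged exon). Exon indices within a gene follow genomic order.
    """

    def __init__(self, counts: pd.DataFrame, exons: pd.DataFrame, samples: pd.DataFrame):
        if not isinstance(counts.index, pd.MultiIndex) or counts.index.names != ["gene", "exon_index"]:
            raise ValueError("exon counts must be indexed by (gene, exon_index)")
        self.counts = _validate_counts(counts, "exon")
        if not counts.index.equals(exons.index):
            raise ValueError("exon interval table must align with the count index")
        for col in ("chrom", "start", "end"):
            if col not in exons.columns:
                raise ValueError(f"exon table missing column {col!r}")
        if (exons["start"] >= exons["end"]).any():
            raise ValueError("exon intervals must satisfy start < end")
        self.exons = exons
        self.samples = _validate_samples(samples, self.counts.columns)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index.get_level_values("gene").unique()

    def samples_in(self, group: str | None = None, tissue: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if group is not None:
            mask &= self.samples["group"] == group
        if tissue is not None:
            mask &= self.samples["tissue"] == tissue
        return list(self.samples.index[mask])

    def gene_counts(self) -> "CountMatrix":
        """Sum exons to gene-level counts (the composite-gene counting model)."""
        summed = self.counts.groupby(level="gene", sort=False).sum()
        return CountMatrix(summed, self.samples)

    def __repr__(self) -> str:
        return (
            f"<ExonCountMatrix {len(self.genes)} genes, "
            f"{self.counts.shape[0]} exons x {self.counts.shape[1]} samples>"
        )
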