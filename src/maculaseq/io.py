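"""Readers and writers for the tabular and genomic formats the pipeline touches.

Conventions
-----------
* Genomic intervals are 0-based half-open internally (the refFlat native
  convention); SNP positions are 1-based (the VCF convention). Conversion
  happens only at I/O boundaries.
* All tables are TSV, UTF-8, ``.`` decimal, header row required.

The transcript-model machinery builds "composite genes": the union of all of
a gene's transcript exons, which defines the exon counting bins and the
exonic length used for FPKM.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EXON_KEY_COLUMNS, CountMatrix, ExonCountMatrix


class RefFlatParseError(ValueError):
    """Raised for a malformed refFlat row; the message names the line number."""


REFFLAT_COLUMNS = (
    "geneName",
    "name",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "exonCount",
    "exonStarts",
    "exonEnds",
)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript of a gene: an ordered list of exon intervals.

    Exons are 0-based half-open genomic intervals with strictly increasing
    starts, all on one chromosome.
    """

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        prev_start = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"exon interval [{start}, {end}) has start >= end")
            if prev_start is not None and start <= prev_start:
                raise ValueError("exon starts must be strictly increasing")
            prev_start = start

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class CompositeGene:
    """Union of all transcript exons of one gene: its counting model.

    ``merged_exons`` are pairwise-disjoint sorted 0-based half-open intervals;
    ``exonic_length`` is their total length in base pairs.
    """

    gene_symbol: str
    chrom: str
    strand: str
    merged_exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.merged_exons:
            raise ValueError("composite gene must have at least one exon")
        prev_end = None
        for start, end in self.merged_exons:
            if start >= end:
                raise ValueError(f"interval [{start}, {end}) has start >= end")
            if prev_end is not None and start <= prev_end:
                raise ValueError("merged exons must be disjoint and sorted")
            prev_end = end

    @property
    def exonic_length(self) -> int:
        return sum(end - start for start, end in self.merged_exons)


def _parse_coord_list(text: str, n_expected: int, line_no: int, what: str) -> list[int]:
    parts = [p for p in text.strip().split(",") if p != ""]
    if len(parts) != n_expected:
        raise RefFlatParseError(
            f"line {line_no}: exonCount is {n_expected} but {what} lists {len(parts)} values"
        )
    try:
        return [int(p) for p in parts]
    except ValueError as exc:
        raise RefFlatParseError(f"line {line_no}: non-integer coordinate in {what}") from exc


def read_refflat(path) -> list[TranscriptModel]:
    """Parse a UCSC refFlat gene table into transcript models.

    The 11-column dialect is expected: geneName, name, chrom, strand, txStart,
    txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds (the last two are
    comma-terminated coordinate lists). Coordinates are kept 0-based half-open.
    """
    models: list[TranscriptModel] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields_ = line.split("\t")
            if len(fields_) < 11:
                raise RefFlatParseError(
                    f"line {line_no}: expected 11 tab-delimited fields, got {len(fields_)}"
                )
            gene, name, chrom, strand = fields_[0], fields_[1], fields_[2], fields_[3]
            try:
                exon_count = int(fields_[8])
            except ValueError as exc:
                raise RefFlatParseError(f"line {line_no}: non-integer exonCount") from exc
            starts = _parse_coord_list(fields_[9], exon_count, line_no, "exonStarts")
            ends = _parse_coord_list(fields_[10], exon_count, line_no, "exonEnds")
            exons = tuple(zip(starts, ends))
            try:
                model = TranscriptModel(gene, name, chrom, strand, exons)
            except ValueError as exc:
                raise RefFlatParseError(f"line {line_no}: {exc}") from exc
            models.append(model)
    return models


def write_refflat(models, path) -> None:
    """Write transcript models back to the 11-column refFlat dialect.

    cdsStart/cdsEnd are not modelled; they are written as the transcript
    bounds, which round-trips files produced by this writer byte-identically.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for m in models:
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            row = (
                m.gene_symbol,
                m.transcript_id,
                m.chrom,
                m.strand,
                str(m.tx_start),
                str(m.tx_end),
                str(m.tx_start),
                str(m.tx_end),
                str(len(m.exons)),
                starts,
                ends,
            )
            fh.write("\t".join(row) + "\n")


def merge_intervals(intervals) -> tuple[tuple[int, int], ...]:
    """Union of half-open intervals, returned disjoint and sorted."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def merge_transcripts(transcripts) -> CompositeGene:
    """Merge the transcripts of one gene into a single composite gene.

    The merged exon list is the interval union of all input exons. Transcripts
    must share one chromosome; on strand conflict the majority strand is
    emitted with a warning (downstream counting is strand-agnostic).
    """
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("cannot merge an empty transcript list")
    chroms = {t.chrom for t in transcripts}
    if len(chroms) > 1:
        raise ValueError(f"transcripts span multiple chromosomes: {sorted(chroms)}")
    symbols = {t.gene_symbol for t in transcripts}
    if len(symbols) > 1:
        raise ValueError(f"transcripts carry multiple gene symbols: {sorted(symbols)}")
    strands = Counter(t.strand for t in transcripts)
    if len(strands) > 1:
        warnings.warn(
            f"strand conflict for {transcripts[0].gene_symbol}; using majority strand",
            stacklevel=2,
        )
    strand = max(sorted(strands), key=strands.__getitem__)
    exons = merge_intervals(iv for t in transcripts for iv in t.exons)
    return CompositeGene(transcripts[0].gene_symbol, transcripts[0].chrom, strand, exons)


def build_composite_genes(models) -> dict[str, CompositeGene]:
    """Group transcript models by gene symbol and merge each group.

    Identical symbols on different chromosomes are treated as distinct genes
    suffixed by chromosome, preventing nonsensical cross-chromosome unions.
    """
    by_symbol: dict[str, list[TranscriptModel]] = defaultdict(list)
    for m in models:
        by_symbol[m.gene_symbol].append(m)
    composites: dict[str, CompositeGene] = {}
    for symbol, group in by_symbol.items():
        chroms = sorted({t.chrom for t in group})
        if len(chroms) == 1:
            composites[symbol] = merge_transcripts(group)
        else:
            for chrom in chroms:
                sub = [t for t in group if t.chrom == chrom]
                composites[f"{symbol}_{chrom}"] = merge_transcripts(sub)
    return composites


# ---------------------------------------------------------------------------
# Count tables


def read_sample_sheet(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in samples.columns:
        raise ValueError("sample sheet must have a 'sample' column")
    if samples["sample"].duplicated().any():
        raise ValueError("duplicate samples in sample sheet")
    return samples.set_index("sample")


def read_count_table(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t")
    if "gene" not in counts.columns:
        raise ValueError("count table must have a 'gene' column")
    counts = counts.set_index("gene")
    _reject_bad_counts(counts)
    return CountMatrix(counts, read_sample_sheet(samples_path))


def write_count_table(matrix: CountMatrix, counts_path, samples_path=None) -> None:
    out = matrix.counts.copy()
    out.index.name = "gene"
    out.to_csv(counts_path, sep="\t", lineterminator="\n")
    if samples_path is not None:
        write_sample_sheet(matrix.samples, samples_path)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", lineterminator="\n")


def _reject_bad_counts(counts: pd.DataFrame) -> None:
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count table contains non-numeric entries")
    if not np.allclose(values, np.round(values), atol=0, rtol=0):
        raise ValueError("count table contains non-integer entries")
    if (values < 0).any():
        raise ValueError("count table contains negative entries")


def read_exon_count_table(counts_path, samples_path) -> ExonCountMatrix:
    table = pd.read_csv(counts_path, sep="\t")
    missing = [c for c in EXON_KEY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"exon count table missing key columns: {missing}")
    table = table.set_index(["gene", "exon_index"])
    exons = table[["chrom", "start", "end"]]
    counts = table.drop(columns=["chrom", "start", "end"])
    _reject_bad_counts(counts)
    return ExonCountMatrix(counts, exons, read_sample_sheet(samples_path))


def write_exon_count_table(matrix: ExonCountMatrix, counts_path, samples_path=None) -> None:
    out = pd.concat([matrix.exons, matrix.counts], axis=1).reset_index()
    out.to_csv(counts_path, sep="\t", index=False, lineterminator="\n")
    if samples_path is not None:
        write_sample_sheet(matrix.samples, samples_path)


# ---------------------------------------------------------------------------
# Genotypes, allelic counts and LD proxies

GENOTYPE_SOURCES = ("chip", "taqman", "proxy")

_IUPAC = set("ACGTRYSWKMBDHVN")


def read_genotypes(path) -> pd.DataFrame:
    """Read a genotype table: sample, snp_id, allele1, allele2, source."""
    geno = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample", "snp_id", "allele1", "allele2", "source"]
    missing = [c for c in required if c not in geno.columns]
    if missing:
        raise ValueError(f"genotype table missing columns: {missing}")
    bad_source = set(geno["source"]) - set(GENOTYPE_SOURCES)
    if bad_source:
        raise ValueError(f"unknown genotype sources: {sorted(bad_source)}")
    for col in ("allele1", "allele2"):
        bad = geno[~geno[col].isin(_IUPAC)]
        if len(bad):
            raise ValueError(f"{col} contains non-IUPAC bases: {sorted(set(bad[col]))[:5]}")
    return geno


def read_genotypes_vcf(path, source: str = "chip") -> pd.DataFrame:
    """Map a VCF (v4.2, GT field only) onto the genotype record schema.

    Each sample x variant call becomes one row; missing calls (./.) are
    skipped. Requires cyvcf2.
    """
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    sample_names = vcf.samples
    for variant in vcf:
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        alleles = [variant.REF] + list(variant.ALT)
        for sample, gt in zip(sample_names, variant.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                continue
            rows.append(
                {
                    "sample": sample,
                    "snp_id": snp_id,
                    "allele1": alleles[a1],
                    "allele2": alleles[a2],
                    "source": source,
                }
            )
    return pd.DataFrame(rows, columns=["sample", "snp_id", "allele1", "allele2", "source"])


ALLELIC_COLUMNS = (
    "sample",
    "tissue",
    "group",
    "snp_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_reads",
    "alt_reads",
)


def read_allelic_counts(path) -> pd.DataFrame:
    """Read per-sample per-SNP allelic read counts (positions are 1-based)."""
    records = pd.read_csv(path, sep="\t")
    missing = [c for c in ALLELIC_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"allelic count table missing columns: {missing}")
    for col in ("ref_reads", "alt_reads"):
        if (records[col] < 0).any():
            raise ValueError(f"{col} contains negative read counts")
        records[col] = records[col].astype(np.int64)
    for col in ("ref", "alt"):
        bad = records[~records[col].isin(_IUPAC)]
        if len(bad):
            raise ValueError(f"{col} contains non-IUPAC bases")
    return records


@dataclass
class ProxyMap:
    """target SNP -> [(proxy SNP, r^2), ...] linkage-disequilibrium lookups."""

    entries: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def add(self, target: str, proxy: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 must be in [0, 1], got {r2}")
        self.entries.setdefault(target, []).append((proxy, float(r2)))

    def proxies(self, target: str, min_r2: float = 0.0) -> list[tuple[str, float]]:
        return [(p, r2) for p, r2 in self.entries.get(target, []) if r2 >= min_r2]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target_snp": t, "proxy_snp": p, "r2": r2}
            for t, pairs in self.entries.items()
            for p, r2 in pairs
        ]
        return pd.DataFrame(rows, columns=["target_snp", "proxy_snp", "r2"])


def read_proxy_map(path) -> ProxyMap:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("target_snp", "proxy_snp", "r2") if c not in table.columns]
    if missing:
        raise ValueError(f"proxy table missing columns: {missing}")
    pm = ProxyMap()
    for row in table.itertuples(index=False):
        pm.add(row.target_snp, row.proxy_snp, row.r2)
    return pm


def write_proxy_map(pm: ProxyMap, path) -> None:
    pm.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_provenance(path, seed: int, config_dict: dict) -> None:
    """Record the seed and a hash of the generating configuration."""
    import hashlib

    blob = json.dumps(config_dict, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"seed": seed, "config_sha256": digest, "config": config_dict}, fh, indent=2, default=str)
        fh.write("\n")
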