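"""Exon-level chi-square differential splicing.

For each gene, replicate counts are summed ("merged") within each condition,
exons with fewer than 10 merged counts in either condition are dropped, and
the remaining K x 2 table (exons x conditions) is tested with a Pearson
chi-square (df = K - 1) for a shift in exon usage. Raw p-values are
Bonferroni-corrected over the testable genes of the comparison. The reported
splice signal is the exon with the biggest absolute log2 ratio of normalized
(within-gene proportion) counts between conditions; a gene is called
differentially spliced when the corrected p-value is below 0.05 and the fold
change at that exon is at least 1.5.

Because the statistic operates on within-gene proportions it is exactly
invariant to a pure expression change: scaling one condition's counts leaves
every per-exon log2 ratio, and the chi-square under equal proportions, at
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .containers import ExonCountMatrix
from .io import CompositeGene
from .thresholds import Thresholds


def merge_replicates(matrix: ExonCountMatrix, group: str, tissue: str | None = None) -> pd.Series:
    """Element-wise sum of exon counts across one condition's replicates."""
    cols = matrix.samples_in(group=group, tissue=tissue)
    if not cols:
        raise ValueError(f"no samples in group {group!r}")
    return matrix.counts[cols].sum(axis=1)


def eligible_exons(
    merged_a: np.ndarray, merged_b: np.ndarray, thresholds: Thresholds = Thresholds()
) -> np.ndarray:
    """Indices of exons with merged count >= exon_min_count in both conditions.

    The threshold is boundary-inclusive. A gene is testable only when at
    least two exons survive (df = K - 1 >= 1).
    """
    merged_a = np.asarray(merged_a)
    merged_b = np.asarray(merged_b)
    keep = (merged_a >= thresholds.exon_min_count) & (merged_b >= thresholds.exon_min_count)
    return np.flatnonzero(keep)


def splice_chi2(counts_a, counts_b) -> tuple[float, int, float]:
    """Pearson chi-square on the K x 2 exons-by-conditions table.

    Returns (chi2, df, p) with df = K - 1 and the upper-tail chi-square
    p-value. No continuity correction is applied.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.size < 2:
        raise ValueError("chi-square needs at least 2 exons")
    total = counts_a.sum() + counts_b.sum()
    if total == 0:
        raise ValueError("chi-square undefined for an all-zero table")
    table = np.column_stack([counts_a, counts_b])
    chi2, p, df, _ = chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def splice_log2_ratios(counts_a, counts_b) -> tuple[np.ndarray, int]:
    """Per-exon signed log2 normalized-count ratios and the top exon.

    Each condition's counts are normalized to within-gene proportions; the
    per-exon ratio is log2(prop_A / prop_B). The top exon maximises the
    absolute ratio, ties breaking to the lowest index.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    prop_a = counts_a / counts_a.sum()
    prop_b = counts_b / counts_b.sum()
    ratios = np.log2(prop_a / prop_b)
    magnitudes = np.abs(ratios)
    # ties (within floating-point noise) break to the lowest exon index
    top = int(np.flatnonzero(magnitudes >= magnitudes.max() * (1.0 - 1e-12))[0])
    return ratios, top


def bonferroni(p, m: int):
    """min(1, p * m) for a family of m tests; accepts a scalar or vector."""
    if m <= 0:
        raise ValueError(f"family size m must be positive, got {m}")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


class ExonChiSquareSplicing:
    """Exon-usage chi-square model for one two-condition comparison.

    Parameters
    ----------
    data
        ExonCountMatrix whose exon intervals are the composite genes' merged
        exons in genomic order.
    contrast
        (group_A, group_B) condition labels.
    tissue
        Restrict to samples of this tissue (None keeps all).
    """

    def __init__(
        self,
        data: ExonCountMatrix,
        contrast: tuple[str, str],
        tissue: str | None = None,
        thresholds: Thresholds = Thresholds(),
    ):
        self.data = data
        self.contrast = tuple(contrast)
        self.tissue = tissue
        self.thresholds = thresholds

    def fit(self) -> "SpliceResults":
        merged_a = merge_replicates(self.data, self.contrast[0], self.tissue)
        merged_b = merge_replicates(self.data, self.contrast[1], self.tissue)

        rows = []
        untestable = []
        per_gene_ratios: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for gene, idx in merged_a.groupby(level="gene", sort=False).groups.items():
            a = merged_a.loc[idx].to_numpy()
            b = merged_b.loc[idx].to_numpy()
            exon_indices = merged_a.loc[idx].index.get_level_values("exon_index").to_numpy()
            keep = eligible_exons(a, b, self.thresholds)
            if keep.size < 2:
                untestable.append(
                    {
                        "gene": gene,
                        "n_exons": len(a),
                        "n_eligible": int(keep.size),
                        "reason": "fewer_than_2_eligible_exons",
                    }
                )
                continue
            chi2, df, p = splice_chi2(a[keep], b[keep])
            ratios, top = splice_log2_ratios(a[keep], b[keep])
            per_gene_ratios[gene] = (exon_indices[keep], ratios)
            rows.append(
                {
                    "gene": gene,
                    "chi2": chi2,
                    "df": df,
                    "p": p,
                    "n_exons_tested": int(keep.size),
                    "top_exon": int(exon_indices[keep][top]),
                    "splice_log2_ratio": float(ratios[top]),
                    "per_exon_log2": ";".join(f"{r:.6g}" for r in ratios),
                }
            )

        table = pd.DataFrame(
            rows,
            columns=[
                "gene",
                "chi2",
                "df",
                "p",
                "n_exons_tested",
                "top_exon",
                "splice_log2_ratio",
                "per_exon_log2",
            ],
        )
        m = len(table)
        if m:
            table["p_bonf"] = bonferroni(table["p"].to_numpy(), m)
            table["fold_change"] = np.where(
                table["splice_log2_ratio"] >= 0,
                2.0 ** table["splice_log2_ratio"],
                -(2.0 ** (-table["splice_log2_ratio"])),
            )
            table["significant"] = (table["p_bonf"] < self.thresholds.padj_cut) & (
                table["splice_log2_ratio"].abs() >= np.log2(self.thresholds.fc_cut)
            )
        else:
            table["p_bonf"] = []
            table["fold_change"] = []
            table["significant"] = []
        table = table[
            [
                "gene",
                "chi2",
                "df",
                "p",
                "p_bonf",
                "n_exons_tested",
                "top_exon",
                "splice_log2_ratio",
                "fold_change",
                "significant",
                "per_exon_log2",
            ]
        ]
        return SpliceResults(
            table,
            pd.DataFrame(untestable, columns=["gene", "n_exons", "n_eligible", "reason"]),
            self.contrast,
            self.thresholds,
            per_gene_ratios,
        )


@dataclass
class SpliceResults:
    """Per-gene splicing test results for one comparison.

    ``table`` columns include the chi-square statistic, raw and
    Bonferroni-corrected p, the top exon and its signed log2 ratio, and the
    per-exon ratio vector (semicolon-joined in TSV output). ``untestable``
    records genes with fewer than two eligible exons — distinguished from
    "tested, no evidence" rather than being assigned p = 1.
    """

    table: pd.DataFrame
    untestable: pd.DataFrame
    contrast: tuple[str, str]
    thresholds: Thresholds
    _ratios: dict

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        lines = [
            "Exon-level chi-square differential splicing",
            f"  contrast:         {self.contrast[0]} vs {self.contrast[1]}",
            f"  genes testable:   {len(self.table)}",
            f"  genes untestable: {len(self.untestable)}",
            f"  significant:      {len(self.significant())} "
            f"(Bonferroni p < {self.thresholds.padj_cut}, |FC| >= {self.thresholds.fc_cut})",
        ]
        return "\n".join(lines)

    def ratio_track(self, gene: str, composite: CompositeGene) -> pd.DataFrame:
        """bedGraph-style records carrying each tested exon's log2 ratio."""
        if gene not in self._ratios:
            raise KeyError(f"gene {gene!r} was not testable in this comparison")
        exon_indices, ratios = self._ratios[gene]
        return per_exon_ratio_track(gene, exon_indices, ratios, composite)

    def to_tsv(self, path, untestable_path=None) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")
        if untestable_path is not None:
            self.untestable.to_csv(untestable_path, sep="\t", index=False, lineterminator="\n")


def dsg_table(
    data: ExonCountMatrix,
    contrast: tuple[str, str],
    thresholds: Thresholds = Thresholds(),
    tissue: str | None = None,
) -> SpliceResults:
    """Convenience wrapper: build and fit an ExonChiSquareSplicing model."""
    return ExonChiSquareSplicing(data, contrast, tissue=tissue, thresholds=thresholds).fit()


def per_exon_ratio_track(
    gene: str, exon_indices, ratios, composite: CompositeGene
) -> pd.DataFrame:
    """One bedGraph interval per tested merged exon with its log2 ratio.

    The value is constant over the exon; exons with ratio 0 are still
    emitted. True per-base coverage would require read alignments.
    """
    rows = []
    for e_idx, value in zip(exon_indices, np.asarray(ratios, dtype=float)):
        start, end = composite.merged_exons[int(e_idx)]
        rows.append({"chrom": composite.chrom, "start": start, "end": end, "value": value})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(track: pd.DataFrame, gene: str, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"track type=bedGraph name={gene}\n")
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("track"):
                continue
            chrom, start, end, value = line.rstrip("\n").split("\t")
            rows.append({"chrom": chrom, "start": int(start), "end": int(end), "value": float(value)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
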