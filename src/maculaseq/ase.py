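"""Per-individual allele-specific expression (ASE).

At each AMD-associated coding SNP, read counts over the two alleles of a
confirmed heterozygote are tested for imbalance with an exact binomial test
against an equal 0.5 split. The procedure is:

1. keep records whose genotype call is heterozygous and consistent with the
   record's ref/alt alleles;
2. require at least 10 informative reads (boundary inclusive);
3. monoallelic records (minor-allele reads exactly 0) stay in the tested set
   only when a linkage-disequilibrium proxy SNP with r^2 >= 0.8 confirms the
   heterozygous genotype in the same individual — a chip-genotyping error at
   the target would otherwise masquerade as complete silencing of one allele;
4. exact binomial p per record, Benjamini-Hochberg corrected within a
   configurable family (default: all tested records of one tissue).

Summaries render per-SNP "k/n" cells — significant over tested heterozygotes
per disease group and tissue — with "0/0" marking cells with no testable
heterozygote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .expression import bh_adjust
from .io import ProxyMap
from .thresholds import Thresholds

FAMILIES = ("tissue", "snp", "global")


def binomial_ase_test(ref_reads: int, alt_reads: int, method: str = "minlike") -> float:
    """Exact two-sided binomial test of the allele split against p0 = 0.5.

    ``method='minlike'`` (default) sums the probabilities of all outcomes no
    more likely than the observed one. Under p0 = 0.5 the distribution is
    symmetric and within one n the point probabilities are distinct except
    for the mirror pair (k, n-k), so the sum reduces exactly to the two tails
    P(X <= min(k, n-k)) + P(X >= max(k, n-k)). ``method='doubling'`` doubles
    the smaller tail instead. Both are capped at 1.
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    n = ref_reads + alt_reads
    if n < 1:
        raise ValueError("binomial test needs at least one read")
    m = min(ref_reads, alt_reads)
    if method == "minlike":
        if 2 * m == n:
            return 1.0
        p = binom.cdf(m, n, 0.5) + binom.sf(n - m - 1, n, 0.5)
    elif method == "doubling":
        p = 2.0 * binom.cdf(m, n, 0.5)
    else:
        raise ValueError("method must be 'minlike' or 'doubling'")
    return float(min(1.0, p))


def select_heterozygotes(
    genotypes: pd.DataFrame, records: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep allelic records whose primary genotype is a consistent heterozygote.

    A record is kept iff a genotype exists for (sample, snp_id), has two
    distinct alleles, and those alleles are exactly the record's {ref, alt}.
    Excluded records are returned with machine-readable reasons:
    ``no_genotype``, ``homozygous``, or ``allele_mismatch``.
    """
    primary = genotypes[genotypes["source"] != "proxy"]
    geno_map = {
        (row.sample, row.snp_id): (row.allele1, row.allele2)
        for row in primary.itertuples(index=False)
    }
    kept_idx, reasons = [], []
    for idx, row in records.iterrows():
        call = geno_map.get((row["sample"], row["snp_id"]))
        if call is None:
            reasons.append((idx, "no_genotype"))
        elif call[0] == call[1]:
            reasons.append((idx, "homozygous"))
        elif {call[0], call[1]} != {row["ref"], row["alt"]}:
            reasons.append((idx, "allele_mismatch"))
        else:
            kept_idx.append(idx)
    kept = records.loc[kept_idx]
    excluded = records.loc[[i for i, _ in reasons]].copy()
    excluded["reason"] = [r for _, r in reasons]
    return kept, excluded


def depth_filter(
    records: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep records with ref_reads + alt_reads >= ase_min_reads (inclusive)."""
    total = records["ref_reads"] + records["alt_reads"]
    kept = records[total >= thresholds.ase_min_reads]
    excluded = records[total < thresholds.ase_min_reads].copy()
    excluded["reason"] = "below_depth_threshold"
    return kept, excluded


def confirm_monoallelic(
    record, genotypes: pd.DataFrame, proxy_map: ProxyMap, thresholds: Thresholds = Thresholds()
) -> str:
    """Proxy confirmation status for one heterozygous record.

    Returns ``not_required`` when both alleles have reads, ``confirmed`` when
    some proxy with r^2 >= proxy_r2_min has a heterozygous genotype call in
    the same individual, otherwise ``unconfirmed``.
    """
    minor = min(record["ref_reads"], record["alt_reads"])
    if minor > 0:
        return "not_required"
    proxies = proxy_map.proxies(record["snp_id"], min_r2=thresholds.proxy_r2_min)
    if not proxies:
        return "unconfirmed"
    sample_geno = genotypes[genotypes["sample"] == record["sample"]]
    for proxy_snp, _r2 in proxies:
        calls = sample_geno[sample_geno["snp_id"] == proxy_snp]
        for call in calls.itertuples(index=False):
            if call.allele1 != call.allele2:
                return "confirmed"
    return "unconfirmed"


class AllelicImbalance:
    """Per-individual allelic-imbalance model over a cohort's SNP read counts.

    Parameters
    ----------
    genotypes, records, proxy_map
        Genotype calls, allelic read-count records and LD-proxy lookups.
    family
        Benjamini-Hochberg family: 'tissue' (default, all tested records of
        one tissue jointly), 'snp' (per tissue x SNP) or 'global'.
    method
        Two-sidedness of the exact test: 'minlike' or 'doubling'.
    """

    def __init__(
        self,
        genotypes: pd.DataFrame,
        records: pd.DataFrame,
        proxy_map: ProxyMap | None = None,
        thresholds: Thresholds = Thresholds(),
        family: str = "tissue",
        method: str = "minlike",
    ):
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        self.genotypes = genotypes
        self.records = records
        self.proxy_map = proxy_map or ProxyMap()
        self.thresholds = thresholds
        self.family = family
        self.method = method

    def fit(self) -> "ASEResults":
        het, excl_geno = select_heterozygotes(self.genotypes, self.records)
        deep, excl_depth = depth_filter(het, self.thresholds)

        statuses = [
            confirm_monoallelic(row, self.genotypes, self.proxy_map, self.thresholds)
            for _, row in deep.iterrows()
        ]
        deep = deep.copy()
        deep["proxy_confirmed"] = statuses
        unconfirmed = deep[deep["proxy_confirmed"] == "unconfirmed"].copy()
        unconfirmed["reason"] = "monoallelic_unconfirmed_by_proxy"
        tested = deep[deep["proxy_confirmed"] != "unconfirmed"].copy()

        total = tested["ref_reads"] + tested["alt_reads"]
        tested["total_reads"] = total
        tested["minor_fraction"] = np.minimum(tested["ref_reads"], tested["alt_reads"]) / total
        tested["monoallelic"] = np.minimum(tested["ref_reads"], tested["alt_reads"]) == 0
        tested["p"] = [
            binomial_ase_test(r, a, method=self.method)
            for r, a in zip(tested["ref_reads"], tested["alt_reads"])
        ]
        tested["padj"] = self._adjust_within_family(tested)
        tested["significant"] = tested["padj"] < self.thresholds.padj_cut

        exclusions = pd.concat(
            [excl_geno, excl_depth, unconfirmed.drop(columns=["proxy_confirmed"])],
            ignore_index=True,
        )
        columns = [
            "sample",
            "tissue",
            "group",
            "snp_id",
            "ref_reads",
            "alt_reads",
            "total_reads",
            "minor_fraction",
            "p",
            "padj",
            "significant",
            "monoallelic",
            "proxy_confirmed",
        ]
        table = tested[columns].sort_values(["tissue", "snp_id", "group", "sample"]).reset_index(drop=True)
        return ASEResults(table, exclusions.reset_index(drop=True), self.thresholds, self.family)

    def _adjust_within_family(self, tested: pd.DataFrame) -> np.ndarray:
        if len(tested) == 0:
            return np.array([])
        if self.family == "global":
            return bh_adjust(tested["p"].to_numpy())
        keys = (
            tested["tissue"]
            if self.family == "tissue"
            else tested["tissue"].str.cat(tested["snp_id"], sep="|")
        )
        padj = np.empty(len(tested))
        for _, idx in tested.groupby(keys, sort=False).groups.items():
            pos = tested.index.get_indexer(idx)
            padj[pos] = bh_adjust(tested["p"].to_numpy()[pos])
        return padj


@dataclass
class ASEResults:
    """Tested allelic records with exact-test p-values and BH flags."""

    table: pd.DataFrame
    exclusions: pd.DataFrame
    thresholds: Thresholds
    family: str

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary_table(self) -> pd.DataFrame:
        return summarize_ase(self.table)

    def summary(self) -> str:
        lines = [
            "Allele-specific expression (exact binomial, BH-corrected)",
            f"  BH family:        {self.family}",
            f"  records tested:   {len(self.table)}",
            f"  records excluded: {len(self.exclusions)}",
            f"  significant:      {len(self.significant())} (padj < {self.thresholds.padj_cut})",
        ]
        return "\n".join(lines)

    def to_tsv(self, path, summary_path=None, exclusions_path=None) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")
        if summary_path is not None:
            self.summary_table().to_csv(summary_path, sep="\t", lineterminator="\n")
        if exclusions_path is not None:
            self.exclusions.to_csv(exclusions_path, sep="\t", index=False, lineterminator="\n")


def ase_pipeline(
    genotypes: pd.DataFrame,
    records: pd.DataFrame,
    proxy_map: ProxyMap | None = None,
    thresholds: Thresholds = Thresholds(),
    family: str = "tissue",
    method: str = "minlike",
) -> ASEResults:
    """Convenience wrapper: build and fit an AllelicImbalance model."""
    return AllelicImbalance(genotypes, records, proxy_map, thresholds, family, method).fit()


def summarize_ase(table: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP per-tissue per-group "k/n" cells.

    n counts tested heterozygotes (post depth filter and proxy confirmation),
    k the significant ones among them; cells with no tested individual render
    as "0/0".
    """
    if len(table) == 0:
        return pd.DataFrame()
    grouped = table.groupby(["snp_id", "tissue", "group"])["significant"].agg(["sum", "count"])
    cells = grouped.apply(lambda row: f"{int(row['sum'])}/{int(row['count'])}", axis=1)
    wide = cells.unstack(["tissue", "group"]).fillna("0/0")
    wide = wide.sort_index(axis=1)
    return wide
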