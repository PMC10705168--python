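"""Cross-comparison integration: overlaps, concordance, loci annotation,
cross-dataset validation, and qPCR ddCt concordance.

Result sets from different disease comparisons are intersected and
partitioned by the sign of the fold change; differentially expressed and
differentially spliced sets are laid side by side (opposing signs annotated,
not excluded); significant genes are annotated against the bundled list of
previously reported AMD risk loci; and discovery hits are checked for
significance in an independent validation expression table. The qPCR helper
implements relative 2^-ddCt quantification against an endogenous control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._loci import AMD_LOCI
from .thresholds import Thresholds


@dataclass
class ComparisonResultSet:
    """Significant rows of one (tissue, contrast, analysis) comparison.

    ``table`` is indexed by gene and must carry ``log2fc`` (for DSG sets this
    is the top-exon splice log2 ratio) and ``padj``. One row per gene.
    """

    tissue: str
    contrast: tuple[str, str]
    analysis: str  # "DEG" or "DSG"
    table: pd.DataFrame

    def __post_init__(self):
        if self.analysis not in ("DEG", "DSG"):
            raise ValueError("analysis must be 'DEG' or 'DSG'")
        for col in ("log2fc", "padj"):
            if col not in self.table.columns:
                raise ValueError(f"result table missing column {col!r}")
        if self.table.index.has_duplicates:
            raise ValueError("one row per gene required")

    @classmethod
    def from_de_results(cls, results, tissue: str) -> "ComparisonResultSet":
        sig = results.significant().set_index("gene")[["log2fc", "padj"]]
        return cls(tissue, results.contrast, "DEG", sig)

    @classmethod
    def from_splice_results(cls, results, tissue: str) -> "ComparisonResultSet":
        sig = results.significant().set_index("gene")
        table = pd.DataFrame(
            {"log2fc": sig["splice_log2_ratio"], "padj": sig["p_bonf"]}
        )
        return cls(tissue, results.contrast, "DSG", table)

    @property
    def direction(self) -> pd.Series:
        return np.sign(self.table["log2fc"]).replace(0, 1).astype(int)

    @property
    def genes(self) -> set[str]:
        return set(self.table.index)


@dataclass
class OverlapResult:
    overlap: set = field(default_factory=set)
    concordant: set = field(default_factory=set)
    discordant: set = field(default_factory=set)


def overlap_concordant(a: ComparisonResultSet, b: ComparisonResultSet) -> OverlapResult:
    """Genes significant in both comparisons, split by direction agreement.

    concordant and discordant partition the overlap exactly:
    |concordant| + |discordant| = |overlap|.
    """
    if a.tissue != b.tissue or a.analysis != b.analysis:
        raise ValueError("overlap requires the same tissue and analysis type")
    overlap = a.genes & b.genes
    da, db = a.direction, b.direction
    concordant = {g for g in overlap if da[g] == db[g]}
    return OverlapResult(overlap, concordant, overlap - concordant)


def deg_dsg_overlap(deg: ComparisonResultSet, dsg: ComparisonResultSet) -> pd.DataFrame:
    """Genes significant as both DEG and DSG, with both analyses' statistics.

    Genes whose expression and splice fold changes point in opposite
    directions are annotated ``opposing=True`` rather than removed.
    """
    if deg.analysis != "DEG" or dsg.analysis != "DSG":
        raise ValueError("expected a DEG set and a DSG set")
    if deg.tissue != dsg.tissue or deg.contrast != dsg.contrast:
        raise ValueError("DEG/DSG overlap requires the same tissue and contrast")
    shared = sorted(deg.genes & dsg.genes)
    out = pd.DataFrame(
        {
            "log2fc_deg": deg.table.loc[shared, "log2fc"],
            "padj_deg": deg.table.loc[shared, "padj"],
            "splice_log2_ratio": dsg.table.loc[shared, "log2fc"],
            "padj_dsg": dsg.table.loc[shared, "padj"],
        },
        index=pd.Index(shared, name="gene"),
    )
    out["opposing"] = np.sign(out["log2fc_deg"]) != np.sign(out["splice_log2_ratio"])
    return out


def amd_loci_annotate(results: ComparisonResultSet, loci=AMD_LOCI) -> pd.DataFrame:
    """Restrict a significant result set to known AMD risk loci.

    Emits the sign convention of the published loci tables: '+' for
    upregulated, '-' for downregulated, plus the signed fold change and the
    adjusted p-value. For baseline tissue-vs-tissue contrasts the sign column
    doubles as the tissue of higher expression.
    """
    loci_set = set(loci)
    rows = results.table[results.table.index.isin(loci_set)].copy()
    rows["direction"] = np.where(rows["log2fc"] >= 0, "+", "-")
    rows["fold_change"] = np.where(
        rows["log2fc"] >= 0, 2.0 ** rows["log2fc"], -(2.0 ** (-rows["log2fc"]))
    )
    rows["higher_in"] = np.where(
        rows["log2fc"] >= 0, results.contrast[0], results.contrast[1]
    )
    return rows[["direction", "fold_change", "padj", "higher_in"]].sort_index()


def cross_dataset_validate(
    discovery_deg: ComparisonResultSet,
    validation: pd.DataFrame,
    discovery_dsg: ComparisonResultSet | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Validate discovery hits in an independent expression result table.

    A gene is validated iff it is significant in the discovery set (in both
    the DEG and DSG sets when both are supplied) and has padj < padj_cut in
    the validation table. Direction agreement between discovery and
    validation is recorded but not required.

    ``validation`` must carry gene, log2fc, padj columns.
    """
    for col in ("gene", "log2fc", "padj"):
        if col not in validation.columns:
            raise ValueError(f"validation table missing column {col!r}")
    val = validation.set_index("gene")
    candidates = discovery_deg.genes
    if discovery_dsg is not None:
        candidates = candidates & discovery_dsg.genes
    rows = []
    for gene in sorted(candidates):
        if gene not in val.index:
            continue
        v = val.loc[gene]
        if v["padj"] >= thresholds.padj_cut:
            continue
        row = {
            "gene": gene,
            "log2fc_deg": discovery_deg.table.loc[gene, "log2fc"],
            "padj_deg": discovery_deg.table.loc[gene, "padj"],
            "log2fc_validation": v["log2fc"],
            "padj_validation": v["padj"],
            "direction_concordant": np.sign(discovery_deg.table.loc[gene, "log2fc"])
            == np.sign(v["log2fc"]),
        }
        if discovery_dsg is not None:
            row["splice_log2_ratio"] = discovery_dsg.table.loc[gene, "log2fc"]
            row["padj_dsg"] = discovery_dsg.table.loc[gene, "padj"]
            row["opposing_deg_dsg"] = np.sign(row["log2fc_deg"]) != np.sign(
                row["splice_log2_ratio"]
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()


@dataclass
class DdctResult:
    delta_ct_case: float
    delta_ct_control: float
    ddct: float
    fold_change: float
    undetected: bool
    note: str = ""


def ddct_fold_change(
    ct_target: dict,
    ct_reference: dict,
    case_samples,
    control_samples,
    rnaseq_log2fc: float | None = None,
) -> DdctResult:
    """Relative qPCR quantification by the 2^-ddCt method.

    Per sample, dCt = mean(target Ct replicates) - mean(reference Ct
    replicates); ddCt = mean dCt over cases - mean dCt over controls; the
    fold change is 2^-ddCt. A sample with no detectable target Ct renders
    the fold change undefined (NaN) and is reported in the note. When an
    RNA-seq log2 fold change is supplied, direction concordance is noted.
    """
    def mean_ct(table, sample):
        values = table.get(sample)
        if values is None:
            return np.nan
        values = np.asarray(list(values), dtype=float)
        values = values[np.isfinite(values)]
        return values.mean() if values.size else np.nan

    def group_dct(samples):
        dcts, missing = [], []
        for s in samples:
            ref = mean_ct(ct_reference, s)
            if np.isnan(ref):
                raise ValueError(f"reference gene Ct missing for sample {s}")
            tgt = mean_ct(ct_target, s)
            if np.isnan(tgt):
                missing.append(s)
            else:
                dcts.append(tgt - ref)
        return dcts, missing

    case_dct, case_missing = group_dct(case_samples)
    control_dct, control_missing = group_dct(control_samples)
    missing = case_missing + control_missing
    if not case_dct or not control_dct:
        return DdctResult(
            np.nan, np.nan, np.nan, np.nan, True,
            f"target undetected in samples: {missing}",
        )
    dct_case = float(np.mean(case_dct))
    dct_control = float(np.mean(control_dct))
    ddct = dct_case - dct_control
    fold = 2.0**-ddct
    note = f"target undetected in samples: {missing}" if missing else ""
    if rnaseq_log2fc is not None:
        concordant = np.sign(-ddct) == np.sign(rnaseq_log2fc) or ddct == 0
        note = (note + "; " if note else "") + (
            "direction concordant with RNA-seq" if concordant else "direction discordant with RNA-seq"
        )
    return DdctResult(dct_case, dct_control, ddct, fold, False, note)
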