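"""Marker-panel tissue-contamination QC and distribution summaries.

The bundled panels are genes expressed essentially exclusively in one of the
two dissected tissues: retinal phototransduction genes for the neural retina
and BEST1/RDH5/RPE65 for the RPE/choroid. A library whose opposite-tissue
panel captures more than 1% of reads is flagged as contaminated by the
microdissection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .thresholds import Thresholds


@dataclass(frozen=True)
class MarkerPanel:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError("marker panel must contain at least one gene")


RETINA_PANEL = MarkerPanel(
    "retina_phototransduction",
    (
        "GNGT1", "GUCA1A", "PDE6A", "GNB1", "CNGB1", "GNAT1", "CNGA1",
        "PDE6B", "PDE6G", "PRPH2", "RHO", "ROM1", "SAG", "SLC24A1",
    ),
)

RPE_CHOROID_PANEL = MarkerPanel("rpe_choroid", ("BEST1", "RDH5", "RPE65"))

DEFAULT_PANELS = {"retina": RETINA_PANEL, "RPE_choroid": RPE_CHOROID_PANEL}


def panel_fraction(matrix: CountMatrix, panel: MarkerPanel) -> pd.Series:
    """Percentage of each sample's reads mapped to the panel's genes."""
    present = [g for g in panel.genes if g in matrix.genes]
    missing = set(panel.genes) - set(present)
    if missing:
        warnings.warn(
            f"panel {panel.name}: {len(missing)} gene(s) absent from matrix, treated as 0",
            stacklevel=2,
        )
    totals = matrix.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"zero library size for samples: {empty}")
    panel_sum = matrix.counts.loc[present].sum(axis=0) if present else pd.Series(0, index=totals.index)
    return 100.0 * panel_sum / totals


def contamination_flags(
    matrix: CountMatrix,
    panels: dict[str, MarkerPanel] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Flag samples whose opposite-tissue marker share exceeds the cutoff.

    An RPE/choroid sample is flagged iff its retina-panel fraction is
    strictly greater than ``contamination_pct`` (default 1.0%); retina
    samples are checked against the RPE/choroid panel symmetrically. The rule
    is strict: a fraction exactly at the cutoff is not flagged.
    """
    panels = panels or DEFAULT_PANELS
    fractions = {tissue: panel_fraction(matrix, panel) for tissue, panel in panels.items()}
    rows = []
    for sample in matrix.sample_ids:
        tissue = matrix.samples.loc[sample, "tissue"]
        flagged, reason = False, ""
        for panel_tissue, frac in fractions.items():
            if panel_tissue == tissue:
                continue
            if frac[sample] > thresholds.contamination_pct:
                flagged = True
                reason = (
                    f"{panels[panel_tissue].name} panel at {frac[sample]:.3g}% "
                    f"> {thresholds.contamination_pct}%"
                )
        row = {"sample": sample, "tissue": tissue, "flagged": flagged, "reason": reason}
        for panel_tissue, frac in fractions.items():
            row[f"{panels[panel_tissue].name}_pct"] = frac[sample]
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def log10_fpkm_long(fpkm_matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Long-format (gene, sample, tissue, group, log10_fpkm) records.

    Zero-FPKM entries are dropped (no pseudocount is added) so the
    distributions summarise expressed genes only.
    """
    long = fpkm_matrix.stack().rename("fpkm").reset_index()
    long.columns = ["gene", "sample", "fpkm"]
    long = long[long["fpkm"] > 0].copy()
    long["log10_fpkm"] = np.log10(long["fpkm"])
    long["tissue"] = long["sample"].map(samples["tissue"])
    long["group"] = long["sample"].map(samples["group"])
    return long[["gene", "sample", "tissue", "group", "log10_fpkm"]].reset_index(drop=True)


def count_filter(matrix: CountMatrix, min_count: int | None = None,
                 thresholds: Thresholds = Thresholds()) -> CountMatrix:
    """Keep genes whose total count is at least ``min_count`` (default 20)."""
    cutoff = thresholds.cluster_min_count if min_count is None else min_count
    keep = matrix.counts.sum(axis=1) >= cutoff
    return CountMatrix(matrix.counts[keep], matrix.samples)
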