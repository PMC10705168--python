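import numpy as np
import pandas as pd
import pytest

from maculaseq.containers import CountMatrix, ExonCountMatrix


@pytest.fixture
def small_count_matrix():
    counts = pd.DataFrame(
        {
            "s1": [10, 100, 0, 40],
            "s2": [12, 90, 5, 38],
            "s3": [20, 210, 1, 85],
            "s4": [18, 190, 0, 80],
        },
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene"),
    )
    samples = pd.DataFrame(
        {
            "group": ["normal", "normal", "iAMD", "iAMD"],
            "tissue": ["RPE_choroid"] * 4,
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    return CountMatrix(counts, samples)


def make_exon_matrix(per_sample_exon_counts: dict, groups: dict, gene="gX") -> ExonCountMatrix:
    """Build a one-gene ExonCountMatrix from {sample: [exon counts]}."""
    n_exons = len(next(iter(per_sample_exon_counts.values())))
    index = pd.MultiIndex.from_product([[gene], range(n_exons)], names=["gene", "exon_index"])
    counts = pd.DataFrame(per_sample_exon_counts, index=index)
    exons = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [1000 * (e + 1) for e in range(n_exons)],
            "end": [1000 * (e + 1) + 500 for e in range(n_exons)],
        },
        index=index,
    )
    samples = pd.DataFrame(
        {"group": [groups[s] for s in counts.columns], "tissue": "RPE_choroid"},
        index=pd.Index(list(counts.columns), name="sample"),
    )
    return ExonCountMatrix(counts, exons, samples)
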