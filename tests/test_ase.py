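import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from maculaseq.ase import (
    ase_pipeline,
    binomial_ase_test,
    confirm_monoallelic,
    depth_filter,
    select_heterozygotes,
    summarize_ase,
)
from maculaseq.expression import bh_adjust
from maculaseq.io import ProxyMap
from maculaseq.thresholds import Thresholds


def enumeration_oracle(k, n):
    """Sum P(j) over all outcomes j with P(j) <= P(k) under Binomial(n, 0.5)."""
    pmf = binom.pmf(np.arange(n + 1), n, 0.5)
    return min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-12)].sum())


def make_records(rows):
    return pd.DataFrame(
        rows,
        columns=["sample", "tissue", "group", "snp_id", "chrom", "pos", "ref", "alt",
                 "ref_reads", "alt_reads"],
    )


def het(sample, snp, ref="C", alt="T", source="chip"):
    return {"sample": sample, "snp_id": snp, "allele1": ref, "allele2": alt, "source": source}


class TestBinomialTest:
    def test_balanced_split_is_one(self):
        assert binomial_ase_test(5, 5) == 1.0

    def test_monoallelic_ten_reads(self):
        assert binomial_ase_test(10, 0) == pytest.approx(2 / 1024, rel=1e-12)

    def test_fifteen_three(self):
        assert binomial_ase_test(15, 3) == pytest.approx(enumeration_oracle(3, 18), rel=1e-12)

    def test_matches_enumeration_broadly(self):
        for n in (1, 2, 7, 12, 25, 41):
            for k in range(n + 1):
                assert binomial_ase_test(n - k, k) == pytest.approx(
                    enumeration_oracle(k, n), abs=1e-13
                )

    def test_symmetry_and_monotonicity(self):
        n = 37
        ps = [binomial_ase_test(n - k, k) for k in range(n + 1)]
        for k in range(n + 1):
            assert ps[k] == pytest.approx(ps[n - k], abs=0)
        half = ps[: n // 2 + 1]
        assert all(half[i] <= half[i + 1] + 1e-15 for i in range(len(half) - 1))

    def test_doubling_variant(self):
        assert binomial_ase_test(10, 0, method="doubling") == pytest.approx(2 / 1024)
        assert binomial_ase_test(5, 5, method="doubling") <= 2.0 * 0.5 + 1e-12

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            binomial_ase_test(0, 0)


class TestHeterozygoteSelection:
    def test_kept_excluded_and_mismatch(self):
        genotypes = pd.DataFrame(
            [het("s1", "rs1"), {"sample": "s2", "snp_id": "rs1", "allele1": "C",
                                "allele2": "C", "source": "chip"},
             {"sample": "s3", "snp_id": "rs1", "allele1": "A", "allele2": "G",
              "source": "chip"}]
        )
        records = make_records(
            [
                ("s1", "RPE_choroid", "normal", "rs1", "chr1", 100, "C", "T", 6, 6),
                ("s2", "RPE_choroid", "normal", "rs1", "chr1", 100, "C", "T", 9, 3),
                ("s3", "RPE_choroid", "normal", "rs1", "chr1", 100, "C", "T", 5, 5),
                ("s4", "RPE_choroid", "normal", "rs1", "chr1", 100, "C", "T", 5, 5),
            ]
        )
        kept, excluded = select_heterozygotes(genotypes, records)
        assert list(kept["sample"]) == ["s1"]
        reasons = dict(zip(excluded["sample"], excluded["reason"]))
        assert reasons == {"s2": "homozygous", "s3": "allele_mismatch", "s4": "no_genotype"}


class TestDepthFilter:
    def test_boundary_inclusive(self):
        records = make_records(
            [
                ("s1", "retina", "normal", "rs1", "chr1", 1, "C", "T", 6, 4),
                ("s2", "retina", "normal", "rs1", "chr1", 1, "C", "T", 9, 0),
            ]
        )
        kept, excluded = depth_filter(records)
        assert list(kept["sample"]) == ["s1"]
        assert list(excluded["sample"]) == ["s2"]

    def test_exclusion_tally_matches_recount(self):
        rng = np.random.default_rng(4)
        rows = [
            ("s%d" % i, "retina", "normal", "rs1", "chr1", 1, "C", "T",
             int(rng.integers(0, 15)), int(rng.integers(0, 15)))
            for i in range(50)
        ]
        records = make_records(rows)
        kept, excluded = depth_filter(records)
        total = records["ref_reads"] + records["alt_reads"]
        assert len(excluded) == int((total < 10).sum())
        assert len(kept) + len(excluded) == 50


class TestProxyConfirmation:
    def record(self, ref_reads, alt_reads):
        return pd.Series(
            {"sample": "s1", "snp_id": "rsT", "ref": "C", "alt": "T",
             "ref_reads": ref_reads, "alt_reads": alt_reads}
        )

    def test_not_required_when_both_alleles_seen(self):
        pm = ProxyMap()
        assert confirm_monoallelic(self.record(8, 4), pd.DataFrame(), pm) == "not_required"

    def test_confirmed_by_high_r2_het_proxy(self):
        pm = ProxyMap()
        pm.add("rsT", "rsP", 1.0)
        genotypes = pd.DataFrame([het("s1", "rsP", source="proxy")])
        assert confirm_monoallelic(self.record(12, 0), genotypes, pm) == "confirmed"

    def test_low_r2_proxy_insufficient(self):
        pm = ProxyMap()
        pm.add("rsT", "rsP", 0.7)
        genotypes = pd.DataFrame([het("s1", "rsP", source="proxy")])
        assert confirm_monoallelic(self.record(12, 0), genotypes, pm) == "unconfirmed"

    def test_proxy_absent_from_genotypes_is_no_evidence(self):
        pm = ProxyMap()
        pm.add("rsT", "rsP", 0.95)
        assert confirm_monoallelic(self.record(12, 0), pd.DataFrame(columns=["sample", "snp_id", "allele1", "allele2", "source"]), pm) == "unconfirmed"


class TestPipeline:
    def test_bh_flags_match_hand_step_up(self):
        # six heterozygotes with distinct allele splits at depth 20
        splits = [(20, 0), (18, 2), (15, 5), (13, 7), (11, 9), (10, 10)]
        rows = [
            (f"s{i}", "RPE_choroid", "normal", "rs1", "chr1", 1, "C", "T", r, a)
            for i, (r, a) in enumerate(splits)
        ]
        genotypes = pd.DataFrame([het(f"s{i}", "rs1") for i in range(6)])
        pm = ProxyMap()
        pm.add("rs1", "rsP", 1.0)
        genotypes = pd.concat(
            [genotypes, pd.DataFrame([het("s0", "rsP", source="proxy")])], ignore_index=True
        )
        res = ase_pipeline(genotypes, make_records(rows), pm)
        raw = np.array([binomial_ase_test(r, a) for r, a in splits])
        expected_padj = bh_adjust(raw)
        got = res.table.set_index("sample")
        for i in range(6):
            assert got.loc[f"s{i}", "padj"] == pytest.approx(
                expected_padj[i], rel=1e-12
            )

    def test_record_order_invariance(self):
        rng = np.random.default_rng(9)
        rows = [
            (f"s{i}", "RPE_choroid", "normal", "rs1", "chr1", 1, "C", "T",
             int(rng.integers(5, 40)), int(rng.integers(5, 40)))
            for i in range(12)
        ]
        genotypes = pd.DataFrame([het(f"s{i}", "rs1") for i in range(12)])
        a = ase_pipeline(genotypes, make_records(rows))
        b = ase_pipeline(genotypes, make_records(rows[::-1]))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_unconfirmed_monoallelic_removed_before_bh(self):
        rows = [
            ("s0", "RPE_choroid", "normal", "rs1", "chr1", 1, "C", "T", 30, 0),
            ("s1", "RPE_choroid", "normal", "rs1", "chr1", 1, "C", "T", 20, 10),
        ]
        genotypes = pd.DataFrame([het("s0", "rs1"), het("s1", "rs1")])
        res = ase_pipeline(genotypes, make_records(rows), ProxyMap())
        assert list(res.table["sample"]) == ["s1"]
        assert "monoallelic_unconfirmed_by_proxy" in set(res.exclusions["reason"])


class TestSummary:
    def test_k_over_n_cells_and_empty_cells(self):
        table = pd.DataFrame(
            {
                "snp_id": ["rs1"] * 6 + ["rs2"],
                "tissue": ["RPE_choroid"] * 6 + ["retina"],
                "group": ["normal"] * 6 + ["iAMD"],
                "significant": [True, True, False, False, False, False, False],
            }
        )
        wide = summarize_ase(table)
        assert wide.loc["rs1", ("RPE_choroid", "normal")] == "2/6"
        assert wide.loc["rs2", ("RPE_choroid", "normal")] == "0/0"
        assert wide.loc["rs2", ("retina", "iAMD")] == "0/1"

    def test_k_never_exceeds_n(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame(
            {
                "snp_id": rng.choice(["rs1", "rs2", "rs3"], size=60),
                "tissue": rng.choice(["RPE_choroid", "retina"], size=60),
                "group": rng.choice(["normal", "iAMD", "NEO"], size=60),
                "significant": rng.random(60) < 0.3,
            }
        )
        wide = summarize_ase(table)
        for cell in wide.to_numpy().ravel():
            k, n = map(int, cell.split("/"))
            assert k <= n
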